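"""3' readthrough quantification, revised gene annotation and metagene profiles.

Coordinates follow the package-wide 0-based half-open convention; the 3'
boundary (TTS) of a minus-strand gene is its interval start, and "downstream"
offsets are signed strand-aware (positive = past the TTS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoverageTrack, GeneModel, InputError, TranscribedSegment


class InsufficientDataError(ValueError):
    pass


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class ExtensionRecord:
    gene_id: str
    state: str
    extension: int
    segment_start: int
    segment_end: int

    def __post_init__(self) -> None:
        if self.extension < 0:
            raise InputError("extension must be >= 0")


@dataclass(frozen=True)
class RevisedGeneBody:
    name: str  # member gene ids joined by ":"
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def members(self) -> list[str]:
        return self.name.split(":")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def de_eligible(self) -> bool:
        return len(self.members) == 1


@dataclass
class MetageneProfile:
    anchor: str
    window: tuple[int, int]
    bin_width: int
    values: np.ndarray  # per-bin mean scaled coverage, in [0,1]
    n_genes: int


def _overlapping_segment(
    gene: GeneModel, segments: list[TranscribedSegment]
) -> TranscribedSegment | None:
    """The segment containing the gene's last transcribed base, if any."""
    base = gene.three_prime_base
    for s in segments:
        if s.chrom == gene.chrom and s.strand == gene.strand and s.start <= base < s.end:
            return s
    return None


def compute_tts_extension(
    gene: GeneModel, segments: list[TranscribedSegment], state: str
) -> ExtensionRecord | None:
    """Readthrough length for one gene in one state, or None when no segment
    overlaps the annotated 3' end."""
    seg = _overlapping_segment(gene, segments)
    if seg is None:
        return None
    if gene.strand == "+":
        ext = max(0, seg.end - gene.end)
    else:
        ext = max(0, gene.start - seg.start)
    return ExtensionRecord(
        gene_id=gene.gene_id,
        state=state,
        extension=ext,
        segment_start=seg.start,
        segment_end=seg.end,
    )


def extension_table(
    genes: list[GeneModel], segments_by_state: dict[str, list[TranscribedSegment]]
) -> pd.DataFrame:
    """Long-form extension records over all genes and states (eligible only)."""
    rows = []
    for state, segs in segments_by_state.items():
        for g in genes:
            rec = compute_tts_extension(g, segs, state)
            if rec is not None:
                rows.append(
                    {"gene_id": rec.gene_id, "state": state, "extension": rec.extension}
                )
    return pd.DataFrame(rows, columns=["gene_id", "state", "extension"])


def tts_offset_distribution(
    genes: list[GeneModel],
    segments_by_state: dict[str, list[TranscribedSegment]],
    window: int = 20_000,
    bin_width: int = 500,
) -> tuple[dict[str, np.ndarray], np.ndarray, list[str]]:
    """Histograms of signed segment-3'-boundary offsets from the TTS, per state.

    Only genes whose 3' end is overlapped by a segment in EVERY state are
    used.  Returns (per-state histogram, bin edges, gene ids used).
    """
    if len(segments_by_state) < 2:
        raise InputError("need at least two states")
    per_state_offsets: dict[str, dict[str, int]] = {}
    for state, segs in segments_by_state.items():
        offs = {}
        for g in genes:
            seg = _overlapping_segment(g, segs)
            if seg is None:
                continue
            offs[g.gene_id] = (seg.end - gene_tts(g)) if g.strand == "+" else (gene_tts(g) - seg.start)
        per_state_offsets[state] = offs
    common = set.intersection(*(set(v) for v in per_state_offsets.values())) if per_state_offsets else set()
    edges = np.arange(-window, window + bin_width, bin_width)
    hists = {}
    for state, offs in per_state_offsets.items():
        vals = [offs[g] for g in common]
        hists[state] = np.histogram(vals, bins=edges)[0]
    if not common:
        import warnings

        warnings.warn("no genes have a 3'-overlapping segment in every state")
    return hists, edges, sorted(common)


def gene_tts(gene: GeneModel) -> int:
    return gene.tts


def mean_extension_difference(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean extension difference (B - A) over common genes, with bootstrap SE.

    The gene sets are intersected first; the SE is a nonparametric bootstrap
    over genes of the paired per-gene differences.
    """
    a = records_a.set_index("gene_id")["extension"]
    b = records_b.set_index("gene_id")["extension"]
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise InsufficientDataError(f"only {len(common)} common genes")
    diffs = (b.loc[common] - a.loc[common]).to_numpy(dtype=float)
    delta = float(diffs.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diffs), size=(n_boot, len(diffs)))
    boot = diffs[idx].mean(axis=1)
    return delta, float(boot.std(ddof=1))


def elongation_rate(delta_nt: float, delta_days: float) -> dict[str, float]:
    """Elongation rate in kb/min from a 3' advance over a time interval.

    Returns both the raw rate and the value rounded to one significant
    figure (the convention used when quoting slow torpor-bout elongation).
    """
    if delta_days <= 0:
        raise InputError("delta_days must be > 0")
    rate = (delta_nt / 1000.0) / (delta_days * 1440.0)
    return {"rate_kb_per_min": rate, "rounded_1sf": round_to_sig_figs(rate, 1)}


def round_to_sig_figs(x: float, n: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


def delta_days_below_threshold(
    design: pd.DataFrame, state_a: str, state_b: str, column: str = "days_below_8"
) -> float:
    """Difference of state means of days with Tb below threshold (B - A)."""
    if column not in design.columns:
        raise InputError(f"design lacks column {column!r}")
    sub = design[design["state"].isin([state_a, state_b])]
    if sub[column].isna().any():
        raise InputError(f"missing {column!r} metadata")
    means = sub.groupby("state")[column].mean()
    return float(means[state_b] - means[state_a])


def revise_annotation(
    genes: list[GeneModel],
    maximal_segments: list[TranscribedSegment],
    tss_trim: int = 500,
    min_length: int = 50,
) -> tuple[list[RevisedGeneBody], list[str]]:
    """Substitute extended 3' boundaries, merge overlapping genes, trim the TSS.

    Order: substitute -> merge (names joined by ":") -> trim ``tss_trim`` nt
    from each merged body's 5' end.  Bodies <= ``min_length`` nt after
    trimming are dropped and returned in the drop log.  Strands are handled
    independently.
    """
    extended = []
    for g in genes:
        seg = _overlapping_segment(g, maximal_segments)
        start, end = g.start, g.end
        if seg is not None:
            if g.strand == "+" and seg.end > end:
                end = seg.end
            elif g.strand == "-" and seg.start < start:
                start = seg.start
        extended.append((g.chrom, start, end, g.strand, g.gene_id))

    merged: list[RevisedGeneBody] = []
    dropped: list[str] = []
    by_key: dict[tuple[str, str], list] = {}
    for chrom, start, end, strand, gid in extended:
        by_key.setdefault((chrom, strand), []).append((start, end, gid))
    for (chrom, strand), items in sorted(by_key.items()):
        items.sort()
        cur = [items[0][0], items[0][1], [items[0][2]]]
        groups = []
        for start, end, gid in items[1:]:
            if start < cur[1]:
                cur[1] = max(cur[1], end)
                cur[2].append(gid)
            else:
                groups.append(cur)
                cur = [start, end, [gid]]
        groups.append(cur)
        for start, end, members in groups:
            if strand == "+":
                start += tss_trim
            else:
                end -= tss_trim
            name = ":".join(members)
            if end - start <= min_length:
                dropped.append(name)
                continue
            merged.append(RevisedGeneBody(name=name, chrom=chrom, start=start, end=end, strand=strand))
    merged.sort(key=lambda b: (b.chrom, b.strand, b.start))
    return merged, dropped


def quantify_gene_bodies(
    bodies: list[RevisedGeneBody], tracks: dict[str, CoverageTrack]
) -> pd.DataFrame:
    """Coverage-sum quantification per body per sample.

    Returns a body x sample matrix indexed by body name, with a
    ``de_eligible`` attrs entry flagging single-member bodies.
    """
    data = {}
    for sample, track in tracks.items():
        col = []
        for b in bodies:
            arr = track.get(b.chrom, b.strand)
            col.append(float(arr[b.start : b.end].sum()))
        data[sample] = col
    out = pd.DataFrame(data, index=[b.name for b in bodies])
    out.attrs["de_eligible"] = {b.name: b.de_eligible for b in bodies}
    return out


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Standard TPM: per-kb rate normalized so each column sums to 1e6."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise InputError("body lengths must be > 0")
    rate = counts.div(lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        import warnings

        warnings.warn(f"all-zero TPM column(s): {list(colsum.index[zero_cols])}")
        colsum = colsum.replace(0, np.nan)
    tpm = rate.div(colsum, axis=1) * 1e6
    return tpm.fillna(0.0)


def _gene_window(gene: GeneModel, anchor: str, window: tuple[int, int]) -> tuple[int, int]:
    """Genomic interval of the anchored window (strand-aware)."""
    if gene.strand == "+":
        anchor_pos = gene.start if anchor == "TSS" else gene.end
        return anchor_pos + window[0], anchor_pos + window[1]
    anchor_pos = gene.end if anchor == "TSS" else gene.start
    return anchor_pos - window[1], anchor_pos - window[0]


def metagene_profile(
    tracks: dict[str, CoverageTrack],
    design: pd.DataFrame,
    genes: list[GeneModel],
    anchor: str = "TTS",
    window: tuple[int, int] = (-1000, 5000),
    bin_width: int = 50,
    tpm: pd.DataFrame | None = None,
    sequences: dict[str, str] | None = None,
    min_tpm: float = 25.0,
    tpm_states: tuple[str, ...] = ("SA", "IBA"),
    min_bin_frac: float = 0.33,
    min_samples: int = 3,
    max_n_run: int = 20,
) -> dict[str, MetageneProfile]:
    """Per-state metagene profiles of scaled, library-size-normalized coverage.

    Gene filters: windows non-overlapping with any other same-strand gene
    window; no N-run > ``max_n_run`` in the window (when sequences given);
    state-mean TPM >= ``min_tpm`` in one of ``tpm_states`` (when tpm given);
    >= ``min_bin_frac`` of bins nonzero in >= ``min_samples`` samples.
    Minus-strand windows are orientation-flipped before averaging.
    """
    if anchor not in ("TSS", "TTS"):
        raise InputError("anchor must be 'TSS' or 'TTS'")
    span = window[1] - window[0]
    if span % bin_width:
        raise InputError("window span must be a multiple of bin width")
    n_bins = span // bin_width
    counts = {"total": len(genes), "overlap": 0, "n_run": 0, "tpm": 0, "bins": 0}

    windows = {g.gene_id: _gene_window(g, anchor, window) for g in genes}
    sample_states = design.set_index("sample")["state"]
    totals = {s: t.total() for s, t in tracks.items()}

    def binned(arr_slice: np.ndarray) -> np.ndarray:
        return arr_slice.reshape(n_bins, bin_width).mean(axis=1)

    used_genes = []
    per_gene_binned: dict[str, dict[str, np.ndarray]] = {}
    for g in genes:
        lo, hi = windows[g.gene_id]
        chrom_len = next(iter(tracks.values())).chrom_lengths[g.chrom]
        if lo < 0 or hi > chrom_len:
            counts["overlap"] += 1
            continue
        overlap = any(
            o.gene_id != g.gene_id
            and o.chrom == g.chrom
            and o.strand == g.strand
            and windows[o.gene_id][0] < hi
            and lo < windows[o.gene_id][1]
            for o in genes
        )
        if overlap:
            counts["overlap"] += 1
            continue
        if sequences is not None:
            win_seq = sequences[g.chrom][lo:hi]
            if "N" * (max_n_run + 1) in win_seq:
                counts["n_run"] += 1
                continue
        if tpm is not None and g.gene_id in tpm.index:
            state_means = tpm.loc[g.gene_id].groupby(sample_states).mean()
            if not any(state_means.get(s, 0.0) >= min_tpm for s in tpm_states):
                counts["tpm"] += 1
                continue
        per_sample = {}
        n_ok = 0
        for sample, track in tracks.items():
            sl = track.get(g.chrom, g.strand)[lo:hi]
            if g.strand == "-":
                sl = sl[::-1]
            bv = binned(sl)
            if (bv > 0).mean() >= min_bin_frac:
                n_ok += 1
            per_sample[sample] = bv
        if n_ok < min_samples:
            counts["bins"] += 1
            continue
        per_gene_binned[g.gene_id] = per_sample
        used_genes.append(g.gene_id)

    if not used_genes:
        raise FilterError(f"no genes pass metagene filters: {counts}")

    profiles = {}
    for state in design["state"].unique():
        state_samples = design.loc[design["state"] == state, "sample"]
        gene_vectors = []
        for gid in used_genes:
            acc = np.zeros(n_bins)
            for sample in state_samples:
                norm = totals[sample] or 1.0
                acc += per_gene_binned[gid][sample] / norm
            m = acc.max()
            if m > 0:
                gene_vectors.append(acc / m)
        vec = np.mean(gene_vectors, axis=0) if gene_vectors else np.zeros(n_bins)
        profiles[state] = MetageneProfile(
            anchor=anchor,
            window=window,
            bin_width=bin_width,
            values=np.clip(vec, 0.0, 1.0),
            n_genes=len(used_genes),
        )
    return profiles
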