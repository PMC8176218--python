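"""Synthetic-data generation with a written truth table.

Every downstream stage of the pipeline is exercised on data produced here:
genomes with gene models, strand-specific nascent coverage with 3'
readthrough tails, negative-binomial count matrices following pattern
templates, allele-count tables with genomic polymorphisms visible in both
assays, and junction-count tables with cold-shifted PSI.

With ``deterministic=True`` all coverage is emitted at its expected value,
so downstream estimators must recover the truth exactly — that property is
used as an oracle throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    CoverageTrack,
    GeneModel,
    PatternLibrary,
    make_design,
    nascent_pattern_library,
    rna_pattern_library,
)

AU_MOTIF_RNA = "UAUUUAU"  # canonical ARE core; DNA sense equivalent below
AU_MOTIF_DNA = "TATTTAT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class EditingSim:
    """Knobs for the A-to-G editing / polymorphism simulation."""

    n_sites: int = 60
    n_polymorphic: int = 10
    depth: int = 50
    rates: dict[str, float] | None = None  # per-state editing rate; default set by SimConfig


@dataclass
class SplicingSim:
    n_lsv: int = 30
    junctions_per_lsv: int = 2
    cold_dpsi_effect: float = 0.3
    depth: int = 200
    ir_fraction: float = 0.2
    base_alt_psi: float = 0.2


@dataclass
class SimConfig:
    """All simulation knobs; see field names for meaning.

    ``pattern_mix`` maps template names (or ``"flat"``) to fractions summing
    to 1.  ``extension_truth`` maps each state to (mean, spread) of the true
    3' readthrough in nt; a gene's extension is drawn uniformly in
    mean +/- spread.  ``gc_by_pattern`` / ``au_motifs_by_pattern`` key gene
    classes by pattern-name prefix, with a required ``"default"`` entry.
    """

    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (2000, 4000)
    intergenic_gap_range: tuple[int, int] = (4000, 8000)
    strand_balance: float = 0.5
    states: tuple[str, ...] = ("SA", "IBA", "Ent", "ET", "LT")
    replicates_per_state: int = 3
    seed: int = 0
    extension_truth: dict[str, tuple[float, float]] = field(default_factory=dict)
    nb_dispersion: float = 0.05
    pattern_mix: dict[str, float] = field(default_factory=lambda: {"flat": 1.0})
    pattern_library: PatternLibrary | None = None
    editing: EditingSim = field(default_factory=EditingSim)
    splicing: SplicingSim = field(default_factory=SplicingSim)
    gc_by_pattern: dict[str, float] = field(default_factory=lambda: {"default": 0.45})
    au_motifs_by_pattern: dict[str, int] = field(default_factory=lambda: {"default": 1})
    cold_states: tuple[str, ...] | None = None
    entry_states: tuple[str, ...] = ("Ent",)
    tandem_pairs: int = 0
    tandem_gap: int = 500
    n_gap_runs: tuple[tuple[str, int, int], ...] = ()
    expression_level: float = 500.0
    sex_effect: float = 1.0
    plateau: float = 10.0
    peak5: float = 5.0
    peak3: float = 3.0
    peak_width: int = 100
    utr3_len: int = 400
    background_rate: float = 0.0
    deterministic: bool = False

    def __post_init__(self) -> None:
        if not self.extension_truth:
            self.extension_truth = {s: (0.0, 0.0) for s in self.states}
        if self.pattern_library is None and self.needs_library():
            self.pattern_library = default_library_for(self.states)
        if self.editing.rates is None:
            cold = set(self.cold_set())
            self.editing.rates = {s: (0.3 if s in cold else 0.05) for s in self.states}
        self.validate()

    def needs_library(self) -> bool:
        return any(name != "flat" for name in self.pattern_mix)

    def cold_set(self) -> tuple[str, ...]:
        if self.cold_states is not None:
            return self.cold_states
        return tuple(s for s in self.states if s in ("ET", "LT", "Ar"))

    def validate(self) -> None:
        if min(self.n_chromosomes, self.chrom_length, self.replicates_per_state) <= 0:
            raise ConfigError("counts must be > 0")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if len(set(self.states)) != len(self.states):
            raise ConfigError("states must be unique")
        if not 0 <= self.strand_balance <= 1:
            raise ConfigError("strand_balance must be in [0,1]")
        mix_total = sum(self.pattern_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ConfigError(f"pattern_mix must sum to 1 (got {mix_total})")
        if any(f < 0 or f > 1 for f in self.pattern_mix.values()):
            raise ConfigError("pattern_mix fractions must be in [0,1]")
        for state, (mean, spread) in self.extension_truth.items():
            if mean < 0 or spread < 0:
                raise ConfigError(f"extension_truth for {state} must be non-negative")
        if self.needs_library():
            lib = self.pattern_library
            for name in self.pattern_mix:
                if name != "flat" and (lib is None or name not in lib.templates):
                    raise ConfigError(f"unknown pattern name {name!r}")
        if "default" not in self.gc_by_pattern or "default" not in self.au_motifs_by_pattern:
            raise ConfigError("gc_by_pattern and au_motifs_by_pattern need a 'default' entry")


def default_library_for(states: tuple[str, ...]) -> PatternLibrary:
    if set(states) == {"SA", "IBA", "Ent", "Ar", "SpD"}:
        return rna_pattern_library()
    if set(states) == {"SA", "IBA", "Ent", "ET", "LT"}:
        return nascent_pattern_library()
    raise ConfigError(f"no default pattern library for states {states}; supply one")


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset (genes, editing sites, LSVs)."""

    genes: pd.DataFrame
    sites: pd.DataFrame
    lsvs: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        self.lsvs.to_csv(outdir / "truth_lsvs.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "TruthTable":
        outdir = Path(outdir)
        return cls(
            genes=pd.read_csv(outdir / "truth_genes.tsv", sep="\t"),
            sites=pd.read_csv(outdir / "truth_sites.tsv", sep="\t"),
            lsvs=pd.read_csv(outdir / "truth_lsvs.tsv", sep="\t"),
        )


def _class_lookup(table: dict, pattern: str):
    """Longest prefix match of pattern name against class keys; 'default' fallback."""
    best, best_len = table["default"], -1
    for key, val in table.items():
        if key != "default" and pattern.startswith(key) and len(key) > best_len:
            best, best_len = val, len(key)
    return best


def _exact_gc_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Sequence with exactly round(gc*length) G/C bases, as a char array."""
    n_gc = int(round(gc * length))
    bases = np.empty(length, dtype="U1")
    gc_choices = rng.choice(np.array(["G", "C"]), size=n_gc)
    at_choices = rng.choice(np.array(["A", "T"]), size=length - n_gc)
    pos = rng.permutation(length)
    bases[pos[:n_gc]] = gc_choices
    bases[pos[n_gc:]] = at_choices
    return bases


def build_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel], TruthTable]:
    """Lay out genes on random chromosomes and write the full truth table.

    Genes are placed left to right with intergenic gaps drawn from config;
    the first ``tandem_pairs`` pairs are forced onto the same strand with a
    short ``tandem_gap`` (for readthrough-into-neighbor scenarios).
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {c: _exact_gc_sequence(config.chrom_length, 0.42, rng) for c in chrom_names}

    # ---- place genes -------------------------------------------------------
    lib = config.pattern_library
    pattern_names = list(config.pattern_mix)
    pattern_probs = np.array([config.pattern_mix[p] for p in pattern_names])
    cursors = {c: 0 for c in chrom_names}
    genes: list[GeneModel] = []
    rows = []
    tandem_remaining = config.tandem_pairs * 2
    prev_strand = "+"

    chrom_idx = 0
    for i in range(config.n_genes):
        in_tandem_second = tandem_remaining > 0 and i % 2 == 1
        chrom = chrom_names[chrom_idx % config.n_chromosomes]
        length = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        if in_tandem_second:
            gap = config.tandem_gap
            strand = prev_strand
            tandem_remaining -= 2
        else:
            gap = int(
                rng.integers(config.intergenic_gap_range[0], config.intergenic_gap_range[1] + 1)
            )
            strand = "+" if rng.random() < config.strand_balance else "-"
        start = cursors[chrom] + gap
        end = start + length
        if end > config.chrom_length:
            raise ConfigError(
                f"genes cannot fit: gene {i} needs [{start},{end}) on {chrom} "
                f"of length {config.chrom_length}"
            )
        cursors[chrom] = end
        if not (tandem_remaining > 0 and i % 2 == 0):
            chrom_idx += 1  # keep tandem partners on one chromosome
        prev_strand = strand

        pattern = str(rng.choice(pattern_names, p=pattern_probs))
        gc = _class_lookup(config.gc_by_pattern, pattern)
        n_motifs = _class_lookup(config.au_motifs_by_pattern, pattern)

        # sense-coordinate sequence with exact GC, motifs in the 3' UTR
        sense = _exact_gc_sequence(length, gc, rng)
        utr3_len = min(config.utr3_len, length // 4)
        motif = np.array(list(AU_MOTIF_DNA))
        placed = 0
        if n_motifs > 0 and utr3_len >= len(AU_MOTIF_DNA):
            slots = max(1, utr3_len // max(n_motifs, 1))
            for m in range(n_motifs):
                off = length - utr3_len + m * slots
                if off + len(motif) <= length:
                    sense[off : off + len(motif)] = motif
                    placed += 1
        if strand == "+":
            seqs[chrom][start:end] = sense
        else:
            seqs[chrom][start:end] = np.array(list(reverse_complement("".join(sense))))

        # two-exon structure in sense coords: exon1 [0,e1), intron, exon2 [i2,L)
        e1 = int(length * 0.4)
        i2 = int(length * 0.6)
        cds_sense = (min(100, e1 - 1), length - utr3_len)
        if strand == "+":
            exons = ((start, start + e1), (start + i2, end))
            cds = (start + cds_sense[0], start + cds_sense[1])
        else:
            exons = ((start, start + length - i2), (start + length - e1, end))
            cds = (start + length - cds_sense[1], start + length - cds_sense[0])
        gc_real = float(np.isin(sense, ["G", "C"]).mean())
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=exons,
                cds=cds,
                gc=gc_real,
            )
        )

        row = {
            "gene_id": f"g{i + 1:04d}",
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": strand,
            "pattern": pattern,
            "gc": gc_real,
            "au_motifs": placed,
        }
        for state in config.states:
            if pattern == "flat":
                mu = config.expression_level
            else:
                tmpl = lib.templates[pattern][lib.states.index(state)]
                mu = config.expression_level * (0.1 + 0.9 * tmpl)
            row[f"mu_{state}"] = mu
        clipped = False
        for state in config.states:
            mean, spread = config.extension_truth.get(state, (0.0, 0.0))
            ext = max(0.0, rng.uniform(mean - spread, mean + spread)) if spread else mean
            ext = int(round(ext))
            if strand == "+" and end + ext > config.chrom_length:
                ext, clipped = config.chrom_length - end, True
            elif strand == "-" and start - ext < 0:
                ext, clipped = start, True
            row[f"ext_{state}"] = ext
        row["ext_clipped"] = clipped
        rows.append(row)

    gene_truth = pd.DataFrame(
        rows,
        columns=(
            ["gene_id", "chrom", "start", "end", "strand", "pattern", "gc", "au_motifs"]
            + [f"mu_{s}" for s in config.states]
            + [f"ext_{s}" for s in config.states]
            + ["ext_clipped"]
        )
        if rows
        else None,
    )
    if gene_truth.empty:
        gene_truth = pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "pattern", "gc", "au_motifs"]
        )

    # ---- N-gap runs --------------------------------------------------------
    for chrom, pos, run_len in config.n_gap_runs:
        seqs[chrom][pos : pos + run_len] = "N"

    # ---- editing-site truth ------------------------------------------------
    site_rows = []
    if genes:
        for j in range(config.editing.n_sites):
            g = genes[int(rng.integers(len(genes)))]
            offset = int(rng.integers(200, g.length - 200))
            pos = g.start + offset
            ref, alt = ("A", "G") if g.strand == "+" else ("T", "C")
            seqs[g.chrom][pos] = ref  # genome carries the reference base
            polymorphic = j < config.editing.n_polymorphic
            row = {
                "site_id": f"s{j + 1:04d}",
                "chrom": g.chrom,
                "pos0": pos,
                "gene_id": g.gene_id,
                "strand": g.strand,
                "ref": ref,
                "alt": alt,
                "polymorphic": polymorphic,
            }
            for state in config.states:
                row[f"rate_{state}"] = 0.0 if polymorphic else config.editing.rates[state]
            site_rows.append(row)
    site_truth = pd.DataFrame(site_rows) if site_rows else pd.DataFrame(
        columns=["site_id", "chrom", "pos0", "gene_id", "strand", "ref", "alt", "polymorphic"]
    )

    # ---- LSV truth ---------------------------------------------------------
    lsv_rows = []
    cold = set(config.cold_set())
    entry = set(config.entry_states)
    sp = config.splicing
    n_ir = int(round(sp.n_lsv * sp.ir_fraction))
    if genes:
        for k in range(sp.n_lsv):
            g = genes[k % len(genes)]
            has_ir = k < n_ir
            J = sp.junctions_per_lsv
            base = np.full(J, sp.base_alt_psi / (J - 1))
            base[0] = 1.0 - sp.base_alt_psi
            for state in config.states:
                mult = 1.0 if state in cold else (0.5 if state in entry else 0.0)
                psi = base.copy()
                shift = sp.cold_dpsi_effect * mult
                shift = min(shift, psi[0] - 0.01)
                psi[0] -= shift
                psi[1] += shift
                for jx in range(J):
                    lsv_rows.append(
                        {
                            "lsv_id": f"lsv{k + 1:04d}",
                            "gene_id": g.gene_id,
                            "junction_id": jx,
                            "ir_flag": has_ir and jx == J - 1,
                            "state": state,
                            "psi": psi[jx],
                        }
                    )
    if lsv_rows:
        lsv_truth = (
            pd.DataFrame(lsv_rows)
            .pivot_table(
                index=["lsv_id", "gene_id", "junction_id", "ir_flag"],
                columns="state",
                values="psi",
                sort=False,
            )
            .reset_index()
        )
        lsv_truth.columns = [
            c if c in ("lsv_id", "gene_id", "junction_id", "ir_flag") else f"psi_{c}"
            for c in lsv_truth.columns
        ]
    else:
        lsv_truth = pd.DataFrame(columns=["lsv_id", "gene_id", "junction_id", "ir_flag"])

    sequences = {c: "".join(seqs[c]) for c in chrom_names}
    return sequences, genes, TruthTable(genes=gene_truth, sites=site_truth, lsvs=lsv_truth)


def _expected_gene_profile(length: int, plateau: float, config: SimConfig) -> np.ndarray:
    """Expected sense-axis coverage over the gene body (5' and 3' peaks included)."""
    prof = np.full(length, plateau)
    w = min(config.peak_width, length)
    prof[:w] *= config.peak5
    prof[length - w :] *= config.peak3
    return prof


def _tail_profile(ext: int, plateau: float) -> np.ndarray:
    """Exponential readthrough tail: half-distance ext/3, hard-truncated at ext."""
    if ext <= 0:
        return np.zeros(0)
    d = np.arange(1, ext + 1, dtype=float)
    return plateau * np.power(2.0, -3.0 * d / ext)


def simulate_nascent(
    genes: list[GeneModel],
    truth: TruthTable,
    design: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
) -> dict[str, CoverageTrack]:
    """Per-sample strand-specific coverage tracks with state-true readthrough tails."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chrom_lengths = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    gt = truth.genes.set_index("gene_id")
    tracks: dict[str, CoverageTrack] = {}
    for _, sample in design.iterrows():
        state = sample["state"]
        track = CoverageTrack(chrom_lengths)
        for g in genes:
            row = gt.loc[g.gene_id]
            plateau = config.plateau * (row[f"mu_{state}"] / config.expression_level)
            body = _expected_gene_profile(g.length, plateau, config)
            ext = int(row[f"ext_{state}"])
            tail = _tail_profile(ext, plateau)
            arr = track.get(g.chrom, g.strand)
            if g.strand == "+":
                expected = np.concatenate([body, tail])
                lo, hi = g.start, min(g.end + ext, len(arr))
                expected = expected[: hi - lo]
            else:
                expected = np.concatenate([tail[::-1], body[::-1]])
                lo, hi = max(g.start - ext, 0), g.end
                expected = expected[-(hi - lo) :]
            if config.deterministic:
                arr[lo:hi] += expected
            else:
                arr[lo:hi] += rng.poisson(expected)
        if config.background_rate > 0:
            for key in list(track.keys()):
                arr = track.get(*key)
                if config.deterministic:
                    arr += config.background_rate
                else:
                    arr += rng.poisson(config.background_rate, size=len(arr))
        tracks[sample["sample"]] = track
    return tracks


def simulate_expression(
    genes: list[GeneModel],
    truth: TruthTable,
    design: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
    size_factors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Gene x sample count matrix: NB(mu = size_factor * sex_effect * state mean)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gt = truth.genes
    counts = {}
    for _, sample in design.iterrows():
        mu = gt[f"mu_{sample['state']}"].to_numpy(dtype=float).copy()
        sf = 1.0 if size_factors is None else size_factors.get(sample["sample"], 1.0)
        mu *= sf
        if sample["sex"] == "M":
            mu *= config.sex_effect
        if config.nb_dispersion < 1e-12:
            counts[sample["sample"]] = rng.poisson(mu)
        else:
            n = 1.0 / config.nb_dispersion
            p = n / (n + mu)
            counts[sample["sample"]] = rng.negative_binomial(n, p)
    return pd.DataFrame(counts, index=gt["gene_id"].to_numpy())


def simulate_editing(
    truth: TruthTable,
    design: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
    nascent_design: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allele-count tables for the steady-state and nascent assays.

    Polymorphic sites carry the alternate allele at frequency ~0.5 in BOTH
    assays; true editing sites carry it only in the steady-state assay, at
    the state's configured rate.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if nascent_design is None:
        nascent_design = design
    depth = config.editing.depth
    tables = []
    for assay, dsgn in (("rna", design), ("nascent", nascent_design)):
        rows = []
        for _, site in truth.sites.iterrows():
            for _, sample in dsgn.iterrows():
                if site["polymorphic"]:
                    rate = 0.5
                elif assay == "rna":
                    rate = site[f"rate_{sample['state']}"]
                else:
                    rate = 0.0
                alt = int(rng.binomial(depth, rate)) if depth > 0 else 0
                rows.append(
                    {
                        "site_id": site["site_id"],
                        "chrom": site["chrom"],
                        "pos0": site["pos0"],
                        "ref": site["ref"],
                        "alt": site["alt"],
                        "sample": sample["sample"],
                        "state": sample["state"],
                        "ref_count": depth - alt,
                        "alt_count": alt,
                    }
                )
        tables.append(pd.DataFrame(rows))
    return tables[0], tables[1]


def simulate_junctions(
    truth: TruthTable,
    design: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Junction counts per sample: multinomial(depth, PSI of the sample's state)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    depth = config.splicing.depth
    rows = []
    for (lsv_id, gene_id), grp in truth.lsvs.groupby(["lsv_id", "gene_id"], sort=False):
        grp = grp.sort_values("junction_id")
        for _, sample in design.iterrows():
            psi = grp[f"psi_{sample['state']}"].to_numpy(dtype=float)
            if abs(psi.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{lsv_id}: PSI vector does not sum to 1 in {sample['state']}")
            draws = rng.multinomial(depth, psi) if depth > 0 else np.zeros(len(psi), dtype=int)
            for jx, (_, jrow) in enumerate(grp.iterrows()):
                rows.append(
                    {
                        "lsv_id": lsv_id,
                        "gene_id": gene_id,
                        "junction_id": int(jrow["junction_id"]),
                        "ir_flag": bool(jrow["ir_flag"]),
                        "sample": sample["sample"],
                        "state": sample["state"],
                        "count": int(draws[jx]),
                    }
                )
    return pd.DataFrame(rows)


def simulate_concordance_fc(
    n_genes: int,
    mode: str,
    seed: int = 0,
    effect_sd: float = 2.0,
    noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Paired log2 fold changes for the two assays.

    ``mode="transcription"``: steady-state changes are driven by the shared
    transcriptional effect (high correlation expected).  ``mode="stability"``:
    the two assays change independently (correlation near zero expected).
    """
    rng = np.random.default_rng(seed)
    if mode == "transcription":
        shared = rng.normal(0, effect_sd, n_genes)
        fc_nascent = shared + rng.normal(0, noise_sd, n_genes)
        fc_rna = shared + rng.normal(0, noise_sd, n_genes)
    elif mode == "stability":
        fc_nascent = rng.normal(0, effect_sd, n_genes)
        fc_rna = rng.normal(0, effect_sd, n_genes)
    else:
        raise ConfigError(f"unknown concordance mode {mode!r}")
    return pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:04d}" for i in range(n_genes)],
            "fc_rna": fc_rna,
            "fc_nascent": fc_nascent,
        }
    )


def simulate_dataset(config: SimConfig, outdir: str | Path | None = None):
    """Run the full generator; optionally write everything as text files."""
    from . import io as hio

    sequences, genes, truth = build_genome(config)
    design = make_design(config.states, config.replicates_per_state)
    tracks = simulate_nascent(genes, truth, design, config)
    counts = simulate_expression(genes, truth, design, config)
    rna_sites, nascent_sites = simulate_editing(truth, design, config)
    junctions = simulate_junctions(truth, design, config)
    bundle = {
        "sequences": sequences,
        "genes": genes,
        "truth": truth,
        "design": design,
        "tracks": tracks,
        "counts": counts,
        "rna_sites": rna_sites,
        "nascent_sites": nascent_sites,
        "junctions": junctions,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_fasta(sequences, outdir / "genome.fa")
        hio.write_bed12(genes, outdir / "genes.bed")
        truth.write(outdir)
        hio.write_tsv(design, outdir / "design.tsv")
        hio.write_tsv(counts.reset_index(names="gene_id"), outdir / "counts.tsv")
        hio.write_tsv(rna_sites, outdir / "sites_rna.tsv")
        hio.write_tsv(nascent_sites, outdir / "sites_nascent.tsv")
        hio.write_tsv(junctions, outdir / "junctions.tsv")
        for sample, track in tracks.items():
            hio.write_bedgraph(track, outdir / f"coverage_{sample}")
    return bundle
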