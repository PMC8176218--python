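"""Steady-state vs nascent-transcription concordance and 3' k-mer enrichment.

The deep-torpor nascent state (LT) is treated as equivalent to the
steady-state arousal group (Ar) when intersecting DE sets across assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import InputError
from .expression import bh_adjust

QUADRANTS = ("pos_up", "pos_down", "stable_RNA", "deferred", "concordant_null")


@dataclass(frozen=True)
class DEIntersection:
    both: frozenset
    rna_only: frozenset
    nascent_only: frozenset

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.both), len(self.rna_only), len(self.nascent_only)


def intersect_de_sets(de_rna: set, de_nascent: set) -> DEIntersection:
    """Partition DE gene ids into shared / steady-state-only / nascent-only."""
    both = set(de_rna) & set(de_nascent)
    result = DEIntersection(
        both=frozenset(both),
        rna_only=frozenset(set(de_rna) - both),
        nascent_only=frozenset(set(de_nascent) - both),
    )
    if not both:
        import warnings

        warnings.warn("DE sets do not intersect")
    return result


def fc_correlation(records: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson r (with two-sided p) of the two log2FC columns.

    Expects columns ``fc_rna`` and ``fc_nascent``; returns (nan, nan, n)
    when either column has zero variance.
    """
    x = records["fc_rna"].to_numpy(dtype=float)
    y = records["fc_nascent"].to_numpy(dtype=float)
    n = len(records)
    if n < 3:
        raise InputError("need >= 3 genes for a correlation")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def classify_concordance(records: pd.DataFrame) -> pd.DataFrame:
    """Sign-based quadrant labels for paired fold changes.

    pos_up / pos_down: same-sign changes; stable_RNA: RNA up while nascent
    down; deferred: nascent up while RNA down; exact zeros are counted as
    concordant_null.
    """
    def quadrant(fr: float, fn: float) -> str:
        if fr == 0 or fn == 0:
            return "concordant_null"
        if fr > 0 and fn > 0:
            return "pos_up"
        if fr < 0 and fn < 0:
            return "pos_down"
        if fr > 0 and fn < 0:
            return "stable_RNA"
        return "deferred"

    out = records.copy()
    out["quadrant"] = [
        quadrant(fr, fn) for fr, fn in zip(out["fc_rna"], out["fc_nascent"])
    ]
    return out


def quadrant_summary(classified: pd.DataFrame) -> pd.Series:
    return classified["quadrant"].value_counts().reindex(QUADRANTS, fill_value=0)


def _count_kmers(sequences: list[str], k: int) -> tuple[dict[str, int], int, int]:
    """k-mer counts, total window count, and number of too-short sequences."""
    counts: dict[str, int] = {}
    total = 0
    skipped = 0
    for seq in sequences:
        s = seq.upper().replace("U", "T")
        if len(s) < k:
            skipped += 1
            continue
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
            total += 1
    return counts, total, skipped


def kmer_enrichment(
    fg_sequences: list[str],
    bg_sequences: list[str],
    k: int = 6,
) -> pd.DataFrame:
    """Per-k-mer foreground-vs-background enrichment with binomial tests.

    Frequencies are per sliding window; p-values are two-sided binomial
    tests of the foreground count against the (pseudocounted) background
    frequency, BH-adjusted.  attrs carry skip counts and the A/U fraction
    of the top-20 enriched k-mers.
    """
    if not fg_sequences or not bg_sequences:
        raise InputError("foreground and background sequence sets must be non-empty")
    fg, fg_total, fg_skip = _count_kmers(fg_sequences, k)
    bg, bg_total, bg_skip = _count_kmers(bg_sequences, k)
    if fg_total == 0 or bg_total == 0:
        raise InputError(
            f"every sequence shorter than k={k} "
            f"(skipped {fg_skip} foreground, {bg_skip} background)"
        )
    n_kmers = 4 ** k
    kmers = sorted(set(fg) | set(bg))
    rows = []
    for kmer in kmers:
        fc = fg.get(kmer, 0)
        bc = bg.get(kmer, 0)
        bg_freq = (bc + 1) / (bg_total + n_kmers)
        p = stats.binomtest(fc, fg_total, bg_freq, alternative="two-sided").pvalue
        fg_freq = fc / fg_total
        rows.append(
            {
                "kmer": kmer,
                "fg_count": fc,
                "bg_count": bc,
                "fg_freq": fg_freq,
                "bg_freq": bc / bg_total,
                "log2_enrichment": float(np.log2((fg_freq + 1e-12) / bg_freq)),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(
        ["log2_enrichment", "fg_count"], ascending=[False, False]
    ).reset_index(drop=True)
    top = out.head(20)["kmer"]
    au = sum(c in "AT" for kmer in top for c in kmer)
    out.attrs["au_fraction_top20"] = au / max(1, sum(len(kk) for kk in top))
    out.attrs["skipped_fg"] = fg_skip
    out.attrs["skipped_bg"] = bg_skip
    return out
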