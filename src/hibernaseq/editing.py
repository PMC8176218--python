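"""A-to-I (read as A-to-G) editing-site detection from allele-count tables.

Sites are filtered on coverage, tested for state variability with G-tests,
strand-resolved into substitution classes, cleansed of genomic polymorphisms
by requiring absence from the nascent-assay variant list, and classified by
genomic region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, InputError
from .expression import bh_adjust

SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def filter_sites_by_coverage(
    table: pd.DataFrame, min_depth: int = 10, min_samples: int = 7
) -> pd.DataFrame:
    """Keep sites with depth >= min_depth in at least ``min_samples`` samples."""
    depth = table["ref_count"] + table["alt_count"]
    ok = (
        table.assign(_depth_ok=depth >= min_depth)
        .groupby("site_id")["_depth_ok"]
        .sum()
    )
    keep = ok.index[ok >= min_samples]
    return table[table["site_id"].isin(keep)].copy()


def g_test(observed: np.ndarray) -> tuple[float, float, int]:
    """Likelihood-ratio (G) test of independence on a 2-D contingency table.

    A 0.5 pseudo-count is added only when a margin is zero.  Returns
    (G, p, df) with df = (rows-1)(cols-1).
    """
    obs = np.asarray(observed, dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        obs = obs + 0.5
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(g), float(stats.chi2.sf(g, df)), df


def _state_pooled(table: pd.DataFrame) -> pd.DataFrame:
    return table.groupby(["site_id", "state"])[["ref_count", "alt_count"]].sum()


def test_state_variability(
    table: pd.DataFrame, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-site G-test of allele-frequency variability across states.

    Counts are pooled within state; degenerate (single-allele) tables get
    p = 1.  q is BH-adjusted across sites.
    """
    pooled = _state_pooled(table)
    rows = []
    for site_id, grp in pooled.groupby(level="site_id"):
        obs = grp[["ref_count", "alt_count"]].to_numpy(dtype=float)
        covered = obs.sum(axis=1) > 0
        obs = obs[covered]
        if obs.shape[0] < 2:
            raise InputError(f"{site_id}: fewer than two states with coverage")
        if (obs.sum(axis=0) == 0).any():
            rows.append({"site_id": site_id, "g_stat": 0.0, "p": 1.0})
            continue
        g, p, _ = g_test(obs)
        rows.append({"site_id": site_id, "g_stat": g, "p": p})
    res = pd.DataFrame(rows).set_index("site_id")
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["variable"] = res["q"] < q_threshold
    return res


def pooled_editing_frequency(table: pd.DataFrame) -> pd.DataFrame:
    """Per-site per-state alt-allele frequency from pooled counts."""
    pooled = _state_pooled(table).reset_index()
    depth = pooled["ref_count"] + pooled["alt_count"]
    pooled["frequency"] = np.where(depth > 0, pooled["alt_count"] / depth.where(depth > 0, 1), np.nan)
    return pooled


def substitution_spectrum(
    sites: pd.DataFrame, strand_col: str = "strand"
) -> tuple[pd.Series, int]:
    """Counts per substitution class after strand-resolving minus-strand sites.

    A genomic T>C site hosted on a minus-strand gene is counted as A>G.
    Sites with ambiguous bases are excluded and counted separately.
    """
    per_site = sites.drop_duplicates("site_id")
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    excluded = 0
    for _, row in per_site.iterrows():
        ref, alt = str(row["ref"]).upper(), str(row["alt"]).upper()
        if ref not in _COMP or alt not in _COMP or ref == alt:
            excluded += 1
            continue
        if row.get(strand_col, "+") == "-":
            ref, alt = _COMP[ref], _COMP[alt]
        counts[f"{ref}>{alt}"] += 1
    return pd.Series(counts).reindex(SUBSTITUTION_CLASSES), excluded


def cross_assay_filter(
    rna_sites: list | pd.Index | set,
    nascent_variants: list | pd.Index | set,
) -> tuple[list, int]:
    """Drop candidate sites also seen as variants in the nascent assay.

    Shared sites are presumed genomic polymorphisms.  Returns the retained
    site keys (input order preserved) and the excluded count.
    """
    nascent = set(nascent_variants)
    retained = [s for s in rna_sites if s not in nascent]
    return retained, len(list(rna_sites)) - len(retained)


def pairwise_differential_editing(
    table: pd.DataFrame, state_a: str, state_b: str
) -> pd.DataFrame:
    """Two-proportion G-test of pooled editing frequency between two states."""
    pooled = _state_pooled(table)
    rows = []
    for site_id, grp in pooled.groupby(level="site_id"):
        grp = grp.droplevel("site_id")
        if state_a not in grp.index or state_b not in grp.index:
            continue
        a = grp.loc[state_a]
        b = grp.loc[state_b]
        depth_a, depth_b = a.sum(), b.sum()
        if depth_a == 0 or depth_b == 0:
            rows.append({"site_id": site_id, "delta_ef": np.nan, "p": np.nan})
            continue
        ef_a = a["alt_count"] / depth_a
        ef_b = b["alt_count"] / depth_b
        obs = np.array([[a["ref_count"], a["alt_count"]], [b["ref_count"], b["alt_count"]]])
        g, p, _ = g_test(obs)
        rows.append({"site_id": site_id, "delta_ef": float(ef_b - ef_a), "p": p})
    res = pd.DataFrame(rows).set_index("site_id")
    tested = res["p"].notna()
    res["q"] = np.nan
    if tested.any():
        res.loc[tested, "q"] = bh_adjust(res.loc[tested, "p"].to_numpy())
    return res


def cold_enriched_sites(
    table: pd.DataFrame, cold_state: str, q_threshold: float = 0.05
) -> list[str]:
    """Sites with significantly higher editing in ``cold_state`` than every
    other state (pairwise q < threshold and positive delta in all pairs)."""
    states = [s for s in table["state"].unique() if s != cold_state]
    enriched: set[str] | None = None
    for other in states:
        res = pairwise_differential_editing(table, other, cold_state)
        hits = set(res.index[(res["q"] < q_threshold) & (res["delta_ef"] > 0)])
        enriched = hits if enriched is None else enriched & hits
    return sorted(enriched or set())


def annotate_region(
    chrom: str, pos0: int, genes: list[GeneModel]
) -> str:
    """Region class by interval containment: CDS > UTR > intron > intergenic."""
    best = "intergenic"
    rank = {"CDS": 0, "5'UTR": 1, "3'UTR": 1, "intron": 2, "intergenic": 3}
    for g in genes:
        if g.chrom != chrom or not (g.start <= pos0 < g.end):
            continue
        exonic = any(s <= pos0 < e for s, e in (g.exons or ((g.start, g.end),)))
        if not exonic:
            cls = "intron"
        elif g.cds is not None and g.cds[0] <= pos0 < g.cds[1]:
            cls = "CDS"
        elif g.cds is None:
            cls = "3'UTR"
        else:
            after_cds = pos0 >= g.cds[1] if g.strand == "+" else pos0 < g.cds[0]
            cls = "3'UTR" if after_cds else "5'UTR"
        if rank[cls] < rank[best]:
            best = cls
    return best


def annotate_regions(sites: pd.DataFrame, genes: list[GeneModel]) -> pd.Series:
    per_site = sites.drop_duplicates("site_id").set_index("site_id")
    return pd.Series(
        {sid: annotate_region(row["chrom"], int(row["pos0"]), genes)
         for sid, row in per_site.iterrows()},
        name="region",
    )


def overlap_reference(
    sites: set, reference: set, universe_size: int
) -> tuple[int, float]:
    """Overlap count with a reference site set plus hypergeometric tail p.

    p = P(overlap >= observed) drawing |sites| from a universe containing
    |reference| marked elements.
    """
    sites, reference = set(sites), set(reference)
    if universe_size < len(sites | reference):
        raise InputError("universe smaller than the union of the site sets")
    n_overlap = len(sites & reference)
    p = float(stats.hypergeom.sf(n_overlap - 1, universe_size, len(reference), len(sites)))
    return n_overlap, p
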