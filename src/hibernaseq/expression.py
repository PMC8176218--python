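"""Differential expression across physiological states with a sex covariate.

Count matrices are normalized by median-of-ratios size factors, filtered on
a pseudocounted log2 level rule, tested gene-wise with a negative-binomial
likelihood-ratio test (full model: state + sex; reduced: sex), and DE genes
are assigned to reference pattern templates by Pearson correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import InputError, PatternLibrary

LOG_PSEUDOCOUNT = 8.0  # declared stand-in for a variance-stabilizing transform


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with nonzero geometric mean."""
    if (counts.sum(axis=0) == 0).any():
        raise InputError("sample with all-zero counts")
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)
    usable = log_ref.notna() & np.isfinite(log_ref)
    if not usable.any():
        raise InputError("no gene has nonzero counts in every sample")
    ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def normalize_and_filter(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    min_level: float = 7.0,
    min_samples: int = 4,
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, pd.Series, pd.Index]:
    """Normalize and keep genes expressed in at least one state.

    A gene is retained iff log2(normalized + pseudocount) >= ``min_level``
    in at least ``min_samples`` individuals of at least one state.
    Returns (filtered log matrix, size factors, kept gene index).
    """
    sf = size_factors_median_ratio(counts)
    norm = counts.div(sf, axis=1)
    logm = np.log2(norm + pseudocount)
    states = design.set_index("sample")["state"]
    keep = pd.Series(False, index=counts.index)
    for state in states.unique():
        samples = states.index[states == state]
        n_hi = (logm[samples] >= min_level).sum(axis=1)
        keep |= n_hi >= min_samples
    kept = counts.index[keep]
    return logm.loc[kept], sf, kept


def _mom_dispersion(norm_gene: np.ndarray, state_codes: np.ndarray, floor: float = 1e-8) -> float:
    """Pooled method-of-moments NB dispersion from within-state moments."""
    num = 0.0
    den = 0.0
    for s in np.unique(state_codes):
        y = norm_gene[state_codes == s]
        if len(y) < 2:
            continue
        m = y.mean()
        v = y.var(ddof=1)
        num += (len(y) - 1) * (v - m)
        den += (len(y) - 1) * m * m
    if den <= 0:
        return floor
    return max(floor, num / den)


def nb_lrt_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    q_threshold: float = 0.001,
    dispersion_floor: float = 1e-8,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Gene-wise NB likelihood-ratio test of state effect, controlling for sex.

    Per gene: dispersion by method of moments, moderated by taking the
    maximum of the gene's own estimate and the across-gene median (guards
    against chance underestimation that would inflate the LRT); GLM fits of
    state + sex vs sex alone with log size-factor offsets; LRT p from
    chi-square with df = n_states - 1; BH adjustment over converged genes.
    """
    design = design.set_index("sample").loc[counts.columns]
    states = design["state"].to_numpy()
    if len(np.unique(states)) < 2:
        raise InputError("need >= 2 states")
    if counts.empty:
        raise InputError("empty count matrix")
    sf = size_factors_median_ratio(counts) if size_factors is None else size_factors
    offset = np.log(sf.to_numpy())
    state_d = pd.get_dummies(pd.Series(states), drop_first=True, dtype=float).to_numpy()
    sex = (design["sex"] == "M").to_numpy(dtype=float).reshape(-1, 1)
    intercept = np.ones((len(states), 1))
    X_full = np.hstack([intercept, state_d, sex])
    X_red = np.hstack([intercept, sex])
    df_lrt = len(np.unique(states)) - 1
    state_codes = pd.factorize(states)[0]
    norm = counts.div(sf, axis=1)
    raw_alpha = {
        gene: _mom_dispersion(norm.loc[gene].to_numpy(), state_codes, dispersion_floor)
        for gene in counts.index
    }
    alpha_prior = float(np.median(list(raw_alpha.values())))

    rows = []
    for gene in counts.index:
        y = counts.loc[gene].to_numpy(dtype=float)
        alpha = max(raw_alpha[gene], alpha_prior)
        family = (
            sm.families.Poisson()
            if alpha <= dispersion_floor
            else sm.families.NegativeBinomial(alpha=alpha)
        )
        stat = p = np.nan
        converged = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.GLM(y, X_full, family=family, offset=offset).fit(maxiter=100)
                red = sm.GLM(y, X_red, family=family, offset=offset).fit(maxiter=100)
            stat = 2.0 * (full.llf - red.llf)
            if np.isfinite(stat):
                stat = max(stat, 0.0)
                p = float(stats.chi2.sf(stat, df_lrt))
                converged = bool(full.converged and red.converged)
        except Exception:
            pass
        row = {"gene_id": gene, "lrt_stat": stat, "p": p if converged else np.nan,
               "dispersion": alpha, "converged": converged}
        for s in np.unique(states):
            row[f"mean_{s}"] = float(np.log2(norm.loc[gene, states == s].mean() + 1))
        rows.append(row)

    res = pd.DataFrame(rows).set_index("gene_id")
    res["q"] = np.nan
    tested = res["p"].notna()
    res.loc[tested, "q"] = bh_adjust(res.loc[tested, "p"].to_numpy())
    res["de"] = res["q"] <= q_threshold
    return res


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, clipped to [0,1])."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def assign_pattern(
    state_means: np.ndarray | pd.Series,
    library: PatternLibrary,
    r_min: float = 0.8,
) -> tuple[str, float]:
    """Best-correlated template name (or 'Unassigned') and its Pearson r.

    The means vector must be aligned to the library's state order.  Exact
    ties break toward library order.  Zero-variance vectors are Unassigned.
    """
    v = np.asarray(state_means, dtype=float)
    if v.shape != (len(library.states),):
        raise InputError("state means not aligned to library states")
    if np.allclose(v, v[0]):
        return "Unassigned", float("nan")
    best_name, best_r = "Unassigned", -np.inf
    for name, tmpl in library.templates.items():
        r = float(np.corrcoef(v, tmpl)[0, 1])
        if r > best_r:
            best_name, best_r = name, r
    if best_r >= r_min:
        return best_name, best_r
    return "Unassigned", best_r


def assign_patterns(
    state_mean_matrix: pd.DataFrame, library: PatternLibrary, r_min: float = 0.8
) -> pd.DataFrame:
    """Vectorized pattern assignment; rows = genes, columns = library states."""
    out = []
    for gene, row in state_mean_matrix[list(library.states)].iterrows():
        name, r = assign_pattern(row.to_numpy(), library, r_min)
        out.append({"gene_id": gene, "pattern": name, "r": r})
    return pd.DataFrame(out).set_index("gene_id")


def pairwise_log2fc(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    state_a: str,
    state_b: str,
    pseudocount: float = 0.5,
    size_factors: pd.Series | None = None,
) -> pd.Series:
    """Per-gene log2 of the normalized state-mean ratio, B over A.

    Size factors default to median-of-ratios; pass precomputed (or unit)
    factors to skip renormalization.
    """
    design = design.set_index("sample").loc[counts.columns]
    sf = size_factors_median_ratio(counts) if size_factors is None else size_factors
    norm = counts.div(sf, axis=1)
    mean_a = norm.loc[:, (design["state"] == state_a).to_numpy()].mean(axis=1)
    mean_b = norm.loc[:, (design["state"] == state_b).to_numpy()].mean(axis=1)
    fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    fc.name = f"log2fc_{state_b}_vs_{state_a}"
    return fc


def gc_content_compare(
    direction_sets: dict[str, tuple[set[str], set[str]]],
    gc: pd.Series,
) -> pd.DataFrame:
    """Rank-sum comparison of GC content between up- and down-regulated sets.

    ``direction_sets`` maps a transition label to (up gene ids, down gene
    ids).  Empty sets give an NA row; single-gene sets use the exact test
    and are flagged low-n.
    """
    rows = []
    for transition, (up, down) in direction_sets.items():
        gc_up = gc.reindex(sorted(up)).dropna()
        gc_down = gc.reindex(sorted(down)).dropna()
        if len(gc_up) == 0 or len(gc_down) == 0:
            rows.append(
                {"transition": transition, "n_up": len(gc_up), "n_down": len(gc_down),
                 "median_gc_up": np.nan, "median_gc_down": np.nan, "p": np.nan, "low_n": True}
            )
            continue
        p = float(stats.mannwhitneyu(gc_up, gc_down, alternative="two-sided", method="auto").pvalue)
        rows.append(
            {
                "transition": transition,
                "n_up": len(gc_up),
                "n_down": len(gc_down),
                "median_gc_up": float(gc_up.median()),
                "median_gc_down": float(gc_down.median()),
                "p": p,
                "low_n": min(len(gc_up), len(gc_down)) < 3,
            }
        )
    return pd.DataFrame(rows)
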