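"""PSI / dPSI splicing analysis on junction-count tables.

Each local splicing variation (LSV) groups >= 2 alternative junctions.
Significance of a PSI change between states uses a Dirichlet posterior on
pooled state counts: an event is called when the Monte-Carlo estimate of
P(|dPSI| >= threshold) reaches the probability criterion (default
0.2 / 99.9%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .core import InputError
from .expression import assign_pattern


@dataclass(frozen=True)
class SpliceCall:
    lsv_id: str
    junction_id: int
    transition: str
    mean_dpsi: float
    prob_dpsi: float
    significant: bool


def _lsv_matrix(lsv: pd.DataFrame) -> pd.DataFrame:
    """sample x junction count matrix for one LSV (validates shape)."""
    mat = lsv.pivot_table(index="sample", columns="junction_id", values="count", sort=True)
    if mat.shape[1] < 2:
        raise InputError("an LSV needs >= 2 junctions")
    if (mat.to_numpy() < 0).any():
        raise InputError("junction counts must be >= 0")
    return mat


def compute_psi(lsv: pd.DataFrame, sample: str) -> np.ndarray:
    """PSI vector for one sample (NaN vector when the sample has no reads)."""
    mat = _lsv_matrix(lsv)
    counts = mat.loc[sample].to_numpy(dtype=float)
    total = counts.sum()
    if total == 0:
        return np.full(len(counts), np.nan)
    return counts / total


def psi_by_state(lsv: pd.DataFrame) -> pd.DataFrame:
    """Pooled per-state PSI vectors (state x junction)."""
    pooled = lsv.groupby(["state", "junction_id"])["count"].sum().unstack()
    totals = pooled.sum(axis=1)
    return pooled.div(totals.where(totals > 0), axis=0)


def summer_dominant_junction(lsv: pd.DataFrame, summer_state: str = "SA") -> int | None:
    """Junction with the highest pooled count in the summer-active state.

    Ties break toward the lowest junction index; an all-zero summer state
    returns None (the LSV is excluded downstream).
    """
    sa = lsv[lsv["state"] == summer_state]
    if sa.empty:
        raise InputError(f"no {summer_state} samples in LSV table")
    pooled = sa.groupby("junction_id")["count"].sum().sort_index()
    if pooled.sum() == 0:
        return None
    return int(pooled.idxmax())  # idxmax takes the first (lowest) on ties


def dpsi_significance(
    lsv: pd.DataFrame,
    state_a: str,
    state_b: str,
    threshold: float = 0.2,
    prob: float = 0.999,
    draws: int = 2000,
    seed: int = 0,
    one_sided: bool = False,
) -> list[SpliceCall]:
    """Posterior dPSI calls per junction between two states.

    Posterior per state: Dirichlet(1 + pooled counts).  ``one_sided``
    restricts the criterion to increases in ``state_b``.
    """
    rng = np.random.default_rng(seed)
    pooled = lsv.groupby(["state", "junction_id"])["count"].sum().unstack().sort_index(axis=1)
    if pooled.shape[1] < 2:
        raise InputError("an LSV needs >= 2 junctions")
    for state in (state_a, state_b):
        if state not in pooled.index:
            raise InputError(f"state {state!r} missing from LSV table")
    alpha_a = 1.0 + pooled.loc[state_a].to_numpy(dtype=float)
    alpha_b = 1.0 + pooled.loc[state_b].to_numpy(dtype=float)
    psi_a = rng.dirichlet(alpha_a, size=draws)
    psi_b = rng.dirichlet(alpha_b, size=draws)
    dpsi = psi_b - psi_a
    lsv_id = str(lsv["lsv_id"].iloc[0]) if "lsv_id" in lsv.columns else ""
    calls = []
    for j, junction in enumerate(pooled.columns):
        excess = dpsi[:, j] >= threshold if one_sided else np.abs(dpsi[:, j]) >= threshold
        p_hat = float(excess.mean())
        calls.append(
            SpliceCall(
                lsv_id=lsv_id,
                junction_id=int(junction),
                transition=f"{state_a}->{state_b}",
                mean_dpsi=float(dpsi[:, j].mean()),
                prob_dpsi=p_hat,
                significant=p_hat >= prob,
            )
        )
    return calls


def exact_dpsi_probability(
    counts_a: tuple[float, float],
    counts_b: tuple[float, float],
    threshold: float = 0.2,
    one_sided: bool = False,
) -> float:
    """Closed-form P(|dPSI| >= threshold) for a 2-junction LSV.

    With two junctions the Dirichlet posterior reduces to Beta marginals
    for junction 1; the probability is a 1-D integral over the Beta density
    of state A against the Beta CDF of state B.
    """
    a1, a2 = 1.0 + counts_a[0], 1.0 + counts_a[1]
    b1, b2 = 1.0 + counts_b[0], 1.0 + counts_b[1]
    beta_a = stats.beta(a1, a2)
    beta_b = stats.beta(b1, b2)

    def integrand(x: float) -> float:
        up = beta_b.sf(min(x + threshold, 1.0))
        if one_sided:
            return beta_a.pdf(x) * up
        down = beta_b.cdf(max(x - threshold, 0.0))
        return beta_a.pdf(x) * (up + down)

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return float(min(max(val, 0.0), 1.0))


def call_all_lsvs(
    junctions: pd.DataFrame,
    state_a: str,
    state_b: str,
    threshold: float = 0.2,
    prob: float = 0.999,
    draws: int = 2000,
    seed: int = 0,
    one_sided: bool = False,
) -> pd.DataFrame:
    """dpsi_significance over every LSV in a long-form junction table."""
    rows = []
    for lsv_id, grp in junctions.groupby("lsv_id", sort=False):
        for call in dpsi_significance(
            grp, state_a, state_b, threshold, prob, draws, seed, one_sided
        ):
            rows.append(
                {
                    "lsv_id": lsv_id,
                    "junction_id": call.junction_id,
                    "transition": call.transition,
                    "mean_dpsi": call.mean_dpsi,
                    "prob_dpsi": call.prob_dpsi,
                    "significant": call.significant,
                }
            )
    return pd.DataFrame(rows)


def classify_splicing_patterns(
    junctions: pd.DataFrame,
    significant_lsvs: list[str],
    library,
    summer_state: str = "SA",
    r_min: float = 0.8,
) -> pd.DataFrame:
    """Assign significant events to temperature patterns.

    Non-IR events use the summed PSI of all non-summer-dominant junctions
    per state; events whose LSV carries an intron-retention junction use
    that junction's PSI instead.  Assignment reuses the r >= 0.8 Pearson
    rule of the expression module.
    """
    rows = []
    for lsv_id in significant_lsvs:
        grp = junctions[junctions["lsv_id"] == lsv_id]
        dom = summer_dominant_junction(grp, summer_state)
        if dom is None:
            rows.append({"lsv_id": lsv_id, "pattern": "Unassigned", "r": np.nan, "ir": False})
            continue
        psi = psi_by_state(grp).reindex(list(library.states))
        ir_junctions = grp.loc[grp["ir_flag"], "junction_id"].unique()
        is_ir = len(ir_junctions) > 0
        if is_ir:
            signal = psi[ir_junctions[0]]
        else:
            alt_cols = [c for c in psi.columns if c != dom]
            signal = psi[alt_cols].sum(axis=1)
        if signal.isna().any():
            rows.append({"lsv_id": lsv_id, "pattern": "Unassigned", "r": np.nan, "ir": is_ir})
            continue
        name, r = assign_pattern(signal.to_numpy(), library, r_min)
        rows.append({"lsv_id": lsv_id, "pattern": name, "r": r, "ir": is_ir})
    return pd.DataFrame(rows, columns=["lsv_id", "pattern", "r", "ir"])
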