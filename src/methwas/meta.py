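"""Fixed-effects inverse-variance meta-analysis across cohorts, Bonferroni
control, sign-concordance replication tests, probe pruning and power
utilities for methylome-wide summary statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MetaRecord:
    """Pooled fixed-effects estimate for one probe."""

    b: float
    se: float
    z: float
    p: float
    n_cohorts: int
    q: float                 # Cochran heterogeneity statistic (reported only)
    inputs: list


def ivw_meta(inputs: Sequence[tuple[float, float]]) -> MetaRecord:
    """Inverse-variance-weighted fixed-effects pool of per-cohort (b, se)."""
    if len(inputs) < 2:
        raise ValueError("meta-analysis needs at least two cohorts")
    b = np.array([x[0] for x in inputs], dtype=float)
    se = np.array([x[1] for x in inputs], dtype=float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = se**-2
    pooled_b = float((w * b).sum() / w.sum())
    pooled_se = float(w.sum() ** -0.5)
    z = pooled_b / pooled_se
    q = float((w * (b - pooled_b) ** 2).sum())
    return MetaRecord(b=pooled_b, se=pooled_se, z=z,
                      p=float(2 * stats.norm.sf(abs(z))),
                      n_cohorts=len(inputs), q=q, inputs=list(inputs))


def ivw_meta_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Meta-analyse association tables over the probes present in *all*
    cohorts (the common-probe intersection); per-cohort effects are kept as
    extra columns."""
    if len(tables) < 2:
        raise ValueError("meta-analysis needs at least two cohorts")
    common = tables[0]["Probe"]
    for t in tables[1:]:
        common = common[common.isin(t["Probe"])]
    common = pd.Index(common)
    aligned = [t.set_index("Probe").loc[common] for t in tables]
    B = np.column_stack([a["b"].to_numpy(dtype=float) for a in aligned])
    SE = np.column_stack([a["se"].to_numpy(dtype=float) for a in aligned])
    if (SE <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = SE**-2
    pooled_b = (w * B).sum(1) / w.sum(1)
    pooled_se = w.sum(1) ** -0.5
    z = pooled_b / pooled_se
    out = pd.DataFrame({
        "Chr": aligned[0]["Chr"].to_numpy(), "Probe": common,
        "bp": aligned[0]["bp"].to_numpy(), "Gene": aligned[0]["Gene"].to_numpy(),
        "b": pooled_b, "se": pooled_se, "z": z,
        "p": 2 * stats.norm.sf(np.abs(z)), "n_cohorts": len(tables),
    })
    for i, a in enumerate(aligned, start=1):
        out[f"b_cohort{i}"] = a["b"].to_numpy()
        out[f"se_cohort{i}"] = a["se"].to_numpy()
    out.attrs["n_common_probes"] = len(common)
    return out.reset_index(drop=True)


def bonferroni_threshold(m_tests: int, alpha: float = 0.05) -> float:
    if m_tests < 1:
        raise ValueError("m_tests must be at least 1")
    return alpha / m_tests


def sign_concordance_binomial(k_concordant: int, n_total: int) -> float:
    """Exact one-sided binomial tail P(X >= k), X ~ Bin(n, 1/2)."""
    if not (0 <= k_concordant <= n_total):
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k_concordant - 1, n_total, 0.5))


def prune_probes_by_r2(records: pd.DataFrame, corr: pd.DataFrame,
                       r2_max: float = 0.1,
                       p_max: Optional[float] = None) -> pd.DataFrame:
    """Greedy selection of approximately independent probes: ascending by p
    (ties broken by probe id), keep a candidate iff its squared correlation
    with every kept probe is < ``r2_max``."""
    recs = records.copy()
    if p_max is not None:
        recs = recs[recs["p"] < p_max]
    missing = pd.Index(recs["Probe"]).difference(corr.index)
    if len(missing) or not corr.index.equals(corr.columns):
        raise ValueError("correlation matrix misaligned with records")
    recs = recs.sort_values(["p", "Probe"], kind="mergesort")
    kept: list[str] = []
    for probe in recs["Probe"]:
        if all(corr.loc[probe, k] ** 2 < r2_max for k in kept):
            kept.append(probe)
    return recs[recs["Probe"].isin(kept)]


def empirical_sign_null(discovery: pd.DataFrame, replication: pd.DataFrame,
                        observed_concordant: int, n_select: int = 21,
                        reps: int = 10_000, seed: int = 0) -> float:
    """Empirical p for sign concordance: repeatedly draw ``n_select`` probes
    from the shared universe, count agreeing effect signs across cohorts and
    compare with the observed count. The +1 correction keeps p > 0."""
    shared = pd.Index(discovery["Probe"])
    shared = shared[shared.isin(replication["Probe"])]
    if n_select > len(shared):
        raise ValueError("n_select exceeds the shared probe universe")
    s1 = np.sign(discovery.set_index("Probe").loc[shared, "b"].to_numpy())
    s2 = np.sign(replication.set_index("Probe").loc[shared, "b"].to_numpy())
    agree = (s1 == s2).astype(int)
    rng = np.random.default_rng(seed)
    null = np.empty(reps, dtype=int)
    for r in range(reps):
        null[r] = agree[rng.choice(len(agree), size=n_select, replace=False)].sum()
    return float((1 + (null >= observed_concordant).sum()) / (reps + 1))


def effect_concordance(records_a: pd.DataFrame, records_b: pd.DataFrame,
                       p_threshold: float = 1.0) -> tuple[float, float, int]:
    """Pearson correlation of effect sizes over probes selected (p <
    threshold) in set A and present in set B."""
    sel = records_a[records_a["p"] < p_threshold]
    shared = pd.Index(sel["Probe"])
    shared = shared[shared.isin(records_b["Probe"])]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared probes after selection")
    a = sel.set_index("Probe").loc[shared, "b"].to_numpy(dtype=float)
    b = records_b.set_index("Probe").loc[shared, "b"].to_numpy(dtype=float)
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), int(len(shared))


def replication_power(b_discovery: float, se_model: Callable[[np.ndarray], np.ndarray],
                      alpha: float = 0.05,
                      n_grid: Sequence[int] = tuple(range(100, 10_001, 100)),
                      target: Optional[float] = 0.8) -> tuple[pd.DataFrame, Optional[int]]:
    """One-sided replication power curve: power(n) = Phi(|b|/se(n) - z_a).
    Returns the curve and, when ``target`` is given, the smallest n reaching
    it (requesting a target for a null effect is an error: power stays at
    alpha for every n)."""
    if b_discovery == 0 and target is not None:
        raise ValueError("a null effect cannot reach a finite target power")
    n = np.asarray(list(n_grid), dtype=float)
    se = np.asarray(se_model(n), dtype=float)
    if np.any(np.diff(se) > 0):
        raise ValueError("se_model must be non-increasing in n")
    za = stats.norm.isf(alpha)
    power = stats.norm.cdf(np.abs(b_discovery) / se - za)
    curve = pd.DataFrame({"n": n.astype(int), "power": power})
    n_required = None
    if target is not None:
        reaching = curve[curve["power"] >= target]
        n_required = int(reaching["n"].iloc[0]) if len(reaching) else None
    return curve, n_required
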