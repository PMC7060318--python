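"""Per-probe association scans: initial linear regression, MOA and MOMENT
mixed-model tests, and the genomic inflation factor.

MOA fits each probe as a fixed effect on top of the all-probe random
effect (``y = w_i b_i + C beta + W u + e``); MOMENT splits the random
effect into two components by initial association strength and, for each
target, removes every probe within 50 kb of it from both components.

Both scans use a two-step strategy: variance components are estimated once
under the windowless model and reused for every probe, with the covariance
*shape* fixed and the overall scale re-estimated per probe from the
generalized residual sum of squares (t reference on n - p - 1 df). In the
limit of vanishing component variances this reduces exactly to the
ordinary least-squares scan. The MOMENT window exclusion is applied by a
Woodbury down-date of the fitted covariance, so it is exact given the
fitted components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .data import (CohortDesign, MultiVarianceEstimate, ProbeAnnotation,
                   StandardizedMethylation, assoc_table)
from .mixed_model import reml

#: median of chi-square with 1 df; denominator of the inflation factor
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


def _per_probe_t(numer, denom, yMy, n, p):
    """Shared endgame: b = numer/denom, residual-rescaled se, t-based p."""
    with np.errstate(divide="ignore", invalid="ignore"):
        b = numer / denom
        rss = yMy - numer**2 / denom
        dof = n - p - 1
        s2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(s2 / denom)
        tstat = b / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return b, se, pval


def ols_scan(design: CohortDesign, W: StandardizedMethylation,
             ann: Optional[ProbeAnnotation] = None) -> pd.DataFrame:
    """Initial linear-regression scan: per probe, OLS of y on [C, w_i]."""
    y = design.y
    X = design.design_matrix()
    n, p = X.shape
    Q, _ = np.linalg.qr(X)
    yr = y - Q @ (Q.T @ y)
    Wr = W.values - Q @ (Q.T @ W.values)
    denom = np.einsum("ij,ij->j", Wr, Wr)
    collinear = denom < n * 1e-12
    denom = np.where(collinear, np.nan, denom)
    numer = Wr.T @ yr
    b, se, pval = _per_probe_t(numer, denom, yr @ yr, n, p)
    tab = assoc_table(W.probe_ids, ann, b, se, pval, "OLS")
    tab.loc[collinear, ["se", "p"]] = np.nan
    return tab


def moa_scan(design: CohortDesign, W: StandardizedMethylation,
             ann: Optional[ProbeAnnotation] = None, *,
             variance: Optional[tuple[float, float]] = None) -> pd.DataFrame:
    """MOA: GLS of y on [C, w_i] under V = A sigma_o^2 + I sigma_e^2 fitted
    once from the all-probe model; the target stays in the random term."""
    y = design.y
    X = design.design_matrix()
    n, p = X.shape
    m = W.n_probes
    A = (W.values @ W.values.T) / m
    if variance is None:
        fit = reml(y, X, [A, np.eye(n)])
        so, se_r = fit.sigmas
    else:
        so, se_r = variance
    V = so * A + se_r * np.eye(n)
    c, low = sla.cho_factor(V, lower=True)
    Viy = sla.cho_solve((c, low), y)
    ViX = sla.cho_solve((c, low), X)
    XtViX_inv = np.linalg.inv(X.T @ ViX)
    beta = XtViX_inv @ (ViX.T @ y)
    My = Viy - ViX @ beta                      # P y, with P the GLS annihilator
    yMy = float(y @ My)
    ViW = sla.cho_solve((c, low), W.values)
    XtViW = ViX.T @ W.values                   # p x m
    MW_denom = (np.einsum("ij,ij->j", W.values, ViW)
                - np.einsum("ij,ij->j", XtViW, XtViX_inv @ XtViW))
    numer = W.values.T @ My
    collinear = MW_denom < n * 1e-12
    denom = np.where(collinear, np.nan, MW_denom)
    b, se, pval = _per_probe_t(numer, denom, yMy, n, p)
    tab = assoc_table(W.probe_ids, ann, b, se, pval, "MOA")
    tab.loc[collinear, ["se", "p"]] = np.nan
    return tab


@dataclass
class ProbePartition:
    """Assignment of probes to MOMENT's two random-effect components."""

    group: pd.Series          # 1 (initially associated) or 2, indexed by probe
    pvalues: pd.Series
    threshold: float

    @property
    def m1(self) -> int:
        return int((self.group == 1).sum())

    @property
    def m2(self) -> int:
        return int((self.group == 2).sum())


def partition_probes(initial: pd.DataFrame, threshold_p: float = 0.01) -> ProbePartition:
    """Split probes by their initial-scan p-value: group 1 below the
    threshold, group 2 the rest."""
    pv = pd.Series(initial["p"].to_numpy(), index=initial["Probe"].to_numpy())
    group = pd.Series(np.where(pv.to_numpy() < threshold_p, 1, 2), index=pv.index)
    group[pv.isna()] = 2
    return ProbePartition(group=group, pvalues=pv, threshold=threshold_p)


def window_exclusion(ann: ProbeAnnotation, probe_ids, target: str,
                     window_bp: int = 50_000) -> pd.Index:
    """Probes dropped from MOMENT's random components when testing
    ``target``: same chromosome and |bp difference| < window_bp (the target
    itself included)."""
    sub = ann.table.reindex(probe_ids)
    t = sub.loc[target]
    mask = ((sub["chrom"].astype(str) == str(t["chrom"]))
            & (np.abs(sub["bp"] - t["bp"]) < window_bp))
    return pd.Index(probe_ids)[mask.to_numpy()]


def moment_scan(design: CohortDesign, W: StandardizedMethylation,
                ann: ProbeAnnotation, partition: Optional[ProbePartition] = None,
                *, window_bp: int = 50_000,
                variance: Optional[MultiVarianceEstimate] = None) -> pd.DataFrame:
    """MOMENT: two-component mixed-model scan with all probes within
    ``window_bp`` of the target (same chromosome, |bp difference| <
    window_bp, target included) removed from both random components."""
    y = design.y
    X = design.design_matrix()
    n, p = X.shape
    Wv = W.values
    m = W.n_probes
    missing = W.probe_ids.difference(ann.probe_ids)
    if len(missing):
        raise KeyError(f"annotation missing tested probes: {missing[:5].tolist()}")

    if partition is None:
        partition = partition_probes(ols_scan(design, W, ann))
    group = partition.group.reindex(W.probe_ids).to_numpy()
    idx1 = np.nonzero(group == 1)[0]
    idx2 = np.nonzero(group == 2)[0]
    if len(idx1) == 0:
        warnings.warn("no probes pass the partition threshold; MOMENT "
                      "collapses to a single-component model", stacklevel=2)
    comps, comp_of, comp_m = [], np.zeros(m, dtype=int), []
    for gi, idx in enumerate(x for x in (idx1, idx2) if len(x)):
        Wg = Wv[:, idx]
        comps.append((Wg @ Wg.T) / len(idx))
        comp_of[idx] = gi
        comp_m.append(len(idx))
    if variance is None:
        variance = reml(y, X, comps + [np.eye(n)])
    sig = variance.sigmas
    V = sum(s * G for s, G in zip(sig[:-1], comps)) + sig[-1] * np.eye(n)

    c, low = sla.cho_factor(V, lower=True)
    Vi_y = sla.cho_solve((c, low), y)
    Vi_X = sla.cho_solve((c, low), X)
    Vi_W = sla.cho_solve((c, low), Wv)
    CtViC = X.T @ Vi_X
    CtViy = Vi_X.T @ y
    ytViy = float(y @ Vi_y)
    WtViy = Wv.T @ Vi_y
    WtViC = Wv.T @ Vi_X                      # m x p
    diagWtViW = np.einsum("ij,ij->j", Wv, Vi_W)

    # per-probe Woodbury scale: the down-dated weight of window probe j
    cj = np.array([sig[comp_of[j]] / comp_m[comp_of[j]] for j in range(m)])

    sub = ann.table.reindex(W.probe_ids)
    chrom = sub["chrom"].astype(str).to_numpy()
    bp = sub["bp"].to_numpy(dtype=np.int64)

    b = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    dof = n - p - 1
    weight_floor = 1e-12 * max(float(np.max(sig)), 1.0)
    for i in range(m):
        same = (chrom == chrom[i]) & (np.abs(bp - bp[i]) < window_bp)
        S = np.nonzero(same & (cj > weight_floor))[0]
        if len(S):
            U = Wv[:, S]
            ViU = Vi_W[:, S]
            G = U.T @ ViU                                    # k x k
            cS = cj[S]
            M = np.linalg.inv(np.diag(1.0 / cS) - G)
            UtViy = WtViy[S]
            UtViC = WtViC[S]                                 # k x p
            Utw = ViU.T @ Wv[:, i]                           # U'Vi w_i

            My_corr = M @ UtViy
            yy = ytViy + UtViy @ My_corr
            Cy = CtViy + UtViC.T @ My_corr
            CC = CtViC + UtViC.T @ (M @ UtViC)
            wy = WtViy[i] + Utw @ My_corr
            wC = WtViC[i] + Utw @ (M @ UtViC)
            ww = diagWtViW[i] + Utw @ (M @ Utw)
        else:
            yy, Cy, CC = ytViy, CtViy, CtViC
            wy, wC, ww = WtViy[i], WtViC[i], diagWtViW[i]

        Amat = np.empty((p + 1, p + 1))
        Amat[:p, :p] = CC
        Amat[:p, p] = wC
        Amat[p, :p] = wC
        Amat[p, p] = ww
        rhs = np.concatenate([Cy, [wy]])
        try:
            coef = np.linalg.solve(Amat, rhs)
            cov = np.linalg.inv(Amat)
        except np.linalg.LinAlgError:
            continue
        rss = yy - coef @ rhs
        s2 = max(rss, 0.0) / dof
        b[i] = coef[-1]
        se_i = np.sqrt(s2 * cov[-1, -1])
        if se_i > 0 and np.isfinite(se_i):
            se[i] = se_i
            t = b[i] / se_i
            pval[i] = 2.0 * stats.t.sf(abs(t), dof)
    return assoc_table(W.probe_ids, ann, b, se, pval, "MOMENT")


def genomic_inflation(records: pd.DataFrame | np.ndarray, min_records: int = 30) -> float:
    """lambda = median observed chi-square (from p) / 0.4549364."""
    p = (records["p"].to_numpy(dtype=float)
         if isinstance(records, pd.DataFrame) else np.asarray(records, dtype=float))
    p = p[np.isfinite(p)]
    if len(p) < min_records:
        raise ValueError(f"need at least {min_records} valid p-values")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)
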