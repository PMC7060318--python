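"""Reference-based blood cell-type deconvolution and the composition /
disease / medication analyses built on it.

Cell-type proportions (CTPs) are imputed per sample by constrained least
squares against a reference signature matrix (Houseman-style): minimize
``|| X_ref p - beta_sample ||^2`` subject to ``p >= 0``, followed by
normalization to sum to one. Disease associations are tested one cell type
at a time by logistic regression of case status on the cell type plus sex
and predicted age; granulocytes (eosinophils + neutrophils) are tested as a
composite. Levodopa-equivalent daily dose (LEDD) is midpoint-resolved,
log-transformed and standardized before correlation with CTPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import nnls

from .data import BLOOD_CELL_TYPES

GRANULOCYTE_PARTS = ("eos", "neu")

#: Cell types entered as covariates downstream; eosinophils are excluded to
#: avoid compositional collinearity.
COVARIATE_CELL_TYPES = tuple(t for t in BLOOD_CELL_TYPES if t != "eos")


@dataclass
class CellTypeReference:
    """Reference probes x cell types matrix of mean beta values."""

    signatures: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.signatures.to_numpy(dtype=float)
        if v.shape[1] < 2:
            raise ValueError("reference needs at least two cell types")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("reference signatures must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.signatures.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.signatures.index


def estimate_cell_proportions(betas: pd.DataFrame,
                              ref: CellTypeReference) -> pd.DataFrame:
    """Per-sample nonnegative least-squares deconvolution.

    ``betas``: samples x probes, must cover the reference probes. Returns a
    CTP table with one column per reference cell type plus a derived
    ``granulocyte`` column (eos + neu) when both parts are present.
    """
    missing = ref.probe_ids.difference(betas.columns)
    if len(missing):
        raise KeyError(f"sample matrix lacks reference probes: {missing[:5].tolist()}")
    X = ref.signatures.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("reference signature matrix is rank deficient")
    Y = betas.loc[:, ref.probe_ids].to_numpy(dtype=float)
    out = np.empty((len(Y), X.shape[1]))
    for i, y in enumerate(Y):
        p, _ = nnls(X, y)
        s = p.sum()
        out[i] = p / s if s > 0 else np.full_like(p, 1.0 / len(p))
    ctp = pd.DataFrame(out, index=betas.index, columns=ref.cell_types)
    if all(t in ctp.columns for t in GRANULOCYTE_PARTS):
        ctp["granulocyte"] = ctp[list(GRANULOCYTE_PARTS)].sum(axis=1)
    return ctp


def _logistic_wald(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """(beta, se, p) for the last column of X in a logistic model."""
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        return np.nan, np.nan, np.nan
    if not np.all(np.isfinite(fit.bse)) or fit.bse[-1] > 1e4:
        return fit.params[-1], np.nan, np.nan   # separation: flag p as NA
    return fit.params[-1], fit.bse[-1], fit.pvalues[-1]


def test_ctp_association(y: np.ndarray, ctp: pd.DataFrame,
                         covariates: pd.DataFrame,
                         cell_types: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Logistic regression of case status on each cell type separately,
    adjusted for the supplied covariates (sex and predicted age by default
    upstream). Returns effect, SE and Wald p per cell type."""
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype has no variation; association undefined")
    if cell_types is None:
        cell_types = [c for c in ctp.columns]
    base = np.column_stack([np.ones(len(y)), covariates.to_numpy(dtype=float)])
    rows = []
    for ct in cell_types:
        X = np.column_stack([base, ctp[ct].to_numpy(dtype=float)])
        b, se, p = _logistic_wald(y, X)
        rows.append({"cell_type": ct, "b": b, "se": se, "p": p})
    return pd.DataFrame(rows).set_index("cell_type")


@dataclass
class LEDDRecord:
    """Levodopa equivalent daily dose (mg/day), possibly given as a range."""

    sample_id: str
    value: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    disease_duration: Optional[float] = None
    processed: Optional[float] = None

    def raw(self) -> float:
        if self.value is not None:
            return float(self.value)
        if self.low is not None and self.high is not None:
            return (float(self.low) + float(self.high)) / 2.0   # range midpoint
        return np.nan


def preprocess_ledd(records: Sequence[LEDDRecord]) -> list[LEDDRecord]:
    """Resolve ranges to midpoints, natural-log transform (LEDD is
    right-skewed), then z-standardize over the non-missing values."""
    raw = np.array([r.raw() for r in records], dtype=float)
    obs = ~np.isnan(raw)
    if not obs.any():
        raise ValueError("no non-missing LEDD values")
    if (raw[obs] <= 0).any():
        raise ValueError("LEDD must be positive")
    logged = np.where(obs, np.log(np.where(obs, raw, 1.0)), np.nan)
    sd = np.nanstd(logged, ddof=1)
    if not sd > 0:
        raise ValueError("LEDD has zero variance; standardization undefined")
    z = (logged - np.nanmean(logged)) / sd
    out = []
    for r, v in zip(records, z):
        out.append(LEDDRecord(sample_id=r.sample_id, value=r.value, low=r.low,
                              high=r.high, disease_duration=r.disease_duration,
                              processed=None if np.isnan(v) else float(v)))
    return out


def correlate_ctp_ledd(ctp: pd.DataFrame, ledd: pd.Series,
                       adjust_for: Optional[pd.Series] = None,
                       cell_types: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Pearson correlation of each cell type with processed LEDD among
    cases, optionally residualizing both sides on disease duration first.
    The Bonferroni threshold for the number of types tested is attached."""
    if cell_types is None:
        cell_types = list(COVARIATE_CELL_TYPES)   # six tested types by default
    rows = []
    for ct in cell_types:
        x = ctp[ct].to_numpy(dtype=float)
        v = ledd.to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(v)
        if adjust_for is not None:
            d = adjust_for.to_numpy(dtype=float)
            ok &= np.isfinite(d)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 complete pairs for {ct}")
        xx, vv = x[ok], v[ok]
        if adjust_for is not None:
            D = np.column_stack([np.ones(ok.sum()), adjust_for.to_numpy(dtype=float)[ok]])
            xx = xx - D @ np.linalg.lstsq(D, xx, rcond=None)[0]
            vv = vv - D @ np.linalg.lstsq(D, vv, rcond=None)[0]
        r, p = stats.pearsonr(xx, vv)
        rows.append({"cell_type": ct, "r": r, "p": p, "n": int(ok.sum())})
    out = pd.DataFrame(rows).set_index("cell_type")
    out.attrs["bonferroni_threshold"] = 0.05 / len(cell_types)
    return out


def compare_exposure_extremes(y: np.ndarray, ctp: pd.DataFrame,
                              covariates: pd.DataFrame, ledd: pd.Series,
                              quantile: float = 0.10, min_stratum: int = 10
                              ) -> dict[str, pd.DataFrame]:
    """Case-control CTP contrasts restricted to the most vs least
    medication-exposed cases (top/bottom LEDD quantile), each compared with
    all controls. Similar estimates in the two strata argue against a
    medication-driven composition shift."""
    if not (0 < quantile <= 0.5):
        raise ValueError("quantile must be in (0, 0.5]")
    y = np.asarray(y, dtype=float).ravel()
    cases = (y == 1) & np.isfinite(ledd.to_numpy(dtype=float))
    controls = y == 0
    vals = ledd.to_numpy(dtype=float)
    lo, hi = (np.nanquantile(vals[cases], quantile),
              np.nanquantile(vals[cases], 1 - quantile))
    strata = {"bottom": cases & (vals <= lo), "top": cases & (vals >= hi)}
    out = {}
    for name, in_stratum in strata.items():
        if in_stratum.sum() < min_stratum:
            raise ValueError(f"{name} LEDD stratum has fewer than {min_stratum} cases")
        keep = in_stratum | controls
        out[name] = test_ctp_association(y[keep], ctp.loc[keep],
                                         covariates.loc[keep])
    return out
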