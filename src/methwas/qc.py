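"""Probe- and sample-level quality control, batch residualization and
probe standardization for Illumina-style beta-value matrices.

Filter battery (probe level, applied in this order):

1. detection rate — drop probes detected (detection p < ``detect_p``) in
   fewer than ``detect_rate_min`` of samples;
2. bead count — drop probes with any sample below ``min_beads`` beads;
3. cross-reactive probes (flagged in the annotation or an explicit id list);
4. sex-chromosome probes;
5. lowly variable probes (SD of beta < ``sd_min``).

Sample level: call rate, reported-vs-predicted sex mismatch, and median
methylated signal more than ``signal_sd`` SDs from the cohort median.

Batch structure (slide / sentrix row / column) is removed by regressing
each probe on one-hot batch indicators and keeping the residuals
(re-centred at the original probe mean). Functional/quantile normalization
against control probes is deliberately out of scope; batch residualization
is the explicit, testable replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import MethylationMatrix, ProbeAnnotation, StandardizedMethylation


@dataclass
class QCReport:
    """Per-filter removal counts, in order of application."""

    steps: list = field(default_factory=list)  # (filter name, n removed | None if skipped)
    skipped: list = field(default_factory=list)

    def add(self, name: str, removed: int) -> None:
        self.steps.append((name, removed))

    def skip(self, name: str, reason: str) -> None:
        self.skipped.append((name, reason))

    def removed(self, name: str) -> int:
        for step, n in self.steps:
            if step == name:
                return n
        raise KeyError(name)


def qc_probes(M: MethylationMatrix, ann: ProbeAnnotation, *,
              detect_rate_min: float = 0.95, detect_p: float = 0.01,
              min_beads: int = 3, sd_min: float = 0.02,
              cross_reactive_ids: Optional[Sequence[str]] = None,
              ) -> tuple[MethylationMatrix, QCReport]:
    """Apply the probe-level filter battery; returns the retained matrix
    and a report of removals per filter (skipped filters are recorded)."""
    report = QCReport()
    missing_ann = M.probe_ids.difference(ann.probe_ids)
    if len(missing_ann):
        raise KeyError(f"annotation missing probes present in the matrix: "
                       f"{missing_ann[:5].tolist()}")
    keep = M.probe_ids

    if M.detection_p is not None:
        rate = (M.detection_p.loc[:, keep] < detect_p).mean(axis=0)
        fail = keep[rate < detect_rate_min]
        report.add("detection_rate", len(fail))
        keep = keep.difference(fail, sort=False)
    else:
        report.skip("detection_rate", "no detection p-value layer")

    if M.beads is not None:
        fail = keep[(M.beads.loc[:, keep] < min_beads).any(axis=0)]
        report.add("bead_count", len(fail))
        keep = keep.difference(fail, sort=False)
    else:
        report.skip("bead_count", "no bead-count layer")

    flags = ann.table.reindex(keep)
    cross = flags["cross_reactive"].astype(bool)
    if cross_reactive_ids is not None:
        cross = cross | keep.isin(cross_reactive_ids)
    fail = keep[cross.to_numpy()]
    report.add("cross_reactive", len(fail))
    keep = keep.difference(fail, sort=False)

    flags = ann.table.reindex(keep)
    fail = keep[flags["sex_chromosome"].astype(bool).to_numpy()]
    report.add("sex_chromosome", len(fail))
    keep = keep.difference(fail, sort=False)

    sds = M.beta.loc[:, keep].std(axis=0, ddof=0)
    fail = keep[(sds < sd_min).to_numpy()]
    report.add("low_variance", len(fail))
    keep = keep.difference(fail, sort=False)

    if len(keep) == 0:
        raise ValueError("probe QC removed every probe")

    keep = M.probe_ids[M.probe_ids.isin(keep)]  # preserve input order
    out = MethylationMatrix(
        beta=M.beta.loc[:, keep],
        detection_p=None if M.detection_p is None else M.detection_p.loc[:, keep],
        beads=None if M.beads is None else M.beads.loc[:, keep],
        median_methylated=M.median_methylated,
        reported_sex=M.reported_sex,
        predicted_sex=M.predicted_sex,
    )
    return out, report


def qc_samples(M: MethylationMatrix, *,
               min_detected_probes: Optional[int] = None,
               min_detected_fraction: Optional[float] = None,
               callrate_p: float = 0.001, signal_sd: float = 3.0,
               ) -> tuple[MethylationMatrix, QCReport]:
    """Remove samples failing call-rate, sex-mismatch or signal-outlier
    checks. The absolute 450K-era call-rate threshold generalizes to
    ``min_detected_fraction`` of the matrix's probe count (default 0.927,
    the 450K ratio) so matrices of any size can use it."""
    report = QCReport()
    keep = M.sample_ids
    reasons: dict[str, list[str]] = {}

    if M.detection_p is not None:
        if min_detected_probes is None:
            frac = 0.927 if min_detected_fraction is None else min_detected_fraction
            min_detected_probes = int(np.ceil(frac * M.n_probes))
        detected = (M.detection_p < callrate_p).sum(axis=1)
        fail = keep[(detected < min_detected_probes).to_numpy()]
        reasons["call_rate"] = fail.tolist()
        report.add("call_rate", len(fail))
        keep = keep.difference(fail, sort=False)
    else:
        report.skip("call_rate", "no detection p-value layer")

    if M.reported_sex is not None and M.predicted_sex is not None:
        mism = M.reported_sex.loc[keep] != M.predicted_sex.loc[keep]
        fail = keep[mism.to_numpy()]
        reasons["sex_mismatch"] = fail.tolist()
        report.add("sex_mismatch", len(fail))
        keep = keep.difference(fail, sort=False)
    else:
        report.skip("sex_mismatch", "reported or predicted sex unavailable")

    if M.median_methylated is not None:
        sig = M.median_methylated.loc[keep]
        centre, sd = sig.median(), sig.std(ddof=1)
        if sd > 0:
            fail = keep[(np.abs(sig - centre) > signal_sd * sd).to_numpy()]
        else:
            fail = keep[:0]
        reasons["signal_outlier"] = fail.tolist()
        report.add("signal_outlier", len(fail))
        keep = keep.difference(fail, sort=False)
    else:
        report.skip("signal_outlier", "no median-signal layer")

    if len(keep) == 0:
        raise ValueError("sample QC removed every sample")
    report.steps.append(("reasons", reasons))

    keep = M.sample_ids[M.sample_ids.isin(keep)]
    out = MethylationMatrix(
        beta=M.beta.loc[keep],
        detection_p=None if M.detection_p is None else M.detection_p.loc[keep],
        beads=None if M.beads is None else M.beads.loc[keep],
        median_methylated=None if M.median_methylated is None else M.median_methylated.loc[keep],
        reported_sex=None if M.reported_sex is None else M.reported_sex.loc[keep],
        predicted_sex=None if M.predicted_sex is None else M.predicted_sex.loc[keep],
    )
    return out, report


def residualize_batch(M: MethylationMatrix,
                      batch_factors: pd.DataFrame) -> MethylationMatrix:
    """Regress each probe on one-hot batch indicators (slide/row/column,
    any categorical factors) and keep residuals re-centred at the original
    probe mean. Residual values may leave [0, 1]; downstream modelling uses
    standardized values, so the container check is bypassed on purpose."""
    if not M.sample_ids.equals(pd.Index(batch_factors.index)):
        batch_factors = batch_factors.loc[M.sample_ids]
    cols = []
    for name in batch_factors.columns:
        levels = batch_factors[name].astype("category")
        if len(levels.cat.categories) < 2:
            raise ValueError(f"batch factor {name!r} has a single level; "
                             "it is confounded with the intercept")
        cols.append(pd.get_dummies(levels, prefix=name, drop_first=True))
    X = np.column_stack([np.ones(M.n_samples)] +
                        [c.to_numpy(dtype=float) for c in cols])
    B = M.beta.to_numpy(dtype=float)
    if np.isnan(B).any():
        raise ValueError("residualize_batch requires a complete matrix; "
                         "impute or filter missing values first")
    coef, *_ = np.linalg.lstsq(X, B, rcond=None)
    resid = B - X @ coef
    resid += B.mean(axis=0, keepdims=True)
    out = MethylationMatrix.__new__(MethylationMatrix)
    out.beta = pd.DataFrame(resid, index=M.sample_ids, columns=M.probe_ids)
    out.detection_p = M.detection_p
    out.beads = M.beads
    out.median_methylated = M.median_methylated
    out.reported_sex = M.reported_sex
    out.predicted_sex = M.predicted_sex
    return out


def standardize_probes(M: MethylationMatrix | pd.DataFrame) -> StandardizedMethylation:
    """Column-standardize to mean 0, population (1/n) variance 1.

    Missing values are mean-imputed before scaling (count reported on the
    result). Constant probes are an error — filter them with qc_probes.
    """
    beta = M.beta if isinstance(M, MethylationMatrix) else M
    B = beta.to_numpy(dtype=float).copy()
    means = np.nanmean(B, axis=0)
    nan_mask = np.isnan(B)
    n_imputed = int(nan_mask.sum())
    if n_imputed:
        B[nan_mask] = np.take(means, np.nonzero(nan_mask)[1])
    sds = B.std(axis=0, ddof=0)
    if (sds <= 0).any():
        bad = beta.columns[sds <= 0].tolist()
        raise ValueError(f"constant probes cannot be standardized: {bad[:5]}")
    W = (B - means) / sds
    return StandardizedMethylation(values=W, sample_ids=beta.index,
                                   probe_ids=beta.columns, means=means,
                                   sds=sds, n_imputed=n_imputed)
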