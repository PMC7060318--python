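"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Methylation beta matrices are pandas DataFrames with **samples as rows**
  and **probes as columns**; on disk the transpose is stored (probes as rows)
  because cohorts have far more probes than samples.
* All genomic positions held in memory are 1-based (Illumina manifest
  convention); the BED-like files on disk are 0-based half-open.
* Standardization always uses the population (1/n) variance so that the
  omics relationship matrix ``A = WW'/m`` has mean diagonal exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Leukocyte types resolved by the blood reference, in canonical order.
BLOOD_CELL_TYPES = ("B", "CD4T", "CD8T", "NK", "mono", "eos", "neu")

#: Column order of every association table written by the scans.
ASSOC_COLUMNS = ("Chr", "Probe", "bp", "Gene", "b", "se", "p", "method")


@dataclass
class MethylationMatrix:
    """Sample x probe beta-value matrix with optional QC layers.

    beta values live in [0, 1] where observed; NaN marks missing entries.
    Optional layers (detection p-values, bead counts, per-sample signal
    summaries, reported/predicted sex) enable the corresponding QC filters;
    filters whose layer is absent are skipped and reported as such.
    """

    beta: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    beads: Optional[pd.DataFrame] = None
    median_methylated: Optional[pd.Series] = None
    reported_sex: Optional[pd.Series] = None
    predicted_sex: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("beta values must lie in [0, 1]")
        for name in ("detection_p", "beads"):
            layer = getattr(self, name)
            if layer is not None and layer.shape != self.beta.shape:
                raise ValueError(f"layer {name!r} shape {layer.shape} does not "
                                 f"match beta shape {self.beta.shape}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]


@dataclass
class ProbeAnnotation:
    """Genomic annotation for probes: chromosome, 1-based bp, gene, flags."""

    table: pd.DataFrame  # index: probe id; columns: chrom, bp, gene, cross_reactive, sex_chromosome

    REQUIRED = ("chrom", "bp")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"annotation missing column {col!r}")
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids in annotation: {dups[:5]}")
        if (t["bp"] <= 0).any():
            raise ValueError("probe positions must be positive (1-based)")
        for col, default in (("gene", ""), ("cross_reactive", False),
                             ("sex_chromosome", None)):
            if col not in t.columns:
                if col == "sex_chromosome":
                    chroms = t["chrom"].astype(str).str.removeprefix("chr")
                    t[col] = chroms.isin(["X", "Y"])
                else:
                    t[col] = default

    def subset(self, probe_ids: Sequence[str]) -> "ProbeAnnotation":
        missing = [p for p in probe_ids if p not in self.table.index]
        if missing:
            raise KeyError(f"annotation missing probes: {missing[:5]}")
        return ProbeAnnotation(self.table.loc[list(probe_ids)].copy())

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class StandardizedMethylation:
    """Column-standardized methylation matrix W (population 1/n variance)."""

    values: np.ndarray           # n samples x m probes, float64
    sample_ids: pd.Index
    probe_ids: pd.Index
    means: np.ndarray            # per-probe means used
    sds: np.ndarray              # per-probe population SDs used
    n_imputed: int = 0           # missing entries mean-imputed prior to scaling

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.probe_ids)


@dataclass
class CohortDesign:
    """Phenotype and fixed covariates, row-aligned to the methylation matrix.

    ``covariates`` excludes the intercept; :meth:`design_matrix` prepends it.
    """

    y: np.ndarray                 # 0/1 per sample
    covariates: pd.DataFrame      # n x (p-1), numeric
    sample_ids: pd.Index
    metadata: Optional[pd.DataFrame] = None  # batch labels, LEDD, duration, ...

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if len(self.y) != len(self.covariates):
            raise ValueError("y and covariate rows misaligned")
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("phenotype must be coded 0/1")
        C = self.design_matrix()
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("covariate matrix is rank deficient")

    def design_matrix(self) -> np.ndarray:
        C = self.covariates.to_numpy(dtype=float)
        return np.column_stack([np.ones(len(self.y)), C])

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class OmicsRelationshipMatrix:
    """A = WW'/m over standardized probes; methylation analogue of a GRM."""

    A: np.ndarray
    m: int
    sample_ids: pd.Index

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("ORM requires at least one probe (m > 0)")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("ORM must be symmetric")


@dataclass
class VarianceEstimate:
    """REML variance components for the single-ORM (OREML) model."""

    sigma_o: float
    sigma_e: float
    rho2: float
    se_sigma_o: float
    se_sigma_e: float
    se_rho2: float
    loglik: float
    n_iter: int
    converged: bool
    clamped: bool
    p_rho2: Optional[float] = None   # 0.5*chi2_0 + 0.5*chi2_1 mixture LRT vs sigma_o = 0
    history: list = field(default_factory=list)


@dataclass
class MultiVarianceEstimate:
    """REML fit with several variance components (MOMENT two-group model)."""

    sigmas: np.ndarray            # component variances, residual last
    cov_sigmas: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    clamped: bool
    history: list = field(default_factory=list)


@dataclass
class BLUPEffects:
    """Best linear unbiased prediction solutions for all probe effects."""

    u: pd.Series                  # indexed by probe id
    sigma_o: float
    sigma_e: float
    probe_means: pd.Series
    probe_sds: pd.Series

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.u.to_numpy())):
            raise ValueError("BLUP solutions must be finite")


def assoc_table(probe_ids, ann: Optional[ProbeAnnotation], b, se, p,
                method: str) -> pd.DataFrame:
    """Assemble an association table in the fixed output column order."""
    probe_ids = pd.Index(probe_ids)
    if ann is not None:
        sub = ann.table.reindex(probe_ids)
        chrom = sub["chrom"].to_numpy()
        bp = sub["bp"].to_numpy()
        gene = sub["gene"].fillna("").to_numpy()
    else:
        chrom = np.full(len(probe_ids), "", dtype=object)
        bp = np.zeros(len(probe_ids), dtype=int)
        gene = np.full(len(probe_ids), "", dtype=object)
    return pd.DataFrame({
        "Chr": chrom, "Probe": probe_ids.to_numpy(), "bp": bp, "Gene": gene,
        "b": np.asarray(b, dtype=float), "se": np.asarray(se, dtype=float),
        "p": np.asarray(p, dtype=float), "method": method,
    }, columns=list(ASSOC_COLUMNS))
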