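"""Synthetic methylation cohorts, blood cell-type references and cis-QTL
summary-statistic trios with the statistical structure the downstream
analysis assumes.

Generative model for a cohort
-----------------------------
Each probe's logit-scale signal for sample *s* is

    x_sp = logit( sum_k P_sk * B_pk ) + batch_sp + delta_sp + eps_sp

where ``P`` are per-sample leukocyte proportions (Dirichlet), ``B`` are
cell-type-specific probe signatures on the beta scale, ``batch`` are
slide/row/column effects, ``delta`` is intrinsic person-to-person variation
and ``eps`` is measurement noise. Observed beta values are ``expit(x)``,
hence always in [0, 1].

Case-control status follows a liability-threshold model. The liability's
"methylomic" component is a weighted sum of the *measured*, standardized
causal-probe values, rescaled so its sample variance matches the target
exactly; with a Gaussian genetic value and a threshold at quantile 1-K,
the linear (observed-scale) variance explained equals
``h2_liability * z^2 / (K (1-K))`` exactly, so the generator inverts that
relation: the configured ``liability_variance_explained`` is the
observed-scale fraction that a linear mixed model estimates.

All randomness flows from a single seed through named substreams, so
adding a component does not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .celltypes import CellTypeReference
from .data import BLOOD_CELL_TYPES, CohortDesign, MethylationMatrix, ProbeAnnotation

_BASE_PROPORTIONS = {  # typical adult whole blood
    "B": 0.05, "CD4T": 0.15, "CD8T": 0.10, "NK": 0.07,
    "mono": 0.08, "eos": 0.03, "neu": 0.52,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from (seed, component name)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def default_celltype_alpha(concentration: float = 60.0,
                           shift: Optional[dict[str, float]] = None) -> dict[str, float]:
    """Dirichlet parameters around typical blood composition; ``shift`` adds
    to the *mean proportion* of named types (renormalized) before scaling."""
    props = dict(_BASE_PROPORTIONS)
    if shift:
        for k, v in shift.items():
            props[k] = props[k] + v
        total = sum(props.values())
        props = {k: v / total for k, v in props.items()}
    return {k: v * concentration for k, v in props.items()}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 500
    n_probes: int = 2000
    n_chromosomes: int = 22
    probe_spacing_bp: float = 100_000.0     # mean of exponential inter-probe gaps
    n_causal_probes: int = 50
    liability_variance_explained: float = 0.3   # observed (0/1) scale
    covariate_variance_explained: float = 0.05  # liability scale
    case_fraction: float = 0.5
    celltype_alpha_controls: dict = field(default_factory=default_celltype_alpha)
    celltype_alpha_cases: Optional[dict] = None  # None -> same as controls
    n_slides: int = 8
    n_rows: int = 6
    n_columns: int = 2
    batch_sd: float = 0.1        # logit-scale SD of per-(level, probe) effects
    probe_mean_sd: float = 1.2   # logit-scale spread of probe baselines
    signature_sd: float = 2.0    # logit-scale separation at discriminative probes
    signature_fraction: float = 0.15  # fraction of probes that discriminate cell types
    intrinsic_sd: float = 0.8    # logit-scale person-to-person variation
    noise_sd: float = 0.15       # logit-scale measurement noise
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_probes <= 0:
            raise ValueError("sample and probe counts must be positive")
        if not (0 <= self.liability_variance_explained < 1):
            raise ValueError("liability_variance_explained must be in [0, 1)")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0, 1)")
        if self.n_causal_probes > self.n_probes:
            raise ValueError("n_causal_probes cannot exceed n_probes")
        if self.n_causal_probes < 0:
            raise ValueError("n_causal_probes must be non-negative")
        for grp in (self.celltype_alpha_controls, self.celltype_alpha_cases):
            if grp is not None and any(a <= 0 for a in grp.values()):
                raise ValueError("Dirichlet parameters must be strictly positive")
        if self.noise_sd < 0 or self.batch_sd < 0 or self.intrinsic_sd < 0:
            raise ValueError("effect SDs must be non-negative")
        if not (0 <= self.signature_fraction <= 1):
            raise ValueError("signature_fraction must be in [0, 1]")
        K = self.case_fraction
        z2 = norm.pdf(norm.ppf(1 - K)) ** 2
        h2_lia = self.liability_variance_explained * K * (1 - K) / z2
        if h2_lia + self.covariate_variance_explained >= 1:
            raise ValueError(
                "configured variance fractions exceed the liability variance; "
                f"liability-scale methylomic fraction is {h2_lia:.3f}")

    @property
    def h2_liability(self) -> float:
        K = self.case_fraction
        z2 = norm.pdf(norm.ppf(1 - K)) ** 2
        return self.liability_variance_explained * K * (1 - K) / z2


@dataclass
class TruthRecord:
    """Ground truth saved alongside a simulated cohort."""

    causal_probes: pd.Index
    causal_effects: pd.Series          # liability weights on standardized probes
    ctp: pd.DataFrame                  # true per-sample proportions
    batch: pd.DataFrame                # slide/row/column assignments
    rho2_true: float                   # observed-scale variance fraction
    h2_liability: float
    signatures: pd.DataFrame           # probe x cell type beta signatures
    liability: pd.Series

    def __post_init__(self) -> None:
        if not (0 <= self.rho2_true <= 1):
            raise ValueError("rho2_true must be in [0, 1]")


def _probe_annotation(cfg: SimulationConfig, rng: np.random.Generator) -> ProbeAnnotation:
    chrom_of = np.sort(rng.integers(1, cfg.n_chromosomes + 1, size=cfg.n_probes))
    bp = np.empty(cfg.n_probes, dtype=np.int64)
    for c in range(1, cfg.n_chromosomes + 1):
        idx = np.nonzero(chrom_of == c)[0]
        gaps = rng.exponential(cfg.probe_spacing_bp, size=len(idx))
        bp[idx] = 1 + np.cumsum(np.maximum(1, np.round(gaps))).astype(np.int64)
    ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    table = pd.DataFrame({
        "chrom": chrom_of.astype(str), "bp": bp,
        "gene": [f"G{i // 10}" for i in range(cfg.n_probes)],
        "cross_reactive": False, "sex_chromosome": False,
    }, index=pd.Index(ids, name="probe"))
    return ProbeAnnotation(table)


@dataclass
class CohortArchitecture:
    """Probe map, cell signatures and causal architecture shared between
    cohorts of one study (discovery and replication see the same truth)."""

    annotation: ProbeAnnotation
    signatures: np.ndarray         # m x K beta-scale cell signatures
    causal_idx: np.ndarray         # column indices of causal probes
    u_direction: np.ndarray        # unscaled liability weights


def draw_architecture(config: SimulationConfig,
                      seed: Optional[int] = None) -> CohortArchitecture:
    cfg = config
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    K = len(BLOOD_CELL_TYPES)
    ann = _probe_annotation(cfg, substream(seed, "annotation"))
    rng = substream(seed, "signatures")
    mu = rng.normal(0.0, cfg.probe_mean_sd, size=cfg.n_probes)
    # only a subset of probes discriminates cell types, as on real arrays
    disc = rng.uniform(size=cfg.n_probes) < cfg.signature_fraction
    dev = rng.normal(0.0, cfg.signature_sd, size=(cfg.n_probes, K))
    sig_logit = mu[:, None] + dev * disc[:, None]
    rng = substream(seed, "causal")
    causal_idx = np.sort(rng.choice(cfg.n_probes, size=cfg.n_causal_probes,
                                    replace=False))
    u_dir = rng.normal(size=cfg.n_causal_probes)
    return CohortArchitecture(annotation=ann, signatures=expit(sig_logit),
                              causal_idx=causal_idx, u_direction=u_dir)


def simulate_methylation_cohort(config: SimulationConfig,
                                architecture: Optional[CohortArchitecture] = None
                                ) -> tuple[MethylationMatrix, CohortDesign, TruthRecord, ProbeAnnotation]:
    """Generate one cohort: beta matrix, design, ground truth, annotation.

    Pass a shared ``architecture`` to give several cohorts the same probe
    map, cell signatures and causal probes (a discovery/replication pair).
    """
    cfg = config
    cfg.validate()
    n, m = cfg.n_samples, cfg.n_probes
    types = list(BLOOD_CELL_TYPES)
    K = len(types)

    arch = architecture if architecture is not None else draw_architecture(cfg)
    if arch.signatures.shape[0] != m:
        raise ValueError("architecture probe count does not match config")
    ann = arch.annotation
    B_sig = arch.signatures                                    # m x K

    alpha_c = np.array([cfg.celltype_alpha_controls[t] for t in types])
    rng = substream(cfg.seed, "ctp")
    P = rng.dirichlet(alpha_c, size=n)                         # n x K

    rng = substream(cfg.seed, "batch")
    batch = pd.DataFrame({
        "slide": rng.integers(cfg.n_slides, size=n),
        "row": rng.integers(cfg.n_rows, size=n),
        "column": rng.integers(cfg.n_columns, size=n),
    }, index=[f"c{cfg.seed}s{i:05d}" for i in range(n)])
    batch_mat = np.zeros((n, m))
    if cfg.batch_sd > 0:
        for fac, n_lev in (("slide", cfg.n_slides), ("row", cfg.n_rows),
                           ("column", cfg.n_columns)):
            eff = rng.normal(0.0, cfg.batch_sd, size=(n_lev, m))
            batch_mat += eff[batch[fac].to_numpy()]

    rng = substream(cfg.seed, "covariates")
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.normal(65.0, 8.0, size=n)
    smoking = rng.normal(0.0, 1.0, size=n)

    delta = substream(cfg.seed, "intrinsic").normal(0.0, cfg.intrinsic_sd, size=(n, m))
    eps = substream(cfg.seed, "noise").normal(0.0, cfg.noise_sd, size=(n, m))

    def assemble(P_now: np.ndarray) -> np.ndarray:
        mix = P_now @ B_sig.T                                  # n x m, in (0, 1)
        return expit(logit(np.clip(mix, 1e-12, 1 - 1e-12)) + batch_mat + delta + eps)

    beta = assemble(P)

    # liability on the measured causal probes, net of batch and composition
    # (the disease-relevant intra-cell-type signal), exact variance fractions
    rng = substream(cfg.seed, "liability")
    causal = pd.Index(arch.causal_idx)
    causal_ids = ann.probe_ids[causal]
    h2 = cfg.h2_liability
    u = np.zeros(cfg.n_causal_probes)
    g = np.zeros(n)
    if cfg.n_causal_probes > 0 and h2 > 0:
        nuis = [np.ones(n)]
        for fac, n_lev in (("slide", cfg.n_slides), ("row", cfg.n_rows),
                           ("column", cfg.n_columns)):
            lab = batch[fac].to_numpy()
            nuis.extend((lab == lev).astype(float) for lev in range(1, n_lev))
        nuis.append(P[:, :-1])  # composition (drop one type: sums to 1)
        D = np.column_stack([np.atleast_2d(a).T if a.ndim == 1 else a for a in nuis])
        Wc = beta[:, causal]
        Wc = Wc - D @ np.linalg.lstsq(D, Wc, rcond=None)[0]
        Wc = (Wc - Wc.mean(0)) / Wc.std(0, ddof=0)
        u = arch.u_direction.astype(float)
        g_raw = Wc @ u
        scale = np.sqrt(h2) / g_raw.std(ddof=0)
        g, u = g_raw * scale, u * scale

    # components orthogonalized in sample so the realized fractions (and the
    # total liability variance of 1) are exact, not just in expectation
    def _orth_scale(x, others, target_var):
        if target_var <= 0:
            return np.zeros(n)
        D = np.column_stack([np.ones(n)] + others)
        r = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
        return r / r.std(ddof=0) * np.sqrt(target_var)

    v_cov = cfg.covariate_variance_explained
    cov_part = np.zeros(n)
    if v_cov > 0:
        raw = (0.4 * (sex - sex.mean()) / max(sex.std(ddof=0), 1e-12)
               - 0.3 * (age - age.mean()) / age.std(ddof=0)
               + 0.3 * (smoking - smoking.mean()) / smoking.std(ddof=0))
        cov_part = _orth_scale(raw, [g], v_cov)
    e = _orth_scale(rng.normal(size=n), [g, cov_part],
                    max(1.0 - h2 - v_cov, 1e-12))
    liability = g + cov_part + e
    thr = np.quantile(liability, 1 - cfg.case_fraction)
    y = (liability > thr).astype(float)

    # disease -> composition shift (reverse causation): redraw case CTPs
    if cfg.celltype_alpha_cases is not None:
        alpha_a = np.array([cfg.celltype_alpha_cases[t] for t in types])
        rng2 = substream(cfg.seed, "ctp_cases")
        case_idx = np.nonzero(y == 1)[0]
        P[case_idx] = rng2.dirichlet(alpha_a, size=len(case_idx))
        beta = assemble(P)

    sample_ids = pd.Index(batch.index, name="sample")
    M = MethylationMatrix(beta=pd.DataFrame(beta, index=sample_ids,
                                            columns=ann.probe_ids))
    # LEDD (mg/day) and disease duration for cases only
    rng = substream(cfg.seed, "ledd")
    duration = np.where(y == 1, rng.gamma(2.0, 3.0, size=n), np.nan)
    ledd = np.where(y == 1, np.exp(np.log(300.0) + 0.08 * duration
                                   + rng.normal(0.0, 0.4, size=n)), np.nan)
    meta = batch.copy()
    meta.index = sample_ids
    meta["ledd"] = ledd
    meta["disease_duration"] = duration

    design = CohortDesign(
        y=y,
        covariates=pd.DataFrame({"sex": sex, "age": age, "smoking": smoking},
                                index=sample_ids),
        sample_ids=sample_ids,
        metadata=meta,
    )
    truth = TruthRecord(
        causal_probes=causal_ids,
        causal_effects=pd.Series(u, index=causal_ids),
        ctp=pd.DataFrame(P, index=sample_ids, columns=types),
        batch=batch.set_index(sample_ids),
        rho2_true=cfg.liability_variance_explained,
        h2_liability=h2,
        signatures=pd.DataFrame(B_sig, index=ann.probe_ids, columns=types),
        liability=pd.Series(liability, index=sample_ids),
    )
    return M, design, truth, ann


def simulate_celltype_reference(n_celltypes: int = 7, n_reference_probes: int = 100,
                                separation: float = 1.5, seed: int = 0) -> CellTypeReference:
    """Reference mean-methylation signatures with per-type separation
    (logit-scale SD). ``separation = 0`` yields identical columns."""
    if n_celltypes < 2:
        raise ValueError("need at least 2 cell types")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if n_reference_probes < n_celltypes:
        raise ValueError("need at least as many reference probes as cell types")
    rng = substream(seed, "celltype_reference")
    names = (list(BLOOD_CELL_TYPES) if n_celltypes == 7
             else [f"CT{k + 1}" for k in range(n_celltypes)])
    mu = rng.normal(0.0, 1.0, size=n_reference_probes)
    dev = rng.normal(0.0, 1.0, size=(n_reference_probes, n_celltypes)) * separation
    ref = expit(mu[:, None] + dev)
    ids = pd.Index([f"ref{i:05d}" for i in range(n_reference_probes)], name="probe")
    return CellTypeReference(signatures=pd.DataFrame(ref, index=ids, columns=names))


# ---------------------------------------------------------------------------
# cis-QTL summary-statistic trios for SMR / HEIDI
# ---------------------------------------------------------------------------

SCENARIOS = ("shared_causal", "linkage_two_causal")


@dataclass
class TrioConfig:
    """Cis-window architecture for a (mQTL, eQTL, GWAS) summary trio."""

    n_snps: int = 30
    n_ref: int = 500              # LD reference panel size
    start_bp: int = 1_000_000
    snp_spacing_bp: int = 5_000
    ld_rho: float = 0.9           # AR(1) latent LD decay per adjacent SNP
    maf_range: tuple = (0.1, 0.5)
    b_zx: float = 0.5             # SNP -> methylation (standardized scales)
    b_xw: float = -0.4            # methylation -> expression
    b_wy: float = 0.0             # expression -> trait
    linkage_r: float = 0.5        # LD between the two causal SNPs (linkage scenario)
    n_mqtl: int = 20_000
    n_eqtl: int = 20_000
    n_gwas: int = 100_000
    probe_bp: int = 1_050_000
    gene_tss: int = 1_100_000


@dataclass
class SummaryTrioTruth:
    causal_snps: list
    b_zx: float
    b_xw: float
    b_wy: float
    ld: np.ndarray                # true cis-window LD correlation matrix

    def __post_init__(self) -> None:
        R = self.ld
        if not np.allclose(R, R.T, atol=1e-10) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("LD matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValueError("LD matrix must be positive semi-definite")


def _marginal_summary(beta_joint: np.ndarray, R: np.ndarray, L: np.ndarray,
                      n: int, rng: np.random.Generator,
                      snps: pd.DataFrame) -> pd.DataFrame:
    """Marginal GWAS-style summary statistics: bhat ~ N(R b_joint, R/n)."""
    bhat = R @ beta_joint + (L @ rng.normal(size=len(beta_joint))) / np.sqrt(n)
    se = np.full(len(beta_joint), 1.0 / np.sqrt(n))
    z = bhat / se
    out = snps.copy()
    out["b"], out["se"], out["p"], out["N"] = bhat, se, 2 * norm.sf(np.abs(z)), n
    return out


def simulate_summary_trio(config: TrioConfig, scenario: str = "shared_causal",
                          seed: int = 0):
    """Generate (mQTL, eQTL, GWAS) summary sets, an LD reference and truth.

    ``shared_causal``: one variant drives methylation, which drives
    expression, which (optionally) drives the trait — all three summary sets
    reflect the same causal variant. ``linkage_two_causal``: methylation and
    expression have *distinct* causal variants in LD ``linkage_r``, the
    configuration HEIDI is designed to flag.
    """
    from .smr import LDReference

    cfg = config
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if cfg.n_snps < 2:
        raise ValueError("cis window must contain at least 2 SNPs")

    m = cfg.n_snps
    R = cfg.ld_rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    L = np.linalg.cholesky(R + 1e-10 * np.eye(m))

    rng = substream(seed, "trio_snps")
    positions = cfg.start_bp + cfg.snp_spacing_bp * np.arange(m)
    freqs = rng.uniform(*cfg.maf_range, size=m)
    alleles = np.array(list("ACGT"))
    a_idx = rng.integers(0, 4, size=m)
    b_idx = (a_idx + rng.integers(1, 4, size=m)) % 4
    snps = pd.DataFrame({
        "SNP": [f"rs{i + 1:06d}" for i in range(m)],
        "A1": alleles[a_idx], "A2": alleles[b_idx], "freq": freqs,
    })

    c1 = m // 2
    beta_zx = np.zeros(m)
    beta_zx[c1] = cfg.b_zx
    if scenario == "shared_causal":
        causal = [snps.loc[c1, "SNP"]]
        beta_zw = beta_zx * cfg.b_xw                 # mediated through methylation
    else:
        lag = max(1, int(round(np.log(cfg.linkage_r) / np.log(cfg.ld_rho))))
        c2 = min(m - 1, c1 + lag)
        causal = [snps.loc[c1, "SNP"], snps.loc[c2, "SNP"]]
        beta_zw = np.zeros(m)
        beta_zw[c2] = cfg.b_xw                       # distinct causal variant
    beta_zy = beta_zw * cfg.b_wy

    mqtl = _marginal_summary(beta_zx, R, L, cfg.n_mqtl, substream(seed, "trio_mqtl"), snps)
    eqtl = _marginal_summary(beta_zw, R, L, cfg.n_eqtl, substream(seed, "trio_eqtl"), snps)
    gwas = _marginal_summary(beta_zy, R, L, cfg.n_gwas, substream(seed, "trio_gwas"), snps)

    # LD reference panel: imputed-style continuous dosages with LD exactly R
    rng = substream(seed, "trio_panel")
    Z = rng.normal(size=(cfg.n_ref, m)) @ L.T
    dosage = 2 * freqs + np.sqrt(2 * freqs * (1 - freqs)) * Z
    ld = LDReference(snp_ids=snps["SNP"].tolist(), genotypes=dosage,
                     positions=positions)
    truth = SummaryTrioTruth(causal_snps=causal, b_zx=cfg.b_zx,
                             b_xw=cfg.b_xw, b_wy=cfg.b_wy, ld=R)
    return {"mqtl": mqtl, "eqtl": eqtl, "gwas": gwas}, ld, truth
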