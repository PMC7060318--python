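"""Shared fixtures: small seeded synthetic cohorts and helpers."""

import numpy as np
import pandas as pd
import pytest

import methwas as mw


def make_design(cohort, truth, *, with_ctp=True, covariates=None):
    """Assemble the analysis design: sex/age/smoking plus (true) CTPs
    without eosinophils, mirroring the study's fixed-effect set."""
    design = cohort
    cov = design.covariates if covariates is None else covariates
    if with_ctp:
        cov = cov.join(truth.ctp[[c for c in truth.ctp.columns if c != "eos"]])
    return mw.CohortDesign(y=design.y, covariates=cov,
                           sample_ids=design.sample_ids,
                           metadata=design.metadata)


def prepared_cohort(cfg, architecture=None):
    """Simulate, residualize batch and standardize; returns the pieces
    downstream tests need."""
    M, design, truth, ann = mw.simulate_methylation_cohort(cfg, architecture)
    M = mw.residualize_batch(M, design.metadata[["slide", "row", "column"]])
    W = mw.standardize_probes(M)
    return M, make_design(design, truth), truth, ann, W


@pytest.fixture(scope="session")
def small_cohort():
    """n=150, m=300 cohort with signal, reused across read-only tests."""
    cfg = mw.SimulationConfig(n_samples=150, n_probes=300, n_causal_probes=20,
                              seed=7)
    return prepared_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No causal probes, no composition difference: fully null phenotype."""
    cfg = mw.SimulationConfig(n_samples=150, n_probes=300, n_causal_probes=0,
                              liability_variance_explained=0.0, seed=11)
    return prepared_cohort(cfg)


@pytest.fixture
def toy_beta():
    """Tiny handmade beta matrix (4 samples x 5 probes)."""
    rng = np.random.default_rng(5)
    beta = pd.DataFrame(rng.uniform(0.1, 0.9, size=(4, 5)),
                        index=[f"s{i}" for i in range(4)],
                        columns=[f"p{j}" for j in range(5)])
    return beta


def toy_annotation(probe_ids, chrom="1", start_bp=1_000_000, spacing=200_000):
    bp = start_bp + spacing * np.arange(len(probe_ids))
    return mw.ProbeAnnotation(pd.DataFrame(
        {"chrom": chrom, "bp": bp, "gene": "", "cross_reactive": False,
         "sex_chromosome": False}, index=pd.Index(probe_ids, name="probe")))
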