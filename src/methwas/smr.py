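"""Summary-data-based Mendelian randomization (SMR) and the HEIDI test.

SMR estimates the effect of an exposure (methylation or expression) on an
outcome from summary statistics only, instrumenting with the top cis-QTL:
``b_xy = b_zy / b_zx`` with the test statistic
``chi2_SMR = z_zy^2 z_zx^2 / (z_zy^2 + z_zx^2)`` on 1 df.

HEIDI (heterogeneity in dependent instruments) asks whether the ratio
estimate is constant across cis-SNPs in LD with the instrument: under a
single shared causal variant every SNP yields the same b_xy, whereas two
distinct causal variants in linkage produce heterogeneous ratios. The
statistic sums squared standardized deviations ``d_i = b_xy(i) -
b_xy(top)`` whose joint covariance follows from the LD correlations by the
delta method; the null distribution is an eigenvalue-weighted sum of 1-df
chi-squares, evaluated by Imhof's numerical inversion (with a Monte-Carlo
fallback).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

MIN_PANEL_SIZE = 50


@dataclass
class LDReference:
    """Cis-window LD: a genotype-dosage panel or a correlation matrix."""

    snp_ids: list
    genotypes: Optional[np.ndarray] = None     # individuals x SNPs
    correlation: Optional[np.ndarray] = None
    positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.genotypes is None and self.correlation is None:
            raise ValueError("supply genotypes or a correlation matrix")
        if self.genotypes is not None and len(self.genotypes) < MIN_PANEL_SIZE:
            raise ValueError(f"LD panel needs >= {MIN_PANEL_SIZE} individuals")
        if self.correlation is not None:
            R = self.correlation
            if not np.allclose(R, R.T, atol=1e-8):
                raise ValueError("LD correlation matrix must be symmetric")
            if np.abs(R).max() > 1 + 1e-8:
                raise ValueError("correlations must lie in [-1, 1]")
            if np.linalg.eigvalsh(R).min() < -1e-6:
                raise ValueError("LD correlation matrix must be PSD")

    def corr(self) -> pd.DataFrame:
        if self.correlation is not None:
            R = self.correlation
        else:
            R = np.corrcoef(self.genotypes, rowvar=False)
        return pd.DataFrame(R, index=self.snp_ids, columns=self.snp_ids)


@dataclass
class SMRResult:
    exposure: str
    outcome: str
    instrument: Optional[str]
    b_xy: Optional[float] = None
    se: Optional[float] = None
    p_smr: Optional[float] = None
    p_heidi: Optional[float] = None
    n_heidi_snps: int = 0
    status: str = "ok"       # ok | no-instrument | heidi-not-run


def select_instrument(exposure: pd.DataFrame, p_instrument: float = 5e-8,
                      positions: Optional[pd.Series] = None) -> Optional[str]:
    """Top cis-QTL: smallest exposure p below the instrument threshold.
    Ties break to the smaller bp (when positions are given) then SNP id."""
    if exposure.empty:
        raise ValueError("empty cis window")
    df = exposure.copy()
    if positions is not None:
        df["_bp"] = positions.reindex(df["SNP"]).to_numpy()
        df = df.sort_values(["p", "_bp", "SNP"], kind="mergesort")
    else:
        df = df.sort_values(["p", "SNP"], kind="mergesort")
    top = df.iloc[0]
    if top["p"] >= p_instrument:
        return None
    return str(top["SNP"])


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Align the outcome set to the exposure's effect alleles; flips the
    outcome effect sign where A1/A2 are swapped, errors on mismatches."""
    e = exposure.set_index("SNP")
    o = outcome.set_index("SNP")
    shared = e.index.intersection(o.index)
    e, o = e.loc[shared], o.loc[shared]
    same = (e["A1"].str.upper() == o["A1"].str.upper()) & \
           (e["A2"].str.upper() == o["A2"].str.upper())
    flipped = (e["A1"].str.upper() == o["A2"].str.upper()) & \
              (e["A2"].str.upper() == o["A1"].str.upper())
    bad = ~(same | flipped)
    if bad.any():
        raise ValueError(f"allele mismatch at {shared[bad][:5].tolist()}")
    out = o.copy()
    out.loc[flipped, "b"] = -out.loc[flipped, "b"]
    out.loc[flipped, ["A1", "A2"]] = e.loc[flipped, ["A1", "A2"]].to_numpy()
    out["b_exposure"] = e["b"]
    out["se_exposure"] = e["se"]
    out["p_exposure"] = e["p"]
    return out.reset_index()


def smr_test(b_zx: float, se_zx: float, b_zy: float, se_zy: float
             ) -> tuple[float, float, float]:
    """(b_xy, se, p_SMR) from instrument-level exposure/outcome effects."""
    if b_zx == 0:
        raise ZeroDivisionError("exposure effect at the instrument is zero")
    z_zx, z_zy = b_zx / se_zx, b_zy / se_zy
    b_xy = b_zy / b_zx
    if z_zy == 0:
        return b_xy, abs(se_zy / b_zx), 1.0
    chi2 = (z_zy**2 * z_zx**2) / (z_zy**2 + z_zx**2)
    se = np.sqrt((se_zy**2 + b_xy**2 * se_zx**2) / b_zx**2)
    return float(b_xy), float(se), float(stats.chi2.sf(chi2, 1))


def imhof_tail(q: float, eigenvalues: np.ndarray) -> float:
    """P(sum_k lambda_k chi2_1 > q) by Imhof's numerical inversion."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[np.abs(lam) > 1e-12]
    if lam.size == 0:
        return 1.0

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    # integrate one oscillation period at a time; the envelope decays, so
    # the per-period contributions form a (near) alternating series
    freq = 0.5 * q + 0.5 * np.sum(np.abs(lam))   # d theta / du at u = 0
    L = 2.0 * np.pi / max(freq, 1e-3)
    val, u0 = 0.0, 0.0
    for _ in range(100_000):
        part, _ = integrate.quad(integrand, u0, u0 + L, limit=100)
        val += part
        u0 += L
        if abs(part) < 1e-9 and u0 > 5 * L:
            break
    return float(min(max(0.5 + val / np.pi, 1e-300), 1.0))


def mc_tail(q: float, eigenvalues: np.ndarray, reps: int = 200_000,
            seed: int = 0) -> float:
    """Monte-Carlo fallback for the weighted chi-square tail."""
    rng = np.random.default_rng(seed)
    draws = rng.chisquare(1, size=(reps, len(eigenvalues))) @ np.asarray(eigenvalues)
    return float((1 + (draws > q).sum()) / (reps + 1))


def heidi_test(exposure: pd.DataFrame, outcome: pd.DataFrame, ld: LDReference,
               instrument: Optional[str] = None, *, snp_p_max: float = 1.6e-3,
               ld_prune: tuple[float, float] = (0.05, 0.9), max_snps: int = 20,
               min_snps: int = 3, tail: str = "imhof"
               ) -> tuple[Optional[float], int, str]:
    """(p_HEIDI, n_snps, status). SNPs enter if their exposure p is below
    ``snp_p_max`` and their r^2 with the instrument lies inside
    ``ld_prune``; at most ``max_snps`` strongest instruments are used."""
    joined = harmonize(exposure, outcome)
    positions = (pd.Series(ld.positions, index=ld.snp_ids)
                 if ld.positions is not None else None)
    if instrument is None:
        instrument = select_instrument(
            exposure[exposure["SNP"].isin(joined["SNP"])],
            p_instrument=1.0, positions=positions)
    if instrument not in set(joined["SNP"]):
        raise KeyError(f"instrument {instrument!r} absent after harmonization")
    R = ld.corr()
    j = joined.set_index("SNP")
    top = j.loc[instrument]
    r2_with_top = R.loc[instrument].reindex(j.index) ** 2
    eligible = (
        (j.index != instrument)
        & (j["p_exposure"] < snp_p_max)
        & (r2_with_top >= ld_prune[0]) & (r2_with_top <= ld_prune[1])
    )
    cand = j[eligible].sort_values("p_exposure").head(max_snps)
    if len(cand) < min_snps:
        return None, int(len(cand)), "heidi-not-run"

    ids = [instrument] + cand.index.tolist()
    Rs = R.loc[ids, ids].to_numpy()
    bzx = np.concatenate([[top["b_exposure"]], cand["b_exposure"].to_numpy()])
    szx = np.concatenate([[top["se_exposure"]], cand["se_exposure"].to_numpy()])
    bzy = np.concatenate([[top["b"]], cand["b"].to_numpy()])
    szy = np.concatenate([[top["se"]], cand["se"].to_numpy()])

    bxy = bzy / bzx
    d = bxy[1:] - bxy[0]
    nc = len(d)
    # delta-method Jacobians of d w.r.t. (b_zy over all SNPs) and (b_zx ...)
    Jy = np.zeros((nc, nc + 1))
    Jx = np.zeros((nc, nc + 1))
    Jy[:, 0] = -1.0 / bzx[0]
    Jx[:, 0] = bzy[0] / bzx[0] ** 2
    for i in range(nc):
        Jy[i, i + 1] = 1.0 / bzx[i + 1]
        Jx[i, i + 1] = -bzy[i + 1] / bzx[i + 1] ** 2
    Sy = Rs * np.outer(szy, szy)
    Sx = Rs * np.outer(szx, szx)
    cov_d = Jy @ Sy @ Jy.T + Jx @ Sx @ Jx.T
    sd = np.sqrt(np.diag(cov_d))
    z = d / sd
    corr_d = cov_d / np.outer(sd, sd)
    T = float(z @ z)
    lam = np.linalg.eigvalsh((corr_d + corr_d.T) / 2.0)
    lam = lam[lam > 1e-10]
    p = imhof_tail(T, lam) if tail == "imhof" else mc_tail(T, lam)
    return p, nc, "ok"


def filter_genes_with_eqtl(eqtl_by_gene: dict[str, pd.DataFrame],
                           p: float = 5e-8) -> list[str]:
    """Genes whose best cis-eQTL p is strictly below the threshold."""
    return [g for g, df in eqtl_by_gene.items()
            if len(df) and df["p"].min() < p]


def chain_m2e2t(mqtl: pd.DataFrame, eqtl_by_gene: dict[str, pd.DataFrame],
                gwas: pd.DataFrame, ld: LDReference, *,
                probe_id: str, probe_bp: int, gene_tss: dict[str, int],
                cis_bp: float = 2e6, p_instrument: float = 5e-8,
                p_eqtl_gene: float = 5e-8, alpha: float = 0.05
                ) -> tuple[list[SMRResult], float]:
    """Run SMR + HEIDI for methylation->expression, methylation->trait and
    expression->trait over every gene with TSS within ``cis_bp`` of the
    probe and at least one significant cis-eQTL. Returns all results and
    the Bonferroni threshold over the number of tests performed."""
    positions = (pd.Series(ld.positions, index=ld.snp_ids)
                 if ld.positions is not None else None)
    genes = [g for g in filter_genes_with_eqtl(eqtl_by_gene, p=p_eqtl_gene)
             if abs(gene_tss[g] - probe_bp) <= cis_bp]
    results: list[SMRResult] = []

    def one(exp_df, out_df, exp_name, out_name):
        instr = select_instrument(exp_df, p_instrument=p_instrument,
                                  positions=positions)
        if instr is None:
            results.append(SMRResult(exposure=exp_name, outcome=out_name,
                                     instrument=None, status="no-instrument"))
            return
        joined = harmonize(exp_df, out_df).set_index("SNP")
        row = joined.loc[instr]
        b_xy, se, p_smr = smr_test(row["b_exposure"], row["se_exposure"],
                                   row["b"], row["se"])
        p_heidi, n_snps, status = heidi_test(exp_df, out_df, ld, instrument=instr)
        results.append(SMRResult(exposure=exp_name, outcome=out_name,
                                 instrument=instr, b_xy=b_xy, se=se,
                                 p_smr=p_smr, p_heidi=p_heidi,
                                 n_heidi_snps=n_snps,
                                 status="ok" if status == "ok" else status))

    one(mqtl, gwas, probe_id, "trait")
    for g in genes:
        one(mqtl, eqtl_by_gene[g], probe_id, g)
        one(eqtl_by_gene[g], gwas, g, "trait")
    # multiplicity follows the number of candidate genes carried forward
    # (each gene contributes one methylation->expression hypothesis)
    n_tests = max(1, len(genes))
    return results, alpha / n_tests
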