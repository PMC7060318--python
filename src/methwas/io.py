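"""Readers and writers for every on-disk format the pipeline touches.

Policy: tolerant reader, strict writer. All writers are deterministic
(stable row order, 6-significant-digit formatting). On-disk genomic
intervals are BED-convention 0-based half-open; every in-memory position
is 1-based, and the conversion lives only in this module.

Formats
-------
* beta matrix TSV(.gz): probes as rows, samples as columns, ``NA`` missing
* probe annotation: BED-like (chrom, start, end, probe, gene, flags)
* covariate / CTP tables: TSV with a sample-id first column
* association tables: Chr, Probe, bp, Gene, b, se, p, method
* COJO-style .ma summary statistics: SNP A1 A2 freq b se p N
* ORM: an ids file plus a lower-triangle TSV
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .data import MethylationMatrix, OmicsRelationshipMatrix, ProbeAnnotation

PathLike = Union[str, Path]
_FMT = "%.6g"


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_beta_matrix(path: PathLike, validate_range: bool = True) -> MethylationMatrix:
    """Beta matrix TSV: header of sample ids, rows keyed by probe id,
    ``NA`` for missing; optionally gzipped. Values outside [0, 1] are an
    error naming the offending cells unless ``validate_range=False`` (for
    batch-residualized matrices, which legitimately leave the interval)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"])
    numeric = df.apply(pd.to_numeric, errors="coerce")
    vals = numeric.to_numpy(dtype=float)
    out_of_range = ((vals < 0) | (vals > 1)) if validate_range else \
        np.zeros_like(vals, dtype=bool)
    nonnum = (numeric.isna() & df.notna()).to_numpy()
    if out_of_range.any() or nonnum.any():
        cells = []
        rr, cc = np.nonzero(out_of_range | nonnum)
        for r, c in zip(rr[:5], cc[:5]):
            cells.append(f"(probe={df.index[r]}, sample={df.columns[c]}, "
                         f"value={df.iat[r, c]!r})")
        raise ValueError("invalid beta values: " + ", ".join(cells))
    if validate_range:
        return MethylationMatrix(beta=numeric.T)   # samples x probes in memory
    out = MethylationMatrix.__new__(MethylationMatrix)
    out.beta = numeric.T
    out.detection_p = out.beads = out.median_methylated = None
    out.reported_sex = out.predicted_sex = None
    return out


def write_beta_matrix(M: MethylationMatrix, path: PathLike) -> None:
    df = M.beta.T   # probes as rows on disk
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", na_rep="NA", float_format=_FMT)


def read_probe_annotation(path: PathLike) -> ProbeAnnotation:
    """BED-like annotation; converts 0-based half-open intervals to 1-based
    positions and normalizes 'chr4' and '4' to the same label."""
    cols = ["chrom", "start", "end", "probe", "gene", "cross_reactive",
            "sex_chromosome"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[:df.shape[1]]
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]]["probe"].tolist()
        raise ValueError(f"start >= end for probes {bad[:5]}")
    if df["probe"].duplicated().any():
        dups = df.loc[df["probe"].duplicated(), "probe"].tolist()
        raise ValueError(f"duplicate probe ids {dups[:5]}")
    gene = (df["gene"].fillna("") if "gene" in df.columns
            else pd.Series("", index=df.index))
    table = pd.DataFrame({
        "chrom": df["chrom"].astype(str).str.removeprefix("chr").to_numpy(),
        "bp": df["end"].astype(np.int64).to_numpy(),  # end of 1-bp interval = 1-based
        "gene": gene.to_numpy(),
    }, index=pd.Index(df["probe"].to_numpy(), name="probe"))
    for flag in ("cross_reactive", "sex_chromosome"):
        if flag in df.columns:
            table[flag] = df[flag].astype(bool).to_numpy()
    return ProbeAnnotation(table)


def write_probe_annotation(ann: ProbeAnnotation, path: PathLike) -> None:
    t = ann.table
    out = pd.DataFrame({
        "chrom": t["chrom"].astype(str),
        "start": t["bp"].astype(np.int64) - 1,   # back to 0-based half-open
        "end": t["bp"].astype(np.int64),
        "probe": t.index,
        "gene": t["gene"],
        "cross_reactive": t["cross_reactive"].astype(int),
        "sex_chromosome": t["sex_chromosome"].astype(int),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


def read_summary_ma(path: PathLike) -> pd.DataFrame:
    """COJO-style .ma summary statistics (whitespace-delimited, header)."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in MA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f".ma file missing columns {missing}")
    extra = [c for c in df.columns if c not in MA_COLUMNS]
    if extra:
        import warnings
        warnings.warn(f"ignoring extra .ma columns {extra}", stacklevel=2)
    df = df[MA_COLUMNS].copy()
    for col in ("freq", "b", "se", "p"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    bad = df.index[df["se"] <= 0]
    if len(bad):
        raise ValueError(f"non-positive se at row(s) {[int(i) + 2 for i in bad[:5]]}")
    return df


def write_summary_ma(df: pd.DataFrame, path: PathLike) -> None:
    df[MA_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FMT)


def read_covariates(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_covariates(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", float_format=_FMT)


def read_association(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["Chr"] = df["Chr"].astype(str)
    return df


def write_association(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


def write_orm(orm: OmicsRelationshipMatrix, prefix: PathLike) -> None:
    """ids file (<prefix>.orm.id) plus lower-triangle TSV (<prefix>.orm.tsv):
    columns i, j (0-based, i >= j), value."""
    prefix = Path(prefix)
    pd.Series(orm.sample_ids).to_csv(prefix.with_suffix(".orm.id"),
                                     sep="\t", index=False, header=False)
    n = orm.A.shape[0]
    ii, jj = np.tril_indices(n)
    tri = pd.DataFrame({"i": ii, "j": jj, "value": orm.A[ii, jj]})
    tri["m"] = orm.m
    tri.to_csv(prefix.with_suffix(".orm.tsv"), sep="\t", index=False,
               float_format="%.10g")


def read_orm(prefix: PathLike) -> OmicsRelationshipMatrix:
    prefix = Path(prefix)
    ids = pd.read_csv(prefix.with_suffix(".orm.id"), sep="\t",
                      header=None)[0]
    tri = pd.read_csv(prefix.with_suffix(".orm.tsv"), sep="\t")
    n = len(ids)
    A = np.zeros((n, n))
    A[tri["i"], tri["j"]] = tri["value"]
    A = A + np.tril(A, -1).T
    return OmicsRelationshipMatrix(A=A, m=int(tri["m"].iloc[0]),
                                   sample_ids=pd.Index(ids))
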