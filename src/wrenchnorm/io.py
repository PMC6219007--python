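"""Readers and writers for count tables, metadata and factor outputs.

Two count dialects are supported, both features-as-rows: a dense TSV (first
column feature IDs, header row sample IDs, integer cells) and a MatrixMarket
coordinate file accompanied by newline-delimited ``features.txt`` /
``samples.txt`` ID files.  Metadata is a TSV with ``sample`` and ``group``
columns.  Factor outputs are TSVs with a provenance header comment.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .baselines import BaselineFactors
from .containers import CountMatrix, GroupDesign
from .wrench import NormalizationResult

__all__ = ["read_counts", "read_metadata", "write_counts", "write_factors"]

log = logging.getLogger("wrenchnorm")


def read_counts(
    path: str | Path,
    dialect: str = "tsv",
    features_path: str | Path | None = None,
    samples_path: str | Path | None = None,
    transpose: bool = False,
) -> CountMatrix:
    """Load a validated feature-by-sample count matrix.

    ``dialect="tsv"`` expects a dense table; ``dialect="matrixmarket"``
    expects a coordinate file plus ID sidecars (defaults: ``features.txt`` and
    ``samples.txt`` next to the matrix).  ``transpose`` accepts
    samples-as-rows tables.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if df.empty:
            raise ValueError(f"{path}: empty count table")
        if transpose:
            df = df.T
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                row = df.index[bad.isna()][0]
                raise ValueError(f"{path}: non-numeric cell at feature {row!r}, sample {col!r}")
        arr = df.to_numpy(dtype=float)
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"{path}: negative count at feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        frac = np.argwhere(~np.isclose(arr, np.round(arr)))
        if frac.size:
            i, j = frac[0]
            raise ValueError(
                f"{path}: non-integer count at feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        return CountMatrix.from_frame(df)
    if dialect == "matrixmarket":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        features_path = Path(features_path) if features_path else path.parent / "features.txt"
        samples_path = Path(samples_path) if samples_path else path.parent / "samples.txt"
        feats = [l.strip() for l in Path(features_path).read_text().splitlines() if l.strip()]
        samps = [l.strip() for l in Path(samples_path).read_text().splitlines() if l.strip()]
        if transpose:
            mat = mat.T
        if len(feats) != mat.shape[0]:
            raise ValueError(
                f"{features_path}: {len(feats)} feature ids for {mat.shape[0]} matrix rows"
            )
        if len(samps) != mat.shape[1]:
            raise ValueError(
                f"{samples_path}: {len(samps)} sample ids for {mat.shape[1]} matrix columns"
            )
        return CountMatrix(mat, feature_ids=feats, sample_ids=samps)
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'matrixmarket'")


def write_counts(counts: CountMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a count matrix in either supported dialect."""
    path = Path(path)
    if dialect == "tsv":
        df = counts.to_frame()
        df.index.name = "feature"
        df.to_csv(path, sep="\t")
    elif dialect == "matrixmarket":
        spio.mmwrite(str(path), sparse.coo_matrix(counts.counts), field="integer")
        (path.parent / "features.txt").write_text("\n".join(counts.feature_ids) + "\n")
        (path.parent / "samples.txt").write_text("\n".join(counts.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_metadata(path: str | Path) -> GroupDesign:
    """Load a ``sample``/``group`` TSV into a GroupDesign.

    Extra columns are logged and ignored; duplicate sample rows are an error.
    Coverage against a count matrix is checked at pairing time via
    :meth:`GroupDesign.labels_for`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: metadata must have a {col!r} column")
    extra = [c for c in df.columns if c not in ("sample", "group")]
    if extra:
        log.info("ignoring extra metadata columns: %s", extra)
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: duplicated sample rows: {dupes[:5]}")
    return GroupDesign.from_labels(df["sample"].tolist(), df["group"].tolist())


def _provenance_line(seed: int | None) -> str:
    line = f"# wrenchnorm {__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def write_factors(
    result: NormalizationResult | BaselineFactors,
    path: str | Path,
    design: GroupDesign | None = None,
    seed: int | None = None,
) -> None:
    """Write per-sample factors as TSV (10 significant digits, NA for failures)."""
    path = Path(path)
    if isinstance(result, BaselineFactors):
        sample_ids = [f"S{j}" for j in range(result.ccf.shape[0])]
        rows = {
            "sample": sample_ids,
            "ccf": result.ccf,
            "nf": [np.nan] * result.ccf.shape[0],
            "method": result.method,
            "failure_reason": [r or "" for r in result.failure_reasons],
        }
        df = pd.DataFrame(rows)
    else:
        sample_ids = result.sample_ids or [f"S{j}" for j in range(result.ccf.shape[0])]
        df = pd.DataFrame(
            {
                "sample": sample_ids,
                "ccf": result.ccf,
                "nf": result.nf,
                "estimator": result.estimator,
            }
        )
        reasons = result.diagnostics.get("failure_reasons")
        if reasons is not None:
            df["failure_reason"] = [r or "" for r in reasons]
    if design is not None:
        df.insert(1, "group", design.labels_for(list(df["sample"])))
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_factors(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for factor TSVs (skips the provenance comment)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
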