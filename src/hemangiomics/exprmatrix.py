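"""Expression matrices, sample sheets, and microarray-style preprocessing.

The container is a thin wrapper over a pandas DataFrame (features x
samples) carrying a scale flag (``log2`` intensities or ``raw`` counts).
Preprocessing mirrors a standard Illumina BeadChip workflow: a detection
filter (detection p-value below alpha in at least ``min_samples``
samples), quantile normalization to the mean empirical distribution, and
a log2 transform.  An optional, clearly flagged surrogate background
subtraction (per-sample 5th percentile) is available for data without
negative-control probes; it is disabled by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

VALID_SCALES = ("log2", "raw")


class MatrixFormatError(ValueError):
    """Raised when a matrix file or container violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Features x samples numeric matrix with a declared scale.

    ``data`` is indexed by feature ID with sample IDs as columns; both must
    be unique.  ``scale`` declares whether values are log2 intensities or
    raw counts.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        dup_f = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_f):
            raise MatrixFormatError(f"duplicate feature IDs: {list(map(str, dup_f[:5]))}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_s):
            raise MatrixFormatError(f"duplicate sample IDs: {list(map(str, dup_s[:5]))}")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            bad = [str(c) for c, dt in self.data.dtypes.items()
                   if not np.issubdtype(dt, np.number)]
            raise MatrixFormatError(f"non-numeric columns: {bad[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, keep: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[keep], scale=self.scale)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.scale == other.scale and self.data.equals(other.data)


@dataclass
class SampleSheet:
    """Per-sample annotations: group label plus optional time and arm."""

    table: pd.DataFrame  # columns: sample, group[, time, arm]
    groups: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if "sample" not in self.table.columns or "group" not in self.table.columns:
            raise MatrixFormatError("sample sheet needs 'sample' and 'group' columns")
        if self.table["sample"].duplicated().any():
            dups = self.table["sample"][self.table["sample"].duplicated()].tolist()
            raise MatrixFormatError(f"duplicate samples in sheet: {dups[:5]}")
        if not self.groups:
            self.groups = tuple(pd.unique(self.table["group"]))
        unknown = set(self.table["group"]) - set(self.groups)
        if unknown:
            raise MatrixFormatError(f"group labels outside declared set: {sorted(unknown)}")

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample")["group"]

    def samples_in(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample"].tolist()

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        sheet_samples = set(self.table["sample"])
        missing = [s for s in matrix.sample_ids if s not in sheet_samples]
        if missing:
            raise MatrixFormatError(f"matrix samples missing from sheet: {missing[:5]}")


@dataclass
class DetectionFilterConfig:
    """Detection-call filter: keep features detected (p < alpha) in
    at least ``min_samples`` samples."""

    alpha: float = 0.05
    min_samples: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_samples < 1:
            raise ValueError(f"min_samples must be >= 1, got {self.min_samples}")


def read_matrix(path: str | Path, scale: str = "log2", sep: str = "\t") -> ExpressionMatrix:
    """Read a TSV/CSV matrix: header row of sample IDs, first column feature IDs."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise MatrixFormatError(f"empty file: {path}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise MatrixFormatError(f"no sample columns in {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise MatrixFormatError(
                    f"non-numeric values in sample {col!r}, e.g. feature {bad[0]!r}")
            df[col] = coerced
    df.index = df.index.map(str)
    df.index.name = None
    df.columns = df.columns.map(str)
    return ExpressionMatrix(df, scale=scale)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.data.to_csv(path, sep=sep, index_label="feature")


def read_sample_sheet(path: str | Path, sep: str = "\t") -> SampleSheet:
    df = pd.read_csv(path, sep=sep, dtype={"sample": str, "group": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, sep: str = "\t") -> None:
    sheet.table.to_csv(path, sep=sep, index=False)


def detection_filter(matrix: ExpressionMatrix, detection_p: ExpressionMatrix,
                     cfg: DetectionFilterConfig | None = None) -> ExpressionMatrix:
    """Keep features whose detection p-value is strictly below ``alpha``
    in at least ``min_samples`` samples; order preserved."""
    cfg = cfg or DetectionFilterConfig()
    if (matrix.feature_ids != detection_p.feature_ids
            or matrix.sample_ids != detection_p.sample_ids):
        raise MatrixFormatError("detection p matrix must match expression matrix IDs/shape")
    p = detection_p.values
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise MatrixFormatError("detection p-values must lie in [0, 1]")
    n_detected = (p < cfg.alpha).sum(axis=1)
    keep = n_detected >= cfg.min_samples
    return ExpressionMatrix(matrix.data.loc[keep], scale=matrix.scale)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    Each sample's sorted values are replaced by the across-sample mean of
    sorted values; ties within a sample receive the mean of the reference
    values for their tied ranks (mid-rank convention).  Idempotent and
    rank-preserving within each sample.
    """
    x = matrix.values
    if np.isnan(x).any():
        raise MatrixFormatError("missing values are not supported (no imputation)")
    n_feat, n_samp = x.shape
    if n_feat == 0 or n_samp == 0:
        return matrix
    reference = np.sort(x, axis=0).mean(axis=1)  # mean of order statistics
    out = np.empty_like(x, dtype=float)
    positions = np.arange(1, n_feat + 1, dtype=float)
    for j in range(n_samp):
        ranks = rankdata(x[:, j], method="average")
        # mid-rank ties land between adjacent order statistics
        out[:, j] = np.interp(ranks, positions, reference)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        scale=matrix.scale)


def log2_transform(matrix: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise log2(value + offset); sets the scale flag to log2."""
    if offset < 0:
        raise ValueError(f"offset must be non-negative, got {offset}")
    x = matrix.values + offset
    bad = (x <= 0).any(axis=1)
    if bad.any():
        offenders = [str(f) for f in matrix.data.index[bad][:10]]
        raise ValueError(
            f"log2 transform needs value + offset > 0; offending features: {offenders}")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(x), index=matrix.data.index, columns=matrix.data.columns),
        scale="log2")


def background_subtract(matrix: ExpressionMatrix, quantile: float = 0.05,
                        floor: float = 1e-6) -> ExpressionMatrix:
    """Surrogate background correction: subtract each sample's ``quantile``
    value and floor at ``floor``.

    This is a deliberately simple stand-in for convolution-model background
    correction, intended for synthetic data without negative-control
    probes.  Disabled by default in all pipelines; enable explicitly.
    """
    x = matrix.values
    bg = np.quantile(x, quantile, axis=0, keepdims=True)
    out = np.maximum(x - bg, floor)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        scale=matrix.scale)
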