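"""Validated in-memory containers for count data and experimental designs.

Counts are stored features-as-rows (the usual OTU-table orientation): a
``CountMatrix`` holds a ``p × n`` non-negative integer matrix together with
unique feature and sample identifiers.  A ``GroupDesign`` maps each sample to
exactly one experimental group and designates one group as the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "GroupDesign"]


class DegenerateSampleError(ValueError):
    """A sample with zero total count cannot be normalized."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclass(frozen=True)
class CountMatrix:
    """Feature-by-sample matrix of raw sequencing counts Y.

    Parameters
    ----------
    counts
        ``(p, n)`` array of non-negative integers; rows are features,
        columns are samples.
    feature_ids, sample_ids
        Unique string identifiers for rows and columns.
    """

    counts: np.ndarray
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-D feature-by-sample matrix")
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(f"negative count at feature row {i}, sample column {j}")
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(f"non-integer count at feature row {i}, sample column {j}")
        arr = np.round(arr).astype(np.int64)
        p, n = arr.shape
        if p < 1 or n < 1:
            raise ValueError("count matrix must be non-empty")
        object.__setattr__(self, "counts", arr)
        fid = self.feature_ids if self.feature_ids is not None else [f"F{i}" for i in range(p)]
        sid = self.sample_ids if self.sample_ids is not None else [f"S{j}" for j in range(n)]
        fid, sid = _check_unique(fid, "feature"), _check_unique(sid, "sample")
        if len(fid) != p:
            raise ValueError(f"{len(fid)} feature ids for {p} rows")
        if len(sid) != n:
            raise ValueError(f"{len(sid)} sample ids for {n} columns")
        object.__setattr__(self, "feature_ids", fid)
        object.__setattr__(self, "sample_ids", sid)
        totals = arr.sum(axis=0)
        if np.any(totals == 0):
            bad = [sid[j] for j in np.flatnonzero(totals == 0)]
            raise DegenerateSampleError(f"all-zero sample(s): {bad}")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def depths(self) -> np.ndarray:
        """Per-sample totals τ_j (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def proportions(self) -> np.ndarray:
        """Observed per-sample proportions q̂_ji = Y_ji / τ_j."""
        return self.counts / self.depths[None, :]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to experimental groups with a control group."""

    group_of: Mapping[str, str]
    groups: list[str] = field(default=None)  # type: ignore[assignment]
    control_group: str = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mapping = {str(k): str(v) for k, v in dict(self.group_of).items()}
        if not mapping:
            raise ValueError("empty design")
        object.__setattr__(self, "group_of", mapping)
        seen: list[str] = []
        for g in mapping.values():
            if g not in seen:
                seen.append(g)
        groups = [str(g) for g in (self.groups if self.groups is not None else seen)]
        if set(groups) != set(seen):
            raise ValueError("groups list does not match the labels present in group_of")
        object.__setattr__(self, "groups", groups)
        control = str(self.control_group) if self.control_group is not None else groups[0]
        if control not in groups:
            raise ValueError(f"control group {control!r} not among groups {groups}")
        object.__setattr__(self, "control_group", control)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Group label per sample, erroring on samples missing from the design."""
        missing = [s for s in sample_ids if s not in self.group_of]
        if missing:
            raise KeyError(f"samples missing from design: {missing[:5]}")
        return np.array([self.group_of[s] for s in sample_ids])

    def indices_by_group(self, sample_ids: Sequence[str]) -> dict[str, np.ndarray]:
        labels = self.labels_for(sample_ids)
        return {g: np.flatnonzero(labels == g) for g in self.groups}

    @classmethod
    def from_labels(
        cls, sample_ids: Sequence[str], labels: Sequence[str], control_group: str | None = None
    ) -> "GroupDesign":
        if len(sample_ids) != len(labels):
            raise ValueError("sample_ids and labels differ in length")
        return cls(dict(zip(map(str, sample_ids), map(str, labels))), control_group=control_group)
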