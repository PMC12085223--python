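"""Core data containers for the screening/testing pipeline.

A :class:`FeatureMatrix` holds an ``n x p`` numeric predictor table (samples as
rows) together with unique feature names; an :class:`Outcome` holds the length-n
response, either continuous or binary (coded 0/1).  Both validate eagerly so
that every downstream operation can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = ["FeatureMatrix", "Outcome"]

OutcomeKind = Literal["continuous", "binary"]


def _as_float_array(values, ndim: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or infinite entries")
    return arr


@dataclass
class FeatureMatrix:
    """Numeric predictor table: ``values`` is n samples x p features."""

    values: np.ndarray
    feature_names: Sequence[str]
    sample_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, 2, "feature matrix")
        n, p = self.values.shape
        if n < 10:
            raise ValueError(f"need at least 10 samples, got {n}")
        if p < 1:
            raise ValueError("need at least one feature")
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.feature_names) != p:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        dupes = _duplicates(self.feature_names)
        if dupes:
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != n:
                raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        """New matrix keeping only the given feature columns (order preserved)."""
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=[self.feature_names[j] for j in idx],
            sample_ids=self.sample_ids,
        )

    def rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        """New matrix keeping only the given sample rows."""
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[idx, :],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx] if self.sample_ids else None,
        )


@dataclass
class Outcome:
    """Response vector; binary outcomes must be coded {0, 1} with both classes."""

    values: np.ndarray
    kind: OutcomeKind = "continuous"

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, 1, "outcome")
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.kind == "binary":
            uniq = set(np.unique(self.values))
            if not uniq <= {0.0, 1.0}:
                raise ValueError("binary outcome must be coded {0, 1}")
            if len(uniq) != 2:
                raise ValueError("binary outcome must contain both classes")

    def __len__(self) -> int:
        return len(self.values)

    def take(self, indices: Sequence[int]) -> "Outcome":
        return Outcome(values=self.values[list(indices)], kind=self.kind)


def _duplicates(names: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for name in names:
        if name in seen:
            dup.add(name)
        seen.add(name)
    return dup
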