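"""Feature matrices: the common container for latent and expert feature tables.

A :class:`FeatureMatrix` is an m-samples x n-features real matrix with named
columns, opaque per-sample identifiers, and a ``source`` tag distinguishing
latent (model-derived) from expert (interpretable) features.  Two matrices are
*paired* when their sample identifiers agree element-wise and in order — the
precondition for fitting a transition matrix between them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "PairingError"]


class PairingError(ValueError):
    """Raised when two feature matrices do not describe the same samples."""


def _check_finite(values: np.ndarray) -> None:
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        r, c = bad[0]
        raise ValueError(
            f"non-finite entry at row {r}, column {c} "
            f"({len(bad)} non-finite entries total)"
        )


@dataclass
class FeatureMatrix:
    """An m x n table of per-sample feature values.

    Parameters
    ----------
    values
        Real matrix, rows are samples, columns are features.
    sample_ids
        One opaque identifier per row.
    feature_names
        One name per column.
    source
        Either ``"latent"`` (produced by a model) or ``"expert"``
        (interpretable, expert-defined).
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    source: str = "latent"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        m, n = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(m)]
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(n)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.sample_ids) != m:
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids for {m} rows"
            )
        if len(self.feature_names) != n:
            raise ValueError(
                f"{len(self.feature_names)} feature_names for {n} columns"
            )
        if self.source not in ("latent", "expert"):
            raise ValueError(f"source must be 'latent' or 'expert', got {self.source!r}")
        _check_finite(self.values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def is_paired_with(self, other: "FeatureMatrix") -> bool:
        return self.sample_ids == other.sample_ids

    def require_paired(self, other: "FeatureMatrix") -> None:
        if not self.is_paired_with(other):
            raise PairingError(
                "matrices are not paired: sample identifiers differ "
                "(both must come from the same samples in the same order)"
            )

    def subset(self, row_index: Sequence[int]) -> "FeatureMatrix":
        """Row subset preserving pairing semantics (same order as given)."""
        idx = list(row_index)
        return FeatureMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            source=self.source,
        )

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset by feature name."""
        pos = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in pos]
        if missing:
            raise KeyError(f"unknown feature(s): {missing}")
        cols = [pos[f] for f in names]
        return FeatureMatrix(
            values=self.values[:, cols],
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            source=self.source,
        )

    # ------------------------------------------------------------------ I/O
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        # 17 significant digits: lossless for float64 round-trips
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "latent") -> "FeatureMatrix":
        df = pd.read_csv(path, dtype={0: str})
        if df.shape[1] < 2:
            raise ValueError(f"{path}: need a sample-id column plus >=1 feature column")
        ids = df.iloc[:, 0].astype(str).tolist()
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        return cls(values=values, sample_ids=ids,
                   feature_names=list(df.columns[1:]), source=source)

    def to_npy(self, path: str | Path) -> None:
        """NPY matrix plus JSON sidecar (``<path>.json``) carrying metadata."""
        path = Path(path)
        np.save(path, self.values)
        sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npy" \
            else path.with_suffix(".json")
        sidecar.write_text(json.dumps({
            "sample_ids": self.sample_ids,
            "feature_names": self.feature_names,
            "source": self.source,
        }))

    @classmethod
    def from_npy(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        values = np.load(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        return cls(values=values, sample_ids=meta["sample_ids"],
                   feature_names=meta["feature_names"], source=meta["source"])
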