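"""Core data containers: omics matrices, survival tables, two-view image sets.

CSV conventions
---------------
An :class:`OmicsMatrix` round-trips as a CSV with rows = samples, first
column = sample ID, header = feature IDs. A :class:`SurvivalTable` is a
3-column CSV (sample_id, time, event).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicsMatrix", "SurvivalTable", "TwoViewDataset"]


@dataclass
class OmicsMatrix:
    """A samples x features continuous matrix with IDs and a modality tag."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    modality_name: str = "omics"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("values shape inconsistent with ID lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx) -> "OmicsMatrix":
        idx = np.asarray(idx)
        return OmicsMatrix(self.values[idx],
                           [self.sample_ids[i] for i in idx],
                           list(self.feature_ids), self.modality_name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, modality_name: str | None = None) -> "OmicsMatrix":
        df = pd.read_csv(path, index_col=0)
        name = modality_name or "omics"
        return cls(df.to_numpy(dtype=np.float64), list(df.index.astype(str)),
                   list(df.columns.astype(str)), name)


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes: per-sample time and event indicator.

    ``event == 1`` marks an observed event (death); ``event == 0`` marks a
    right-censored sample whose event had not occurred at ``time``.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=np.float64).reshape(-1)
        self.event = np.asarray(self.event).reshape(-1).astype(int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event lengths inconsistent with sample IDs")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx) -> "SurvivalTable":
        idx = np.asarray(idx)
        return SurvivalTable([self.sample_ids[i] for i in idx],
                             self.time[idx], self.event[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids,
                             "time": self.time, "event": self.event})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalTable":
        df = pd.read_csv(path)
        return cls(list(df["sample_id"].astype(str)),
                   df["time"].to_numpy(), df["event"].to_numpy())


@dataclass
class TwoViewDataset:
    """Paired flattened views of the same underlying images.

    ``view1`` holds the flattened original images and ``view2`` the
    flattened 90-degree counter-clockwise rotations, each independently
    corrupted by the chosen noise.
    """

    view1: np.ndarray
    view2: np.ndarray
    labels: np.ndarray
    noise_kind: str = "none"
    image_shape: tuple[int, int] = field(default=(28, 28))

    def __post_init__(self):
        self.view1 = np.asarray(self.view1, dtype=np.float64)
        self.view2 = np.asarray(self.view2, dtype=np.float64)
        self.labels = np.asarray(self.labels).reshape(-1).astype(int)
        if self.view1.shape != self.view2.shape:
            raise ValueError("views must have identical shapes")
        if self.view1.shape[0] != self.labels.shape[0]:
            raise ValueError("label count mismatch")
        for v in (self.view1, self.view2):
            if v.min() < 0 or v.max() > 1:
                raise ValueError("pixel intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.view1.shape[0]

    def subset(self, idx) -> "TwoViewDataset":
        idx = np.asarray(idx)
        return TwoViewDataset(self.view1[idx], self.view2[idx],
                              self.labels[idx], self.noise_kind,
                              self.image_shape)
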