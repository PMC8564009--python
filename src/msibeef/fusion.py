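"""Feature containers, z-score normalization and feature-level fusion.

A *single-modality* feature set comes from one extraction route (band means
"MS", color "CIELAB", or co-occurrence "Texture").  A *multiple-modality*
set concatenates several routes column-wise after per-column
standardization.  Normalization parameters are always fitted on a
designated training subset only and applied unchanged to held-out rows, so
test information never leaks into the transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["MODALITIES", "FeatureVector", "FeatureMatrix", "fuse", "zscore_fit_transform"]

MODALITIES = ("MS", "CIELAB", "Texture")


@dataclass(frozen=True)
class FeatureVector:
    """One sample's named, ordered features with a modality tag per entry."""

    values: np.ndarray
    names: tuple[str, ...]
    modalities: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if not (len(values) == len(self.names) == len(self.modalities)):
            raise ValueError("values, names and modalities must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}; expected one of {MODALITIES}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "modalities", tuple(self.modalities))


@dataclass
class FeatureMatrix:
    """Rectangular feature table: rows are samples, columns named features.

    ``labels`` (optional) holds the class of each row; ``normalization``
    records the per-column (mean, sd) applied to produce ``values``, or
    ``None`` for raw features.
    """

    values: np.ndarray
    names: tuple[str, ...]
    modalities: tuple[str, ...]
    labels: np.ndarray | None = None
    normalization: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (samples x features)")
        self.names = tuple(self.names)
        self.modalities = tuple(self.modalities)
        if not (self.values.shape[1] == len(self.names) == len(self.modalities)):
            raise ValueError("column count, names and modalities must agree")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("one label per row required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_vectors(
        cls, vectors: Sequence[FeatureVector], labels: Sequence | None = None
    ) -> "FeatureMatrix":
        if not vectors:
            raise ValueError("need at least one feature vector")
        first = vectors[0]
        for v in vectors[1:]:
            if v.names != first.names or v.modalities != first.modalities:
                raise ValueError("all feature vectors must share one schema")
        return cls(
            values=np.vstack([v.values for v in vectors]),
            names=first.names,
            modalities=first.modalities,
            labels=None if labels is None else np.asarray(labels),
        )

    def select_modalities(self, modalities: Iterable[str]) -> "FeatureMatrix":
        """Columns belonging to the given modalities, in current column order."""
        wanted = tuple(modalities)
        for m in wanted:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
        keep = [i for i, m in enumerate(self.modalities) if m in wanted]
        if not keep:
            raise ValueError(f"no columns with modality in {wanted}")
        return FeatureMatrix(
            values=self.values[:, keep],
            names=tuple(self.names[i] for i in keep),
            modalities=tuple(self.modalities[i] for i in keep),
            labels=self.labels,
        )

    def take(self, indices: np.ndarray) -> "FeatureMatrix":
        """Row subset (e.g. a CV fold), keeping schema and per-row labels."""
        indices = np.asarray(indices)
        return FeatureMatrix(
            values=self.values[indices],
            names=self.names,
            modalities=self.modalities,
            labels=None if self.labels is None else self.labels[indices],
            normalization=self.normalization,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.names))
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, modalities: Sequence[str], label_column: str = "label"
    ) -> "FeatureMatrix":
        labels = None
        if label_column in df.columns:
            labels = df[label_column].to_numpy()
            df = df.drop(columns=[label_column])
        return cls(
            values=df.to_numpy(dtype=np.float64),
            names=tuple(df.columns),
            modalities=tuple(modalities),
            labels=labels,
        )


def fuse(blocks: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature blocks sharing the same rows.

    Blocks must have equal row counts, identical labels (where present) and
    disjoint feature names; block order fixes column order.
    """
    if not blocks:
        raise ValueError("need at least one block to fuse")
    n = blocks[0].n_samples
    labels = blocks[0].labels
    for b in blocks[1:]:
        if b.n_samples != n:
            raise ValueError(f"row count mismatch: {b.n_samples} != {n}")
        if (labels is None) != (b.labels is None) or (
            labels is not None and not np.array_equal(labels, b.labels)
        ):
            raise ValueError("blocks disagree on row labels; not the same samples")
    names: list[str] = []
    for b in blocks:
        names.extend(b.names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names across fused blocks")
    return FeatureMatrix(
        values=np.hstack([b.values for b in blocks]),
        names=tuple(names),
        modalities=tuple(m for b in blocks for m in b.modalities),
        labels=labels,
    )


def zscore_fit_transform(
    train: FeatureMatrix, apply_to: FeatureMatrix | None = None, ddof: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix | None]:
    """Standardize columns to zero mean / unit sd, fitted on ``train`` only.

    The population standard deviation (``ddof=0``) is the default.  Constant
    training columns (sd = 0) are mapped to 0 with a warning — they carry no
    information at training scale.  ``apply_to`` (if given) is transformed
    with the same parameters.
    """
    if train.n_samples == 0:
        raise ValueError("empty training matrix")
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=ddof)
    constant = sd == 0
    if constant.any():
        names = [train.names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant feature column(s) mapped to 0: {names}", stacklevel=2)
    safe_sd = np.where(constant, 1.0, sd)

    def _apply(m: FeatureMatrix) -> FeatureMatrix:
        z = (m.values - mean) / safe_sd
        z[:, constant] = 0.0
        return replace(m, values=z, normalization=(mean.copy(), sd.copy()))

    train_t = _apply(train)
    apply_t = None if apply_to is None else _apply(apply_to)
    return train_t, apply_t
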