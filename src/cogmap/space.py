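"""Semantic spaces: labelled feature matrices acting as a memory store.

A :class:`SemanticSpace` holds one stored "memory" per row — here animal
species described by numeric semantic features (height, weight, number of
legs, a subjective danger level, and coded reproduction/fur/lungs traits).
Two fixture spaces ship with the package: ``animals_train`` (32 species,
the memory matrix the network is trained on) and ``animals_test`` (6 novel
species used to probe feature inference).

The value ``-1`` is reserved as the missing-feature sentinel of
:class:`PartialFeatureVector`; stored memories must never contain it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SemanticSpace",
    "PartialFeatureVector",
    "MISSING_SENTINEL",
    "FIXTURE_NAMES",
    "load_space",
    "write_space",
    "generate_random_space",
]

#: Sentinel marking an unknown feature in a partial input vector.
MISSING_SENTINEL = -1.0

#: Embedded datasets addressable by name in :func:`load_space`.
FIXTURE_NAMES = ("animals_train", "animals_test")


class SpaceValidationError(ValueError):
    """A table violates the semantic-space contract."""


@dataclass(frozen=True)
class SemanticSpace:
    """An immutable memory matrix with named states and features.

    Parameters
    ----------
    state_names:
        Unique identifier per state (row).
    features:
        Real matrix of shape ``(n_states, n_features)``.
    feature_names:
        Ordered column names.
    class_labels:
        Optional categorical label per state (e.g. taxonomic class).
    """

    state_names: tuple[str, ...]
    features: np.ndarray
    feature_names: tuple[str, ...]
    class_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        feats.setflags(write=False)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if self.class_labels is not None:
            object.__setattr__(self, "class_labels", tuple(self.class_labels))

        if feats.ndim != 2:
            raise SpaceValidationError("features must be a 2-D matrix")
        n, f = feats.shape
        if n < 2:
            raise SpaceValidationError("a semantic space needs at least 2 states")
        if f < 1:
            raise SpaceValidationError("a semantic space needs at least 1 feature")
        if len(self.state_names) != n:
            raise SpaceValidationError("state_names length does not match features")
        if len(self.feature_names) != f:
            raise SpaceValidationError("feature_names length does not match features")
        if len(set(self.state_names)) != n:
            dupes = sorted({s for s in self.state_names if self.state_names.count(s) > 1})
            raise SpaceValidationError(f"duplicate state names: {dupes}")
        if self.class_labels is not None and len(self.class_labels) != n:
            raise SpaceValidationError("class_labels length does not match features")
        if not np.all(np.isfinite(feats)):
            raise SpaceValidationError("all feature values must be finite")
        if np.any(feats == MISSING_SENTINEL):
            raise SpaceValidationError(
                f"stored memories must not contain the missing-value sentinel "
                f"{MISSING_SENTINEL}"
            )

    @property
    def n_states(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def feature_ranges(self) -> np.ndarray:
        """Per-feature ``max - min`` over the memory matrix."""
        return self.features.max(axis=0) - self.features.min(axis=0)

    def zscored(self) -> "SemanticSpace":
        """Copy with each feature standardised to zero mean, unit variance."""
        feats = np.asarray(self.features, dtype=float)
        std = feats.std(axis=0)
        std[std == 0] = 1.0
        return SemanticSpace(
            self.state_names,
            (feats - feats.mean(axis=0)) / std,
            self.feature_names,
            self.class_labels,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df.insert(0, "name", list(self.state_names))
        if self.class_labels is not None:
            df["class"] = list(self.class_labels)
        return df


@dataclass(frozen=True)
class PartialFeatureVector:
    """A feature vector where unknown entries hold the sentinel ``-1``."""

    values: np.ndarray
    mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        vals.setflags(write=False)
        mask = vals != MISSING_SENTINEL
        mask.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mask", mask)
        if not mask.any():
            raise SpaceValidationError("at least one feature must be known")
        if not np.all(np.isfinite(vals[mask])):
            raise SpaceValidationError("known features must be finite")

    @property
    def n_missing(self) -> int:
        return int((~self.mask).sum())

    @classmethod
    def from_full(cls, values: np.ndarray, missing: "list[int] | np.ndarray" = ()) -> "PartialFeatureVector":
        """Mask the given positions of a complete vector with the sentinel."""
        vals = np.array(values, dtype=float)
        vals[np.asarray(missing, dtype=int)] = MISSING_SENTINEL
        return cls(vals)


def _fixture_path(name: str) -> Path:
    return Path(str(importlib.resources.files("cogmap").joinpath("data", f"{name}.csv")))


def load_space(table: str | Path) -> SemanticSpace:
    """Load a semantic space from a CSV table or an embedded fixture name.

    The table needs a header row; the first column holds state names, an
    optional ``class`` column holds categorical labels, and every other
    column is parsed as a numeric feature (column order preserved).
    """
    if isinstance(table, str) and table in FIXTURE_NAMES:
        path = _fixture_path(table)
    else:
        path = Path(table)
        if not path.exists():
            raise FileNotFoundError(
                f"no such file or fixture: {table!r} (fixtures: {', '.join(FIXTURE_NAMES)})"
            )
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise SpaceValidationError("table needs a name column and at least one feature")
    name_col = df.columns[0]
    names = df[name_col].astype(str).tolist()
    labels = df["class"].astype(str).tolist() if "class" in df.columns else None
    feature_cols = [c for c in df.columns[1:] if c != "class"]
    values = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise SpaceValidationError(
                    f"non-numeric feature value {cell!r} at row {i + 2} "
                    f"(state {names[i]!r}), column {col!r}"
                ) from None
    return SemanticSpace(names, values, feature_cols, labels)


def write_space(space: SemanticSpace, path: str | Path) -> None:
    """Write a space back to CSV in the same layout ``load_space`` reads."""
    df = space.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def generate_random_space(
    n_states: int,
    n_features: int,
    n_classes: int = 1,
    class_separation: float = 10.0,
    seed: int | None = None,
) -> SemanticSpace:
    """Draw a synthetic semantic space around well-separated class centroids.

    States are assigned round-robin to ``n_classes`` classes; each class
    centroid is an isotropic Gaussian draw scaled by ``class_separation``,
    and states scatter around their centroid with unit noise. With
    ``class_separation = 0`` all centroids coincide and the classes are
    statistically indistinguishable.
    """
    if n_states < 2 or n_classes < 1 or n_states < n_classes or n_features < 1:
        raise SpaceValidationError(
            "need n_states >= n_classes >= 1, n_states >= 2, n_features >= 1"
        )
    if class_separation < 0:
        raise SpaceValidationError("class_separation must be non-negative")
    rng = np.random.default_rng(seed)
    centroids = rng.normal(size=(n_classes, n_features)) * class_separation
    assignment = np.arange(n_states) % n_classes
    feats = centroids[assignment] + rng.normal(size=(n_states, n_features))
    # Nudge the (measure-zero) collisions with the -1 sentinel off it.
    feats[feats == MISSING_SENTINEL] += 1e-9
    names = [f"s{i:03d}" for i in range(n_states)]
    labels = [f"c{k}" for k in assignment]
    return SemanticSpace(names, feats, [f"f{j}" for j in range(n_features)], labels)
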