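"""Core in-memory containers shared by every pipeline stage.

The common currency is the :class:`OmicsMatrix` — a features × samples numeric
table tagged with its biological layer (mRNA, lncRNA, or microbial OTU) and the
scale its values are on (raw intensity/counts, log2, or per-feature Z-scores).
Sample annotations (two-level group plus batch factors) live in
:class:`SampleMetadata`, and GMT-style gene sets in :class:`GeneSetCollection`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Layer",
    "Scale",
    "OmicsMatrix",
    "SampleMetadata",
    "GeneSetCollection",
]


class Layer(str, Enum):
    MRNA = "mrna"
    LNCRNA = "lncrna"
    OTU = "otu"
    #: internal: the joint mRNA+lncRNA array before the ID-prefix layer split
    TRANSCRIPT = "transcript"


class Scale(str, Enum):
    RAW = "raw"
    LOG2 = "log2"
    ZSCORE = "zscore"


@dataclass
class OmicsMatrix:
    """Feature × sample numeric matrix with layer and scale tags.

    Parameters
    ----------
    data:
        DataFrame with feature IDs as the index and sample IDs as columns.
        Values must be finite floats; missing cells are rejected.
    layer:
        Biological layer of the features.
    scale:
        Scale of the values (``raw`` intensities/counts, ``log2``, ``zscore``).
    """

    data: pd.DataFrame
    layer: Layer
    scale: Scale

    def __post_init__(self) -> None:
        self.layer = Layer(self.layer)
        self.scale = Scale(self.scale)
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("OmicsMatrix.data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("OmicsMatrix values must be numeric")
        if values.size and not np.isfinite(values).all():
            raise ValueError("OmicsMatrix values must be finite (no missing cells)")

    # -- convenience views -------------------------------------------------

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
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_values(self, values: np.ndarray, scale: Scale | None = None) -> "OmicsMatrix":
        """Return a copy with the same IDs but new values (and optionally scale)."""
        df = pd.DataFrame(np.asarray(values, dtype=float),
                          index=self.data.index, columns=self.data.columns)
        return OmicsMatrix(df, self.layer, scale if scale is not None else self.scale)

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return OmicsMatrix(self.data.loc[list(feature_ids)], self.layer, self.scale)


@dataclass
class SampleMetadata:
    """Per-sample group assignment and batch factor levels.

    ``table`` is indexed by sample ID with a ``group`` column (exactly two
    levels, both non-empty) and one column per batch factor (every level must
    contain at least two samples so batch variances are estimable).
    """

    table: pd.DataFrame
    group_col: str = "group"
    batch_cols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample IDs in metadata")
        if self.group_col not in self.table.columns:
            raise ValueError(f"metadata lacks group column {self.group_col!r}")
        groups = self.table[self.group_col].unique()
        if len(groups) != 2:
            raise ValueError(f"group must have exactly two levels, got {list(groups)}")
        self.batch_cols = tuple(self.batch_cols)
        for col in self.batch_cols:
            if col not in self.table.columns:
                raise ValueError(f"metadata lacks batch column {col!r}")
            counts = self.table[col].value_counts()
            if (counts < 2).any():
                bad = counts[counts < 2].index.tolist()
                raise ValueError(
                    f"batch factor {col!r} has levels with <2 samples: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.table.index]

    @property
    def group_levels(self) -> list[str]:
        # stable order: first occurrence wins (group A = reference)
        seen: dict[str, None] = {}
        for g in self.table[self.group_col]:
            seen.setdefault(str(g), None)
        return list(seen)

    def groups_for(self, sample_ids) -> np.ndarray:
        return self.table.loc[list(sample_ids), self.group_col].to_numpy()

    def aligned_to(self, m: OmicsMatrix) -> "SampleMetadata":
        """Metadata restricted/reordered to the samples of ``m``."""
        missing = [s for s in m.sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing[:5]}")
        return SampleMetadata(self.table.loc[m.sample_ids],
                              self.group_col, self.batch_cols)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics) with an optional explicit universe."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    universe: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def members(self, name: str) -> set[str]:
        return set(self.sets[name][1])

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)
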