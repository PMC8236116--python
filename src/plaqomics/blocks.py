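"""Core containers for aligned multi-omics data.

An :class:`OmicsBlock` holds one omics layer as a features x samples matrix
(log-scale abundances after normalization) with ``NaN`` marking missing
entries.  A :class:`MultiOmicsDataset` bundles several blocks measured on the
same samples together with the binary phenotype, the patient pairing labels
and optional continuous plaque-trait covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["OmicsBlock", "MultiOmicsDataset"]


@dataclass
class OmicsBlock:
    """One omics layer: a features x samples abundance matrix.

    Parameters
    ----------
    name : str
        Block label, e.g. ``"gene"``, ``"protein"`` or ``"peptide"``.
    values : pandas.DataFrame
        Features as rows (index = feature ids), samples as columns
        (columns = sample ids).  ``NaN`` encodes a missing measurement.
    """

    name: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"block {self.name!r}: duplicate feature ids {dup[:5]}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"block {self.name!r}: duplicate sample ids {dup[:5]}")
        self.values = self.values.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True where the value is undefined)."""
        return self.values.isna()

    @property
    def has_missing(self) -> bool:
        return bool(self.values.isna().to_numpy().any())

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing samples."""
        return self.values.isna().mean(axis=1)

    def overall_missing_fraction(self) -> float:
        return float(self.values.isna().to_numpy().mean())

    # -- manipulation ----------------------------------------------------
    def with_values(self, values: pd.DataFrame) -> "OmicsBlock":
        return OmicsBlock(self.name, values)

    def select_features(self, feature_ids: Sequence[str]) -> "OmicsBlock":
        return OmicsBlock(self.name, self.values.loc[list(feature_ids)])

    def select_samples(self, sample_ids: Sequence[str]) -> "OmicsBlock":
        return OmicsBlock(self.name, self.values.loc[:, list(sample_ids)])

    def to_samples_by_features(self) -> np.ndarray:
        """Return the matrix oriented samples x features (the model orientation)."""
        return self.values.to_numpy().T


@dataclass
class MultiOmicsDataset:
    """Aligned omics blocks plus phenotype, pairing and trait covariates.

    Invariants: every block carries exactly the same samples in the same
    order, and the phenotype has exactly two levels.
    """

    blocks: list[OmicsBlock]
    y: pd.Series
    patient_id: pd.Series | None = None
    traits: pd.DataFrame | None = None
    positive_label: str | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("dataset needs at least one block")
        ref = self.blocks[0].sample_ids
        for b in self.blocks[1:]:
            if not b.sample_ids.equals(ref):
                raise ValueError(
                    f"block {b.name!r} sample ids differ from block "
                    f"{self.blocks[0].name!r}"
                )
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate block names {names}")
        self.y = pd.Series(self.y)
        if not self.y.index.equals(ref):
            self.y = self.y.reindex(ref)
        if self.y.isna().any():
            raise ValueError("phenotype missing for some samples")
        levels = pd.unique(self.y)
        if len(levels) != 2:
            raise ValueError(f"phenotype must have exactly 2 levels, got {list(levels)}")
        if self.positive_label is None:
            self.positive_label = sorted(map(str, levels))[-1]
        elif self.positive_label not in set(map(str, levels)):
            raise ValueError(f"positive_label {self.positive_label!r} not a phenotype level")
        if self.patient_id is not None:
            self.patient_id = pd.Series(self.patient_id).reindex(ref)
        if self.traits is not None:
            self.traits = self.traits.reindex(ref)

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.blocks[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    @property
    def classes(self) -> list[str]:
        return sorted(map(str, pd.unique(self.y)))

    def block(self, name: str) -> OmicsBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no block named {name!r}")

    def has_missing(self) -> bool:
        return any(b.has_missing for b in self.blocks)

    # -- subsetting ------------------------------------------------------
    def subset(self, indices: Sequence[int]) -> "MultiOmicsDataset":
        """Positional sample subset; repeats allowed (bootstrap copies).

        Repeated samples get a ``#<k>`` suffix so sample ids stay unique.
        """
        indices = list(indices)
        base = self.sample_ids.to_numpy()
        seen: dict[str, int] = {}
        new_ids = []
        for i in indices:
            sid = str(base[i])
            k = seen.get(sid, 0)
            seen[sid] = k + 1
            new_ids.append(sid if k == 0 else f"{sid}#{k}")
        blocks = []
        for b in self.blocks:
            vals = b.values.iloc[:, indices].copy()
            vals.columns = new_ids
            blocks.append(OmicsBlock(b.name, vals))
        y = pd.Series(self.y.to_numpy()[indices], index=new_ids)
        pid = None
        if self.patient_id is not None:
            pid = pd.Series(self.patient_id.to_numpy()[indices], index=new_ids)
        traits = None
        if self.traits is not None:
            traits = self.traits.iloc[indices].copy()
            traits.index = new_ids
        return MultiOmicsDataset(blocks, y, pid, traits, positive_label=self.positive_label)

    def with_blocks(self, blocks: list[OmicsBlock]) -> "MultiOmicsDataset":
        return MultiOmicsDataset(
            blocks, self.y, self.patient_id, self.traits, positive_label=self.positive_label
        )

    def with_permuted_labels(self, seed: int) -> "MultiOmicsDataset":
        """Return a copy with the phenotype labels randomly permuted."""
        rng = np.random.default_rng(seed)
        perm = rng.permutation(self.n_samples)
        y = pd.Series(self.y.to_numpy()[perm], index=self.sample_ids)
        return MultiOmicsDataset(
            self.blocks, y, self.patient_id, self.traits, positive_label=self.positive_label
        )
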