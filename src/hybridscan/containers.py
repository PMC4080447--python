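"""In-memory containers shared across the pipeline stages.

Dosages count haplotypes of parent-1 (P1) ancestry, so 2 = homozygous P1,
1 = heterozygous, 0 = homozygous P2; missing entries are NaN.  The hybrid
index of an individual is its mean dosage over called markers divided by 2,
i.e. the proportion of its genome deriving from P1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import markers_frame

#: hidden-state order used by the posterior matrices: hom-P1, het, hom-P2
STATES = ("hom1", "het", "hom2")
#: dosage carried by each state
STATE_DOSAGE = np.array([2, 1, 0])


@dataclass(eq=False)
class AncestryGenotypeMatrix:
    """Individuals x markers dosage matrix (0/1/2/NaN) of P1 ancestry."""

    data: pd.DataFrame  # float; index = individuals, columns = "group:pos" IDs

    def __post_init__(self):
        vals = self.data.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-dosage value {vals[i, j]!r} at individual "
                f"{self.data.index[i]!r}, marker {self.data.columns[j]!r}"
            )
        if self.data.columns.duplicated().any():
            raise ValueError("duplicated marker IDs")

    @property
    def markers(self) -> pd.DataFrame:
        return markers_frame(self.data.columns)

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    @property
    def hybrid_index(self) -> pd.Series:
        """Proportion of P1 ancestry per individual; NaN if nothing called."""
        return self.data.mean(axis=1, skipna=True) / 2.0

    def dosage(self, marker: str) -> np.ndarray:
        return self.data[marker].to_numpy(dtype=float)

    def select_markers(self, ids) -> "AncestryGenotypeMatrix":
        return AncestryGenotypeMatrix(self.data.loc[:, list(ids)])

    def select_individuals(self, ids) -> "AncestryGenotypeMatrix":
        return AncestryGenotypeMatrix(self.data.loc[list(ids)])


@dataclass(eq=False)
class ReadCountTable:
    """Per-individual, per-marker counts of reads supporting each parent."""

    p1: pd.DataFrame  # reads supporting the P1 allele
    p2: pd.DataFrame  # reads supporting the P2 allele

    def __post_init__(self):
        if not self.p1.shape == self.p2.shape:
            raise ValueError("p1/p2 count tables must have identical shape")
        if not (self.p1.columns.equals(self.p2.columns) and self.p1.index.equals(self.p2.index)):
            raise ValueError("p1/p2 count tables must share index and columns")
        if (self.p1.to_numpy() < 0).any() or (self.p2.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def markers(self) -> pd.DataFrame:
        return markers_frame(self.p1.columns)

    @property
    def total(self) -> pd.DataFrame:
        return self.p1 + self.p2


@dataclass(eq=False)
class PosteriorMatrix:
    """Per individual x marker posterior over (hom-P1, het, hom-P2)."""

    probs: np.ndarray  # (n_individuals, n_markers, 3)
    individuals: pd.Index
    marker_ids: pd.Index

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.individuals = pd.Index(self.individuals)
        self.marker_ids = pd.Index(self.marker_ids)
        if self.probs.shape != (len(self.individuals), len(self.marker_ids), 3):
            raise ValueError("posterior array shape mismatch")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("posterior triples must sum to 1")

    @property
    def markers(self) -> pd.DataFrame:
        return markers_frame(self.marker_ids)

    def select_markers(self, ids) -> "PosteriorMatrix":
        idx = self.marker_ids.get_indexer(list(ids))
        if (idx < 0).any():
            raise KeyError("unknown marker ID")
        return PosteriorMatrix(self.probs[:, idx, :], self.individuals, pd.Index(list(ids)))

    def to_frame(self) -> pd.DataFrame:
        """Wide frame with three columns per marker, suffixed .hom1/.het/.hom2."""
        cols, blocks = [], []
        for k, st in enumerate(STATES):
            cols.extend(f"{m}.{st}" for m in self.marker_ids)
            blocks.append(self.probs[:, :, k])
        # interleave per marker for readability
        frame = pd.DataFrame(
            np.concatenate(blocks, axis=1), index=self.individuals, columns=cols
        )
        order = [f"{m}.{st}" for m in self.marker_ids for st in STATES]
        return frame[order]
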