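"""Genome map and marker coordinate handling.

Coordinates are 0-based, half-open throughout: a marker at position ``x``
takes the ancestry of the segment containing ``x``.  The map assumes a
uniform recombination rate, by default 1 cM per 378 kb (the genome-wide
average used for swordtail linkage groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CM_PER_KB = 1.0 / 378.0


def marker_id(group: str, pos: int) -> str:
    return f"{group}:{int(pos)}"


def parse_marker_id(mid: str) -> tuple[str, int]:
    group, _, pos = mid.rpartition(":")
    return group, int(pos)


def markers_frame(ids) -> pd.DataFrame:
    """Parse ``group:pos`` marker IDs into a (group, pos) frame indexed by ID."""
    rows = [parse_marker_id(m) for m in ids]
    return pd.DataFrame(rows, columns=["group", "pos"], index=list(ids))


@dataclass(eq=False)
class GenomeMap:
    """Linkage groups with lengths (bp), a uniform map rate and optional markers.

    Parameters
    ----------
    linkage_groups
        Sequence of ``(group_id, length_bp)``.
    cm_per_kb
        Uniform recombination rate in cM/kb; default 1/378.
    markers
        Optional frame with columns ``group`` and ``pos`` (strictly
        increasing within each group), indexed by marker ID.
    """

    linkage_groups: tuple
    cm_per_kb: float = DEFAULT_CM_PER_KB
    markers: pd.DataFrame | None = field(default=None)

    def __post_init__(self):
        self.linkage_groups = tuple((str(g), int(L)) for g, L in self.linkage_groups)
        if not self.linkage_groups:
            raise ValueError("need at least one linkage group")
        if any(L <= 0 for _, L in self.linkage_groups):
            raise ValueError("linkage group lengths must be > 0")
        if self.cm_per_kb <= 0:
            raise ValueError("recombination rate must be > 0")
        if self.markers is not None:
            self._validate_markers(self.markers)

    def _validate_markers(self, mk: pd.DataFrame) -> None:
        lengths = self.group_lengths
        for group, sub in mk.groupby("group", sort=False):
            if group not in lengths:
                raise ValueError(f"marker group {group!r} not in map")
            pos = sub["pos"].to_numpy()
            if (pos < 0).any() or (pos >= lengths[group]).any():
                raise ValueError(f"marker position off group {group!r}")
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"marker positions not strictly increasing on {group!r}")

    @property
    def group_lengths(self) -> dict:
        return dict(self.linkage_groups)

    @property
    def group_ids(self) -> list:
        return [g for g, _ in self.linkage_groups]

    @property
    def morgans_per_bp(self) -> float:
        # cM/kb -> Morgans/bp
        return self.cm_per_kb / 100.0 / 1000.0

    def group_morgans(self, group: str) -> float:
        return self.group_lengths[group] * self.morgans_per_bp

    @property
    def total_morgans(self) -> float:
        return sum(L for _, L in self.linkage_groups) * self.morgans_per_bp

    def bp_to_morgans(self, d_bp) -> float:
        return np.asarray(d_bp, dtype=float) * self.morgans_per_bp

    def with_markers(self, markers: pd.DataFrame) -> "GenomeMap":
        mk = markers.copy()
        if mk.index.duplicated().any():
            raise ValueError("duplicated marker IDs")
        return GenomeMap(self.linkage_groups, self.cm_per_kb, mk)

    def uniform_markers(self, spacing_bp: int, offset_bp: int = 0) -> "GenomeMap":
        """Attach markers every ``spacing_bp`` along every group."""
        rows, ids = [], []
        for group, L in self.linkage_groups:
            for pos in range(offset_bp, L, spacing_bp):
                rows.append((group, pos))
                ids.append(marker_id(group, pos))
        mk = pd.DataFrame(rows, columns=["group", "pos"], index=ids)
        return self.with_markers(mk)

    def require_markers(self) -> pd.DataFrame:
        if self.markers is None:
            raise ValueError("GenomeMap has no markers attached")
        return self.markers
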