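"""Collapsing marker-level significant pairs into independent LD regions.

Contiguous markers on a chromosome typically carry the same cross-chromosome
LD signal; clustering walks each group left to right and starts a new block
whenever the focal marker is no longer significantly associated (p >=
threshold) with the last member of the current block.  Blocks from two
populations are intersected partner-pair by partner-pair to narrow candidate
regions, and a local-vs-cross-chromosome LD comparison flags block edges
that look like assembly artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AncestryGenotypeMatrix
from .genome import GenomeMap, parse_marker_id
from .ld import ancestry_R, pair_pvalue


@dataclass(eq=False)
class LDBlock:
    group: str
    start: int
    end: int
    members: list  # marker IDs, sorted by position

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("block interval must have start < end")

    def interval(self) -> tuple:
        return (self.start, self.end)


def cluster_blocks(
    significant_markers,
    geno: AncestryGenotypeMatrix,
    p_threshold: float = 0.013,
    method: str = "ordinal_logistic",
) -> list:
    """Greedy left-to-right clustering of significant markers on one group.

    A focal marker joins the current cluster iff its pairwise p-value with
    the cluster's *last* member is below the threshold; otherwise it starts
    a new cluster.  Single-marker blocks get the marker's unit BED interval.
    """
    mk = [(m, *parse_marker_id(m)) for m in significant_markers]
    groups = {g for _, g, _ in mk}
    if len(groups) > 1:
        raise ValueError("cluster_blocks expects markers from a single group")
    mk.sort(key=lambda t: t[2])
    blocks = []
    current = []
    for m, group, pos in mk:
        if current:
            last = current[-1]
            _, p = pair_pvalue(
                geno.dosage(last[0]), geno.dosage(m), method=method
            )
            if p >= p_threshold:
                blocks.append(current)
                current = []
        current.append((m, group, pos))
    if current:
        blocks.append(current)
    out = []
    for cluster in blocks:
        group = cluster[0][1]
        start = cluster[0][2]
        end = cluster[-1][2]
        if end == start:
            end = start + 1  # zero-length block -> the marker's BED interval
        out.append(LDBlock(group, start, end, [m for m, _, _ in cluster]))
    return out


def blocks_from_joint_pairs(
    joint: pd.DataFrame,
    geno: AncestryGenotypeMatrix,
    p_threshold: float = 0.013,
    method: str = "ordinal_logistic",
) -> pd.DataFrame:
    """Cluster the markers of joint-significant pairs and pair up the blocks.

    Returns one row per (block_a, block_b) partner pair with the member
    marker-pair count and the dominant sign concordance.
    """
    if len(joint) == 0:
        return pd.DataFrame(
            columns=["group_a", "start_a", "end_a", "group_b", "start_b", "end_b",
                     "n_marker_pairs", "concordance"]
        )
    by_group = {}
    for col in ("marker_i", "marker_j"):
        for m in joint[col]:
            g, _ = parse_marker_id(m)
            by_group.setdefault(g, set()).add(m)
    block_of = {}
    for g, ms in by_group.items():
        for blk in cluster_blocks(sorted(ms), geno, p_threshold, method):
            for m in blk.members:
                block_of[m] = blk
    rows = {}
    for _, row in joint.iterrows():
        ba = block_of[row["marker_i"]]
        bb = block_of[row["marker_j"]]
        if (ba.group, ba.start) > (bb.group, bb.start):
            ba, bb = bb, ba
        key = (id(ba), id(bb))
        entry = rows.setdefault(
            key,
            {"group_a": ba.group, "start_a": ba.start, "end_a": ba.end,
             "group_b": bb.group, "start_b": bb.start, "end_b": bb.end,
             "n_marker_pairs": 0, "signs": []},
        )
        entry["n_marker_pairs"] += 1
        entry["signs"].append(row.get("concordance", ""))
    recs = []
    for entry in rows.values():
        signs = entry.pop("signs")
        entry["concordance"] = max(set(signs), key=signs.count) if signs else ""
        recs.append(entry)
    return pd.DataFrame(recs)


def intersect_populations(pairs1: pd.DataFrame, pairs2: pd.DataFrame) -> pd.DataFrame:
    """Interval intersection of partner block pairs found in two populations.

    A pair of region pairs matches when both sides overlap (same groups,
    intersecting intervals); the result carries the intersected intervals.
    Pairs with an empty intersection on either side are dropped.
    """
    rows = []
    for _, a in pairs1.iterrows():
        for _, b in pairs2.iterrows():
            for flip in (False, True):
                ga, gb = ("group_a", "group_b") if not flip else ("group_b", "group_a")
                sa, ea = ("start_a", "end_a") if not flip else ("start_b", "end_b")
                sb, eb = ("start_b", "end_b") if not flip else ("start_a", "end_a")
                if a["group_a"] != b[ga] or a["group_b"] != b[gb]:
                    continue
                lo_a = max(a["start_a"], b[sa])
                hi_a = min(a["end_a"], b[ea])
                lo_b = max(a["start_b"], b[sb])
                hi_b = min(a["end_b"], b[eb])
                if lo_a < hi_a and lo_b < hi_b:
                    rows.append(
                        (a["group_a"], lo_a, hi_a, a["group_b"], lo_b, hi_b)
                    )
                break
    return pd.DataFrame(
        rows, columns=["group_a", "start_a", "end_a", "group_b", "start_b", "end_b"]
    ).drop_duplicates().reset_index(drop=True)


def misassembly_check(
    blocks: list,
    geno: AncestryGenotypeMatrix,
    local_radius: float = 300_000.0,
):
    """Compare local vs cross-chromosome LD at block-edge markers.

    A block-edge marker is flagged when its maximum cross-chromosome R^2
    exceeds its maximum R^2 with same-group neighbours within
    ``local_radius`` (a translocated contig would show exactly that).  Edge
    markers with no neighbour in the radius are excluded from the
    denominator.  Returns ``(per-marker frame, flagged fraction)``.
    """
    markers = geno.markers
    data = geno.data.to_numpy(dtype=float)
    ids = list(geno.data.columns)
    idx_of = {m: k for k, m in enumerate(ids)}
    groups = markers["group"].to_numpy()
    pos = markers["pos"].to_numpy()
    rows = []
    for blk in blocks:
        edges = {blk.members[0], blk.members[-1]}
        for m in edges:
            k = idx_of[m]
            local = np.nonzero(
                (groups == groups[k]) & (np.abs(pos - pos[k]) <= local_radius)
                & (np.arange(len(ids)) != k)
            )[0]
            if len(local) == 0:
                rows.append((m, np.nan, np.nan, None))
                continue
            cross = np.nonzero(groups != groups[k])[0]
            local_vals = np.array([ancestry_R(data[:, k], data[:, j])[1] for j in local])
            cross_vals = np.array([ancestry_R(data[:, k], data[:, j])[1] for j in cross])
            local_r2 = np.nanmax(local_vals) if np.isfinite(local_vals).any() else np.nan
            cross_r2 = np.nanmax(cross_vals) if np.isfinite(cross_vals).any() else np.nan
            flagged = bool(np.nan_to_num(cross_r2) > np.nan_to_num(local_r2))
            rows.append((m, local_r2, cross_r2, flagged))
    frame = pd.DataFrame(rows, columns=["marker", "local_R2", "cross_R2", "flagged"])
    evaluated = frame["flagged"].notna()
    frac = float(frame.loc[evaluated, "flagged"].astype(bool).mean()) if evaluated.any() else np.nan
    return frame, frac
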