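"""Per-site divergence of LD regions versus the genomic background.

Consumes precomputed per-region divergent-site counts and aligned lengths
(optionally split into synonymous/nonsynonymous site classes) and asks, by
resampling, whether regions in significant cross-chromosome LD are more
diverged between the parental species than same-size draws from the
genomic background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeMap

REQUIRED_COLUMNS = ("group", "start", "end", "divergent_sites", "aligned_length")


def region_divergence(table: pd.DataFrame, count_col: str = "divergent_sites",
                      length_col: str = "aligned_length") -> pd.Series:
    """Divergence per region: divergent site count / aligned length."""
    if (table[length_col] <= 0).any():
        raise ValueError("aligned_length must be > 0 for every region")
    if (table[count_col] > table[length_col]).any():
        raise ValueError("site counts exceed region length")
    return table[count_col] / table[length_col]


def expand_single_marker_regions(regions: pd.DataFrame, gmap: GenomeMap) -> pd.DataFrame:
    """Extend single-marker (zero-length) regions to their flanking markers.

    A region spanning a single marker is widened to run from the nearest
    upstream marker to the nearest downstream marker on the same group; at a
    group edge only the available side is extended.
    """
    mk = gmap.require_markers()
    out = regions.copy()
    for i, row in regions.iterrows():
        if row["end"] - row["start"] > 1:
            continue
        sub = mk[mk["group"] == row["group"]]["pos"].to_numpy()
        pos = row["start"]
        left = sub[sub < pos]
        right = sub[sub > pos]
        out.loc[i, "start"] = int(left.max()) if len(left) else int(row["start"])
        out.loc[i, "end"] = int(right.min()) if len(right) else int(row["end"])
    return out


@dataclass(eq=False)
class BackgroundComparison:
    observed_mean: float
    observed_ci: tuple
    observed_median: float
    null_means: np.ndarray
    p_value: float


def background_comparison(
    ld_regions: pd.DataFrame,
    background_regions: pd.DataFrame,
    n_null: int = 1000,
    seed: int = 0,
    count_col: str = "divergent_sites",
    length_col: str = "aligned_length",
) -> BackgroundComparison:
    """One-sided resampling test: are LD regions more diverged than background?

    The observed CI resamples LD regions with replacement; the null
    distribution is the mean divergence of ``n_null`` same-size background
    samples drawn without replacement; p is the fraction of null means at or
    above the observed mean.
    """
    if len(background_regions) <= len(ld_regions):
        raise ValueError("background must be larger than the LD region set")
    rng = np.random.default_rng(seed)
    ld_div = region_divergence(ld_regions, count_col, length_col).to_numpy()
    bg_div = region_divergence(background_regions, count_col, length_col).to_numpy()
    observed = float(ld_div.mean())
    boot = np.array(
        [ld_div[rng.integers(0, len(ld_div), len(ld_div))].mean() for _ in range(n_null)]
    )
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    null_means = np.array(
        [rng.choice(bg_div, size=len(ld_div), replace=False).mean() for _ in range(n_null)]
    )
    p = float((null_means >= observed - 1e-15).mean())
    return BackgroundComparison(observed, ci, float(np.median(ld_div)), null_means, p)
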