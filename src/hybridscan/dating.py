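"""Dating a hybrid zone from the decay of admixture LD with distance.

A single admixture pulse T generations ago leaves pairwise disequilibrium
D(x) = a exp(-T x) between markers x Morgans apart: each generation of
random mating multiplies D by (1 - c) ~ exp(-x).  Fitting the exponential
to (distance, D) points therefore estimates the number of generations since
admixture.  D is measured as half the dosage covariance (the diploid
composite-D convention), restricted to markers informative for the minor
parental species (autapomorphic markers in real data; tagged subsets in
synthetic data), and distance uses the uniform 1 cM/378 kb map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .containers import AncestryGenotypeMatrix
from .genome import GenomeMap

MIN_POINTS = 10


def pairwise_D(
    geno: AncestryGenotypeMatrix,
    gmap: GenomeMap,
    minor_parent: str = "P1",
    markers=None,
    max_dist_bp: float | None = None,
) -> pd.DataFrame:
    """Within-group (distance in Morgans, D) points from dosage covariances.

    ``markers`` restricts the computation to a caller-supplied informative
    subset (e.g. minor-parent autapomorphic markers); ``minor_parent``
    selects the dosage orientation, which leaves covariances unchanged but
    makes D at zero distance the minor-parent ancestry variance.
    """
    data = geno.data if markers is None else geno.data[list(markers)]
    mk = AncestryGenotypeMatrix(data).markers
    dosage = data.to_numpy(dtype=float)
    if minor_parent == "P2":
        dosage = 2.0 - dosage
    rows = []
    for group, sub in mk.groupby("group", sort=False):
        idx = mk.index.get_indexer(sub.index)
        if len(idx) < 2:
            continue
        pos = sub["pos"].to_numpy(dtype=float)
        cov = pd.DataFrame(dosage[:, idx]).cov(min_periods=2).to_numpy()
        iu, ju = np.triu_indices(len(idx), k=1)
        d_bp = np.abs(pos[ju] - pos[iu])
        D = cov[iu, ju] / 2.0
        ok = np.isfinite(D)
        if max_dist_bp is not None:
            ok &= d_bp <= max_dist_bp
        for d, v in zip(d_bp[ok], D[ok]):
            rows.append((gmap.bp_to_morgans(d), v))
    points = pd.DataFrame(rows, columns=["x", "D"])
    if len(points) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} (x, D) points, got {len(points)}")
    return points


@dataclass(eq=False)
class DecayFit:
    T_hat: float
    a_hat: float
    ci: tuple | None  # bootstrap CI on T
    points: pd.DataFrame


def _exp_decay(x, a, T):
    return a * np.exp(-T * x)


def _fit(points: pd.DataFrame):
    x = points["x"].to_numpy()
    D = points["D"].to_numpy()
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct distances")
    a0 = max(D.max(), 1e-6)
    T0 = 1.0 / max(x.mean(), 1e-12)
    try:
        popt, _ = curve_fit(_exp_decay, x, D, p0=(a0, T0), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"exponential decay fit did not converge: {err}") from err
    a_hat, T_hat = popt
    if T_hat < 0:
        import warnings

        warnings.warn("fitted T < 0; clipping to 0")
        T_hat = 0.0
    return float(a_hat), float(T_hat)


def fit_decay(points: pd.DataFrame, n_boot: int = 0, seed: int = 0) -> DecayFit:
    """Nonlinear least squares for D = a exp(-T x).

    The optional bootstrap here resamples *points* (marker pairs); the
    individual-level bootstrap is in :func:`estimate_age`, which can
    recompute points from resampled individuals.
    """
    a_hat, T_hat = _fit(points)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        ts = []
        for _ in range(n_boot):
            take = rng.integers(0, len(points), len(points))
            try:
                ts.append(_fit(points.iloc[take])[1])
            except (ValueError, RuntimeError):
                continue
        if ts:
            lo, hi = np.percentile(ts, [2.5, 97.5])
            ci = (float(min(lo, T_hat)), float(max(hi, T_hat)))
    return DecayFit(T_hat, a_hat, ci, points)


def estimate_age(
    geno: AncestryGenotypeMatrix,
    gmap: GenomeMap,
    minor_parent: str = "P1",
    markers=None,
    max_dist_bp: float | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> DecayFit:
    """Generations since admixture, with an individual-resampling bootstrap CI."""
    points = pairwise_D(geno, gmap, minor_parent, markers, max_dist_bp)
    fit = fit_decay(points)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        ts = []
        for _ in range(n_boot):
            take = rng.integers(0, geno.n_individuals, geno.n_individuals)
            boot = AncestryGenotypeMatrix(
                geno.data.iloc[take].reset_index(drop=True)
            )
            try:
                pts = pairwise_D(boot, gmap, minor_parent, markers, max_dist_bp)
                ts.append(_fit(pts)[1])
            except (ValueError, RuntimeError):
                continue
        if ts:
            lo, hi = np.percentile(ts, [2.5, 97.5])
            ci = (float(min(lo, fit.T_hat)), float(max(hi, fit.T_hat)))
    return DecayFit(fit.T_hat, fit.a_hat, ci, points)
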