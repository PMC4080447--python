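"""Cross-chromosome ancestry linkage disequilibrium scanning and calibration.

R between two markers is the Pearson correlation of unphased ancestry
dosages over pairwise-complete individuals (the composite-LD estimator for
unphased data).  Per-pair significance comes from a proportional-odds
ordinal regression of one marker's dosage on the other, stabilised by a
weak ridge penalty on the slope (a Gaussian prior with standard deviation
2.5, the conventional weakly-informative default for ordered-logit
stabilisation, which keeps the slope finite under complete separation); the
slope/SE ratio is referred to a Student t distribution with n - 2 degrees
of freedom.  An exact permutation test is available both as a fallback for
degenerate tables and as an independent testing oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit

from .containers import AncestryGenotypeMatrix
from .genome import GenomeMap

RIDGE_PRIOR_VARIANCE = 2.5**2


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def ancestry_R(x, y):
    """Signed dosage correlation R and R^2 over pairwise-complete individuals.

    Returns ``(nan, nan)`` when either vector is constant after deletion
    (undefined; such pairs are excluded from scans).
    """
    x, y = _complete_pairs(x, y)
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r


def _ordinal_nll_grad(theta, levels_x, counts, ridge_var):
    """Penalised negative log-likelihood + gradient for proportional odds.

    ``counts`` has shape (n_levels_y, n_x_values); theta = (cutpoints...,
    slope).  P(y <= k | x) = expit(alpha_k - beta x).
    """
    n_cut = counts.shape[0] - 1
    alphas = theta[:n_cut]
    beta = theta[n_cut]
    eta = alphas[:, None] - beta * levels_x[None, :]  # (n_cut, n_x)
    F = expit(eta)
    # cell probabilities: F_k - F_{k-1} with F_-1 = 0, F_K = 1
    upper = np.vstack([F, np.ones_like(levels_x)])
    lower = np.vstack([np.zeros_like(levels_x), F])
    cell = np.clip(upper - lower, 1e-300, None)
    nll = -(counts * np.log(cell)).sum() + beta**2 / (2.0 * ridge_var)

    dF = F * (1.0 - F)  # dF/d eta
    grad = np.zeros_like(theta)
    ratio = counts / cell
    # d cell_k / d alpha_j: +dF_j if j == k, -dF_j if j == k-1
    for j in range(n_cut):
        grad[j] = -((ratio[j] - ratio[j + 1]) * dF[j]).sum()
    # d cell / d beta: -x * (dF_k - dF_{k-1})
    dcell_dbeta = np.vstack([dF, np.zeros_like(levels_x)]) - np.vstack(
        [np.zeros_like(levels_x), dF]
    )
    grad[n_cut] = (ratio * dcell_dbeta * levels_x[None, :]).sum() + beta / ridge_var
    return nll, grad


def _ordinal_fit(x, y, ridge_var=RIDGE_PRIOR_VARIANCE):
    """Fit the penalised proportional-odds model; return (beta, se) or None."""
    y_levels = np.unique(y)
    x_levels = np.unique(x)
    if len(y_levels) < 2 or len(x_levels) < 2:
        return None
    counts = np.zeros((len(y_levels), len(x_levels)))
    for yi, xi in zip(y, x):
        counts[np.searchsorted(y_levels, yi), np.searchsorted(x_levels, xi)] += 1
    n_cut = len(y_levels) - 1
    # start from the marginal cumulative logits, slope 0
    cum = counts.sum(axis=1).cumsum() / counts.sum()
    theta0 = np.concatenate([np.log(cum[:-1] / (1 - cum[:-1])), [0.0]])
    res = optimize.minimize(
        _ordinal_nll_grad,
        theta0,
        args=(x_levels.astype(float), counts, ridge_var),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 200},
    )
    theta = res.x
    # observed information by central differences of the analytic gradient
    h = 1e-5
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (
            _ordinal_nll_grad(tp, x_levels.astype(float), counts, ridge_var)[1]
            - _ordinal_nll_grad(tm, x_levels.astype(float), counts, ridge_var)[1]
        ) / (2 * h)
    H = (H + H.T) / 2.0
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    var_beta = cov[n_cut, n_cut]
    if not np.isfinite(var_beta) or var_beta <= 0:
        return None
    return float(theta[n_cut]), float(np.sqrt(var_beta))


def _permutation_pvalue(x, y, n_perm, rng):
    r, _ = ancestry_R(x, y)
    stat = 0.0 if not np.isfinite(r) else abs(r)
    hits = 0
    for _ in range(n_perm):
        rp, _ = ancestry_R(x, rng.permutation(y))
        rp = 0.0 if not np.isfinite(rp) else abs(rp)
        if rp >= stat - 1e-15:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def pair_pvalue(
    x,
    y,
    method: str = "ordinal_logistic",
    n_perm: int = 999,
    seed: int = 0,
    orientation: str = "second",
):
    """Two-sided p-value for association between two dosage vectors.

    ``method='ordinal_logistic'`` regresses y on x (proportional odds with a
    weak ridge on the slope) and refers slope/SE to Student t with
    ``n_complete - 2`` df; degenerate tables fall back to the permutation
    test.  ``orientation='symmetric'`` averages the t statistics of both
    regression orientations.  Returns ``(t_stat, p)``; the permutation
    method returns ``(nan, p)``.
    """
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < 3:
        return np.nan, 1.0
    if method == "permutation":
        rng = np.random.default_rng(seed)
        return np.nan, _permutation_pvalue(x, y, n_perm, rng)
    if method != "ordinal_logistic":
        raise ValueError(f"unknown method {method!r}")

    fits = []
    orientations = [(x, y)] if orientation == "second" else [(x, y), (y, x)]
    for xv, yv in orientations:
        fit = _ordinal_fit(xv, yv)
        if fit is not None:
            fits.append(fit[0] / fit[1])
    if not fits:
        rng = np.random.default_rng(seed)
        return np.nan, _permutation_pvalue(x, y, n_perm, rng)
    t = float(np.mean(fits))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return t, max(p, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# genome-wide scans
# ---------------------------------------------------------------------------

def scan(
    geno: AncestryGenotypeMatrix,
    method: str = "ordinal_logistic",
    compute_p: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """All between-group marker pairs with R, R^2 and (optionally) p-values.

    Within-group pairs are excluded; pairs with undefined R (constant
    marker) are dropped.
    """
    markers = geno.markers
    cols = geno.data.columns
    data = geno.data.to_numpy(dtype=float)
    groups = markers["group"].to_numpy()
    rows = []
    for i, j in itertools.combinations(range(len(cols)), 2):
        if groups[i] == groups[j]:
            continue
        x, y = data[:, i], data[:, j]
        r, r2 = ancestry_R(x, y)
        if not np.isfinite(r):
            continue
        n = int((~(np.isnan(x) | np.isnan(y))).sum())
        if compute_p:
            t, p = pair_pvalue(x, y, method=method, seed=seed + i * len(cols) + j)
        else:
            t, p = np.nan, np.nan
        rows.append(
            (cols[i], cols[j], groups[i], groups[j], n, r, r2, t, p,
             "conspecific" if r > 0 else "heterospecific")
        )
    return pd.DataFrame(
        rows,
        columns=["marker_i", "marker_j", "group_i", "group_j", "n", "R", "R2", "t", "p", "sign"],
    )


@dataclass(eq=False)
class DecayProfile:
    """Mean R^2 in distance bins, and where the profile crosses 0.5."""

    bins: pd.DataFrame  # columns: center, mean_R2, n_pairs
    crossing_distance: float | None
    window: float


def pairwise_complete_corr(data: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlation matrix of a columns-as-markers array."""
    df = pd.DataFrame(data)
    return df.corr(min_periods=2).to_numpy()


def decay_profile(
    geno: AncestryGenotypeMatrix,
    gmap: GenomeMap,
    window: float = 100_000.0,
    max_dist: float | None = None,
) -> DecayProfile:
    """Within-group R^2 decay with physical distance, binned in windows.

    The crossing distance is where the binned profile first falls below
    R^2 = 0.5, linearly interpolated between adjacent bin centers; ``None``
    if the profile never crosses.
    """
    markers = geno.markers
    data = geno.data.to_numpy(dtype=float)
    dists, r2s = [], []
    for group, sub in markers.groupby("group", sort=False):
        idx = markers.index.get_indexer(sub.index)
        pos = sub["pos"].to_numpy(dtype=float)
        corr = pairwise_complete_corr(data[:, idx])
        iu, ju = np.triu_indices(len(pos), k=1)
        d = np.abs(pos[ju] - pos[iu])
        r = corr[iu, ju]
        ok = np.isfinite(r)
        if max_dist is not None:
            ok &= d <= max_dist
        dists.append(d[ok])
        r2s.append(r[ok] ** 2)
    d = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    if len(d) == 0:
        raise ValueError("no within-group marker pairs")
    edges = np.arange(0.0, d.max() + window, window)
    which = np.digitize(d, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.sum() == 0:
            continue
        rows.append(((edges[b] + edges[b + 1]) / 2.0, r2[sel].mean(), int(sel.sum())))
    bins = pd.DataFrame(rows, columns=["center", "mean_R2", "n_pairs"])
    crossing = None
    vals = bins["mean_R2"].to_numpy()
    centers = bins["center"].to_numpy()
    below = np.nonzero(vals < 0.5)[0]
    if len(below) > 0:
        k = below[0]
        if k == 0:
            crossing = float(centers[0])
        else:
            x0, x1 = centers[k - 1], centers[k]
            y0, y1 = vals[k - 1], vals[k]
            crossing = float(x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0))
    return DecayProfile(bins, crossing, window)


# ---------------------------------------------------------------------------
# effective number of tests, FDR calibration, joint significance
# ---------------------------------------------------------------------------

def effective_marker_number(corr: np.ndarray) -> float:
    """Effective number of independent markers by spectral decomposition.

    Li & Ji's construction: with eigenvalues lambda_i of the marker
    correlation matrix, M_eff = sum_i [ I(lambda_i >= 1) + (lambda_i -
    floor(lambda_i)) ].  Returned unrounded.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


@dataclass(eq=False)
class FDRCalibration:
    M_eff: float
    table: pd.DataFrame  # threshold, expected_fp, observed, fdr


def joint_significant_pairs(
    res1: pd.DataFrame, res2: pd.DataFrame, p_threshold: float = 0.013
) -> pd.DataFrame:
    """Pairs with p < threshold in both populations, with sign concordance."""
    keys = ["marker_i", "marker_j"]
    if len(res1) != len(res2) or not (
        res1[keys].reset_index(drop=True).equals(res2[keys].reset_index(drop=True))
    ):
        merged = res1.merge(res2, on=keys + ["group_i", "group_j"], suffixes=("_1", "_2"))
        if len(merged) != len(res1) or len(merged) != len(res2):
            raise ValueError("scan results cover different pair universes")
    else:
        merged = res1.merge(res2, on=keys + ["group_i", "group_j"], suffixes=("_1", "_2"))
    sig = merged[(merged["p_1"] < p_threshold) & (merged["p_2"] < p_threshold)].copy()

    def concord(row):
        s1, s2 = row["sign_1"], row["sign_2"]
        if s1 == s2 == "conspecific":
            return "conspecific_both"
        if s1 == s2 == "heterospecific":
            return "heterospecific_both"
        return "discordant"

    sig["concordance"] = sig.apply(concord, axis=1) if len(sig) else pd.Series(dtype=object)
    return sig


def permutation_fdr(
    geno1: AncestryGenotypeMatrix,
    geno2: AncestryGenotypeMatrix,
    M_eff: float,
    thresholds,
    reps: int = 1000,
    seed: int = 0,
    method: str = "ordinal_logistic",
    observed_counts: dict | None = None,
) -> FDRCalibration:
    """Permutation null calibration of joint-significance thresholds.

    Per replicate, ceil(M_eff) markers are sampled from the shared marker
    set, each marker's genotypes are independently permuted across
    individuals within each population (destroying association, preserving
    marginal dosage frequencies), and joint positives at each threshold are
    counted.  FDR(threshold) = mean permuted joint count / observed joint
    count; infinity when nothing is observed.
    """
    rng = np.random.default_rng(seed)
    shared = [m for m in geno1.data.columns if m in set(geno2.data.columns)]
    m_take = int(np.ceil(M_eff))
    if m_take > len(shared):
        raise ValueError("M_eff exceeds the number of shared markers")
    thresholds = list(thresholds)
    if observed_counts is None:
        s1 = scan(geno1.select_markers(shared), method=method, seed=int(rng.integers(2**31 - 1)))
        s2 = scan(geno2.select_markers(shared), method=method, seed=int(rng.integers(2**31 - 1)))
        observed_counts = {
            thr: int(len(joint_significant_pairs(s1, s2, thr))) for thr in thresholds
        }
    fp = {thr: 0.0 for thr in thresholds}
    for _ in range(reps):
        take = list(rng.choice(shared, size=m_take, replace=False))
        perms = []
        for g in (geno1, geno2):
            sub = g.data[take].copy()
            for c in take:
                sub[c] = rng.permutation(sub[c].to_numpy())
            perms.append(AncestryGenotypeMatrix(sub))
        r1 = scan(perms[0], method=method, seed=int(rng.integers(2**31 - 1)))
        r2 = scan(perms[1], method=method, seed=int(rng.integers(2**31 - 1)))
        joint_p = r1.merge(r2, on=["marker_i", "marker_j"], suffixes=("_1", "_2"))
        for thr in thresholds:
            fp[thr] += int(
                ((joint_p["p_1"] < thr) & (joint_p["p_2"] < thr)).sum()
            )
    rows = []
    for thr in thresholds:
        expected = fp[thr] / reps
        obs = observed_counts.get(thr, 0)
        rows.append((thr, expected, obs, expected / obs if obs > 0 else np.inf))
    return FDRCalibration(
        float(M_eff), pd.DataFrame(rows, columns=["threshold", "expected_fp", "observed", "fdr"])
    )


def conspecific_excess_test(
    joint_pairs: pd.DataFrame,
    background: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    sign_column: str = "sign_1",
):
    """Is the conspecific fraction among significant pairs an excess?

    Compares the fraction of positive-R pairs in the significant set to
    ``n_boot`` same-size samples drawn (without replacement) from the
    genomic background (pairs not significant in either population).
    Returns ``(observed_fraction, p)`` with p = (1 + #null >= observed) /
    (n_boot + 1).
    """
    if len(joint_pairs) == 0:
        raise ValueError("empty significant set")
    if len(background) < len(joint_pairs):
        raise ValueError("background smaller than the significant set")
    rng = np.random.default_rng(seed)
    obs_signs = (joint_pairs[sign_column] == "conspecific").to_numpy()
    observed = obs_signs.mean()
    bg = (background[sign_column] == "conspecific").to_numpy()
    k = len(joint_pairs)
    hits = 0
    for _ in range(n_boot):
        frac = rng.choice(bg, size=k, replace=False).mean()
        if frac >= observed - 1e-15:
            hits += 1
    return float(observed), (1 + hits) / (n_boot + 1)


def demographic_fdr(
    scenarios: dict,
    base_scenarios,
    gmap: GenomeMap,
    n_effective_tests: float,
    observed_positive_count: int,
    threshold: float = 0.013,
    sample_sizes=(170, 143),
    method: str = "ordinal_logistic",
    seed: int = 0,
) -> pd.DataFrame:
    """Expected FDR under neutral demographic null scenarios.

    For every named :class:`~hybridscan.simulate.DemographicScenario` (or
    ``None`` for the plain pulse), both base populations are re-simulated
    with that demography, all cross-group pairs are tested in each
    population, and the joint false-positive rate is taken as the product of
    the two marginal rates (the populations are independent).  The expected
    FDR scales that rate by the effective number of cross-group tests over
    the observed positive count.
    """
    from .simulate import HybridZoneScenario, genotypes_at_markers, simulate_hybrid_population

    rng = np.random.default_rng(seed)
    rows = []
    for name, demo in scenarios.items():
        marginal = []
        for base, n_samp in zip(base_scenarios, sample_sizes):
            scen = HybridZoneScenario(
                admix_p=base.admix_p,
                T_gen=base.T_gen,
                N=base.N,
                incompatibilities=(),
                demography=demo,
                seed=int(rng.integers(2**31 - 1)),
            )
            pop = simulate_hybrid_population(scen, gmap)
            take = rng.choice(len(pop), size=min(n_samp, len(pop)), replace=False)
            geno = genotypes_at_markers([pop[i] for i in take], gmap)
            res = scan(geno, method=method, seed=int(rng.integers(2**31 - 1)))
            marginal.append((res["p"] < threshold).mean() if len(res) else 0.0)
        joint_rate = marginal[0] * marginal[1]
        expected_fp = joint_rate * n_effective_tests
        rows.append((name, marginal[0], marginal[1], joint_rate,
                     expected_fp, expected_fp / observed_positive_count))
    return pd.DataFrame(
        rows,
        columns=["scenario", "rate_pop1", "rate_pop2", "joint_rate", "expected_fp", "fdr"],
    )
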