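"""Two-locus Bateson-Dobzhansky-Muller selection machinery and ABC inference.

Genotypes at each locus are coded by the number of parent-1 ("M",
malinche-like) alleles: 0 = BB, 1 = MB, 2 = MM.  A pair of unlinked loci
(recombination fraction c = 1/2) is iterated through a selection -> gamete
production -> drift (multinomial sampling of 2N gametes) -> random-union
recursion.  Two mirror-image BDM fitness matrices (variants "A" and "B")
penalise the genotype combinations never exposed to selection in the
parental lineages with fitness 1 - s; variant "ALL_HYBRID" penalises every
non-parental combination.

Rejection ABC with local-linear regression adjustment infers (s, N, T,
admix_p) from three summary statistics of a set of locus pairs: frequency of
major-parent double homozygotes, pooled frequency of minor-parent
homozygote/heterozygote combinations, and mean ancestry proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd
from scipy import stats as sps

GENOTYPE_LABELS = {0: "BB", 1: "MB", 2: "MM"}
#: collapsed genotype-pair classes (orientation-symmetric under the BDM model)
COLLAPSED_CLASSES = (
    ("MM_MM", ((2, 2),)),
    ("MM_MB", ((2, 1), (1, 2))),
    ("MM_BB", ((2, 0), (0, 2))),
    ("MB_MB", ((1, 1),)),
    ("MB_BB", ((1, 0), (0, 1))),
    ("BB_BB", ((0, 0),)),
)


# ---------------------------------------------------------------------------
# fitness matrices and the deterministic/drift recursion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitnessMatrix:
    """3x3 fitness over (locus-1 genotype) x (locus-2 genotype)."""

    values: np.ndarray
    variant: str
    s: float


def fitness_matrix(variant: str, s: float) -> FitnessMatrix:
    """BDM fitness matrix for one incompatibility variant.

    Variant "A": a derived M allele at locus 1 is incompatible with a B
    allele at locus 2, so every genotype with >=1 M at locus 1 and >=1 B at
    locus 2 has fitness 1-s.  Variant "B" is the mirror.  "ALL_HYBRID"
    penalises everything but the two parental double homozygotes.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must be in [0, 1]")
    w = np.ones((3, 3))
    for g1 in range(3):
        for g2 in range(3):
            if variant == "A":
                hit = g1 >= 1 and g2 <= 1
            elif variant == "B":
                hit = g1 <= 1 and g2 >= 1
            elif variant == "ALL_HYBRID":
                hit = not (g1 == g2 == 0 or g1 == g2 == 2)
            else:
                raise ValueError(f"unknown variant {variant!r}")
            if hit:
                w[g1, g2] = 1.0 - s
    return FitnessMatrix(w, variant, s)


@dataclass(frozen=True)
class TwoLocusGenotypeFreqs:
    """Frequencies of the 9 two-locus genotype classes."""

    values: np.ndarray  # (3, 3), indexed [g1, g2]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (3, 3):
            raise ValueError("expected a 3x3 frequency array")
        if (v < -1e-12).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")
        object.__setattr__(self, "values", v)

    def gamete_freqs(self) -> np.ndarray:
        """Haplotype frequencies x[a, b] (a, b = M allele present, 0/1).

        With unlinked loci (c = 1/2) the two alleles of a gamete are
        independent draws within the individual, so phase never enters.
        """
        return _gametes_from_genotypes(self.values)

    def mean_ancestry(self) -> float:
        g = np.arange(3)
        return float(np.einsum("ij,i->", self.values, g) + np.einsum("ij,j->", self.values, g)) / 4.0


def _gametes_from_genotypes(freqs: np.ndarray) -> np.ndarray:
    """x[a, b], a/b in {0 (B), 1 (M)}; independent allele draws (c = 1/2)."""
    pm1 = np.array([0.0, 0.5, 1.0])  # P(M transmitted | locus genotype)
    x = np.empty((2, 2))
    for a in (0, 1):
        wa = pm1 if a else 1 - pm1
        for b in (0, 1):
            wb = pm1 if b else 1 - pm1
            x[a, b] = float(wa @ freqs @ wb)
    return x


def _union_of_gametes(x: np.ndarray) -> np.ndarray:
    """Random union of two independent gametes -> 9 genotype frequencies."""
    geno = np.zeros((3, 3))
    for a in (0, 1):
        for b in (0, 1):
            for a2 in (0, 1):
                for b2 in (0, 1):
                    geno[a + a2, b + b2] += x[a, b] * x[a2, b2]
    return geno


def gamete_D(x: np.ndarray) -> float:
    """Gamete-level disequilibrium x_MM * x_BB - x_MB * x_BM."""
    return float(x[1, 1] * x[0, 0] - x[1, 0] * x[0, 1])


def pulse_freqs(admix_p: float) -> TwoLocusGenotypeFreqs:
    """Genotype frequencies right after an admixture pulse (maximal LD)."""
    x = np.array([[1.0 - admix_p, 0.0], [0.0, admix_p]])
    return TwoLocusGenotypeFreqs(_union_of_gametes(x))


def iterate_generation(
    freqs: TwoLocusGenotypeFreqs,
    fitness: FitnessMatrix,
    N: int | None = None,
    rng=None,
) -> TwoLocusGenotypeFreqs:
    """One generation: selection, gamete production, drift, random union.

    ``N=None`` runs the deterministic (infinite-population) recursion;
    otherwise drift is multinomial sampling of 2N gametes over the four
    gamete classes.
    """
    f = freqs.values * fitness.values
    tot = f.sum()
    if tot <= 0:
        raise RuntimeError("selection drove all genotype frequencies to zero")
    x = _gametes_from_genotypes(f / tot)
    if N is not None:
        rng = np.random.default_rng() if rng is None else rng
        counts = rng.multinomial(2 * int(N), x.ravel())
        x = counts.reshape(2, 2) / (2.0 * N)
    return TwoLocusGenotypeFreqs(_union_of_gametes(x))


# ---------------------------------------------------------------------------
# vectorised pair-set simulation (numba kernel)
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _pair_set_kernel(s_arr, p_arr, T_arr, N_arr, sample_sizes, major_is_m, seed):
    """Summary stats for each (s, p, T, N) draw over a set of locus pairs.

    Each pair is assigned fitness variant A or B by a fair coin, iterated T
    generations from the pulse state with multinomial drift of 2N gametes,
    and its final genotype frequencies are multinomially sampled at that
    pair's sample size.  Returns (n_sims, 3) stats: major double-homozygote
    frequency, pooled minor hom/het frequency, mean ancestry.
    """
    np.random.seed(seed)
    n_sims = s_arr.shape[0]
    n_pairs = sample_sizes.shape[0]
    out = np.empty((n_sims, 3))
    G = np.empty((3, 3))
    x = np.empty(4)  # gamete classes: index 2*a+b, a/b in {0(B),1(M)}
    counts = np.empty(9, dtype=np.int64)
    for sim in range(n_sims):
        s = s_arr[sim]
        p = p_arr[sim]
        T = int(T_arr[sim])
        twoN = 2 * int(N_arr[sim])
        acc0 = 0.0
        acc1 = 0.0
        acc2 = 0.0
        for pair in range(n_pairs):
            variant_a = np.random.random() < 0.5
            # pulse gametes: M-M at p, B-B at 1-p
            x[0] = 1.0 - p
            x[1] = 0.0
            x[2] = 0.0
            x[3] = p
            for _ in range(T):
                # random union of gametes -> genotypes
                for g1 in range(3):
                    for g2 in range(3):
                        G[g1, g2] = 0.0
                for a in range(2):
                    for b in range(2):
                        xab = x[2 * a + b]
                        if xab == 0.0:
                            continue
                        for a2 in range(2):
                            for b2 in range(2):
                                G[a + a2, b + b2] += xab * x[2 * a2 + b2]
                # selection
                tot = 0.0
                for g1 in range(3):
                    for g2 in range(3):
                        if variant_a:
                            hit = g1 >= 1 and g2 <= 1
                        else:
                            hit = g1 <= 1 and g2 >= 1
                        if hit:
                            G[g1, g2] *= 1.0 - s
                        tot += G[g1, g2]
                # gamete production (c = 1/2: independent allele draws)
                xm1 = 0.0  # P(M at locus 1)
                xm2 = 0.0
                dmm = 0.0  # freq of M-M gamete
                for g1 in range(3):
                    for g2 in range(3):
                        f = G[g1, g2] / tot
                        xm1 += f * g1 / 2.0
                        xm2 += f * g2 / 2.0
                        dmm += f * (g1 / 2.0) * (g2 / 2.0)
                x[3] = dmm
                x[2] = xm1 - dmm
                x[1] = xm2 - dmm
                x[0] = 1.0 - xm1 - xm2 + dmm
                # drift: multinomial 2N via sequential binomials
                n_rem = twoN
                p_rem = 1.0
                for c in range(3):
                    pc = x[c]
                    if pc < 0.0:  # guard float round-off
                        pc = 0.0
                    if p_rem <= 0.0 or n_rem <= 0:
                        k = 0
                    else:
                        pp = pc / p_rem
                        if pp > 1.0:
                            pp = 1.0
                        k = np.random.binomial(n_rem, pp)
                    x[c] = k / twoN
                    n_rem -= k
                    p_rem -= pc
                x[3] = n_rem / twoN
            # final genotype distribution
            for g1 in range(3):
                for g2 in range(3):
                    G[g1, g2] = 0.0
            for a in range(2):
                for b in range(2):
                    xab = x[2 * a + b]
                    if xab == 0.0:
                        continue
                    for a2 in range(2):
                        for b2 in range(2):
                            G[a + a2, b + b2] += xab * x[2 * a2 + b2]
            # multinomial sample of n individuals
            n_ind = sample_sizes[pair]
            n_rem = n_ind
            p_rem = 1.0
            for c in range(9):
                pc = G[c // 3, c % 3]
                if pc < 0.0:
                    pc = 0.0
                if c == 8:
                    counts[c] = n_rem
                    break
                if p_rem <= 0.0 or n_rem <= 0:
                    k = 0
                else:
                    pp = pc / p_rem
                    if pp > 1.0:
                        pp = 1.0
                    k = np.random.binomial(n_rem, pp)
                counts[c] = k
                n_rem -= k
                p_rem -= pc
            # summary statistics for this pair
            anc = 0.0
            for c in range(9):
                anc += counts[c] * (c // 3 + c % 3)
            anc /= 4.0 * n_ind
            if major_is_m:
                dh = counts[8] / n_ind  # (2, 2)
                mh = (counts[1] + counts[3]) / n_ind  # (0,1) + (1,0)
            else:
                dh = counts[0] / n_ind  # (0, 0)
                mh = (counts[7] + counts[5]) / n_ind  # (2,1) + (1,2)
            acc0 += dh
            acc1 += mh
            acc2 += anc
        out[sim, 0] = acc0 / n_pairs
        out[sim, 1] = acc1 / n_pairs
        out[sim, 2] = acc2 / n_pairs
    return out


@dataclass(frozen=True)
class SummaryStats:
    """Pair-set summary statistics used for ABC."""

    f_major_double_hom: float
    f_minor_hom_het: float
    mean_ancestry: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.f_major_double_hom, self.f_minor_hom_het, self.mean_ancestry]
        )


def _as_sample_sizes(sample_sizes, n_pairs: int) -> np.ndarray:
    if sample_sizes is None:
        sample_sizes = 170
    if np.isscalar(sample_sizes):
        return np.full(n_pairs, int(sample_sizes), dtype=np.int64)
    arr = np.asarray(sample_sizes, dtype=np.int64)
    if arr.shape[0] != n_pairs:
        raise ValueError("sample_sizes length must equal n_pairs")
    return arr


def simulate_pair_set(
    s: float,
    admix_p: float,
    T_gen: int,
    N: int,
    n_pairs: int = 207,
    sample_sizes=None,
    major: str = "M",
    seed: int = 0,
) -> SummaryStats:
    """Simulate a set of incompatibility pairs and return mean summary stats."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    sizes = _as_sample_sizes(sample_sizes, n_pairs)
    stats = _pair_set_kernel(
        np.array([float(s)]),
        np.array([float(admix_p)]),
        np.array([float(T_gen)]),
        np.array([float(N)]),
        sizes,
        major == "M",
        int(seed) % (2**31 - 1),
    )[0]
    return SummaryStats(*stats)


# ---------------------------------------------------------------------------
# ABC: rejection + local-linear regression adjustment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ABCPrior:
    """Independent uniform priors on (s, admix_p, T, N)."""

    s: tuple = (0.0, 0.1)
    admix_p: tuple = (0.5, 0.72)
    T: tuple = (40, 70)
    N: tuple = (50, 5000)

    def __post_init__(self):
        for name in ("s", "admix_p", "T", "N"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"prior bounds for {name} must be ordered")

    def bounds(self) -> dict:
        return {"s": self.s, "admix_p": self.admix_p, "T": self.T, "N": self.N}

    def draw(self, n: int, rng) -> pd.DataFrame:
        cols = {
            name: rng.uniform(lo, hi, n) for name, (lo, hi) in self.bounds().items()
        }
        return pd.DataFrame(cols)


#: population-specific priors (major parent M in Tlatemaco, B in Calnali)
TLATEMACO_PRIOR = ABCPrior(admix_p=(0.5, 0.72), T=(40, 70))
CALNALI_PRIOR = ABCPrior(admix_p=(0.18, 0.5), T=(20, 50))


@dataclass(eq=False)
class ABCPosterior:
    """Accepted and regression-adjusted ABC draws with MAP summaries."""

    accepted: pd.DataFrame  # raw accepted parameter draws
    adjusted: pd.DataFrame  # regression-adjusted draws
    map_estimate: dict
    ci95: dict
    prior: ABCPrior


def _logit(u):
    return np.log(u) - np.log1p(-u)


def _to_unbounded(vals, lo, hi):
    u = np.clip((vals - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return _logit(u)


def _from_unbounded(z, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-z))


def _kde_map(vals, lo, hi):
    vals = np.asarray(vals)
    if np.ptp(vals) < 1e-12:
        return float(vals[0])
    kde = sps.gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(max(lo, vals.min()), min(hi, vals.max()), 512)
    return float(grid[np.argmax(kde(grid))])


def abc_infer(
    observed: SummaryStats,
    prior: ABCPrior,
    n_sims: int = 100_000,
    tolerance: float = 0.005,
    n_pairs: int = 207,
    sample_sizes=None,
    major: str = "M",
    seed: int = 0,
) -> ABCPosterior:
    """Rejection ABC with local-linear regression adjustment.

    Parameters are drawn from ``prior``, pair sets simulated with
    :func:`simulate_pair_set`'s kernel, and the ``tolerance`` fraction of
    draws nearest to ``observed`` in normalised Euclidean summary-statistic
    distance is kept.  Accepted parameters are logit-transformed to the prior
    support, shifted by a local-linear regression on the statistics, and
    back-transformed; the MAP is the mode of a Silverman-bandwidth KDE.
    """
    rng = np.random.default_rng(seed)
    draws = prior.draw(n_sims, rng)
    sizes = _as_sample_sizes(sample_sizes, n_pairs)
    stats = _pair_set_kernel(
        draws["s"].to_numpy(),
        draws["admix_p"].to_numpy(),
        draws["T"].to_numpy(),
        draws["N"].to_numpy(),
        sizes,
        major == "M",
        int(rng.integers(2**31 - 1)),
    )
    stat_names = ["f_major_double_hom", "f_minor_hom_het", "mean_ancestry"]
    obs = observed.to_array()
    sd = stats.std(axis=0)
    sd[sd == 0] = 1.0
    dist = np.sqrt((((stats - obs) / sd) ** 2).sum(axis=1))
    n_keep = max(10, int(round(tolerance * n_sims)))
    keep = np.argsort(dist)[:n_keep]

    accepted = draws.iloc[keep].reset_index(drop=True)
    accepted_stats = stats[keep]
    for j, name in enumerate(stat_names):
        accepted[name] = accepted_stats[:, j]

    # local-linear regression adjustment on the accepted set
    S = (accepted_stats - obs) / sd
    usable = accepted_stats.std(axis=0) > 1e-12
    adjusted = {}
    bounds = prior.bounds()
    if usable.sum() == 0:
        warnings.warn("accepted summary statistics are degenerate; skipping adjustment")
        adj_df = accepted[["s", "admix_p", "T", "N"]].copy()
    else:
        X = np.column_stack([np.ones(len(keep)), S[:, usable]])
        beta, *_ = np.linalg.lstsq(X, np.column_stack(
            [_to_unbounded(accepted[p].to_numpy(), *bounds[p]) for p in bounds]
        ), rcond=None)
        for j, p in enumerate(bounds):
            z = _to_unbounded(accepted[p].to_numpy(), *bounds[p])
            z_adj = z - S[:, usable] @ beta[1:, j]
            adjusted[p] = _from_unbounded(z_adj, *bounds[p])
        adj_df = pd.DataFrame(adjusted)

    map_est, ci = {}, {}
    for p, (lo, hi) in bounds.items():
        vals = adj_df[p].to_numpy()
        map_est[p] = _kde_map(vals, lo, hi)
        ci[p] = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    return ABCPosterior(accepted, adj_df, map_est, ci, prior)


# ---------------------------------------------------------------------------
# random-mating expectations and posterior predictive checks
# ---------------------------------------------------------------------------

def random_mating_expectation(x, y):
    """Observed vs Hardy-Weinberg-expected two-locus genotype frequencies.

    Returns ``(observed, expected, deviations, collapsed)`` where the first
    three are 3x3 arrays over (locus-1, locus-2) genotypes and ``collapsed``
    averages deviations over orientation-symmetric classes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) == 0:
        raise ValueError("no complete genotype pairs")
    pa = x.mean() / 2.0
    pb = y.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic locus: random-mating expectation undefined")
    e1 = np.array([(1 - pa) ** 2, 2 * pa * (1 - pa), pa**2])
    e2 = np.array([(1 - pb) ** 2, 2 * pb * (1 - pb), pb**2])
    expected = np.outer(e1, e2)
    observed = np.zeros((3, 3))
    for g1, g2 in zip(x.astype(int), y.astype(int)):
        observed[g1, g2] += 1
    observed /= len(x)
    dev = observed - expected
    collapsed = {
        label: float(np.mean([dev[c] for c in cells]))
        for label, cells in COLLAPSED_CLASSES
    }
    return observed, expected, dev, collapsed


def _dosages_from_counts(counts: np.ndarray, rng):
    """Expand a 3x3 genotype count table into paired dosage vectors."""
    g1, g2 = [], []
    for a in range(3):
        for b in range(3):
            g1.extend([a] * int(counts[a, b]))
            g2.extend([b] * int(counts[a, b]))
    g1 = np.array(g1, dtype=float)
    g2 = np.array(g2, dtype=float)
    perm = rng.permutation(len(g1))
    return g1[perm], g2[perm]


def default_significance_rule(p_threshold: float = 0.013):
    """Pair passes if conspecific (R > 0) and ordinal-regression p < threshold."""
    from .ld import ancestry_R, pair_pvalue

    def rule(x, y) -> bool:
        r, _ = ancestry_R(x, y)
        if not np.isfinite(r) or r <= 0:
            return False
        _, p = pair_pvalue(x, y)
        return p < p_threshold

    return rule


def posterior_predictive(
    posterior: ABCPosterior,
    n_draws: int = 100,
    pair_target: int = 207,
    significance_rule=None,
    sample_size: int = 170,
    major: str = "M",
    seed: int = 0,
    max_attempts_factor: int = 200,
) -> pd.DataFrame:
    """Deviation-from-random-mating distributions under the fitted posterior.

    For each of ``n_draws`` joint posterior draws, locus pairs are simulated
    and screened with ``significance_rule`` until ``pair_target`` accepted
    pairs accumulate; per-pair deviations from random-mating expectations are
    averaged over pairs.  Returns a frame (n_draws x collapsed classes).
    """
    if len(posterior.adjusted) == 0:
        raise ValueError("empty posterior")
    rule = significance_rule or default_significance_rule()
    rng = np.random.default_rng(seed)
    rows = []
    labels = [label for label, _ in COLLAPSED_CLASSES]
    for _ in range(n_draws):
        params = posterior.adjusted.iloc[int(rng.integers(len(posterior.adjusted)))]
        accepted = []
        attempts = 0
        cap = max_attempts_factor * pair_target
        while len(accepted) < pair_target:
            attempts += 1
            if attempts > cap:
                raise RuntimeError(
                    "significance rule not satisfied within the attempt cap"
                )
            variant = "A" if rng.random() < 0.5 else "B"
            fit = fitness_matrix(variant, float(params["s"]))
            freqs = pulse_freqs(float(params["admix_p"]))
            N = int(round(params["N"]))
            for _ in range(int(round(params["T"]))):
                freqs = iterate_generation(freqs, fit, N=N, rng=rng)
            counts = rng.multinomial(sample_size, freqs.values.ravel()).reshape(3, 3)
            x, y = _dosages_from_counts(counts, rng)
            try:
                if not rule(x, y):
                    continue
            except ValueError:
                continue
            _, _, _, collapsed = random_mating_expectation(x, y)
            accepted.append([collapsed[c] for c in labels])
        rows.append(np.mean(accepted, axis=0))
    return pd.DataFrame(rows, columns=labels)
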