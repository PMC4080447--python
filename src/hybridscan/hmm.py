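"""MSG-style hidden Markov ancestry calling from allele-specific read counts.

Three hidden states per marker (hom-P1, het, hom-P2) with binomial read
emissions: the P1-read count at a marker with n reads is Binomial(n, q) with
q = 1 - deltapar2 (hom-P1), 1/2 (het) or deltapar1 (hom-P2), where the
deltapar parameters are the per-read rates of calls to the wrong parent
measured in parental individuals (deltapar1 for P2/birchmanni-ancestry
templates, deltapar2 for P1/malinche).

Transitions model each haplotype as a two-state ancestry chain: over an
inter-marker distance of d bp a haplotype switches ancestry with probability
q(d) = 1 - exp(-lambda d), where lambda = morgans_per_bp * rfac *
(recRate / 24 Morgans).  ``recRate`` plays its published role as an
expected genome-wide ancestry-junction count calibrated on a 24-group,
one-Morgan-per-chromosome genome (about one crossover per chromosome per
meiosis times an a-priori number of generations of admixture), so dividing
by the 24-Morgan reference turns it into junctions per Morgan regardless of
the map actually analysed; ``rfac`` is a tuning scalar.  The diploid
transition matrix is the product chain of the two haplotypes, so hom <-> hom
moves require a double switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import STATE_DOSAGE, AncestryGenotypeMatrix, PosteriorMatrix, ReadCountTable
from .genome import GenomeMap

NAIVE_PRIORS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


@dataclass(frozen=True)
class HMMParams:
    deltapar1: float = 0.05  # per-read error toward P1 in P2-ancestry tracts
    deltapar2: float = 0.04  # per-read error toward P2 in P1-ancestry tracts
    recRate: float = 240.0  # expected genome-wide ancestry junction count
    rfac: float = 3.0
    priors: tuple = NAIVE_PRIORS

    def __post_init__(self):
        for v in (self.deltapar1, self.deltapar2):
            if not 0.0 <= v <= 1.0:
                raise ValueError("error parameters must be probabilities")
        pr = np.asarray(self.priors, dtype=float)
        if pr.shape != (3,) or abs(pr.sum() - 1.0) > 1e-9 or (pr < 0).any():
            raise ValueError("priors must be a non-negative triple summing to 1")

    def with_priors(self, priors) -> "HMMParams":
        return HMMParams(self.deltapar1, self.deltapar2, self.recRate, self.rfac, tuple(priors))


#: map length (Morgans) on which recRate's junction count was calibrated:
#: 24 linkage groups at roughly one crossover per chromosome per meiosis
REFERENCE_MAP_MORGANS = 24.0


def _switch_rate_per_bp(gmap: GenomeMap, params: HMMParams) -> float:
    junctions_per_morgan = params.recRate / REFERENCE_MAP_MORGANS
    return gmap.morgans_per_bp * params.rfac * junctions_per_morgan


def transition_matrix(d_bp: float, gmap: GenomeMap, params: HMMParams) -> np.ndarray:
    """Diploid 3-state transition matrix across an inter-marker gap of d bp."""
    q = 1.0 - np.exp(-_switch_rate_per_bp(gmap, params) * d_bp)
    r = 1.0 - q
    return np.array(
        [
            [r * r, 2 * q * r, q * q],
            [q * r, r * r + q * q, q * r],
            [q * q, 2 * q * r, r * r],
        ]
    )


def _log_emissions(k1: np.ndarray, n: np.ndarray, params: HMMParams) -> np.ndarray:
    """Unnormalised log emission probabilities, shape (n_ind, n_markers, 3).

    Binomial coefficients are state-independent and omitted.  Markers with
    zero reads are state-uninformative (log-emission 0 in every state).
    """
    succ = np.array([1.0 - params.deltapar2, 0.5, params.deltapar1])
    k1 = k1[..., None]
    k2 = (n[..., None]) - k1
    with np.errstate(divide="ignore", invalid="ignore"):
        # 0 * log(0) -> 0 so that error rates of exactly 0 stay well defined
        t1 = np.where(k1 > 0, k1 * np.log(succ), 0.0)
        t2 = np.where(k2 > 0, k2 * np.log1p(-succ), 0.0)
    return t1 + t2


def _group_slices(markers: pd.DataFrame):
    start = 0
    for group, sub in markers.groupby("group", sort=False):
        pos = sub["pos"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"markers not sorted by position on group {group!r}")
        yield group, slice(start, start + len(sub)), pos
        start += len(sub)


def infer_ancestry(
    reads: ReadCountTable, gmap: GenomeMap, params: HMMParams
) -> PosteriorMatrix:
    """Forward-backward posterior ancestry per individual and marker."""
    markers = reads.markers
    k1 = reads.p1.to_numpy(dtype=float)
    n = k1 + reads.p2.to_numpy(dtype=float)
    log_e = _log_emissions(k1, n, params)
    e = np.exp(log_e - log_e.max(axis=2, keepdims=True))
    priors = np.asarray(params.priors, dtype=float)
    post = np.empty_like(e)

    for _, sl, pos in _group_slices(markers):
        eg = e[:, sl, :]
        m = eg.shape[1]
        trans = [transition_matrix(d, gmap, params) for d in np.diff(pos)]
        alpha = np.empty_like(eg)
        a = priors[None, :] * eg[:, 0, :]
        alpha[:, 0, :] = a / a.sum(axis=1, keepdims=True)
        for t in range(1, m):
            a = (alpha[:, t - 1, :] @ trans[t - 1]) * eg[:, t, :]
            alpha[:, t, :] = a / a.sum(axis=1, keepdims=True)
        beta = np.ones_like(eg)
        for t in range(m - 2, -1, -1):
            b = (beta[:, t + 1, :] * eg[:, t + 1, :]) @ trans[t].T
            beta[:, t, :] = b / b.sum(axis=1, keepdims=True)
        p = alpha * beta
        post[:, sl, :] = p / p.sum(axis=2, keepdims=True)

    return PosteriorMatrix(post, reads.p1.index, reads.p1.columns)


def two_pass_priors(
    reads: ReadCountTable, gmap: GenomeMap, params: HMMParams
):
    """Learn population state-frequency priors from a naive first pass.

    Runs the HMM with naive (1/3, 1/3, 1/3) priors, sets the priors to the
    population-mean posterior state frequencies, and reruns.  Returns the
    second-pass posteriors and the learned priors.
    """
    first = infer_ancestry(reads, gmap, params.with_priors(NAIVE_PRIORS))
    learned = first.probs.mean(axis=(0, 1))
    learned = learned / learned.sum()
    second = infer_ancestry(reads, gmap, params.with_priors(tuple(learned)))
    return second, tuple(float(v) for v in learned)


def hard_calls(
    post: PosteriorMatrix, ambiguity_threshold: float = 0.95
) -> AncestryGenotypeMatrix:
    """Dosage calls: argmax state when its posterior exceeds the threshold.

    Calls with maximum posterior <= ``ambiguity_threshold`` are set missing
    (ambiguous), following the convention that excluding such calls is what
    pushes hard-call accuracy above 98% on MSG-like data.
    """
    best = post.probs.argmax(axis=2)
    conf = post.probs.max(axis=2)
    dosage = STATE_DOSAGE[best].astype(float)
    dosage[conf <= ambiguity_threshold] = np.nan
    data = pd.DataFrame(dosage, index=post.individuals, columns=post.marker_ids)
    return AncestryGenotypeMatrix(data)


def filter_markers(
    geno: AncestryGenotypeMatrix, max_missing: float = 0.15
) -> AncestryGenotypeMatrix:
    """Drop markers missing/ambiguous in more than ``max_missing`` of individuals."""
    frac = geno.data.isna().mean(axis=0)
    return geno.select_markers(geno.data.columns[frac <= max_missing])


def thin_markers(post: PosteriorMatrix, tol: float = 0.1) -> PosteriorMatrix:
    """Greedy thinning: keep markers whose posteriors moved by more than tol.

    Left-to-right per linkage group, a marker is kept iff some individual's
    posterior for some state differs from the last *kept* marker by at least
    ``tol`` (so ``tol=0`` keeps every marker); the first marker of each
    group is always kept.
    """
    keep = np.zeros(len(post.marker_ids), dtype=bool)
    for _, sl, _ in _group_slices(post.markers):
        probs = post.probs[:, sl, :]
        idx = np.arange(sl.start, sl.stop)
        last = 0
        keep[idx[0]] = True
        for j in range(1, probs.shape[1]):
            if np.abs(probs[:, j, :] - probs[:, last, :]).max() >= tol:
                keep[idx[j]] = True
                last = j
    return post.select_markers(post.marker_ids[keep])


def classify_hybrids(geno: AncestryGenotypeMatrix) -> pd.DataFrame:
    """Hybrid flags and outlier exclusions from the hybrid index.

    An individual is a hybrid iff both parents contributed at least 10% of
    its called genome (0.10 <= hybrid index <= 0.90).  Hybrids whose index
    falls outside the normal-approximation 99% interval of the hybrid-index
    distribution (mean +/- 2.576 sd over hybrids) are additionally flagged
    for exclusion as ancestry outliers.
    """
    h = geno.hybrid_index
    undefined = h.isna()
    is_hybrid = (h >= 0.10) & (h <= 0.90) & ~undefined
    excluded = pd.Series(False, index=h.index)
    hh = h[is_hybrid]
    if len(hh) >= 2 and hh.std(ddof=1) > 0:
        sd = hh.std(ddof=1)
        lo, hi = hh.mean() - 2.576 * sd, hh.mean() + 2.576 * sd
        excluded = ((h < lo) | (h > hi)) & is_hybrid
    return pd.DataFrame(
        {
            "hybrid_index": h,
            "is_hybrid": is_hybrid,
            "excluded": excluded,
            "undefined": undefined,
        }
    )


def block_detection_power(
    gmap: GenomeMap,
    block_sizes,
    depth: float,
    params: HMMParams,
    reps: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Empirical probability of detecting an inserted opposite-ancestry block.

    For each block size, ``reps`` single-group individuals homozygous for P2
    receive one homozygous-P1 block at a uniform position; reads are
    simulated, the HMM run, and the block scored detected iff any marker
    inside it is hard-called hom-P1.
    """
    from .simulate import simulate_reads

    markers = gmap.require_markers()
    group, length = gmap.linkage_groups[0]
    pos = markers.loc[markers["group"] == group, "pos"].to_numpy()
    ids = markers.index[markers["group"] == group]
    rng = np.random.default_rng(seed)
    power = {}
    for size in block_sizes:
        if size >= length:
            raise ValueError("block size must be smaller than the chromosome")
        hits = 0
        for rep in range(reps):
            start = rng.uniform(0, length - size)
            inside = (pos >= start) & (pos < start + size)
            dosage = np.where(inside, 2.0, 0.0)[None, :]
            geno = AncestryGenotypeMatrix(
                pd.DataFrame(dosage, index=["sim"], columns=ids)
            )
            reads = simulate_reads(
                geno, depth, err_p1=params.deltapar2, err_p2=params.deltapar1,
                seed=int(rng.integers(2**31 - 1)),
            )
            post = infer_ancestry(reads, gmap, params)
            calls = hard_calls(post).data.to_numpy()[0]
            if np.any(calls[inside] == 2.0):
                hits += 1
        power[int(size)] = hits / reps
    return pd.Series(power).sort_index()
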