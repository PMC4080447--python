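"""Forward-time simulation of hybrid-zone populations and shallow-read data.

The model is a Wright-Fisher admixture pulse: generation 0 is a mix of pure
parental diploids at proportion ``admix_p`` of parent-1 (P1) genomes; every
later generation, parents are sampled in proportion to fitness (epistatic
selection on planted two-locus incompatibilities), gametes are formed with
Poisson-distributed crossovers on a uniform map, and an optional fraction of
individuals is replaced by pure parental migrants.  Genomes are mosaics of
ancestry segments in 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bdm import fitness_matrix
from .containers import AncestryGenotypeMatrix, ReadCountTable
from .genome import GenomeMap, marker_id

_EMPTY = np.empty(0)


# ---------------------------------------------------------------------------
# haplotypes: (first_ancestry, internal_breakpoints); ancestry alternates at
# every breakpoint, which guarantees the tiling invariant by construction.
# ---------------------------------------------------------------------------

def pure_haplotype(ancestry: int):
    return (int(ancestry), _EMPTY)


def haplotype_ancestry(hap, pos):
    """Ancestry (0 = P2, 1 = P1) of a haplotype at position(s) ``pos``."""
    first, breaks = hap
    pos = np.asarray(pos)
    if breaks.size == 0:
        return np.full(pos.shape, first, dtype=np.int8)
    return ((first + np.searchsorted(breaks, pos, side="right")) % 2).astype(np.int8)


def _ancestry_scalar(hap, x) -> int:
    first, breaks = hap
    if breaks.size == 0:
        return first
    return (first + int(np.searchsorted(breaks, x, side="right"))) % 2


def haplotype_segments(hap, length):
    """List of (start, end, ancestry) half-open segments tiling [0, length)."""
    first, breaks = hap
    edges = np.concatenate(([0.0], breaks, [float(length)]))
    return [
        (edges[i], edges[i + 1], (first + i) % 2)
        for i in range(len(edges) - 1)
    ]


def recombine(hap_start, hap_other, cross):
    """Gamete following ``hap_start`` and switching template at each crossover."""
    pts = np.unique(np.concatenate((hap_start[1], hap_other[1], cross)))
    starts = np.concatenate(([0.0], pts))
    from_other = (np.searchsorted(cross, starts, side="right") % 2).astype(bool)
    anc_a = haplotype_ancestry(hap_start, starts)
    anc_b = haplotype_ancestry(hap_other, starts)
    anc = np.where(from_other, anc_b, anc_a)
    switch = anc[1:] != anc[:-1]
    return (int(anc[0]), starts[1:][switch])


@dataclass(eq=False)
class DiploidAncestryGenome:
    """Two mosaic haplotypes per linkage group (parallel to the map's groups)."""

    haplotypes: list  # [(hapA, hapB), ...] in map group order

    def dosage_at(self, group_index: int, pos):
        a, b = self.haplotypes[group_index]
        return haplotype_ancestry(a, pos) + haplotype_ancestry(b, pos)

    def segments(self, group_index: int, length):
        a, b = self.haplotypes[group_index]
        return haplotype_segments(a, length), haplotype_segments(b, length)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class IncompatibilitySpec:
    """A planted two-locus incompatibility between unlinked loci."""

    locus1: tuple  # (group, position)
    locus2: tuple
    variant: str = "A"
    s: float = 0.0

    def __post_init__(self):
        if self.locus1[0] == self.locus2[0]:
            raise ValueError("planted incompatibility loci must be on different groups")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("selection coefficient must be in [0, 1]")


@dataclass
class DemographicScenario:
    """Demographic perturbations of the hybrid population.

    Coalescent-style quantities (``4Nm``, burst times in units of t/4N) are
    converted to forward time with ``Ne_parental``, so e.g. ``migration_4Nm =
    80`` with the default Ne of 10,500 is a per-generation migrant fraction of
    80 / (4 * 10500) ~ 0.0019 from each parental source.
    """

    bottleneck_fraction: float = 1.0
    migration_4Nm: float = 0.0  # ongoing, per parental source
    burst: tuple | None = None  # (t_start/4N, t_end/4N, 4Nm, source)
    theta: float = 0.0016
    rho: float = 0.0016
    Ne_parental: int = 10500

    def __post_init__(self):
        if not 0.0 < self.bottleneck_fraction <= 1.0:
            raise ValueError("bottleneck_fraction must be in (0, 1]")
        if self.migration_4Nm < 0:
            raise ValueError("migration rate must be >= 0")

    def t_div_4n(self, dxy: float) -> float:
        """Divergence time in 4N units implied by D_xy and theta."""
        return 0.5 * (dxy / self.theta - 1.0)

    def migrant_fraction(self) -> float:
        return self.migration_4Nm / (4.0 * self.Ne_parental)

    def burst_window_generations(self):
        """Burst window as (gens-ago start, gens-ago end, fraction, source)."""
        if self.burst is None:
            return None
        t0, t1, four_nm, source = self.burst
        return (
            t0 * 4.0 * self.Ne_parental,
            t1 * 4.0 * self.Ne_parental,
            four_nm / (4.0 * self.Ne_parental),
            source,
        )


@dataclass
class HybridZoneScenario:
    """All parameters of one simulated hybrid population."""

    admix_p: float  # initial proportion of P1 (malinche-like) genomes
    T_gen: int
    N: int
    incompatibilities: tuple = ()
    demography: DemographicScenario | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.admix_p <= 1.0:
            raise ValueError("admix_p must be in [0, 1]")
        if self.N < 2:
            raise ValueError("population size must be >= 2")
        if self.T_gen < 0:
            raise ValueError("T_gen must be >= 0")
        self.incompatibilities = tuple(self.incompatibilities)


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation
# ---------------------------------------------------------------------------

def _locus_indices(scenario: HybridZoneScenario, gmap: GenomeMap):
    group_index = {g: i for i, (g, _) in enumerate(gmap.linkage_groups)}
    lengths = gmap.group_lengths
    out = []
    for inc in scenario.incompatibilities:
        for group, pos in (inc.locus1, inc.locus2):
            if group not in group_index:
                raise ValueError(f"incompatibility locus group {group!r} not in map")
            if not 0 <= pos < lengths[group]:
                raise ValueError(f"incompatibility locus {group}:{pos} outside group")
        w = fitness_matrix(inc.variant, inc.s).values
        out.append(
            (
                group_index[inc.locus1[0]],
                float(inc.locus1[1]),
                group_index[inc.locus2[0]],
                float(inc.locus2[1]),
                w,
            )
        )
    return out


def _fitness(pop, planted) -> np.ndarray:
    w = np.ones(len(pop))
    for gi1, x1, gi2, x2, mat in planted:
        for k, genome in enumerate(pop):
            a1, b1 = genome.haplotypes[gi1]
            a2, b2 = genome.haplotypes[gi2]
            g1 = _ancestry_scalar(a1, x1) + _ancestry_scalar(b1, x1)
            g2 = _ancestry_scalar(a2, x2) + _ancestry_scalar(b2, x2)
            w[k] *= mat[g1, g2]
    return w


def _pure_genome(ancestry: int, n_groups: int) -> DiploidAncestryGenome:
    hap = pure_haplotype(ancestry)
    return DiploidAncestryGenome([(hap, hap)] * n_groups)


def simulate_hybrid_population(scenario: HybridZoneScenario, gmap: GenomeMap, rng=None):
    """Simulate ``scenario.N`` diploids, ``scenario.T_gen`` generations after a pulse.

    Returns a list of :class:`DiploidAncestryGenome`.  Deterministic given
    ``scenario.seed`` (or an explicit ``rng``).
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    planted = _locus_indices(scenario, gmap)
    groups = gmap.linkage_groups
    n_groups = len(groups)
    lengths = np.array([L for _, L in groups], dtype=float)
    morgans = lengths * gmap.morgans_per_bp

    demo = scenario.demography
    n_pop = scenario.N
    if demo is not None:
        n_pop = max(2, int(round(scenario.N * demo.bottleneck_fraction)))

    p1_pure = _pure_genome(1, n_groups)
    p2_pure = _pure_genome(0, n_groups)
    is_p1 = rng.random(n_pop) < scenario.admix_p
    pop = [p1_pure if f else p2_pure for f in is_p1]

    major_anc = 1 if scenario.admix_p >= 0.5 else 0
    m_ongoing = demo.migrant_fraction() if demo is not None else 0.0
    burst = demo.burst_window_generations() if demo is not None else None

    for gen in range(1, scenario.T_gen + 1):
        if planted and any(p[4].min() < 1.0 for p in planted):
            w = _fitness(pop, planted)
            total = w.sum()
            if total <= 0:
                raise RuntimeError("selection eliminated every individual")
            parents = rng.choice(n_pop, size=(n_pop, 2), p=w / total)
        else:
            parents = rng.integers(0, n_pop, size=(n_pop, 2))

        ncross = rng.poisson(morgans, size=(n_pop, 2, n_groups))
        start = rng.integers(0, 2, size=(n_pop, 2, n_groups))
        new_pop = []
        for i in range(n_pop):
            haps = []
            for g in range(n_groups):
                gametes = []
                for side in range(2):
                    parent = pop[parents[i, side]]
                    pa, pb = parent.haplotypes[g]
                    if start[i, side, g]:
                        pa, pb = pb, pa
                    k = ncross[i, side, g]
                    if k == 0:
                        gametes.append(pa)
                    else:
                        cross = np.sort(rng.uniform(0.0, lengths[g], k))
                        gametes.append(recombine(pa, pb, cross))
                haps.append((gametes[0], gametes[1]))
            new_pop.append(DiploidAncestryGenome(haps))
        pop = new_pop

        # migrant replacement by pure parentals
        rates = []  # (fraction, source-ancestry)
        if m_ongoing > 0:
            rates.append((m_ongoing, 1))
            rates.append((m_ongoing, 0))
        if burst is not None:
            t0, t1, frac, source = burst
            gens_ago = scenario.T_gen - gen
            if t0 <= gens_ago <= t1:
                if source == "both":
                    rates.append((frac / 2.0, 1))
                    rates.append((frac / 2.0, 0))
                else:
                    anc = major_anc if source == "major" else 1 - major_anc
                    rates.append((frac, anc))
        for frac, anc in rates:
            n_mig = rng.binomial(n_pop, min(frac, 1.0))
            if n_mig:
                for idx in rng.choice(n_pop, size=n_mig, replace=False):
                    pop[idx] = p1_pure if anc == 1 else p2_pure

    return pop


# ---------------------------------------------------------------------------
# observation models
# ---------------------------------------------------------------------------

def genotypes_at_markers(pop, gmap: GenomeMap) -> AncestryGenotypeMatrix:
    """P1-dosage of every individual at the map's markers (no missingness)."""
    mk = gmap.require_markers()
    group_index = {g: i for i, (g, _) in enumerate(gmap.linkage_groups)}
    cols = {}
    order = []
    for group, sub in mk.groupby("group", sort=False):
        gi = group_index[group]
        pos = sub["pos"].to_numpy(dtype=float)
        block = np.empty((len(pop), len(pos)), dtype=np.int8)
        for k, genome in enumerate(pop):
            block[k, :] = genome.dosage_at(gi, pos)
        for j, mid in enumerate(sub.index):
            cols[mid] = block[:, j]
            order.append(mid)
    data = pd.DataFrame(cols, columns=order, dtype=float)
    data.index = [f"ind{i}" for i in range(len(pop))]
    return AncestryGenotypeMatrix(data)


def simulate_reads(
    geno: AncestryGenotypeMatrix,
    depth_per_marker: float,
    err_p1: float = 0.04,
    err_p2: float = 0.05,
    seed: int = 0,
) -> ReadCountTable:
    """Shallow-read sampling of an ancestry genotype matrix.

    Read counts per marker are Poisson(``depth_per_marker``); each read draws
    one of the two haplotypes uniformly and reports its parental allele,
    flipped with the error rate of that parent (``err_p1`` for P1-ancestry
    templates, ``err_p2`` for P2).
    """
    if depth_per_marker < 0:
        raise ValueError("depth must be >= 0")
    for e in (err_p1, err_p2):
        if not 0.0 <= e < 0.5:
            raise ValueError("error rates must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    dosage = geno.data.to_numpy(dtype=float)
    if np.isnan(dosage).any():
        raise ValueError("read simulation requires complete genotypes")
    n = rng.poisson(depth_per_marker, size=dosage.shape)
    p_report_p1 = (dosage / 2.0) * (1.0 - err_p1) + (1.0 - dosage / 2.0) * err_p2
    k1 = rng.binomial(n, p_report_p1)
    p1 = pd.DataFrame(k1, index=geno.data.index, columns=geno.data.columns)
    p2 = pd.DataFrame(n - k1, index=geno.data.index, columns=geno.data.columns)
    return ReadCountTable(p1, p2)


def ancestry_block_lengths(pop, gmap: GenomeMap) -> dict:
    """Lengths (bp) of maximal constant-ancestry haplotype segments, by parent."""
    if not pop:
        raise ValueError("empty population")
    out = {1: [], 0: []}
    for gi, (_, L) in enumerate(gmap.linkage_groups):
        for genome in pop:
            for hap in genome.haplotypes[gi]:
                for s, e, anc in haplotype_segments(hap, L):
                    out[anc].append(e - s)
    return {"P1": np.array(out[1]), "P2": np.array(out[0])}
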