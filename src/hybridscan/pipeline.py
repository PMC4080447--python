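"""End-to-end driver: genotyping, LD scan, blocks, dating, ABC, divergence.

The pipeline runs two populations through the full analysis chain the
library implements: (simulate ->) read sampling -> HMM genotyping with
two-pass priors -> marker filtering/thinning -> hybrid classification ->
cross-chromosome LD scan in each population -> permutation FDR calibration
-> joint significant pairs -> LD blocks and intersection -> conspecific
excess test -> hybrid-zone age -> ABC on the conspecific pair set ->
posterior predictive checks -> divergence comparison.  Every stage draws
its seed deterministically from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bdm import ABCPrior, SummaryStats, abc_infer, posterior_predictive
from .blocks import blocks_from_joint_pairs, intersect_populations, misassembly_check
from .containers import AncestryGenotypeMatrix
from .dating import estimate_age
from .divergence import background_comparison
from .genome import GenomeMap
from .hmm import HMMParams, classify_hybrids, filter_markers, hard_calls, thin_markers, two_pass_priors
from .ld import conspecific_excess_test, effective_marker_number, joint_significant_pairs, permutation_fdr, scan
from .simulate import HybridZoneScenario, genotypes_at_markers, simulate_hybrid_population, simulate_reads


@dataclass
class PopulationInput:
    """One population: provided genotypes, or a scenario to simulate."""

    name: str
    genotypes: AncestryGenotypeMatrix | None = None
    scenario: HybridZoneScenario | None = None
    sample_n: int | None = None
    minor_parent: str = "P1"
    major: str = "M"  # major-parent allele frame for ABC summary stats

    def __post_init__(self):
        if (self.genotypes is None) == (self.scenario is None):
            raise ValueError("provide exactly one of genotypes or scenario")


@dataclass
class PipelineConfig:
    gmap: GenomeMap  # must carry markers
    populations: tuple  # two PopulationInput
    seed: int = 0
    out_dir: str | None = None
    # genotyping
    use_hmm: bool = True
    depth: float = 8.0
    hmm_params: HMMParams = field(default_factory=HMMParams)
    ambiguity_threshold: float = 0.95
    max_missing: float = 0.15
    thin_tol: float = 0.1
    # scanning / significance
    p_threshold: float = 0.013
    fdr_reps: int = 0  # 0 disables permutation FDR calibration
    fdr_thresholds: tuple = (0.013, 0.007)
    conspecific_boot: int = 1000
    # dating
    age_max_dist_bp: float | None = None
    # ABC / posterior predictive
    abc_priors: tuple | None = None  # one ABCPrior per population; None disables
    abc_n_sims: int = 20000
    abc_tolerance: float = 0.01
    ppc_draws: int = 0
    ppc_pair_target: int = 20
    # divergence
    divergence_tables: tuple | None = None  # (ld_regions, background_regions)

    def __post_init__(self):
        if len(self.populations) != 2:
            raise ValueError("the pipeline expects exactly two populations")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold out of range")


def _genotype_population(pop: PopulationInput, cfg: PipelineConfig, rng) -> dict:
    out = {}
    if pop.scenario is not None:
        genomes = simulate_hybrid_population(pop.scenario, cfg.gmap)
        if pop.sample_n is not None and pop.sample_n < len(genomes):
            take = rng.choice(len(genomes), size=pop.sample_n, replace=False)
            genomes = [genomes[i] for i in take]
        truth = genotypes_at_markers(genomes, cfg.gmap)
        out["truth"] = truth
        if cfg.use_hmm:
            reads = simulate_reads(
                truth, cfg.depth,
                err_p1=cfg.hmm_params.deltapar2, err_p2=cfg.hmm_params.deltapar1,
                seed=int(rng.integers(2**31 - 1)),
            )
            post, priors = two_pass_priors(reads, cfg.gmap, cfg.hmm_params)
            out["priors"] = priors
            post = thin_markers(post, cfg.thin_tol)
            geno = hard_calls(post, cfg.ambiguity_threshold)
            geno = filter_markers(geno, cfg.max_missing)
        else:
            geno = truth
    else:
        geno = pop.genotypes
        geno = filter_markers(geno, cfg.max_missing)
    classes = classify_hybrids(geno)
    keep = classes.index[classes["is_hybrid"] & ~classes["excluded"]]
    out["classification"] = classes
    out["genotypes"] = geno.select_individuals(keep) if len(keep) else geno
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns a results dict.

    When ``config.out_dir`` is set, tabular artifacts and a run manifest
    (seed, version, thresholds) are written there as TSV/JSON.
    """
    rng = np.random.default_rng(config.seed)
    results: dict = {"populations": {}}

    genos = []
    for pop in config.populations:
        res = _genotype_population(pop, config, rng)
        results["populations"][pop.name] = res
        genos.append(res["genotypes"])

    shared = [m for m in genos[0].data.columns if m in set(genos[1].data.columns)]
    genos = [g.select_markers(shared) for g in genos]

    scans = []
    for g in genos:
        scans.append(scan(g, seed=int(rng.integers(2**31 - 1))))
    results["scans"] = scans

    corr = genos[0].data.corr(min_periods=2).fillna(0.0).to_numpy()
    np.fill_diagonal(corr, 1.0)
    results["M_eff"] = effective_marker_number(corr)

    if config.fdr_reps > 0:
        results["fdr"] = permutation_fdr(
            genos[0], genos[1], results["M_eff"], config.fdr_thresholds,
            reps=config.fdr_reps, seed=int(rng.integers(2**31 - 1)),
        )

    joint = joint_significant_pairs(scans[0], scans[1], config.p_threshold)
    results["joint_pairs"] = joint

    merged = scans[0].merge(
        scans[1], on=["marker_i", "marker_j", "group_i", "group_j"], suffixes=("_1", "_2")
    )
    background = merged[
        (merged["p_1"] >= config.p_threshold) & (merged["p_2"] >= config.p_threshold)
    ]
    results["background_pairs"] = background
    if len(joint) > 0 and len(background) > len(joint):
        obs, p = conspecific_excess_test(
            joint, background, n_boot=config.conspecific_boot,
            seed=int(rng.integers(2**31 - 1)),
        )
        results["conspecific_excess"] = {"observed_fraction": obs, "p": p}

    pair_tables = []
    for g in genos:
        pair_tables.append(
            blocks_from_joint_pairs(joint, g, config.p_threshold)
        )
    results["block_pairs"] = pair_tables
    results["intersected_regions"] = intersect_populations(*pair_tables)

    ages = {}
    for pop, g in zip(config.populations, genos):
        try:
            fit = estimate_age(
                g, config.gmap, minor_parent=pop.minor_parent,
                max_dist_bp=config.age_max_dist_bp,
            )
            ages[pop.name] = {"T_hat": fit.T_hat, "a_hat": fit.a_hat}
        except (ValueError, RuntimeError) as err:
            ages[pop.name] = {"error": str(err)}
    results["age"] = ages

    if config.abc_priors is not None:
        conspecific = joint[joint.get("concordance", pd.Series(dtype=object)) == "conspecific_both"]
        results["abc"] = {}
        for k, (pop, g, prior) in enumerate(zip(config.populations, genos, config.abc_priors)):
            stats = _observed_pair_stats(conspecific, g, major=pop.major)
            if stats is None:
                continue
            post = abc_infer(
                stats, prior, n_sims=config.abc_n_sims, tolerance=config.abc_tolerance,
                n_pairs=max(1, len(conspecific)), sample_sizes=g.n_individuals,
                major=pop.major, seed=int(rng.integers(2**31 - 1)),
            )
            entry = {"posterior": post, "observed_stats": stats}
            if config.ppc_draws > 0:
                entry["ppc"] = posterior_predictive(
                    post, n_draws=config.ppc_draws, pair_target=config.ppc_pair_target,
                    sample_size=g.n_individuals, seed=int(rng.integers(2**31 - 1)),
                )
            results["abc"][pop.name] = entry

    if config.divergence_tables is not None:
        ld_tab, bg_tab = config.divergence_tables
        results["divergence"] = background_comparison(
            ld_tab, bg_tab, seed=int(rng.integers(2**31 - 1))
        )

    if config.out_dir is not None:
        _write_outputs(config, results)
    return results


def _observed_pair_stats(joint: pd.DataFrame, geno: AncestryGenotypeMatrix, major: str):
    """Summary statistics of the observed significant pair set for ABC."""
    if len(joint) == 0:
        return None
    dh, mh, anc = [], [], []
    for _, row in joint.iterrows():
        x = geno.dosage(row["marker_i"])
        y = geno.dosage(row["marker_j"])
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if len(x) == 0:
            continue
        if major == "M":
            dh.append(np.mean((x == 2) & (y == 2)))
            mh.append(np.mean(((x == 0) & (y == 1)) | ((x == 1) & (y == 0))))
        else:
            dh.append(np.mean((x == 0) & (y == 0)))
            mh.append(np.mean(((x == 2) & (y == 1)) | ((x == 1) & (y == 2))))
        anc.append((x.mean() + y.mean()) / 4.0)
    if not dh:
        return None
    return SummaryStats(float(np.mean(dh)), float(np.mean(mh)), float(np.mean(anc)))


def _write_outputs(config: PipelineConfig, results: dict) -> None:
    from .io import write_genotype_matrix, write_json

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, res in results["populations"].items():
        write_genotype_matrix(res["genotypes"], out / f"genotypes_{name}.tsv")
        res["classification"].to_csv(out / f"classification_{name}.tsv", sep="\t")
    for k, sc in enumerate(results["scans"]):
        sc.to_csv(out / f"scan_pop{k + 1}.tsv", sep="\t", index=False)
    results["joint_pairs"].to_csv(out / "joint_pairs.tsv", sep="\t", index=False)
    results["intersected_regions"].to_csv(out / "intersected_regions.tsv", sep="\t", index=False)
    summary = {
        "M_eff": results["M_eff"],
        "age": results["age"],
        "conspecific_excess": results.get("conspecific_excess"),
    }
    if "fdr" in results:
        summary["fdr"] = results["fdr"].table.to_dict(orient="records")
    if "abc" in results:
        summary["abc"] = {
            name: {"map": entry["posterior"].map_estimate, "ci95": entry["posterior"].ci95}
            for name, entry in results["abc"].items()
        }
    write_json(summary, out / "summary.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "p_threshold": config.p_threshold,
        "ambiguity_threshold": config.ambiguity_threshold,
        "max_missing": config.max_missing,
        "thin_tol": config.thin_tol,
        "use_hmm": config.use_hmm,
        "depth": config.depth,
    }
    write_json(manifest, out / "manifest.json")
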