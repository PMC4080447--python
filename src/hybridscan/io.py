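"""Tab-delimited and YAML file formats.

Genotype matrices are TSV with individuals as rows and ``group:pos`` marker
IDs as columns (values 0/1/2/NA); read counts use paired ``<marker>.p1`` /
``<marker>.p2`` columns; marker maps are 4-column BED-like TSV (group,
start, end, id; 0-based half-open); posteriors carry three columns per
marker suffixed ``.hom1/.het/.hom2``; simulation scenarios are YAML files
whose keys match the scenario dataclasses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import STATES, AncestryGenotypeMatrix, PosteriorMatrix, ReadCountTable
from .genome import GenomeMap
from .simulate import DemographicScenario, HybridZoneScenario, IncompatibilitySpec

INDEX_NAME = "individual"


def _check_duplicate_header(path) -> None:
    # pandas mangles duplicate column names, so inspect the raw header
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                cols = line.rstrip("\n").split("\t")[1:]
                seen = set()
                for c in cols:
                    if c in seen:
                        raise ValueError(f"duplicated marker ID {c!r} in {path}")
                    seen.add(c)
                return


def read_genotype_matrix(path) -> AncestryGenotypeMatrix:
    _check_duplicate_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = None
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.upper() != "NA")
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"non-dosage value {df[col][bad].iloc[0]!r} at row {row!r}, column {col!r}")
        df[col] = vals
    return AncestryGenotypeMatrix(df.astype(float))


def write_genotype_matrix(geno: AncestryGenotypeMatrix, path) -> None:
    out = geno.data.copy()
    out.index.name = INDEX_NAME
    out.to_csv(path, sep="\t", na_rep="NA")


def read_marker_map(path, linkage_groups=None, cm_per_kb=None) -> pd.DataFrame:
    """Read a BED-like marker file; returns a (group, pos) frame indexed by ID."""
    bed = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["group", "start", "end", "id"], dtype={"group": str},
    )
    mk = pd.DataFrame(
        {"group": bed["group"], "pos": bed["start"].astype(int)}
    )
    mk.index = bed["id"]
    return mk


def write_marker_map(gmap: GenomeMap, path) -> None:
    mk = gmap.require_markers()
    bed = pd.DataFrame(
        {
            "group": mk["group"],
            "start": mk["pos"].astype(int),
            "end": mk["pos"].astype(int) + 1,
            "id": mk.index,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_read_counts(path) -> ReadCountTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    p1_cols = [c for c in df.columns if c.endswith(".p1")]
    markers = [c[:-3] for c in p1_cols]
    p1 = df[[m + ".p1" for m in markers]].copy()
    p2 = df[[m + ".p2" for m in markers]].copy()
    p1.columns = markers
    p2.columns = markers
    return ReadCountTable(p1.astype(int), p2.astype(int))


def write_read_counts(reads: ReadCountTable, path) -> None:
    out = {}
    for m in reads.p1.columns:
        out[m + ".p1"] = reads.p1[m]
        out[m + ".p2"] = reads.p2[m]
    df = pd.DataFrame(out, index=reads.p1.index)
    df.index.name = INDEX_NAME
    df.to_csv(path, sep="\t")


def write_posteriors(post: PosteriorMatrix, path) -> None:
    frame = post.to_frame()
    frame.index.name = INDEX_NAME
    frame.to_csv(path, sep="\t")


def read_posteriors(path) -> PosteriorMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    marker_ids = []
    for c in df.columns:
        if c.endswith("." + STATES[0]):
            marker_ids.append(c[: -len(STATES[0]) - 1])
    probs = np.stack(
        [df[[f"{m}.{st}" for m in marker_ids]].to_numpy() for st in STATES], axis=2
    )
    return PosteriorMatrix(probs, df.index, pd.Index(marker_ids))


# ---------------------------------------------------------------------------
# scenario configs
# ---------------------------------------------------------------------------

def scenario_from_dict(d: dict) -> HybridZoneScenario:
    incs = tuple(
        IncompatibilitySpec(
            locus1=(str(i["locus1"][0]), int(i["locus1"][1])),
            locus2=(str(i["locus2"][0]), int(i["locus2"][1])),
            variant=i.get("variant", "A"),
            s=float(i.get("s", 0.0)),
        )
        for i in d.get("incompatibilities", [])
    )
    demo = d.get("demography")
    demography = None
    if demo is not None:
        burst = demo.get("burst")
        demography = DemographicScenario(
            bottleneck_fraction=float(demo.get("bottleneck_fraction", 1.0)),
            migration_4Nm=float(demo.get("migration_4Nm", 0.0)),
            burst=tuple(burst) if burst is not None else None,
            theta=float(demo.get("theta", 0.0016)),
            rho=float(demo.get("rho", 0.0016)),
            Ne_parental=int(demo.get("Ne_parental", 10500)),
        )
    return HybridZoneScenario(
        admix_p=float(d["admix_p"]),
        T_gen=int(d["T_gen"]),
        N=int(d["N"]),
        incompatibilities=incs,
        demography=demography,
        seed=int(d.get("seed", 0)),
    )


def read_scenario(path) -> HybridZoneScenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def write_scenario(scenario: HybridZoneScenario, path) -> None:
    d = {
        "admix_p": scenario.admix_p,
        "T_gen": scenario.T_gen,
        "N": scenario.N,
        "seed": scenario.seed,
        "incompatibilities": [
            {
                "locus1": list(i.locus1),
                "locus2": list(i.locus2),
                "variant": i.variant,
                "s": i.s,
            }
            for i in scenario.incompatibilities
        ],
    }
    if scenario.demography is not None:
        demo = scenario.demography
        d["demography"] = {
            "bottleneck_fraction": demo.bottleneck_fraction,
            "migration_4Nm": demo.migration_4Nm,
            "burst": list(demo.burst) if demo.burst is not None else None,
            "theta": demo.theta,
            "rho": demo.rho,
            "Ne_parental": demo.Ne_parental,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
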