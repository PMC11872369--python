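"""Configuration, seeding and end-to-end orchestration.

A single YAML config drives the whole pipeline; every default is pre-filled
so ``run_all`` works out of the box on synthetic data. Stages run in order
simulate -> prep -> overlap -> fit -> project -> align -> phylo, each
writing plain-text artifacts into a run directory; a manifest records the
config, the per-stage seeds and a content hash of every output, so a rerun
with the same config reproduces the hashes byte for byte.

Seeding: a single ``master_seed`` fans out deterministically to every
random stage through ``numpy.random.SeedSequence(master, spawn_key=...)``
counters (stage index first, then replicate indices); no stage touches
global random state.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely import geometry as sgeom

from . import geo, overlap, phylo, prep, sdm, survival, synthetic, transfer

log = logging.getLogger(__name__)

# stage indices for seed fan-out
_S_SIMULATE, _S_PREP, _S_OVERLAP, _S_FIT = 10, 20, 30, 40


def stage_seed(master: int, *key: int) -> int:
    """Deterministic child seed < 2**31 for a stage/replicate counter key."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Defaults encode the analysis parameters (correlation cutoff 0.70,
#: 200 km training buffer, 5 pseudo-absence replicates, k = 4 blocks, 25 %
#: random hold-out, 10 CV runs, overlap thresholds 0.3/0.6, SSR window 2,
#: minimal SR 0.1) together with a desk-scale synthetic world on which they
#: run in seconds. Scale-dependent sampling sizes (grid extent, occurrence
#: counts, pseudo-absence counts and exclusion radii) are set to match that
#: world's 100 km extent rather than a continental one.
DEFAULT_CONFIG: dict = {
    "master_seed": 0,
    "log_level": "INFO",
    "synthetic": {
        "n_layers": 4,
        "grid_shape": [100, 100],
        "cell_size_km": 1.0,
        "autocorr_range_km": 10.0,
        # one deliberately collinear pair (r = 0.85) so variable selection
        # has work to do
        "layer_correlation": [
            [1.00, 0.85, 0.20, 0.00],
            [0.85, 1.00, 0.20, 0.00],
            [0.20, 0.20, 1.00, 0.10],
            [0.00, 0.00, 0.10, 1.00],
        ],
        "species": {
            "ex1": {"optima": [1.0, 1.0, -0.8, 0.3],
                    "breadths": [0.8, 0.8, 1.0, 1.2],
                    "n_occurrences": 200, "bias_strength": 0.5},
            "nat1": {"optima": [-0.5, -0.5, 0.5, 0.0],
                     "breadths": [1.0, 1.0, 1.0, 1.2],
                     "n_occurrences": 200, "bias_strength": 0.0},
        },
        "inventory": {
            "species": [
                ["ex1", "sectA", False], ["exA2", "sectA", False],
                ["exA3", "sectA", False],
                ["nat1", "sectB", True], ["nat2", "sectB", True],
                ["natB3", "sectB", True],
                ["exC1", "sectC", False], ["exC2", "sectC", False],
                ["exC3", "sectC", False],
            ],
            "n_individuals": 60,
            "baseline_logit": 1.5,
            "section_effects": {"sectA": -2.0},
            "garden_effects": {"G1": -0.3, "G3": 0.3},
            "cause_mix": {"climate": 0.45, "unknown": 0.25, "pest": 0.15,
                          "mechanical": 0.10, "horticultural": 0.05},
            "period": [2000, 2021],
        },
        "districts": {"D1": [5, 5, 30, 30], "D2": [40, 40, 65, 65],
                      "D3": [70, 70, 95, 95]},   # [xmin, ymin, xmax, ymax] km
    },
    "prep": {
        "thin_km": 1.0,
        "thin_reps": 10,
        "corr_cutoff": 0.70,
        "n_sample_cells": 10000,
    },
    "overlap": {
        "pair": ["ex1", "nat1"],
        "R": 100,
        "n_reps": 99,
        "corrected": True,
        "regional_buffer_km": 30.0,
    },
    "sdm": {
        "species": "ex1",
        "variable_groups": {"selected": None},  # None -> layers kept by prep
        "pa": {"strategies": ["GE", "ES"], "n": 800, "exclusion_km": 5.0,
               "replicates": 5, "es_quantile": 0.95},
        "cv": {"strategies": ["random", "block"], "k": 4, "runs": 10,
               "test_fraction": 0.25},
        "buffer_km": 200.0,
        "penalty_grid": list(sdm.DEFAULT_PENALTY_GRID),
        "block_size_km": None,
    },
    "thresholds": {"minimal_sr": 0.1, "ssr_window": 2.0,
                   "hs_t_low": 0.3, "hs_t_high": 0.6},
    "native_species": {"G1": ["nat1", "nat2", "natB3"],
                       "G2": ["nat1", "nat2", "natB3"],
                       "G3": ["nat1", "nat2", "natB3"]},
    "gardens": {"G1": "D1", "G2": "D2", "G3": "D3"},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: "str | Path | None" = None,
                overrides: dict | None = None) -> dict:
    """Merge a YAML config file (and/or an override mapping) over the
    defaults; raises if the result fails validation."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Every violated constraint, as human-readable strings (empty = valid)."""
    p: list[str] = []
    t = cfg.get("thresholds", {})
    lo, hi = t.get("hs_t_low", 0.3), t.get("hs_t_high", 0.6)
    if not (0 <= lo < hi <= 1):
        p.append(f"thresholds: need 0 <= hs_t_low < hs_t_high <= 1, "
                 f"got {lo}, {hi}")
    if not (0 < t.get("minimal_sr", 0.1) < 1):
        p.append("thresholds: minimal_sr must be in (0, 1)")
    if t.get("ssr_window", 2.0) <= 0:
        p.append("thresholds: ssr_window must be > 0")
    if not cfg.get("native_species"):
        p.append("native_species: at least one region's native list required")
    syn = cfg.get("synthetic", {})
    shape = syn.get("grid_shape", [0, 0])
    if min(shape) < 10:
        p.append("synthetic.grid_shape: must be at least 10 x 10")
    n_cells = shape[0] * shape[1]
    if cfg.get("sdm", {}).get("pa", {}).get("n", 0) > n_cells:
        p.append("sdm.pa.n exceeds the total number of grid cells "
                 "(checked fully at run time)")
    C = syn.get("layer_correlation")
    if C is not None:
        C = np.asarray(C, float)
        if C.shape != (syn["n_layers"], syn["n_layers"]):
            p.append("synthetic.layer_correlation: wrong shape")
        elif not np.allclose(C, C.T) or np.linalg.eigvalsh(C).min() < -1e-10:
            p.append("synthetic.layer_correlation: must be symmetric PSD")
    cv = cfg.get("sdm", {}).get("cv", {})
    if not 0 < cv.get("test_fraction", 0.25) < 1:
        p.append("sdm.cv.test_fraction must be in (0, 1)")
    mix = syn.get("inventory", {}).get("cause_mix", {})
    if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
        p.append("synthetic.inventory.cause_mix must sum to 1")
    gardens = set(cfg.get("gardens", {}))
    natives = set(cfg.get("native_species", {}))
    if gardens and natives and not gardens <= natives:
        p.append(f"native_species missing for gardens: "
                 f"{sorted(gardens - natives)}")
    return p


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate(cfg: dict, outdir: Path) -> dict:
    """Generate the synthetic world: env stack, occurrences, native-range
    polygons, district polygons, inventory."""
    syn = cfg["synthetic"]
    master = cfg["master_seed"]
    env_spec = synthetic.EnvFieldSpec(
        n_layers=syn["n_layers"],
        grid_shape=tuple(syn["grid_shape"]),
        cell_size=syn["cell_size_km"],
        autocorr_range=syn["autocorr_range_km"],
        layer_correlation=(np.asarray(syn["layer_correlation"], float)
                           if syn.get("layer_correlation") is not None else None),
        seed=stage_seed(master, _S_SIMULATE, 0),
    )
    env = synthetic.gen_env_stack(env_spec)
    geo.write_env_stack(env, outdir / "env.tif")

    occ_frames, ranges = [], {}
    for i, (name, sp) in enumerate(sorted(syn["species"].items())):
        vspec = synthetic.VirtualSpeciesSpec(
            optima=np.asarray(sp["optima"], float),
            breadths=np.asarray(sp["breadths"], float),
            n_occurrences=sp["n_occurrences"],
            bias_strength=sp.get("bias_strength", 0.0),
            seed=stage_seed(master, _S_SIMULATE, 1, i),
            name=name,
        )
        suit = synthetic.gen_true_suitability(env, vspec)
        occ = synthetic.sample_occurrences(suit, env, vspec)
        occ_frames.append(occ)
        hull = sgeom.MultiPoint(list(zip(occ["lon"], occ["lat"]))).convex_hull
        ranges[name] = hull.buffer(5.0)
    occurrences = pd.concat(occ_frames, ignore_index=True)
    geo.write_occurrences(occurrences, outdir / "occurrences.csv")
    geo.write_regions(geo.RegionPolygons(ranges), outdir / "native_ranges.geojson")

    districts = {
        name: sgeom.box(*bounds)
        for name, bounds in syn["districts"].items()
    }
    geo.write_regions(geo.RegionPolygons(districts), outdir / "districts.geojson")

    inv_cfg = syn["inventory"]
    inv_spec = synthetic.InventorySimSpec(
        species=[tuple(s) for s in inv_cfg["species"]],
        gardens=sorted(cfg["gardens"]),
        n_individuals=inv_cfg["n_individuals"],
        baseline_logit=inv_cfg["baseline_logit"],
        section_effects=dict(inv_cfg.get("section_effects", {})),
        garden_effects=dict(inv_cfg.get("garden_effects", {})),
        cause_mix=dict(inv_cfg["cause_mix"]),
        period=tuple(inv_cfg["period"]),
        seed=stage_seed(master, _S_SIMULATE, 2),
    )
    inventory = synthetic.gen_inventory(inv_spec)
    geo.write_inventory(inventory, outdir / "inventory.csv")
    return {"env": env, "occurrences": occurrences, "inventory": inventory,
            "districts": geo.RegionPolygons(districts),
            "native_ranges": geo.RegionPolygons(ranges)}


def run_prep(cfg: dict, outdir: Path) -> dict:
    """Clean, range-filter and thin occurrences; select environmental
    variables by the correlation cutoff."""
    pc = cfg["prep"]
    master = cfg["master_seed"]
    env = geo.read_env_stack(outdir / "env.tif")
    occ = geo.read_occurrences(outdir / "occurrences.csv")
    ranges = geo.read_regions(outdir / "native_ranges.geojson")
    geographic = env.is_geographic

    cleaned_frames, thin_report = [], {}
    for i, species in enumerate(sorted(occ["species"].unique())):
        one = occ[occ["species"] == species].reset_index(drop=True)
        one, _rep = prep.clean_coordinates(one, geographic=geographic)
        if species in ranges.polygons:
            one = prep.filter_native_range(
                one, geo.RegionPolygons({species: ranges.polygons[species]}))
        thin = prep.thin_min_distance(
            one, pc["thin_km"], pc["thin_reps"],
            seed=stage_seed(master, _S_PREP, i), geographic=geographic)
        thin_report[species] = {"n_input": thin.n_input,
                                "n_retained": thin.n_retained,
                                "replicate_id": thin.replicate_id}
        cleaned_frames.append(thin.retained)
    cleaned = pd.concat(cleaned_frames, ignore_index=True)
    geo.write_occurrences(cleaned, outdir / "occurrences_thinned.csv")

    selection = prep.filter_correlated(
        env, cutoff=pc["corr_cutoff"], n_sample_cells=pc["n_sample_cells"],
        seed=stage_seed(master, _S_PREP, 99))
    report = {
        "kept": selection.kept,
        "dropped": [{"layer": d[0], "partner": d[1], "r": d[2]}
                    for d in selection.dropped],
        "cutoff": selection.cutoff,
        "thinning": thin_report,
    }
    (outdir / "prep_report.json").write_text(json.dumps(report, indent=2,
                                                        sort_keys=True))
    return {"occurrences": cleaned, "selection": selection}


def run_overlap(cfg: dict, outdir: Path) -> dict:
    """Niche similarity of the configured species pair at two background
    extents (regional buffers vs the full grid)."""
    oc = cfg["overlap"]
    master = cfg["master_seed"]
    env = geo.read_env_stack(outdir / "env.tif")
    occ = geo.read_occurrences(outdir / "occurrences_thinned.csv")
    sp1, sp2 = oc["pair"]
    occ1 = occ[occ["species"] == sp1]
    occ2 = occ[occ["species"] == sp2]
    if len(occ1) == 0 or len(occ2) == 0:
        raise ValueError(f"overlap pair {oc['pair']} not found in occurrences")

    results = {}
    for e_i, extent in enumerate(("regional", "full")):
        if extent == "regional":
            bg1 = sdm.build_training_region(occ1, env,
                                            oc["regional_buffer_km"]).mask
            bg2 = sdm.build_training_region(occ2, env,
                                            oc["regional_buffer_km"]).mask
        else:
            bg1 = bg2 = env.valid_mask()
        res = overlap.background_similarity_test(
            occ1, bg1, occ2, bg2, env, n_reps=oc["n_reps"],
            seed=stage_seed(master, _S_OVERLAP, e_i), R=oc["R"],
            corrected=oc["corrected"])
        results[extent] = {
            "D": res.D, "I": res.I, "p_D": res.p_D, "p_I": res.p_I,
            "p_D_directional": list(res.p_D_directional),
            "p_I_directional": list(res.p_I_directional),
            "n_reps": res.n_reps,
        }
    (outdir / "overlap.json").write_text(json.dumps(results, indent=2,
                                                    sort_keys=True))
    return results


def run_fit(cfg: dict, outdir: Path) -> dict:
    """Fit the full model matrix for the configured species."""
    sc = cfg["sdm"]
    env = geo.read_env_stack(outdir / "env.tif")
    occ = geo.read_occurrences(outdir / "occurrences_thinned.csv")
    report = json.loads((outdir / "prep_report.json").read_text())
    species = sc["species"]
    occ_sp = occ[occ["species"] == species].reset_index(drop=True)
    if len(occ_sp) == 0:
        raise ValueError(f"no occurrences for sdm species {species!r}")

    groups = {}
    for gname, layers in sc["variable_groups"].items():
        groups[gname] = list(report["kept"]) if layers is None else list(layers)

    mm_cfg = sdm.ModelMatrixConfig(
        species=species,
        variable_groups=groups,
        pa_strategies=tuple(sc["pa"]["strategies"]),
        cv_strategies=tuple(sc["cv"]["strategies"]),
        pa_n=sc["pa"]["n"],
        pa_exclusion_km=sc["pa"]["exclusion_km"],
        pa_replicates=sc["pa"]["replicates"],
        es_quantile=sc["pa"]["es_quantile"],
        cv_runs=sc["cv"]["runs"],
        cv_k=sc["cv"]["k"],
        test_fraction=sc["cv"]["test_fraction"],
        buffer_km=sc["buffer_km"],
        penalty_grid=tuple(sc["penalty_grid"]),
        block_size_km=sc.get("block_size_km"),
        master_seed=stage_seed(cfg["master_seed"], _S_FIT),
    )
    models, metrics = sdm.run_model_matrix(occ_sp, env, mm_cfg)
    metrics.to_csv(outdir / "model_metrics.csv", index=False)
    payload = [m.to_dict() | {
        "variable_group": row["variable_group"],
        "pa_strategy": row["pa_strategy"],
        "cv_strategy": row["cv_strategy"],
    } for m, (_, row) in zip(models, metrics.iterrows())]
    (outdir / "models.json").write_text(json.dumps(payload, sort_keys=True))
    return {"models": models, "metrics": metrics}


def run_project(cfg: dict, outdir: Path) -> pd.DataFrame:
    """Ensemble-average each configuration family's models onto the target
    grid and aggregate to district means."""
    t = cfg["thresholds"]
    env = geo.read_env_stack(outdir / "env.tif")
    districts = geo.read_regions(outdir / "districts.geojson")
    payload = json.loads((outdir / "models.json").read_text())
    rows = []
    families: dict[tuple, list] = {}
    for d in payload:
        key = (d["variable_group"], d["pa_strategy"], d["cv_strategy"])
        families.setdefault(key, []).append(sdm.FittedSDM.from_dict(d))
    for (group, pa_s, cv_s), models in sorted(families.items()):
        smap = transfer.ensemble_project(models, env, species=cfg["sdm"]["species"])
        for dh in transfer.zonal_mean(smap, districts, env,
                                      t["hs_t_low"], t["hs_t_high"]):
            rows.append({
                "species": cfg["sdm"]["species"],
                "variable_group": group, "pa_strategy": pa_s,
                "cv_strategy": cv_s, "district": dh.district,
                "mean_hs": dh.mean_hs, "n_cells": dh.n_cells,
                "hs_class": dh.hs_class, "n_models": smap.n_models,
            })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "district_hs.csv", index=False)
    return df


def run_align(cfg: dict, outdir: Path) -> dict:
    """SR/SSR from the inventory, survival classes, and HS-SR verdicts per
    model-configuration family and garden."""
    t = cfg["thresholds"]
    thresholds = survival.SurvivalThresholds(
        minimal_sr=t["minimal_sr"], ssr_window=t["ssr_window"],
        hs_t_low=t["hs_t_low"], hs_t_high=t["hs_t_high"])
    inventory = geo.read_inventory(outdir / "inventory.csv")
    district_hs = pd.read_csv(outdir / "district_hs.csv")
    period = tuple(cfg["synthetic"]["inventory"]["period"])
    sr_table = survival.compute_sr(inventory, period=period)

    ssr_rows = []
    for garden, natives in sorted(cfg["native_species"].items()):
        for res in survival.compute_ssr(sr_table, natives, garden):
            ssr_rows.append(res.__dict__ | {
                "sr_class": survival.classify_sr(res.sr, res.ssr, thresholds)})
    ssr_df = pd.DataFrame(ssr_rows)
    ssr_df.to_csv(outdir / "ssr.csv", index=False)

    district_of = cfg["gardens"]
    sdm_species = cfg["sdm"]["species"]
    verdict_rows = []
    for _, hs_row in district_hs.iterrows():
        gardens = [g for g, d in district_of.items()
                   if d == hs_row["district"]]
        for garden in gardens:
            sub = ssr_df[(ssr_df["species"] == sdm_species)
                         & (ssr_df["region"] == garden)]
            if len(sub) == 0 or hs_row["hs_class"] is None:
                continue
            v = survival.alignment_verdict(hs_row["hs_class"],
                                           sub.iloc[0]["sr_class"],
                                           species=sdm_species, region=garden)
            verdict_rows.append(v.__dict__ | {
                "variable_group": hs_row["variable_group"],
                "pa_strategy": hs_row["pa_strategy"],
                "cv_strategy": hs_row["cv_strategy"],
            })
    verdicts = pd.DataFrame(verdict_rows)
    verdicts.to_csv(outdir / "verdicts.csv", index=False)
    counts = survival.alignment_counts(verdicts, by=("species",))
    counts.to_csv(outdir / "alignment_counts.csv", index=False)
    return {"sr": sr_table, "ssr": ssr_df, "verdicts": verdicts,
            "counts": counts}


def run_phylo(cfg: dict, outdir: Path) -> dict:
    """Section means, section-vs-rest tests and garden rank patterns from
    the inventory-derived survival table."""
    inventory = geo.read_inventory(outdir / "inventory.csv")
    sections = {s[0]: s[1] for s in cfg["synthetic"]["inventory"]["species"]}
    sr_table = survival.compute_sr(inventory)
    sr_long = sr_table.rename(columns={"garden": "garden"}).copy()
    sr_long["section"] = sr_long["species"].map(sections)
    means = phylo.section_means(sr_long)
    tests = phylo.all_section_tests(sr_long)
    patterns = phylo.garden_rank_pattern(sr_long)
    means.to_csv(outdir / "section_means.csv", index=False)
    tests.to_csv(outdir / "section_tests.csv", index=False)
    (outdir / "rank_patterns.json").write_text(
        patterns.to_json(orient="records", indent=2))
    return {"means": means, "tests": tests, "patterns": patterns}


# ---------------------------------------------------------------------------
# run-all + manifest
# ---------------------------------------------------------------------------

STAGES = ("simulate", "prep", "overlap", "fit", "project", "align", "phylo")


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: dict, outdir: "str | Path") -> dict:
    """Execute every stage in order and write a manifest of content hashes.

    Re-running with the same config reproduces every hash. Stage failures
    propagate with the stage name attached.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_used.yaml").write_text(
        yaml.safe_dump(cfg, sort_keys=True))
    runners = {
        "simulate": simulate, "prep": run_prep, "overlap": run_overlap,
        "fit": run_fit, "project": run_project, "align": run_align,
        "phylo": run_phylo,
    }
    for stage in STAGES:
        log.info("stage %s ...", stage)
        try:
            runners[stage](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    files = sorted(p for p in outdir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "master_seed": cfg["master_seed"],
        "stages": list(STAGES),
        "parameters": {
            "corr_cutoff": cfg["prep"]["corr_cutoff"],
            "thin_km": cfg["prep"]["thin_km"],
            "buffer_km": cfg["sdm"]["buffer_km"],
            "pa_exclusion_km": cfg["sdm"]["pa"]["exclusion_km"],
            "pa_n": cfg["sdm"]["pa"]["n"],
            "pa_replicates": cfg["sdm"]["pa"]["replicates"],
            "cv_k": cfg["sdm"]["cv"]["k"],
            "cv_runs": cfg["sdm"]["cv"]["runs"],
            "test_fraction": cfg["sdm"]["cv"]["test_fraction"],
            "overlap_n_reps": cfg["overlap"]["n_reps"],
            "thresholds": cfg["thresholds"],
        },
        "outputs": {str(p.relative_to(outdir)): _hash_file(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    log.info("run complete: %d outputs in %s", len(files), outdir)
    return manifest
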