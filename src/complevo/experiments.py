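"""Replicate orchestration, figure-style experiment presets, and summaries.

An *experiment* is a set of named conditions (fully specified simulation
configurations, up to the per-replicate seed) run for a number of replicates
each.  Replicate ``r`` of every condition uses ``run_seed = base_seed + r``,
so conditions are paired on seeds and results are order-independent.  For NK
conditions whose landscape seed is left unset, replicate ``r`` draws a fresh
landscape with a seed derived from the base seed, again paired across
conditions.

Outputs are plain text: one trajectory CSV per replicate, a ``summary.csv``
of per-condition statistics, and a ``metadata.json`` that alone suffices to
rerun the experiment.  Already-written replicate files are skipped on rerun,
so interrupted experiments resume where they stopped.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import run
from .landscapes import (NKLandscape, TwoLocusLandscape, _LandscapeBase,
                         landscape_to_json, make_two_locus)
from .observers import CENSORED
from .population import SimulationConfig

__all__ = [
    "ExperimentPreset",
    "PRESETS",
    "FIG2A_FITNESS",
    "fig2a_landscape",
    "config_from_dict",
    "config_to_dict",
    "load_experiment_file",
    "run_experiment",
    "summarize_replicates",
]

#: Two-locus fitness assignments of the minimal valley-crossing model:
#: local peak at 00, global peak at 11, lethal single-mutant intermediates.
FIG2A_FITNESS = {"f00": 0.2, "f01": 0.0, "f10": 0.0, "f11": 1.0}


def fig2a_landscape() -> TwoLocusLandscape:
    """The shipped two-locus fixture landscape (f00=0.2, f01=f10=0, f11=1)."""
    return make_two_locus(**FIG2A_FITNESS)


# --- config (de)serialization ---------------------------------------------

def _landscape_from_spec(spec: dict, replicate_seed: int | None = None) -> _LandscapeBase:
    spec = dict(spec)
    kind = spec.pop("type")
    if kind == "two_locus":
        return make_two_locus(spec["f00"], spec["f01"], spec["f10"], spec["f11"])
    if kind == "nk":
        seed = spec.get("seed")
        if seed is None:
            if replicate_seed is None:
                raise ValueError("NK landscape spec has no seed and no replicate seed was provided")
            seed = replicate_seed
        return NKLandscape.generate(spec["N"], spec["K"], seed,
                                    normalize=spec.get("normalize", True))
    raise ValueError(f"unknown landscape type {kind!r}")


def _landscape_to_spec(landscape: _LandscapeBase) -> dict:
    if isinstance(landscape, TwoLocusLandscape):
        t = landscape.fitness_table
        return {"type": "two_locus", "f00": t["00"], "f01": t["01"],
                "f10": t["10"], "f11": t["11"]}
    if isinstance(landscape, NKLandscape):
        return {"type": "nk", "N": landscape.N, "K": landscape.K, "seed": landscape.seed}
    raise TypeError(f"cannot serialize landscape {type(landscape)!r}")


def config_from_dict(doc: dict, replicate_seed: int | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a flat mapping (YAML/JSON)."""
    doc = dict(doc)
    landscape = _landscape_from_spec(doc.pop("landscape"), replicate_seed)
    return SimulationConfig(landscape=landscape, **doc)


def config_to_dict(config: SimulationConfig) -> dict:
    doc = asdict(config)
    doc["landscape"] = _landscape_to_spec(config.landscape)
    if not isinstance(doc["initial_genotype"], str):
        doc["initial_genotype"] = "".join(map(str, config.initial_genotype))
    return doc


# --- presets ---------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentPreset:
    """Named set of conditions reproducing one published-figure protocol."""

    name: str
    description: str
    conditions: dict  # condition name -> config dict (landscape spec included)
    replicates: int = 100


def _two_locus_base(**over) -> dict:
    base = {
        "landscape": {"type": "two_locus", **FIG2A_FITNESS},
        "S": 10_000, "alpha": 0.001, "alpha_C": 0.001, "beta_C": 5.0,
        "initial_genotype": "00", "fitness_threshold": 0.95,
        "max_generations": 10_000,
    }
    base.update(over)
    return base


def _nk_base(K: int, **over) -> dict:
    base = {
        "landscape": {"type": "nk", "N": 5, "K": K},  # fresh landscape per replicate
        "S": 10_000, "alpha": 0.001, "alpha_C": 0.001, "beta_C": 5.0,
        "initial_genotype": "00000", "fitness_threshold": 0.95,
        "max_generations": 10_000, "grouping": "kin", "parasites_enabled": True,
    }
    base.update(over)
    return base


def _build_presets() -> dict:
    presets = {}

    presets["fig2"] = ExperimentPreset(
        "fig2",
        "Two-locus valley crossing: non-interacting (m=1) vs full "
        "trans-complementation in random pairs (m=2), no parasites.",
        {
            "m1": _two_locus_base(m=1, rule="none", parasites_enabled=False),
            "m2_full_trans": _two_locus_base(m=2, rule="full_trans",
                                             grouping="random", parasites_enabled=False),
        })

    for grouping in ("random", "kin"):
        presets[f"fig3_{grouping}"] = ExperimentPreset(
            f"fig3_{grouping}",
            f"Two-locus model with genetic parasites, {grouping} groups: "
            "m=1 control, m=2 helpers only, and m=2 allowing parasites.",
            {
                "m1": _two_locus_base(m=1, rule="none", parasites_enabled=False),
                "m2_no_parasites": _two_locus_base(m=2, rule="full_trans",
                                                   grouping=grouping,
                                                   parasites_enabled=False),
                "m2_parasites": _two_locus_base(m=2, rule="full_trans",
                                                grouping=grouping,
                                                parasites_enabled=True),
            })

    presets["fig4"] = ExperimentPreset(
        "fig4",
        "Two-locus full cis-complementation in kin groups with parasites.",
        {
            "m1": _two_locus_base(m=1, rule="none", parasites_enabled=False),
            "m2_full_cis": _two_locus_base(m=2, rule="full_cis", grouping="kin",
                                           parasites_enabled=True),
        })

    for K in (1, 4):
        presets[f"fig5_k{K}"] = ExperimentPreset(
            f"fig5_k{K}",
            f"NK landscapes (N=5, K={K}), kin groups with parasites: group-size "
            "sweep under full trans-complementation.",
            {"m1": _nk_base(K, m=1, rule="none", parasites_enabled=False),
             **{f"m{m}_full_trans": _nk_base(K, m=m, rule="full_trans")
                for m in (2, 5, 10)}})

    presets["fig6"] = ExperimentPreset(
        "fig6",
        "Rugged-landscape exploration (N=5, K=4): random starts, 150 "
        "generations, mutation-effect scan, kin groups with parasites.",
        {
            **{"m1": _nk_base(4, m=1, rule="none", parasites_enabled=False,
                              alpha=0.0005, initial_genotype="random",
                              fitness_threshold=2.0, max_generations=150,
                              measure_mutation_effects=True)},
            **{f"m{m}_full_trans": _nk_base(4, m=m, rule="full_trans", alpha=0.0005,
                                            initial_genotype="random",
                                            fitness_threshold=2.0, max_generations=150,
                                            measure_mutation_effects=True)
               for m in (2, 5, 10)},
        },
        replicates=10)

    presets["s1_beta_sweep"] = ExperimentPreset(
        "s1_beta_sweep",
        "Parasite intra-group advantage sweep (beta_C = 1..5), two-locus "
        "model, random pairs vs m=1 control.",
        {
            "m1": _two_locus_base(m=1, rule="none", parasites_enabled=False),
            **{f"m2_beta{b}": _two_locus_base(m=2, rule="full_trans",
                                              grouping="random",
                                              parasites_enabled=True,
                                              beta_C=float(b))
               for b in range(1, 6)},
        })

    presets["s2_avg_trans"] = ExperimentPreset(
        "s2_avg_trans",
        "Average (dosage-dependent) trans-complementation vs m=1, two-locus.",
        {
            "m1": _two_locus_base(m=1, rule="none", parasites_enabled=False),
            "m2_average_trans": _two_locus_base(m=2, rule="average_trans",
                                                grouping="random",
                                                parasites_enabled=False),
        })

    presets["s3_avg_cis"] = ExperimentPreset(
        "s3_avg_cis",
        "Average cis-complementation in kin groups with parasites, two-locus.",
        {
            "m1": _two_locus_base(m=1, rule="none", parasites_enabled=False),
            "m2_average_cis": _two_locus_base(m=2, rule="average_cis",
                                              grouping="kin",
                                              parasites_enabled=True),
        })
    return presets


PRESETS = _build_presets()

#: Offset separating per-replicate landscape seeds from run seeds.
_LANDSCAPE_SEED_OFFSET = 1_000_003


def load_experiment_file(path) -> ExperimentPreset:
    """Load an experiment description from a YAML file.

    The document has keys ``name``, ``replicates``, optional ``base`` (shared
    config fields) and ``conditions`` (mapping of condition name to config
    overrides).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = doc.get("base", {})
    conditions = {}
    for cname, over in doc["conditions"].items():
        merged = {**base, **(over or {})}
        if "landscape" not in merged:
            raise ValueError(f"condition {cname!r} has no landscape spec")
        conditions[cname] = merged
    return ExperimentPreset(name=doc.get("name", Path(path).stem),
                            description=doc.get("description", ""),
                            conditions=conditions,
                            replicates=int(doc.get("replicates", 100)))


def run_experiment(experiment, out_dir, replicates: int | None = None,
                   base_seed: int = 0, overrides: dict | None = None,
                   progress: bool = False) -> pd.DataFrame:
    """Run every (condition, replicate) of an experiment and write outputs.

    ``experiment`` is a preset name, an :class:`ExperimentPreset`, or a path
    to an experiment YAML file.  ``overrides`` is a mapping of config fields
    applied to every condition (e.g. ``{"S": 1000}`` for a scaled-down rerun).
    Returns the per-replicate results table (also written to
    ``results.csv``); ``summary.csv`` holds per-condition statistics.
    """
    if isinstance(experiment, str) and experiment in PRESETS:
        preset = PRESETS[experiment]
    elif isinstance(experiment, ExperimentPreset):
        preset = experiment
    else:
        preset = load_experiment_file(experiment)
    replicates = preset.replicates if replicates is None else replicates
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    resolved = {}
    iterator = preset.conditions.items()
    for cname, cdict in iterator:
        cdict = {**cdict, **(overrides or {})}
        resolved[cname] = cdict
        for r in range(replicates):
            seed = base_seed + r
            landscape_seed = base_seed + _LANDSCAPE_SEED_OFFSET + r
            traj_path = out / f"{cname}_rep{r:03d}.csv"
            cfg = config_from_dict({**cdict, "run_seed": seed},
                                   replicate_seed=landscape_seed)
            if traj_path.exists():
                traj = pd.read_csv(traj_path)
                reached = bool(traj["mean_fitness"].gt(cfg.fitness_threshold).any())
                gens = (int(traj.loc[traj["mean_fitness"] > cfg.fitness_threshold,
                                     "generation"].iloc[0])
                        if reached else CENSORED)
            else:
                result = run(cfg)
                traj = result.trajectory
                traj.insert(0, "condition", cname)
                traj.insert(1, "replicate", r)
                traj.insert(2, "seed", seed)
                traj.to_csv(traj_path, index=False, float_format="%.10g")
                reached = result.reached_threshold
                gens = result.generations_to_threshold
            rows.append({"condition": cname, "replicate": r, "seed": seed,
                         "reached_threshold": reached,
                         "generations_to_threshold": gens})
            if progress:
                print(f"[{cname} rep {r}] "
                      + (f"reached at {gens}" if reached else "censored"))
    results = pd.DataFrame(rows)
    results.to_csv(out / "results.csv", index=False)
    summary = summarize_results(results)
    summary.to_csv(out / "summary.csv", index=False)
    meta = {
        "experiment": preset.name,
        "description": preset.description,
        "replicates": replicates,
        "base_seed": base_seed,
        "conditions": resolved,
        "package_version": __version__,
        "landscapes": {
            cname: (landscape_to_json(config_from_dict(
                {**cdict, "run_seed": 0}, replicate_seed=base_seed + _LANDSCAPE_SEED_OFFSET)
                .landscape) if cdict["landscape"].get("seed") is not None
                or cdict["landscape"]["type"] == "two_locus" else "per-replicate")
            for cname, cdict in resolved.items()
        },
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    return results


def summarize_results(results: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean, SEM and censoring of generations-to-threshold.

    The mean and SEM are computed over uncensored replicates; censored runs
    (threshold never crossed) are reported via ``n_censored`` and
    ``censored_fraction`` rather than silently dropped.  SEM is the sample
    standard deviation over the square root of the replicate count, and is
    missing for a single replicate.
    """
    out = []
    for cname, sub in results.groupby("condition", sort=False):
        gens = sub.loc[sub["generations_to_threshold"] != CENSORED,
                       "generations_to_threshold"]
        n, n_cens = len(sub), int((sub["generations_to_threshold"] == CENSORED).sum())
        out.append({
            "condition": cname,
            "n_replicates": n,
            "n_censored": n_cens,
            "censored_fraction": n_cens / n,
            "mean_generations": gens.mean() if len(gens) else math.nan,
            "sem_generations": (gens.std(ddof=1) / math.sqrt(len(gens))
                                if len(gens) > 1 else math.nan),
        })
    return pd.DataFrame(out)


def summarize_replicates(trajectory_files, threshold: float = 0.95) -> pd.DataFrame:
    """Summarize trajectory CSVs (as written by :func:`run_experiment`).

    Each file must carry ``condition``, ``replicate``, ``generation`` and
    ``mean_fitness`` columns; time-to-threshold is re-derived from the
    trajectories at the given threshold.
    """
    files = list(trajectory_files)
    if not files:
        raise ValueError("no trajectory files given")
    rows = []
    for path in files:
        traj = pd.read_csv(path)
        hit = traj.loc[traj["mean_fitness"] > threshold, "generation"]
        rows.append({
            "condition": traj["condition"].iloc[0] if "condition" in traj else Path(path).stem,
            "replicate": int(traj["replicate"].iloc[0]) if "replicate" in traj else 0,
            "seed": int(traj["seed"].iloc[0]) if "seed" in traj else -1,
            "reached_threshold": bool(len(hit)),
            "generations_to_threshold": int(hit.iloc[0]) if len(hit) else CENSORED,
        })
    return summarize_results(pd.DataFrame(rows))
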