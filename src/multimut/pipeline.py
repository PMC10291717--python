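"""End-to-end orchestration: build -> connectivity -> modules -> roles -> stability.

A run is described by a manifest (plain dict, typically loaded from YAML):

.. code-block:: yaml

    synthetic:                      # either this ...
      intact_preset: intact_like
      invaded_preset: invaded_like
      overlap_fraction: 0.8
    # input: interactions.csv      # ... or a deposited edge list
    seed: 1
    shuffles: 100                  # null-model shuffles
    detect_trials: 20              # Infomap optimizer trials
    single_reps: 100               # cascades per species, single removal
    auc_runs: 100                  # sequential-removal runs per scenario
    scenarios: [most-to-least, least-to-most, random]
    R: {scheme: uniform}           # or {scheme: constant, value: 0.5}
    plant_normalization: both-layers

Every stochastic stage derives its substream from the root seed, so a rerun
with the same manifest reproduces the summary exactly.  The stability stage
uses the role assignment of its own network state.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    connectivity_summary,
    group_summary,
    indirect_link_matrix,
    indirect_link_turnover,
    interlayer_plant_presence,
    per_species_indirect_stats,
)
from .coextinction import (
    build_dependencies,
    random_R,
    robustness_experiment,
    single_removal_experiment,
    species_role_map,
)
from .modularity import detect_modules, module_count_null_test, module_layer_summary
from .network import (
    DISPERSAL,
    POLLINATION,
    InteractionTable,
    assemble_multilayer,
    read_interactions,
    write_multilayer,
)
from .roles import assign_roles, role_percentages, role_transitions
from .synthetic import generate_state_pair, load_preset

DEFAULTS = {
    "seed": 0,
    "shuffles": 100,
    "detect_trials": 20,
    "single_reps": 100,
    "auc_runs": 100,
    "scenarios": ["most-to-least", "least-to-most", "random"],
    "R": {"scheme": "uniform"},
    "plant_normalization": "both-layers",
}


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


def load_manifest(path: str | Path) -> dict:
    manifest = yaml.safe_load(Path(path).read_text())
    if not isinstance(manifest, dict):
        raise PipelineError("manifest: expected a mapping")
    return manifest


def _validate(manifest: dict) -> dict:
    cfg = {**DEFAULTS, **manifest}
    if ("synthetic" in cfg) == ("input" in cfg):
        raise PipelineError("manifest: exactly one of 'synthetic' or 'input' is required")
    for key in ("shuffles", "detect_trials", "single_reps", "auc_runs"):
        if int(cfg[key]) < 1:
            raise PipelineError(f"manifest: {key} must be >= 1, got {cfg[key]}")
    for scenario in cfg["scenarios"]:
        if scenario not in ("most-to-least", "least-to-most", "random"):
            raise PipelineError(f"manifest: unknown scenario {scenario!r}")
    if cfg["R"].get("scheme") not in ("uniform", "constant", "per-group"):
        raise PipelineError(f"manifest: unknown R scheme {cfg['R']!r}")
    return cfg


def _log(quiet: bool, stage: str, started: float) -> None:
    if not quiet:
        print(f"[multimut] {stage}: {time.perf_counter() - started:.2f}s", file=sys.stderr)


def _load_tables(cfg: dict) -> dict[str, tuple[InteractionTable, InteractionTable]]:
    if "input" in cfg:
        path = Path(cfg["input"])
        if not path.exists():
            raise PipelineError(f"build: input file {path} does not exist")
        tables = read_interactions(path)
        states = sorted({state for state, _ in tables})
        out = {}
        for state in states:
            try:
                out[state] = (tables[(state, POLLINATION)], tables[(state, DISPERSAL)])
            except KeyError as exc:
                raise PipelineError(f"build: state {state!r} lacks layer {exc}") from exc
        return out
    syn = cfg["synthetic"]
    intact = load_preset(syn.get("intact_preset", "intact_like"))
    invaded = load_preset(syn.get("invaded_preset", "invaded_like"))
    return generate_state_pair(
        intact, invaded, syn.get("overlap_fraction", 0.8), seed=cfg["seed"]
    )


def _r_config(cfg: dict, network, seed: int):
    scheme = cfg["R"]["scheme"]
    if scheme == "constant":
        return float(cfg["R"].get("value", 0.5))
    if scheme == "per-group":
        return {g: float(v) for g, v in cfg["R"]["values"].items()}
    return random_R(network, seed)


def run_pipeline(manifest: dict, outdir: str | Path, quiet: bool = False) -> dict:
    """Execute all stages for every state in the manifest; return the summary."""
    cfg = _validate(manifest)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    states = _load_tables(cfg)

    summary: dict = {"version": __version__, "seed": seed, "states": {}}
    bundles: dict[str, dict] = {}
    for offset, (state, (pol, disp)) in enumerate(sorted(states.items())):
        state_seed = seed + 1000 * offset
        state_summary: dict = {}
        t0 = time.perf_counter()
        try:
            network = assemble_multilayer(pol, disp)
            write_multilayer(network, outdir)
            state_summary["network"] = network.summary()
        except Exception as exc:
            raise PipelineError(f"build[{state}]: {exc}") from exc
        _log(quiet, f"build[{state}]", t0)

        t0 = time.perf_counter()
        try:
            ilm = indirect_link_matrix(network)
            stats = per_species_indirect_stats(ilm)
            stats.to_csv(outdir / f"{state}_indirect_links_per_species.csv", index=False)
            ilm.matrix.to_csv(outdir / f"{state}_indirect_link_matrix.csv")
            state_summary["connectivity"] = connectivity_summary(network)
        except Exception as exc:
            raise PipelineError(f"connectivity[{state}]: {exc}") from exc
        _log(quiet, f"connectivity[{state}]", t0)

        t0 = time.perf_counter()
        try:
            partition = detect_modules(network, seed=state_seed, trials=int(cfg["detect_trials"]))
            partition.assignments.to_csv(outdir / f"{state}_modules.csv", index=False)
            module_layer_summary(partition).to_csv(
                outdir / f"{state}_module_layer_summary.csv", index=False
            )
            null = module_count_null_test(
                pol,
                disp,
                n_shuffles=int(cfg["shuffles"]),
                seed=state_seed,
                trials=int(cfg["detect_trials"]),
            )
            state_summary["modularity"] = {"codelength": partition.codelength, **null.to_dict()}
        except Exception as exc:
            raise PipelineError(f"modules[{state}]: {exc}") from exc
        _log(quiet, f"modules[{state}]", t0)

        t0 = time.perf_counter()
        try:
            roles_df = assign_roles(network, partition)
            roles_df.to_csv(outdir / f"{state}_roles.csv", index=False)
            pct = role_percentages(roles_df)
            pct.to_csv(outdir / f"{state}_role_percentages.csv", index=False)
            state_summary["roles"] = {
                row["role"]: row["pct_state_nodes"] for _, row in pct.iterrows()
            }
        except Exception as exc:
            raise PipelineError(f"roles[{state}]: {exc}") from exc
        _log(quiet, f"roles[{state}]", t0)

        t0 = time.perf_counter()
        try:
            r_cfg = _r_config(cfg, network, state_seed)
            deps = build_dependencies(network, r_cfg, cfg["plant_normalization"])
            role_map = species_role_map(roles_df)
            single = single_removal_experiment(
                deps, reps=int(cfg["single_reps"]), seed=state_seed, roles=role_map
            )
            single.to_csv(outdir / f"{state}_single_removal_E.csv", index=False)
            mean_e_by_role = single.groupby("role")["mean_E"].mean().to_dict()
            aucs = {}
            for scenario in cfg["scenarios"]:
                sample = robustness_experiment(
                    deps, scenario, role_map, n_runs=int(cfg["auc_runs"]), seed=state_seed
                )
                sample.to_csv(
                    outdir / f"{state}_auc_{scenario.replace('-', '_')}.csv", index=False
                )
                aucs[scenario] = {
                    "mean": float(sample["auc"].mean()),
                    "sd": float(sample["auc"].std(ddof=1)),
                    "n_runs": int(cfg["auc_runs"]),
                }
            state_summary["stability"] = {
                "mean_E_overall": float(single["mean_E"].mean()),
                "mean_E_by_role": {k: float(v) for k, v in mean_e_by_role.items()},
                "auc": aucs,
            }
        except Exception as exc:
            raise PipelineError(f"stability[{state}]: {exc}") from exc
        _log(quiet, f"stability[{state}]", t0)

        summary["states"][state] = state_summary
        bundles[state] = {"network": network, "ilm": ilm, "roles": roles_df}

    if len(bundles) == 2:
        (state_a, a), (state_b, b) = sorted(bundles.items())
        summary["turnover_jaccard"] = indirect_link_turnover(a["ilm"], b["ilm"])
        interlayer_plant_presence(a["network"], b["network"]).to_csv(
            outdir / "interlayer_plant_presence.csv", index=False
        )
        transitions = role_transitions(a["roles"], b["roles"])
        transitions.to_csv(outdir / "role_transitions.csv", index=False)
        summary["role_transitions"] = transitions.to_dict(orient="records")

    manifest_out = {**cfg, "version": __version__}
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest_out, sort_keys=False))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def compare_states(summary: dict) -> pd.DataFrame:
    """Side-by-side headline quantities for a two-state summary, with ratios."""
    states = sorted(summary["states"])
    if len(states) != 2:
        raise ValueError(f"need exactly two states, got {states}")
    a, b = states
    rows = []

    def add(quantity: str, getter) -> None:
        va, vb = getter(summary["states"][a]), getter(summary["states"][b])
        ratio = float("nan")
        if va is not None and vb is not None and vb not in (0, None):
            ratio = va / vb
        rows.append({"quantity": quantity, a: va, b: vb, f"{a}/{b}": ratio})

    add("n_species", lambda s: s["network"]["n_species"])
    add("n_interlayer_plants", lambda s: s["network"]["n_interlayer_plants"])
    add("n_modules", lambda s: s.get("modularity", {}).get("observed_modules"))
    add("null_p_value", lambda s: s.get("modularity", {}).get("p_value"))
    add("pct_peripheral", lambda s: s.get("roles", {}).get("peripheral"))
    add("pct_connector", lambda s: s.get("roles", {}).get("connector"))
    add("mean_E", lambda s: s.get("stability", {}).get("mean_E_overall"))
    for scenario in ("most-to-least", "least-to-most", "random"):
        add(
            f"auc_{scenario}",
            lambda s, sc=scenario: s.get("stability", {}).get("auc", {}).get(sc, {}).get("mean"),
        )
    df = pd.DataFrame(rows)
    missing = df[df[[a, b]].isna().any(axis=1)]["quantity"].tolist()
    if missing:
        df.attrs["missing_stages"] = missing
    return df
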