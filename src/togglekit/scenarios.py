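"""Built-in analysis scenarios: parameter sweeps behind the package's studies.

Each :class:`Scenario` bundles a named, seeded, fully specified job — the
parameter sets, sweep axes and resolutions for one of the standard analyses
(nullcline panels, stability phase diagrams, barrier sweeps, population-fate
evolution, balancing maps, multi-switch capacity).  Resolutions are kept
modest (tens of grid points per axis) so every scenario runs end-to-end on a
single CPU in minutes; :func:`run_scenario` executes a scenario and writes
long-format CSV tables, scalar JSON summaries and a manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .params import ReducedParams, ToggleParams, toggle_from_reduced
from .stability import find_fixed_points, nullclines, stability_diagram
from .potential import barrier_sweep
from .balancing import mismatch_error, optimize_competition
from .population import evolve, generations_to_steady, stationary_composition
from .multiswitch import collective_stability, ncrit_sweep


@dataclass(frozen=True)
class Scenario:
    """A named, seeded, resolvable analysis job."""

    name: str
    target: str          # which analysis module the scenario drives
    description: str
    spec: dict = field(default_factory=dict)
    seed: int = 0


def builtin_scenarios() -> list[Scenario]:
    """The shipped scenario suite (reduced-resolution standard analyses)."""
    return [
        Scenario(
            name="fig1a", target="nullclines",
            description="Nullcline panels: moderate vs strong sequestration "
                        "of a balanced switch.",
            spec={"param_sets": [
                {"alpha_y": 10, "alpha_z": 10, "beta_y": 1, "beta_z": 1},
                {"alpha_y": 10, "alpha_z": 10, "beta_y": 10, "beta_z": 10},
            ], "n_grid": 201},
        ),
        Scenario(
            name="fig3a", target="stability_diagram",
            description="Balanced-switch stability over (beta0, b): boundary "
                        "independent of b; unrealizable cells marked.",
            spec={"x": "beta0", "y": "b",
                  "x_values": list(np.linspace(1, 36, 15)),
                  "y_values": list(np.geomspace(1 / 16, 16, 13)),
                  "fixed": {"alpha0": 10.0, "a": 1.0}},
            seed=301,
        ),
        Scenario(
            name="fig3b", target="stability_diagram",
            description="Stability over (a, alpha0) at fixed sequestration.",
            spec={"x": "a", "y": "alpha0",
                  "x_values": list(np.linspace(1, 3, 11)),
                  "y_values": list(np.linspace(2, 14, 13)),
                  "fixed": {"beta0": 6.0, "b": 1.0}},
            seed=302,
        ),
        Scenario(
            name="fig3c", target="stability_diagram_panels",
            description="Stability over (a, alpha0): shifting a fixed overall "
                        "load toward the stronger side preserves bistability.",
            spec={"x": "a", "y": "alpha0",
                  "x_values": list(np.linspace(1, 3, 9)),
                  "y_values": list(np.linspace(2, 14, 9)),
                  "panels": [{"beta0": 1.0, "b": 1.0}, {"beta0": 6.0, "b": 1.0},
                             {"beta0": 6.0, "b": 6.0}, {"beta0": 6.0, "b": 1 / 6}]},
            seed=303,
        ),
        Scenario(
            name="fig2a", target="barriers",
            description="Barrier pairs: balanced, sequestered, unbalanced.",
            spec={"variants": [
                {"alpha_y": 10, "alpha_z": 10, "beta_y": 0.25, "beta_z": 0.25},
                {"alpha_y": 10, "alpha_z": 10, "beta_y": 0, "beta_z": 0},
                {"alpha_y": 9.33, "alpha_z": 10.72, "beta_y": 0, "beta_z": 0},
            ], "grid": 61},
        ),
        Scenario(
            name="fig4", target="barriers",
            description="Barrier sweep over toggle variants with increasing "
                        "alpha0, with and without sequestration.",
            spec={"variants": (
                [{"alpha_y": 10, "alpha_z": az, "beta_y": 0, "beta_z": 0}
                 for az in (10, 12, 14, 16)]
                + [{"alpha_y": ay, "alpha_z": 10, "beta_y": 0, "beta_z": 0}
                   for ay in (12, 14, 16)]
                + [{"alpha_y": 10, "alpha_z": az, "beta_y": 0.25, "beta_z": 0.25}
                   for az in (10, 12, 14, 16)]
            ), "grid": 61},
        ),
        Scenario(
            name="fig5", target="population",
            description="Population-fate evolution for the three switching-"
                        "probability pairs, both seed states.",
            spec={"pairs": [[0.02, 0.2], [0.1, 0.05], [0.1, 0.15]],
                  "generations": 8},
        ),
        Scenario(
            name="fig6a", target="balance_map",
            description="Misclassification error over (a, alpha0) without "
                        "competition.",
            spec={"a_values": [1.0, 1.25, 1.5, 1.75, 2.0],
                  "alpha0_values": [4, 6, 8, 10], "n_grid": 61},
        ),
        Scenario(
            name="fig6b", target="balance_optimize",
            description="Minimized misclassification error after competition "
                        "optimization.",
            spec={"a_values": [1.0, 1.5, 2.0], "alpha0_values": [10],
                  "search_grid": 31, "n_grid": 61},
        ),
        Scenario(
            name="fig7a", target="multiswitch_labels",
            description="Collective stability of N copies of a bistable "
                        "switch.",
            spec={"alpha_y": 25, "alpha_z": 20, "beta_y": 1, "beta_z": 1.5,
                  "n_values": [1, 2, 3, 4, 5, 6], "n_ic": 100},
            seed=701,
        ),
        Scenario(
            name="fig7bc", target="ncrit_sweep",
            description="Critical switch number over (alpha0, a).",
            spec={"alpha0_values": [10, 15, 20, 25],
                  "a_values": [1.0, 1.2, 1.4, 1.6],
                  "beta0": 2.25, "b": 1.0, "n_max": 64},
            seed=702,
        ),
    ]


def get_scenario(name: str) -> Scenario:
    for s in builtin_scenarios():
        if s.name == name:
            return s
    raise KeyError(f"unknown scenario {name!r}")


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_scenario(scenario: Scenario, outdir: str | Path) -> dict:
    """Execute a scenario, writing CSV/JSON outputs and a manifest.

    Deterministic given the scenario's seed; returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    outputs: list[str] = []
    summary: dict = {}
    spec = scenario.spec
    target = scenario.target

    if target == "nullclines":
        rows = []
        for k, ps in enumerate(spec["param_sets"]):
            p = ToggleParams.from_dict(ps)
            grid = np.linspace(0, 1.2 * max(p.alpha_y, p.alpha_z), spec["n_grid"])
            for axis in ("y", "z"):
                for coord, roots in zip(grid, nullclines(p, axis, grid)):
                    for r in roots:
                        y, z = (r, coord) if axis == "y" else (coord, r)
                        rows.append({"param_set": k, "nullcline": axis,
                                     "y": y, "z": z})
            stab = find_fixed_points(p)
            summary[f"param_set_{k}"] = {
                "params": ps, "label": stab.label,
                "fixed_points": [[fp.y, fp.z, fp.klass]
                                 for fp in stab.fixed_points],
            }
        _write_csv(pd.DataFrame(rows), outdir / "nullclines.csv")
        outputs.append("nullclines.csv")

    elif target == "stability_diagram":
        df = stability_diagram(spec["x"], spec["y"], spec["x_values"],
                               spec["y_values"], spec["fixed"],
                               seed=scenario.seed)
        _write_csv(df, outdir / "diagram.csv")
        outputs.append("diagram.csv")
        summary["n_bistable"] = int((df["label"] == "bistable").sum())

    elif target == "stability_diagram_panels":
        frames = []
        for i, fixed in enumerate(spec["panels"]):
            df = stability_diagram(spec["x"], spec["y"], spec["x_values"],
                                   spec["y_values"], fixed,
                                   seed=scenario.seed + i)
            df["panel"] = i
            for k, v in fixed.items():
                df[k] = v
            frames.append(df)
        _write_csv(pd.concat(frames, ignore_index=True), outdir / "diagram.csv")
        outputs.append("diagram.csv")

    elif target == "barriers":
        variants = [ToggleParams.from_dict(v) for v in spec["variants"]]
        df = barrier_sweep(variants, grid_spec=spec.get("grid", 61))
        _write_csv(df, outdir / "barriers.csv")
        outputs.append("barriers.csv")
        summary["normalization"] = df.attrs["normalization"]

    elif target == "population":
        frames = []
        steady = {}
        for py, pz in spec["pairs"]:
            for seed_state in (0, 1):
                dists = evolve(py, pz, spec["generations"], seed_state)
                for d in dists:
                    f = d.to_frame()
                    f["py"] = py
                    f["pz"] = pz
                    frames.append(f)
                steady[f"py={py},pz={pz},seed={seed_state}"] = {
                    "stationary_fraction": stationary_composition(py, pz),
                    "generations_to_steady":
                        generations_to_steady(py, pz, seed_state),
                }
        _write_csv(pd.concat(frames, ignore_index=True),
                   outdir / "distributions.csv")
        outputs.append("distributions.csv")
        summary["steady_state"] = steady

    elif target == "balance_map":
        rows = []
        for a in spec["a_values"]:
            for alpha0 in spec["alpha0_values"]:
                p = toggle_from_reduced(ReducedParams(alpha0=alpha0, a=a))
                res = mismatch_error(p, n_grid=spec["n_grid"])
                rows.append({"a": a, "alpha0": alpha0, "label": res.label,
                             "e_psi_percent": res.e_psi_percent})
        _write_csv(pd.DataFrame(rows), outdir / "balance.csv")
        outputs.append("balance.csv")

    elif target == "balance_optimize":
        rows = []
        for a in spec["a_values"]:
            for alpha0 in spec["alpha0_values"]:
                p = toggle_from_reduced(ReducedParams(alpha0=alpha0, a=a))
                res = optimize_competition(
                    p.alpha_y, p.alpha_z,
                    search_grid=spec.get("search_grid", 31),
                    n_grid=spec["n_grid"])
                rows.append({"a": a, "alpha0": alpha0,
                             "beta_y_opt": res.beta_opt[0],
                             "beta_z_opt": res.beta_opt[1],
                             "e_psi_percent": res.e_psi_percent})
        _write_csv(pd.DataFrame(rows), outdir / "balance_opt.csv")
        outputs.append("balance_opt.csv")

    elif target == "multiswitch_labels":
        p = ToggleParams(alpha_y=spec["alpha_y"], alpha_z=spec["alpha_z"],
                         beta_y=spec["beta_y"], beta_z=spec["beta_z"])
        rows = [{"n": n,
                 "label": collective_stability(n, p, n_ic=spec["n_ic"],
                                               seed=scenario.seed + n)}
                for n in spec["n_values"]]
        _write_csv(pd.DataFrame(rows), outdir / "labels.csv")
        outputs.append("labels.csv")

    elif target == "ncrit_sweep":
        df = ncrit_sweep(spec["alpha0_values"], spec["a_values"],
                         beta0=spec["beta0"], b=spec["b"],
                         n_max=spec["n_max"], seed=scenario.seed)
        _write_csv(df, outdir / "ncrit.csv")
        outputs.append("ncrit.csv")

    else:
        raise ValueError(f"unknown scenario target {target!r}")

    manifest = {
        "scenario": scenario.name,
        "target": target,
        "description": scenario.description,
        "spec": _jsonable(spec),
        "seed": scenario.seed,
        "version": __version__,
        "runtime_s": round(time.time() - t0, 3),
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    if summary:
        (outdir / "summary.json").write_text(
            json.dumps(_jsonable(summary), indent=2) + "\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
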