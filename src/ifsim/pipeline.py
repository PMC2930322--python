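"""Experiment recipes: end-to-end desk-scale protocols.

A recipe is an ordered list of stages; each stage names a registered
operation and its parameters, consumes products of earlier stages from a
shared context, and writes its artifacts under the output directory.
Re-running a recipe with identical seeds reproduces all numeric outputs;
every run writes a config echo (with seeds and a content hash) alongside
the results.

Built-in recipes:

* ``dimer_solution_vs_substrate`` / ``tetramer_solution_vs_substrate`` -- solution vs on-substrate
  equilibration and the conformational observables (end-to-end length,
  projection area, SASA), means +- sd over seeds;
* ``afm_nacl_conditions`` -- synthetic vimentin and K5/K14 NaCl scenes through the
  morphometry pipeline;
* ``afm_condensation_conditions`` -- the CaCl2 and glutaraldehyde K5/K14 scenes;
* ``calibration_report`` -- the adhesion calibration curve.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import afm_morphometry, afm_synthetic
from .conformation import cg_sasa, end_to_end_length, projection_area
from .dynamics import SimulationConfig, Trajectory, check_convergence, run_simulation
from .energetics import (
    ForceFieldParams,
    PER_RESIDUE_WELL_KCAL,
    calibrate_bead_well_depth,
    calibrated_lattice,
    single_bead_well,
)
from .geometry import build_dimer, build_tetramer, lattice_for_model
from .io import save_config, write_xyz_trajectory

__all__ = [
    "ExperimentRecipe",
    "run_recipe",
    "built_in_recipe",
    "RECIPES",
    "deposit_subunit",
    "solution_subunit",
    "trailing_mean",
]


# ---------------------------------------------------------------------------
# protocol helpers (used by recipes, tests and the acceptance script)

def _build(kind: str):
    if kind == "dimer":
        return build_dimer()
    if kind == "tetramer":
        return build_tetramer()
    raise ValueError(f"unknown subunit kind {kind!r}")


def deposit_subunit(
    kind: str,
    seed: int,
    n_steps: int = 400_000,
    timestep: float = 2e-4,
    record_every: int = 4000,
    margin: float = 25.0,
) -> Trajectory:
    """Deposition protocol: extended subunit placed 3 nm above a
    calibrated lattice, deposition pull active, Langevin at 300 K."""
    model = _build(kind).placed_above_plane(3.0)
    lattice = calibrated_lattice(
        lattice_for_model(model, margin=margin), model.residues_per_bead
    )
    cfg = SimulationConfig(
        timestep=timestep,
        n_steps=n_steps,
        seed=seed,
        record_every=record_every,
        environment="substrate",
        record_energies=False,
    )
    return run_simulation(model, lattice, ForceFieldParams(), cfg)


def solution_subunit(
    kind: str,
    seed: int,
    n_steps: int = 600_000,
    timestep: float = 2e-3,
    record_every: int = 6000,
) -> Trajectory:
    """Free (solution) equilibration from the extended build.

    Without the stiff adhesion term the integrator is stable at a 10x
    larger timestep, which is what makes solution equilibration of the
    slow tetramer arm modes affordable at desk scale.
    """
    model = _build(kind)
    cfg = SimulationConfig(
        timestep=timestep,
        n_steps=n_steps,
        seed=seed,
        record_every=record_every,
        environment="solution",
        record_energies=False,
    )
    return run_simulation(model, None, ForceFieldParams(), cfg)


def trailing_mean(values, frac: float = 0.25) -> float:
    """Mean over the trailing fraction of a series (the averaging window
    used after convergence)."""
    v = np.asarray(values, dtype=float)
    k = max(int(len(v) * frac), 1)
    return float(v[-k:].mean())


def _condition_metrics(traj: Trajectory, frac: float = 0.25) -> dict:
    model = traj.model
    k = max(int(traj.n_frames * frac), 1)
    lee, area, sasa = [], [], []
    for pos in traj.positions[-k:]:
        lee.append(end_to_end_length(model, pos))
        area.append(projection_area(pos, model.radii, grid_resolution=0.5))
        sasa.append(cg_sasa(pos, model.radii, n_sphere_points=240))
    conv, _ = check_convergence(traj)
    return {
        "L_ee": float(np.mean(lee)),
        "projection_area": float(np.mean(area)),
        "sasa": float(np.mean(sasa)),
        "converged": bool(conv),
    }


# ---------------------------------------------------------------------------
# recipe machinery

@dataclass
class ExperimentRecipe:
    name: str
    stages: list  # list of {"name": str, "op": str, "params": dict}
    seeds: list = field(default_factory=lambda: [1, 2, 3])


class StageError(RuntimeError):
    def __init__(self, stage: str, seed, err: Exception):
        super().__init__(f"stage {stage!r} failed (seed {seed}): {err}")
        self.stage = stage


def _op_subunit_conditions(ctx, seeds, outdir, kind, n_steps_substrate,
                           n_steps_solution):
    rows = []
    for seed in seeds:
        for condition, traj in (
            ("solution", solution_subunit(kind, seed, n_steps=n_steps_solution)),
            ("substrate", deposit_subunit(kind, seed, n_steps=n_steps_substrate)),
        ):
            m = _condition_metrics(traj)
            rows.append({"kind": kind, "condition": condition, "seed": seed, **m})
            write_xyz_trajectory(
                Path(outdir) / f"{kind}_{condition}_seed{seed}.xyz", traj
            )
    df = pd.DataFrame(rows)
    df.to_csv(Path(outdir) / f"{kind}_metrics_per_seed.csv", index=False)
    summary = (
        df.groupby("condition")[["L_ee", "projection_area", "sasa"]]
        .agg(["mean", "std"])
    )
    ctx["tables"].append((f"{kind}_conditions", summary))
    ctx["report"][f"{kind}"] = {
        cond: {
            "L_ee_mean": float(df[df.condition == cond].L_ee.mean()),
            "L_ee_sd": float(df[df.condition == cond].L_ee.std(ddof=1)),
            "projection_area_mean": float(
                df[df.condition == cond].projection_area.mean()
            ),
            "sasa_mean": float(df[df.condition == cond].sasa.mean()),
        }
        for cond in ("solution", "substrate")
    }


def _op_afm_condition(ctx, seeds, outdir, preset, n_subunits, image_size,
                      tip_radius, noise_sigma):
    rows = []
    for seed in seeds:
        scene = afm_synthetic.generate_scene(
            preset, n_subunits, image_size=image_size, seed=seed
        )
        scene = afm_synthetic.render_tip_dilation(scene, tip_radius)
        scene = afm_synthetic.add_noise(scene, noise_sigma, seed=seed + 7919)
        afm_synthetic.write_tiff(
            Path(outdir) / f"{preset}_seed{seed}.tiff", scene
        )
        kept, summary, _ = afm_morphometry.measure_image(scene)
        rows.append({"preset": preset, "seed": seed, **summary})
        pd.DataFrame([r.__dict__ for r in kept]).to_csv(
            Path(outdir) / f"{preset}_objects_seed{seed}.csv", index=False
        )
    df = pd.DataFrame(rows)
    df.to_csv(Path(outdir) / f"{preset}_summary_per_seed.csv", index=False)
    ctx["report"][preset] = {
        "mean_height": float(df.mean_height.mean()),
        "mean_area": float(df.mean_area.mean()),
        "n_mean": float(df.n.mean()),
    }


def _op_calibration_report(ctx, seeds, outdir, targets, pair_r_min):
    from .geometry import build_substrate

    lattice = build_substrate(0.98, 30.0, 30.0)
    rows = []
    for target in targets:
        eps = calibrate_bead_well_depth(target, pair_r_min, lattice)
        from .energetics import LJParams, replace_lattice_lj

        achieved, z0 = single_bead_well(
            replace_lattice_lj(lattice, LJParams(eps, pair_r_min))
        )
        rows.append(
            {
                "target_kcal_mol": target,
                "eps_pair": eps,
                "achieved_well": achieved,
                "residual": achieved - target,
                "z_min_nm": z0,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(Path(outdir) / "calibration.csv", index=False)
    ctx["report"]["calibration"] = {
        "max_abs_residual": float(df.residual.abs().max())
    }


_OPS = {
    "subunit_conditions": _op_subunit_conditions,
    "afm_condition": _op_afm_condition,
    "calibration_report": _op_calibration_report,
}


def run_recipe(recipe: ExperimentRecipe, outdir) -> dict:
    """Execute a recipe; returns the report dict (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = {"report": {}, "tables": []}
    echo = {
        "recipe": recipe.name,
        "seeds": list(recipe.seeds),
        "stages": recipe.stages,
    }
    echo["config_hash"] = hashlib.sha256(
        json.dumps(echo, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    save_config(echo, outdir / "config_echo.json")
    for stage in recipe.stages:
        op = stage.get("op")
        if op not in _OPS:
            raise ValueError(
                f"recipe {recipe.name!r}: unknown stage operation {op!r} "
                f"(stage {stage.get('name', '?')!r})"
            )
        try:
            _OPS[op](ctx, recipe.seeds, outdir, **stage.get("params", {}))
        except ValueError:
            raise
        except Exception as err:  # pragma: no cover - defensive
            raise StageError(stage.get("name", op), recipe.seeds, err) from err
    report = {"recipe": recipe.name, "config_hash": echo["config_hash"],
              "seeds": list(recipe.seeds), **ctx["report"]}
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True)
    )
    return report


def built_in_recipe(name: str, seeds=None, scale: float = 1.0) -> ExperimentRecipe:
    """Construct one of the named desk-scale recipes.

    ``scale`` < 1 shortens simulations / shrinks scenes proportionally
    (useful for smoke tests).
    """
    seeds = list(seeds) if seeds is not None else [1, 2, 3]
    s = scale

    def ss(n):
        return max(int(n * s), 2000)

    if name == "dimer_solution_vs_substrate":
        stages = [
            {
                "name": "dimer solution vs substrate",
                "op": "subunit_conditions",
                "params": {
                    "kind": "dimer",
                    "n_steps_substrate": ss(400_000),
                    "n_steps_solution": ss(600_000),
                },
            }
        ]
    elif name == "tetramer_solution_vs_substrate":
        stages = [
            {
                "name": "tetramer solution vs substrate",
                "op": "subunit_conditions",
                "params": {
                    "kind": "tetramer",
                    "n_steps_substrate": ss(400_000),
                    "n_steps_solution": ss(600_000),
                },
            }
        ]
    elif name == "afm_nacl_conditions":
        stages = [
            {
                "name": preset,
                "op": "afm_condition",
                "params": {
                    "preset": preset,
                    "n_subunits": max(int(300 * s), 30),
                    "image_size": 3000.0 if preset == "K5K14_NaCl" else 2000.0,
                    "tip_radius": 3.0,
                    "noise_sigma": 0.03,
                },
            }
            for preset in ("vimentin_NaCl", "K5K14_NaCl")
        ]
    elif name == "afm_condensation_conditions":
        stages = [
            {
                "name": preset,
                "op": "afm_condition",
                "params": {
                    "preset": preset,
                    "n_subunits": max(int(300 * s), 30),
                    "image_size": 2000.0,
                    "tip_radius": 3.0,
                    "noise_sigma": 0.03,
                },
            }
            for preset in ("K5K14_glutaraldehyde", "K5K14_CaCl2")
        ]
    elif name == "calibration_report":
        stages = [
            {
                "name": "calibration",
                "op": "calibration_report",
                "params": {
                    "targets": [
                        PER_RESIDUE_WELL_KCAL,
                        9.0,
                        18.0 * PER_RESIDUE_WELL_KCAL,
                    ],
                    "pair_r_min": 1.0,
                },
            }
        ]
    else:
        raise ValueError(f"unknown recipe {name!r}")
    return ExperimentRecipe(name=name, stages=stages, seeds=seeds)


RECIPES = (
    "dimer_solution_vs_substrate",
    "tetramer_solution_vs_substrate",
    "afm_nacl_conditions",
    "afm_condensation_conditions",
    "calibration_report",
)
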