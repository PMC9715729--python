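"""Pipeline orchestration: build -> simulate/ingest -> classify -> kinetics
-> diffusion -> isotherms, driven by a YAML config.

Every stage writes machine-readable CSV/JSON artifacts into the output
directory; ``summary.json`` records the config hash and seed so a run is
reproducible and self-describing.  Stage outputs are pure functions of
(inputs, config, seed): re-running with the same config is byte-identical.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffusion as dif
from . import geometry as geo
from . import isotherms as iso
from . import kinetics as kin
from .constants import M_WATER
from .fibril import surface_report
from .simulate import emulate_paper_system, simulate
from .trajio import ROLE_FIBRIL_CARBON, ROLE_WATER_OXYGEN, read_frames, select

log = logging.getLogger("fibrilsorb")

__all__ = ["RunConfig", "load_config", "validate", "run", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "results/run",
    "source": {"kind": "synthetic", "scale": 0.01, "n_frames": 200, "trap": "hull", "trajectory": None},
    "stages": {"classify": True, "kinetics": True, "diffusion": True, "isotherm": True},
    "parameters": {
        "nn_k": 50,
        "dt_ps": 10.0,
        "shell_cutoff_nm": 0.0,
        "moving_average_n": 100,
        "isotherm_variant": "park",
        "hakalahti_K_C": None,
        "temperature_list": [],
    },
}

_SCHEMA_TYPES = {
    ("seed",): int,
    ("output_dir",): str,
    ("source", "kind"): str,
    ("source", "scale"): (int, float),
    ("source", "n_frames"): int,
    ("source", "trap"): str,
    ("source", "trajectory"): (str, type(None)),
    ("stages", "classify"): bool,
    ("stages", "kinetics"): bool,
    ("stages", "diffusion"): bool,
    ("stages", "isotherm"): bool,
    ("parameters", "nn_k"): int,
    ("parameters", "dt_ps"): (int, float),
    ("parameters", "shell_cutoff_nm"): (int, float),
    ("parameters", "moving_average_n"): int,
    ("parameters", "isotherm_variant"): str,
    ("parameters", "hakalahti_K_C"): (int, float, type(None)),
    ("parameters", "temperature_list"): list,
}


@dataclass
class RunConfig:
    raw: dict

    @property
    def seed(self) -> int:
        return self.raw["seed"]

    def __getitem__(self, key):
        return self.raw[key]

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    raw = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        raw = _merge(raw, user)
    if overrides:
        raw = _merge(raw, overrides)
    return RunConfig(raw=raw)


def validate(config: RunConfig | dict) -> list[tuple[str, str]]:
    """Schema and invariant check; returns (level, message) diagnostics."""
    raw = config.raw if isinstance(config, RunConfig) else config
    diags: list[tuple[str, str]] = []

    def walk(node: dict, ref: dict, prefix: tuple):
        for key, val in node.items():
            if key not in ref:
                near = difflib.get_close_matches(str(key), [str(k) for k in ref], n=1)
                hint = f"; did you mean {near[0]!r}?" if near else ""
                diags.append(("warning", f"unknown key {'.'.join(prefix + (str(key),))!r}{hint}"))
                continue
            if isinstance(ref[key], dict) and isinstance(val, dict):
                walk(val, ref[key], prefix + (key,))
            else:
                want = _SCHEMA_TYPES.get(prefix + (key,))
                if want is not None and not isinstance(val, want) or isinstance(val, bool) and want is int:
                    diags.append(
                        ("error", f"{'.'.join(prefix + (str(key),))}: expected {want}, got {type(val).__name__}")
                    )

    walk(raw, DEFAULT_CONFIG, ())
    src = raw.get("source", {})
    par = raw.get("parameters", {})
    if src.get("kind") not in ("synthetic", "files"):
        diags.append(("error", f"source.kind must be 'synthetic' or 'files', got {src.get('kind')!r}"))
    if src.get("kind") == "synthetic" and not (0 < float(src.get("scale", 0)) <= 1):
        diags.append(("error", f"source.scale must be in (0, 1], got {src.get('scale')}"))
    if src.get("kind") == "synthetic" and src.get("trap", "hull") not in ("hull", "block"):
        diags.append(("error", f"source.trap must be 'hull' or 'block', got {src.get('trap')!r}"))
    if src.get("kind") == "files":
        p = src.get("trajectory")
        if not p or not Path(p).exists():
            diags.append(("error", f"source.trajectory does not exist: {p!r}"))
    if isinstance(par.get("dt_ps"), (int, float)) and par.get("dt_ps", 1) <= 0:
        diags.append(("error", f"parameters.dt_ps must be > 0, got {par.get('dt_ps')}"))
    if isinstance(par.get("nn_k"), int) and par.get("nn_k", 1) < 1:
        diags.append(("error", f"parameters.nn_k must be >= 1, got {par.get('nn_k')}"))
    if isinstance(par.get("moving_average_n"), int) and par.get("moving_average_n", 1) < 1:
        diags.append(("error", "parameters.moving_average_n must be >= 1"))
    if par.get("isotherm_variant") not in ("park", "hakalahti"):
        diags.append(("error", f"isotherm_variant must be 'park' or 'hakalahti', got {par.get('isotherm_variant')!r}"))
    elif par.get("isotherm_variant") == "hakalahti" and par.get("hakalahti_K_C") is None:
        diags.append(("error", "hakalahti variant requires parameters.hakalahti_K_C (not stated in its source)"))
    return diags


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the summary dict (also written to ``summary.json``).  A stage
    failure aborts with the failing stage named; artifacts written by
    earlier stages are retained.
    """
    errors = [m for lvl, m in validate(config) if lvl == "error"]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(out_dir if out_dir is not None else config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    par = config["parameters"]
    stages = config["stages"]
    summary: dict = {"config_hash": config.digest(), "seed": config.seed, "stages_run": []}

    stage = "ingest"
    try:
        src = config["source"]
        structure = None
        truth = None
        if src["kind"] == "synthetic":
            log.info("stage=%s building synthetic system scale=%s", stage, src["scale"])
            sim_cfg = emulate_paper_system(
                float(src["scale"]),
                n_frames=src["n_frames"],
                seed=config.seed,
                trap=src.get("trap", "hull"),
            )
            sim_cfg.dt = float(par["dt_ps"])
            traj, truth = simulate(sim_cfg)
            structure = getattr(sim_cfg, "structure", None)
            _dump(
                {
                    "D_bulk_nm2_ps": truth.D_bulk,
                    "D_sorbed_nm2_ps": truth.D_sorbed,
                    "expected_sorbed_fraction": truth.expected_sorbed_fraction,
                    "seed": truth.seed,
                    "config": truth.config,
                },
                out / "ground_truth.json",
            )
        else:
            traj = read_frames(src["trajectory"])
        summary["n_frames"] = traj.n_frames
        summary["n_waters"] = int((traj.roles == ROLE_WATER_OXYGEN).sum())
        summary["stages_run"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    labels = None
    if stages["classify"]:
        stage = "classify"
        try:
            log.info("stage=%s frames=0..%d", stage, traj.n_frames - 1)
            labels = geo.label_trajectory(traj, shell_cutoff=float(par["shell_cutoff_nm"]))
            occ = geo.occupancy_series(labels)
            pd.DataFrame(occ).to_csv(out / "occupancy.csv", index=False, float_format="%.6f")
            first = traj.frame(0)
            carbons = select(first, ROLE_FIBRIL_CARBON)
            waters = select(first, ROLE_WATER_OXYGEN)
            k = min(int(par["nn_k"]), len(waters))
            nn_rows = []
            for f in (0, traj.n_frames - 1):
                fr = traj.frame(f)
                nn = geo.mean_nn_distance(
                    select(fr, ROLE_FIBRIL_CARBON), select(fr, ROLE_WATER_OXYGEN), k=k
                )
                nn_rows.append({"time_ps": fr.time, "k": k, "mean_nn_nm": nn.mean_distance})
            pd.DataFrame(nn_rows).to_csv(out / "nn_distance.csv", index=False, float_format="%.6f")
            _dump({"hull_volume_nm3": geo.hull_volume(carbons)}, out / "hull_volume.json")
            summary["mean_sorbed_count"] = float(np.mean(occ["count"]))
            summary["stages_run"].append(stage)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if stages["kinetics"]:
        stage = "kinetics"
        try:
            if labels is None:
                raise RuntimeError("kinetics requires the classify stage")
            log.info("stage=%s", stage)
            lab = np.stack([l.sorbed for l in labels])
            stats = kin.residence_stats(lab, dt=traj.frame_interval or float(par["dt_ps"]))
            runs = stats.all_runs()
            pd.DataFrame({"run_ps": runs}).to_csv(out / "residence_runs.csv", index=False)
            res = {
                "mean_total_ps": stats.mean_total,
                "sd_total_ps": stats.sd_total,
                "fraction_of_simulation": stats.fraction_of_simulation,
                "n_runs": int(len(runs)),
            }
            _dump(res, out / "residence_summary.json")
            summary["residence"] = res
            if structure is not None:
                rep = surface_report(structure)
                sw = kin.swelling(summary["mean_sorbed_count"], M_WATER, rep.dry_mass)
                _dump(
                    {"S_percent": sw.S, "W_t_g": sw.W_t, "W_O_g": sw.W_O},
                    out / "swelling.json",
                )
                summary["swelling_percent"] = sw.S
            counts = np.array([l.n_sorbed for l in labels], dtype=float)
            smooth = kin.moving_average(counts, int(par["moving_average_n"]))
            pd.DataFrame(
                {"time_ps": [l.time for l in labels], "count": counts, "smoothed": smooth}
            ).to_csv(out / "sorbed_count_smoothed.csv", index=False, float_format="%.6f")
            summary["stages_run"].append(stage)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if stages["diffusion"]:
        stage = "diffusion"
        try:
            if labels is None:
                raise RuntimeError("diffusion requires the classify stage")
            log.info("stage=%s", stage)
            steps = dif.partition_steps(traj, labels)
            est: dict = {"step_counts": steps.counts()}
            for phase in dif.PHASES:
                if est["step_counts"][phase] > 0:
                    e = dif.estimate_D(steps, phase)
                    est[phase] = {
                        "D_1e5_cm2_s": e.D,
                        "uncertainty": e.uncertainty,
                        "n_steps": e.n_steps,
                        "t_tot_ps": e.t_tot,
                        "msd_nm2": e.msd,
                    }
            for phase in ("WW", "CC"):
                if est["step_counts"][phase] >= 2:
                    tw = dif.two_interval_D(steps, phase)
                    est[f"two_interval_{phase}"] = {
                        "first": tw.first.D,
                        "second": tw.second.D,
                        "ratio": tw.ratio,
                    }
            if truth is not None:
                est["ground_truth_D_1e5_cm2_s"] = {
                    "WW": truth.D_bulk * 1e3,
                    "CC": truth.D_sorbed * 1e3,
                }
            _dump(est, out / "diffusion.json")
            summary["diffusion"] = {
                p: est[p]["D_1e5_cm2_s"] for p in dif.PHASES if p in est
            }
            tlist = par["temperature_list"]
            if len(tlist) >= 2:
                temps = [float(e["T"]) for e in tlist]
                dvals = [float(e["D"]) for e in tlist]
                fit = dif.temperature_fit(temps, dvals)
                _dump(
                    {
                        "temperatures_C": temps,
                        "D_1e5_cm2_s": dvals,
                        "linear_intercept": fit.intercept,
                        "linear_slope_per_C": fit.slope,
                        "arrhenius_E_A_kJ_mol": fit.E_A,
                        "arrhenius_ln_D0": fit.ln_D0,
                    },
                    out / "temperature_fits.json",
                )
                summary["temperature_fit"] = {"E_A_kJ_mol": fit.E_A, "slope": fit.slope}
            summary["stages_run"].append(stage)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if stages["isotherm"]:
        stage = "isotherm"
        try:
            log.info("stage=%s variant=%s", stage, par["isotherm_variant"])
            grid = np.round(np.arange(0.0, 1.0001, 0.01), 4)
            if par["isotherm_variant"] == "park":
                params = iso.PARK_DEFAULTS
            else:
                params = iso.HakalahtiParams(K_C=float(par["hakalahti_K_C"]))
            table = iso.composite_isotherm(grid, params, par["isotherm_variant"])
            table.to_csv(out / "isotherm.csv", index=False, float_format="%.8g")
            states = {
                "state_A": {
                    "T_C": iso.STATE_A.temperature,
                    "RH_percent": iso.STATE_A.rh,
                    "partial_pressure_kPa": iso.STATE_A.partial_pressure,
                    "absolute_humidity_kg_m3": iso.absolute_humidity(iso.STATE_A),
                },
                "state_B": {
                    "T_C": iso.STATE_B.temperature,
                    "RH_percent": iso.STATE_B.rh,
                    "partial_pressure_kPa": iso.STATE_B.partial_pressure,
                    "absolute_humidity_kg_m3": iso.absolute_humidity(iso.STATE_B),
                },
            }
            _dump(states, out / "humidity_states.json")
            summary["stages_run"].append(stage)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    _dump(summary, out / "summary.json")
    return summary
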