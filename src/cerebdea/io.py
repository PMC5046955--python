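"""Configuration files, result serialisation and figure-style reports.

Configs are YAML with three blocks (``plant``, ``scheme``, ``run``); unknown
keys are rejected so typos fail loudly.  Results are written as columnar
text (tab-separated, header line) plus a key-value metrics file, so every
figure can be regenerated from the files alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .loop import PIDController, SchemeConfig, SimulationResult, TABLE_SCHEMES
from .plant import (
    CreepProcess,
    HammersteinPlant,
    LinearDynamics,
    SplineSNL,
    StaticNonlinearity,
)

__all__ = [
    "PlantConfig",
    "RunConfig",
    "load_config",
    "dump_config",
    "write_result",
    "read_series",
    "report",
]


@dataclass
class PlantConfig:
    """Serialisable Hammerstein-plant parameters.

    By default the static nonlinearity is the calibrated monotone spline;
    setting ``c1`` (and optionally ``c2``) switches to the quadratic family.
    """

    c1: float | None = None
    c2: float = 0.0
    u_max: float | None = None
    tau: float = 0.1
    dt: float = 0.02
    kappa_max: float = 0.12
    tau_c: float = 600.0
    noise_sd: float = 0.02

    def build(self, rng_seed: int = 0) -> HammersteinPlant:
        if self.c1 is not None:
            snl = StaticNonlinearity(self.c1, self.c2, self.u_max or 3.4)
        elif self.u_max is not None:
            snl = SplineSNL(u_max=self.u_max)
        else:
            snl = SplineSNL()
        return HammersteinPlant(
            snl=snl,
            lds=LinearDynamics(self.tau, self.dt),
            creep=CreepProcess(self.kappa_max, self.tau_c),
            noise_sd=self.noise_sd,
            rng_seed=rng_seed,
        )


@dataclass
class RunConfig:
    """Top-level run description: plant + scheme + execution settings."""

    plant: PlantConfig = field(default_factory=PlantConfig)
    scheme: SchemeConfig = field(default_factory=lambda: SchemeConfig.preset("1"))
    seeds: tuple = (0,)
    out_dir: str = "results"


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{where}' block: {sorted(unknown)}")


def _scheme_from_dict(block: dict) -> SchemeConfig:
    block = dict(block)
    scheme_id = str(block.pop("id", block.pop("scheme_id", "1")))
    pid_block = block.pop("pid", None)
    allowed = {f.name for f in dataclasses.fields(SchemeConfig)} - {
        "scheme_id", "pid"
    }
    _check_keys(block, allowed, "scheme")
    for key in ("sigma", "rho", "gains_init", "amp_range"):
        if key in block:
            block[key] = tuple(block[key])
    if "rho" in block and not np.all(np.diff(block["rho"]) > 0):
        raise ValueError(f"scheme.rho must be strictly increasing: {block['rho']}")
    if "sigma" in block and len(block["sigma"]) > 1 and not np.all(
        np.diff(block["sigma"]) > 0
    ):
        raise ValueError(
            f"scheme.sigma must be strictly increasing: {block['sigma']}"
        )
    for key in ("beta", "zeta"):
        if key in block and block[key] < 0:
            raise ValueError(f"scheme.{key} must be >= 0, got {block[key]}")
    cfg = SchemeConfig.preset(scheme_id, **block)
    if pid_block is not None:
        _check_keys(pid_block, {"kp", "ki", "kd", "windup_limit"}, "scheme.pid")
        cfg = dataclasses.replace(cfg, pid=PIDController(**pid_block))
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty or missing ``scheme`` block with only an ``id`` falls back to the
    published defaults for that scheme.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    _check_keys(raw, {"plant", "scheme", "run"}, "top level")
    plant_block = raw.get("plant") or {}
    _check_keys(plant_block, {f.name for f in dataclasses.fields(PlantConfig)},
                "plant")
    plant = PlantConfig(**plant_block)
    if plant.noise_sd < 0 or plant.tau <= 0:
        raise ValueError("plant.noise_sd must be >= 0 and plant.tau > 0")
    scheme = _scheme_from_dict(raw.get("scheme") or {})
    run_block = dict(raw.get("run") or {})
    _check_keys(run_block, {"seeds", "out_dir"}, "run")
    seeds = tuple(int(s) for s in run_block.get("seeds", (0,)))
    return RunConfig(plant=plant, scheme=scheme, seeds=seeds,
                     out_dir=str(run_block.get("out_dir", "results")))


def _config_to_dict(cfg: RunConfig) -> dict:
    scheme = dataclasses.asdict(cfg.scheme)
    scheme["id"] = scheme.pop("scheme_id")
    scheme["pid"] = {k: v for k, v in scheme["pid"].items()
                     if not k.startswith("_")}
    for key in ("sigma", "rho", "gains_init", "amp_range"):
        scheme[key] = list(scheme[key])
    return {
        "plant": dataclasses.asdict(cfg.plant),
        "scheme": scheme,
        "run": {"seeds": list(cfg.seeds), "out_dir": cfg.out_dir},
    }


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(cfg), sort_keys=False))


def write_result(result: SimulationResult, out_dir: str | Path) -> list[Path]:
    """Write a deterministic file set for one run; return the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    series = out / "series.tsv"
    frame = result.to_frame()
    frame.to_csv(series, sep="\t", index=False, float_format="%.9g")
    paths.append(series)

    metrics = out / "metrics.txt"
    lines = [f"{k}: {v}" for k, v in result.summary().items()]
    lines.append(f"cerebdea_version: {__version__}")
    metrics.write_text("\n".join(lines) + "\n")
    paths.append(metrics)

    for name, t_arr, arr in (
        ("weights.tsv", result.weight_t, result.weights),
        ("gains.tsv", result.gain_t, result.gains),
    ):
        p = out / name
        header = "t\t" + "\t".join(f"c{i}" for i in range(arr.shape[1]))
        np.savetxt(p, np.column_stack([t_arr, arr]), delimiter="\t",
                   header=header, comments="", fmt="%.9g")
        paths.append(p)

    cfg_path = out / "config.yaml"
    dump_config(RunConfig(scheme=result.config,
                          seeds=(result.config.seed,),
                          out_dir=str(out)), cfg_path)
    paths.append(cfg_path)
    return paths


def read_series(out_dir: str | Path):
    """Reload the series table written by :func:`write_result`."""
    import pandas as pd

    return pd.read_csv(Path(out_dir) / "series.tsv", sep="\t")


def report(results: list[SimulationResult], out_dir: str | Path,
           snl: StaticNonlinearity | None = None) -> list[Path]:
    """Render the standard comparison figures from in-memory results.

    Produces: learning curves (windowed RMS), cerebellar output over time,
    weight trajectories, and — for runs with a plastic brainstem — the learnt
    recruitment nonlinearity against the inverse of the plant's static
    nonlinearity.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("need at least one result")
    t0 = results[0].t
    for res in results[1:]:
        if len(res.t) != len(t0) or abs(res.t[-1] - t0[-1]) > 1e-9:
            raise ValueError("results have mismatched time bases")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(7, 4))
    for res in results:
        w = res.windowed_rms()
        tw = (np.arange(len(w)) + 0.5) * res.rms_window_s
        ax.plot(tw, w, label=f"scheme {res.config.scheme_id}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("windowed RMS error (mm)")
    ax.legend()
    fig.tight_layout()
    p = out / "learning_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(7, 4))
    for res in results:
        dec = max(1, len(res.t) // 2000)
        ax.plot(res.t[::dec], res.z[::dec],
                label=f"scheme {res.config.scheme_id}", alpha=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cerebellar output z (V)")
    ax.legend()
    fig.tight_layout()
    p = out / "cerebellar_output.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(1, len(results), figsize=(4 * len(results), 3.2),
                             squeeze=False)
    for ax, res in zip(axes[0], results):
        ax.plot(res.weight_t, res.weights, lw=0.7)
        ax.set_title(f"scheme {res.config.scheme_id}")
        ax.set_xlabel("time (s)")
    axes[0][0].set_ylabel("cerebellar weights")
    fig.tight_layout()
    p = out / "weight_trajectories.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    plastic = [res for res in results if res.config.zeta > 0]
    if plastic and snl is not None:
        from .brainstem import BrainstemModel

        fig, ax = plt.subplots(figsize=(5, 4))
        v_grid = np.linspace(0.0, snl.d_max, 200)
        ax.plot(v_grid, [snl.inverse(d) for d in v_grid], "k--",
                label="inverse of plant nonlinearity")
        for res in plastic:
            bs = BrainstemModel(gains=res.gains[-1],
                                rho=np.asarray(res.config.rho))
            ax.plot(v_grid, bs.nonlinearity_curve(v_grid),
                    label=f"learnt (scheme {res.config.scheme_id})")
            bs0 = BrainstemModel(gains=res.gains[0],
                                 rho=np.asarray(res.config.rho))
            ax.plot(v_grid, bs0.nonlinearity_curve(v_grid), ":",
                    label="initial linear approximation")
        ax.set_xlabel("drive v (mm)")
        ax.set_ylabel("command u (V)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = out / "learnt_nonlinearity.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    return paths
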