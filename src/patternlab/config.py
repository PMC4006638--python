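"""Run configuration: TOML schema, validation and the run orchestrator.

A run is fully described by a plain TOML file (model + parameter overrides,
grid, integrator, noise, initial condition, analysis requests); together
with a seed it reproduces bitwise on one platform.  The exact configuration
is echoed into the output directory next to the trajectory.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import tomllib
from pathlib import Path

import numpy as np

from .grid import GridSpec
from .integrators import NoiseSpec, Trajectory, integrate_adaptive, integrate_fixed
from .models.brusselator import (
    BrusselatorParams,
    brusselator_steady_state,
    make_brusselator_rhs,
)
from .models.cortical import (
    CORTICAL_COMPONENTS,
    CorticalParams,
    CorticalState,
    cortical_noise_spec,
    make_cortical_rhs,
)
from .models.vanderpol import VanDerPolParams, make_vdp_rhs
from . import spectral
from .io import save_trajectory, write_json

log = logging.getLogger("patternlab")

_MODELS = ("vanderpol", "brusselator", "cortical")


class ConfigError(ValueError):
    """Raised with every schema violation listed at once."""


def load_config(path) -> dict:
    with open(path, "rb") as f:
        return tomllib.load(f)


def packaged_config(name: str) -> dict:
    """Load one of the example configurations shipped with the package."""
    from importlib.resources import files

    res = files("patternlab.configs") / f"{name}.toml"
    return tomllib.loads(res.read_text())


def _params_for(model: str, overrides: dict):
    cls = {"vanderpol": VanDerPolParams, "brusselator": BrusselatorParams,
           "cortical": CorticalParams}[model]
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(overrides) - known
    if bad:
        raise ConfigError(f"unknown {model} parameters: {sorted(bad)}")
    return cls(**overrides)


def validate(config: dict) -> list[str]:
    """Collect all schema problems; empty list means valid."""
    problems = []
    model = config.get("model", {}).get("name")
    if model not in _MODELS:
        problems.append(f"model.name must be one of {_MODELS}, got {model!r}")
    grid = config.get("grid")
    if model in ("brusselator", "cortical"):
        if not grid:
            problems.append("grid section required for spatial models")
        else:
            try:
                GridSpec(grid.get("ndim", 2), tuple(grid.get("npoints", ())),
                         grid.get("spacing", 0.0))
            except Exception as exc:
                problems.append(f"grid: {exc}")
    integ = config.get("integrator", {})
    kind = integ.get("kind", "fixed")
    if kind not in ("fixed", "adaptive"):
        problems.append(f"integrator.kind must be fixed|adaptive, got {kind!r}")
    if kind == "fixed" and not integ.get("dt", 0) > 0:
        problems.append("integrator.dt must be positive for fixed stepping")
    span = integ.get("t_span")
    if not (isinstance(span, (list, tuple)) and len(span) == 2
            and span[1] > span[0]):
        problems.append("integrator.t_span must be an increasing pair")
    if model == "cortical":
        d2 = config.get("model", {}).get("params", {}).get("D2")
        if d2 is not None and not (0.0 <= d2 <= 2.0):
            problems.append(
                f"cortical D2 = {d2} cm^2 outside the tabulated range [0, 2]"
            )
    try:
        _params_for(model, config.get("model", {}).get("params", {}))
    except ConfigError as exc:
        problems.append(str(exc))
    except Exception as exc:
        problems.append(f"model.params: {exc}")
    return problems


def _cfl_warning(model: str, params, grid: GridSpec, dt: float) -> str | None:
    diff = 0.0
    if model == "brusselator":
        diff = max(params.D_X, params.D_Y)
    elif model == "cortical":
        diff = max(params.D1_eff, params.D2) / min(params.tau_e, params.tau_i)
    if diff > 0 and dt > grid.spacing**2 / (4.0 * diff):
        return (f"dt = {dt} exceeds h^2/(4 D) = "
                f"{grid.spacing**2 / (4 * diff):.3g}; diffusion may be unstable")
    return None


def _build(config: dict, seed: int | None):
    """RHS, initial flat state, noise spec and metadata from a config."""
    model = config["model"]["name"]
    params = _params_for(model, config.get("model", {}).get("params", {}))
    init_cfg = config.get("initial", {})
    noise_cfg = config.get("noise", {})
    rng = np.random.default_rng(seed)

    if model == "vanderpol":
        rhs = make_vdp_rhs(params)
        y0 = np.array(init_cfg.get("state", [2.0, 0.0]), dtype=float)
        return rhs, y0, None, params, None, None

    g = config["grid"]
    grid = GridSpec(g.get("ndim", 2), tuple(g["npoints"]), g["spacing"])
    pert = init_cfg.get("perturbation", 0.0)

    if model == "brusselator":
        rhs = make_brusselator_rhs(params, grid)
        X0, Y0 = brusselator_steady_state(params)
        flat = np.concatenate([
            np.full(grid.nnodes, X0), np.full(grid.nnodes, Y0)
        ])
        if pert:
            flat = flat + pert * rng.standard_normal(flat.shape)
        return rhs, flat, None, params, grid, ("X", "Y")

    # cortical
    if noise_cfg:
        params = dataclasses.replace(
            params,
            noise_mode=noise_cfg.get("mode", params.noise_mode),
            noise_amp=noise_cfg.get("amplitude", params.noise_amp),
        )
    from .linstab import select_branch, steady_states

    states = steady_states("cortical", params)
    branch = init_cfg.get("branch")
    ss = select_branch(states, branch=branch)
    st = CorticalState.homogeneous(grid, params, ss.values["V_e"],
                                   ss.values["V_i"])
    flat = st.flatten()
    if pert:
        layout = st.layout
        for name in ("V_e", "V_i"):
            sl = layout.slice_of(name)
            flat[sl] = flat[sl] + pert * rng.standard_normal(grid.nnodes)
    rhs = make_cortical_rhs(params, grid)
    noise = cortical_noise_spec(params, grid)
    return rhs, flat, noise, params, grid, CORTICAL_COMPONENTS


def _analyse(config: dict, traj: Trajectory, grid: GridSpec | None,
             components, params) -> dict:
    """Run the requested analyses on a finished trajectory."""
    requests = config.get("analysis", {}).get("requests", [])
    if not requests:
        return {}
    out: dict = {}
    model = config["model"]["name"]
    block = grid.nnodes if grid is not None else 1
    # field watched by default: activator X, or excitatory firing rate via V_e
    comp = config.get("analysis", {}).get("component")
    if comp is None:
        comp = "X" if model == "brusselator" else "V_e"
    ci = list(components).index(comp) if components else 0
    fields = traj.states[:, ci * block:(ci + 1) * block]
    settled = spectral.settled(fields)
    last = settled[-1].reshape(grid.shape) if grid is not None else None

    if "spatial_spectrum" in requests and last is not None:
        spec = spectral.spatial_spectrum(last, grid)
        out["spatial_spectrum"] = {
            "dominant_q": spec.dominant,
            "resolution": spec.resolution,
            "peaks": spec.peaks[:5],
        }
    if "angular_modes" in requests and grid is not None and grid.ndim == 2:
        band = config.get("analysis", {}).get("q_band")
        if band is None:
            spec = spectral.spatial_spectrum(last, grid)
            q0 = spec.dominant
            band = [max(q0 - 2 * spec.resolution, spec.resolution),
                    q0 + 2 * spec.resolution]
        out["angular_modes"] = spectral.angular_modes(last, grid, tuple(band))
    probe_series = None
    if grid is not None:
        probe = config.get("analysis", {}).get("probe", [0] * grid.ndim)
        flat_idx = int(np.ravel_multi_index(tuple(probe), grid.shape))
        probe_series = settled[:, flat_idx]
    else:
        probe_series = settled[:, 0]
    dt_saved = float(np.median(np.diff(traj.times)))
    if "temporal_spectrum" in requests and probe_series.size > 8:
        spec = spectral.temporal_spectrum(probe_series, dt_saved)
        out["temporal_spectrum"] = {
            "dominant_hz": spec.dominant,
            "resolution_hz": spec.resolution,
            "peaks": spec.peaks[:5],
        }
    if "beat" in requests and probe_series.size > 8:
        try:
            beat = spectral.beat_frequency(probe_series, dt_saved)
            out["beat"] = dataclasses.asdict(beat)
        except ValueError as exc:
            out["beat"] = {"error": str(exc)}
    if "variance" in requests:
        spatial_var = float(np.var(settled[-1]))
        temporal_var = float(np.mean(np.var(settled[-settled.shape[0] // 3:],
                                            axis=0)))
        out["variance"] = {"spatial": spatial_var, "temporal": temporal_var}
    return out


def run(config: dict, seed: int | None = None, outdir=None) -> dict:
    """Simulate, analyse and (optionally) write an output bundle.

    Returns {"trajectory": Trajectory, "analysis": dict, "files": [...]};
    with ``outdir`` given, writes trajectory.h5, analysis.json, the config
    echo and a log file there.
    """
    problems = validate(config)
    if problems:
        raise ConfigError("; ".join(problems))
    model = config["model"]["name"]
    integ = config.get("integrator", {})
    if seed is None:
        seed = config.get("noise", {}).get("seed", 0)
    rhs, y0, noise, params, grid, components = _build(config, seed)

    t_span = tuple(integ["t_span"])
    t_start = time.perf_counter()
    if integ.get("kind", "fixed") == "adaptive":
        n_dense = integ.get("n_dense", 1001)
        traj = integrate_adaptive(
            rhs, y0, t_span, rtol=integ.get("rtol", 1e-8),
            atol=integ.get("atol", 1e-10),
            dense_times=np.linspace(*t_span, n_dense), noise=noise,
        )
    else:
        dt = integ["dt"]
        if grid is not None:
            warning = _cfl_warning(model, params, grid, dt)
            if warning:
                log.warning(warning)
        traj = integrate_fixed(
            rhs, y0, t_span, dt, scheme=integ.get("scheme", "rk4"),
            noise=noise, seed=seed,
            save_every=integ.get("save_every", 1),
            layout=getattr(rhs, "layout", None),
        )
    wall = time.perf_counter() - t_start
    traj.provenance.update({"model": model, "wall_time_s": wall,
                            "seed": seed})
    analysis = _analyse(config, traj, grid, components, params)

    files = []
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_trajectory(outdir / "trajectory.h5", traj,
                        component_names=components, grid=grid, config=config)
        write_json(outdir / "analysis.json", analysis)
        write_json(outdir / "config_echo.json", config)
        (outdir / "run.log").write_text(
            f"model={model} seed={seed} wall_time_s={wall:.2f} "
            f"n_saved={traj.times.size}\n"
        )
        files = [str(outdir / n) for n in
                 ("trajectory.h5", "analysis.json", "config_echo.json",
                  "run.log")]
    return {"trajectory": traj, "analysis": analysis, "files": files,
            "params": params, "grid": grid, "components": components}
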