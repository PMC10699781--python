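"""Persistence, velocity import/export, configuration and the CLI.

Run archives are single HDF5 files holding the parameter set, scenario,
grid, every snapshot (m, the orientation as both the double-angle pair
and the canonical angle, u, v, p), the scalar summary table and
provenance attributes.  Numeric payloads round-trip bit-exactly.  An
end-marker attribute written last lets a truncated file be detected on
read instead of yielding garbage.

Imported gridded velocities (emulating PIV output) use a plain-text
long-format table with columns ``t, x, y, u, v`` on a regular space-time
grid; ``#`` header lines declare units (``unit_length`` in {m, mm, um},
``unit_time`` in {s, min, h}).  Coordinates are converted to the
importer's target units (default um / min), with the scale factors
applied consistently to positions and velocities.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path

import click
import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import DiskGrid, FieldState, ModelParams, phi_to_double_angle
from .config import default_params, load_defaults
from .lagrangian import (
    VelocitySeries,
    benchmark_flow,
    ftle,
    morphoskeleton,
)
from .mechanics import infer_active_force
from .simulator import SimulationResult, parameter_sweep, run_2d
from .cable_dynamics import uniform_equilibria

__all__ = [
    "SCHEMA_VERSION",
    "write_archive",
    "read_archive",
    "export_snapshot_csv",
    "import_snapshot_csv",
    "write_velocity_series",
    "import_velocity_series",
    "cli",
]

SCHEMA_VERSION = 1

_LENGTH_UNITS = {"m": 1e6, "mm": 1e3, "um": 1.0, "micron": 1.0, "µm": 1.0}
_TIME_UNITS = {"s": 1.0 / 60.0, "sec": 1.0 / 60.0, "min": 1.0, "h": 60.0, "hr": 60.0}


# --------------------------------------------------------------------------
# Run archives (HDF5)
# --------------------------------------------------------------------------

def write_archive(result: SimulationResult, path) -> Path:
    """Serialize a :class:`SimulationResult` to one HDF5 file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["code_version"] = __version__
        f.attrs["scenario_name"] = result.scenario_name
        f.attrs["completed"] = result.completed
        f.attrs["message"] = result.message
        f.attrs["params"] = json.dumps(asdict(result.params))
        gg = f.create_group("grid")
        gg.attrs["nr"] = result.grid.nr
        gg.attrs["ntheta"] = result.grid.ntheta
        gg.attrs["R"] = result.grid.R
        gg.attrs["ap_angle"] = result.grid.ap_angle
        sg = f.create_group("snapshots")
        sg.create_dataset("t", data=result.times)
        for name in ("m", "phi", "u", "v", "p"):
            arrs = [getattr(st, name) for st in result.states]
            if any(a is None for a in arrs):
                continue
            sg.create_dataset(name, data=np.stack(arrs))
        c2, s2 = phi_to_double_angle(np.stack([st.phi for st in result.states]))
        sg.create_dataset("cos2phi", data=c2)
        sg.create_dataset("sin2phi", data=s2)
        tg = f.create_group("summaries")
        for col in result.summaries.columns:
            tg.create_dataset(col, data=result.summaries[col].to_numpy())
        f.attrs["complete_marker"] = True  # written last
    return path


def read_archive(path) -> SimulationResult:
    """Read an archive written by :func:`write_archive`.

    Raises on schema mismatch and on files missing the end marker
    (truncated or interrupted writes).
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"archive schema version {version} != supported {SCHEMA_VERSION}"
            )
        if not bool(f.attrs.get("complete_marker", False)):
            raise ValueError(f"archive {path} is incomplete (missing end marker)")
        params = ModelParams(**json.loads(f.attrs["params"]))
        gg = f["grid"]
        grid = DiskGrid(
            nr=int(gg.attrs["nr"]),
            ntheta=int(gg.attrs["ntheta"]),
            R=float(gg.attrs["R"]),
            ap_angle=float(gg.attrs["ap_angle"]),
        )
        sg = f["snapshots"]
        times = sg["t"][:]
        fields = {
            name: sg[name][:] if name in sg else None
            for name in ("m", "phi", "u", "v", "p")
        }
        states = []
        for i, t in enumerate(times):
            states.append(
                FieldState(
                    grid=grid,
                    t=float(t),
                    m=fields["m"][i],
                    phi=fields["phi"][i],
                    u=None if fields["u"] is None else fields["u"][i],
                    v=None if fields["v"] is None else fields["v"][i],
                    p=None if fields["p"] is None else fields["p"][i],
                )
            )
        summaries = pd.DataFrame({k: f["summaries"][k][:] for k in f["summaries"]})
        return SimulationResult(
            grid=grid,
            params=params,
            times=times,
            states=states,
            summaries=summaries,
            scenario_name=str(f.attrs["scenario_name"]),
            completed=bool(f.attrs["completed"]),
            message=str(f.attrs["message"]),
        )


# --------------------------------------------------------------------------
# CSV snapshot export (single fields)
# --------------------------------------------------------------------------

def export_snapshot_csv(state: FieldState, path) -> Path:
    """Long-format CSV (r, theta, x, y, m, phi, u, v) of one snapshot."""
    grid = state.grid
    r, th = grid.mesh_polar()
    x, y = grid.mesh_xy()
    df = pd.DataFrame(
        {
            "r": r.ravel(),
            "theta": th.ravel(),
            "x": x.ravel(),
            "y": y.ravel(),
            "m": state.m.ravel(),
            "phi": state.phi.ravel(),
        }
    )
    for name in ("u", "v", "p"):
        arr = getattr(state, name)
        if arr is not None:
            df[name] = arr.ravel()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# t: {state.t!r}\n# nr: {grid.nr}\n# ntheta: {grid.ntheta}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def import_snapshot_csv(path, grid: DiskGrid) -> FieldState:
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    shape = grid.shape
    kwargs = {}
    for name in ("u", "v", "p"):
        if name in df:
            kwargs[name] = df[name].to_numpy().reshape(shape)
    return FieldState(
        grid=grid,
        t=float(eval(header.get("t", "0.0"))),  # repr'd float round-trips exactly
        m=df["m"].to_numpy().reshape(shape),
        phi=df["phi"].to_numpy().reshape(shape),
        **kwargs,
    )


# --------------------------------------------------------------------------
# Gridded-velocity (PIV dialect) import / export
# --------------------------------------------------------------------------

def write_velocity_series(
    vseries: VelocitySeries, path, unit_length: str = "um", unit_time: str = "min"
) -> Path:
    """Write the long-format plain-text velocity dialect."""
    path = Path(path)
    nt, ny, nx = vseries.u.shape
    T, Y, X = np.meshgrid(vseries.times, vseries.y, vseries.x, indexing="ij")
    df = pd.DataFrame(
        {
            "t": T.ravel(),
            "x": X.ravel(),
            "y": Y.ravel(),
            "u": vseries.u.ravel(),
            "v": vseries.v.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# unit_length: {unit_length}\n# unit_time: {unit_time}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def import_velocity_series(
    path,
    gap_policy: str = "error",
    target_length: str = "um",
    target_time: str = "min",
    tol: float = 1e-8,
) -> VelocitySeries:
    """Import the plain-text velocity table dialect.

    The table must form a regular (t, y, x) grid.  Missing nodes are
    either an error listing the offending coordinates (``gap_policy =
    "error"``) or filled by per-frame nearest interpolation
    (``"interpolate"``), reported via the returned object's
    ``fill_report`` attribute.  Unit headers are converted to the target
    units; the documented factors are 1 mm = 1000 um and 1 h = 60 min.
    """
    if gap_policy not in ("error", "interpolate"):
        raise ValueError("gap_policy must be 'error' or 'interpolate'")
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    for col in ("t", "x", "y", "u", "v"):
        if col not in df:
            raise ValueError(f"velocity table is missing column {col!r}")
    lu = header.get("unit_length", "um")
    tu = header.get("unit_time", "min")
    if lu not in _LENGTH_UNITS or tu not in _TIME_UNITS:
        raise ValueError(f"unknown units in header: {lu!r}/{tu!r}")
    lscale = _LENGTH_UNITS[lu] / _LENGTH_UNITS[target_length]
    tscale = _TIME_UNITS[tu] / _TIME_UNITS[target_time]
    df = df.assign(
        t=df.t * tscale,
        x=df.x * lscale,
        y=df.y * lscale,
        u=df.u * lscale / tscale,
        v=df.v * lscale / tscale,
    )

    def _axis(vals):
        out = [vals[0]]
        for v in vals[1:]:
            if abs(v - out[-1]) > tol:
                out.append(v)
        return np.asarray(out)

    times = _axis(np.sort(df.t.unique()))
    xs = _axis(np.sort(df.x.unique()))
    ys = _axis(np.sort(df.y.unique()))
    it = np.searchsorted(times, df.t.to_numpy() - tol)
    ix = np.searchsorted(xs, df.x.to_numpy() - tol)
    iy = np.searchsorted(ys, df.y.to_numpy() - tol)
    u = np.full((times.size, ys.size, xs.size), np.nan)
    v = np.full_like(u, np.nan)
    u[it, iy, ix] = df.u.to_numpy()
    v[it, iy, ix] = df.v.to_numpy()
    missing = np.argwhere(np.isnan(u))
    fill_report = []
    if missing.size:
        coords = [
            (float(times[i]), float(xs[k]), float(ys[j])) for i, j, k in missing[:20]
        ]
        if gap_policy == "error":
            raise ValueError(
                f"velocity grid has {len(missing)} missing nodes; first (t, x, y): "
                f"{coords}"
            )
        from scipy.ndimage import distance_transform_edt

        for i in range(times.size):
            bad = np.isnan(u[i])
            if bad.any():
                idx = distance_transform_edt(
                    bad, return_distances=False, return_indices=True
                )
                u[i] = u[i][tuple(idx)]
                v[i] = v[i][tuple(idx)]
        fill_report = coords
    vs = VelocitySeries(times=times, x=xs, y=ys, u=u, v=v)
    vs.fill_report = fill_report
    return vs


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------

def _load_config(config_path) -> dict:
    cfg = load_defaults()
    if config_path:
        with open(config_path) as fh:
            user = yaml.safe_load(fh) or {}
        from .config import merge_config

        cfg = merge_config(cfg, user)
    return cfg


def _params_grid_from_cfg(cfg):
    params = ModelParams(**cfg["params"])
    params_cfg = cfg["params"]
    grid = DiskGrid(
        nr=cfg["grid"]["nr"],
        ntheta=cfg["grid"]["ntheta"],
        R=params_cfg["R"],
        ap_angle=np.deg2rad(cfg["grid"]["ap_angle_deg"]),
    )
    return params, grid


def _open_series(input_path) -> VelocitySeries:
    input_path = str(input_path)
    if input_path.endswith((".h5", ".hdf5")):
        return read_archive(input_path).to_velocity_series()
    return import_velocity_series(input_path)


@click.group()
@click.version_option(version=__version__)
def cli():
    """Mechanochemical gastrulation-flow simulator and morphoskeleton tools."""


@cli.command()
@click.option("--scenario", default="wild_type", show_default=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", required=True, type=click.Path())
@click.option("--t-end", type=float, default=None)
@click.option("--nr", type=int, default=None)
@click.option("--ntheta", type=int, default=None)
def simulate(scenario, config_path, out, t_end, nr, ntheta):
    """Run the 2D model for a named scenario and write an archive."""
    cfg = _load_config(config_path)
    if nr:
        cfg["grid"]["nr"] = nr
    if ntheta:
        cfg["grid"]["ntheta"] = ntheta
    params, grid = _params_grid_from_cfg(cfg)
    known = set(cfg["scenarios"]) | {"custom"}
    if scenario not in known:
        raise click.UsageError(
            f"unknown scenario {scenario!r}; valid options: {sorted(known)}"
        )
    run_cfg = cfg["run"]
    click.echo(
        f"simulate: scenario={scenario} grid={grid.nr}x{grid.ntheta} "
        f"t_end={t_end if t_end is not None else run_cfg['t_end']} "
        f"cfl={run_cfg['cfl']} params={asdict(params)}"
    )
    res = run_2d(
        scenario,
        params,
        grid=grid,
        t_end=t_end,
        cfl=run_cfg["cfl"],
        dt_max=run_cfg["dt_max"],
        output_every=run_cfg["output_every"],
    )
    write_archive(res, out)
    click.echo(f"wrote {out} ({len(res.states)} snapshots, completed={res.completed})")
    if not res.completed:
        sys.exit(1)


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def equilibria(config_path):
    """Print the uniform equilibria of the intensity kinetics."""
    cfg = _load_config(config_path)
    params, _ = _params_grid_from_cfg(cfg)
    eq = uniform_equilibria(params)
    click.echo("root\tstability")
    for r, s in zip(eq.roots, eq.stability):
        click.echo(f"{r:.9g}\t{s}")


@cli.command()
@click.option("--scenario", default="wild_type", show_default=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--param", "sweep_param", required=True)
@click.option("--values", required=True, help="comma-separated list")
@click.option("--out", required=True, type=click.Path())
@click.option("--t-end", type=float, default=None)
def sweep(scenario, config_path, sweep_param, values, out, t_end):
    """One reduced-resolution run per parameter value; writes a CSV table."""
    cfg = _load_config(config_path)
    params, _ = _params_grid_from_cfg(cfg)
    vals = [float(v) for v in values.split(",")]
    table = parameter_sweep(scenario, params, sweep_param, vals, t_end=t_end)
    table.to_csv(out, index=False)
    click.echo(f"wrote {out} ({len(table)} rows)")


@cli.command(name="ftle")
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--t0", type=float, required=True)
@click.option("--tf", required=True, help="final time, or END for the series end")
@click.option("--direction", type=click.Choice(["forward", "backward"]), default="forward")
@click.option("--display", type=click.Choice(["auto", "initial"]), default="auto",
              help="'initial' pulls backward FTLE to initial positions (DOA)")
@click.option("--n-grid", type=int, default=49, show_default=True)
@click.option("--out", required=True, type=click.Path())
def ftle_cmd(input_path, t0, tf, direction, display, n_grid, out):
    """FTLE of an archived run or imported velocity table; writes CSV."""
    vs = _open_series(input_path)
    tf_val = vs.tf if str(tf).upper() == "END" else float(tf)
    lo = max(vs.x[0], vs.y[0])
    hi = min(vs.x[-1], vs.y[-1])
    xs = np.linspace(lo, hi, n_grid)
    if direction == "backward" and display == "initial":
        ms = morphoskeleton(vs, xs, xs, t0, tf_val)
        fld = ms.doa
    else:
        fld = ftle(vs, xs, xs, t0, tf_val, direction)
    X, Y = np.meshgrid(fld.x, fld.y)
    pd.DataFrame(
        {
            "x": X.ravel(),
            "y": Y.ravel(),
            "ftle": fld.values.ravel(),
            "flagged": fld.flags.ravel().astype(int),
        }
    ).to_csv(out, index=False)
    click.echo(
        f"wrote {out} (direction={fld.direction}, display={fld.display}, "
        f"t0={fld.t0}, tf={fld.tf})"
    )


@cli.command(name="morphoskeleton")
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--t0", type=float, required=True)
@click.option("--tf", required=True)
@click.option("--quantile", type=float, default=0.95, show_default=True)
@click.option("--n-grid", type=int, default=49, show_default=True)
@click.option("--out", required=True, type=click.Path())
def morphoskeleton_cmd(input_path, t0, tf, quantile, n_grid, out):
    """Repeller/attractor masks and DOA of a velocity series; writes CSV."""
    vs = _open_series(input_path)
    tf_val = vs.tf if str(tf).upper() == "END" else float(tf)
    lo = max(vs.x[0], vs.y[0])
    hi = min(vs.x[-1], vs.y[-1])
    xs = np.linspace(lo, hi, n_grid)
    ms = morphoskeleton(vs, xs, xs, t0, tf_val, ridge_quantile=quantile)
    X, Y = np.meshgrid(xs, xs)
    pd.DataFrame(
        {
            "x": X.ravel(),
            "y": Y.ravel(),
            "repeller": ms.repeller_mask.ravel().astype(int),
            "attractor": ms.attractor_mask.ravel().astype(int),
            "doa": ms.doa.values.ravel(),
            "forward_ftle": ms.forward.values.ravel(),
            "backward_ftle": ms.backward.values.ravel(),
        }
    ).to_csv(out, index=False)
    click.echo(f"wrote {out}")


@cli.command(name="infer-force")
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--p1", type=float, default=None, help="override viscosity ratio")
@click.option("--smooth-space", type=int, default=1, show_default=True)
@click.option("--smooth-time", type=int, default=1, show_default=True)
@click.option("--out", required=True, type=click.Path())
def infer_force_cmd(input_path, p1, smooth_space, smooth_time, out):
    """Active-force inference from gridded velocities; writes CSV."""
    vs = _open_series(input_path)
    params = default_params() if p1 is None else default_params(p1=p1)
    fa = infer_active_force(vs, params, smooth_space=smooth_space, smooth_time=smooth_time)
    T, Y, X = np.meshgrid(vs.times, vs.y, vs.x, indexing="ij")
    pd.DataFrame(
        {
            "t": T.ravel(),
            "x": X.ravel(),
            "y": Y.ravel(),
            "fax": fa[..., 0].ravel(),
            "fay": fa[..., 1].ravel(),
        }
    ).to_csv(out, index=False)
    click.echo(f"wrote {out}")


@cli.command()
@click.option("--name", required=True)
@click.option("--out", required=True, type=click.Path())
@click.option("--n", type=int, default=64, show_default=True)
@click.option("--extent", type=float, default=2.0, show_default=True)
def benchmark(name, out, n, extent):
    """Write one of the analytic benchmark flows to the velocity dialect."""
    try:
        vs = benchmark_flow(name, extent=extent, n=n)
    except ValueError as exc:
        raise click.UsageError(str(exc))
    write_velocity_series(vs, out)
    click.echo(f"wrote {out}")
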