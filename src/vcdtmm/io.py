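"""Configuration loading and CSV readers/writers.

Canonical on-disk formats (all plain text):

* dispersion CSV: ``wavenumber_cm-1,eps_re,eps_im,kappa_re,kappa_im`` with
  optional ``mu_re,mu_im`` columns, strictly increasing first column;
* spectrum CSV: ``wavenumber_cm-1,T_plus,T_minus,A_plus,A_minus,vcd``;
* map CSV (long format): ``theta_deg,wavenumber_cm-1,vcd_bl,vcd_parallel,
  vcd_full,dev_itf,dev_cpl,masked``.

Output files start with a ``# vcdtmm csv schema=1`` comment line; readers
skip ``#`` comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aperture import ApertureConfig
from .materials import ChiralMaterial, DispersionTable, OscillatorSet, ideal_absorber, vacuum
from .spectra import AngularMap, SpectrumSet
from .tmm import Layer, Stack

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "load_config",
    "read_dispersion_csv",
    "write_dispersion_csv",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_map_csv",
]

SCHEMA_COMMENT = "# vcdtmm csv schema=1"

_DISPERSION_COLS = ["wavenumber_cm-1", "eps_re", "eps_im", "kappa_re", "kappa_im"]
_DISPERSION_MU_COLS = ["mu_re", "mu_im"]
_SPECTRUM_COLS = ["wavenumber_cm-1", "T_plus", "T_minus", "A_plus", "A_minus", "vcd"]
_MAP_COLS = [
    "theta_deg",
    "wavenumber_cm-1",
    "vcd_bl",
    "vcd_parallel",
    "vcd_full",
    "dev_itf",
    "dev_cpl",
    "masked",
]

DEFAULT_GRID = (200.0, 4500.0, 1.0)


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


# ---------------------------------------------------------------------------
# dispersion CSV


def read_dispersion_csv(path) -> DispersionTable:
    """Read a tabulated-dispersion CSV into a :class:`DispersionTable`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dispersion file not found: {path}")
    try:
        # round_trip parsing keeps write-then-read bit-identical
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ConfigError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = list(df.columns)
    has_mu = cols == _DISPERSION_COLS + _DISPERSION_MU_COLS
    if not (cols == _DISPERSION_COLS or has_mu):
        raise ConfigError(
            f"{path}: malformed header {cols}; expected {_DISPERSION_COLS} "
            f"optionally followed by {_DISPERSION_MU_COLS}"
        )
    for col in cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ConfigError(f"{path}: non-numeric cells in column '{col}'")
    if df[cols[0]].isna().any() or df.isna().any().any():
        raise ConfigError(f"{path}: missing/non-numeric cells present")
    nu = df["wavenumber_cm-1"].to_numpy(float)
    if np.any(np.diff(nu) <= 0.0):
        raise ConfigError(f"{path}: wavenumber_cm-1 must be strictly increasing")
    eps = df["eps_re"].to_numpy(float) + 1j * df["eps_im"].to_numpy(float)
    kappa = df["kappa_re"].to_numpy(float) + 1j * df["kappa_im"].to_numpy(float)
    mu = None
    if has_mu:
        mu = df["mu_re"].to_numpy(float) + 1j * df["mu_im"].to_numpy(float)
    try:
        return DispersionTable(nu_grid=nu, eps=eps, kappa=kappa, mu=mu)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _write_csv(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        # shortest-roundtrip formatting: numeric round trips are bit-identical
        df.to_csv(fh, index=False, float_format=lambda x: repr(float(x)))


def write_dispersion_csv(table: DispersionTable, path) -> None:
    data = {
        "wavenumber_cm-1": table.nu_grid,
        "eps_re": table.eps.real,
        "eps_im": table.eps.imag,
        "kappa_re": table.kappa.real,
        "kappa_im": table.kappa.imag,
    }
    if not np.all(table.mu == 1.0):
        data["mu_re"] = table.mu.real
        data["mu_im"] = table.mu.imag
    _write_csv(pd.DataFrame(data), path)


# ---------------------------------------------------------------------------
# spectrum / map CSV


def write_spectrum_csv(spectrum: SpectrumSet, path) -> None:
    _write_csv(
        pd.DataFrame(
            {
                "wavenumber_cm-1": spectrum.nu_grid,
                "T_plus": spectrum.T_plus,
                "T_minus": spectrum.T_minus,
                "A_plus": spectrum.A_plus,
                "A_minus": spectrum.A_minus,
                "vcd": spectrum.vcd,
            }
        ),
        path,
    )


def read_spectrum_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != _SPECTRUM_COLS:
        raise ConfigError(f"{path}: malformed spectrum header {list(df.columns)}")
    return df


def write_map_csv(amap: AngularMap, path) -> None:
    """Long-format (theta, nu) rows of the decomposition map."""
    theta = np.repeat(amap.theta_grid, amap.nu_grid.size)
    nu = np.tile(amap.nu_grid, amap.theta_grid.size)
    _write_csv(
        pd.DataFrame(
            {
                "theta_deg": theta,
                "wavenumber_cm-1": nu,
                "vcd_bl": amap.vcd_bl.ravel(),
                "vcd_parallel": amap.vcd_parallel.ravel(),
                "vcd_full": amap.vcd_full.ravel(),
                "dev_itf": amap.dev_itf.ravel(),
                "dev_cpl": amap.dev_cpl.ravel(),
                "masked": amap.mask.ravel().astype(int),
            }
        ),
        path,
    )


# ---------------------------------------------------------------------------
# simulation config


@dataclass(frozen=True)
class SimulationConfig:
    """Validated end-to-end simulation description."""

    materials: dict[str, ChiralMaterial]
    stack: Stack
    thetas_deg: tuple[float, ...]
    aperture: ApertureConfig | None
    nu_grid: np.ndarray
    outputs: dict[str, str] = field(default_factory=dict)
    seed: int = 0


_PRESETS = {"ideal_absorber": ideal_absorber, "vacuum": vacuum, "air": vacuum}


def _material_from_spec(name: str, spec, base_dir: Path) -> ChiralMaterial:
    key = f"materials.{name}"
    if isinstance(spec, str):
        if spec not in _PRESETS:
            raise ConfigError(f"{key}: unknown preset '{spec}'")
        return _PRESETS[spec]()
    if not isinstance(spec, dict):
        raise ConfigError(f"{key}: expected a preset name or a mapping")
    kinds = [k for k in ("preset", "oscillators", "dispersion_file", "constants") if k in spec]
    if len(kinds) != 1:
        raise ConfigError(
            f"{key}: exactly one of preset/oscillators/dispersion_file/constants required"
        )
    kind = kinds[0]
    if kind == "preset":
        preset = spec["preset"]
        if preset not in _PRESETS:
            raise ConfigError(f"{key}.preset: unknown preset '{preset}'")
        if preset == "ideal_absorber" and "kappa_0" in spec:
            return ideal_absorber(kappa_0=float(spec["kappa_0"]))
        return _PRESETS[preset]()
    if kind == "oscillators":
        block = spec["oscillators"]
        try:
            osc = OscillatorSet(
                eps_inf=float(block["eps_inf"]),
                nu_p=float(block["nu_p"]),
                kappa_0=float(block.get("kappa_0", 0.0)),
                oscillators=tuple(tuple(map(float, row)) for row in block.get("oscillators", [])),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{key}.oscillators: {exc}") from exc
        return ChiralMaterial.from_oscillators(osc, name=name)
    if kind == "dispersion_file":
        fpath = Path(spec["dispersion_file"])
        if not fpath.is_absolute():
            fpath = base_dir / fpath
        table = read_dispersion_csv(fpath)
        return ChiralMaterial.from_table(table, name=name)
    block = spec["constants"]

    def cval(v):
        if isinstance(v, (list, tuple)):
            re, im = v
            return complex(float(re), float(im))
        return complex(float(v), 0.0)

    try:
        return ChiralMaterial.from_constants(
            cval(block.get("eps", 1.0)),
            cval(block.get("mu", 1.0)),
            cval(block.get("kappa", 0.0)),
            name=name,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{key}.constants: {exc}") from exc


def _resolve(materials: dict[str, ChiralMaterial], ref, key: str) -> ChiralMaterial:
    if ref in materials:
        return materials[ref]
    if isinstance(ref, str) and ref in _PRESETS:
        return _PRESETS[ref]()
    raise ConfigError(f"{key}: unresolved material reference '{ref}'")


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML/JSON simulation config.

    Defaults: ambient/exit vacuum, single plane wave at theta = 0, grid
    200-4500 cm^-1 with 1 cm^-1 step.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with path.open() as fh:
        raw = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    materials = {
        str(mname): _material_from_spec(str(mname), mspec, path.parent)
        for mname, mspec in (raw.get("materials") or {}).items()
    }

    stack_block = raw.get("stack")
    if not isinstance(stack_block, dict) or "layers" not in stack_block:
        raise ConfigError("stack.layers: required")
    ambient = _resolve(materials, stack_block.get("ambient", "vacuum"), "stack.ambient")
    exit_m = _resolve(materials, stack_block.get("exit", "vacuum"), "stack.exit")
    layers = []
    for i, lspec in enumerate(stack_block["layers"]):
        lkey = f"stack.layers[{i}]"
        if not isinstance(lspec, dict) or "material" not in lspec:
            raise ConfigError(f"{lkey}.material: required")
        thickness = lspec.get("thickness_um")
        if thickness is None:
            raise ConfigError(f"{lkey}.thickness_um: required")
        thickness = float(thickness)
        if thickness <= 0.0:
            raise ConfigError(f"{lkey}.thickness_um: must be > 0, got {thickness}")
        layers.append(Layer(_resolve(materials, lspec["material"], f"{lkey}.material"), thickness))
    stack = Stack(ambient=ambient, layers=tuple(layers), exit=exit_m)

    grid_block = raw.get("grid") or {}
    start = float(grid_block.get("start", DEFAULT_GRID[0]))
    stop = float(grid_block.get("stop", DEFAULT_GRID[1]))
    step = float(grid_block.get("step", DEFAULT_GRID[2]))
    if step <= 0.0:
        raise ConfigError(f"grid.step: must be > 0, got {step}")
    if not 0.0 < start < stop:
        raise ConfigError(f"grid: need 0 < start < stop, got [{start}, {stop}]")
    nu_grid = np.arange(start, stop + 0.5 * step, step)

    illum = raw.get("illumination") or {}
    aperture_cfg = None
    thetas: tuple[float, ...] = (0.0,)
    if "aperture" in illum:
        ap = illum["aperture"]
        try:
            aperture_cfg = ApertureConfig(
                na_in=float(ap["na_in"]),
                na_out=float(ap["na_out"]),
                n_in=int(ap.get("n_angles", 64)),
                n_out=int(ap.get("n_angles", 64)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"illumination.aperture: {exc}") from exc
    elif "theta_deg" in illum:
        raw_thetas = illum["theta_deg"]
        if np.isscalar(raw_thetas):
            raw_thetas = [raw_thetas]
        thetas = tuple(float(t) for t in raw_thetas)
        for t in thetas:
            if not 0.0 <= t < 90.0:
                raise ConfigError(f"illumination.theta_deg: must be in [0, 90), got {t}")

    return SimulationConfig(
        materials=materials,
        stack=stack,
        thetas_deg=thetas,
        aperture=aperture_cfg,
        nu_grid=nu_grid,
        outputs={str(k): str(v) for k, v in (raw.get("outputs") or {}).items()},
        seed=int(raw.get("seed", 0)),
    )
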