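"""Config parsing, CSV writers and packaged run fixtures.

Configs are plain text, one ``key = value`` per line, ``#`` comments.
Every key has a documented default; unknown keys are an error, not a
warning, so typos cannot silently fall back to defaults.  All interface
units are SI (m, V, S/m); reported fields are kV/cm and power uW/cm^2.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .geometry import ChannelGeometryND, SecondaryCellGeometry
from .kinetics import ButlerVolmerParams, CellKinetics, platinum_water

__all__ = [
    "RunConfig",
    "ConfigError",
    "parse_config",
    "load_config",
    "packaged_config",
    "PACKAGED_CONFIGS",
    "write_sweep_csv",
    "write_profile_csv",
    "run_from_config",
]


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


_DEFAULTS: dict[str, object] = {
    "model": None,  # 'primary' | 'secondary' (required)
    # primary geometry (non-dimensional)
    "G": 1.0,
    "epsilon": 0.1,
    # sweep lists (comma-separated); empty means single solve
    "G_list": "",
    "eps_list": "",
    "sigma_list": "",
    "vapp_list": "",
    # secondary geometry (metres) and physics
    "length_m": 10e-6,
    "insulator_m": 100e-9,
    "height_m": 20e-6,
    "sigma": 0.0005,
    "vapp": 2.7,
    # kinetics overrides (SI units; defaults = packaged platinum/water)
    "i0_anode": 1e-4,
    "i0_cathode": 1e5,
    "alpha_a_anode": 0.5,
    "alpha_c_anode": 0.5,
    "alpha_a_cathode": 0.5,
    "alpha_c_cathode": 0.5,
    "E_eq_anode": 1.23,
    "E_eq_cathode": -0.83,
    "T": 298.0,
    # numerics
    "n_base": 64,
    "grading": 2.0,
    "outer_tol": 1e-6,
    "max_outer": 60,
    # outputs
    "out": "results.csv",
    "profile_out": "",
}

_STR_KEYS = {"model", "out", "profile_out", "G_list", "eps_list", "sigma_list", "vapp_list"}
_INT_KEYS = {"n_base", "max_outer"}


@dataclass(frozen=True)
class RunConfig:
    """A validated run configuration (see ``_DEFAULTS`` for the key set)."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.values[key]

    def float_list(self, key: str) -> list[float]:
        raw = str(self.values[key]).strip()
        return [float(tok) for tok in raw.split(",") if tok.strip()] if raw else []

    def kinetics(self) -> CellKinetics:
        v = self.values
        return CellKinetics(
            anode=ButlerVolmerParams(
                i0=v["i0_anode"], alpha_a=v["alpha_a_anode"],
                alpha_c=v["alpha_c_anode"], E_eq=v["E_eq_anode"], T=v["T"],
            ),
            cathode=ButlerVolmerParams(
                i0=v["i0_cathode"], alpha_a=v["alpha_a_cathode"],
                alpha_c=v["alpha_c_cathode"], E_eq=v["E_eq_cathode"], T=v["T"],
            ),
        )

    def secondary_geometry(self) -> SecondaryCellGeometry:
        v = self.values
        return SecondaryCellGeometry(
            length=v["length_m"], insulator_thickness=v["insulator_m"],
            height=v["height_m"],
        )

    def channel_geometry(self) -> ChannelGeometryND:
        return ChannelGeometryND(G=self.values["G"], epsilon=self.values["epsilon"])


def parse_config(text: str) -> RunConfig:
    values = dict(_DEFAULTS)
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in _DEFAULTS:
            accepted = ", ".join(sorted(_DEFAULTS))
            raise ConfigError(f"unknown key '{key}' (accepted keys: {accepted})")
        if key in _STR_KEYS:
            values[key] = raw
        elif key in _INT_KEYS:
            try:
                values[key] = int(raw)
            except ValueError as exc:
                raise ConfigError(f"key '{key}': expected integer, got {raw!r}") from exc
        else:
            try:
                values[key] = float(raw)
            except ValueError as exc:
                raise ConfigError(f"key '{key}': expected number, got {raw!r}") from exc
    if values["model"] not in ("primary", "secondary"):
        raise ConfigError(
            f"key 'model': expected 'primary' or 'secondary', got {values['model']!r}"
        )
    return RunConfig(values=values)


def load_config(path: str | Path) -> RunConfig:
    return parse_config(Path(path).read_text())


# packaged run fixtures -----------------------------------------------------

PACKAGED_CONFIGS: dict[str, str] = {
    # probe-field sweep over aspect ratio and relative insulator thickness
    "channel_sweep": """
model = primary
G_list = 0.1, 0.5, 1, 2
eps_list = 0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9
n_base = 64
out = channel_sweep.csv
""",
    # centreline field profiles above the insulator, one CSV per conductivity
    "centerline_profiles": """
model = secondary
sigma_list = 0.0005, 0.005, 0.05
vapp = 2.9
n_base = 48
grading = 2.5
out = secondary_results.csv
profile_out = centerline
""",
}


def packaged_config(name: str) -> RunConfig:
    try:
        return parse_config(PACKAGED_CONFIGS[name])
    except KeyError:
        raise ConfigError(
            f"unknown packaged config '{name}' "
            f"(available: {', '.join(sorted(PACKAGED_CONFIGS))})"
        ) from None


# CSV writers ---------------------------------------------------------------


def _write_csv(table: pd.DataFrame, path: str | Path, header_lines: list[str]) -> None:
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty table")
    buf = _io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    table.to_csv(buf, index=False, float_format="%.12g", lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def write_sweep_csv(table: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """RFC-4180 CSV with '#' comment lines carrying parameter provenance;
    12 significant digits, fixed column order."""
    header = [f"{k} = {v}" for k, v in (params or {}).items()]
    _write_csv(table, path, header)


def write_profile_csv(profile: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    header = ["centerline |E| profile above the insulator (y_um, E_kV_cm)"]
    header += [f"{k} = {v}" for k, v in (params or {}).items()]
    _write_csv(profile, path, header)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# run driver ----------------------------------------------------------------


def run_from_config(cfg: RunConfig | str | Path, out_dir: str | Path = ".") -> list[Path]:
    """Execute the solve/sweep a config describes; returns written paths.

    Raises on any non-converged mandatory solve (the CLI converts this into
    a nonzero exit status).
    """
    from .primary import solve_primary, sweep_primary
    from .secondary import (
        SecondaryCellSpec,
        centerline_profile,
        insulator_centre_field,
        solve_secondary,
        sweep_secondary,
    )

    if not isinstance(cfg, RunConfig):
        cfg = load_config(cfg)
    v = cfg.values
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    provenance = {k: v[k] for k in sorted(v) if str(v[k]) != str(_DEFAULTS[k])}
    provenance["model"] = v["model"]

    if v["model"] == "primary":
        G_list = cfg.float_list("G_list") or [v["G"]]
        eps_list = cfg.float_list("eps_list") or [v["epsilon"]]
        table = sweep_primary(
            G_list, eps_list, n_base=v["n_base"], grading=v["grading"]
        )
        if not table["converged"].all():
            raise RuntimeError("primary sweep contains non-converged solves")
        path = out_dir / v["out"]
        write_sweep_csv(table, path, provenance)
        written.append(path)
        return written

    kin = cfg.kinetics()
    geom = cfg.secondary_geometry()
    sigma_list = cfg.float_list("sigma_list") or [v["sigma"]]
    vapp_list = cfg.float_list("vapp_list") or [v["vapp"]]
    rows = []
    for sigma in sigma_list:
        for V in vapp_list:
            spec = SecondaryCellSpec(geometry=geom, kinetics=kin, sigma=sigma, V_app=V)
            sol = solve_secondary(
                spec, n_base=v["n_base"], grading=v["grading"],
                outer_tol=v["outer_tol"], max_outer=v["max_outer"],
            )
            rows.append(
                {
                    "sigma": sigma,
                    "V_app": V,
                    "E_centre_kV_cm": insulator_centre_field(sol),
                    "I_total_A_per_m": sol.I_total,
                    "P_uW_cm2": sol.P,
                    "converged": sol.converged,
                }
            )
            if v["profile_out"]:
                ppath = out_dir / f"{v['profile_out']}_sigma{sigma:g}_V{V:g}.csv"
                write_profile_csv(
                    centerline_profile(sol), ppath,
                    {**provenance, "sigma": sigma, "vapp": V},
                )
                written.append(ppath)
    table = pd.DataFrame(rows)
    path = out_dir / v["out"]
    write_sweep_csv(table, path, provenance)
    written.append(path)
    return written
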