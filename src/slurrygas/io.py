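"""Scenario configuration (YAML), forcing tables (CSV) and trajectory output.

The config dialect is a small versioned YAML document that mirrors the
Scenario dataclass.  Every key is optional: omitted sections inherit from
the shipped ``builtin`` parameter set, so the minimal valid config is
``{version: 1, duration: 365}``.  Unknown keys are rejected (they are the
usual symptom of a units or spelling mistake), and all values are in the
model's native units: kg slurry, g COD, g S, g N, degC, days.  Loading then
dumping then loading reproduces the same scenario.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .kinetics import (
    CardinalParams,
    InhibitionConstants,
    KSTemperatureParams,
    MicrobialGroup,
    qmax_opt_from_linear_rule,
)
from .management import ManagementScheme
from .reactor import InfluentComposition, TransferParams
from .simulator import ForcingSeries, Scenario, SolverSettings, Trajectory
from .stoichiometry import Productivities

__all__ = [
    "CONFIG_VERSION",
    "load_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "dump_scenario",
    "read_forcing_table",
    "write_forcing_table",
    "write_trajectory",
]

CONFIG_VERSION = 1

_TOP_KEYS = {
    "version", "defaults", "duration", "output_dt", "management", "influent",
    "transfer", "hydrolysis", "ks_params", "productivities", "forcings",
    "groups", "include_sulfate_reducer", "solver", "initial_state",
    "n_warmup_cycles",
}
_GROUP_KEYS = {
    "id", "cardinal", "Y", "k_d", "KS_coef", "KS_SO4", "inhibition",
    "C_X_in", "X_init", "is_sulfate_reducer",
}
_FORCING_KEYS = {"kind", "file", "temperature", "pH", "t_end", "times",
                 "slurry_mass", "mean", "amplitude", "period", "base", "low",
                 "t_step", "step_duration", "sd", "seed"}


class ConfigError(ValueError):
    """Raised for schema violations; the message lists every failure."""


def _check_keys(d: dict, allowed: set, where: str, errors: list) -> None:
    for key in d:
        if key not in allowed:
            errors.append(f"{where}: unknown key {key!r} (allowed: {sorted(allowed)})")


def _build(cls, d: dict, where: str, errors: list):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(d, fields, where, errors)
    try:
        return cls(**{k: v for k, v in d.items() if k in fields})
    except (ValueError, TypeError) as exc:
        errors.append(f"{where}: {exc}")
        return None


def _group_from_dict(d: dict, errors: list) -> MicrobialGroup | None:
    where = f"groups[{d.get('id', '?')}]"
    _check_keys(d, _GROUP_KEYS, where, errors)
    d = dict(d)
    card = dict(d.pop("cardinal", {}))
    if "rate_opt" not in card and "T_opt" in card:
        card["rate_opt"] = qmax_opt_from_linear_rule(card["T_opt"])
    cardinal = _build(CardinalParams, card, where + ".cardinal", errors)
    inhib = _build(InhibitionConstants, dict(d.pop("inhibition", {})),
                   where + ".inhibition", errors)
    if cardinal is None or inhib is None:
        return None
    try:
        return MicrobialGroup(cardinal=cardinal, inhibition=inhib, **d)
    except (ValueError, TypeError) as exc:
        errors.append(f"{where}: {exc}")
        return None


def _forcings_from_dict(d: dict, duration: float, base_dir: Path,
                        errors: list) -> ForcingSeries | None:
    _check_keys(d, _FORCING_KEYS, "forcings", errors)
    d = dict(d)
    if "file" in d:
        try:
            return read_forcing_table(base_dir / d["file"])
        except (OSError, ValueError) as exc:
            errors.append(f"forcings.file: {exc}")
            return None
    if "times" in d:
        try:
            return ForcingSeries(
                times=np.asarray(d["times"], dtype=float),
                temperature=np.asarray(d.get("temperature", 20.0), dtype=float),
                pH=np.asarray(d.get("pH", 7.0), dtype=float),
                slurry_mass=(np.asarray(d["slurry_mass"], dtype=float)
                             if "slurry_mass" in d else None),
            )
        except ValueError as exc:
            errors.append(f"forcings: {exc}")
            return None
    from .experiments import make_forcings  # circular-safe: runtime import
    kind = d.pop("kind", "constant")
    seed = d.pop("seed", 0)
    d.setdefault("t_end", duration)
    try:
        return make_forcings(kind, d, seed=seed)
    except (KeyError, ValueError) as exc:
        errors.append(f"forcings: {exc}")
        return None


def scenario_from_dict(cfg: dict, base_dir: Path | str = ".") -> Scenario:
    """Validate a config mapping and build the Scenario (defaults applied)."""
    errors: list[str] = []
    cfg = dict(cfg or {})
    _check_keys(cfg, _TOP_KEYS, "config", errors)
    version = cfg.get("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        errors.append(f"config: unsupported version {version!r}")
    preset = cfg.get("defaults", "builtin")
    if preset != "builtin":
        errors.append(f"config: unknown defaults set {preset!r}")

    duration = float(cfg.get("duration", 365.0))
    management = _build(ManagementScheme, dict(cfg.get("management", {})),
                        "management", errors) or ManagementScheme()
    influent = _build(InfluentComposition, dict(cfg.get("influent", {})),
                      "influent", errors) or defaults.default_influent()
    transfer = _build(TransferParams, dict(cfg.get("transfer", {})),
                      "transfer", errors) or defaults.default_transfer()
    hyd_cfg = dict(cfg.get("hydrolysis", {}))
    if hyd_cfg:
        hydrolysis = _build(CardinalParams, hyd_cfg, "hydrolysis", errors)
    else:
        hydrolysis = defaults.default_hydrolysis()
    ks_cfg = dict(cfg.get("ks_params", {}))
    if ks_cfg:
        ks_params = _build(KSTemperatureParams, ks_cfg, "ks_params", errors)
    else:
        ks_params = defaults.default_ks_params()
    prod_cfg = dict(cfg.get("productivities", {}))
    if prod_cfg:
        productivities = _build(Productivities, prod_cfg, "productivities", errors)
    else:
        productivities = defaults.default_productivity_set()
    solver = _build(SolverSettings, dict(cfg.get("solver", {})), "solver", errors) \
        or SolverSettings()

    if "groups" in cfg:
        groups = [g for g in (_group_from_dict(dict(gd), errors)
                              for gd in cfg["groups"]) if g is not None]
    else:
        groups = defaults.default_methanogens()
    if cfg.get("include_sulfate_reducer", False):
        if not any(g.is_sulfate_reducer for g in groups):
            groups = groups + [defaults.default_sulfate_reducer()]

    forcings = _forcings_from_dict(dict(cfg.get("forcings", {})), duration,
                                   Path(base_dir), errors)
    if forcings is None and not errors:
        forcings = ForcingSeries.constant(20.0, 7.0, duration)

    if errors:
        raise ConfigError("invalid scenario config:\n  " + "\n  ".join(errors))
    return Scenario(
        groups=groups, hydrolysis=hydrolysis, ks_params=ks_params,
        influent=influent, management=management, transfer=transfer,
        productivities=productivities, forcings=forcings, duration=duration,
        output_dt=float(cfg.get("output_dt", 1.0)), solver=solver,
        n_warmup_cycles=int(cfg.get("n_warmup_cycles", 5)),
    )


def load_scenario(path: str | Path) -> Scenario:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return scenario_from_dict(cfg or {}, base_dir=path.parent)


def scenario_to_dict(scen: Scenario) -> dict:
    """Fully resolved config mapping (round-trips through scenario_from_dict)."""
    def _asdict(obj):
        return dataclasses.asdict(obj)

    groups = []
    for g in scen.groups:
        gd = _asdict(g)
        gd["cardinal"] = _asdict(g.cardinal)
        gd["inhibition"] = _asdict(g.inhibition)
        groups.append(gd)
    f = scen.forcings
    forc = {"times": f.times.tolist(), "temperature": f.temperature.tolist(),
            "pH": f.pH.tolist()}
    if f.slurry_mass is not None:
        forc["slurry_mass"] = f.slurry_mass.tolist()
    return {
        "version": CONFIG_VERSION,
        "duration": scen.duration,
        "output_dt": scen.output_dt,
        "n_warmup_cycles": scen.n_warmup_cycles,
        "management": _asdict(scen.management),
        "influent": _asdict(scen.influent),
        "transfer": _asdict(scen.transfer),
        "hydrolysis": _asdict(scen.hydrolysis),
        "ks_params": _asdict(scen.ks_params),
        "productivities": _asdict(scen.productivities),
        "groups": groups,
        "forcings": forc,
        "solver": _asdict(scen.solver),
    }


def dump_scenario(scen: Scenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scen), fh, sort_keys=False)


def read_forcing_table(path: str | Path) -> ForcingSeries:
    """Read a delimited forcing table: time_d, temp_c, [ph], [slurry_mass_kg]."""
    df = pd.read_csv(path)
    missing = {"time_d", "temp_c"} - set(df.columns)
    if missing:
        raise ValueError(f"forcing table missing columns: {sorted(missing)}")
    t = df["time_d"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("forcing table times must be strictly increasing")
    return ForcingSeries(
        times=t,
        temperature=df["temp_c"].to_numpy(dtype=float),
        pH=(df["ph"].to_numpy(dtype=float) if "ph" in df.columns
            else np.full_like(t, 7.0)),
        slurry_mass=(df["slurry_mass_kg"].to_numpy(dtype=float)
                     if "slurry_mass_kg" in df.columns else None),
    )


def write_forcing_table(f: ForcingSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_d": f.times, "temp_c": f.temperature, "ph": f.pH})
    if f.slurry_mass is not None:
        df["slurry_mass_kg"] = f.slurry_mass
    df.to_csv(path, index=False)


def write_trajectory(traj: Trajectory, out_dir: str | Path,
                     scenario: Scenario | None = None) -> dict:
    """Write a trajectory as CSV tables plus a JSON summary.

    Emits ``states.csv`` (daily states and forcings), ``rates.csv``
    (per-process rates), ``events.csv`` (removal log) and ``summary.json``
    (cumulative emissions, audit residual inputs, convergence flags, and —
    when the scenario is supplied — the fully resolved parameter set).
    Returns the summary mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj.states.drop(columns=[c for c in traj.states.columns
                              if c.startswith("_")]).to_csv(out / "states.csv")
    traj.rates.to_csv(out / "rates.csv")
    ev_rows = []
    for e in traj.events:
        row = {"time_d": e.time, "M_m_before": e.M_m_before,
               "M_m_after": e.M_m_after, "f_resid": e.f_resid}
        for pool, mass in e.removed.items():
            if pool == "X":
                row["removed_X_total"] = float(np.sum(mass))
            else:
                row[f"removed_{pool}"] = float(mass)
        ev_rows.append(row)
    pd.DataFrame(ev_rows).to_csv(out / "events.csv", index=False)
    summary = dict(traj.summary)
    summary["audit"] = {
        "initial_cod": traj.initial_cod,
        "cod_inflow_cum": traj.cod_inflow_cum,
        "stored_cod_final": traj.stored_cod_final,
        "cod_removed_cum": traj.cod_removed_cum,
        "cod_respired_cum": traj.cod_respired_cum,
    }
    if scenario is not None:
        summary["scenario"] = scenario_to_dict(scenario)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
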