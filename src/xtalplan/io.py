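"""CSV/JSON readers and writers for the observation and result schemas.

CSV headers carry explicit units (``time_h``, ``length_um``,
``conc0_mg_ml``) so a file can never silently change unit conventions.
Result files embed the package version, the full configuration echo and
the seed, which is sufficient to re-run a deterministic computation
bit-identically.  Metadata on CSV outputs rides in ``#``-prefixed comment
lines that pandas skips on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .errors import ValidationError
from .estimate import GrowthSeries, KineticParameters, NucleationEvents
from .scan import ScanTable
from .simulate import SimulationResult

GROWTH_COLUMNS = ["container_id", "conc0_mg_ml", "time_h", "length_um"]
EVENT_COLUMNS = ["conc0_mg_ml", "volume_ml", "onset_h"]

__all__ = [
    "read_growth_series",
    "write_growth_series",
    "read_nucleation_events",
    "write_nucleation_events",
    "read_params_json",
    "write_params_json",
    "write_simulation_json",
    "write_scan_csv",
    "write_trajectory_csv",
]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    for col in required:
        if col == "container_id":
            continue
        bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value in column '{col}' at row {bad.index[0] + 2}"
            )
        if df[col].isna().any():
            row = int(df[df[col].isna()].index[0]) + 2
            raise ValidationError(f"{path}: missing value in column '{col}' at row {row}")
    return df


def read_growth_series(path: str | Path) -> list[GrowthSeries]:
    """Read growth time courses; one series per container_id, times validated."""
    df = _read_csv(path, GROWTH_COLUMNS)
    out = []
    for cid, grp in df.groupby("container_id", sort=False):
        conc = grp["conc0_mg_ml"].unique()
        if conc.size != 1:
            raise ValidationError(
                f"{path}: container {cid!r} has multiple conc0_mg_ml values {conc}"
            )
        t = grp["time_h"].to_numpy(dtype=float)
        if t.size >= 2 and not (pd.Series(t).diff().dropna() > 0).all():
            raise ValidationError(
                f"{path}: non-monotone time_h for container {cid!r}"
            )
        out.append(
            GrowthSeries(
                container_id=str(cid),
                conc0_mg_ml=float(conc[0]),
                times_h=t,
                lengths_um=grp["length_um"].to_numpy(dtype=float),
            )
        )
    return out


def write_growth_series(series: list[GrowthSeries], path: str | Path, *, seed: int | None = None) -> None:
    rows = []
    for s in series:
        for t, L in zip(s.times_h, s.lengths_um):
            rows.append(
                {"container_id": s.container_id, "conc0_mg_ml": s.conc0_mg_ml,
                 "time_h": t, "length_um": L}
            )
    _write_csv(pd.DataFrame(rows, columns=GROWTH_COLUMNS), path, seed=seed)


def read_nucleation_events(path: str | Path) -> list[NucleationEvents]:
    """Read onset tables; one object per (conc0, volume) container group."""
    df = _read_csv(path, EVENT_COLUMNS)
    out = []
    group_cols = ["conc0_mg_ml", "volume_ml"]
    if "container_id" in df.columns:
        group_cols = ["container_id"] + group_cols
    for key, grp in df.groupby(group_cols, sort=False):
        onset = grp["onset_h"].sort_values().to_numpy(dtype=float)
        out.append(
            NucleationEvents(
                conc0_mg_ml=float(grp["conc0_mg_ml"].iloc[0]),
                container_volume_ml=float(grp["volume_ml"].iloc[0]),
                onset_times_h=onset,
            )
        )
    return out


def write_nucleation_events(
    events: list[NucleationEvents], path: str | Path, *, seed: int | None = None
) -> None:
    rows = []
    for i, e in enumerate(events):
        for t in e.onset_times_h:
            rows.append(
                {"container_id": f"cont{i}", "conc0_mg_ml": e.conc0_mg_ml,
                 "volume_ml": e.container_volume_ml, "onset_h": t}
            )
    _write_csv(
        pd.DataFrame(rows, columns=["container_id"] + EVENT_COLUMNS), path, seed=seed
    )


def _metadata(seed: int | None, config: dict | None = None) -> dict:
    meta: dict[str, Any] = {"package": "xtalplan", "version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config"] = config
    return meta


def _write_csv(df: pd.DataFrame, path: str | Path, *, seed: int | None = None,
               config: dict | None = None) -> None:
    header = "".join(
        f"# {k}: {json.dumps(v, sort_keys=True)}\n"
        for k, v in _metadata(seed, config).items()
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def write_params_json(
    params: KineticParameters, path: str | Path, *, seed: int | None = None
) -> None:
    payload = {"metadata": _metadata(seed), "params": params.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_params_json(path: str | Path) -> KineticParameters:
    payload = json.loads(Path(path).read_text())
    d = payload.get("params", payload)
    try:
        return KineticParameters.from_dict(d)
    except KeyError as exc:
        raise ValidationError(f"{path}: missing parameter field {exc}") from exc


def write_simulation_json(result: SimulationResult, path: str | Path) -> None:
    payload = {
        "metadata": _metadata(result.config.seed, result.config.to_dict()),
        "result": result.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_trajectory_csv(result: SimulationResult, path: str | Path) -> None:
    _write_csv(
        result.trajectory, path,
        seed=result.config.seed, config=result.config.to_dict(),
    )


def write_scan_csv(table: ScanTable, path: str | Path) -> None:
    req = table.request
    config = {
        "conc_grid_mg_ml": list(req.conc_grid_mg_ml),
        "volume_grid_ul": list(req.volume_grid_ul),
        "target_edge_mm": req.target_edge_mm,
        "mode": req.mode,
        "dt_h": req.dt_h,
        "t_max_h": req.t_max_h,
        "c_s_g_ml": req.c_s_g_ml,
    }
    _write_csv(table.frame, path, seed=req.seed, config=config)
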