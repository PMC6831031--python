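"""File formats: CSV dialects for the four data streams, JSON results, YAML config.

Dialects (headers are fixed):

* lane profiles      ``base_index,intensity``            (+ YAML manifest)
* band time courses  ``time_min,Is,Id,row_type``         (row_type: data|boiled)
* titrations         ``conc_nM,anisotropy``
* stopped-flow       ``time_s,signal,segment``           (+ ``# key: value`` header block)

Simulated datasets round-trip through these writers/readers together with a
JSON ground-truth sidecar.  Malformed rows are reported with their file
line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .binding import TitrationSeries
from .fluorescence import ConditionDescriptor, FluorTrace, LabelSite, SubstrateClass
from .footprint import LaneProfile
from .simulate import TruthRecord
from .unwinding import BandTimeCourse


class SchemaError(ValueError):
    """A file does not match its documented dialect."""


def _read_csv(path: str | Path, expected_cols: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in expected_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def _check_numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.index[values.isna()]
    if len(bad):
        # +2: header line plus 1-based counting
        raise SchemaError(f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}")
    return values.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# lane profiles
# ---------------------------------------------------------------------------

def write_profile(path: str | Path, lane: LaneProfile) -> None:
    df = pd.DataFrame(
        {"base_index": np.arange(1, len(lane) + 1), "intensity": lane.intensities}
    )
    df.to_csv(path, index=False)


def read_profile(
    path: str | Path, substrate: str = "unknown", replicate: str = "r1",
    is_control: bool = False,
) -> LaneProfile:
    path = Path(path)
    df = _read_csv(path, ["base_index", "intensity"])
    base = _check_numeric(df, "base_index", path).astype(int)
    intensity = _check_numeric(df, "intensity", path)
    if not np.array_equal(base, np.arange(1, base.size + 1)):
        raise SchemaError(f"{path}: base_index must run 1..N contiguously")
    return LaneProfile(
        substrate=substrate, replicate=replicate, intensities=intensity,
        is_control=is_control,
    )


def write_lane_manifest(
    path: str | Path, substrate: str, control: str, replicates: Sequence[str]
) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"substrate": substrate, "control": control, "replicates": list(replicates)},
            fh,
        )


def read_lane_manifest(path: str | Path) -> tuple[list[LaneProfile], LaneProfile]:
    """Load a replicate lane set and its control via a YAML manifest."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: manifest not found")
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    for key in ("substrate", "control", "replicates"):
        if key not in spec:
            raise SchemaError(f"{path}: manifest missing required key {key!r}")
    base = path.parent
    substrate = spec["substrate"]
    control = read_profile(
        base / spec["control"], substrate=substrate, replicate="control", is_control=True
    )
    lanes = [
        read_profile(base / rel, substrate=substrate, replicate=f"rep{i + 1}")
        for i, rel in enumerate(spec["replicates"])
    ]
    if not lanes:
        raise SchemaError(f"{path}: manifest lists no replicate lanes")
    return lanes, control


# ---------------------------------------------------------------------------
# band time courses
# ---------------------------------------------------------------------------

def write_timecourse(path: str | Path, tc: BandTimeCourse) -> None:
    rows = pd.DataFrame(
        {
            "time_min": np.append(tc.times, np.nan),
            "Is": np.append(tc.i_ss, tc.i_ss_boiled),
            "Id": np.append(tc.i_ds, tc.i_ds_boiled),
            "row_type": ["data"] * tc.times.size + ["boiled"],
        }
    )
    rows.to_csv(path, index=False)


def read_timecourse(path: str | Path, substrate: str = "unknown") -> BandTimeCourse:
    path = Path(path)
    df = _read_csv(path, ["time_min", "Is", "Id", "row_type"])
    boiled = df[df["row_type"] == "boiled"]
    data = df[df["row_type"] == "data"]
    if boiled.empty:
        raise SchemaError(f"{path}: missing boiled-control row (row_type == 'boiled')")
    if data.empty:
        raise SchemaError(f"{path}: no data rows")
    times = _check_numeric(data, "time_min", path)
    if times.size == 0 or times[0] != 0.0:
        raise SchemaError(f"{path}: missing zero-time row (first data row must have time_min=0)")
    return BandTimeCourse(
        substrate=substrate,
        times=times,
        i_ss=_check_numeric(data, "Is", path),
        i_ds=_check_numeric(data, "Id", path),
        i_ss_boiled=float(boiled["Is"].iloc[0]),
        i_ds_boiled=float(boiled["Id"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def write_titration(path: str | Path, series: TitrationSeries) -> None:
    pd.DataFrame(
        {"conc_nM": series.concentrations, "anisotropy": series.anisotropy}
    ).to_csv(path, index=False)


def read_titration(path: str | Path) -> TitrationSeries:
    path = Path(path)
    df = _read_csv(path, ["conc_nM", "anisotropy"])
    return TitrationSeries(
        concentrations=_check_numeric(df, "conc_nM", path),
        anisotropy=_check_numeric(df, "anisotropy", path),
    )


# ---------------------------------------------------------------------------
# stopped-flow traces
# ---------------------------------------------------------------------------

def write_trace(path: str | Path, trace: FluorTrace) -> None:
    with open(path, "w") as fh:
        if trace.condition is not None:
            cond = trace.condition
            fh.write(f"# label_site: {cond.label_site.value}\n")
            fh.write(f"# block: {cond.block}\n")
            fh.write(f"# substrate_class: {cond.substrate_class.value}\n")
            fh.write(f"# atp: {cond.atp}\n")
        pd.DataFrame(
            {"time_s": trace.time, "signal": trace.signal, "segment": trace.segment}
        ).to_csv(fh, index=False)


def _parse_condition_header(path: Path) -> Optional[ConditionDescriptor]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
    if not meta:
        return None
    try:
        return ConditionDescriptor(
            label_site=LabelSite(meta["label_site"]),
            block=meta["block"] == "True",
            substrate_class=SubstrateClass(meta["substrate_class"]),
            atp=meta.get("atp", "True") == "True",
        )
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed condition header block ({exc})") from exc


def read_trace(path: str | Path) -> FluorTrace:
    path = Path(path)
    condition = _parse_condition_header(path)
    df = _read_csv(path, ["time_s", "signal", "segment"])
    t = _check_numeric(df, "time_s", path)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0))
        raise SchemaError(f"{path}: non-monotone time_s near line {bad + 3}")
    return FluorTrace(
        time=t,
        signal=_check_numeric(df, "signal", path),
        segment=_check_numeric(df, "segment", path).astype(int),
        condition=condition,
    )


# ---------------------------------------------------------------------------
# truth sidecars, results, config
# ---------------------------------------------------------------------------

def write_truth(path: str | Path, truth: TruthRecord) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)


def read_truth(path: str | Path) -> TruthRecord:
    with open(path) as fh:
        return TruthRecord.from_dict(json.load(fh))


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


_CONFIG_KEYS = {
    "substrate", "regions", "population", "noise", "seed", "fit", "output_dir",
    "truth_direction", "kinetics",
}


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration, rejecting unknown top-level keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return cfg
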