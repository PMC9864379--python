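"""CSV readers/writers for the three tabular input dialects.

All files are comma-separated UTF-8 with a header row. Parsing is strict:
missing required columns and non-numeric cells are hard errors, never
silently defaulted, and every downstream stage consumes only the validated
typed objects produced here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .correct import TitrationPoint, TitrationSeries
from .dsc import Thermogram, ThermogramError
from .relax import RelaxationDataset, RelaxationRecord


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


#: required columns per dialect
TITRATION_COLUMNS = ("peak_id", "dmso_vv_percent", "delay_ms", "volume_raw",
                     "solution_volume_uL")
RELAXATION_COLUMNS = ("residue", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err")
THERMOGRAM_COLUMNS = ("temperature_C", "cp")


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in required:
        if col == "peak_id":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0] + 2}"
            )
        df[col] = coerced
    return df


def read_titration_table(
    path: str | Path, t1_ms: float = 5.5, t2_ms: float = 11.0
) -> list[TitrationSeries]:
    """Read a long-format dual-delay titration CSV into per-peak series.

    Each (peak_id, dmso_vv_percent) condition must appear with exactly the
    two delays t1_ms and t2_ms; duplicated (peak_id, dmso, delay) rows are
    an error. Points are sorted by ascending DMSO within each series.
    """
    df = _read_csv(path, TITRATION_COLUMNS)
    dup_mask = df.duplicated(["peak_id", "dmso_vv_percent", "delay_ms"], keep=False)
    if dup_mask.any():
        dups = (df.loc[dup_mask, ["peak_id", "dmso_vv_percent", "delay_ms"]]
                .drop_duplicates().to_dict("records"))
        raise SchemaError(f"{path}: duplicated (peak_id, dmso, delay) rows: {dups}")

    series: list[TitrationSeries] = []
    for pid, g in df.groupby("peak_id", sort=True):
        points = []
        for vv, gg in g.groupby("dmso_vv_percent", sort=True):
            by_delay = {float(r.delay_ms): r for r in gg.itertuples()}
            if not {t1_ms, t2_ms} <= set(by_delay):
                raise SchemaError(
                    f"{path}: peak {pid!r} at {vv} v/v% lacks both delays "
                    f"({t1_ms}, {t2_ms} ms); found {sorted(by_delay)}"
                )
            r1, r2 = by_delay[t1_ms], by_delay[t2_ms]
            pulse = getattr(r1, "pulse_scale", 1.0)
            if pulse is None or (isinstance(pulse, float) and np.isnan(pulse)):
                pulse = 1.0
            points.append(TitrationPoint(
                dmso_vv_percent=float(vv),
                volume_short=float(r1.volume_raw),
                volume_long=float(r2.volume_raw),
                solution_volume=float(r1.solution_volume_uL),
                pulse_scale=float(pulse),
            ))
        series.append(TitrationSeries(str(pid), points, t1_ms, t2_ms))
    return series


def write_titration_table(series: list[TitrationSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for p in s.points:
            for delay, vol in ((s.t1_ms, p.volume_short), (s.t2_ms, p.volume_long)):
                rows.append({
                    "peak_id": s.peak_id,
                    "dmso_vv_percent": p.dmso_vv_percent,
                    "delay_ms": delay,
                    "volume_raw": vol,
                    "solution_volume_uL": p.solution_volume,
                    "pulse_scale": p.pulse_scale,
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_corrected_table(series: list[TitrationSeries], path: str | Path) -> None:
    """Corrected titration output: adds i0_extrap, t2_apparent_ms, i_rel."""
    rows = []
    for s in series:
        for p in s.points:
            rows.append({
                "peak_id": s.peak_id,
                "dmso_vv_percent": p.dmso_vv_percent,
                "dmso_molar": p.dmso_molar,
                "solution_volume_uL": p.solution_volume,
                "i0_extrap": p.i0_extrap,
                "t2_apparent_ms": p.t2_apparent_ms,
                "i_rel": p.i_rel,
                "censored": p.censored,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_corrected_table(path: str | Path) -> list[TitrationSeries]:
    df = _read_csv(path, ("peak_id", "dmso_vv_percent", "i_rel"))
    series = []
    for pid, g in df.groupby("peak_id", sort=True):
        points = []
        for r in g.itertuples():
            censored = bool(getattr(r, "censored", False))
            p = TitrationPoint(
                dmso_vv_percent=float(r.dmso_vv_percent),
                volume_short=1.0, volume_long=0.5,
                solution_volume=float(getattr(r, "solution_volume_uL", 1.0) or 1.0),
                dmso_molar=(float(r.dmso_molar)
                            if hasattr(r, "dmso_molar") and pd.notna(r.dmso_molar)
                            else None),
            )
            p.censored = censored
            p.i_rel = None if censored or pd.isna(r.i_rel) else float(r.i_rel)
            points.append(p)
        series.append(TitrationSeries(str(pid), points))
    return series


def read_relaxation_table(path: str | Path, field_15N_MHz: float) -> RelaxationDataset:
    """Read per-residue R1/R2/NOE rates; positivity is enforced per record."""
    df = _read_csv(path, RELAXATION_COLUMNS)
    records = [
        RelaxationRecord(int(r.residue), float(r.R1), float(r.R1_err),
                         float(r.R2), float(r.R2_err),
                         float(r.NOE), float(r.NOE_err))
        for r in df.itertuples()
    ]
    return RelaxationDataset(records, field_15N_MHz)


def write_relaxation_table(dataset: RelaxationDataset, path: str | Path) -> None:
    rows = [{
        "residue": r.residue, "R1": r.R1, "R1_err": r.R1_err,
        "R2": r.R2, "R2_err": r.R2_err, "NOE": r.NOE, "NOE_err": r.NOE_err,
    } for r in dataset.records]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_thermogram(path: str | Path, dmso_vv_percent: float = 0.0) -> Thermogram:
    """Read a Cp(T) trace; two-column, or three-column with a reference trace.

    The optional third column ``cp_reference`` is subtracted downstream by
    excess_heat_capacity; here it is preserved on the returned object as
    ``reference_cp``.
    """
    df = _read_csv(path, THERMOGRAM_COLUMNS)
    temps = df["temperature_C"].to_numpy()
    dT = np.diff(temps)
    bad = np.flatnonzero(dT <= 0)
    if bad.size:
        raise ThermogramError(
            f"{path}: temperature not strictly increasing at index {int(bad[0]) + 1}"
        )
    tg = Thermogram(temps, df["cp"].to_numpy(), dmso_vv_percent)
    if "cp_reference" in df.columns:
        tg.reference_cp = df["cp_reference"].to_numpy()  # type: ignore[attr-defined]
    return tg


def write_thermogram(tg: Thermogram, path: str | Path,
                     reference: Thermogram | None = None) -> None:
    data = {"temperature_C": tg.temperature_C, "cp": tg.cp}
    if reference is not None:
        data["cp_reference"] = reference.cp
    pd.DataFrame(data).to_csv(path, index=False)


def read_restraint_pairs(path: str | Path) -> list[tuple[int, int]]:
    """Two-column CSV of residue-index pairs (residue_i, residue_j)."""
    df = _read_csv(path, ("residue_i", "residue_j"))
    return [(int(r.residue_i), int(r.residue_j)) for r in df.itertuples()]
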