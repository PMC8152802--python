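"""CSV readers/writers and JSON result serialisation.

File layout (UTF-8, comma-separated, header row, ISO 8601 dates):

``eggs.csv``::

    egg_id,site_id,trap_id,collection_date,status,
    length_rep1_um,length_rep2_um,length_rep3_um,
    width_rep1_um,width_rep2_um,width_rep3_um

Morphometry columns may be empty (all six at once).  ``meteo.csv``::

    date,tmin_C,tmax_C,sunshine_min,rainfall_mm

Readers validate every row; offending rows are reported with their file
row number rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .core import EggRecord, EggStatus, MeteoDay, ValidationError

__all__ = [
    "EGG_COLUMNS",
    "METEO_COLUMNS",
    "SchemaError",
    "RowError",
    "RowErrorGroup",
    "read_eggs",
    "write_eggs",
    "read_meteo",
    "write_meteo",
    "write_summary",
]

EGG_COLUMNS = [
    "egg_id",
    "site_id",
    "trap_id",
    "collection_date",
    "status",
    "length_rep1_um",
    "length_rep2_um",
    "length_rep3_um",
    "width_rep1_um",
    "width_rep2_um",
    "width_rep3_um",
]

METEO_COLUMNS = ["date", "tmin_C", "tmax_C", "sunshine_min", "rainfall_mm"]


class SchemaError(ValueError):
    """The file header does not provide the mandatory columns."""


@dataclasses.dataclass(frozen=True)
class RowError:
    row: int  # 1-based data row number (header = row 0)
    egg_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row} (egg_id={self.egg_id!r}): {self.message}"


class RowErrorGroup(ValueError):
    def __init__(self, errors: Sequence[RowError]):
        self.errors = list(errors)
        super().__init__(
            f"{len(self.errors)} invalid row(s): "
            + "; ".join(str(e) for e in self.errors[:10])
        )


def _parse_reps(row: Mapping[str, Any], prefix: str) -> tuple[float, ...]:
    vals = []
    for i in (1, 2, 3):
        v = row.get(f"{prefix}_rep{i}_um")
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            vals.append(None)
        else:
            vals.append(float(v))
    present = [v for v in vals if v is not None]
    if not present:
        return ()
    if len(present) != 3:
        raise ValidationError(f"{prefix} reps incomplete: {vals}")
    return tuple(present)


def read_eggs(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    errors: str = "raise",
) -> list[EggRecord] | tuple[list[EggRecord], list[RowError]]:
    """Read per-egg records from CSV.

    ``schema`` optionally maps canonical column names to the names used in
    the file.  With ``errors="raise"`` (default) any invalid row aborts the
    read with a :class:`RowErrorGroup` listing every offending row; with
    ``errors="collect"`` the valid records and the error list are returned
    as a pair.
    """
    df = pd.read_csv(path, dtype=str)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in EGG_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    for c in EGG_COLUMNS[5:]:
        if c not in df.columns:
            df[c] = None

    records: list[EggRecord] = []
    row_errors: list[RowError] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        egg_id = str(row.get("egg_id", ""))
        try:
            date = dt.date.fromisoformat(str(row["collection_date"]))
        except (TypeError, ValueError):
            row_errors.append(
                RowError(i, egg_id, f"unparseable date {row['collection_date']!r}")
            )
            continue
        try:
            status = EggStatus(str(row["status"]))
        except ValueError:
            row_errors.append(RowError(i, egg_id, f"unknown status {row['status']!r}"))
            continue
        try:
            rec = EggRecord(
                egg_id=egg_id,
                site_id=str(row["site_id"]),
                trap_id=str(row["trap_id"]),
                collection_date=date,
                status=status,
                length_reps_um=_parse_reps(row, "length"),
                width_reps_um=_parse_reps(row, "width"),
            )
        except (ValidationError, ValueError) as exc:
            row_errors.append(RowError(i, egg_id, str(exc)))
            continue
        records.append(rec)

    if errors == "collect":
        return records, row_errors
    if row_errors:
        raise RowErrorGroup(row_errors)
    return records


def write_eggs(records: Iterable[EggRecord], path: str | Path) -> None:
    """Write records as CSV with a deterministic column order (round-trips)."""
    rows = []
    for r in records:
        reps_l = list(r.length_reps_um) + [None] * (3 - len(r.length_reps_um))
        reps_w = list(r.width_reps_um) + [None] * (3 - len(r.width_reps_um))
        rows.append(
            {
                "egg_id": r.egg_id,
                "site_id": r.site_id,
                "trap_id": r.trap_id,
                "collection_date": r.collection_date.isoformat(),
                "status": r.status.value,
                "length_rep1_um": reps_l[0],
                "length_rep2_um": reps_l[1],
                "length_rep3_um": reps_l[2],
                "width_rep1_um": reps_w[0],
                "width_rep2_um": reps_w[1],
                "width_rep3_um": reps_w[2],
            }
        )
    df = pd.DataFrame(rows, columns=EGG_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def read_meteo(path: str | Path) -> list[MeteoDay]:
    df = pd.read_csv(path)
    missing = [c for c in METEO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    out = []
    for row in df.to_dict("records"):
        out.append(
            MeteoDay(
                date=dt.date.fromisoformat(str(row["date"])),
                tmin_C=float(row["tmin_C"]),
                tmax_C=float(row["tmax_C"]),
                sunshine_min=float(row["sunshine_min"]),
                rainfall_mm=float(row["rainfall_mm"]),
            )
        )
    return out


def write_meteo(days: Iterable[MeteoDay], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "date": d.date.isoformat(),
                "tmin_C": d.tmin_C,
                "tmax_C": d.tmax_C,
                "sunshine_min": d.sunshine_min,
                "rainfall_mm": d.rainfall_mm,
            }
            for d in days
        ],
        columns=METEO_COLUMNS,
    )
    df.to_csv(path, index=False, lineterminator="\n")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dt.date):
        return obj.isoformat()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    if isinstance(obj, float) and obj != obj:  # NaN
        return None
    return obj


def write_summary(result: Any, path: str | Path) -> None:
    """Serialise any result object (dataclass, mapping, sequence) as JSON."""
    Path(path).write_text(json.dumps(_jsonable(result), indent=2, sort_keys=True) + "\n")
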