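"""Reading and writing plate-reader tables.

The canonical on-disk layout is a long CSV: one row per well per timepoint,
with columns ``plate_id, well, strain_id, role, condition, time_h, od_raw,
f390, f470``.  ``od_raw`` is the uncorrected OD600 reading; ``f390``/``f470``
are raw fluorescence intensities at 390 nm and 470 nm excitation (512 nm
emission).  A wide dialect (one column per timepoint, one row per
well x channel) is accepted as a convenience and converted to the same
in-memory structure.

Background subtraction and OD linearisation are *not* performed here; they
belong to :mod:`phscreen.calibration` and :mod:`phscreen.growth`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

WELL_RE = re.compile(r"^[A-P](0[1-9]|1[0-9]|2[0-4])$")
ROLES = frozenset({"wild_type", "mutant", "blank", "slow_grower"})

LONG_COLUMNS = [
    "plate_id", "well", "strain_id", "role", "condition",
    "time_h", "od_raw", "f390", "f470",
]
CHANNELS = ["od_raw", "f390", "f470"]


@dataclass(frozen=True)
class WellRecord:
    """Static metadata of one microplate well."""

    plate_id: str
    well: str
    strain_id: str | None
    role: str
    condition: str

    def __post_init__(self) -> None:
        if not WELL_RE.match(self.well):
            raise ValidationError(f"malformed well id {self.well!r}")
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown role {self.role!r} for well {self.well}; "
                f"expected one of {sorted(ROLES)}"
            )
        if self.role == "blank" and self.strain_id:
            raise ValidationError(
                f"blank well {self.well} must not carry a strain_id"
            )


@dataclass
class PlateTimeCourse:
    """Per-well OD and two-channel fluorescence series on a shared time grid.

    ``od_raw``, ``f390`` and ``f470`` are ``(n_wells, n_times)`` arrays whose
    row order follows ``wells``.  NaN marks explicitly masked readings.
    """

    plate_id: str
    condition: str
    wells: list[WellRecord]
    times: np.ndarray
    od_raw: np.ndarray
    f390: np.ndarray
    f470: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError("times must be one-dimensional")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"plate {self.plate_id}: times must be strictly increasing"
            )
        shape = (len(self.wells), len(self.times))
        for name in CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValidationError(
                    f"plate {self.plate_id}: {name} has shape {arr.shape}, "
                    f"expected {shape}"
                )
            setattr(self, name, arr)

    @property
    def well_ids(self) -> list[str]:
        return [w.well for w in self.wells]

    def role_mask(self, role: str) -> np.ndarray:
        return np.array([w.role == role for w in self.wells], dtype=bool)

    def well_index(self, well: str) -> int:
        return self.well_ids.index(well)

    def to_long_frame(self) -> pd.DataFrame:
        """Export as the canonical long table (one row per well x timepoint)."""
        n_t = len(self.times)
        frames = []
        for i, w in enumerate(self.wells):
            frames.append(pd.DataFrame({
                "plate_id": w.plate_id,
                "well": w.well,
                "strain_id": w.strain_id if w.strain_id is not None else "",
                "role": w.role,
                "condition": w.condition,
                "time_h": self.times,
                "od_raw": self.od_raw[i],
                "f390": self.f390[i],
                "f470": self.f470[i],
            }))
        out = pd.concat(frames, ignore_index=True)
        return out[LONG_COLUMNS]


def _require_columns(df: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def _plates_from_long(df: pd.DataFrame) -> list[PlateTimeCourse]:
    dup = df.duplicated(subset=["plate_id", "condition", "well", "time_h"])
    if dup.any():
        rows = df.loc[dup, ["plate_id", "well", "time_h"]].head(3)
        raise ValidationError(
            "duplicate (plate, condition, well, time) rows, e.g.\n"
            f"{rows.to_string(index=False)}"
        )
    plates = []
    for (plate_id, condition), grp in df.groupby(
        ["plate_id", "condition"], sort=True
    ):
        times = np.sort(grp["time_h"].unique().astype(float))
        wells = []
        mats = {c: [] for c in CHANNELS}
        pivots = {
            c: grp.pivot(index="well", columns="time_h", values=c)
            .reindex(columns=times)
            for c in CHANNELS
        }
        for well in sorted(grp["well"].unique()):
            meta = grp[grp["well"] == well].iloc[0]
            strain = meta["strain_id"]
            if pd.isna(strain) or str(strain) == "":
                strain = None
            else:
                strain = str(strain)
            wells.append(WellRecord(
                plate_id=str(plate_id), well=str(well), strain_id=strain,
                role=str(meta["role"]), condition=str(condition),
            ))
            for c in CHANNELS:
                mats[c].append(pivots[c].loc[well].to_numpy(dtype=float))
        plates.append(PlateTimeCourse(
            plate_id=str(plate_id), condition=str(condition), wells=wells,
            times=times,
            od_raw=np.vstack(mats["od_raw"]),
            f390=np.vstack(mats["f390"]),
            f470=np.vstack(mats["f470"]),
        ))
    return plates


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    meta_cols = ["plate_id", "well", "strain_id", "role", "condition", "channel"]
    _require_columns(df, meta_cols)
    df = df.copy()
    df["strain_id"] = df["strain_id"].fillna("")
    time_cols = [c for c in df.columns if c not in meta_cols]
    if not time_cols:
        raise SchemaError("wide table has no timepoint columns")
    try:
        times = {c: float(c) for c in time_cols}
    except ValueError as exc:
        raise SchemaError(f"non-numeric timepoint column header: {exc}") from exc
    molten = df.melt(
        id_vars=meta_cols, value_vars=time_cols,
        var_name="time_h", value_name="value",
    )
    molten["time_h"] = molten["time_h"].map(times)
    bad = set(molten["channel"].unique()) - set(CHANNELS)
    if bad:
        raise SchemaError(f"unknown channel name(s): {sorted(bad)}")
    wide = molten.pivot(
        index=["plate_id", "well", "strain_id", "role", "condition", "time_h"],
        columns="channel", values="value",
    ).reset_index()
    _require_columns(wide, CHANNELS)
    return wide[LONG_COLUMNS]


def read_timecourse(
    path,
    format: str = "long_csv",
    time_unit: str = "hours",
) -> list[PlateTimeCourse]:
    """Read plate time courses; one :class:`PlateTimeCourse` per plate x condition.

    Parameters
    ----------
    format
        ``"long_csv"`` (canonical) or ``"wide_csv"`` (one timepoint per column,
        one row per well x channel).
    time_unit
        ``"hours"`` or ``"minutes"``; minutes are converted to decimal hours.
    """
    if format not in ("long_csv", "wide_csv"):
        raise ValueError(f"unknown format {format!r}")
    if time_unit not in ("hours", "minutes"):
        raise ValueError(f"unknown time_unit {time_unit!r}")
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str,
                                  "strain_id": str, "role": str,
                                  "condition": str})
    if format == "wide_csv":
        df = _wide_to_long(df)
    else:
        _require_columns(df, LONG_COLUMNS)
    df = df.copy()
    df["time_h"] = pd.to_numeric(df["time_h"], errors="raise").astype(float)
    if time_unit == "minutes":
        df["time_h"] = df["time_h"] / 60.0
    return _plates_from_long(df)


def write_timecourse(plates, path) -> None:
    """Write one or more plates as a single canonical long CSV."""
    if isinstance(plates, PlateTimeCourse):
        plates = [plates]
    frame = pd.concat([p.to_long_frame() for p in plates], ignore_index=True)
    frame.to_csv(path, index=False)


def read_annotation(path) -> dict[str, set[str]]:
    """Read a two-column (strain_id, term) table into a term -> strain-set map.

    Duplicated rows collapse; a header row named ``strain_id,term`` is
    accepted and skipped.
    """
    df = pd.read_csv(path, header=None, names=["strain_id", "term"],
                     dtype=str, skip_blank_lines=True)
    if len(df) and df.iloc[0].tolist() == ["strain_id", "term"]:
        df = df.iloc[1:]
    df = df.dropna()
    if df.empty:
        raise ValidationError(f"annotation file {path} is empty")
    out: dict[str, set[str]] = {}
    for strain, term in zip(df["strain_id"], df["term"]):
        out.setdefault(str(term), set()).add(str(strain))
    return out


def write_annotation(annotation: dict[str, set[str]], path) -> None:
    rows = [(s, t) for t in sorted(annotation) for s in sorted(annotation[t])]
    pd.DataFrame(rows, columns=["strain_id", "term"]).to_csv(path, index=False)


def read_calibration_table(path) -> pd.DataFrame:
    """Read a calibration-standard table with columns ``ph, ratio``."""
    df = pd.read_csv(path)
    _require_columns(df, ["ph", "ratio"])
    return df[["ph", "ratio"]].astype(float)


def write_calibration_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, ["ph", "ratio"])
    df[["ph", "ratio"]].to_csv(path, index=False)
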