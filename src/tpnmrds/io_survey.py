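"""Survey-table I/O, truncation, and covariate coding.

Reads the two flat tables an aerial line-transect survey produces — a
detections table (one row per detected animal group, with its perpendicular
distance to the transect, sighting covariates, and the dual-observer capture
history) and a transects table (one row per surveyed transect with its
stratum and length) — validates them, applies left/right distance
truncation, and builds the coded covariates the detection models consume.

Units: perpendicular and search distances in metres, transect lengths in
kilometres, habitat areas in km².  All unit conversion happens in
:mod:`tpnmrds.mrds_estimator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurveyDataError",
    "ColumnMapping",
    "CrewGroups",
    "StratumDesign",
    "SurveyDesign",
    "read_detections",
    "read_transects",
    "truncate",
    "code_covariates",
    "write_detections",
]

ACTIVITIES = frozenset({"bedded", "feeding", "standing", "walking", "running"})
TRANSECT_TYPES = frozenset({"contour", "straight", "hinged"})
HISTORIES = frozenset({"pilot", "backseat", "both"})

#: canonical column name -> required flag
_DETECTION_COLUMNS = {
    "distance": True,
    "search_distance": True,
    "group_size": True,
    "activity": True,
    "percent_cover": True,
    "transect_type": True,
    "pilot": True,
    "observer": True,
    "stratum": True,
    "history": True,
    "transect_id": False,
    "group_type": False,
    "plane_speed": False,
    "percent_snow": False,
}


class SurveyDataError(ValueError):
    """Raised for malformed survey tables; carries a row-indexed report."""

    def __init__(self, message: str, row_errors: list[tuple[int, str]] | None = None):
        self.row_errors = row_errors or []
        if self.row_errors:
            detail = "; ".join(f"row {i}: {msg}" for i, msg in self.row_errors[:20])
            message = f"{message} ({len(self.row_errors)} bad rows: {detail})"
        super().__init__(message)


@dataclass(frozen=True)
class ColumnMapping:
    """Maps canonical detection/transect column names onto a CSV dialect.

    ``detections`` and ``transects`` map canonical names (the keys used
    throughout this package) to the column headers actually present in the
    files.  Unmapped names default to themselves.
    """

    detections: dict[str, str] = field(default_factory=dict)
    transects: dict[str, str] = field(default_factory=dict)

    def detection_column(self, canonical: str) -> str:
        return self.detections.get(canonical, canonical)

    def transect_column(self, canonical: str) -> str:
        return self.transects.get(canonical, canonical)


@dataclass(frozen=True)
class CrewGroups:
    """Pilot/observer id -> group assignment (0 or 1).

    Crews with heterogeneous sighting ability are pooled into two groups per
    seat, which enter the models as binary covariates.
    """

    pilot_groups: dict[str, int] = field(default_factory=dict)
    observer_groups: dict[str, int] = field(default_factory=dict)

    def pilot_group(self, pilot_id: str) -> int:
        try:
            return int(self.pilot_groups[str(pilot_id)])
        except KeyError:
            raise SurveyDataError(f"unknown pilot id {pilot_id!r}: not in crew grouping config") from None

    def observer_group(self, observer_id: str) -> int:
        try:
            return int(self.observer_groups[str(observer_id)])
        except KeyError:
            raise SurveyDataError(f"unknown observer id {observer_id!r}: not in crew grouping config") from None


@dataclass
class StratumDesign:
    label: str
    habitat_area: float  # km^2
    transect_lengths: pd.Series  # km, indexed by transect id

    @property
    def n_transects(self) -> int:
        return len(self.transect_lengths)

    @property
    def effort(self) -> float:
        """Total transect length surveyed (km)."""
        return float(self.transect_lengths.sum())


@dataclass
class SurveyDesign:
    """Strata with habitat areas and per-transect effort, plus truncation.

    ``w`` is the right truncation distance and ``w_b`` the edge of the
    under-aircraft blind spot (left truncation), both in metres.
    """

    strata: dict[str, StratumDesign]
    w: float = 1000.0
    w_b: float = 22.0

    def __post_init__(self):
        if not 0 <= self.w_b < self.w:
            raise SurveyDataError(f"need 0 <= w_b < w, got w_b={self.w_b}, w={self.w}")
        for s in self.strata.values():
            if s.habitat_area <= 0:
                raise SurveyDataError(f"stratum {s.label!r}: habitat area must be > 0")
            if s.n_transects == 0:
                raise SurveyDataError(f"stratum {s.label!r} has no transects")
            if (s.transect_lengths <= 0).any():
                raise SurveyDataError(f"stratum {s.label!r}: non-positive transect length")

    def stratum(self, label: str) -> StratumDesign:
        return self.strata[str(label)]


def read_detections(path, mapping: ColumnMapping | None = None) -> pd.DataFrame:
    """Read and validate a detections CSV into the canonical frame.

    Returns a DataFrame with canonical column names; every row either parses
    cleanly or the whole read fails with a :class:`SurveyDataError` listing
    the offending rows by line.
    """
    mapping = mapping or ColumnMapping()
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)

    missing = [
        c for c, required in _DETECTION_COLUMNS.items()
        if required and mapping.detection_column(c) not in raw.columns
    ]
    if missing:
        cols = ", ".join(mapping.detection_column(c) for c in missing)
        raise SurveyDataError(f"detections file is missing required column(s): {cols}")

    df = pd.DataFrame(index=raw.index)
    for canonical in _DETECTION_COLUMNS:
        src = mapping.detection_column(canonical)
        if src in raw.columns:
            df[canonical] = raw[src]

    errors: list[tuple[int, str]] = []

    def _numeric(col, kind=float, lo=None):
        if col not in df:
            return
        out = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[out.isna() & df[col].notna()]:
            errors.append((i + 2, f"unparseable {col} {df.loc[i, col]!r}"))
        if lo is not None:
            for i in df.index[out < lo]:
                errors.append((i + 2, f"{col} {out[i]} < {lo}"))
        if kind is int:
            bad = out.notna() & (out != out.round())
            for i in df.index[bad]:
                errors.append((i + 2, f"{col} {out[i]} is not an integer"))
        df[col] = out

    _numeric("distance", lo=0.0)
    _numeric("search_distance", lo=0.0)
    _numeric("group_size", kind=int, lo=1)
    _numeric("percent_cover", kind=int, lo=0)
    _numeric("plane_speed")
    _numeric("percent_snow")

    pc = df["percent_cover"]
    for i in df.index[pc.notna() & ((pc > 100) | (pc % 10 != 0))]:
        errors.append((i + 2, f"percent_cover {pc[i]} not a multiple of 10 in 0..100"))

    for col, levels in [("activity", ACTIVITIES), ("transect_type", TRANSECT_TYPES), ("history", HISTORIES)]:
        vals = df[col].astype(str).str.strip().str.lower()
        for i in df.index[~vals.isin(levels)]:
            errors.append((i + 2, f"{col} {df.loc[i, col]!r} not one of {sorted(levels)}"))
        df[col] = vals

    if errors:
        raise SurveyDataError("detections file failed validation", sorted(errors))

    df["group_size"] = df["group_size"].astype(int)
    df["percent_cover"] = df["percent_cover"].astype(int)
    for col in ("pilot", "observer", "stratum"):
        df[col] = df[col].astype(str).str.strip()
    if "transect_id" in df:
        df["transect_id"] = df["transect_id"].astype(str).str.strip()
    return df


def read_transects(path, mapping: ColumnMapping | None = None) -> pd.DataFrame:
    """Read a transects CSV: columns stratum, transect_id (optional), length (km)."""
    mapping = mapping or ColumnMapping()
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    for canonical in ("stratum", "length"):
        if mapping.transect_column(canonical) not in raw.columns:
            raise SurveyDataError(f"transects file is missing required column {mapping.transect_column(canonical)!r}")

    df = pd.DataFrame(index=raw.index)
    df["stratum"] = raw[mapping.transect_column("stratum")].astype(str).str.strip()
    id_col = mapping.transect_column("transect_id")
    if id_col in raw.columns:
        df["transect_id"] = raw[id_col].astype(str).str.strip()
    else:
        df["transect_id"] = [f"T{i+1}" for i in df.index]

    length = pd.to_numeric(raw[mapping.transect_column("length")], errors="coerce")
    errors = [(i + 2, f"unparseable length {raw.loc[i, mapping.transect_column('length')]!r}")
              for i in df.index[length.isna()]]
    errors += [(i + 2, f"non-positive length {length[i]}") for i in df.index[length <= 0]]
    if errors:
        raise SurveyDataError("transects file failed validation", sorted(errors))
    df["length"] = length.astype(float)
    return df


def build_design(transects: pd.DataFrame, habitat_areas: dict[str, float],
                 w: float = 1000.0, w_b: float = 22.0) -> SurveyDesign:
    """Assemble a :class:`SurveyDesign` from a transects frame and stratum areas."""
    strata = {}
    for label, sub in transects.groupby("stratum"):
        if label not in habitat_areas:
            raise SurveyDataError(f"no habitat area configured for stratum {label!r}")
        lengths = sub.set_index("transect_id")["length"]
        strata[str(label)] = StratumDesign(str(label), float(habitat_areas[label]), lengths)
    for label in habitat_areas:
        if str(label) not in strata:
            raise SurveyDataError(f"stratum {label!r} has no transects")
    return SurveyDesign(strata, w=w, w_b=w_b)


def truncate(detections: pd.DataFrame, w: float, w_b: float = 0.0):
    """Right/left truncation of the distance data.

    Keeps rows with ``w_b <= distance <= w``.  Returns ``(retained, report)``
    where the report counts removals per stratum and overall.
    """
    if not w_b < w:
        raise SurveyDataError(f"need w_b < w, got w_b={w_b}, w={w}")
    keep = (detections["distance"] >= w_b) & (detections["distance"] <= w)
    removed = detections.loc[~keep]
    report = {"overall": int(len(removed))}
    for label, sub in detections.groupby("stratum"):
        report[str(label)] = int((~keep.loc[sub.index]).sum())
    return detections.loc[keep].copy(), report


def code_covariates(detections: pd.DataFrame, crew: CrewGroups,
                    stratum_reference: str | None = None) -> pd.DataFrame:
    """Append the model covariates, coded deterministically from the raw fields.

    - ``bed``       : 1 for bedded groups
    - ``pcvr5``     : percent cover / 20  (0..5)
    - ``bin2sd1000``: 1 if search distance exceeded 1000 m
    - ``tranflat``  : 1 for straight/hinged transects, 0 for contour
    - ``pilot_group``, ``observer_group``: crew pooling per *crew*
    - ``stratum_indicator``: 1 for strata other than ``stratum_reference``
      (default: the lexicographically first stratum is the reference)

    The asymmetry indicator of the detection model (1 beyond the fitted apex)
    is *not* coded here: it depends on the fitted apex distance and is formed
    inside the detection fit.
    """
    df = detections.copy()
    df["bed"] = (df["activity"] == "bedded").astype(int)
    df["pcvr5"] = df["percent_cover"] / 20.0
    df["bin2sd1000"] = (df["search_distance"] > 1000.0).astype(int)
    df["tranflat"] = df["transect_type"].isin(["straight", "hinged"]).astype(int)
    df["pilot_group"] = df["pilot"].map(crew.pilot_group)
    df["observer_group"] = df["observer"].map(crew.observer_group)
    if stratum_reference is None:
        stratum_reference = sorted(df["stratum"].unique())[0] if len(df) else ""
    df["stratum_indicator"] = (df["stratum"] != str(stratum_reference)).astype(int)
    return df


def write_detections(detections: pd.DataFrame, path,
                     mapping: ColumnMapping | None = None) -> None:
    """Write a canonical detections frame back to CSV (round-trips with read)."""
    mapping = mapping or ColumnMapping()
    cols = [c for c in _DETECTION_COLUMNS if c in detections.columns]
    out = detections[cols].rename(columns={c: mapping.detection_column(c) for c in cols})
    out.to_csv(path, index=False)
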