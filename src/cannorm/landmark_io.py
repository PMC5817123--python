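"""Reading and writing landmark data: TPS files, measurement and census tables.

TPS is the plain-text dialect written by the tpsDig digitizer: records of the
form ``LM=<n>`` followed by *n* whitespace-separated ``x y`` lines, with
optional ``ID=``, ``IMAGE=`` and ``SCALE=`` keys.  A ``SCALE`` value converts
pixel coordinates to millimetres multiplicatively.  Landmark roles (fixed
vs. semilandmark) and bilateral pairing are not part of the TPS format; they
are supplied by a sidecar schema (:class:`LandmarkSchema`), typically loaded
from a YAML file.

All indices in schema files follow the 1-based TPS convention; in-memory
arrays are 0-based.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "LandmarkConfiguration",
    "LandmarkSchema",
    "MeasurementRecord",
    "CensusRecord",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "read_schema",
    "resample_semilandmarks",
    "read_measurements_csv",
    "write_measurements_csv",
    "read_census_csv",
    "write_census_csv",
]

MEASUREMENT_COLUMNS = ["HW", "JW1", "JW2", "EW", "HL1", "HL2", "HL3", "SVL"]


class TPSParseError(ValueError):
    """Raised when a TPS file violates the expected record structure."""


@dataclass
class LandmarkSchema:
    """Sidecar description of landmark roles and bilateral pairing.

    ``pairs`` lists 1-based (left, right) index pairs for bilaterally paired
    points; ``midline`` lists 1-based indices of unpaired on-axis points.
    ``semi`` flags which 1-based indices are semilandmarks.
    """

    n_points: int
    semi: tuple[int, ...] = ()
    pairs: tuple[tuple[int, int], ...] = ()
    midline: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        used: set[int] = set()
        for a, b in self.pairs:
            for i in (a, b):
                if not 1 <= i <= self.n_points:
                    raise ValueError(f"pair index {i} out of range 1..{self.n_points}")
                if i in used:
                    raise ValueError(f"index {i} appears in more than one pair")
                used.add(i)
        for i in self.midline:
            if not 1 <= i <= self.n_points:
                raise ValueError(f"midline index {i} out of range")
            if i in used:
                raise ValueError(f"midline index {i} also paired")

    def roles(self) -> list[str]:
        semi = set(self.semi)
        return ["semi" if i + 1 in semi else "fixed" for i in range(self.n_points)]

    def pairs0(self) -> list[tuple[int, int]]:
        """Pairs as 0-based indices."""
        return [(a - 1, b - 1) for a, b in self.pairs]

    def midline0(self) -> list[int]:
        return [i - 1 for i in self.midline]


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmark set in a single view.

    Coordinates are in millimetres after scale calibration.  ``point_roles``
    parallels ``points`` with ``"fixed"`` or ``"semi"``; ``pair_map`` holds
    0-based bilateral pairs (dorsal view only), ``midline`` the 0-based
    unpaired on-axis points.
    """

    specimen_id: str
    view: str
    points: np.ndarray
    point_roles: list[str] = field(default_factory=list)
    pair_map: list[tuple[int, int]] = field(default_factory=list)
    midline: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("a configuration needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinate")
        if not self.point_roles:
            self.point_roles = ["fixed"] * len(self.points)
        if len(self.point_roles) != len(self.points):
            raise ValueError("point_roles length mismatch")
        if self.view not in ("dorsal", "lateral"):
            raise ValueError(f"unknown view {self.view!r}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def apply_schema(self, schema: LandmarkSchema) -> "LandmarkConfiguration":
        if schema.n_points != self.n_points:
            raise ValueError(
                f"schema expects {schema.n_points} points, configuration has {self.n_points}"
            )
        self.point_roles = schema.roles()
        self.pair_map = schema.pairs0()
        self.midline = schema.midline0()
        return self


@dataclass
class MeasurementRecord:
    """Linear body dimensions (mm) of one specimen plus cannibalism evidence flags.

    HW: head width; JW1/JW2: jaw widths; EW: eye width; HL1-3: head lengths;
    SVL: snout-vent length.  ``stomach_conspecific`` marks a visually confirmed
    conspecific in the stomach; ``visual_cannibal`` marks the enlarged-jaw /
    large-body visual call.
    """

    specimen_id: str
    HW: float
    JW1: float
    JW2: float
    EW: float
    HL1: float
    HL2: float
    HL3: float
    SVL: float
    stomach_conspecific: bool = False
    visual_cannibal: bool = False

    def __post_init__(self) -> None:
        for name in MEASUREMENT_COLUMNS:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{self.specimen_id}: {name} must be positive, got {v}")
        if self.SVL <= self.HW:
            raise ValueError(f"{self.specimen_id}: SVL ({self.SVL}) must exceed HW ({self.HW})")


@dataclass
class CensusRecord:
    """Per-tank census: initial stocking, survivors, cannibals (x1), victims (x2)."""

    tank_id: str
    n_initial: int
    n_survivors: int
    n_cannibals: int

    def __post_init__(self) -> None:
        for name in ("n_initial", "n_survivors", "n_cannibals"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.tank_id}: {name} negative")
        if self.n_survivors > self.n_initial:
            raise ValueError(f"{self.tank_id}: survivors exceed initial count")
        if self.n_cannibals > self.n_survivors:
            raise ValueError(f"{self.tank_id}: cannibal count exceeds survivors")

    @property
    def x1(self) -> int:
        """Number of surviving cannibals."""
        return self.n_cannibals

    @property
    def x2(self) -> int:
        """Number of cannibalized victims (missing larvae)."""
        return self.n_initial - self.n_survivors


# ---------------------------------------------------------------------------
# TPS


def _parse_key(line: str) -> tuple[str, str] | None:
    if "=" in line:
        key, _, value = line.partition("=")
        key = key.strip().upper()
        if key.isalpha() or (key[:2] == "LM" and key[2:].isdigit()):
            return key, value.strip()
    return None


def read_tps(
    path: str | Path,
    schema: LandmarkSchema | None = None,
    view: str = "dorsal",
) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations.

    Both ``LM=<n>`` and the dialect ``LM<n>=<n>`` headers are accepted.  When a
    ``SCALE=`` key is present, coordinates are multiplied by it.  Records lacking
    an ``ID=`` key are named ``spec<k>`` by 1-based record order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[LandmarkConfiguration] = []
    i = 0
    rec_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        kv = _parse_key(line)
        if kv is None or not kv[0].startswith("LM"):
            raise TPSParseError(f"{path}: expected LM= header at line {i + 1}, got {line!r}")
        try:
            n = int(kv[1])
        except ValueError as exc:
            raise TPSParseError(f"{path}: bad landmark count at line {i + 1}") from exc
        rec_no += 1
        i += 1
        pts = []
        while len(pts) < n and i < len(lines):
            raw = lines[i].strip()
            if not raw or _parse_key(raw) is not None:
                break
            parts = raw.split()
            if len(parts) != 2:
                raise TPSParseError(f"{path}: line {i + 1}: expected 'x y', got {raw!r}")
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(
                    f"{path}: non-numeric coordinate at line {i + 1}: {raw!r}"
                ) from exc
            i += 1
        if len(pts) != n:
            raise TPSParseError(
                f"{path}: record {rec_no} declares LM={n} but has {len(pts)} coordinate lines"
            )
        spec_id = f"spec{rec_no}"
        scale = None
        while i < len(lines):
            raw = lines[i].strip()
            kv = _parse_key(raw)
            if kv is None:
                if raw:
                    break
                i += 1
                continue
            if kv[0].startswith("LM"):
                break
            if kv[0] == "ID":
                spec_id = kv[1]
            elif kv[0] == "SCALE":
                scale = float(kv[1])
            i += 1
        coords = np.array(pts, dtype=float)
        if scale is not None:
            coords = coords * scale
        cfg = LandmarkConfiguration(specimen_id=spec_id, view=view, points=coords)
        if schema is not None:
            cfg.apply_schema(schema)
        records.append(cfg)
    return records


def write_tps(path: str | Path, configs: Iterable[LandmarkConfiguration]) -> None:
    """Write configurations in TPS format (SCALE omitted: coordinates are in mm)."""
    out = []
    for cfg in configs:
        out.append(f"LM={cfg.n_points}")
        for x, y in cfg.points:
            out.append(f"{x:.9f} {y:.9f}")
        out.append(f"ID={cfg.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


def read_schema(path: str | Path) -> dict[str, LandmarkSchema]:
    """Load view-keyed landmark schemas from a YAML file.

    Expected layout::

        dorsal:
          n_points: 30
          semi: [11, 12, ...]
          pairs: [[1, 2], [4, 5], ...]
          midline: [3]
        lateral:
          n_points: 20
          semi: [9, 10, ...]
    """
    raw = yaml.safe_load(Path(path).read_text())
    schemas = {}
    for view, block in raw.items():
        schemas[view] = LandmarkSchema(
            n_points=int(block["n_points"]),
            semi=tuple(int(i) for i in block.get("semi", ())),
            pairs=tuple((int(a), int(b)) for a, b in block.get("pairs", ())),
            midline=tuple(int(i) for i in block.get("midline", ())),
        )
    return schemas


# ---------------------------------------------------------------------------
# Semilandmark resampling


def resample_semilandmarks(curve_points: Sequence, n_semi: int) -> np.ndarray:
    """Place ``n_semi`` points at equal arc-length spacing strictly between a
    polyline's endpoints.

    The curve is treated as a piecewise-linear path; the *k*-th semilandmark
    sits at arc length ``k / (n_semi + 1)`` of the total path length.  The
    result is stable under refinement of the input polyline.
    """
    pts = np.asarray(curve_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("curve must be an (n >= 2, 2) array")
    if n_semi < 0:
        raise ValueError("n_semi must be >= 0")
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = seglen.sum()
    if total <= 0:
        raise ValueError("degenerate zero-length curve")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = total * np.arange(1, n_semi + 1) / (n_semi + 1)
    out = np.empty((n_semi, 2))
    for k, t in enumerate(targets):
        j = int(np.searchsorted(cum, t, side="right") - 1)
        j = min(j, len(seglen) - 1)
        frac = (t - cum[j]) / seglen[j] if seglen[j] > 0 else 0.0
        out[k] = pts[j] + frac * seg[j]
    return out


# ---------------------------------------------------------------------------
# CSV tables

_CENSUS_COLS = ["tank_id", "n_initial", "n_survivors", "n_cannibals"]
_MEAS_COLS = ["specimen_id"] + MEASUREMENT_COLUMNS + ["stomach_conspecific", "visual_cannibal"]


def _check_header(header: Sequence[str], required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_census_csv(path: str | Path) -> list[CensusRecord]:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames or [], _CENSUS_COLS, path)
        return [
            CensusRecord(
                tank_id=row["tank_id"],
                n_initial=int(row["n_initial"]),
                n_survivors=int(row["n_survivors"]),
                n_cannibals=int(row["n_cannibals"]),
            )
            for row in reader
        ]


def write_census_csv(path: str | Path, records: Iterable[CensusRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CENSUS_COLS)
        for r in records:
            w.writerow([r.tank_id, r.n_initial, r.n_survivors, r.n_cannibals])


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in ("1", "true", "yes")


def read_measurements_csv(path: str | Path) -> list[MeasurementRecord]:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames or [], ["specimen_id"] + MEASUREMENT_COLUMNS, path)
        out = []
        for row in reader:
            out.append(
                MeasurementRecord(
                    specimen_id=row["specimen_id"],
                    **{c: float(row[c]) for c in MEASUREMENT_COLUMNS},
                    stomach_conspecific=_parse_bool(row.get("stomach_conspecific", "")),
                    visual_cannibal=_parse_bool(row.get("visual_cannibal", "")),
                )
            )
        return out


def write_measurements_csv(path: str | Path, records: Iterable[MeasurementRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_MEAS_COLS)
        for r in records:
            w.writerow(
                [r.specimen_id]
                + [repr(getattr(r, c)) for c in MEASUREMENT_COLUMNS]
                + [str(r.stomach_conspecific).lower(), str(r.visual_cannibal).lower()]
            )
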