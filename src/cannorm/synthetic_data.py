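"""Synthetic dimorphic-population studies with known ground truth.

The generator emulates the density-manipulation experiment the analysis is
built for: 10 high-density tanks stocked with 30 larvae each, and 30
single-larva (Solitary) tanks pooled into one hypothetical zero-interaction
population.  Per high-density tank it draws a victim count x2 (1-9), couples
a cannibal count x1 to it, partitions the victims among cannibals with a
configurable concentration (egalitarian -> fully exclusive), and grows each
survivor's latent size by the victims it consumed.

Two latent variables drive every specimen:

* ``s`` - latent size score.  Cannibals gain ``gain_per_victim`` per victim
  consumed, so tanks with more victims develop a wider, right-skewed size
  distribution.
* shape score - under the high-density integration rule,
  ``shape = intercept + slope * s + N(0, sigma)`` with a negative default
  slope: larger animals express a more cannibal-like (tetragonal-head,
  shallow-fin) shape.  Solitary specimens draw shape independently of size.

Landmarks are produced by deforming dorsal/lateral template outlines along
two fixed basis vectors (head-widening; fin-shallowing) by the negated shape
score, scaling by size, and adding isotropic digitizing noise.  The linear
measurements (HW, JW1, ..., SVL) are read geometrically off the deformed
configurations, so every downstream module sees mutually consistent data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .landmark_io import (
    CensusRecord,
    LandmarkConfiguration,
    LandmarkSchema,
    MeasurementRecord,
    write_census_csv,
    write_measurements_csv,
    write_tps,
)

__all__ = [
    "GeneratorParams",
    "SyntheticStudy",
    "dorsal_template",
    "lateral_template",
    "default_schemas",
    "generate_specimen",
    "generate_study",
    "write_study",
]


# ---------------------------------------------------------------------------
# Templates: unitless outlines; the dorsal midline is the y-axis.

_N_SIDE_FIXED = 9
_N_SIDE_SEMI = 10


def dorsal_template() -> tuple[np.ndarray, np.ndarray, LandmarkSchema]:
    """Symmetric dorsal head outline and its head-widening deformation basis.

    Returns ``(points, widen_basis, schema)``.  Points: one midline snout tip
    followed by 19 left-side points (9 fixed, 10 semi) and their 19 mirror
    images.  The widening basis pushes the anterior outline laterally,
    turning a trigonal head tetragonal at positive coefficients.
    """
    thetas = np.linspace(80, -80, _N_SIDE_FIXED + _N_SIDE_SEMI) * np.pi / 180.0
    a, b = 0.6, 1.0
    left = np.column_stack([-a * np.cos(thetas) ** 1.0, b * np.sin(thetas)])
    snout = np.array([[0.0, 1.05]])
    pts = np.vstack([snout, left, left * [-1.0, 1.0]])

    # anterior widening: Gaussian bump centred on the jaw region (y ~ 0.55)
    g = np.exp(-(((left[:, 1] - 0.55) / 0.35) ** 2))
    basis = np.zeros_like(pts)
    basis[1 : 1 + len(left), 0] = -0.18 * g
    basis[1 + len(left) :, 0] = 0.18 * g

    n_side = len(left)
    fixed_idx = np.linspace(0, n_side - 1, _N_SIDE_FIXED).round().astype(int)
    semi_left = [i + 2 for i in range(n_side) if i not in set(fixed_idx)]  # 1-based
    semi = tuple(semi_left) + tuple(i + n_side for i in semi_left)
    pairs = tuple((i + 2, i + 2 + n_side) for i in range(n_side))
    schema = LandmarkSchema(n_points=len(pts), semi=semi, pairs=pairs, midline=(1,))
    return pts, basis, schema


def lateral_template() -> tuple[np.ndarray, np.ndarray, LandmarkSchema]:
    """Lateral body outline (snout to vent, caudal fin excluded) and its
    fin-shallowing basis.  8 fixed landmarks, 12 semilandmarks."""
    # dorsal outline from snout over head and dorsal fin, then ventral back
    dorsal_x = np.array([0.00, 0.12, 0.30, 0.55, 0.80, 1.05, 1.30, 1.45, 1.55, 1.60])
    dorsal_y = np.array([0.25, 0.38, 0.45, 0.48, 0.55, 0.62, 0.58, 0.52, 0.45, 0.30])
    ventral_x = np.array([1.55, 1.35, 1.05, 0.75, 0.48, 0.30, 0.15, 0.05, 0.00, 0.02])
    ventral_y = np.array([0.05, 0.02, 0.00, 0.00, 0.02, 0.04, 0.06, 0.10, 0.15, 0.20])
    pts = np.column_stack(
        [np.concatenate([dorsal_x, ventral_x]), np.concatenate([dorsal_y, ventral_y])]
    )
    # fin-shallowing: depress the dorsal-fin crest (x in [0.7, 1.5])
    g = np.exp(-(((pts[:, 0] - 1.1) / 0.35) ** 2)) * (pts[:, 1] > 0.3)
    basis = np.zeros_like(pts)
    basis[:, 1] = -0.22 * g
    fixed = (1, 3, 5, 7, 10, 11, 14, 19)  # snout, head top, fin crest, vent, belly
    semi = tuple(i for i in range(1, len(pts) + 1) if i not in fixed)
    schema = LandmarkSchema(n_points=len(pts), semi=semi)
    return pts, basis, schema


def default_schemas() -> dict[str, LandmarkSchema]:
    return {"dorsal": dorsal_template()[2], "lateral": lateral_template()[2]}


# indices used to read measurements off the templates (0-based)
_SNOUT = 0
_LEFT0 = 1  # first left-side point
_NSIDE = _N_SIDE_FIXED + _N_SIDE_SEMI


def _pair(i_side: int) -> tuple[int, int]:
    return _LEFT0 + i_side, _LEFT0 + _NSIDE + i_side


_MEAS_PAIRS = {"JW1": _pair(3), "JW2": _pair(5), "EW": _pair(2), "HW": _pair(9)}
_LAT_SNOUT, _LAT_VENT = 0, 10  # lateral outline: snout tip / vent landmark


def measure_configuration(dorsal: np.ndarray, lateral: np.ndarray) -> dict[str, float]:
    """Linear measurements (mm) read geometrically off a specimen's landmarks."""
    d = {}
    for name, (i, j) in _MEAS_PAIRS.items():
        d[name] = float(np.linalg.norm(dorsal[i] - dorsal[j]))
    snout = dorsal[_SNOUT]
    for k, i_side in zip((1, 2, 3), (4, 9, 14)):
        left, right = _pair(i_side)
        mid = 0.5 * (dorsal[left] + dorsal[right])
        d[f"HL{k}"] = float(np.linalg.norm(snout - mid))
    d["SVL"] = float(np.linalg.norm(lateral[_LAT_SNOUT] - lateral[_LAT_VENT]))
    return d


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class GeneratorParams:
    """Study-design and latent-model parameters.

    Defaults mirror the experimental design being emulated: 10 high-density
    tanks of 30 larvae, 30 pooled Solitary animals, victim counts spanning
    1-9, at most a handful of cannibals per tank.
    """

    n_tanks: int = 10
    n_per_tank: int = 30
    n_solitary: int = 30
    victim_min: int = 1
    victim_max: int = 9
    p_extra_cannibal: float = 0.35  # each extra victim may recruit a cannibal
    max_cannibals: int = 6
    partition_concentration: float = 0.5  # Dirichlet conc.: small -> exclusive
    gain_per_victim: float = 1.2  # latent size gain per victim consumed
    integration_slope: float = -0.4  # shape per unit latent size (high density)
    integration_intercept: float = 0.2
    integration_sigma: float = 0.45
    solitary_size_sigma: float = 0.8
    solitary_shape_mean: float = -0.1
    solitary_shape_sigma: float = 0.3
    view_shape_sigma: float = 0.35  # per-view deviation from the common shape factor
    size_mm: float = 10.0  # template-to-mm scale of an average larva
    size_rel: float = 0.06  # relative geometric growth per latent size unit
    landmark_noise: float = 0.004  # isotropic digitizing noise, template units
    p_stomach_visible: float = 0.3
    p_visual_flag: float = 0.5

    def validate(self) -> None:
        if min(self.n_tanks, self.n_per_tank, self.n_solitary) < 1:
            raise ValueError("counts must be >= 1")
        for name in ("integration_sigma", "solitary_size_sigma", "solitary_shape_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.victim_min <= self.victim_max:
            raise ValueError("victim range invalid")


@dataclass
class SyntheticStudy:
    params: GeneratorParams
    seed: int
    dorsal: list[LandmarkConfiguration]
    lateral: list[LandmarkConfiguration]
    measurements: list[MeasurementRecord]
    census: list[CensusRecord]
    truth: pd.DataFrame  # specimen_id, tank_id, category, size, shape, victims_consumed
    schemas: dict[str, LandmarkSchema] = field(default_factory=default_schemas)


# ---------------------------------------------------------------------------
# Generation


def generate_specimen(
    category: str,
    s: float,
    params: GeneratorParams,
    rng: np.random.Generator,
    specimen_id: str = "spec",
    shape: float | None = None,
):
    """One specimen's dorsal/lateral configurations and measurements.

    ``shape`` overrides the latent shape score; otherwise it is drawn from the
    category's rule (high-density integration line, or the independent
    Solitary cloud).  Low shape scores are cannibal-like, so the deformation
    coefficient applied to the widening/shallowing bases is ``-shape``.
    """
    if category not in ("Cannibal", "NonCannibal", "Solitary"):
        raise ValueError(f"unknown category {category!r}")
    if not np.isfinite(s):
        raise ValueError("latent size must be finite")
    if shape is None:
        if category == "Solitary":
            shape = params.solitary_shape_mean + params.solitary_shape_sigma * rng.standard_normal()
        else:
            shape = (
                params.integration_intercept
                + params.integration_slope * s
                + params.integration_sigma * rng.standard_normal()
            )
    # each view expresses the common shape factor plus its own deviation
    u_d = -(float(shape) + params.view_shape_sigma * rng.standard_normal())
    u_l = -(float(shape) + params.view_shape_sigma * rng.standard_normal())

    d_pts, d_basis, d_schema = dorsal_template()
    l_pts, l_basis, l_schema = lateral_template()
    scale = params.size_mm * max(1.0 + params.size_rel * s, 0.2)
    noise = params.landmark_noise
    dorsal = scale * (d_pts + u_d * d_basis + noise * rng.standard_normal(d_pts.shape))
    lateral = scale * (l_pts + u_l * l_basis + noise * rng.standard_normal(l_pts.shape))

    meas = measure_configuration(dorsal, lateral)
    cfg_d = LandmarkConfiguration(specimen_id=specimen_id, view="dorsal", points=dorsal)
    cfg_d.apply_schema(d_schema)
    cfg_l = LandmarkConfiguration(specimen_id=specimen_id, view="lateral", points=lateral)
    cfg_l.apply_schema(l_schema)
    return cfg_d, cfg_l, meas, float(shape)


def generate_study(params: GeneratorParams | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a full study: tanks, censuses, landmark configurations,
    measurements, and the latent ground truth, reproducibly from ``seed``."""
    params = params or GeneratorParams()
    params.validate()
    rng = np.random.default_rng(seed)

    dorsal, lateral, measurements, census, truth_rows = [], [], [], [], []

    def _add(spec_id, tank_id, category, s, victims_consumed):
        cfg_d, cfg_l, meas, shape = generate_specimen(
            category, s, params, rng, specimen_id=spec_id
        )
        dorsal.append(cfg_d)
        lateral.append(cfg_l)
        stomach = bool(
            category == "Cannibal"
            and victims_consumed >= 1
            and rng.random() < params.p_stomach_visible
        )
        visual = bool(
            category == "Cannibal"
            and victims_consumed >= 2
            and rng.random() < params.p_visual_flag
        )
        measurements.append(
            MeasurementRecord(
                specimen_id=spec_id,
                **{k: meas[k] for k in ("HW", "JW1", "JW2", "EW", "HL1", "HL2", "HL3", "SVL")},
                stomach_conspecific=stomach,
                visual_cannibal=visual,
            )
        )
        truth_rows.append(
            dict(
                specimen_id=spec_id,
                tank_id=tank_id,
                category=category,
                size=s,
                shape=shape,
                victims_consumed=victims_consumed,
            )
        )

    for t in range(1, params.n_tanks + 1):
        tank = f"g{t}"
        for _attempt in range(100):
            x2 = int(rng.integers(params.victim_min, params.victim_max + 1))
            survivors = params.n_per_tank - x2
            x1 = 1 + int(rng.binomial(x2 - 1, params.p_extra_cannibal)) if x2 > 1 else 1
            x1 = min(x1, params.max_cannibals)
            if x1 <= survivors:
                break
            warnings.warn(f"{tank}: infeasible cannibal count, resampling")
        census.append(
            CensusRecord(
                tank_id=tank,
                n_initial=params.n_per_tank,
                n_survivors=survivors,
                n_cannibals=x1,
            )
        )
        # partition victims among cannibals: small concentration -> one
        # dominant consumer (exclusive exploitation)
        weights = rng.dirichlet([params.partition_concentration] * x1)
        consumed = rng.multinomial(x2, weights)
        for i in range(survivors):
            is_cannibal = i < x1
            vic = int(consumed[i]) if is_cannibal else 0
            s = rng.standard_normal() + params.gain_per_victim * vic
            _add(
                f"{tank}_s{i + 1:02d}",
                tank,
                "Cannibal" if is_cannibal else "NonCannibal",
                s,
                vic,
            )

    for i in range(params.n_solitary):
        s = params.solitary_size_sigma * rng.standard_normal()
        _add(f"sol_s{i + 1:02d}", "sol", "Solitary", s, 0)

    return SyntheticStudy(
        params=params,
        seed=seed,
        dorsal=dorsal,
        lateral=lateral,
        measurements=measurements,
        census=census,
        truth=pd.DataFrame(truth_rows),
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write a study as TPS + CSV files plus a JSON manifest of params/seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_tps(out / "dorsal.tps", study.dorsal)
    write_tps(out / "lateral.tps", study.lateral)
    write_measurements_csv(out / "measurements.csv", study.measurements)
    write_census_csv(out / "census.csv", study.census)
    study.truth.to_csv(out / "truth.csv", index=False)
    manifest = {"seed": study.seed, "params": asdict(study.params)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
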