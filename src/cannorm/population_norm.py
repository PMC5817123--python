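"""Per-population dimorphism statistics and census-distribution association.

Each high-density tank is one population; its census vector is X = (x1, x2)
(surviving cannibal count, victim count) and its size-shape distribution
statistics form Y = (y1, y2, y3):

* y1 - Pearson correlation of the joint dominant size and shape scores,
* y2 - moment coefficient of skewness of the size scores,
* y3 - moment coefficient of skewness of the shape scores.

Solitary specimens (low-density treatment) are pooled into a single
hypothetical zero-cannibal, zero-victim population ("sol") serving as the
no-interaction reference.

The module also provides the census-vs-distribution correlation suite (RV,
first-axis PLS correlation and the separate Pearson correlations, each with a
permutation test) and a planned-contrast one-way ANOVA comparing score
variation among victim-count-keyed populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .integration_stats import rv_permutation_test, two_block_pls
from .sma_regression import pearson_test

__all__ = [
    "PopulationSummary",
    "ContrastAnovaTable",
    "skewness",
    "population_distribution_stats",
    "census_correlation_suite",
    "summaries_to_blocks",
    "anova_planned_contrasts",
]


@dataclass
class PopulationSummary:
    tank_id: str
    x1: int
    x2: int
    y1: float
    y2: float
    y3: float

    def __post_init__(self) -> None:
        if abs(self.y1) > 1 + 1e-12:
            raise ValueError(f"{self.tank_id}: |y1| > 1")
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError(f"{self.tank_id}: negative census count")


@dataclass
class ContrastAnovaTable:
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def skewness(values, bias_corrected: bool = False) -> float:
    """Moment coefficient of skewness g1 = m3 / m2^(3/2) with 1/n moments.

    ``bias_corrected`` applies the sample adjustment
    sqrt(n(n-1))/(n-2) * g1 instead.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("skewness needs at least 3 values")
    m2 = np.mean((v - v.mean()) ** 2)
    if m2 == 0:
        raise ValueError("zero variance")
    g1 = float(np.mean((v - v.mean()) ** 3) / m2**1.5)
    if bias_corrected:
        g1 *= np.sqrt(n * (n - 1)) / (n - 2)
    return g1


def population_distribution_stats(
    scores: pd.DataFrame,
    census=None,
    solitary_label: str = "Solitary",
    sol_id: str = "sol",
    bias_corrected: bool = False,
) -> list[PopulationSummary]:
    """Per-tank distribution statistics (y1, y2, y3) plus the pooled Solitary row.

    ``scores`` needs columns ``tank_id``, ``category``, ``pc1_size``,
    ``pc1_shape``.  ``census`` is an optional list of
    :class:`~cannorm.landmark_io.CensusRecord` providing x1/x2 per tank;
    without it the x columns are filled with the per-tank cannibal label count
    and zero victims.  Tanks with fewer than 3 scored survivors are excluded
    with a warning.
    """
    required = {"tank_id", "category", "pc1_size", "pc1_shape"}
    if not required <= set(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")
    census_map = {}
    if census is not None:
        census_map = {c.tank_id: (c.x1, c.x2) for c in census}

    out: list[PopulationSummary] = []
    sol_mask = scores["category"] == solitary_label
    groups = [(sol_id, scores[sol_mask])] + [
        (tid, grp) for tid, grp in scores[~sol_mask].groupby("tank_id", sort=True)
    ]
    for tid, grp in groups:
        if len(grp) < 3:
            warnings.warn(f"tank {tid}: fewer than 3 scored specimens, excluded")
            continue
        y1 = float(np.corrcoef(grp["pc1_size"], grp["pc1_shape"])[0, 1])
        y2 = skewness(grp["pc1_size"], bias_corrected=bias_corrected)
        y3 = skewness(grp["pc1_shape"], bias_corrected=bias_corrected)
        if tid == sol_id:
            x1, x2 = 0, 0
        elif tid in census_map:
            x1, x2 = census_map[tid]
        else:
            x1, x2 = int((grp["category"] == "Cannibal").sum()), 0
        out.append(PopulationSummary(tank_id=str(tid), x1=x1, x2=x2, y1=y1, y2=y2, y3=y3))
    return out


def summaries_to_blocks(summaries) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Return (frame, X block (x1,x2), Y block (y1,y2,y3)) from summaries."""
    df = pd.DataFrame(
        [
            dict(tank_id=s.tank_id, x1=s.x1, x2=s.x2, y1=s.y1, y2=s.y2, y3=s.y3)
            for s in summaries
        ]
    )
    return df, df[["x1", "x2"]].to_numpy(float), df[["y1", "y2", "y3"]].to_numpy(float)


def census_correlation_suite(summaries, n_perm: int = 10_000, seed=None) -> dict:
    """The nine census-vs-distribution statistics with permutation p-values.

    Keys: ``rv_X_Y``, ``r_pls1_X_Y``, ``rv_x1_Y``, ``r_pls1_x1_Y``,
    ``rv_x2_Y``, ``r_pls1_x2_Y``, ``r_x2_y1``, ``r_x2_y2``, ``r_x2_y3``.
    Each value is a dict with the statistic and (when ``n_perm > 0``) its
    permutation p; Pearson entries also carry the closed-form t and df.
    """
    df, X, Y = summaries_to_blocks(summaries)
    if len(df) < 4:
        raise ValueError("need at least 4 populations")
    x1 = X[:, [0]]
    x2 = X[:, [1]]
    rng = np.random.default_rng(seed)

    def _sub():
        return int(rng.integers(0, 2**31 - 1))

    out: dict[str, dict] = {}
    for key, block in (("X", X), ("x1", x1), ("x2", x2)):
        rv = rv_permutation_test(block, Y, n=n_perm, seed=_sub()) if n_perm else None
        pls = two_block_pls(block, Y, n_perm=n_perm, seed=_sub())
        if rv is None:
            from .integration_stats import escoufier_rv

            rv = escoufier_rv(block, Y)
        out[f"rv_{key}_Y"] = {"value": rv.rv, "p_value": rv.p_value}
        out[f"r_pls1_{key}_Y"] = {"value": pls.r_pls1, "p_value": pls.p_value}

    for j, yname in enumerate(("y1", "y2", "y3")):
        res = pearson_test(x2[:, 0], Y[:, j])
        p_perm = None
        if n_perm:
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(len(df))
                rp = np.corrcoef(x2[:, 0], Y[perm, j])[0, 1]
                if abs(rp) >= abs(res.r):
                    exceed += 1
            p_perm = (exceed + 1) / (n_perm + 1)
        out[f"r_x2_{yname}"] = {
            "value": res.r,
            "t": res.t,
            "df": res.df,
            "p_value": p_perm if p_perm is not None else res.p_value,
        }
    return out


# ---------------------------------------------------------------------------
# Planned-contrast ANOVA


def anova_planned_contrasts(
    values,
    population,
    victims,
    solitary_id: str = "sol",
    decomposition: str = "regression",
) -> ContrastAnovaTable:
    """One-way ANOVA across victim-count-keyed populations with planned contrasts.

    ``values`` are specimen scores, ``population`` their population ids and
    ``victims`` the per-specimen victim count of their population (0 for the
    Solitary pseudo-population).  The among-group sum of squares is decomposed
    as:

    * ``decomposition="regression"``: a group-size-weighted linear regression
      of group means on victim count (1 df) plus the deviation from that
      regression (g - 2 df).  The regression term is tested against the
      deviation mean square; all other terms against the within-group mean
      square.
    * ``decomposition="nonzero"``: variation among the nonzero-victim groups
      (g - 2 df) as the remainder after the Solitary-vs-rest contrast.

    The 1-df Solitary-vs-pooled-others contrast is reported in both modes.
    SS additivity of each decomposition is exact by construction.
    """
    v = np.asarray(values, dtype=float)
    pop = np.asarray(population)
    vic = np.asarray(victims, dtype=float)
    if not (len(v) == len(pop) == len(vic)):
        raise ValueError("values, population and victims must align")
    groups = sorted(set(pop.tolist()), key=lambda g: (g != solitary_id, g))
    g = len(groups)
    if g < 3:
        raise ValueError("need at least 3 populations")
    if len({vic[pop == grp][0] for grp in groups if grp != solitary_id}) < 2:
        raise ValueError("need at least 2 distinct nonzero victim counts")

    n = len(v)
    grand = v.mean()
    ns = np.array([(pop == grp).sum() for grp in groups], float)
    if ns.min() < 2:
        raise ValueError("each population needs at least 2 specimens")
    means = np.array([v[pop == grp].mean() for grp in groups])
    xg = np.array([vic[pop == grp][0] for grp in groups])

    ss_among = float(np.sum(ns * (means - grand) ** 2))
    df_among = g - 1
    ss_within = float(sum(((v[pop == grp] - m) ** 2).sum() for grp, m in zip(groups, means)))
    df_within = n - g
    ms_within = ss_within / df_within

    # 1-df contrast: Solitary vs pooled others, as the between-group SS of the
    # two-way split {solitary} vs {rest}
    sol_mask = pop == solitary_id
    m_sol, n_sol = v[sol_mask].mean(), sol_mask.sum()
    m_rest, n_rest = v[~sol_mask].mean(), (~sol_mask).sum()
    ss_sol = float(n_sol * (m_sol - grand) ** 2 + n_rest * (m_rest - grand) ** 2)

    rows = [
        ("Among groups", ss_among, df_among, ss_among / df_among, (ss_among / df_among) / ms_within, df_among, df_within),
        ("Solitary vs rest", ss_sol, 1, ss_sol, ss_sol / ms_within, 1, df_within),
    ]

    if decomposition == "regression":
        # group-size-weighted regression of group means on victim count
        xw = np.sum(ns * xg) / ns.sum()
        sxx = np.sum(ns * (xg - xw) ** 2)
        sxm = np.sum(ns * (xg - xw) * (means - grand))
        ss_reg = float(sxm**2 / sxx)
        ss_dev = ss_among - ss_reg
        df_dev = df_among - 1
        ms_dev = ss_dev / df_dev
        rows.append(("Regression slope", ss_reg, 1, ss_reg, ss_reg / ms_dev, 1, df_dev))
        rows.append(("Deviation from regression", ss_dev, df_dev, ms_dev, ms_dev / ms_within, df_dev, df_within))
    elif decomposition == "nonzero":
        ss_nz = ss_among - ss_sol
        df_nz = df_among - 1
        ms_nz = ss_nz / df_nz
        rows.append(("Among nonzero victim groups", ss_nz, df_nz, ms_nz, ms_nz / ms_within, df_nz, df_within))
    else:
        raise ValueError(f"unknown decomposition {decomposition!r}")

    rows.append(("Within groups", ss_within, df_within, ms_within, np.nan, np.nan, np.nan))

    table = pd.DataFrame(
        rows, columns=["source", "SS", "df", "MS", "F", "df_num", "df_den"]
    )
    table["p"] = [
        float(sps.f.sf(f, dn, dd)) if np.isfinite(f) else np.nan
        for f, dn, dd in zip(table["F"], table["df_num"], table["df_den"])
    ]
    return ContrastAnovaTable(rows=table)
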