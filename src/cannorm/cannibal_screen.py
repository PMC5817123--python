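"""Classify survivors into cannibal / non-cannibal morphs from body dimensions.

Two hard visual criteria seed the classification: a conspecific visible in the
stomach (unambiguous) and the enlarged-jaw/large-body visual call.  A
semi-supervised linear-discriminant self-training classifier then propagates
those seed labels through the remaining specimens using the seven head
dimensions, SVL, and the ratios JW1/HW and HW/SVL as features.  When no seed
labels exist at all, the classical jaw-width/head-width ratio rule
(JW1/HW > 0.9, strict) is applied instead.

The classifier backend is pluggable: any object with sklearn-style
``fit(X, y)`` / ``predict_proba(X)`` can replace the default LDA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .landmark_io import MeasurementRecord

__all__ = ["ScreenResult", "ratio_criterion", "screen_population"]

FEATURES = ["HW", "JW1", "JW2", "EW", "HL1", "HL2", "HL3", "SVL"]


@dataclass
class ScreenResult:
    specimen_id: str
    label: str  # "cannibal" | "noncannibal"
    score: float  # classifier cannibal probability (or 0/1 for rule-based calls)
    basis: str  # "stomach" | "visual" | "ratio" | "classifier"


def ratio_criterion(record: MeasurementRecord, which_jaw: str = "JW1") -> bool:
    """Jaw-width/head-width rule: True iff JW/HW > 0.9 (strict)."""
    jw = getattr(record, which_jaw)
    if record.HW <= 0:
        raise ValueError("HW must be positive")
    return jw / record.HW > 0.9


def _feature_matrix(records) -> np.ndarray:
    base = np.array([[getattr(r, f) for f in FEATURES] for r in records], dtype=float)
    ratios = np.column_stack([base[:, 1] / base[:, 0], base[:, 0] / base[:, 7]])
    return np.column_stack([base, ratios])


def screen_population(
    records,
    classifier=None,
    max_rounds: int = 20,
    which_jaw: str = "JW1",
) -> list[ScreenResult]:
    """Label every record cannibal/noncannibal.

    Specimens flagged ``stomach_conspecific`` or ``visual_cannibal`` are fixed
    cannibal seeds.  If any seed exists, self-training starts from the seeds
    plus provisional ratio-rule calls (which may flip later) and iterates an
    LDA classifier until the label assignment is stable or ``max_rounds`` is
    reached; seed labels never flip.  Without seeds the ratio rule alone
    decides every specimen.
    """
    records = list(records)
    if len(records) < 5:
        raise ValueError("need at least 5 records to screen a population")
    X = _feature_matrix(records)
    if np.allclose(X, X[0]):
        raise ValueError("all records identical: nothing to discriminate")

    seeds = np.array(
        [r.stomach_conspecific or r.visual_cannibal for r in records], dtype=bool
    )
    basis_seed = [
        "stomach" if r.stomach_conspecific else ("visual" if r.visual_cannibal else "")
        for r in records
    ]

    if not seeds.any():
        return [
            ScreenResult(
                specimen_id=r.specimen_id,
                label="cannibal" if ratio_criterion(r, which_jaw) else "noncannibal",
                score=1.0 if ratio_criterion(r, which_jaw) else 0.0,
                basis="ratio",
            )
            for r in records
        ]

    # standardize features for numerical stability of the discriminant
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    # initial provisional labels: hard seeds plus the classical ratio rule
    # (provisional calls may flip during self-training; seeds may not)
    labels = seeds | np.array([ratio_criterion(r, which_jaw) for r in records])
    # balanced priors: seeds are a sparse, biased sample of the cannibal class,
    # so class-frequency priors would anchor the boundary at the seed rate
    clf = classifier if classifier is not None else LinearDiscriminantAnalysis(
        priors=[0.5, 0.5]
    )
    proba = labels.astype(float)
    for _ in range(max_rounds):
        if labels.all() or not labels.any():
            break
        clf.fit(Z, labels.astype(int))
        proba = clf.predict_proba(Z)[:, 1]
        new = proba > 0.5
        new[seeds] = True  # hard evidence never flips
        if np.array_equal(new, labels):
            labels = new
            break
        labels = new

    out = []
    for i, r in enumerate(records):
        out.append(
            ScreenResult(
                specimen_id=r.specimen_id,
                label="cannibal" if labels[i] else "noncannibal",
                score=float(proba[i]) if not seeds[i] else 1.0,
                basis=basis_seed[i] or "classifier",
            )
        )
    return out
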