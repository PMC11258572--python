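"""Scoring of the three clinical outcome instruments and change variables.

RPQ: 16 symptom items rated 0-4; total 0 (no symptoms) to 64 (worst), with
a three-factor split into somatic / emotional / cognitive subscores.  Items
rated above 1 qualify as post-concussive symptoms.

BTACT: six cognitive subtests; each raw score is standardized against
normative means/SDs and the composite is the mean of the six subtest
z-scores.  The shipped norms are synthetic placeholders (see data file).

GOSE: 8-point global outcome scale dichotomized into recovered (= 8) vs
non-recovered (<= 7).

Rates of change are signed differences between visits divided by the days
between them; a true absolute-value mode is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "RPQ_ITEMS",
    "BTACT_SUBTESTS",
    "RPQScores",
    "BTACTScores",
    "RecoveryStatus",
    "load_rpq_factors",
    "load_btact_norms",
    "score_rpq",
    "score_btact",
    "dichotomize_gose",
    "rate_of_change",
]


def _load_yaml(name: str) -> dict:
    with resources.files("natsc.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def load_rpq_factors() -> tuple[list[str], dict[str, list[str]]]:
    """Item order and factor membership; factor membership is data, not code."""
    cfg = _load_yaml("rpq_factors.yaml")
    items, factors = cfg["items"], cfg["factors"]
    assigned = [it for members in factors.values() for it in members]
    if sorted(assigned) != sorted(items):
        raise ValueError("RPQ factor map must assign every item exactly once")
    return items, factors


def load_btact_norms(path=None) -> dict[str, dict[str, float]]:
    if path is None:
        cfg = _load_yaml("btact_norms_synthetic.yaml")
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    norms = cfg["subtests"]
    for name, ms in norms.items():
        if ms["sd"] <= 0:
            raise ValueError(f"normative SD for {name} must be positive")
    return norms


RPQ_ITEMS, RPQ_FACTORS = load_rpq_factors()
BTACT_SUBTESTS = list(load_btact_norms().keys())


@dataclass(frozen=True)
class RPQScores:
    total: int
    somatic: int
    emotional: int
    cognitive: int
    qualifying_items: frozenset[int]   # 0-based indices with score > 1

    def __post_init__(self) -> None:
        if not 0 <= self.total <= 64:
            raise ValueError("RPQ total outside 0-64")
        if self.cognitive > 12 or self.emotional > 16:
            raise ValueError("RPQ subscore exceeds its factor maximum")
        if self.somatic + self.emotional + self.cognitive != self.total:
            raise ValueError("RPQ subscores must sum to the total")


@dataclass(frozen=True)
class BTACTScores:
    subtest_z: dict[str, float]
    composite_z: float


@dataclass(frozen=True)
class RecoveryStatus:
    recovered: bool


def score_rpq(items) -> RPQScores:
    """Total, three-factor subscores and qualifying-item set for 16 items."""
    arr = np.asarray(items)
    if arr.shape != (16,):
        raise ValueError("RPQ requires exactly 16 item scores")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise ValueError("RPQ items must be integers")
        arr = arr.astype(int)
    if arr.min() < 0 or arr.max() > 4:
        raise ValueError("RPQ items must be in 0-4")

    idx = {name: i for i, name in enumerate(RPQ_ITEMS)}
    sub = {
        fac: int(sum(arr[idx[name]] for name in members))
        for fac, members in RPQ_FACTORS.items()
    }
    return RPQScores(
        total=int(arr.sum()),
        somatic=sub["somatic"],
        emotional=sub["emotional"],
        cognitive=sub["cognitive"],
        qualifying_items=frozenset(int(i) for i in np.nonzero(arr > 1)[0]),
    )


def score_btact(
    raw: dict[str, float],
    norms: dict[str, dict[str, float]] | None = None,
    impute_policy: str | None = None,
) -> BTACTScores:
    """Subtest z-scores vs norms; composite = mean of the six z-scores.

    Missing subtests (absent key or NaN) leave the composite undefined
    unless ``impute_policy='mean_available'``, which averages the z-scores
    that are present.
    """
    if norms is None:
        norms = load_btact_norms()
    z: dict[str, float] = {}
    for name, ms in norms.items():
        val = raw.get(name)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            z[name] = float("nan")
        else:
            z[name] = (float(val) - ms["mean"]) / ms["sd"]
    zs = np.array(list(z.values()))
    present = np.isfinite(zs)
    if present.all():
        composite = float(zs.mean())
    elif impute_policy == "mean_available" and present.any():
        composite = float(zs[present].mean())
    else:
        composite = float("nan")
    return BTACTScores(subtest_z=z, composite_z=composite)


def dichotomize_gose(gose: int) -> RecoveryStatus:
    """Recovered iff GOSE equals 8; 3-7 are non-recovered."""
    if not (isinstance(gose, (int, np.integer)) or float(gose).is_integer()):
        raise ValueError("GOSE must be an integer")
    g = int(gose)
    if not 3 <= g <= 8:
        raise ValueError("GOSE must be in 3-8")
    return RecoveryStatus(recovered=(g == 8))


def rate_of_change(
    value_late: float, value_early: float, days_between: float, absolute: bool = False
) -> float:
    """Per-day change between two visits (signed by default)."""
    if days_between <= 0:
        raise ValueError("days_between must be positive")
    rate = (value_late - value_early) / days_between
    return abs(rate) if absolute else rate
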