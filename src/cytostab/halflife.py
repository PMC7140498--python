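"""Half-life estimation from substrate-depletion time courses and stability rules.

The assay incubates 1 µM compound with liver cytosol fractions at 37 °C,
measures % parent remaining at 0, 5, 10, 15, 30 and 60 min, and estimates the
in vitro half-life by the substrate-depletion method: first-order decay is
assumed, ln(remaining%) is regressed on time, and t½ = ln 2 / k with
k = −slope. Half-lives beyond 120 min cannot be extrapolated by the assay and
are reported capped at ">120".

Classification thresholds:

* unstable  ⇔ t½ ≤ 30 min (not capped); stable otherwise
* substrate ⇔ t½ < 60 min (not capped) — used for composition summaries
* pair shift: fold = right/left; ≥1.5-fold up → positive, ≥1.5-fold down →
  negative, both members capped → inconclusive, anything else → no shift
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from scipy import stats

CAP_MINUTES = 120.0
UNSTABLE_THRESHOLD = 30.0  # minutes, inclusive
SUBSTRATE_THRESHOLD = 60.0  # minutes, strict
SHIFT_FOLD = 1.5  # symmetric no-shift band
DEFAULT_TIMES = (0.0, 5.0, 10.0, 15.0, 30.0, 60.0)

AMIDE_SMARTS = Chem.MolFromSmarts("[CX3](=O)[NX3]")
ESTER_SMARTS = Chem.MolFromSmarts("[CX3](=O)O[#6]")


class HalfLifeEstimationError(ValueError):
    """Raised when a depletion time course cannot support a half-life fit."""


@dataclass(frozen=True)
class HalfLife:
    """A fitted in vitro half-life in minutes; ``capped`` means ">120"."""

    value: float
    capped: bool = False

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError(f"half-life must be positive, got {self.value}")
        if self.capped and self.value != CAP_MINUTES:
            raise ValueError("capped half-life must equal the 120 min cap")


@dataclass(frozen=True)
class ShiftCategory:
    """Categorized change in t½ from the left to the right member of a pair."""

    label: str  # positive | negative | no_shift | inconclusive
    fold_change: float  # right/left ratio, capped values entering as 120

    LABELS = ("positive", "negative", "no_shift", "inconclusive")

    def __post_init__(self):
        if self.label not in self.LABELS:
            raise ValueError(f"unknown shift label {self.label!r}")


@dataclass(frozen=True)
class DepletionTimeCourse:
    """% parent remaining on the fixed incubation grid (minutes)."""

    times: tuple[float, ...] = DEFAULT_TIMES
    remaining: tuple[float, ...] = ()

    def __post_init__(self):
        if len(self.times) != len(self.remaining):
            raise ValueError("times and remaining must have equal length")
        t = np.asarray(self.times)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")
        if np.sum(np.isfinite(self.remaining)) < 3:
            raise ValueError("need at least 3 finite remaining values")


def fit_half_life(tc: DepletionTimeCourse) -> HalfLife:
    """Log-linear OLS substrate-depletion estimate of the half-life.

    Points with remaining ≤ 1% are excluded (log blow-up guard) provided at
    least 3 points survive the exclusion. If depletion is absent or slower
    than the assay window resolves (k ≤ 0 or t½ > 120 min) the result is
    capped at 120 min.
    """
    t = np.asarray(tc.times, dtype=float)
    r = np.asarray(tc.remaining, dtype=float)
    usable = np.isfinite(r) & (r > 0)
    if r[0] <= 0 or not np.isfinite(r[0]):
        raise HalfLifeEstimationError("remaining at t=0 must be positive")
    if not np.any(usable & (t > 0)):
        raise HalfLifeEstimationError("no positive remaining value at t > 0")
    if usable.sum() < 3:
        raise HalfLifeEstimationError("fewer than 3 usable points")
    keep = usable & (r > 1.0)
    if keep.sum() < 3:
        keep = usable
    slope = stats.linregress(t[keep], np.log(r[keep])).slope
    k = -slope
    if k <= 0:
        return HalfLife(CAP_MINUTES, True)
    t_half = math.log(2) / k
    if t_half > CAP_MINUTES:
        return HalfLife(CAP_MINUTES, True)
    return HalfLife(t_half, False)


def classify_stability(h: HalfLife) -> str:
    """Binary stability class: unstable ⇔ t½ ≤ 30 min and not capped."""
    return "unstable" if (not h.capped and h.value <= UNSTABLE_THRESHOLD) else "stable"


def is_substrate(h: HalfLife) -> bool:
    """Substrate of the cytosolic enzymes ⇔ t½ < 60 min and not capped."""
    return (not h.capped) and h.value < SUBSTRATE_THRESHOLD


def classify_pair_shift(left: HalfLife, right: HalfLife) -> ShiftCategory:
    """Categorize the left→right t½ change of a matched pair.

    Both members capped → inconclusive (the assay cannot resolve a change
    beyond its 120 min ceiling); otherwise capped values enter the fold ratio
    as 120. The no-shift band is symmetric at 1.5-fold.
    """
    if left.capped and right.capped:
        return ShiftCategory("inconclusive", 1.0)
    fold = right.value / left.value
    if fold >= SHIFT_FOLD:
        return ShiftCategory("positive", fold)
    if fold <= 1.0 / SHIFT_FOLD:
        return ShiftCategory("negative", fold)
    return ShiftCategory("no_shift", fold)


def round_percent(numerator: int, denominator: int) -> float:
    """Percentage with half-up rounding to one decimal (table convention)."""
    if denominator == 0:
        return 0.0
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_dataset(records: Sequence) -> dict:
    """Composition summary of a deduplicated single-species record set.

    Reports total n, unstable count/percentage, substrate (t½ < 60 min)
    count, and amide/ester substructure matches among the substrates —
    the functional groups pointing at amidase/esterase versus AO/XO routes.
    """
    n = len(records)
    n_unstable = sum(1 for r in records if r.stability_class == "unstable")
    substrates = [r for r in records if is_substrate(r.half_life)]
    n_amide = 0
    n_ester = 0
    for r in substrates:
        mol = Chem.MolFromSmiles(r.smiles_std)
        if mol is None:
            continue
        if mol.HasSubstructMatch(AMIDE_SMARTS):
            n_amide += 1
        if mol.HasSubstructMatch(ESTER_SMARTS):
            n_ester += 1
    return {
        "n_total": n,
        "n_unstable": n_unstable,
        "pct_unstable": round_percent(n_unstable, n),
        "n_substrates": len(substrates),
        "n_amide_substrates": n_amide,
        "pct_amide_substrates": round_percent(n_amide, len(substrates)),
        "n_ester_substrates": n_ester,
        "pct_ester_substrates": round_percent(n_ester, len(substrates)),
    }


def read_timecourses_csv(path: str | Path) -> dict[str, DepletionTimeCourse]:
    """Read long-format `id,t_min,pct_remaining` time courses."""
    rows: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.setdefault(row["id"], []).append(
                (float(row["t_min"]), float(row["pct_remaining"]))
            )
    out = {}
    for cid, pts in rows.items():
        pts.sort()
        out[cid] = DepletionTimeCourse(
            times=tuple(p[0] for p in pts), remaining=tuple(p[1] for p in pts)
        )
    return out
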