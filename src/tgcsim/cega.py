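"""Clarke error-grid analysis (C-EGA).

Classifies paired (reference, estimated) glucose values into the five
clinical-accuracy zones of Clarke et al. (1987):

* **A** -- accurate: within 20% of reference, or both hypoglycemic (<70 mg/dL);
* **B** -- benign error: outside 20% but not leading to inappropriate treatment;
* **C** -- overcorrection of acceptable glucose levels;
* **D** -- dangerous failure to detect hypo- or hyperglycemia;
* **E** -- erroneous treatment (confusing hypo- and hyperglycemia).

Zones A+B are conventionally "clinically acceptable". The zone geometry
is evaluated in mg/dL (1 mmol/L = 18.016 mg/dL); classification is unit
invariant. Boundary overlaps are resolved by the precedence
A > E > C > D > B (ties go to the better-defined zone), with all
inequalities non-strict; the non-strict comparisons carry a 1e-6 mg/dL
tolerance so points mathematically on a zone boundary classify
inclusively regardless of floating-point conversion error.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .units import MG_DL_PER_MMOL_L

__all__ = [
    "EgaZone",
    "EgaSummary",
    "classify",
    "classify_mg_dl",
    "classify_batch",
    "acceptable",
    "summarize",
    "round_half_up",
    "plot_grid",
]

ZONES = ("A", "B", "C", "D", "E")

#: tolerance (mg/dL) making boundary membership robust to float conversion
_BOUNDARY_TOL = 1e-6


class EgaZone(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"


def classify_mg_dl(r: float, e: float) -> EgaZone:
    """Classify a (reference, estimate) pair given in mg/dL."""
    if r <= 0 or e <= 0:
        raise ValueError("glucose values must be positive")
    tol = _BOUNDARY_TOL
    # A: within 20% of reference, or both in the hypoglycemic corner
    if abs(e - r) <= 0.2 * r + tol or (r < 70 and e < 70):
        return EgaZone.A
    # E: hypo read as hyper or vice versa
    if (r <= 70 + tol and e >= 180 - tol) or (r >= 180 - tol and e <= 70 + tol):
        return EgaZone.E
    # C: overcorrection regions
    if (70 - tol <= r <= 290 + tol and e >= r + 110 - tol) or (
        130 - tol <= r <= 180 + tol and e <= (7.0 / 5.0) * r - 182 + tol
    ):
        return EgaZone.C
    # D: failure to detect hypo- or hyperglycemia
    if (r >= 240 - tol and 70 - tol <= e <= 180 + tol) or (
        r <= 70 + tol and 70 - tol <= e <= 180 + tol
    ):
        return EgaZone.D
    return EgaZone.B


def classify(reference_mmol_l: float, estimate_mmol_l: float) -> EgaZone:
    """Classify a (reference, estimate) pair given in mmol/L."""
    if reference_mmol_l <= 0 or estimate_mmol_l <= 0:
        raise ValueError("glucose values must be positive")
    return classify_mg_dl(
        reference_mmol_l * MG_DL_PER_MMOL_L, estimate_mmol_l * MG_DL_PER_MMOL_L
    )


def classify_batch(
    reference_mmol_l: np.ndarray, estimate_mmol_l: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`classify`; returns an array of zone letters."""
    r = np.asarray(reference_mmol_l, dtype=float) * MG_DL_PER_MMOL_L
    e = np.asarray(estimate_mmol_l, dtype=float) * MG_DL_PER_MMOL_L
    if np.any(r <= 0) or np.any(e <= 0):
        raise ValueError("glucose values must be positive")
    tol = _BOUNDARY_TOL
    zone_a = (np.abs(e - r) <= 0.2 * r + tol) | ((r < 70) & (e < 70))
    zone_e = ((r <= 70 + tol) & (e >= 180 - tol)) | ((r >= 180 - tol) & (e <= 70 + tol))
    zone_c = ((r >= 70 - tol) & (r <= 290 + tol) & (e >= r + 110 - tol)) | (
        (r >= 130 - tol) & (r <= 180 + tol) & (e <= (7.0 / 5.0) * r - 182 + tol)
    )
    zone_d = ((r >= 240 - tol) & (e >= 70 - tol) & (e <= 180 + tol)) | (
        (r <= 70 + tol) & (e >= 70 - tol) & (e <= 180 + tol)
    )
    return np.select([zone_a, zone_e, zone_c, zone_d], ["A", "E", "C", "D"], default="B")


def acceptable(zone: EgaZone | str) -> bool:
    """True iff the zone is clinically acceptable (A or B)."""
    return EgaZone(zone) in (EgaZone.A, EgaZone.B)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero, as printed percentages are."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EgaSummary:
    """Zone counts and percentages over a set of paired points."""

    n_pairs: int
    counts: Mapping[str, int]
    percents: Mapping[str, float]
    acceptable_percent: float

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "counts": dict(self.counts),
            "percents": dict(self.percents),
            "acceptable_percent": self.acceptable_percent,
        }


def summarize(
    pairs: Iterable[tuple[float, float] | EgaZone | str],
) -> EgaSummary:
    """Summarize paired points (or pre-classified zones) into zone statistics.

    Accepts an iterable of ``(reference, estimate)`` mmol/L pairs, or of
    zone labels for worked-arithmetic use. Percentages are computed from
    the exact counts and rounded half-up to one decimal.
    """
    items = list(pairs)
    if not items:
        raise ValueError("summarize requires at least one pair")
    counts = {z: 0 for z in ZONES}
    for item in items:
        if isinstance(item, (EgaZone, str)):
            zone = EgaZone(item)
        else:
            zone = classify(item[0], item[1])
        counts[zone.value] += 1
    n = len(items)
    percents = {z: round_half_up(100.0 * c / n) for z, c in counts.items()}
    acceptable_pct = round_half_up(100.0 * (counts["A"] + counts["B"]) / n)
    return EgaSummary(
        n_pairs=n, counts=counts, percents=percents, acceptable_percent=acceptable_pct
    )


def plot_grid(reference_mmol_l, estimate_mmol_l, ax=None, units: str = "mmol/L"):
    """Scatter paired points on the Clarke grid with zone boundary lines."""
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    r = np.asarray(reference_mmol_l, dtype=float)
    e = np.asarray(estimate_mmol_l, dtype=float)
    scale = 1.0 if units == "mg/dL" else 1.0 / MG_DL_PER_MMOL_L
    lim = 400 * scale
    # zone boundary segments in mg/dL, scaled into requested units
    segs = [
        [(0, 0), (400, 400)],
        [(58.33, 70), (400, 480)],  # e = 1.2 r
        [(70, 56), (400, 320)],  # e = 0.8 r
        [(70, 0), (70, 56)],
        [(0, 70), (58.33, 70)],
        [(70, 180), (290, 400)],  # upper C boundary e = r + 110
        [(130, 0), (180, 70)],  # lower C boundary e = 1.4 r - 182
        [(0, 180), (70, 180)],
        [(240, 70), (400, 70)],
        [(240, 70), (240, 180)],
        [(240, 180), (400, 180)],
        [(70, 70), (70, 180)],  # left D box right edge
        [(70, 180), (0, 180)],
        [(180, 0), (180, 70)],
    ]
    for seg in segs:
        (x0, y0), (x1, y1) = seg
        ax.plot(
            [x0 * scale, x1 * scale],
            [y0 * scale, y1 * scale],
            color="0.6",
            lw=0.8,
            zorder=1,
        )
    if units == "mg/dL":
        ax.scatter(r * MG_DL_PER_MMOL_L, e * MG_DL_PER_MMOL_L, s=12, zorder=2)
        ax.set_xlabel("reference glucose (mg/dL)")
        ax.set_ylabel("CGM glucose (mg/dL)")
    else:
        ax.scatter(r, e, s=12, zorder=2)
        ax.set_xlabel("reference glucose (mmol/L)")
        ax.set_ylabel("CGM glucose (mmol/L)")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_aspect("equal")
    return ax
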