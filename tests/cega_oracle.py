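"""Independent brute-force Clarke-grid oracle.

Builds the five zone regions as explicit polygons (in mg/dL) and
classifies points by point-in-polygon membership with the same
precedence (A > E > C > D > B) and inclusive boundaries as the
classifier under test. Entirely separate code path: geometry predicates
come from shapely, not from the package's inequality logic.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

MG_PER_MMOL = 18.016
_M = 2000.0  # generous outer bound, mg/dL
_EPS = 1e-6  # inclusive-boundary buffer, mg/dL


def zone_polygons() -> dict[str, shapely.Geometry]:
    a = unary_union(
        [Polygon([(0, 0), (_M, 0.8 * _M), (_M, 1.2 * _M)]), box(0, 0, 70, 70)]
    )
    e = unary_union([box(0, 180, 70, _M), box(180, 0, _M, 70)])
    c = unary_union(
        [
            Polygon([(70, 180), (290, 400), (290, _M), (70, _M)]),
            Polygon([(130, 0), (180, 0), (180, 70)]),
        ]
    )
    d = unary_union([box(240, 70, _M, 180), box(0, 70, 70, 180)])
    return {z: poly.buffer(_EPS) for z, poly in (("A", a), ("E", e), ("C", c), ("D", d))}


def oracle_classify(ref_mmol_l: np.ndarray, est_mmol_l: np.ndarray) -> np.ndarray:
    """Zone letters for paired mmol/L points via polygon membership."""
    polys = zone_polygons()
    pts = shapely.points(
        np.asarray(ref_mmol_l, dtype=float) * MG_PER_MMOL,
        np.asarray(est_mmol_l, dtype=float) * MG_PER_MMOL,
    )
    conds = [shapely.covers(polys[z], pts) for z in ("A", "E", "C", "D")]
    return np.select(conds, ["A", "E", "C", "D"], default="B")
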