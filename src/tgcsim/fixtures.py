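"""Deterministic fixture generation: canned traces, a cohort, C-EGA pairs.

Everything here is synthetic and produced by the package's own
generators; fixed seed in, byte-identical files out.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cega import classify
from .config import save_cohort
from .patient import make_cohort

__all__ = ["generate_fixtures"]


def _write_trace(path: Path, t: np.ndarray, g: np.ndarray) -> None:
    df = pd.DataFrame({"t_min": t.astype(int), "g_mmol_l": g})
    df.to_csv(path, index=False, float_format="%.6f")


def generate_fixtures(seed: int, out_dir: str | Path) -> list[Path]:
    """Write the fixture set into ``out_dir``; returns the file paths.

    * ``constant_trace.csv`` -- 24 h at 5.0 mmol/L;
    * ``step_trace.csv`` -- 12 h at 7.0 then 12 h at 5.0 mmol/L;
    * ``ramp_trace.csv`` -- linear 8.0 -> 4.0 mmol/L over 24 h;
    * ``cohort.json`` -- a 12-patient synthetic cohort;
    * ``cega_pairs.csv`` -- paired points covering every Clarke zone.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    t = np.arange(0, 1441, 5)

    p = out / "constant_trace.csv"
    _write_trace(p, t, np.full_like(t, 5.0, dtype=float))
    written.append(p)

    p = out / "step_trace.csv"
    g = np.where(t < 720, 7.0, 5.0).astype(float)
    _write_trace(p, t, g)
    written.append(p)

    p = out / "ramp_trace.csv"
    _write_trace(p, t, 8.0 - 4.0 * t / 1440.0)
    written.append(p)

    p = out / "cohort.json"
    save_cohort(make_cohort(12, seed), p)
    written.append(p)

    # one hand-picked pair per zone, verified through the classifier,
    # plus a seeded cloud of near-identity points
    anchors = [
        (5.5, 5.5),  # A
        (10.0, 12.1),  # B
        (4.0, 11.0),  # C
        (3.3, 6.7),  # D
        (2.8, 10.5),  # E
    ]
    zones = [classify(r, e).value for r, e in anchors]
    assert sorted(zones) == ["A", "B", "C", "D", "E"], zones
    rng = np.random.default_rng(seed)
    ref = rng.uniform(3.0, 12.0, size=25)
    est = ref * rng.normal(1.0, 0.08, size=25)
    rows = anchors + list(zip(ref.round(3), est.round(3)))
    p = out / "cega_pairs.csv"
    pd.DataFrame(rows, columns=["reference_mmol_l", "estimate_mmol_l"]).to_csv(
        p, index=False, float_format="%.3f"
    )
    written.append(p)
    return written
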