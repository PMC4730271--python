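"""Charge-hydropathy / CDF (CH-CDF) classification of whole proteins.

Two binary classifiers are combined per protein:

- the CH-plot, a linear boundary in mean-net-charge vs mean-hydropathy space
  separating extended disordered proteins (above the line) from compact ones;
- the CDF analysis, which compares the cumulative distribution of a protein's
  per-residue disorder scores against a fixed boundary curve; proteins whose
  curve lies above the boundary (many low-scoring residues) are called
  ordered.

Each protein becomes a point (x = signed mean CDF distance, y = signed CH
distance) and falls in one of four quadrants: Q1 (CDF-ordered,
CH-disordered), Q2 (ordered by both), Q3 (CH-compact, CDF-disordered —
putative molten globules / hybrids), Q4 (disordered by both — extended
IDPs).  Points exactly on a boundary are assigned to the ordered side of
that axis so the partition is deterministic.

The boundary parameters are data, not code: they ship in
``config/default_boundaries.yaml`` and are overridable everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import isfinite
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

#: side-chain charge at neutral pH; histidine treated as neutral
RESIDUE_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}

#: width of the hydropathy smoothing window (centred, truncated at the ends)
HYDROPATHY_WINDOW = 5


@dataclass
class CHBoundary:
    """Line <R> = slope * <H> + intercept in charge-hydropathy space."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"CH boundary slope must be positive, got {self.slope}")


@dataclass
class CDFBoundary:
    """Ordered (score_threshold, boundary_fraction) pairs defining the CDF boundary."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(f)) for t, f in self.points)
        if len(pts) < 2:
            raise ValueError("CDF boundary needs at least 2 points")
        thresholds = [t for t, _ in pts]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("CDF boundary thresholds must be strictly increasing")
        for t, f in pts:
            if not (0 <= t <= 1 and 0 <= f <= 1):
                raise ValueError("CDF boundary values must lie in [0, 1]")
        self.points = pts

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.points])


@dataclass
class CHCDFPoint:
    protein_id: str
    x: float  # signed CDF distance; > 0 means CDF calls the protein ordered
    y: float  # signed CH distance; > 0 means the CH-plot calls it extended-disordered
    quadrant: str


def load_boundaries(path: str | Path | None = None) -> tuple[CHBoundary, CDFBoundary]:
    """Load boundary parameters from YAML (``ch: {slope, intercept}``,
    ``cdf: [[threshold, fraction], ...]``); defaults from the packaged config."""
    if path is None:
        text = (
            resources.files("nucdisorder") / "config" / "default_boundaries.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    ch = CHBoundary(slope=float(cfg["ch"]["slope"]), intercept=float(cfg["ch"]["intercept"]))
    cdf = CDFBoundary(points=tuple((float(t), float(f)) for t, f in cfg["cdf"]))
    return ch, cdf


def ch_coordinates(sequence: str, window: int = HYDROPATHY_WINDOW) -> tuple[float, float]:
    """Mean hydropathy (Kyte-Doolittle rescaled to [0,1]) and mean absolute net charge.

    Hydropathy values are rescaled via (h + 4.5) / 9, smoothed over a centred
    window (truncated at the chain ends), then averaged.  'X' residues
    contribute zero charge and the hydropathy midpoint.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    h = np.array([(KYTE_DOOLITTLE.get(a, 0.0) + 4.5) / 9.0 for a in seq])
    q = np.array([RESIDUE_CHARGE.get(a, 0.0) for a in seq])
    # centred moving average with truncated windows at the edges
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(h)))
    idx = np.arange(len(seq))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, len(seq))
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    mean_hydropathy = float(smoothed.mean())
    mean_net_charge = float(abs(q.sum()) / len(seq))
    return mean_hydropathy, mean_net_charge


def ch_distance(sequence: str, boundary: CHBoundary) -> float:
    """Signed vertical distance from the CH boundary; positive above the line."""
    mean_h, mean_q = ch_coordinates(sequence)
    return mean_q - (boundary.slope * mean_h + boundary.intercept)


def cdf_curve(scores: Sequence[float], thresholds: Sequence[float]) -> np.ndarray:
    """Fraction of residues with score <= t, at each threshold t."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score vector")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("scores must lie in [0, 1]")
    t = np.asarray(thresholds, dtype=float)
    return (s[None, :] <= t[:, None]).mean(axis=1)


def cdf_distance(curve: Sequence[float], boundary: CDFBoundary) -> float:
    """Mean signed distance of the protein's CDF curve above the boundary."""
    c = np.asarray(curve, dtype=float)
    if c.size != len(boundary.points):
        raise ValueError(
            f"curve has {c.size} points but the boundary has {len(boundary.points)}"
        )
    return float((c - boundary.fractions).mean())


def classify_quadrant(x: float, y: float) -> str:
    """Quadrant of a CH-CDF point.

    Boundary values go to the ordered side of their axis: x = 0 counts as
    CDF-ordered (like x > 0) and y = 0 as CH-compact (like y < 0), so the
    partition is deterministic.
    """
    if not (isfinite(x) and isfinite(y)):
        raise ValueError(f"non-finite CH-CDF coordinates: x={x}, y={y}")
    if x >= 0:
        return "Q1" if y > 0 else "Q2"
    return "Q4" if y > 0 else "Q3"


def chcdf_point(
    protein_id: str,
    sequence: str,
    scores: Sequence[float],
    ch_boundary: CHBoundary,
    cdf_boundary: CDFBoundary,
) -> CHCDFPoint:
    y = ch_distance(sequence, ch_boundary)
    x = cdf_distance(cdf_curve(scores, cdf_boundary.thresholds), cdf_boundary)
    return CHCDFPoint(protein_id=protein_id, x=x, y=y, quadrant=classify_quadrant(x, y))


def quadrant_fractions(points: Iterable[CHCDFPoint]) -> dict[str, float]:
    """Percentage of a protein group per quadrant, plus the combined Q3+Q4 share."""
    pts = list(points)
    if not pts:
        raise ValueError("cannot compute quadrant fractions of an empty group")
    n = len(pts)
    out = {q: 100.0 * sum(p.quadrant == q for p in pts) / n for q in ("Q1", "Q2", "Q3", "Q4")}
    out["Q3+Q4"] = out["Q3"] + out["Q4"]
    return out
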