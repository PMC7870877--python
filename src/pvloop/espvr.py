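"""Linear and bilinear end-systolic pressure-volume relation (ESPVR) fits,
preload-recruitable stroke work, and phase landmarks.

The bilinear ESPVR splits the time-ordered end-systolic points into two
contiguous runs and picks the split whose two ordinary-least-squares lines
have the highest geometric mean of r^2.  The intersection of the two lines
marks the transition between the fast (shortening-deactivation) and slow
(Frank-Starling) phases of the response to an afterload increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .elastance import ESPoint


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class LinearESPVR:
    """OLS fit of Pes on Ves: P = Ees * (V - V0)."""

    Ees: float          # slope, mmHg/mL
    intercept: float    # mmHg, fitted intercept b
    V0: float           # mL, volume-axis intercept -b/Ees
    r2: float
    n_points: int
    physiological: bool = True  # False when Ees <= 0

    @property
    def slope(self) -> float:
        return self.Ees

    def predict(self, v: np.ndarray) -> np.ndarray:
        return self.Ees * np.asarray(v) + self.intercept


@dataclass(frozen=True)
class BilinearESPVR:
    phase1: LinearESPVR
    phase2: LinearESPVR
    split_index: int            # index of the last point in phase 1
    breakpoint: tuple           # (V*, P*)
    gm_r2: float
    parallel_fallback: bool = False


@dataclass(frozen=True)
class PRSWResult:
    """Stroke work regressed on end-diastolic volume: SW = Mw * (Ved - Vw)."""

    Mw: float       # mmHg
    Vw: float       # mL
    intercept: float
    r2: float
    n_points: int
    meaningful: bool = True


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r^2 of y on x; exact-fit r^2 is 1 even when the
    response is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm = x.mean()
    ym = y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx < 1e-12:
        raise FitError("vertical regression: no variation in the predictor")
    sxy = float(np.sum((x - xm) * (y - ym)))
    m = sxy / sxx
    b = ym - m * xm
    ss_res = float(np.sum((y - m * x - b) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    if ss_tot < 1e-12:
        r2 = 1.0 if ss_res < 1e-10 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return m, b, r2


def fit_linear_espvr(points: Sequence[ESPoint]) -> LinearESPVR:
    """Single linear regression through the end-systolic points.

    A non-positive slope is returned flagged non-physiological rather than
    raised, mirroring how near-horizontal relations are reported rather
    than discarded.
    """
    if len(points) < 3:
        raise FitError("need at least 3 end-systolic points")
    v = np.array([p.Ves for p in points])
    p_ = np.array([p.Pes for p in points])
    if np.ptp(v) < 1e-12:
        raise FitError("vertical ESPVR: all Ves equal")
    m, b, r2 = _ols(v, p_)
    v0 = -b / m if m != 0 else math.nan
    return LinearESPVR(Ees=m, intercept=b, V0=v0, r2=r2,
                       n_points=len(points), physiological=m > 0)


def intersection(
    line1: tuple[float, float], line2: tuple[float, float]
) -> tuple[tuple[float, float], bool]:
    """Intersection (V*, P*) of two lines given as (slope, intercept).

    Returns ``(point, parallel)``; for (near-)parallel lines the point is
    NaN and the flag is set — callers substitute a midpoint fallback.
    """
    m1, b1 = line1
    m2, b2 = line2
    if abs(m1 - m2) < 1e-9 * max(1.0, abs(m1), abs(m2)):
        return (math.nan, math.nan), True
    v = (b2 - b1) / (m1 - m2)
    return (v, m1 * v + b1), False


def fit_bilinear_espvr(points: Sequence[ESPoint], min_seg: int = 3) -> BilinearESPVR:
    """Best contiguous two-line description of the time-ordered ES points.

    Every admissible split (each segment >= ``min_seg`` points) is
    evaluated; the split maximizing sqrt(r2_1 * r2_2) wins, earliest split
    on ties.  Splits where either segment is volume-degenerate are skipped.
    """
    n = len(points)
    if n < 2 * min_seg:
        raise FitError(f"need at least {2 * min_seg} points for a bilinear fit")
    best: Optional[tuple[float, int, LinearESPVR, LinearESPVR]] = None
    for k in range(min_seg - 1, n - min_seg):
        try:
            f1 = fit_linear_espvr(points[: k + 1])
            f2 = fit_linear_espvr(points[k + 1:])
        except FitError:
            continue
        gm = math.sqrt(max(f1.r2, 0.0) * max(f2.r2, 0.0))
        if best is None or gm > best[0] + 1e-12:
            best = (gm, k, f1, f2)
    if best is None:
        raise FitError("no admissible split: volume-degenerate segments")
    gm, k, f1, f2 = best
    bp, parallel = intersection((f1.Ees, f1.intercept), (f2.Ees, f2.intercept))
    if parallel:
        bp = (
            0.5 * (points[k].Ves + points[k + 1].Ves),
            0.5 * (points[k].Pes + points[k + 1].Pes),
        )
    return BilinearESPVR(phase1=f1, phase2=f2, split_index=k,
                         breakpoint=bp, gm_r2=gm, parallel_fallback=parallel)


def fit_prsw(ved: Sequence[float], sw: Sequence[float]) -> PRSWResult:
    """Preload-recruitable stroke work: OLS of stroke work on Ved.

    A near-zero or negative slope (as afterload interventions produce) is
    flagged not meaningful instead of raising.
    """
    ved = np.asarray(ved, float)
    sw = np.asarray(sw, float)
    if len(ved) < 3:
        raise FitError("need at least 3 beats for PRSW")
    if np.ptp(ved) < 1e-12:
        raise FitError("no Ved variation for PRSW")
    m, b, r2 = _ols(ved, sw)
    vw = -b / m if m != 0 else math.nan
    meaningful = m > 0 and r2 >= 0.5
    return PRSWResult(Mw=m, Vw=vw, intercept=b, r2=r2,
                      n_points=len(ved), meaningful=meaningful)


@dataclass(frozen=True)
class Landmarks:
    """Beat indices of the phase landmarks within the analysis window:
    a = start of phase 1, b = end of phase 1 (bilinear split), c = end of
    phase 2.  ``b`` is None for a purely linear description."""

    a: int
    b: Optional[int]
    c: int


def classify_phases(bilinear: Optional[BilinearESPVR], n_beats: int) -> Landmarks:
    """Landmarks from a (bi)linear description of an n-beat window."""
    if n_beats < 1:
        raise FitError("empty window")
    b = bilinear.split_index if bilinear is not None else None
    return Landmarks(a=0, b=b, c=n_beats - 1)
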