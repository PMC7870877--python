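"""Maximal-elastance end-systole detection and iterative slack-volume (Vd).

End of systole is the sample maximizing Emax(t) = P(t) / (V(t) - Vd).  The
slack volume Vd is found by fixed-point iteration: detect end-systolic
points with the current Vd, regress Pes on Ves, take the volume-axis
intercept as the next Vd, and repeat until the change falls below
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import Beat

#: denominator guard (mL): samples with V - Vd below this are inadmissible
DENOM_GUARD_ML = 0.5


class ElastanceError(ValueError):
    pass


class DegenerateESPVRError(ElastanceError):
    """Raised when the end-systolic points cannot support a positive-slope
    regression (no load variation, or slope <= 0)."""


@dataclass(frozen=True)
class ESPoint:
    beat_idx: int
    t_es: float     # s, absolute time of end systole
    Ves: float      # mL
    Pes: float      # mmHg
    Emax: float     # mmHg/mL


@dataclass
class VdEstimate:
    Vd: float
    n_iterations: int
    converged: bool
    history: list = field(default_factory=list)


def beat_emax(beat: Beat, Vd: float, beat_idx: int = 0) -> ESPoint:
    """End-systolic point of one beat: the sample maximizing P/(V - Vd).

    Only samples with positive pressure and V - Vd above a 0.5 mL guard are
    admissible; ties break to the earliest sample (np.argmax convention).
    """
    p = beat.lvp
    v = beat.lvv
    denom = v - Vd
    admissible = (denom > DENOM_GUARD_ML) & (p > 0)
    if not np.any(admissible):
        raise ElastanceError(
            f"beat {beat_idx}: no admissible sample for Emax (Vd={Vd:.1f} mL)"
        )
    ratio = np.where(admissible, p / np.where(admissible, denom, 1.0), -np.inf)
    k = int(np.argmax(ratio))
    return ESPoint(
        beat_idx=beat_idx,
        t_es=beat.t_start_s + k / beat.fs,
        Ves=float(v[k]),
        Pes=float(p[k]),
        Emax=float(ratio[k]),
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) < 1e-12:
        raise DegenerateESPVRError("no volume variation across end-systolic points")
    m, b = np.polyfit(x, y, 1)
    return float(m), float(b)


def estimate_vd(
    beats: list[Beat],
    tol: float = 0.1,
    max_iter: int = 50,
    vd0: float = 0.0,
) -> VdEstimate:
    """Iterative slack-volume estimate over a load-varying beat window.

    Starting from ``vd0``, alternate end-systole detection and Pes-on-Ves
    regression, updating Vd to the x-intercept of the fitted line.  Vd is
    clamped to at most (minimum observed volume - 1 mL) so Emax stays
    finite.  Raises on non-positive regression slope.
    """
    if len(beats) < 3:
        raise ElastanceError("need at least 3 beats to estimate Vd")
    vmin = min(float(np.min(b.lvv)) for b in beats)
    vd = min(vd0, vmin - 1.0)
    history = [vd]
    converged = False
    for _ in range(max_iter):
        pts = [beat_emax(b, vd, i) for i, b in enumerate(beats)]
        m, c = _ols_line([p.Ves for p in pts], [p.Pes for p in pts])
        if m <= 0:
            raise DegenerateESPVRError(f"non-positive ESPVR slope ({m:.3g}) during Vd iteration")
        vd_next = min(-c / m, vmin - 1.0)
        history.append(vd_next)
        if abs(vd_next - vd) < tol:
            vd = vd_next
            converged = True
            break
        vd = vd_next
    return VdEstimate(Vd=vd, n_iterations=len(history) - 1, converged=converged, history=history)


def end_systolic_series(beats: list[Beat], Vd: float) -> list[ESPoint]:
    """One end-systolic point per beat, in beat order."""
    return [beat_emax(b, Vd, i) for i, b in enumerate(beats)]
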