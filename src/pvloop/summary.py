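"""Per-beat and per-phase hemodynamic indices.

End-diastolic values are read at the beat's first sample (the R-wave);
end-systolic values come from the maximal-elastance point; stroke work is
the area enclosed by the pressure-volume loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .beats import Beat
from .elastance import ESPoint
from .espvr import Landmarks


@dataclass(frozen=True)
class BeatIndices:
    Ped: float       # mmHg
    Ved: float       # mL
    Pes: float       # mmHg
    Ves: float       # mL
    SV: float        # mL
    SW: float        # mmHg*mL
    Ea: float        # mmHg/mL; NaN when SV <= 0
    dPdtmax: float   # mmHg/s
    ea_defined: bool = True


@dataclass(frozen=True)
class PhaseSummary:
    landmark: str            # "a", "b" or "c"
    beat_idx: int
    indices: BeatIndices


def loop_area(beat: Beat) -> float:
    """Stroke work as the absolute shoelace area of the closed (V, P) loop."""
    if beat.n_samples < 4:
        raise ValueError("need at least 4 samples for a loop area")
    v = beat.lvv
    p = beat.lvp
    # shoelace with implicit closure last -> first
    area = 0.5 * abs(float(np.dot(v, np.roll(p, -1)) - np.dot(p, np.roll(v, -1))))
    return area


def beat_indices(beat: Beat, es: ESPoint, smooth_dpdt: bool = False) -> BeatIndices:
    """All per-beat indices from a calibrated beat and its end-systolic point.

    dP/dtmax is the maximum centred-difference derivative of LVP; optional
    25 Hz low-pass smoothing is available for noisy recordings but off by
    default.
    """
    ped = float(beat.lvp[0])
    ved = float(beat.lvv[0])
    sv = ved - es.Ves
    sw = loop_area(beat)
    p = beat.lvp
    if smooth_dpdt and beat.n_samples > 24:
        from scipy.signal import butter, filtfilt
        ba = butter(2, 25.0, fs=beat.fs)
        p = filtfilt(*ba, p)
    dpdt = np.gradient(p, 1.0 / beat.fs)
    dpdtmax = float(np.max(dpdt))
    ea_defined = sv > 0
    ea = es.Pes / sv if ea_defined else math.nan
    return BeatIndices(Ped=ped, Ved=ved, Pes=es.Pes, Ves=es.Ves, SV=sv,
                       SW=sw, Ea=ea, dPdtmax=dpdtmax, ea_defined=ea_defined)


def phase_table(
    indices: Sequence[BeatIndices],
    landmarks: Landmarks,
    window: int = 0,
) -> list[PhaseSummary]:
    """Indices at the phase landmarks a / b / c of an analysis window.

    ``window`` > 0 averages each landmark over that many neighbour beats on
    each side; the default reports the single landmark beat.
    """
    out = []
    pairs = [("a", landmarks.a)]
    if landmarks.b is not None:
        pairs.append(("b", landmarks.b))
    pairs.append(("c", landmarks.c))
    for name, idx in pairs:
        lo = max(0, idx - window)
        hi = min(len(indices), idx + window + 1)
        sel = indices[lo:hi]
        if window == 0 or len(sel) == 1:
            ind = indices[idx]
        else:
            def mean(attr):
                vals = [getattr(s, attr) for s in sel]
                return float(np.nanmean(vals))
            ind = BeatIndices(
                Ped=mean("Ped"), Ved=mean("Ved"), Pes=mean("Pes"), Ves=mean("Ves"),
                SV=mean("SV"), SW=mean("SW"), Ea=mean("Ea"), dPdtmax=mean("dPdtmax"),
                ea_defined=all(s.ea_defined for s in sel),
            )
        out.append(PhaseSummary(landmark=name, beat_idx=idx, indices=ind))
    return out
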