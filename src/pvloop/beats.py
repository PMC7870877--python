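"""Beat segmentation, extrasystole exclusion, and conductance calibration.

The R-wave of the ECG defines end of diastole; a beat spans the half-open
sample range [R_i, R_{i+1}).  Raw conductance volume is mapped to absolute
volume with the parallel-conductance offset Vp and the gain factor alpha
(the ratio of conductance-derived to flow-probe stroke volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .synth_hemo import SignalRecording


class CalibrationError(ValueError):
    pass


class SegmentationError(ValueError):
    pass


@dataclass
class Beat:
    """One cardiac cycle: sample range [start, end) starting at the R-wave.

    ``lvp`` and ``lvv`` are views into the recording's channels; end-diastolic
    values are read at the first sample.
    """

    start: int
    end: int
    fs: float
    lvp: np.ndarray
    lvv: np.ndarray
    aoflow: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise SegmentationError("beat end must exceed start")

    @property
    def rr_s(self) -> float:
        return (self.end - self.start) / self.fs

    @property
    def t_start_s(self) -> float:
        return self.start / self.fs

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class CalibrationResult:
    """Conductance gain estimate from baseline beats."""

    alpha: float
    Vp: float
    sv_cond_mean: float
    sv_flow_mean: float
    n_beats: int = 0


def detect_rwaves(
    ecg: np.ndarray,
    fs: float,
    threshold_frac: float = 0.5,
    refractory_s: float = 0.2,
) -> np.ndarray:
    """Indices of R-wave peaks.

    Local maxima above ``threshold_frac`` times the 99.9th-percentile
    amplitude (an adaptive estimate of the R-peak level; since R-waves
    occupy well under 0.1% of the samples, this quantile sits near the
    true peak height and is robust against broadband noise), separated by
    at least the refractory period.  Returns an empty array when no peak
    clears the threshold (flat or pure-noise signals).
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs:
        raise ValueError("need at least 2 s of ECG")
    ref = np.percentile(ecg, 99.9)
    if ref <= 0:
        return np.array([], dtype=int)
    dist = max(int(refractory_s * fs), 1)
    peaks, _ = find_peaks(ecg, height=threshold_frac * ref, distance=dist)
    return peaks.astype(int)


def segment_beats(
    recording: SignalRecording,
    r_indices: Sequence[int],
    volume_channel: str = "lvv",
) -> list[Beat]:
    """One Beat per consecutive R-wave pair; the trailing partial beat after
    the last R-wave is discarded."""
    r = np.asarray(r_indices, dtype=int)
    if len(r) < 2:
        raise SegmentationError("need at least 2 R-waves to segment beats")
    lvp = recording.channels["lvp"]
    lvv = recording.channels[volume_channel]
    aoflow = recording.channels.get("aoflow")
    out = []
    for i0, i1 in zip(r[:-1], r[1:]):
        out.append(Beat(
            start=int(i0), end=int(i1), fs=recording.fs,
            lvp=lvp[i0:i1], lvv=lvv[i0:i1],
            aoflow=None if aoflow is None else aoflow[i0:i1],
        ))
    return out


def filter_extrasystoles(beats: list[Beat], rr_tolerance: float = 0.20) -> list[Beat]:
    """Drop premature beats and their compensatory successors.

    A beat is premature when its RR interval deviates from the running
    median (window 5, centred) by more than ``rr_tolerance``; the
    immediately following beat is removed as well.  Idempotent on regular
    rhythms.
    """
    if len(beats) < 3:
        return list(beats)
    rr = np.array([b.rr_s for b in beats])
    n = len(rr)
    med = np.empty(n)
    for i in range(n):
        lo = max(0, i - 2)
        hi = min(n, i + 3)
        med[i] = np.median(rr[lo:hi])
    bad = np.abs(rr - med) > rr_tolerance * med
    drop = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if bad[i]:
            drop[i] = True
            if i + 1 < n:
                # the following (compensatory) beat goes too, and does not
                # itself initiate further removals
                drop[i + 1] = True
            i += 2
        else:
            i += 1
    return [b for b, d in zip(beats, drop) if not d]


def _flow_sv(beat: Beat) -> float:
    """Stroke volume from the aortic flow probe: integral of positive flow."""
    if beat.aoflow is None:
        raise CalibrationError("beat has no aortic-flow samples")
    q = np.maximum(beat.aoflow, 0.0)
    return float(np.trapezoid(q, dx=1.0 / beat.fs))


def _conductance_sv(beat: Beat) -> float:
    return float(np.max(beat.lvv) - np.min(beat.lvv))


def estimate_alpha(
    beats: list[Beat],
    Vp: float = 0.0,
    baseline: Optional[tuple[float, float]] = None,
) -> CalibrationResult:
    """Gain factor alpha = mean conductance SV / mean flow-probe SV.

    ``beats`` must be segmented on the *raw* conductance channel.  Only
    beats inside the ``baseline`` interval (seconds) are used; without a
    baseline annotation the first three beats are taken.
    """
    if baseline is not None:
        sel = [b for b in beats if baseline[0] <= b.t_start_s and (b.t_start_s + b.rr_s) <= baseline[1]]
    else:
        sel = beats[:3]
    if len(sel) < 3:
        sel = beats[:3]
    if len(sel) < 3:
        raise CalibrationError("need at least 3 baseline beats for alpha")
    sv_c = float(np.mean([_conductance_sv(b) for b in sel]))
    sv_f = float(np.mean([_flow_sv(b) for b in sel]))
    if sv_f <= 0:
        raise CalibrationError("flow-probe stroke volume is non-positive")
    return CalibrationResult(alpha=sv_c / sv_f, Vp=Vp, sv_cond_mean=sv_c,
                             sv_flow_mean=sv_f, n_beats=len(sel))


def calibrate_volume(lvv_raw: np.ndarray, alpha: float, Vp: float) -> np.ndarray:
    """Absolute volume from raw conductance: (raw - Vp) / alpha."""
    if alpha <= 0:
        raise CalibrationError("alpha must be positive")
    return (np.asarray(lvv_raw, dtype=float) - Vp) / alpha


def intervention_window(
    beats: list[Beat],
    onset_s: float,
    min_delta_pes: float = 2.0,
    min_delta_ves: float = 2.0,
) -> list[Beat]:
    """Contiguous beats over which the load intervention actually changes
    pressure or volume.

    Starting at the first beat at/after ``onset_s``, beats are included
    while the beat-to-beat change of the provisional end-systolic pressure
    (peak LVP) or volume (minimum LVV) exceeds the thresholds; the window
    closes after two consecutive quiet beats.  Vd is unknown at this stage,
    so peak pressure / minimum volume stand in for the maximal-elastance
    point — they track load changes equally well.
    """
    if len(beats) < 5:
        raise SegmentationError("need at least 5 beats spanning the intervention")
    pes = np.array([float(np.max(b.lvp)) for b in beats])
    ves = np.array([float(np.min(b.lvv)) for b in beats])
    i_on = next((i for i, b in enumerate(beats) if b.t_start_s >= onset_s - 0.5 * b.rr_s), None)
    if i_on is None or i_on >= len(beats) - 1:
        raise SegmentationError("no beats after the intervention onset")

    active = [
        abs(pes[i] - pes[i - 1]) >= min_delta_pes or abs(ves[i] - ves[i - 1]) >= min_delta_ves
        for i in range(1, len(beats))
    ]  # active[i-1] refers to beat i
    if not any(active[max(i_on - 1, 0):]):
        raise SegmentationError("no load change detected")

    end = len(beats)
    quiet = 0
    started = False
    for i in range(i_on + 1, len(beats)):
        if active[i - 1]:
            started = True
            quiet = 0
        elif started:
            quiet += 1
            if quiet >= 2:
                end = i - 1
                break
    if not started:
        raise SegmentationError("no load change detected")
    return beats[i_on:end]
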