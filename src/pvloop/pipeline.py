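"""End-to-end analysis of one recording: segmentation, calibration,
windowing, Vd, ESPVR fits, PRSW and phase summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from . import beats as beats_mod
from . import elastance, espvr, summary
from .beats import Beat, CalibrationResult
from .elastance import ESPoint, VdEstimate
from .espvr import BilinearESPVR, Landmarks, LinearESPVR, PRSWResult
from .summary import BeatIndices, PhaseSummary
from .synth_hemo import SignalRecording


@dataclass
class RunAnalysis:
    kind: Optional[str]
    calibration: CalibrationResult
    beats: list[Beat]                  # after extrasystole exclusion
    n_excluded: int
    window_start: int                  # index of first window beat within `beats`
    window: list[Beat]
    vd: VdEstimate
    es_points: list[ESPoint]
    linear: LinearESPVR
    bilinear: Optional[BilinearESPVR]
    prsw: Optional[PRSWResult]
    model_used: str                    # "lin" or "bilin"
    landmarks: Landmarks
    indices: list[BeatIndices]         # per window beat
    phases: list[PhaseSummary]

    def beat_table(self) -> pd.DataFrame:
        """Tidy per-beat table over the analysis window."""
        rows = []
        for i, (b, es, ind) in enumerate(zip(self.window, self.es_points, self.indices)):
            rows.append({
                "beat_idx": i,
                "t_start_s": b.t_start_s,
                "rr_s": b.rr_s,
                "ped_mmhg": ind.Ped,
                "ved_ml": ind.Ved,
                "pes_mmhg": ind.Pes,
                "ves_ml": ind.Ves,
                "sv_ml": ind.SV,
                "sw_mmhg_ml": ind.SW,
                "ea_mmhg_ml": ind.Ea,
                "dpdtmax_mmhg_s": ind.dPdtmax,
            })
        return pd.DataFrame(rows)


def analyze_recording(
    recording: SignalRecording,
    vp: float,
    alpha: float | Literal["auto"] = "auto",
    kind: Optional[str] = None,
    model: Literal["auto", "lin", "bilin", "data"] = "auto",
    min_seg: int = 3,
    rr_tolerance: float = 0.20,
    bilin_margin: float = 0.01,
    vd_shared: Optional[float] = None,
    lowpass_hz: Optional[float] = 30.0,
) -> RunAnalysis:
    """Run the full pipeline on one recording.

    ``vp`` is the parallel-conductance volume (known input; saline
    estimation is out of scope).  ``alpha="auto"`` estimates the gain from
    baseline beats against the flow probe.  ``model`` selects the ESPVR
    description: "auto" follows the intervention kind (linear for preload,
    bilinear for afterload runs), "data" picks bilinear when its geometric-
    mean r^2 beats the linear r^2 by more than ``bilin_margin``.

    ``lowpass_hz`` applies a zero-phase 2nd-order Butterworth low-pass to
    the hemodynamic channels before analysis (measurement noise otherwise
    biases the maximal-elastance argmax); pass None for raw signals.
    """
    if kind is None:
        prot = recording.meta.get("protocol") or {}
        kind = prot.get("kind")

    r_idx = beats_mod.detect_rwaves(recording.channels["ecg"], recording.fs)
    if len(r_idx) < 2:
        raise beats_mod.SegmentationError("fewer than 2 R-waves detected")

    if lowpass_hz is not None and lowpass_hz < recording.fs / 2:
        from scipy.signal import butter, filtfilt
        ba = butter(2, lowpass_hz, fs=recording.fs)
        smoothed = {
            ch: (filtfilt(*ba, arr) if ch != "ecg" else arr)
            for ch, arr in recording.channels.items()
        }
        recording = SignalRecording(
            recording.fs, smoothed, annotations=recording.annotations,
            truth=recording.truth, meta=recording.meta,
        )

    # alpha from beats segmented on the raw conductance channel
    raw_beats = beats_mod.segment_beats(recording, r_idx, volume_channel="lvv_raw")
    if alpha == "auto":
        cal = beats_mod.estimate_alpha(raw_beats, Vp=vp, baseline=recording.annotation("baseline"))
    else:
        cal = CalibrationResult(alpha=float(alpha), Vp=vp, sv_cond_mean=np.nan,
                                sv_flow_mean=np.nan)

    calibrated = SignalRecording(
        recording.fs,
        {**recording.channels,
         "lvv": beats_mod.calibrate_volume(recording.channels["lvv_raw"], cal.alpha, vp)},
        annotations=recording.annotations,
        truth=recording.truth,
        meta=recording.meta,
    )
    all_beats = beats_mod.segment_beats(calibrated, r_idx)
    kept = beats_mod.filter_extrasystoles(all_beats, rr_tolerance=rr_tolerance)
    n_excluded = len(all_beats) - len(kept)

    ann = calibrated.annotation("intervention")
    onset = ann[0] if ann else kept[0].t_start_s
    window = beats_mod.intervention_window(kept, onset)
    window_start = next(i for i, b in enumerate(kept) if b.start == window[0].start)

    if vd_shared is not None:
        vd = VdEstimate(Vd=vd_shared, n_iterations=0, converged=True, history=[vd_shared])
    else:
        try:
            vd = elastance.estimate_vd(window)
        except elastance.DegenerateESPVRError:
            # steep two-phase afterload trajectories can defeat the
            # fixed-point iteration (it presupposes a preload sweep);
            # fall back to zero slack volume, flagged unconverged
            vd = VdEstimate(Vd=0.0, n_iterations=0, converged=False, history=[0.0])
    es_points = elastance.end_systolic_series(window, vd.Vd)

    linear = espvr.fit_linear_espvr(es_points)
    bilinear = None
    if len(es_points) >= 2 * min_seg:
        try:
            bilinear = espvr.fit_bilinear_espvr(es_points, min_seg=min_seg)
        except espvr.FitError:
            bilinear = None

    if model == "lin":
        model_used = "lin"
    elif model == "bilin":
        model_used = "bilin" if bilinear is not None else "lin"
    elif model == "data":
        model_used = (
            "bilin"
            if bilinear is not None and bilinear.gm_r2 - linear.r2 > bilin_margin
            else "lin"
        )
    else:  # follow the intervention kind: bilinear only for afterload runs
        model_used = "bilin" if (kind == "pload" and bilinear is not None) else "lin"

    indices = [summary.beat_indices(b, es) for b, es in zip(window, es_points)]

    prsw = None
    ved = [ind.Ved for ind in indices]
    sw = [ind.SW for ind in indices]
    try:
        prsw = espvr.fit_prsw(ved, sw)
    except espvr.FitError:
        prsw = None

    landmarks = espvr.classify_phases(bilinear if model_used == "bilin" else None, len(window))
    phases = summary.phase_table(indices, landmarks)

    return RunAnalysis(
        kind=kind, calibration=cal, beats=kept, n_excluded=n_excluded,
        window_start=window_start, window=window, vd=vd, es_points=es_points,
        linear=linear, bilinear=bilinear, prsw=prsw, model_used=model_used,
        landmarks=landmarks, indices=indices, phases=phases,
    )
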