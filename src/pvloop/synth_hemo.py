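"""Closed-loop time-varying-elastance (TVE) hemodynamic simulator.

The model is a minimal three-compartment closed circulation:

    venous reservoir -> mitral valve -> TVE left ventricle -> aortic valve
    -> three-element Windkessel (Rc, Ca, Rp) -> venous reservoir

The ventricle follows the classical time-varying elastance law

    P(t) = e(t) * Ees * (V(t) - V0_eff)
           + (1 - e(t)) * A * (exp(B * (V(t) - V0d)) - 1)

with a double-Hill activation drive e(t) normalized to [0, 1].  Two
autoregulation mechanisms are represented explicitly:

* shortening deactivation (SDA): the volume-axis intercept V0_eff is an
  affine function of the effective arterial elastance Ea of the *previous*
  beat, ``V0_eff = a * Ea + b`` — an immediate, afterload-proportional
  leftward/rightward shift of the end-systolic PV relation;
* the Frank-Starling mechanism arises naturally from the closed loop: when
  ejection falls, venous volume backs up and end-diastolic volume rises over
  the following beats.

Load interventions (preload reduction by caval occlusion, afterload increase
by resistance ramp, and their combination) are expressed as scheduled ramps
of circulation parameters.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator


class SimulationError(RuntimeError):
    """Raised when the closed-loop integration becomes unphysical."""


class ActivationParams(BaseModel):
    """Shape of the normalized double-Hill activation drive.

    Time constants are fractions of the beat period, so the drive rescales
    with heart rate.
    """

    model_config = ConfigDict(frozen=True)

    tau1: float = Field(0.32, gt=0, description="rise time constant, fraction of period")
    tau2: float = Field(0.55, gt=0, description="decay time constant, fraction of period")
    m1: float = Field(1.9, gt=0)
    m2: float = Field(21.9, gt=0)


class NoiseSD(BaseModel):
    """Additive Gaussian measurement-noise SD per recorded channel."""

    model_config = ConfigDict(frozen=True)

    lvp: float = Field(0.5, ge=0)      # mmHg
    lvv_raw: float = Field(0.5, ge=0)  # mL-equivalent
    aop: float = Field(0.5, ge=0)      # mmHg
    aoflow: float = Field(1.0, ge=0)   # mL/s
    ecg: float = Field(0.0, ge=0)      # mV


class SimConfig(BaseModel):
    """Ground-truth parameters of one simulated animal/run.

    Defaults target a ~50 kg pig under anesthesia (end-diastolic volume
    ~90-120 mL, end-systolic pressure ~70-100 mmHg, heart rate 90/min).
    """

    model_config = ConfigDict(frozen=True)

    heart_rate: float = Field(90.0, ge=40, le=200)  # beats/min
    Ees_true: float = Field(1.2, gt=0)              # mmHg/mL
    V0_base: float = 10.0                           # mL
    sda_slope_a: float = -24.2                      # mL per (mmHg/mL)
    sda_intercept_b: float = 23.0                   # mL
    sda_enabled: bool = False

    edpvr_A: float = Field(0.6, gt=0)               # mmHg
    edpvr_B: float = Field(0.025, gt=0)             # 1/mL
    edpvr_V0d: float = 10.0                         # mL

    Rc: float = Field(0.06, gt=0)                   # mmHg s/mL, characteristic
    Rp: float = Field(1.0, gt=0)                    # mmHg s/mL, peripheral
    Ca: float = Field(1.0, gt=0)                    # mL/mmHg, arterial compliance
    Cv: float = Field(150.0, gt=0)                  # mL/mmHg, venous compliance
    Rm: float = Field(0.05, gt=0)                   # mmHg s/mL, mitral
    Rv_return: float = Field(0.010, gt=0)           # mmHg s/mL, venous return
    total_volume: float = Field(2150.0, gt=0)       # mL (stressed)

    activation: ActivationParams = ActivationParams()
    fs: float = Field(1000.0, gt=0)                 # Hz
    noise_sd: NoiseSD = NoiseSD()

    alpha_true: float = Field(1.0, gt=0)            # conductance gain
    Vp_true: float = 0.0                            # mL, parallel conductance
    seed: int = 0

    # SDA driver: "afterload_ea" senses the arterial load — the measured
    # Ea on settled baseline beats, scaled by the resistance feed-through
    # (Rp/T)^gamma once an afterload intervention begins — so an afterload
    # ramp shifts V0 within 1-2 beats and then holds, while the spurious
    # Pes/SV inflation of a caval occlusion never reaches V0.
    # "measured_ea" feeds back raw previous-beat Pes/SV unconditionally,
    # which is unstable at low stroke volume.
    sda_driver: Literal["afterload_ea", "measured_ea"] = "afterload_ea"
    # first-order smoothing of the SDA driver (weight of the newest value);
    # damps the beat-to-beat feedback without hiding the fast phase-1 response
    sda_smooth: float = Field(0.7, gt=0, le=1)
    # sublinear afterload-sensitivity exponent: the steady-state Ea of the
    # closed loop grows as ~(Rp/T)^gamma because the ratio of end-systolic
    # to mean driving pressure falls mildly with resistance
    sda_gamma: float = Field(0.55, gt=0, le=1.5)
    # the intercept shift completes within a few seconds of the last
    # afterload change and then holds (the SDA phase lasts at most ~5 s)
    sda_settle_s: float = Field(2.5, gt=0)

    extrasystole_beats: tuple[int, ...] = ()
    extrasystole_rr_frac: float = Field(0.65, gt=0.2, lt=0.85)
    extrasystole_amp: float = Field(0.6, gt=0, le=1)

    # unrecorded settling period before t=0 (rounded to whole beats) so the
    # recorded baseline starts at hemodynamic equilibrium
    warmup_s: float = Field(8.0, ge=0)


class ScheduleEvent(BaseModel):
    """One scheduled parameter ramp: scale factor moves linearly to `target`
    over [start_s, start_s + ramp_s] and holds until the next event."""

    model_config = ConfigDict(frozen=True)

    param: Literal["Rp", "Rc", "Rv_return"]
    start_s: float = Field(ge=0)
    ramp_s: float = Field(gt=0)
    target: float = Field(gt=0)  # multiplier applied to the baseline value


class Protocol(BaseModel):
    """A load-intervention schedule.

    kinds: ``vload_normal`` (transient caval occlusion), ``pload``
    (afterload ramp held to end of run), ``vload_high`` (afterload ramp,
    then caval occlusion on the elevated afterload).
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["vload_normal", "pload", "vload_high"]
    schedule: tuple[ScheduleEvent, ...]
    total_duration_s: float = Field(gt=0, le=30)
    annotations: tuple[tuple[str, float, float], ...] = ()

    @model_validator(mode="after")
    def _events_in_range(self) -> "Protocol":
        for ev in self.schedule:
            if not (0 <= ev.start_s <= self.total_duration_s):
                raise ValueError(f"event at {ev.start_s}s outside [0, {self.total_duration_s}]")
        return self


class BeatTruth(BaseModel):
    """Ground-truth log entry for one simulated beat."""

    beat_idx: int
    t_onset_s: float
    period_s: float
    v0_eff_ml: float
    t_es_s: float
    ped_mmhg: float
    ved_ml: float
    pes_mmhg: float
    ves_ml: float
    sv_ml: float
    ea_mmhg_ml: float
    ea_driver_mmhg_ml: float = float("nan")
    is_extrasystole: bool = False


class SignalRecording:
    """Fixed-rate multichannel waveform container.

    Channels (all the same length): ``lvp`` (mmHg), ``lvv`` (true volume,
    mL), ``lvv_raw`` (conductance-equivalent), ``aop`` (mmHg), ``aoflow``
    (mL/s), ``ecg`` (mV).  ``annotations`` are (label, start_s, end_s)
    intervals; ``truth`` is the per-beat ground-truth log (simulated data
    only).
    """

    CHANNELS = ("lvp", "lvv", "lvv_raw", "aop", "aoflow", "ecg")

    def __init__(
        self,
        fs: float,
        channels: dict[str, np.ndarray],
        annotations: Sequence[tuple[str, float, float]] = (),
        truth: Optional[list[BeatTruth]] = None,
        meta: Optional[dict] = None,
    ):
        lengths = {len(v) for v in channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have the same length")
        self.fs = float(fs)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in channels.items()}
        self.annotations = [tuple(a) for a in annotations]
        self.truth = truth
        self.meta = meta or {}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def annotation(self, label: str) -> Optional[tuple[float, float]]:
        for lab, t0, t1 in self.annotations:
            if lab == label:
                return (t0, t1)
        return None


# ---------------------------------------------------------------------------
# activation drive

def _double_hill_raw(t_norm: np.ndarray, p: ActivationParams) -> np.ndarray:
    x1 = (t_norm / p.tau1) ** p.m1
    x2 = (t_norm / p.tau2) ** p.m2
    return (x1 / (1.0 + x1)) / (1.0 + x2)


def _hill_norm_const(p: ActivationParams) -> float:
    grid = np.linspace(0.0, 1.0, 4001, endpoint=False)
    return float(_double_hill_raw(grid, p).max())


_NORM_CACHE: dict[tuple, float] = {}


def activation_curve(t_norm, params: ActivationParams | None = None):
    """Normalized ventricular activation e(t) at phase ``t_norm`` in [0, 1).

    The double-Hill product (rising Hill in ``tau1, m1`` times a falling
    Hill in ``tau2, m2``) is normalized so that its maximum over one period
    is exactly 1.  Scalar or array input.
    """
    p = params or ActivationParams()
    key = (p.tau1, p.tau2, p.m1, p.m2)
    if key not in _NORM_CACHE:
        _NORM_CACHE[key] = _hill_norm_const(p)
    t = np.asarray(t_norm, dtype=float)
    if np.any((t < 0) | (t >= 1)):
        raise ValueError("t_norm must lie in [0, 1)")
    out = _double_hill_raw(t, p) / _NORM_CACHE[key]
    return float(out) if np.isscalar(t_norm) else out


def sda_v0(Ea_beat: float, a: float, b: float) -> float:
    """Effective ESPVR volume intercept under shortening deactivation.

    ``V0_eff = a * Ea + b`` — the afterload-proportional intercept shift.
    The linear law is applied unclipped; V0_eff may go negative at high Ea.
    """
    if Ea_beat < 0:
        raise ValueError("Ea must be non-negative")
    return a * Ea_beat + b


# ---------------------------------------------------------------------------
# protocols

def make_protocol(kind: str, config: SimConfig, pload_target: float = 2.4) -> Protocol:
    """Build the schedule for one of the three load interventions.

    * ``vload_normal``: 6 s caval occlusion (venous-return resistance ramp
      x50 over 0.8 s at t=4 s, released at t=10 s).
    * ``pload``: peripheral-resistance ramp (default x1.9, the occluder
      severity) over 1.5 s at t=4 s, held to the end of the 20 s run.
    * ``vload_high``: the pload ramp first, then a caval occlusion at
      t=14 s with the afterload held, 24 s total.
    """
    occl = 15.0
    if kind == "vload_normal":
        sched = (
            ScheduleEvent(param="Rv_return", start_s=4.0, ramp_s=0.8, target=occl),
            ScheduleEvent(param="Rv_return", start_s=9.0, ramp_s=0.8, target=1.0),
        )
        ann = (("baseline", 1.0, 4.0), ("intervention", 4.0, 9.5))
        return Protocol(kind=kind, schedule=sched, total_duration_s=16.0, annotations=ann)
    if kind == "pload":
        sched = (ScheduleEvent(param="Rp", start_s=4.0, ramp_s=1.5, target=pload_target),)
        ann = (("baseline", 1.0, 4.0), ("intervention", 4.0, 20.0))
        return Protocol(kind=kind, schedule=sched, total_duration_s=20.0, annotations=ann)
    if kind == "vload_high":
        sched = (
            ScheduleEvent(param="Rp", start_s=4.0, ramp_s=1.5, target=pload_target),
            ScheduleEvent(param="Rv_return", start_s=14.0, ramp_s=0.8, target=occl),
            ScheduleEvent(param="Rv_return", start_s=19.0, ramp_s=0.8, target=1.0),
        )
        ann = (("baseline", 1.0, 4.0), ("intervention", 14.0, 19.5))
        return Protocol(kind=kind, schedule=sched, total_duration_s=24.0, annotations=ann)
    raise ValueError(f"unknown intervention kind: {kind!r}")


def _scale_series(events: Sequence[ScheduleEvent], param: str, n: int, fs: float) -> np.ndarray:
    """Per-sample multiplicative scale of one parameter under the schedule."""
    s = np.ones(n)
    current = 1.0
    for ev in sorted((e for e in events if e.param == param), key=lambda e: e.start_s):
        i0 = int(round(ev.start_s * fs))
        i1 = min(int(round((ev.start_s + ev.ramp_s) * fs)), n)
        if i0 >= n:
            break
        s[i0:i1] = np.linspace(current, ev.target, max(i1 - i0, 1), endpoint=False)
        s[i1:] = ev.target
        current = ev.target
    return s


# ---------------------------------------------------------------------------
# closed-loop integration

def _beat_schedule(
    config: SimConfig, duration: float, first_recorded_beat: int = 0
) -> list[tuple[float, float, float, bool]]:
    """(onset_s, period_s, activation_amplitude, is_extrasystole) per beat.

    ``extrasystole_beats`` indices refer to recorded beats, i.e. are offset
    by ``first_recorded_beat`` warm-up beats.
    """
    T = 60.0 / config.heart_rate
    out = []
    t = 0.0
    k = -first_recorded_beat
    while t < duration:
        if k in config.extrasystole_beats:
            out.append((t, config.extrasystole_rr_frac * T, config.extrasystole_amp, True))
            t += config.extrasystole_rr_frac * T
            # compensatory pause
            out.append((t, (2.0 - config.extrasystole_rr_frac) * T, 1.0, False))
            t += (2.0 - config.extrasystole_rr_frac) * T
            k += 2
        else:
            out.append((t, T, 1.0, False))
            t += T
            k += 1
    return out


def simulate_run(config: SimConfig, protocol: Protocol) -> SignalRecording:
    """Integrate the closed loop over the protocol and return the recording.

    Fixed-step RK4 at 1/fs on state (Vlv, Va, Vv); valves are ideal diodes
    with series resistance; V0_eff is updated once per beat from the
    previous beat's Ea (one-beat lag, no within-beat algebraic loop).
    Total blood volume is conserved by construction.
    """
    fs = config.fs
    dt = 1.0 / fs
    T = 60.0 / config.heart_rate
    n_warm_beats = int(round(config.warmup_s / T))
    t_warm = n_warm_beats * T
    n_warm = int(round(t_warm * fs))
    n_rec = int(round(protocol.total_duration_s * fs))
    n = n_warm + n_rec

    ones = np.ones(n_warm)
    rp_s = np.concatenate([ones, _scale_series(protocol.schedule, "Rp", n_rec, fs)]) * config.Rp
    rc_s = np.concatenate([ones, _scale_series(protocol.schedule, "Rc", n_rec, fs)]) * config.Rc
    rv_s = np.concatenate([ones, _scale_series(protocol.schedule, "Rv_return", n_rec, fs)]) * config.Rv_return

    beats = _beat_schedule(config, t_warm + protocol.total_duration_s, n_warm_beats)
    act_p = config.activation
    key = (act_p.tau1, act_p.tau2, act_p.m1, act_p.m2)
    if key not in _NORM_CACHE:
        _NORM_CACHE[key] = _hill_norm_const(act_p)
    norm = _NORM_CACHE[key]
    tau1, tau2, m1, m2 = act_p.tau1, act_p.tau2, act_p.m1, act_p.m2

    Ees = config.Ees_true
    A, B, V0d = config.edpvr_A, config.edpvr_B, config.edpvr_V0d
    Ca, Cv, Rm = config.Ca, config.Cv, config.Rm

    # steady-ish initial state
    Vlv = 110.0
    Va = 75.0 * Ca
    Vv = config.total_volume - Vlv - Va
    if Vv <= 0:
        raise SimulationError("total_volume too small for initial compartments")

    lvp = np.empty(n)
    lvv = np.empty(n)
    aop = np.empty(n)
    aoflow = np.empty(n)
    ecg = np.zeros(n)

    exp = math.exp

    def plv(V: float, e: float, v0: float) -> float:
        return e * Ees * (V - v0) + (1.0 - e) * A * (exp(B * (V - V0d)) - 1.0)

    truth: list[BeatTruth] = []
    v0_eff = config.V0_base
    prev_ea: float | None = None       # measured Ea (Pes/SV) of previous beat
    prev_sv: float | None = None
    sv_slow: float | None = None       # slow EMA of stroke volume
    gate_open = True
    press_ratio: float | None = None   # Ea / (Rp/T)^gamma, gated
    prev_rp_scale: float | None = None

    # The driver is the measured Ea normalized by the arterial-resistance
    # feed-through (Rp/T)^gamma, updated on settled beats only: afterload
    # ramps shift V0 within 1-2 beats via the feed-through, the gated
    # ratio keeps caval-occlusion transients out, and the state freezes
    # shortly after the last afterload ramp, pinning V0 through the
    # Frank-Starling phase.
    afterload_ends = [
        t_warm + ev.start_s + ev.ramp_s
        for ev in protocol.schedule
        if ev.param in ("Rp", "Rc")
    ]
    t_freeze = max(afterload_ends) + config.sda_settle_s if afterload_ends else math.inf
    t_first_afterload = min(
        (t_warm + ev.start_s for ev in protocol.schedule if ev.param in ("Rp", "Rc")),
        default=math.inf,
    )

    drv_state: float | None = None
    max_drift = 0.0
    beat_i = 0
    for beat_i, (onset, period, amp, is_es) in enumerate(beats):
        ea_driver = math.nan
        if config.sda_enabled:
            s = config.sda_smooth
            if config.sda_driver == "measured_ea":
                target = prev_ea if prev_ea is not None else math.nan
            else:
                target = (
                    press_ratio * prev_rp_scale
                    if press_ratio is not None and prev_rp_scale is not None
                    else math.nan
                )
            if math.isfinite(target) and onset < t_freeze:
                drv_state = target if drv_state is None else (1 - s) * drv_state + s * target
            if drv_state is not None:
                ea_driver = drv_state
                v0_eff = sda_v0(max(ea_driver, 0.0), config.sda_slope_a, config.sda_intercept_b)
        else:
            v0_eff = config.V0_base

        i0 = int(round(onset * fs))
        i1 = min(int(round((onset + period) * fs)), n)
        if i0 >= n:
            break

        # ECG fiducial: triangular R-wave, peak 1 mV at the beat onset
        half = max(int(round(0.010 * fs)), 1)
        for j in range(-half, half + 1):
            idx = i0 + j
            if 0 <= idx < n:
                ecg[idx] = max(ecg[idx], amp * (1.0 - abs(j) / half))

        ped = plv(Vlv, 0.0, v0_eff)
        ved = Vlv
        pes = ves = 0.0
        emax_seen = -math.inf
        t_es = onset

        for i in range(i0, i1):
            tn = (i * dt - onset) / period
            if tn < 0.0:
                tn = 0.0
            elif tn >= 1.0:
                tn = 1.0 - 1e-12
            x1 = (tn / tau1) ** m1
            x2 = (tn / tau2) ** m2
            e = amp * (x1 / (1.0 + x1)) / (1.0 + x2) / norm

            rp, rc, rv = rp_s[i], rc_s[i], rv_s[i]

            def deriv(vlv: float, va: float, vv: float):
                p_lv = e * Ees * (vlv - v0_eff) + (1.0 - e) * A * (exp(B * (vlv - V0d)) - 1.0)
                pa = va / Ca
                pv = vv / Cv
                q_fill = (pv - p_lv) / (Rm + rv) if pv > p_lv else 0.0
                q_ao = (p_lv - pa) / rc if p_lv > pa else 0.0
                q_per = (pa - pv) / rp
                return q_fill - q_ao, q_ao - q_per, q_per - q_fill, q_ao

            k1 = deriv(Vlv, Va, Vv)
            k2 = deriv(Vlv + 0.5 * dt * k1[0], Va + 0.5 * dt * k1[1], Vv + 0.5 * dt * k1[2])
            k3 = deriv(Vlv + 0.5 * dt * k2[0], Va + 0.5 * dt * k2[1], Vv + 0.5 * dt * k2[2])
            k4 = deriv(Vlv + dt * k3[0], Va + dt * k3[1], Vv + dt * k3[2])

            p_now = e * Ees * (Vlv - v0_eff) + (1.0 - e) * A * (exp(B * (Vlv - V0d)) - 1.0)
            pa_now = Va / Ca
            lvp[i] = p_now
            lvv[i] = Vlv
            aop[i] = pa_now
            # sample-interval average of aortic flow (integrating flowmeter)
            aoflow[i] = (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]) / 6.0
            # track the true maximal-elastance (end-systolic) point
            if Vlv - v0_eff > 0.5:
                ratio = p_now / (Vlv - v0_eff)
            else:
                ratio = -math.inf
            if ratio > emax_seen:
                emax_seen = ratio
                pes, ves, t_es = p_now, Vlv, i * dt

            Vlv += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            Va += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            Vv += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])

            drift = abs(Vlv + Va + Vv - config.total_volume)
            if drift > max_drift:
                max_drift = drift

            if not (math.isfinite(Vlv) and math.isfinite(Va) and math.isfinite(Vv)):
                raise SimulationError(f"non-finite state at t={i * dt:.3f}s (sample {i})")
            if Vlv < v0_eff - 50.0 or Vlv < -50.0:
                raise SimulationError(f"ventricular volume collapsed at t={i * dt:.3f}s (sample {i})")

        sv = ved - ves
        ea = pes / sv if sv > 1e-6 else math.nan
        if sv > 1e-6:
            gate_open = (
                sv_slow is None
                or (
                    abs(sv - sv_slow) < 0.08 * sv_slow
                    and (prev_sv is None or abs(sv - prev_sv) < 0.08 * prev_sv)
                )
            )
            rp_scale = (float(np.mean(rp_s[i0:i1])) / period) ** config.sda_gamma
            if gate_open and onset + period <= t_first_afterload:
                r_new = ea / rp_scale
                press_ratio = (
                    r_new if press_ratio is None else 0.5 * press_ratio + 0.5 * r_new
                )
            prev_rp_scale = rp_scale
        if onset >= t_warm - 1e-9:
            truth.append(BeatTruth(
                beat_idx=beat_i - n_warm_beats, t_onset_s=onset - t_warm,
                period_s=period, v0_eff_ml=v0_eff,
                t_es_s=t_es - t_warm, ped_mmhg=ped, ved_ml=ved, pes_mmhg=pes,
                ves_ml=ves, sv_ml=sv, ea_mmhg_ml=ea, ea_driver_mmhg_ml=ea_driver,
                is_extrasystole=is_es,
            ))
        if sv > 1e-6:
            prev_ea = ea
            prev_sv = sv
            sv_slow = sv if sv_slow is None else 0.75 * sv_slow + 0.25 * sv

    channels = {
        "lvp": lvp[n_warm:], "lvv": lvv[n_warm:], "lvv_raw": lvv[n_warm:].copy(),
        "aop": aop[n_warm:], "aoflow": aoflow[n_warm:], "ecg": ecg[n_warm:],
    }
    meta = {
        "config": config.model_dump(),
        "protocol": protocol.model_dump(),
        "seed": config.seed,
        "volume_drift_frac": max_drift / config.total_volume,
    }
    return SignalRecording(fs, channels, annotations=protocol.annotations, truth=truth, meta=meta)


def distort_and_noise(recording: SignalRecording, config: SimConfig) -> SignalRecording:
    """Apply the conductance-catheter distortion and measurement noise.

    ``lvv_raw = alpha_true * lvv + Vp_true`` exactly, then seeded additive
    Gaussian noise on every measured channel.  The true ``lvv`` channel and
    the truth log are carried through untouched.
    """
    rng = np.random.default_rng(config.seed)
    ch = {k: v.copy() for k, v in recording.channels.items()}
    ch["lvv_raw"] = config.alpha_true * ch["lvv"] + config.Vp_true
    sd = config.noise_sd
    for name in ("lvp", "lvv_raw", "aop", "aoflow", "ecg"):
        s = getattr(sd, name)
        if s > 0:
            ch[name] = ch[name] + rng.normal(0.0, s, size=len(ch[name]))
    return SignalRecording(
        recording.fs, ch, annotations=recording.annotations,
        truth=recording.truth, meta=dict(recording.meta),
    )
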