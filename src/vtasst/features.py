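"""Extraction of the 25 electrophysiological features from a sweep ladder.

The feature roster mirrors the firing-pattern analysis used to subtype
midbrain somatostatin neurons:

* passive block — resting membrane potential, input resistance, sag ratio,
  membrane time constant, whole-cell capacitance (amplifier metadata);
* rheobase block — measured on the first spike of the lowest-current sweep
  that fires (rheobase current, AP threshold/amplitude/half-width, AHP
  amplitude, AP decay, afterdepolarization amplitude and latency, latency to
  first spike, spike count);
* saturated block — measured on the sweep with the most spikes (saturating
  current, latency to first spike, initial and steady-state maximal firing
  rates, adaptation ratio, waveform metrics, spike count, ISI variability).

Spike detection follows the derivative-threshold convention: the AP
threshold is the first point at which the (smoothed) rate of rise exceeds
10 mV/ms before a peak.  Sub-threshold wiggles whose peak rises less than
20 mV above threshold are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import SweepLadder

__all__ = [
    "SpikeEvent",
    "FeatureVector",
    "FeatureError",
    "detect_spikes",
    "passive_properties",
    "rheobase_features",
    "saturation_features",
    "extract_features",
    "features_to_frame",
    "FEATURE_NAMES",
]

#: dV/dt threshold defining the AP threshold (mV/ms).
SLOPE_THRESHOLD_MV_PER_MS = 10.0
#: minimum rise above threshold for a deflection to count as a spike (mV).
MIN_AP_AMPLITUDE_MV = 20.0
#: an afterdepolarization must exceed the AHP trough by this much (mV).
ADP_MIN_PROMINENCE_MV = 0.5
#: ADP search extends at most this far beyond the AHP trough (ms).
ADP_MAX_WINDOW_MS = 100.0
#: steady-state voltage window at the end of the current step (ms).
STEADY_STATE_WINDOW_MS = 50.0


class FeatureError(RuntimeError):
    """Raised when a feature cannot be computed from the recording."""


@dataclass
class SpikeEvent:
    """One detected action potential and its after-potentials (times in ms)."""

    threshold_time: float
    threshold_v: float
    peak_time: float
    peak_v: float
    ahp_time: float
    ahp_v: float
    halfwidth: float
    decay_time: float
    adp_v: float | None = None
    adp_time: float | None = None

    @property
    def amplitude(self) -> float:
        """AP amplitude: threshold to positive peak (mV)."""
        return self.peak_v - self.threshold_v

    @property
    def ahp_amplitude(self) -> float:
        """AHP amplitude: threshold to most negative after-potential (mV)."""
        return self.threshold_v - self.ahp_v

    @property
    def adp_amplitude(self) -> float:
        """ADP amplitude: AHP trough to ADP bump peak (mV); 0 when absent."""
        if self.adp_v is None:
            return 0.0
        return self.adp_v - self.ahp_v

    @property
    def adp_latency(self) -> float:
        """Interval between the AHP trough and the ADP peak (ms); 0 if none."""
        if self.adp_time is None:
            return 0.0
        return self.adp_time - self.ahp_time


FEATURE_NAMES = [
    # passive
    "rmp",
    "input_resistance",
    "sag",
    "tau_membrane",
    "capacitance_pf",
    # rheobase sweep
    "rheobase_current",
    "ap_threshold",
    "ap_amplitude",
    "ap_halfwidth",
    "ahp_amplitude",
    "ap_decay",
    "adp_amplitude",
    "adp_latency",
    "first_spike_latency_rheo",
    "spike_count_rheo",
    # saturated sweep
    "saturating_current",
    "first_spike_latency_sat",
    "fmax_init",
    "fmax_ss",
    "adaptation_ratio",
    "ap_halfwidth_sat",
    "spike_count_sat",
    "ap_amplitude_sat",
    "ahp_amplitude_sat",
    "isi_cv_sat",
]


@dataclass
class FeatureVector:
    """The 25 named electrophysiological features of one cell.

    Units: voltages mV, times/latencies ms, currents pA, rates Hz,
    resistance MΩ, capacitance pF; sag, adaptation ratio and ISI CV are
    dimensionless.  ``adp_amplitude``/``adp_latency`` are 0 for cells with
    no afterdepolarization.
    """

    rmp: float = np.nan
    input_resistance: float = np.nan
    sag: float = np.nan
    tau_membrane: float = np.nan
    capacitance_pf: float = np.nan
    rheobase_current: float = np.nan
    ap_threshold: float = np.nan
    ap_amplitude: float = np.nan
    ap_halfwidth: float = np.nan
    ahp_amplitude: float = np.nan
    ap_decay: float = np.nan
    adp_amplitude: float = 0.0
    adp_latency: float = 0.0
    first_spike_latency_rheo: float = np.nan
    spike_count_rheo: float = np.nan
    saturating_current: float = np.nan
    first_spike_latency_sat: float = np.nan
    fmax_init: float = np.nan
    fmax_ss: float = np.nan
    adaptation_ratio: float = np.nan
    ap_halfwidth_sat: float = np.nan
    spike_count_sat: float = np.nan
    ap_amplitude_sat: float = np.nan
    ahp_amplitude_sat: float = np.nan
    isi_cv_sat: float = np.nan

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in dc_fields(self)})


def features_to_frame(
    vectors: Sequence[FeatureVector], cell_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Stack feature vectors into a cells x features table."""
    df = pd.DataFrame([v.as_series() for v in vectors])
    if cell_ids is not None:
        df.index = pd.Index(cell_ids, name="cell_id")
    return df


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge replication."""
    window = min(window if window % 2 else window + 1, v.size | 1)
    if v.size < 3 or window < 3:
        return v.astype(float)
    half = window // 2
    padded = np.concatenate([np.full(half, v[0]), v, np.full(half, v[-1])])
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def _smooth3(v: np.ndarray) -> np.ndarray:
    """3-point moving average (the smoothing used for dV/dt)."""
    return _smooth(v, 3)


def _dvdt(v: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference derivative of the smoothed trace, mV/ms."""
    vs = _smooth3(v)
    d = np.empty_like(vs)
    d[1:-1] = (vs[2:] - vs[:-2]) / (2.0 * dt)
    d[0] = (vs[1] - vs[0]) / dt
    d[-1] = (vs[-1] - vs[-2]) / dt
    return d


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def detect_spikes(
    voltage: np.ndarray,
    dt: float,
    slope_threshold: float = SLOPE_THRESHOLD_MV_PER_MS,
    min_amplitude: float = MIN_AP_AMPLITUDE_MV,
    search_end: int | None = None,
) -> list[SpikeEvent]:
    """Detect action potentials on a single voltage trace.

    Parameters
    ----------
    voltage
        Membrane voltage in mV.
    dt
        Sampling interval in ms.
    slope_threshold
        Rate-of-rise defining the AP threshold (mV/ms).
    min_amplitude
        Minimum peak height above threshold for a deflection to count as a
        spike; rejects afterdepolarization bumps and noise wiggles.
    search_end
        Optional sample index bounding the AHP/ADP search (typically the end
        of the current step), so the post-step relaxation is never mistaken
        for an afterhyperpolarization.

    Returns
    -------
    list of :class:`SpikeEvent`, ordered in time; empty for subthreshold
    traces.
    """
    v = np.asarray(voltage, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage trace contains non-finite samples")
    n = v.size
    if n < 5:
        return []
    end = n if search_end is None else min(int(search_end), n)
    d = _dvdt(v, dt)
    above = d > slope_threshold
    # rising edges of suprathreshold dV/dt runs
    edges = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    edges = edges[edges < end]
    if edges.size == 0:
        return []

    # candidate (threshold, peak) pairs: peak = max V between this edge and
    # the next one; merge edges that share a peak
    raw_events: list[tuple[int, int]] = []
    for j, e in enumerate(edges):
        stop = edges[j + 1] if j + 1 < edges.size else end
        if stop <= e:
            continue
        peak = e + int(np.argmax(v[e:stop]))
        # smoothing advances the detected crossing slightly; walk forward
        # to the first raw-slope crossing before the peak
        guard = 0
        while (
            e + 1 < peak and (v[e + 1] - v[e]) / dt <= slope_threshold and guard < 5
        ):
            e += 1
            guard += 1
        if v[peak] - v[e] < min_amplitude:
            continue
        # a genuine peak dominates the following 2 ms (the absolute
        # refractory period); a "peak" at the foot of a larger upstroke is
        # a split detection run, not a spike
        look = v[peak + 1 : min(peak + 1 + int(round(2.0 / dt)), n)]
        if look.size and look.max() > v[peak]:
            continue
        if raw_events and raw_events[-1][1] == peak:
            continue
        raw_events.append((e, peak))

    events: list[SpikeEvent] = []
    for k, (thr_idx, peak_idx) in enumerate(raw_events):
        next_thr = raw_events[k + 1][0] if k + 1 < len(raw_events) else end
        ahp_stop = min(next_thr, end)
        if ahp_stop <= peak_idx + 1:
            ahp_stop = min(peak_idx + 2, n)
        vs = _smooth3(v)
        ahp_idx = peak_idx + 1 + int(np.argmin(vs[peak_idx + 1 : ahp_stop]))
        # locate the trough on the smoothed trace (noise-robust), then
        # refine on the raw samples to undo the smoothing bias at the corner
        w0 = max(peak_idx + 1, ahp_idx - 2)
        w1 = min(ahp_stop, ahp_idx + 3)
        ahp_idx = w0 + int(np.argmin(v[w0:w1]))

        # half-width at threshold + amplitude/2, linear interpolation
        level = v[thr_idx] + 0.5 * (v[peak_idx] - v[thr_idx])
        up = thr_idx + int(np.argmax(v[thr_idx : peak_idx + 1] >= level))
        t_up = _interp_crossing(
            (up - 1) * dt, up * dt, v[up - 1], v[up], level
        ) if up > thr_idx else up * dt
        seg = v[peak_idx:ahp_stop]
        below = np.flatnonzero(seg <= level)
        if below.size:
            dn = peak_idx + int(below[0])
            t_dn = _interp_crossing((dn - 1) * dt, dn * dt, v[dn - 1], v[dn], level)
        else:
            t_dn = (ahp_stop - 1) * dt
        halfwidth = max(t_dn - t_up, dt)

        # afterdepolarization: a transient bump between the AHP trough and
        # the next spike (or +100 ms / the step end, whichever is first)
        adp_v = adp_time = None
        adp_stop = min(next_thr, ahp_idx + int(round(ADP_MAX_WINDOW_MS / dt)), end)
        if adp_stop > ahp_idx + 2:
            # decide on a heavily smoothed window (~2 ms) so a monotone
            # recovery toward baseline with noise is never mistaken for a
            # bump: a genuine afterdepolarization must rise above the
            # trough AND fall back again within the window
            win = _smooth(v[ahp_idx:adp_stop], int(round(2.0 / dt)) + 1)
            m = int(np.argmax(win))
            bump = win[m] - v[ahp_idx]
            falls_after = win[m:].min() <= win[m] - ADP_MIN_PROMINENCE_MV
            if 0 < m < win.size - 1 and bump >= ADP_MIN_PROMINENCE_MV and falls_after:
                # place the peak on the lightly smoothed trace near the
                # heavily smoothed argmax (robust to asymmetric bumps)
                r0 = max(m - 15, 0)
                r1 = min(m + 16, win.size)
                seg = vs[ahp_idx + r0 : ahp_idx + r1]
                adp_idx = ahp_idx + r0 + int(np.argmax(seg))
                adp_v = float(vs[adp_idx])
                adp_time = adp_idx * dt

        events.append(
            SpikeEvent(
                threshold_time=thr_idx * dt,
                threshold_v=float(v[thr_idx]),
                peak_time=peak_idx * dt,
                peak_v=float(v[peak_idx]),
                ahp_time=ahp_idx * dt,
                ahp_v=float(v[ahp_idx]),
                halfwidth=float(halfwidth),
                decay_time=(ahp_idx - peak_idx) * dt,
                adp_v=adp_v,
                adp_time=adp_time,
            )
        )
    return events


def spikes_by_sweep(ladder: SweepLadder, **kwargs) -> list[list[SpikeEvent]]:
    """Detect spikes on every sweep, bounding after-potential searches at the
    step end."""
    step_end = int(round((ladder.step_onset + ladder.step_duration) / ladder.dt))
    return [
        detect_spikes(v, ladder.dt, search_end=step_end, **kwargs)
        for v in ladder.voltages
    ]


# ---------------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------------


def _steady_state(ladder: SweepLadder, trace: np.ndarray) -> float:
    """Mean voltage over the last 50 ms of the current step."""
    i1 = int(round((ladder.step_onset + ladder.step_duration) / ladder.dt))
    i0 = i1 - int(round(STEADY_STATE_WINDOW_MS / ladder.dt))
    return float(trace[i0:i1].mean())


def passive_properties(
    ladder: SweepLadder,
    spikes: Sequence[Sequence[SpikeEvent]] | None = None,
) -> tuple[float, float, float, float]:
    """Resting membrane potential, input resistance, sag ratio and membrane
    time constant.

    * RMP (mV): mean of per-sweep pre-step baselines.
    * Input resistance (MΩ): least-squares slope of steady-state voltage
      (last 50 ms of the step) against injected current over all sweeps
      without action potentials.
    * Sag: ratio of the steady-state mean over the last 50 ms of the
      -100 pA step to the most negative voltage reached during that step.
    * τ (ms): single-exponential fit ``V(t) = V∞ + (V0 − V∞)·exp(−t/τ)``
      over the first 200 ms of the -100 pA step, excluding the first 2 ms
      (capacitive transient); NaN when the fit does not converge.
    """
    if spikes is None:
        spikes = spikes_by_sweep(ladder)
    rmp = float(ladder.baselines().mean())

    quiet = [i for i, ev in enumerate(spikes) if len(ev) == 0]
    if len(quiet) < 2:
        raise FeatureError("fewer than 2 spike-free sweeps; cannot fit input resistance")
    vss = np.array([_steady_state(ladder, ladder.voltages[i]) for i in quiet])
    cur = ladder.currents[quiet]
    slope = np.polyfit(cur, vss, 1)[0]  # mV/pA
    rin = float(slope * 1000.0)  # MΩ

    try:
        vneg = ladder.sweep_at(-100.0)
    except KeyError as exc:
        raise FeatureError("ladder lacks the -100 pA sweep") from exc
    i0 = int(round(ladder.step_onset / ladder.dt))
    i1 = int(round((ladder.step_onset + ladder.step_duration) / ladder.dt))
    step_seg = vneg[i0:i1]
    ss = _steady_state(ladder, vneg)
    peak = float(step_seg.min())
    sag = ss / peak if peak != 0 else np.nan

    # exponential fit of the charging phase
    f0 = i0 + int(round(2.0 / ladder.dt))
    f1 = min(i0 + int(round(200.0 / ladder.dt)), i1)
    t_fit = (np.arange(f0, f1) - i0) * ladder.dt
    v_fit = vneg[f0:f1]

    def _model(t, v_inf, v0, tau):
        return v_inf + (v0 - v_inf) * np.exp(-t / tau)

    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat traces fit degenerately
            popt, _ = curve_fit(
                _model,
                t_fit,
                v_fit,
                p0=(v_fit[-1], vneg[i0 - 1] if i0 else v_fit[0], 20.0),
                maxfev=5000,
            )
        tau = float(abs(popt[2]))
    except RuntimeError:
        tau = np.nan
    return rmp, rin, sag, tau


# ---------------------------------------------------------------------------
# rheobase and saturated blocks
# ---------------------------------------------------------------------------


def rheobase_features(
    ladder: SweepLadder, spikes: Sequence[Sequence[SpikeEvent]]
) -> FeatureVector:
    """Features of the first spike on the lowest-current sweep that fires."""
    firing = [i for i, ev in enumerate(spikes) if len(ev) >= 1]
    if not firing:
        raise FeatureError("no_rheobase")
    i = firing[0]
    first = spikes[i][0]
    return FeatureVector(
        rheobase_current=float(ladder.currents[i]),
        ap_threshold=first.threshold_v,
        ap_amplitude=first.amplitude,
        ap_halfwidth=first.halfwidth,
        ahp_amplitude=first.ahp_amplitude,
        ap_decay=first.decay_time,
        adp_amplitude=first.adp_amplitude,
        adp_latency=first.adp_latency,
        first_spike_latency_rheo=first.threshold_time - ladder.step_onset,
        spike_count_rheo=float(len(spikes[i])),
    )


def _isis(events: Sequence[SpikeEvent]) -> np.ndarray:
    """Interspike intervals between neighboring spike peaks, ms."""
    peaks = np.array([e.peak_time for e in events])
    return np.diff(peaks)


def saturation_features(
    ladder: SweepLadder, spikes: Sequence[Sequence[SpikeEvent]]
) -> FeatureVector:
    """Features of the sweep with the most spikes (ties: lowest current).

    ``fmax_init`` is the inverse of the shortest interspike interval among
    the first three spikes; ``fmax_ss`` the inverse of the mean of the last
    four ISIs (all available ISIs when there are fewer than five spikes);
    both NaN when the saturated sweep has fewer than two spikes.
    """
    counts = np.array([len(ev) for ev in spikes])
    if counts.max() < 1:
        raise FeatureError("no_rheobase")
    i = int(np.argmax(counts))  # argmax returns the first (lowest-current) tie
    events = spikes[i]
    first = events[0]
    out = FeatureVector(
        saturating_current=float(ladder.currents[i]),
        first_spike_latency_sat=first.threshold_time - ladder.step_onset,
        spike_count_sat=float(len(events)),
        ap_halfwidth_sat=first.halfwidth,
        ap_amplitude_sat=first.amplitude,
        ahp_amplitude_sat=first.ahp_amplitude,
    )
    isis = _isis(events)
    if isis.size >= 1:
        early = isis[:2] if isis.size >= 2 else isis  # ISIs among first 3 spikes
        out.fmax_init = float(1000.0 / early.min())
        late = isis[-4:] if isis.size >= 4 else isis
        out.fmax_ss = float(1000.0 / late.mean())
        out.adaptation_ratio = out.fmax_ss / out.fmax_init
        out.isi_cv_sat = float(isis.std(ddof=0) / isis.mean()) if isis.size > 1 else 0.0
    return out


def extract_features(ladder: SweepLadder) -> FeatureVector:
    """Extract the complete 25-feature vector from one sweep ladder.

    Deterministic for fixed input.  Raises :class:`FeatureError` (with the
    offending block named) when a required quantity cannot be computed,
    e.g. ``"no_rheobase"`` for subthreshold-only ladders.
    """
    spikes = spikes_by_sweep(ladder)
    rmp, rin, sag, tau = passive_properties(ladder, spikes)
    rheo = rheobase_features(ladder, spikes)
    sat = saturation_features(ladder, spikes)
    out = FeatureVector(
        rmp=rmp,
        input_resistance=rin,
        sag=sag,
        tau_membrane=tau,
        capacitance_pf=(
            ladder.capacitance_pf if ladder.capacitance_pf is not None else np.nan
        ),
    )
    for name in FEATURE_NAMES[5:15]:
        setattr(out, name, getattr(rheo, name))
    for name in FEATURE_NAMES[15:]:
        setattr(out, name, getattr(sat, name))
    return out
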