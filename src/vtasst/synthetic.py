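"""Synthetic data generation for every stage of the pipeline.

Three neuron subtypes are emulated, parameterized by the summary statistics
of the recorded cohorts (per-feature mean and SD, with SD = SEM·√n where the
source reports SEM):

* **ADP** — afterdepolarizing cells: a prominent depolarizing bump after
  each spike's AHP, moderate firing rates, the most abundant subtype.
* **HFF** — high-frequency firing cells: lowest rheobase, narrow spikes,
  deep AHPs, maximal rates near 129 Hz.
* **Delayed** — cells firing only after a long (~279 ms) delay even at
  saturating excitation, broad slowly-decaying spikes, weak adaptation.

Membrane-potential traces are rendered from smooth piecewise templates
(linear spike flanks, half-cosine ADP bump, exponential passive segments)
rather than a biophysical model, so that every feature the extractor
measures has a closed-form ground-truth value emitted alongside the trace.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .features import FEATURE_NAMES, FeatureVector
from .io import SweepLadder

__all__ = [
    "SubtypeSpec",
    "TraceTemplate",
    "DEFAULT_SUBTYPES",
    "default_cohort",
    "synth_feature_table",
    "synth_trace_ladder",
    "synth_photostim_session",
    "synth_patchseq",
]

# ---------------------------------------------------------------------------
# subtype specifications
# ---------------------------------------------------------------------------

#: physical truncation bounds for feature-table draws
FEATURE_BOUNDS: dict[str, tuple[float, float]] = {
    "rmp": (-90.0, -45.0),
    "input_resistance": (50.0, 3000.0),
    "sag": (0.70, 1.0),
    "tau_membrane": (1.0, 60.0),
    "capacitance_pf": (3.0, 40.0),
    "rheobase_current": (10.0, 600.0),
    "ap_threshold": (-45.0, -10.0),
    "ap_amplitude": (20.0, 130.0),
    "ap_halfwidth": (0.2, 5.0),
    "ahp_amplitude": (0.0, 60.0),
    "ap_decay": (0.3, 30.0),
    "adp_amplitude": (0.0, 40.0),
    "adp_latency": (0.0, 80.0),
    "first_spike_latency_rheo": (1.0, 790.0),
    "spike_count_rheo": (1.0, 30.0),
    "saturating_current": (50.0, 600.0),
    "first_spike_latency_sat": (1.0, 790.0),
    "fmax_init": (2.0, 350.0),
    "fmax_ss": (1.0, 200.0),
    "adaptation_ratio": (0.02, 1.5),
    "ap_halfwidth_sat": (0.2, 6.0),
    "spike_count_sat": (1.0, 120.0),
    "ap_amplitude_sat": (20.0, 130.0),
    "ahp_amplitude_sat": (0.0, 60.0),
    "isi_cv_sat": (0.01, 2.0),
}


@dataclass
class TraceTemplate:
    """Closed-form trace parameters of one cell (all voltages mV, times ms).

    ``*_rheo`` values describe the first spike at rheobase, ``*_sat`` the
    spikes of the saturated (maximal-spike-count) sweep; sweeps in between
    interpolate linearly in injected current.
    """

    rmp: float
    tau: float
    rin: float  # MΩ
    sag_ratio: float
    capacitance_pf: float
    rheobase: float  # pA (snapped up to the current grid when rendered)
    saturating_current: float  # pA
    # AP shape at rheobase
    threshold: float
    amplitude: float
    halfwidth: float
    ahp_amp: float
    decay: float  # peak -> AHP trough, ms
    # AP shape at saturation
    amplitude_sat: float
    halfwidth_sat: float
    ahp_amp_sat: float
    decay_sat: float
    # afterdepolarization (ADP subtype only)
    adp_amp: float = 0.0
    adp_latency: float = 0.0
    # train schedule
    latency_rheo: float = 200.0
    latency_sat: float = 25.0
    count_rheo: int = 2
    count_sat: int = 20
    fmax_init: float = 100.0  # Hz, 1 / shortest early ISI at saturation
    fmax_ss: float = 25.0  # Hz, 1 / mean of last four ISIs at saturation
    isi_rheo: float = 250.0  # gap between the few rheobase-level spikes


@dataclass
class SubtypeSpec:
    """Cohort-level description of one subtype.

    ``features`` maps each of the 25 feature names to (mean, SD) for the
    feature-table generator; ``template`` carries the trace-template
    parameters used to render membrane-potential ladders; ``template_cv``
    is the relative SD applied when drawing per-cell template variants.
    """

    name: str
    n: int
    features: dict[str, tuple[float, float]]
    template: TraceTemplate
    template_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("subtype n must be positive")
        for k, (mu, sd) in self.features.items():
            if k not in FEATURE_BOUNDS:
                raise ValueError(f"unknown feature {k!r}")
            if sd < 0:
                raise ValueError(f"negative SD for feature {k!r}")


def _tbl(mean_sem_n: dict[str, tuple[float, float]], n: int) -> dict:
    """Convert {feature: (mean, SEM)} to {feature: (mean, SEM*sqrt(n))}."""
    return {k: (m, s * math.sqrt(n)) for k, (m, s) in mean_sem_n.items()}


def _adp_spec() -> SubtypeSpec:
    n = 215
    feats = _tbl(
        {
            "input_resistance": (783, 24),
            "rmp": (-69.9, 0.6),
            "capacitance_pf": (13.2, 0.2),
            "sag": (0.963, 0.002),
            "rheobase_current": (18.4, 1.0),
            "ap_threshold": (-31.1, 0.3),
            "ap_amplitude": (95.2, 0.6),
            "adp_amplitude": (13.8, 0.5),
            "first_spike_latency_rheo": (218, 10),
            "ap_halfwidth": (1.01, 0.01),
            "ahp_amplitude": (26.3, 0.5),
            "ap_decay": (2.2, 0.1),
            "spike_count_rheo": (2.1, 0.1),
            "saturating_current": (207, 5),
            "fmax_init": (108, 3),
            "fmax_ss": (25.6, 1.1),
            "adaptation_ratio": (0.28, 0.02),
            "first_spike_latency_sat": (24.8, 3.4),
            "ap_halfwidth_sat": (1.88, 0.04),
            "spike_count_sat": (21.6, 0.9),
            # not reported in the summary table: one-time realistic choices
            "tau_membrane": (15.0, 0.2),
            "adp_latency": (20.0, 0.35),
            "ap_amplitude_sat": (80.0, 0.55),
            "ahp_amplitude_sat": (20.0, 0.35),
            "isi_cv_sat": (0.45, 0.010),
        },
        n,
    )
    tmpl = TraceTemplate(
        rmp=-69.9, tau=15.0, rin=783.0, sag_ratio=0.963, capacitance_pf=13.2,
        rheobase=18.4, saturating_current=207.0,
        threshold=-31.1, amplitude=95.2, halfwidth=1.01, ahp_amp=26.3, decay=2.2,
        amplitude_sat=80.0, halfwidth_sat=1.88, ahp_amp_sat=20.0, decay_sat=4.0,
        adp_amp=13.8, adp_latency=20.0,
        latency_rheo=218.0, latency_sat=24.8, count_rheo=2, count_sat=21,
        fmax_init=108.0, fmax_ss=25.6, isi_rheo=250.0,
    )
    return SubtypeSpec("ADP", n, feats, tmpl)


def _hff_spec() -> SubtypeSpec:
    n = 92
    feats = _tbl(
        {
            "input_resistance": (835, 37),
            "rmp": (-67.8, 0.8),
            "capacitance_pf": (12.4, 0.3),
            "sag": (0.952, 0.002),
            "rheobase_current": (11.9, 1.2),
            "ap_threshold": (-31.7, 0.5),
            "ap_amplitude": (94.0, 0.8),
            "adp_amplitude": (0.0, 0.0),
            "first_spike_latency_rheo": (182, 14),
            "ap_halfwidth": (0.90, 0.02),
            "ahp_amplitude": (35.7, 0.9),
            "ap_decay": (1.84, 0.04),
            "spike_count_rheo": (3.9, 0.2),
            "saturating_current": (209, 11),
            "fmax_init": (129, 5),
            "fmax_ss": (42.9, 3.7),
            "adaptation_ratio": (0.32, 0.02),
            "first_spike_latency_sat": (12.2, 1.2),
            "ap_halfwidth_sat": (1.6, 0.1),
            "spike_count_sat": (39.1, 3.1),
            "tau_membrane": (12.0, 0.25),
            "adp_latency": (0.0, 0.0),
            "ap_amplitude_sat": (78.0, 0.8),
            "ahp_amplitude_sat": (28.0, 0.6),
            "isi_cv_sat": (0.35, 0.015),
        },
        n,
    )
    tmpl = TraceTemplate(
        rmp=-67.8, tau=12.0, rin=835.0, sag_ratio=0.952, capacitance_pf=12.4,
        rheobase=11.9, saturating_current=209.0,
        threshold=-31.7, amplitude=94.0, halfwidth=0.90, ahp_amp=35.7, decay=1.84,
        amplitude_sat=78.0, halfwidth_sat=1.6, ahp_amp_sat=28.0, decay_sat=3.5,
        latency_rheo=182.0, latency_sat=12.2, count_rheo=4, count_sat=39,
        fmax_init=129.0, fmax_ss=42.9, isi_rheo=150.0,
    )
    return SubtypeSpec("HFF", n, feats, tmpl)


def _delayed_spec() -> SubtypeSpec:
    n = 85
    feats = _tbl(
        {
            "input_resistance": (928, 42),
            "rmp": (-64.9, 1.0),
            "capacitance_pf": (15.0, 0.4),
            "sag": (0.961, 0.003),
            "rheobase_current": (40.8, 4.3),
            "ap_threshold": (-25.6, 0.6),
            "ap_amplitude": (87.9, 0.8),
            "adp_amplitude": (0.0, 0.0),
            "first_spike_latency_rheo": (528, 25),
            "ap_halfwidth": (1.46, 0.04),
            "ahp_amplitude": (25.3, 1.5),
            "ap_decay": (7.9, 0.5),
            "spike_count_rheo": (1.4, 0.1),
            "saturating_current": (242, 12),
            "fmax_init": (46, 15),
            "fmax_ss": (21.2, 1.4),
            "adaptation_ratio": (0.80, 0.04),
            "first_spike_latency_sat": (279.0, 20.4),
            "ap_halfwidth_sat": (2.5, 0.1),
            "spike_count_sat": (11.0, 0.8),
            "tau_membrane": (18.0, 0.4),
            "adp_latency": (0.0, 0.0),
            "ap_amplitude_sat": (72.0, 0.8),
            "ahp_amplitude_sat": (18.0, 0.7),
            "isi_cv_sat": (0.15, 0.008),
        },
        n,
    )
    tmpl = TraceTemplate(
        rmp=-64.9, tau=18.0, rin=928.0, sag_ratio=0.961, capacitance_pf=15.0,
        rheobase=40.8, saturating_current=242.0,
        threshold=-25.6, amplitude=87.9, halfwidth=1.46, ahp_amp=25.3, decay=7.9,
        amplitude_sat=72.0, halfwidth_sat=2.5, ahp_amp_sat=18.0, decay_sat=9.0,
        latency_rheo=528.0, latency_sat=279.0, count_rheo=1, count_sat=11,
        fmax_init=46.0, fmax_ss=21.2, isi_rheo=200.0,
    )
    return SubtypeSpec("Delayed", n, feats, tmpl)


def default_cohort() -> list[SubtypeSpec]:
    """The three default subtype specs (cohort sizes 215 / 92 / 85)."""
    return [_adp_spec(), _hff_spec(), _delayed_spec()]


DEFAULT_SUBTYPES = {s.name: s for s in default_cohort()}


# ---------------------------------------------------------------------------
# feature-table generator
# ---------------------------------------------------------------------------


def synth_feature_table(
    specs: Sequence[SubtypeSpec] | None = None,
    seed: int = 0,
):
    """Draw a cells x 25-features table with known subtype labels.

    Each feature is drawn independently from a Gaussian truncated at its
    physical bounds (latencies and counts nonnegative, sag at most 1, ...).
    Features whose spec SD is 0 (e.g. ADP amplitude of non-ADP subtypes)
    are set to the mean exactly.  Reproducible for a fixed seed.

    Returns a :class:`vtasst.clustering.FeatureMatrix` carrying the true
    labels.
    """
    from .clustering import FeatureMatrix  # local import to avoid a cycle
    import pandas as pd

    if specs is None:
        specs = default_cohort()
    if not specs:
        raise ValueError("specs must be nonempty")
    rng = np.random.default_rng(seed)
    rows, labels, ids = [], [], []
    for spec in specs:
        block = np.empty((spec.n, len(FEATURE_NAMES)))
        for j, name in enumerate(FEATURE_NAMES):
            if name not in spec.features:
                raise ValueError(f"spec {spec.name!r} missing feature {name!r}")
            mu, sd = spec.features[name]
            lo, hi = FEATURE_BOUNDS[name]
            if sd == 0:
                block[:, j] = mu
            else:
                a, b = (lo - mu) / sd, (hi - mu) / sd
                block[:, j] = truncnorm.rvs(a, b, loc=mu, scale=sd,
                                            size=spec.n, random_state=rng)
        rows.append(block)
        labels.extend([spec.name] * spec.n)
        ids.extend([f"{spec.name}_{i:04d}" for i in range(spec.n)])
    values = np.vstack(rows)
    df = pd.DataFrame(values, columns=FEATURE_NAMES,
                      index=pd.Index(ids, name="cell_id"))
    return FeatureMatrix(values=df, true_labels=pd.Series(labels, index=df.index))


# ---------------------------------------------------------------------------
# trace-ladder generator
# ---------------------------------------------------------------------------

_FOOT_MS = 5.0  # subthreshold approach to spike threshold (slope 4 mV/ms)
_FOOT_DEPTH = 20.0  # mV below threshold at the foot start
_RISE_MS = 0.3  # upstroke duration (grid-aligned; slope >> 10 mV/ms)
_SAG_SPLIT_MS = 200.0  # charging phase ends / sag relaxation begins
_SAG_TAU_MS = 100.0


def _snap(x: float, dt: float) -> float:
    return round(x / dt) * dt


def _sat_isis(tmpl: TraceTemplate, n_spikes: int, dt: float) -> np.ndarray:
    """ISI schedule: geometric ramp from 1/fmax_init to 1/fmax_ss, then four
    ISIs held at the steady-state value (grid-aligned)."""
    if n_spikes < 2:
        return np.empty(0)
    isi0 = 1000.0 / tmpl.fmax_init
    isif = 1000.0 / tmpl.fmax_ss
    n_isi = n_spikes - 1
    if n_isi >= 5:
        ramp = np.geomspace(isi0, isif, n_isi - 4)
        isis = np.concatenate([ramp, np.full(4, isif)])
    else:
        isis = np.geomspace(isi0, isif, n_isi)
    isis = np.round(isis / dt) * dt
    if np.any(isis < 2.0):
        raise ValueError("ISI schedule violates the 2 ms absolute refractory period")
    return isis


def _render_spike(
    v: np.ndarray,
    dt: float,
    t_thr: float,
    thr: float,
    amp: float,
    hw: float,
    ahp: float,
    decay: float,
    adp_amp: float,
    adp_lat: float,
    next_thr_t: float | None,
    step_end_t: float,
) -> None:
    """Render one AP template in place; all anchor times grid-aligned."""
    i_thr = int(round(t_thr / dt))
    peak = thr + amp
    t_r = _RISE_MS
    t_f = max(2.0 * hw - t_r, dt)
    descent = max(decay - t_f, dt)
    i_peak = i_thr + int(round(t_r / dt))
    i_thr2 = i_peak + int(round(t_f / dt))  # back at threshold level
    i_trough = i_peak + int(round(decay / dt))
    ahp_v = thr - ahp

    n = v.size
    sl = slice(i_thr, min(i_peak + 1, n))
    v[sl] = np.interp(np.arange(sl.start, sl.stop), [i_thr, i_peak], [thr, peak])
    sl = slice(i_peak, min(i_thr2 + 1, n))
    v[sl] = np.interp(np.arange(sl.start, sl.stop), [i_peak, i_thr2], [peak, thr])
    sl = slice(i_thr2, min(i_trough + 1, n))
    v[sl] = np.interp(np.arange(sl.start, sl.stop), [i_thr2, i_trough], [thr, ahp_v])

    v_base = thr - _FOOT_DEPTH
    i_end = int(round(step_end_t / dt))
    if next_thr_t is not None:
        i_next = int(round(next_thr_t / dt))
        gap_ms = (i_next - i_trough) * dt
        if adp_amp > 0 and gap_ms > adp_lat + 40.0:
            _render_adp(v, dt, i_trough, ahp_v, adp_amp, adp_lat, v_base)
            i_foot = i_next - int(round(_FOOT_MS / dt))
            sl = slice(i_foot, i_next + 1)
            v[sl] = np.interp(np.arange(sl.start, sl.stop), [i_foot, i_next],
                              [v[i_foot], thr])
        else:
            # crowded train: rise straight back to the next threshold
            sl = slice(i_trough, min(i_next + 1, n))
            v[sl] = np.interp(np.arange(sl.start, sl.stop), [i_trough, i_next],
                              [ahp_v, thr])
    else:
        stop = min(i_end, n)
        if adp_amp > 0 and (stop - i_trough) * dt > adp_lat + 40.0:
            _render_adp(v, dt, i_trough, ahp_v, adp_amp, adp_lat, v_base)
        else:
            rec = max(int(round((v_base - ahp_v) / 5.0 / dt)), 2)
            sl = slice(i_trough, min(i_trough + rec + 1, stop))
            if sl.stop > sl.start:
                v[sl] = np.interp(np.arange(sl.start, sl.stop),
                                  [i_trough, i_trough + rec], [ahp_v, v_base])
            if i_trough + rec < stop:
                v[i_trough + rec : stop] = v_base


def _render_adp(
    v: np.ndarray,
    dt: float,
    i_trough: int,
    ahp_v: float,
    adp_amp: float,
    adp_lat: float,
    v_base: float,
) -> None:
    """Half-cosine afterdepolarization bump followed by decay to baseline."""
    i_adp = i_trough + int(round(adp_lat / dt))
    adp_v = ahp_v + adp_amp
    sl = slice(i_trough, min(i_adp + 1, v.size))
    ts = np.arange(sl.start, sl.stop)
    v[sl] = ahp_v + adp_amp * 0.5 * (1 - np.cos(np.pi * (ts - i_trough) / (i_adp - i_trough)))
    i_dec = i_adp + int(round(30.0 / dt))
    sl = slice(i_adp, min(i_dec + 1, v.size))
    ts = np.arange(sl.start, sl.stop)
    if sl.stop > sl.start:
        v[sl] = v_base + (adp_v - v_base) * 0.5 * (
            1 + np.cos(np.pi * (ts - i_adp) / (i_dec - i_adp))
        )
    if i_dec < v.size:
        v[i_dec:] = v_base


def synth_trace_ladder(
    spec: SubtypeSpec | TraceTemplate,
    seed: int = 0,
    noise_sd: float = 0.2,
    dt: float = 0.1,
    step_onset: float = 100.0,
    step_duration: float = 800.0,
    post_window: float = 100.0,
    current_min: float = -100.0,
    current_max: float = 600.0,
    current_step: float = 10.0,
    cell_id: str = "synthetic",
) -> tuple[SweepLadder, FeatureVector]:
    """Render one cell's sweep ladder together with its ground truth.

    Subthreshold sweeps are RC relaxations with the template's τ and input
    resistance (the -100 pA sweep additionally carries the sag relaxation);
    sweeps at and above rheobase carry spike trains whose counts, latencies
    and ISI schedules interpolate between the rheobase and saturated
    template blocks.  Gaussian noise of ``noise_sd`` mV is added per sample
    (0 gives the noiseless limit where extraction matches truth to
    numerical precision).

    Returns ``(ladder, truth)`` where ``truth`` is the
    :class:`~vtasst.features.FeatureVector` an ideal extractor would
    recover.
    """
    tmpl = spec.template if isinstance(spec, SubtypeSpec) else spec
    rng = np.random.default_rng(seed)
    currents = np.arange(current_min, current_max + current_step / 2, current_step)
    n_samples = int(round((step_onset + step_duration + post_window) / dt))
    i_on = int(round(step_onset / dt))
    i_off = int(round((step_onset + step_duration) / dt))
    t_step = (np.arange(i_on, i_off) - i_on) * dt

    # current grid anchors for interpolation
    i_rh = currents[currents >= tmpl.rheobase]
    if i_rh.size == 0:
        raise ValueError("rheobase above the current range")
    rheo_grid = float(i_rh[0])
    sat_candidates = currents[currents >= tmpl.saturating_current]
    sat_grid = float(sat_candidates[0]) if sat_candidates.size else float(currents[-1])
    sat_grid = max(sat_grid, rheo_grid + current_step)

    sat_isis = _sat_isis(tmpl, tmpl.count_sat, dt)
    lat_sat = _snap(tmpl.latency_sat, dt)
    lat_rheo = _snap(tmpl.latency_rheo, dt)

    voltages = np.empty((currents.size, n_samples))
    realized: dict[str, np.ndarray] = {}
    for si, cur in enumerate(currents):
        v = np.full(n_samples, tmpl.rmp)
        dv = cur * tmpl.rin / 1000.0  # steady-state deflection, mV
        if cur < rheo_grid:
            if np.isclose(cur, current_min) and tmpl.sag_ratio < 1.0:
                v_ss = tmpl.rmp + dv
                v_trough = v_ss / tmpl.sag_ratio
                split = t_step < _SAG_SPLIT_MS
                v[i_on:i_off][split] = v_trough + (tmpl.rmp - v_trough) * np.exp(
                    -t_step[split] / tmpl.tau
                )
                v[i_on:i_off][~split] = v_ss + (v_trough - v_ss) * np.exp(
                    -(t_step[~split] - _SAG_SPLIT_MS) / _SAG_TAU_MS
                )
            else:
                v[i_on:i_off] = (tmpl.rmp + dv) + (tmpl.rmp - (tmpl.rmp + dv)) * np.exp(
                    -t_step / tmpl.tau
                )
            v_end = v[i_off - 1]
        else:
            frac = min((cur - rheo_grid) / (sat_grid - rheo_grid), 1.0)
            count = (
                tmpl.count_sat
                if frac >= 1.0
                else int(tmpl.count_rheo + frac * (tmpl.count_sat - tmpl.count_rheo))
            )
            count = max(count, 1)
            lat = _snap(lat_rheo + frac * (lat_sat - lat_rheo), dt)
            thr = tmpl.threshold
            amp = tmpl.amplitude + frac * (tmpl.amplitude_sat - tmpl.amplitude)
            hw = tmpl.halfwidth + frac * (tmpl.halfwidth_sat - tmpl.halfwidth)
            ahp = tmpl.ahp_amp + frac * (tmpl.ahp_amp_sat - tmpl.ahp_amp)
            decay = _snap(tmpl.decay + frac * (tmpl.decay_sat - tmpl.decay), dt)
            if frac >= 1.0 and sat_isis.size:
                isis = sat_isis[: count - 1]
            elif count > 1:
                isi0 = tmpl.isi_rheo + frac * (1000.0 / tmpl.fmax_init - tmpl.isi_rheo)
                isif = tmpl.isi_rheo + frac * (1000.0 / tmpl.fmax_ss - tmpl.isi_rheo)
                isis = np.round(np.geomspace(isi0, max(isif, isi0), count - 1) / dt) * dt
            else:
                isis = np.empty(0)
            thr_times = step_onset + lat + np.concatenate([[0.0], np.cumsum(isis)])
            # drop spikes whose template would not fit inside the step
            keep = thr_times < step_onset + step_duration - (decay + 5.0)
            thr_times = thr_times[keep]
            if np.isclose(cur, rheo_grid):
                realized["rheo_n"] = thr_times.size
            if np.isclose(cur, sat_grid):
                realized["sat_isis"] = np.diff(thr_times)
                realized["sat_n"] = thr_times.size

            v_base = thr - _FOOT_DEPTH
            # subthreshold approach toward the foot of the first spike
            v[i_on:i_off] = v_base + (tmpl.rmp - v_base) * np.exp(-t_step / tmpl.tau)
            i_foot = int(round((thr_times[0] - _FOOT_MS) / dt))
            i_first = int(round(thr_times[0] / dt))
            sl = slice(max(i_foot, i_on), i_first + 1)
            v[sl] = np.interp(np.arange(sl.start, sl.stop), [sl.start, i_first],
                              [v[sl.start], thr])
            for k, t_thr in enumerate(thr_times):
                nxt = thr_times[k + 1] if k + 1 < thr_times.size else None
                _render_spike(
                    v, dt, _snap(t_thr, dt), thr, amp, hw, ahp, decay,
                    tmpl.adp_amp, _snap(tmpl.adp_latency, dt) if tmpl.adp_amp else 0.0,
                    nxt, step_onset + step_duration,
                )
            v_end = v[i_off - 1]
        # post-step relaxation back to rest
        t_post = (np.arange(i_off, n_samples) - i_off) * dt
        v[i_off:] = tmpl.rmp + (v_end - tmpl.rmp) * np.exp(-t_post / tmpl.tau)
        voltages[si] = v

    if noise_sd > 0:
        voltages = voltages + rng.normal(0.0, noise_sd, voltages.shape)

    ladder = SweepLadder(
        cell_id=cell_id,
        dt=dt,
        currents=currents,
        voltages=voltages,
        step_onset=step_onset,
        step_duration=step_duration,
        capacitance_pf=tmpl.capacitance_pf,
    )

    # ground truth, from the realized (grid-snapped) schedule
    truth = FeatureVector(
        rmp=tmpl.rmp,
        input_resistance=tmpl.rin,
        sag=tmpl.sag_ratio,
        tau_membrane=tmpl.tau,
        capacitance_pf=tmpl.capacitance_pf,
        rheobase_current=rheo_grid,
        ap_threshold=tmpl.threshold,
        ap_amplitude=tmpl.amplitude,
        ap_halfwidth=tmpl.halfwidth,
        ahp_amplitude=tmpl.ahp_amp,
        ap_decay=_snap(tmpl.decay, dt),
        adp_amplitude=tmpl.adp_amp,
        adp_latency=_snap(tmpl.adp_latency, dt) if tmpl.adp_amp else 0.0,
        first_spike_latency_rheo=lat_rheo,
        spike_count_rheo=float(realized.get("rheo_n", tmpl.count_rheo)),
        saturating_current=sat_grid,
        first_spike_latency_sat=lat_sat,
        spike_count_sat=float(realized.get("sat_n", tmpl.count_sat)),
        ap_halfwidth_sat=tmpl.halfwidth_sat,
        ap_amplitude_sat=tmpl.amplitude_sat,
        ahp_amplitude_sat=tmpl.ahp_amp_sat,
    )
    isis_real = realized.get("sat_isis", sat_isis)
    if isis_real.size:
        early = isis_real[:2] if isis_real.size >= 2 else isis_real
        late = isis_real[-4:] if isis_real.size >= 4 else isis_real
        truth.fmax_init = 1000.0 / early.min()
        truth.fmax_ss = 1000.0 / late.mean()
        truth.adaptation_ratio = truth.fmax_ss / truth.fmax_init
        truth.isi_cv_sat = (
            float(isis_real.std(ddof=0) / isis_real.mean())
            if isis_real.size > 1
            else 0.0
        )
    return ladder, truth


def sample_template(spec: SubtypeSpec, rng: np.random.Generator) -> TraceTemplate:
    """Draw a per-cell template variant with mild multiplicative jitter.

    Keeps the schedule valid: latencies stay positive, spike counts at
    least 1, AP decay at least the downstroke duration.
    """
    t = spec.template
    cv = spec.template_cv

    def j(x, lo=None, hi=None):
        y = x * (1.0 + rng.normal(0.0, cv)) if x else x
        if lo is not None:
            y = max(y, lo)
        if hi is not None:
            y = min(y, hi)
        return y

    hw = j(t.halfwidth, 0.3)
    hw_sat = j(t.halfwidth_sat, 0.4)
    return replace(
        t,
        rmp=t.rmp + rng.normal(0.0, 1.5),
        tau=j(t.tau, 5.0),
        rin=j(t.rin, 100.0),
        sag_ratio=min(j(t.sag_ratio), 0.999),
        capacitance_pf=j(t.capacitance_pf, 4.0),
        rheobase=j(t.rheobase, 5.0),
        saturating_current=j(t.saturating_current, 60.0),
        threshold=t.threshold + rng.normal(0.0, 1.0),
        amplitude=j(t.amplitude, 40.0),
        halfwidth=hw,
        ahp_amp=j(t.ahp_amp, 21.0, 45.0),
        decay=max(j(t.decay, 0.5), 2.0 * hw - _RISE_MS + 0.2),
        amplitude_sat=j(t.amplitude_sat, 35.0),
        halfwidth_sat=hw_sat,
        ahp_amp_sat=j(t.ahp_amp_sat, 5.0, 40.0),
        decay_sat=max(j(t.decay_sat, 1.0), 2.0 * hw_sat - _RISE_MS + 0.2),
        adp_amp=j(t.adp_amp, 2.0) if t.adp_amp else 0.0,
        adp_latency=j(t.adp_latency, 8.0, 60.0) if t.adp_amp else 0.0,
        latency_rheo=j(t.latency_rheo, 20.0, 700.0),
        latency_sat=j(t.latency_sat, 8.0, 600.0),
        count_rheo=max(int(round(j(float(t.count_rheo)))), 1),
        count_sat=max(int(round(j(float(t.count_sat)))), t.count_rheo + 1),
        fmax_init=j(t.fmax_init, 10.0, 300.0),
        fmax_ss=j(t.fmax_ss, 5.0, 100.0),
        isi_rheo=j(t.isi_rheo, 50.0),
    )


# ---------------------------------------------------------------------------
# photostimulation sessions
# ---------------------------------------------------------------------------


def synth_photostim_session(
    n_sources: int,
    footprint_radius_px: float = 1.6,
    connection_prob: float = 0.5,
    amplitude_range_pa: tuple[float, float] = (8.0, 218.0),
    trials: int = 3,
    seed: int = 0,
    rows: int = 32,
    cols: int = 32,
    pitch: float = 16.0,
    p_inside: float = 0.95,
    p_outside: float = 0.01,
    amplitude_noise_pa: float = 2.0,
):
    """Emulate one optical circuit-mapping session on the standard 32x32 grid.

    Each presynaptic source has a disc-shaped light-sensitive region
    (per-trial spike probability ``p_inside`` inside, ``p_outside``
    elsewhere).  Sources connected to the virtual postsynaptic cell
    contribute IPSC events inside their disc, with per-source amplitudes
    drawn from ``amplitude_range_pa``.

    Returns ``(ap_grids, ipsc_grid, truth)`` where ``ap_grids`` is one
    spike-success :class:`~vtasst.optomap.PhotostimGrid` per source and
    ``truth`` records source centers, connectivity and amplitudes.
    """
    from .optomap import PhotostimGrid

    rng = np.random.default_rng(seed)
    r = footprint_radius_px
    margin = int(np.ceil(r)) + 1
    yy, xx = np.mgrid[0:rows, 0:cols]

    centers, discs, connected, amps = [], [], [], []
    for _ in range(n_sources):
        cy = rng.integers(margin, rows - margin)
        cx = rng.integers(margin, cols - margin)
        centers.append((int(cy), int(cx)))
        discs.append((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2)
        connected.append(bool(rng.random() < connection_prob))
        amps.append(float(rng.uniform(*amplitude_range_pa)))

    ap_grids = []
    for disc in discs:
        p = np.where(disc, p_inside, p_outside)
        succ = rng.random((rows, cols, trials)) < p[..., None]
        ap_grids.append(
            PhotostimGrid(mode="ap_success", values=succ, pitch=pitch)
        )

    ipsc = np.zeros((rows, cols, trials))
    for disc, con, amp in zip(discs, connected, amps):
        if not con:
            continue
        for t in range(trials):
            event = (rng.random((rows, cols)) < p_inside) & disc
            contribution = np.where(
                event, np.maximum(amp + rng.normal(0.0, amplitude_noise_pa,
                                                   (rows, cols)), 1.0), 0.0
            )
            ipsc[:, :, t] += contribution
    ipsc_grid = PhotostimGrid(mode="ipsc", values=ipsc, pitch=pitch)
    truth = {
        "centers": centers,
        "connected": connected,
        "amplitudes_pa": amps,
        "radius_px": r,
    }
    return ap_grids, ipsc_grid, truth


# ---------------------------------------------------------------------------
# Patch-seq datasets
# ---------------------------------------------------------------------------


def synth_patchseq(
    n_cells: int = 69,
    n_genes: int = 1000,
    qc_fail_reads: int = 5,
    qc_fail_align: int = 3,
    n_ref_cells: int = 300,
    n_ref_clusters: int = 6,
    n_depth_genes: int = 150,
    seed: int = 0,
):
    """Generate paired Patch-seq and reference single-cell count datasets.

    The Patch-seq cohort contains ``qc_fail_reads`` cells below the 75,500
    total-read floor and ``qc_fail_align`` further cells below the 50%
    alignment floor (defaults reproduce the 61-of-69 survivor margin).
    Counts are negative-binomial around per-cluster centroids.  In the
    reference, a designated subset of ``n_depth_genes`` genes scales with a
    latent per-cell depth factor, so their expression correlates with the
    molecular count; these same genes are given high Patch-seq expression
    so they are detected in every cell, making them the expected
    depth-normalization gene set.

    Returns ``(patchseq_dataset, reference_dataset, truth)`` with
    ``truth["depth_genes"]`` naming the designated subset.
    """
    from .patchseq import PatchSeqDataset, ReferenceDataset

    if qc_fail_reads + qc_fail_align > n_cells:
        raise ValueError("more designated QC failures than cells")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:04d}" for i in range(n_genes)])
    depth_genes = genes[:n_depth_genes]

    # cluster centroids: shared lognormal base + marker boosts
    base = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    centroids = np.tile(base, (n_ref_clusters, 1))
    marker_block = max((n_genes - n_depth_genes) // n_ref_clusters, 10)
    for c in range(n_ref_clusters):
        lo = n_depth_genes + c * marker_block
        hi = min(lo + marker_block, n_genes)
        centroids[c, lo:hi] *= 8.0
    centroids[:, :n_depth_genes] = rng.uniform(20.0, 60.0, n_depth_genes)

    def _nb(mean, r=10.0, size=None):
        mean = np.maximum(mean, 1e-9)
        return rng.negative_binomial(r, r / (r + mean), size=size)

    # reference: depth factor scales the designated genes only
    ref_labels = rng.integers(0, n_ref_clusters, n_ref_cells)
    depth = rng.lognormal(mean=0.0, sigma=0.4, size=n_ref_cells)
    ref_counts = np.empty((n_genes, n_ref_cells), dtype=np.int64)
    for i in range(n_ref_cells):
        mu = centroids[ref_labels[i]].copy()
        mu[:n_depth_genes] *= depth[i]
        ref_counts[:, i] = _nb(mu)
    ref = ReferenceDataset(
        expression=ref_counts,
        gene_names=list(genes),
        cell_ids=[f"ref{i:04d}" for i in range(n_ref_cells)],
        cluster_labels=np.array([f"cluster_{l}" for l in ref_labels]),
        molecular_count=ref_counts.sum(axis=0).astype(float),
    )

    # Patch-seq cohort drawn from the same centroids
    ps_labels = rng.integers(0, n_ref_clusters, n_cells)
    ps_depth = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    for i in range(n_cells):
        mu = centroids[ps_labels[i]].copy()
        mu[:n_depth_genes] *= ps_depth[i]
        counts[:, i] = _nb(mu)
    # designated depth genes must be detected in every cell
    zero = counts[:n_depth_genes] == 0
    counts[:n_depth_genes][zero] = 1

    total_reads = rng.lognormal(mean=np.log(4e6), sigma=0.3, size=n_cells)
    alignment = rng.uniform(0.55, 0.95, n_cells)
    order = rng.permutation(n_cells)
    low_reads = order[:qc_fail_reads]
    low_align = order[qc_fail_reads : qc_fail_reads + qc_fail_align]
    total_reads[low_reads] = rng.uniform(1e4, 75499.0, qc_fail_reads)
    alignment[low_align] = rng.uniform(0.2, 0.499, qc_fail_align)

    ps = PatchSeqDataset(
        counts=counts,
        gene_names=list(genes),
        cell_ids=[f"ps{i:03d}" for i in range(n_cells)],
        total_reads=np.floor(total_reads),
        alignment_rate=alignment,
    )
    truth = {
        "depth_genes": list(depth_genes),
        "patchseq_clusters": np.array([f"cluster_{l}" for l in ps_labels]),
        "low_read_cells": [ps.cell_ids[i] for i in low_reads],
        "low_alignment_cells": [ps.cell_ids[i] for i in low_align],
        "depth_factor": ps_depth,
    }
    return ps, ref, truth
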