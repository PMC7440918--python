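"""Optical footprint and inhibitory input-map analysis, plus
electrochemical utilities.

A photostimulation session scans a laser spot over a 32 x 32 grid
(16 µm pitch, three trials per location).  For a recorded ChR2-expressing
presynaptic cell, the *optical footprint* is the set of spot locations that
evoked an action potential in at least 2/3 of trials; for a postsynaptic
cell, the *input map* keeps locations where an IPSC was evoked in at least
2/3 of trials and stores the mean event amplitude.  Areas are the number of
qualifying pixels times the pixel area (256 µm² at the default pitch).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhotostimGrid",
    "FootprintMap",
    "InputMap",
    "compute_footprint",
    "compute_input_map",
    "count_clusters",
    "convergence_summary",
    "nernst_potential",
    "solution_chloride",
    "CHLORIDE_PER_FORMULA",
]

MIN_TRIALS_FRACTION = 2.0 / 3.0
#: IPSC event floor (pA): amplitudes at or below this do not count as events
IPSC_AMPLITUDE_FLOOR_PA = 5.0
#: event threshold as a multiple of the pixel-baseline noise SD
IPSC_NOISE_SD_MULTIPLE = 3.0


@dataclass
class PhotostimGrid:
    """Trial-resolved photostimulation response grid.

    ``values`` is ``(rows, cols, trials)``: boolean spike successes for
    ``mode="ap_success"``, IPSC amplitudes in pA (0 = no event) for
    ``mode="ipsc"``.  Pixel centers sit at ``(i + 0.5) * pitch`` in a
    row-major, 0-based convention.
    """

    mode: str
    values: np.ndarray
    pitch: float = 16.0
    laser_power_uw: float | None = None
    flash_ms: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.mode not in ("ap_success", "ipsc"):
            raise ValueError(f"unknown grid mode {self.mode!r}")
        if self.values.ndim != 3 or self.values.shape[2] < 1:
            raise ValueError("values must be rows x cols x trials with trials >= 1")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    @property
    def pixel_area_um2(self) -> float:
        return self.pitch**2

    @property
    def field_area_mm2(self) -> float:
        """Total scanned area in mm² (0.26 mm² for the standard 32x32 scan)."""
        return self.values.shape[0] * self.values.shape[1] * self.pitch**2 / 1e6


@dataclass
class FootprintMap:
    """Binary optical footprint with its area."""

    mask: np.ndarray
    pitch: float

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pitch**2


@dataclass
class InputMap:
    """Per-pixel mean IPSC amplitude map with normalization."""

    amplitudes: np.ndarray  # pA; 0 where no qualifying response
    pitch: float

    @property
    def mask(self) -> np.ndarray:
        return self.amplitudes > 0

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pitch**2

    @property
    def max_amplitude_pa(self) -> float:
        return float(self.amplitudes.max()) if self.n_pixels else 0.0

    @property
    def mean_amplitude_pa(self) -> float:
        return float(self.amplitudes[self.mask].mean()) if self.n_pixels else 0.0

    @property
    def normalized_amplitudes(self) -> np.ndarray:
        """Amplitudes scaled to [0, 1] by the map maximum (all-zero maps
        are returned unscaled)."""
        m = self.max_amplitude_pa
        return self.amplitudes / m if m > 0 else self.amplitudes.astype(float)


def compute_footprint(
    grid: PhotostimGrid, min_trials_fraction: float = MIN_TRIALS_FRACTION
) -> FootprintMap:
    """Optical footprint: pixels evoking a spike in >= 2/3 of trials."""
    if grid.mode != "ap_success":
        raise ValueError("footprints need an ap_success grid")
    frac = grid.values.astype(bool).mean(axis=2)
    # tolerate float representation of 2/3 against discrete trial fractions
    mask = frac >= min_trials_fraction - 1e-12
    return FootprintMap(mask=mask, pitch=grid.pitch)


def compute_input_map(
    grid: PhotostimGrid,
    min_trials_fraction: float = MIN_TRIALS_FRACTION,
    amplitude_floor_pa: float = IPSC_AMPLITUDE_FLOOR_PA,
    noise_sd_multiple: float = IPSC_NOISE_SD_MULTIPLE,
) -> InputMap:
    """Inhibitory input map: pixels with an IPSC in >= 2/3 of trials.

    An amplitude counts as an event when it exceeds both the fixed floor
    (default 5 pA) and ``noise_sd_multiple`` times the session noise SD
    estimated from the sub-floor amplitudes.  The pixel amplitude is the
    mean over event trials.
    """
    if grid.mode != "ipsc":
        raise ValueError("input maps need an ipsc grid")
    amps = grid.values.astype(float)
    sub = amps[(amps > 0) & (amps <= amplitude_floor_pa)]
    noise_sd = float(sub.std()) if sub.size else 0.0
    threshold = max(amplitude_floor_pa, noise_sd_multiple * noise_sd)
    events = amps > threshold
    frac = events.mean(axis=2)
    qualify = frac >= min_trials_fraction - 1e-12
    with np.errstate(invalid="ignore"):
        mean_amp = np.where(
            events.any(axis=2),
            amps.sum(axis=2, where=events) / np.maximum(events.sum(axis=2), 1),
            0.0,
        )
    return InputMap(amplitudes=np.where(qualify, mean_amp, 0.0), pitch=grid.pitch)


def count_clusters(map_: FootprintMap | InputMap) -> int:
    """Number of 4-connected pixel clusters in a map."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, n = ndimage.label(map_.mask, structure=structure)
    return int(n)


def convergence_summary(
    footprints: Sequence[FootprintMap], inputs: Sequence[InputMap]
) -> dict:
    """Compare footprint and input-field areas across cells.

    Returns medians, interquartile ranges and the input/footprint median
    ratio.  An input-field median much larger than the footprint median
    indicates convergence of several presynaptic cells; no attempt is made
    to infer the presynaptic cell count.
    """
    if not footprints or not inputs:
        raise ValueError("footprints and inputs must be nonempty")
    fp = np.array([f.area_um2 for f in footprints], dtype=float)
    im = np.array([m.area_um2 for m in inputs], dtype=float)

    def _iqr(x):
        return float(np.percentile(x, 75) - np.percentile(x, 25))

    fp_med = float(median(fp))
    im_med = float(median(im))
    return {
        "footprint_median_um2": fp_med,
        "footprint_iqr_um2": _iqr(fp),
        "footprint_n": len(fp),
        "input_median_um2": im_med,
        "input_iqr_um2": _iqr(im),
        "input_n": len(im),
        "median_ratio": im_med / fp_med if fp_med else np.inf,
    }


# ---------------------------------------------------------------------------
# electrochemistry
# ---------------------------------------------------------------------------

GAS_CONSTANT = 8.31446261815324  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: chloride ions per formula unit for common recording-solution salts
CHLORIDE_PER_FORMULA = {
    "NaCl": 1,
    "KCl": 1,
    "CaCl2": 2,
    "MgCl2": 2,
    "CsCl": 1,
    "TEA-Cl": 1,
    "choline-Cl": 1,
    "HCl": 1,
    "NH4Cl": 1,
}


def nernst_potential(
    valence: int, conc_in: float, conc_out: float, temperature_c: float = 24.0
) -> float:
    """Nernst reversal potential ``E = (RT / zF) ln([out]/[in])`` in mV.

    Concentrations in mM (any common unit, as only the ratio matters);
    temperature in °C.  E.g. the chloride reversal for a 145 mM internal /
    135 mM external chloride pair at 24 °C is +1.8 mV.
    """
    if valence == 0:
        raise ValueError("valence must be nonzero")
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError("concentrations must be positive")
    t_kelvin = temperature_c + 273.15
    return (
        GAS_CONSTANT * t_kelvin / (valence * FARADAY) * np.log(conc_out / conc_in) * 1000.0
    )


def solution_chloride(recipe: Sequence[tuple[str, float]]) -> float:
    """Total chloride concentration (mM) contributed by a salt recipe.

    ``recipe`` is a list of (salt name, mM) pairs; salts must appear in
    :data:`CHLORIDE_PER_FORMULA`.
    """
    total = 0.0
    for salt, mm in recipe:
        if salt not in CHLORIDE_PER_FORMULA:
            raise KeyError(f"unknown salt {salt!r}")
        if mm < 0:
            raise ValueError(f"negative concentration for {salt!r}")
        total += mm * CHLORIDE_PER_FORMULA[salt]
    return total
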