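"""Reading, writing and validation of current-clamp sweep ladders.

A *sweep ladder* is one cell's set of voltage responses to the standard
square-step protocol: 800 ms current injections increasing from -100 pA to
+600 pA in 10 pA increments, sampled at 10 kHz.  The canonical on-disk form
is a self-describing HDF5 container (one file per experiment, one group per
cell); a CSV long format is provided for interchange and Axon Binary files
can be read when the optional ``pyabf`` dependency is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SweepLadder",
    "LadderQCReport",
    "FormatError",
    "ValidationError",
    "read_sweep_ladder",
    "write_sweep_ladder",
    "validate_ladder",
]

#: RMP exclusion limit: depolarized cells resting above this are discarded.
RMP_DEPOLARIZED_LIMIT_MV = -50.0
#: RMP stability limit: per-sweep baseline SD above this is unstable.
RMP_SD_LIMIT_MV = 6.0


class FormatError(RuntimeError):
    """Raised when a file cannot be parsed in the requested dialect."""


class ValidationError(ValueError):
    """Raised when a ladder violates a structural invariant."""


@dataclass
class SweepLadder:
    """One cell's voltage responses to the current-step protocol.

    Parameters
    ----------
    cell_id
        Free-text cell identifier.
    dt
        Sampling interval in ms (0.1 ms = 10 kHz by default).
    currents
        Injected current per sweep in pA, strictly increasing with a
        constant increment (10 pA over -100..+600 pA in the standard
        protocol).
    voltages
        ``(n_sweeps, n_samples)`` membrane voltage in mV.
    step_onset
        Time of current-step onset in ms from the start of each sweep.
    step_duration
        Length of the current step in ms (800 ms in the standard protocol).
    capacitance_pf
        Whole-cell capacitance from the amplifier membrane test, if known.
    age_group
        ``"juvenile"`` or ``"adult"``.
    location
        Optional anatomical annotation (nucleus label, bregma, etc.).
    """

    cell_id: str
    dt: float
    currents: np.ndarray
    voltages: np.ndarray
    step_onset: float
    step_duration: float = 800.0
    capacitance_pf: float | None = None
    age_group: str = "juvenile"
    location: dict | None = None

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        order = np.argsort(self.currents, kind="stable")
        if not np.array_equal(order, np.arange(order.size)):
            self.currents = self.currents[order]
            self.voltages = self.voltages[order]
        self.validate_structure()

    # -- structural invariants ------------------------------------------------
    def validate_structure(self) -> None:
        if self.dt <= 0:
            raise ValidationError("sampling interval dt must be positive")
        if self.voltages.ndim != 2 or self.voltages.shape[0] == 0:
            raise ValidationError("ladder must contain at least one sweep")
        if self.currents.shape[0] != self.voltages.shape[0]:
            raise ValidationError(
                f"{self.currents.shape[0]} currents but "
                f"{self.voltages.shape[0]} voltage traces"
            )
        diffs = np.diff(self.currents)
        if diffs.size:
            if np.any(diffs <= 0):
                bad = int(np.argmax(diffs <= 0)) + 1
                raise ValidationError(
                    f"injected currents not strictly increasing at sweep {bad}"
                )
            if not np.allclose(diffs, diffs[0]):
                bad = int(np.argmax(~np.isclose(diffs, diffs[0]))) + 1
                raise ValidationError(
                    f"non-uniform current increment at sweep {bad} "
                    f"({diffs[bad - 1]:g} pA vs {diffs[0]:g} pA)"
                )
        min_samples = int(round((self.step_onset + self.step_duration) / self.dt))
        if self.voltages.shape[1] < min_samples:
            raise ValidationError(
                "voltage traces shorter than step_onset + step_duration"
            )

    # -- convenience ----------------------------------------------------------
    @property
    def n_sweeps(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms."""
        return np.arange(self.n_samples) * self.dt

    def sweep_at(self, current_pa: float) -> np.ndarray:
        """Voltage trace for the sweep at ``current_pa`` (exact match)."""
        idx = np.flatnonzero(np.isclose(self.currents, current_pa))
        if idx.size == 0:
            raise KeyError(f"no sweep at {current_pa} pA")
        return self.voltages[idx[0]]

    def baselines(self) -> np.ndarray:
        """Per-sweep mean voltage over the pre-step window [0, step_onset)."""
        n_base = int(round(self.step_onset / self.dt))
        if n_base < 1:
            raise ValidationError("step_onset leaves no baseline window")
        return self.voltages[:, :n_base].mean(axis=1)


@dataclass
class LadderQCReport:
    """Resting-membrane-potential quality control verdict for one cell."""

    cell_id: str
    rmp_mean: float
    rmp_sd: float
    passed: bool
    reasons: list = field(default_factory=list)


def validate_ladder(ladder: SweepLadder) -> LadderQCReport:
    """Apply the recording-level RMP exclusion rules.

    A cell fails with reason ``"rmp_depolarized"`` when its resting membrane
    potential (mean of per-sweep pre-step baselines) is above -50 mV, and
    with reason ``"rmp_unstable"`` when the standard deviation of per-sweep
    baselines exceeds 6 mV.  Both thresholds are strict inequalities.
    """
    base = ladder.baselines()
    rmp = float(base.mean())
    sd = float(base.std(ddof=0))
    reasons = []
    if rmp > RMP_DEPOLARIZED_LIMIT_MV:
        reasons.append("rmp_depolarized")
    if sd > RMP_SD_LIMIT_MV:
        reasons.append("rmp_unstable")
    return LadderQCReport(ladder.cell_id, rmp, sd, passed=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# Canonical HDF5 layout: /cells/<id>/voltage  (sweeps x samples, mV)
#   with attrs currents_pa, dt_ms, step_onset_ms, step_duration_ms,
#   optional capacitance_pf, age_group.
# ---------------------------------------------------------------------------

Dialect = Literal["hdf5", "csv-long", "abf"]

_CSV_COLUMNS = ["cell_id", "sweep_index", "current_pa", "time_ms", "voltage_mv"]


def write_sweep_ladder(ladder: SweepLadder, path, dialect: Dialect = "hdf5") -> None:
    """Write ``ladder`` to ``path`` in the requested dialect.

    HDF5 round-trips voltages bit-exactly; CSV to six decimals.  ABF is a
    read-only format.
    """
    ladder.validate_structure()
    path = Path(path)
    if dialect == "hdf5":
        import h5py

        with h5py.File(path, "a") as f:
            grp = f.require_group("cells")
            if ladder.cell_id in grp:
                del grp[ladder.cell_id]
            g = grp.create_group(ladder.cell_id)
            g.create_dataset("voltage", data=ladder.voltages)
            g.attrs["currents_pa"] = ladder.currents
            g.attrs["dt_ms"] = ladder.dt
            g.attrs["step_onset_ms"] = ladder.step_onset
            g.attrs["step_duration_ms"] = ladder.step_duration
            g.attrs["age_group"] = ladder.age_group
            if ladder.capacitance_pf is not None:
                g.attrs["capacitance_pf"] = ladder.capacitance_pf
    elif dialect == "csv-long":
        t = ladder.time
        frames = []
        for i, (cur, v) in enumerate(zip(ladder.currents, ladder.voltages)):
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": ladder.cell_id,
                        "sweep_index": i,
                        "current_pa": cur,
                        "time_ms": t,
                        "voltage_mv": v,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(path, index=False, float_format="%.6f")
    elif dialect == "abf":
        raise FormatError("Axon Binary Format is read-only")
    else:
        raise FormatError(f"unsupported dialect {dialect!r}")


def read_sweep_ladder(
    path,
    dialect: Dialect = "hdf5",
    cell_id: str | None = None,
    step_onset: float | None = None,
    step_duration: float | None = None,
) -> SweepLadder:
    """Read one cell's sweep ladder from ``path``.

    For HDF5 containers holding several cells, ``cell_id`` selects the cell
    (defaults to the only cell present).  The returned ladder always has
    currents sorted ascending and satisfies every structural invariant.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "hdf5":
        import h5py

        try:
            with h5py.File(path, "r") as f:
                cells = f["cells"]
                cid = cell_id or next(iter(cells))
                g = cells[cid]
                return SweepLadder(
                    cell_id=cid,
                    dt=float(g.attrs["dt_ms"]),
                    currents=np.asarray(g.attrs["currents_pa"], dtype=float),
                    voltages=g["voltage"][...],
                    step_onset=float(g.attrs["step_onset_ms"]),
                    step_duration=float(g.attrs["step_duration_ms"]),
                    capacitance_pf=(
                        float(g.attrs["capacitance_pf"])
                        if "capacitance_pf" in g.attrs
                        else None
                    ),
                    age_group=str(g.attrs.get("age_group", "juvenile")),
                )
        except (OSError, KeyError) as exc:
            raise FormatError(f"cannot read HDF5 ladder from {path}: {exc}") from exc
    if dialect == "csv-long":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"cannot parse CSV ladder from {path}: {exc}") from exc
        missing = set(_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"CSV ladder missing columns: {sorted(missing)}")
        if cell_id is not None:
            df = df[df["cell_id"] == cell_id]
        cid = str(df["cell_id"].iloc[0])
        currents, traces = [], []
        for _, sub in df.groupby("sweep_index", sort=True):
            sub = sub.sort_values("time_ms")
            currents.append(float(sub["current_pa"].iloc[0]))
            traces.append(sub["voltage_mv"].to_numpy())
        t = df[df["sweep_index"] == df["sweep_index"].iloc[0]]["time_ms"].to_numpy()
        t = np.sort(t)
        dt = float(np.median(np.diff(t)))
        # step timing is not part of the CSV schema; callers may pass it,
        # otherwise assume the standard protocol (onset = 10% of the trace,
        # 800 ms step)
        n = len(traces[0])
        onset = step_onset if step_onset is not None else round(n * dt * 0.1, 6)
        duration = (
            step_duration if step_duration is not None else min(800.0, n * dt - 2 * onset)
        )
        return SweepLadder(
            cell_id=cid,
            dt=dt,
            currents=np.array(currents),
            voltages=np.vstack(traces),
            step_onset=onset,
            step_duration=duration,
        )
    if dialect == "abf":
        try:
            import pyabf  # type: ignore[import-not-found]
        except ImportError as exc:
            raise FormatError(
                "reading Axon Binary files requires the optional 'abf' extra "
                "(pip install vtasst[abf])"
            ) from exc
        abf = pyabf.ABF(str(path))
        currents, traces = [], []
        for i in abf.sweepList:
            abf.setSweep(i)
            currents.append(float(abf.sweepEpochs.levels[1]) if abf.sweepEpochs else i)
            traces.append(np.asarray(abf.sweepY, dtype=float))
        return SweepLadder(
            cell_id=cell_id or path.stem,
            dt=1000.0 / abf.dataRate,
            currents=np.array(currents),
            voltages=np.vstack(traces),
            step_onset=0.0,
            step_duration=len(traces[0]) * 1000.0 / abf.dataRate,
        )
    raise FormatError(f"unsupported dialect {dialect!r}")
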