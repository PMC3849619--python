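"""Time-frequency energy maps, reconstruction, and parameter-based filtering.

The energy density map renders each selected atom as its Wigner-blob: for a
Gabor atom with envelope exp(-pi*((t-u)/s)^2) the blob is the 2-D Gaussian

    W(t, omega) = (1/pi) * exp(-2*pi*((t-u)/s)^2 - s^2*(omega-omega0)^2/(2*pi))

normalized to unit integral, so the map integral equals the sum of squared
weights.  Cross-terms between atoms are omitted by construction, which is
what makes the map additive and non-negative.  Kronecker deltas render as
time lines and harmonics as frequency lines.

Atom filtering converts book entries to the physical parameters an
electroencephalographer works with (peak-to-peak amplitude in microvolts,
frequency in Hz, width in seconds) and keeps the entries satisfying all
criteria of a filter.  Presets encode the classical sleep-EEG definitions:
slow wave activity (SWA) as >= 50 uV peak-to-peak, >= 0.5 s, 0.5-4 Hz, and
sleep spindles as 11-15 Hz, 0.5-2 s, >= 15 uV peak-to-peak.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace

import numpy as np

from .atoms import atom_waveform  # noqa: F401  (re-exported for map/filter users)
from .mp import BookEntry, Decomposition, entry_waveform

__all__ = [
    "TFMapGrid",
    "AtomFilter",
    "SWA_FILTER",
    "SPINDLE_FILTER",
    "FILTER_PRESETS",
    "energy_map",
    "reconstruct",
    "atom_physical_params",
    "filter_atoms",
    "epoch_occupancy",
]


@dataclass
class TFMapGrid:
    """Time-frequency energy density on a regular grid.

    ``times`` in seconds, ``freqs`` in Hz, ``energy`` of shape
    (n_freqs, n_times), non-negative; the integral approximates the summed
    squared weights of the rendered atoms.
    """

    times: np.ndarray
    freqs: np.ndarray
    energy: np.ndarray

    def integral(self) -> float:
        dt = self.times[1] - self.times[0] if self.times.size > 1 else 1.0
        df = self.freqs[1] - self.freqs[0] if self.freqs.size > 1 else 1.0
        return float(self.energy.sum() * dt * df)

    def to_text(self) -> str:
        """Delimited text export with axis headers (first row: times, first
        column: freqs)."""
        lines = ["time_s\t" + "\t".join(f"{t:.9g}" for t in self.times)]
        for f, row in zip(self.freqs, self.energy):
            lines.append(f"{f:.9g}\t" + "\t".join(f"{v:.9g}" for v in row))
        return "\n".join(lines)


def energy_map(
    decomposition: Decomposition,
    *,
    times: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    n_times: int = 256,
    n_freqs: int = 256,
    channel: int = 0,
    trial: int = 0,
    subset: list[int] | None = None,
) -> TFMapGrid:
    """Sum of per-atom Wigner blobs weighted by squared weights, no cross-terms.

    Grids default to the full epoch and the 0..Nyquist band; custom grids must
    stay within them.
    """
    fs = decomposition.fs
    n = decomposition.n_samples
    if times is None:
        times = np.linspace(0.0, (n - 1) / fs, n_times)
    else:
        times = np.asarray(times, dtype=float)
        if times.min() < 0.0 or times.max() > (n - 1) / fs:
            raise ValueError("time grid extends beyond the epoch")
    if freqs is None:
        freqs = np.linspace(0.0, fs / 2.0, n_freqs)
    else:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.min() < 0.0 or freqs.max() > fs / 2.0:
            raise ValueError("frequency grid extends beyond Nyquist")
    energy = np.zeros((freqs.size, times.size))
    dt = times[1] - times[0] if times.size > 1 else 1.0
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    entries = decomposition.entries
    if subset is not None:
        entries = [entries[i] for i in subset]
    for entry in entries:
        w2 = float(entry.weights[channel, trial]) ** 2
        if w2 == 0.0:
            continue
        if entry.family in ("gabor", "gaussian"):
            s = entry.s
            u_s = entry.u / fs
            f0 = (entry.omega * fs / (2.0 * math.pi)) if entry.omega is not None else 0.0
            # unit-integral 2-D Gaussian in (t [s], f [Hz]) coordinates
            tt = np.exp(-2.0 * math.pi * ((times - u_s) * fs / s) ** 2)
            ff = np.exp(-2.0 * math.pi * (s * (freqs - f0) / fs) ** 2)
            blob = 2.0 * w2 * ff[:, None] * tt[None, :]
            if entry.family == "gaussian":
                # fold the negative-frequency half of the zero-frequency blob
                ff_neg = np.exp(-2.0 * math.pi * (s * (freqs + f0) / fs) ** 2)
                blob = blob + 2.0 * w2 * ff_neg[:, None] * tt[None, :]
            energy += blob
        elif entry.family == "delta":
            j = int(np.argmin(np.abs(times - entry.u / fs)))
            band = freqs.max() - freqs.min() if freqs.size > 1 else 1.0
            energy[:, j] += w2 / (dt * band)
        elif entry.family == "harmonic":
            f0 = entry.omega * fs / (2.0 * math.pi)
            i = int(np.argmin(np.abs(freqs - f0)))
            span = times.max() - times.min() if times.size > 1 else 1.0
            energy[i, :] += w2 / (df * span)
    return TFMapGrid(times=times, freqs=freqs, energy=energy)


def reconstruct(
    decomposition: Decomposition,
    subset: list[int] | None = None,
    *,
    channel: int = 0,
    trial: int = 0,
) -> np.ndarray:
    """Sum of weighted atom waveforms over a subset of book entries.

    The full subset plus the final residual reproduces the original epoch to
    numerical accuracy (telescoping of the pursuit recursion).
    """
    n = decomposition.n_samples
    out = np.zeros(n)
    entries = decomposition.entries
    if subset is not None:
        entries = [entries[i] for i in subset]
    for entry in entries:
        w = float(entry.weights[channel, trial])
        if w == 0.0:
            continue
        out += w * entry_waveform(entry, n, channel, trial)
    return out


def atom_physical_params(
    entry: BookEntry,
    *,
    n_samples: int,
    fs: float,
    calibration: float = 1.0,
    channel: int = 0,
    trial: int = 0,
) -> dict:
    """Physical parameters of a book entry in EEG conventions.

    Returns peak amplitude and peak-to-peak amplitude in uV (peak-to-peak is
    double the mathematical amplitude), frequency in Hz, width and center in
    seconds.
    """
    w = float(entry.weights[channel, trial])
    wf = entry_waveform(entry, n_samples, channel, trial)
    peak = abs(w) * float(np.abs(wf).max()) * calibration
    if entry.family == "harmonic":
        width_s = n_samples / fs
    elif entry.family == "delta":
        width_s = 1.0 / fs
    else:
        width_s = entry.s / fs
    freq_hz = entry.omega * fs / (2.0 * math.pi) if entry.omega is not None else 0.0
    return {
        "peak_uv": peak,
        "p2p_uv": 2.0 * peak,
        "freq_hz": freq_hz,
        "width_s": width_s,
        "center_s": entry.u / fs,
    }


@dataclass(frozen=True)
class AtomFilter:
    """Conjunction of bounds on the physical parameters of book atoms.

    Amplitude bounds are on the *peak-to-peak* value in uV (the EEG
    convention: double the mathematical amplitude); frequency bounds in Hz;
    width bounds in seconds; the time window bounds the atom center in
    seconds.  Unset bounds are inactive; all active criteria combine with
    logical AND.
    """

    min_p2p_uv: float | None = None
    max_p2p_uv: float | None = None
    min_freq_hz: float | None = None
    max_freq_hz: float | None = None
    min_width_s: float | None = None
    max_width_s: float | None = None
    t_start_s: float | None = None
    t_end_s: float | None = None

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.min_p2p_uv, self.max_p2p_uv),
            (self.min_freq_hz, self.max_freq_hz),
            (self.min_width_s, self.max_width_s),
            (self.t_start_s, self.t_end_s),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"filter bound min {lo} exceeds max {hi}")

    def matches(self, params: dict) -> bool:
        checks = (
            (self.min_p2p_uv, params["p2p_uv"], "ge"),
            (self.max_p2p_uv, params["p2p_uv"], "le"),
            (self.min_freq_hz, params["freq_hz"], "ge"),
            (self.max_freq_hz, params["freq_hz"], "le"),
            (self.min_width_s, params["width_s"], "ge"),
            (self.max_width_s, params["width_s"], "le"),
            (self.t_start_s, params["center_s"], "ge"),
            (self.t_end_s, params["center_s"], "le"),
        )
        for bound, value, op in checks:
            if bound is None:
                continue
            if op == "ge" and value < bound:
                return False
            if op == "le" and value > bound:
                return False
        return True


#: Slow wave activity: >= 50 uV peak-to-peak, width >= 0.5 s, 0.5-4 Hz.
SWA_FILTER = AtomFilter(min_p2p_uv=50.0, min_width_s=0.5, min_freq_hz=0.5, max_freq_hz=4.0)

#: Sleep spindles: 11-15 Hz, 0.5-2 s, >= 15 uV peak-to-peak.
SPINDLE_FILTER = AtomFilter(
    min_p2p_uv=15.0, min_freq_hz=11.0, max_freq_hz=15.0, min_width_s=0.5, max_width_s=2.0
)

FILTER_PRESETS = {"swa": SWA_FILTER, "spindle": SPINDLE_FILTER}


def filter_atoms(
    decomposition: Decomposition,
    atom_filter: AtomFilter,
    *,
    channel: int = 0,
    trial: int = 0,
) -> Decomposition:
    """Book entries satisfying all filter criteria, in iteration order.

    Idempotent and order-preserving; an empty result is allowed.  Amplitudes
    are evaluated on the given channel/trial.
    """
    kept = [
        e
        for e in decomposition.entries
        if atom_filter.matches(
            atom_physical_params(
                e,
                n_samples=decomposition.n_samples,
                fs=decomposition.fs,
                calibration=decomposition.calibration,
                channel=channel,
                trial=trial,
            )
        )
    ]
    prov = dict(decomposition.provenance)
    prov["filter"] = {
        k: v for k, v in dataclasses.asdict(atom_filter).items() if v is not None
    }
    return replace(decomposition, entries=kept, provenance=prov, residual=None)


def epoch_occupancy(
    decomposition: Decomposition,
    *,
    width_multiplier: float = 1.0,
) -> float:
    """Percentage of the epoch covered by the union of atom time supports.

    Each atom occupies [u - s/2, u + s/2] (one scale unit, scaled by
    ``width_multiplier``); overlapping supports count once.  Used for
    SWA-occupancy sleep-staging rules (stage III: 20-50%, stage IV: > 50%).
    """
    n = decomposition.n_samples
    intervals = []
    for e in decomposition.entries:
        if e.family == "harmonic":
            half = n / 2.0
        elif e.family == "delta":
            half = 0.5
        else:
            half = width_multiplier * e.s / 2.0
        lo = max(0.0, e.u - half)
        hi = min(float(n), e.u + half)
        if hi > lo:
            intervals.append((lo, hi))
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0.0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return 100.0 * covered / n
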