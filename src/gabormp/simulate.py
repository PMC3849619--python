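"""Synthetic epochs with known ground truth.

Generated epochs are sums of parameterized atoms (peak amplitude in
microvolts) plus white Gaussian noise, reproducible from a seed.  The
``sleep_preset`` emulates the structure of a sleep-EEG epoch: one slow wave
(1.5 Hz, 60 uV peak amplitude, 1.2 s width) and two sleep spindles (12 and
14 Hz, 20 uV, 0.8 s) in background noise -- the configuration the SWA/spindle
filter presets are designed to isolate.

Atom amplitudes here are *mathematical* (peak) amplitudes: the atom
contributes ``amplitude * env(t) * cos(omega*(t-u) + phi)`` to the signal, so
its peak-to-peak excursion is about twice the amplitude (the EEG convention).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .atoms import gabor_window, gabor_carrier
from .io import TrialMatrix

__all__ = [
    "SyntheticAtom",
    "SyntheticSpec",
    "generate_synthetic",
    "sigma_for_snr",
    "sleep_preset",
]


@dataclass(frozen=True)
class SyntheticAtom:
    """One planted atom: center u (samples), frequency f_hz, scale s
    (samples), phase (radians) and peak amplitude in uV.

    ``amplitude`` may be a scalar (shared by all channels/trials) or an array
    of shape (n_channels, n_trials); ``phi`` likewise.
    """

    u: float
    f_hz: float
    s: float
    phi: float | tuple = 0.0
    amplitude: float | tuple = 1.0
    family: str = "gabor"


@dataclass
class SyntheticSpec:
    """Full description of a reproducible synthetic epoch."""

    n_samples: int
    fs: float = 128.0
    n_channels: int = 1
    n_trials: int = 1
    atoms: list[SyntheticAtom] = field(default_factory=list)
    noise_sigma_uv: float = 0.0
    seed: int = 0

    def to_json(self) -> str:
        def enc(a: SyntheticAtom) -> dict:
            d = dict(a.__dict__)
            for key in ("phi", "amplitude"):
                v = d[key]
                if isinstance(v, np.ndarray):
                    d[key] = v.tolist()
            return d

        return json.dumps(
            {
                "n_samples": self.n_samples,
                "fs": self.fs,
                "n_channels": self.n_channels,
                "n_trials": self.n_trials,
                "noise_sigma_uv": self.noise_sigma_uv,
                "seed": self.seed,
                "atoms": [enc(a) for a in self.atoms],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        atoms = [SyntheticAtom(**a) for a in d.pop("atoms", [])]
        return cls(atoms=atoms, **d)


def _broadcast(value, n_c: int, n_k: int) -> np.ndarray:
    """Scalar, per-channel (n_c,), or full (n_c, n_k) parameter array."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full((n_c, n_k), float(arr))
    if arr.ndim == 1 and arr.size == n_c:
        return np.repeat(arr[:, None], n_k, axis=1)
    if arr.shape == (n_c, n_k):
        return arr.copy()
    raise ValueError(
        f"parameter shape {arr.shape} incompatible with {n_c} channels x {n_k} trials"
    )


def generate_synthetic(spec: SyntheticSpec) -> tuple[TrialMatrix, dict]:
    """Synthesize the epoch block and return it with its ground-truth record."""
    n_c, n_k, n = spec.n_channels, spec.n_trials, spec.n_samples
    data = np.zeros((n_c, n_k, n))
    for atom in spec.atoms:
        if atom.f_hz < 0.0 or atom.f_hz > spec.fs / 2.0:
            raise ValueError(f"atom frequency {atom.f_hz} Hz outside [0, Nyquist]")
        omega = 2.0 * math.pi * atom.f_hz / spec.fs
        t_lo, env = gabor_window(atom.u, atom.s, n)
        cos_t, sin_t = gabor_carrier(atom.u, omega, t_lo, env.size)
        amp = _broadcast(atom.amplitude, n_c, n_k)
        phi = _broadcast(atom.phi, n_c, n_k)
        for i in range(n_c):
            for k in range(n_k):
                wave = env * (
                    math.cos(phi[i, k]) * cos_t - math.sin(phi[i, k]) * sin_t
                )
                data[i, k, t_lo : t_lo + env.size] += amp[i, k] * wave
    clean_energy = float((data * data).sum())
    if spec.noise_sigma_uv > 0.0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma_uv, size=data.shape)
    truth = {
        "spec": json.loads(spec.to_json()),
        "clean_energy": clean_energy,
        "snr_db": (
            10.0 * math.log10(
                clean_energy / (spec.noise_sigma_uv**2 * data.size)
            )
            if spec.noise_sigma_uv > 0.0 and clean_energy > 0.0
            else None
        ),
    }
    matrix = TrialMatrix(data=data, fs=spec.fs, calibration=1.0)
    return matrix, truth


def sigma_for_snr(spec: SyntheticSpec, snr_db: float) -> float:
    """Noise sigma (uV) giving the target epoch-level SNR in dB.

    SNR is the ratio of the clean-component energy to the expected noise
    energy over the whole block.
    """
    clean = SyntheticSpec(
        n_samples=spec.n_samples,
        fs=spec.fs,
        n_channels=spec.n_channels,
        n_trials=spec.n_trials,
        atoms=list(spec.atoms),
        noise_sigma_uv=0.0,
        seed=spec.seed,
    )
    matrix, truth = generate_synthetic(clean)
    e = truth["clean_energy"]
    if e <= 0.0:
        raise ValueError("spec has no signal energy; SNR undefined")
    n_total = matrix.data.size
    return math.sqrt(e / (n_total * 10.0 ** (snr_db / 10.0)))


def sleep_preset(
    n_samples: int = 1024,
    fs: float = 128.0,
    snr_db: float | None = 10.0,
    seed: int = 0,
) -> SyntheticSpec:
    """Sleep-like epoch: one SWA wave plus two sleep spindles.

    1.5 Hz / 60 uV / 1.2 s slow wave at 2.5 s, and two 0.8 s / 20 uV spindles
    at 4.5 s (12 Hz) and 6.5 s (14 Hz) -- distinct spindle frequencies within
    the 11-15 Hz band, the feature the pursuit separates where visual scoring
    sees one structure.  ``snr_db`` sets the white-noise level (None for
    noiseless).
    """
    atoms = [
        SyntheticAtom(u=2.5 * fs, f_hz=1.5, s=1.2 * fs, phi=0.0, amplitude=60.0),
        SyntheticAtom(u=4.5 * fs, f_hz=12.0, s=0.8 * fs, phi=1.0, amplitude=20.0),
        SyntheticAtom(u=6.5 * fs, f_hz=14.0, s=0.8 * fs, phi=2.0, amplitude=20.0),
    ]
    spec = SyntheticSpec(n_samples=n_samples, fs=fs, atoms=atoms, seed=seed)
    if snr_db is not None:
        spec.noise_sigma_uv = sigma_for_snr(spec, snr_db)
    return spec
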