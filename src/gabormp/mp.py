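"""Monochannel matching pursuit with product-update bookkeeping.

Each iteration selects the dictionary atom with the largest absolute product
with the current residual (phase optimized in closed form for Gabor and
harmonic atoms), subtracts its projection, and repeats.  The fast engine keeps
the product tables of the whole dictionary up to date through the update
formula  <R^{n+1}x, g_i> = <R^n x, g_i> - w * <g_n, g_i>,  skipping atoms
flagged orthogonal to the selected one; the naive engine recomputes every
product from the residual each iteration and serves as the reference
implementation in tests.

Stopping: the two criteria (maximum number of iterations, percentage of
explained energy) act in logical conjunction -- the pursuit continues only
while the iteration count is below the maximum AND the explained energy is
below the threshold.  Defaults are 50 iterations and 99%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atoms import optimal_phase_from_moments
from .dictionary import Dictionary
from .engine import ProductTables

__all__ = [
    "StoppingRule",
    "BookEntry",
    "Decomposition",
    "mp_decompose",
    "update_products",
    "explained_energy",
    "entry_waveform",
]

#: Interval (iterations) of the residual-vs-table drift guard in the fast engine.
_DRIFT_CHECK_EVERY = 10
_DRIFT_TOL = 1e-6


@dataclass(frozen=True)
class StoppingRule:
    """Conjunction stopping rule: at most ``max_iterations`` atoms, stop early
    once ``energy_percent`` % of the signal energy is explained."""

    max_iterations: int = 50
    energy_percent: float = 99.0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 < self.energy_percent <= 100.0:
            raise ValueError("energy_percent must lie in (0, 100]")


@dataclass
class BookEntry:
    """One selected atom with its per-channel/per-trial weights and phases.

    ``u`` is in samples, ``omega`` in radians/sample (None for delta and
    Gaussian atoms), ``s`` in samples (None for harmonic and delta atoms).
    ``weights``/``phases`` have shape (n_channels, n_trials); monochannel
    books use shape (1, 1).  For phase-carrying families the stored weight is
    non-negative, with sign absorbed into the phase.
    """

    iteration: int
    family: str
    u: float
    omega: float | None
    s: float | None
    weights: np.ndarray
    phases: np.ndarray

    @property
    def weight(self) -> float:
        return float(self.weights.flat[0])

    @property
    def phase(self) -> float:
        return float(self.phases.flat[0])


@dataclass
class Decomposition:
    """The "book": ordered selected atoms, residual-energy trace, provenance."""

    entries: list[BookEntry]
    residual_energy: np.ndarray  # summed over channels/trials, length M+1
    signal_energy: float
    n_samples: int
    n_channels: int
    n_trials: int
    fs: float
    calibration: float
    provenance: dict = field(default_factory=dict)
    residual: np.ndarray | None = None  # (n_channels, n_trials, n_samples)

    def __len__(self) -> int:
        return len(self.entries)

    def explained_energy(self) -> float:
        return explained_energy(self)


def _empty_decomposition(n_samples, n_channels, n_trials, fs, calibration, e0, prov):
    return Decomposition(
        entries=[],
        residual_energy=np.array([e0]),
        signal_energy=e0,
        n_samples=n_samples,
        n_channels=n_channels,
        n_trials=n_trials,
        fs=fs,
        calibration=calibration,
        provenance=prov,
    )


def _provenance(dictionary: Dictionary, stop: StoppingRule, variant: str) -> dict:
    prov = dictionary.provenance()
    prov.update(
        {
            "max_iterations": stop.max_iterations,
            "energy_percent": stop.energy_percent,
            "variant": variant,
        }
    )
    return prov


def entry_waveform(entry: BookEntry, n_samples: int, channel: int = 0, trial: int = 0) -> np.ndarray:
    """Unit-norm discrete waveform of a book entry (for a given channel/trial
    phase)."""
    from .atoms import atom_waveform

    phi = float(entry.phases[channel, trial])
    return atom_waveform(entry.family, entry.u, entry.omega, entry.s, phi, n_samples)


def mp_decompose(
    signal: np.ndarray,
    dictionary: Dictionary,
    stop: StoppingRule | None = None,
    *,
    fs: float = 1.0,
    calibration: float = 1.0,
    engine: str = "fast",
) -> Decomposition:
    """Greedy matching pursuit of a single epoch.

    ``engine="fast"`` maintains product tables with the update formula and the
    orthogonality shortcut; ``engine="naive"`` recomputes all products from
    the residual every iteration.  Both produce the same book to numerical
    accuracy.
    """
    if stop is None:
        stop = StoppingRule()
    if engine not in ("fast", "naive"):
        raise ValueError(f"unknown engine {engine!r}")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("mp_decompose expects a 1-D epoch")
    if x.size != dictionary.config.n_samples:
        raise ValueError(
            f"signal length {x.size} != dictionary n_samples {dictionary.config.n_samples}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    e0 = float(x @ x)
    prov = _provenance(dictionary, stop, "mp")
    if e0 == 0.0:
        dec = _empty_decomposition(x.size, 1, 1, fs, calibration, e0, prov)
        dec.residual = x.reshape(1, 1, -1).copy()
        return dec

    scanner = dictionary.scanner
    residual = x.copy()
    tables = scanner.scan(residual) if engine == "fast" else None
    entries: list[BookEntry] = []
    res_energy = [e0]

    for it in range(stop.max_iterations):
        if engine == "naive":
            tables = scanner.scan(residual)
        cand = scanner.best_atom(tables)
        if cand.score2 <= 0.0:
            break
        params = scanner.atom_params(cand.key, cand.index)
        mom = scanner.moments_at(tables, cand.key, cand.index)
        if mom is not None:
            phi, weight = optimal_phase_from_moments(*mom)
        else:
            phi = 0.0
            weight = float(tables.data[cand.key][0][cand.index])
        wf = scanner.waveform(params["family"], params["u"], params["omega"], params["s"], phi)
        residual -= weight * wf
        if not np.all(np.isfinite(residual)):
            raise RuntimeError(f"non-finite residual at iteration {it}")
        if engine == "fast":
            scanner.update_tables(tables, wf, weight, params)
            if (it + 1) % _DRIFT_CHECK_EVERY == 0:
                d = scanner.drift(tables, residual, cand.key, cand.index)
                if d > _DRIFT_TOL * math.sqrt(e0):
                    raise RuntimeError(
                        f"product table drifted from residual by {d:.3e} at iteration {it}"
                    )
        entries.append(
            BookEntry(
                iteration=it,
                family=params["family"],
                u=params["u"],
                omega=params["omega"],
                s=params["s"],
                weights=np.array([[weight]]),
                phases=np.array([[phi]]),
            )
        )
        e_now = float(residual @ residual)
        res_energy.append(e_now)
        if 100.0 * (1.0 - e_now / e0) >= stop.energy_percent:
            break

    dec = Decomposition(
        entries=entries,
        residual_energy=np.array(res_energy),
        signal_energy=e0,
        n_samples=x.size,
        n_channels=1,
        n_trials=1,
        fs=fs,
        calibration=calibration,
        provenance=prov,
        residual=residual.reshape(1, 1, -1),
    )
    return dec


def update_products(
    prev_products: ProductTables,
    selected: BookEntry,
    weight: float,
    dictionary: Dictionary,
) -> ProductTables:
    """Product-update formula applied to a full per-atom product table.

    Returns a new table with <R^{n+1}x, g_i> = <R^n x, g_i> - w <g_n, g_i>;
    atoms flagged orthogonal to the selected one keep their previous products
    (their cross-product is replaced by zero).
    """
    new = prev_products.copy()
    wf = entry_waveform(selected, dictionary.config.n_samples)
    params = {
        "family": selected.family,
        "u": selected.u,
        "omega": selected.omega,
        "s": selected.s,
    }
    dictionary.scanner.update_tables(new, wf, weight, params)
    return new


def explained_energy(decomposition: Decomposition) -> float:
    """Percentage of the original signal energy captured by the book."""
    e0 = decomposition.signal_energy
    if e0 == 0.0 or len(decomposition.residual_energy) == 0:
        return 0.0
    return 100.0 * (1.0 - float(decomposition.residual_energy[-1]) / e0)
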