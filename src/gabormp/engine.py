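"""Scan machinery: batched windowed-FFT products over a whole dictionary.

For every Gabor scale the dictionary arranges atoms on a regular
(position, frequency) grid whose frequency step is an exact FFT-bin spacing.
The products of a signal with *all* atoms of a scale are then two arrays
``<x, C>`` and ``<x, S>`` obtained from one batched real FFT of the
Gauss-windowed signal (one row per position), and the per-atom optimal phase
and maximal product follow from five scalar moments per atom
(xc, xs, cc, ss, cs) -- the signal moments plus the precomputed discrete Gram
of the C/S pair.  The same machinery evaluates cross-products of a selected
atom with the rest of the dictionary for the product-update formula, restricted
to the columns not excluded by the fast orthogonality test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .atoms import gabor_window
from .dictionary import Dictionary, ScaleInfo

__all__ = ["DictionaryScanner", "ProductTables", "Candidate"]

#: Gram-degeneracy thresholds for the rank-1 (phi = 0) fallback; must match
#: atoms._GRAM_DET_RTOL/_GRAM_SS_RTOL so scan scoring and the scalar phase
#: solver agree bit-for-bit.
_DET_RTOL = 1e-10
_SS_RTOL = 1e-12

_NEG_INF = -np.inf


@dataclass
class Candidate:
    """Best atom of one selection scan."""

    key: tuple  # block key, e.g. ("gabor", j) / ("harmonic",) / ...
    index: tuple  # index within the block's score array
    score2: float  # squared maximal product (sum over signals where relevant)


class ProductTables:
    """Per-block product arrays <x, C>/<x, S> (or plain products) for one signal."""

    def __init__(self, data: dict):
        self.data = data

    def copy(self) -> "ProductTables":
        return ProductTables(
            {k: tuple(a.copy() for a in v) for k, v in self.data.items()}
        )


class _GaborBlock:
    """Geometry, windows and Gram moments of one dictionary scale."""

    def __init__(self, n_samples: int, info: ScaleInfo):
        self.info = info
        self.n_samples = n_samples
        n_u, length = info.n_u, info.fft_len
        self.u = np.arange(n_u) * info.delta_u
        t_lo = np.empty(n_u, dtype=np.int64)
        rows = []
        width = 0
        for i in range(n_u):
            lo, env = gabor_window(self.u[i], info.s, n_samples)
            t_lo[i] = lo
            rows.append(env)
            width = max(width, env.size)
        self.t_lo = t_lo
        self.width = width
        self.env = np.zeros((n_u, width))
        for i, env in enumerate(rows):
            self.env[i, : env.size] = env
        # phase rotation moving the transform origin from t_lo to u
        k = np.arange(1, info.n_omega + 1)
        ang = (info.delta_omega * (self.u - t_lo))[:, None] * k[None, :]
        self.phase = np.exp(1j * ang)
        # Gram moments from the transform of the squared envelope at 2*omega_k
        env2 = self.env * self.env
        f0 = env2.sum(axis=1)
        spec = np.fft.rfft(env2, n=length, axis=1)
        f2 = self._gather_double_freq(spec) * (self.phase * self.phase)
        self.cc = 0.5 * (f0[:, None] + f2.real)
        self.ss = 0.5 * (f0[:, None] - f2.real)
        self.cs = -0.5 * f2.imag
        self.gauss_norm = np.sqrt(f0)
        det = self.cc * self.ss - self.cs * self.cs
        self.fallback = (self.ss <= _SS_RTOL * self.cc) | (det <= _DET_RTOL * self.cc * self.ss)
        self.det = np.where(self.fallback, 1.0, det)

    def _gather_double_freq(self, spec: np.ndarray) -> np.ndarray:
        """F(2*omega_k) from the rfft bins of a real sequence (with folding)."""
        length = self.info.fft_len
        b = 2 * np.arange(1, self.info.n_omega + 1)
        b_mod = b % length
        direct = b_mod <= length // 2
        idx = np.where(direct, b_mod, length - b_mod)
        vals = spec[:, idx]
        return np.where(direct[None, :], vals, np.conj(vals))

    def scan(self, signal_padded: np.ndarray, rows: np.ndarray | None = None):
        """<x, C> and <x, S> for all (or selected) positions, all frequencies."""
        if rows is None:
            env = self.env
            t_lo = self.t_lo
            phase = self.phase
        else:
            env = self.env[rows]
            t_lo = self.t_lo[rows]
            phase = self.phase[rows]
        gather = t_lo[:, None] + np.arange(self.width)[None, :]
        y = signal_padded[gather] * env
        spec = np.fft.rfft(y, n=self.info.fft_len, axis=1)
        g = spec[:, 1 : self.info.n_omega + 1] * phase
        return g.real, -g.imag


class _HarmonicBlock:
    """Pure cosines on the infinite-window frequency grid (u = 0)."""

    def __init__(self, n_samples: int, fft_len: int, n_omega: int):
        self.n_samples = n_samples
        self.fft_len = fft_len
        self.n_omega = n_omega
        self.delta_omega = 2.0 * math.pi / fft_len
        ones = np.ones(n_samples)
        spec = np.fft.rfft(ones, n=fft_len)
        b = 2 * np.arange(1, n_omega + 1)
        b_mod = b % fft_len
        direct = b_mod <= fft_len // 2
        idx = np.where(direct, b_mod, fft_len - b_mod)
        f2 = np.where(direct, spec[idx], np.conj(spec[idx]))
        self.cc = 0.5 * (n_samples + f2.real)
        self.ss = 0.5 * (n_samples - f2.real)
        self.cs = -0.5 * f2.imag
        det = self.cc * self.ss - self.cs * self.cs
        self.fallback = (self.ss <= _SS_RTOL * self.cc) | (det <= _DET_RTOL * self.cc * self.ss)
        self.det = np.where(self.fallback, 1.0, det)

    def scan(self, signal: np.ndarray):
        spec = np.fft.rfft(signal, n=self.fft_len)
        g = spec[1 : self.n_omega + 1]
        return g.real.copy(), -g.imag.copy()


def _score2(xc, xs, cc, ss, cs, det, fallback):
    """Squared phase-maximized product from the five moments (vectorized)."""
    num = ss * xc * xc - 2.0 * cs * xc * xs + cc * xs * xs
    full = num / det
    fb = xc * xc / cc
    return np.where(fallback, fb, full)


class DictionaryScanner:
    """All scan/score/update operations for one dictionary and epoch length."""

    def __init__(self, dictionary: Dictionary):
        self.dictionary = dictionary
        self.n = dictionary.config.n_samples
        fams = dictionary.config.include_families
        self.gabor_blocks: dict[int, _GaborBlock] = {}
        if "gabor" in fams or "gaussian" in fams:
            for info in dictionary.layout.scales:
                self.gabor_blocks[info.j] = _GaborBlock(self.n, info)
        self.harmonic = (
            _HarmonicBlock(
                self.n,
                dictionary.layout.harmonic_fft_len,
                dictionary.layout.n_harmonic,
            )
            if "harmonic" in fams
            else None
        )

    # -- products ----------------------------------------------------------

    def scan(self, signal: np.ndarray) -> ProductTables:
        """Products of ``signal`` with every dictionary atom (full rescan)."""
        signal = np.asarray(signal, dtype=float)
        if signal.size != self.n:
            raise ValueError(f"signal length {signal.size} != dictionary N {self.n}")
        padded = self._pad(signal)
        data: dict = {}
        for key in self.dictionary.block_keys():
            data[key] = self._scan_block(key, signal, padded, None)
        return ProductTables(data)

    def _pad(self, signal: np.ndarray) -> np.ndarray:
        pad = max((b.width for b in self.gabor_blocks.values()), default=1)
        return np.concatenate([signal, np.zeros(pad)])

    def _scan_block(self, key, signal, padded, rows):
        fam = key[0]
        if fam == "gabor":
            xc, xs = self.gabor_blocks[key[1]].scan(padded, rows)
            return (xc, xs)
        if fam == "harmonic":
            return self.harmonic.scan(signal)
        if fam == "delta":
            return (signal.copy(),)
        if fam == "gaussian":
            blk = self.gabor_blocks[key[1]]
            if rows is None:
                gather = blk.t_lo[:, None] + np.arange(blk.width)[None, :]
                env = blk.env
                nrm = blk.gauss_norm
            else:
                gather = blk.t_lo[rows, None] + np.arange(blk.width)[None, :]
                env = blk.env[rows]
                nrm = blk.gauss_norm[rows]
            return ((padded[gather] * env).sum(axis=1) / nrm,)
        raise KeyError(key)

    # -- scoring -----------------------------------------------------------

    def block_scores2(self, tables: ProductTables, key) -> np.ndarray:
        """Squared phase-maximized product for every atom of one block."""
        fam = key[0]
        vals = tables.data[key]
        if fam == "gabor":
            blk = self.gabor_blocks[key[1]]
            sc = _score2(vals[0], vals[1], blk.cc, blk.ss, blk.cs, blk.det, blk.fallback)
        elif fam == "harmonic":
            h = self.harmonic
            sc = _score2(vals[0], vals[1], h.cc, h.ss, h.cs, h.det, h.fallback)
        else:  # delta, gaussian: already unit-norm products
            sc = vals[0] * vals[0]
        mask = self.dictionary.mask(key)
        if mask is not None:
            sc = np.where(mask, sc, _NEG_INF)
        return sc

    def best_atom(self, tables: ProductTables) -> Candidate:
        """Argmax of |<x, g>| over the dictionary, phases optimized.

        Ties break toward the stable enumeration order (family, scale asc,
        u asc, omega asc).
        """
        best: Candidate | None = None
        for key in self.dictionary.block_keys():
            sc = self.block_scores2(tables, key)
            flat = int(np.argmax(sc))
            val = float(sc.flat[flat])
            if best is None or val > best.score2:
                best = Candidate(key=key, index=np.unravel_index(flat, sc.shape), score2=val)
        if best is None or not np.isfinite(best.score2):
            raise ValueError("empty dictionary: no atom to select")
        return best

    def moments_at(self, tables: ProductTables, key, index):
        """(xc, xs, cc, ss, cs) of one Gabor/harmonic atom (None for others)."""
        fam = key[0]
        vals = tables.data[key]
        if fam == "gabor":
            blk = self.gabor_blocks[key[1]]
            iu, k = index
            return (
                float(vals[0][iu, k]),
                float(vals[1][iu, k]),
                float(blk.cc[iu, k]),
                float(blk.ss[iu, k]),
                float(blk.cs[iu, k]),
            )
        if fam == "harmonic":
            h = self.harmonic
            (k,) = index
            return (
                float(vals[0][k]),
                float(vals[1][k]),
                float(h.cc[k]),
                float(h.ss[k]),
                float(h.cs[k]),
            )
        return None

    # -- atom parameters and waveforms --------------------------------------

    def atom_params(self, key, index) -> dict:
        """(family, u, omega, s) of an atom identified by block key + index."""
        fam = key[0]
        if fam == "gabor":
            blk = self.gabor_blocks[key[1]]
            iu, k = index
            return {
                "family": fam,
                "u": float(blk.u[iu]),
                "omega": (k + 1) * blk.info.delta_omega,
                "s": blk.info.s,
            }
        if fam == "harmonic":
            (k,) = index
            return {
                "family": fam,
                "u": 0.0,
                "omega": (k + 1) * self.harmonic.delta_omega,
                "s": None,
            }
        if fam == "delta":
            (iu,) = index
            return {"family": fam, "u": float(iu), "omega": None, "s": None}
        if fam == "gaussian":
            blk = self.gabor_blocks[key[1]]
            (iu,) = index
            return {"family": fam, "u": float(blk.u[iu]), "omega": None, "s": blk.info.s}
        raise KeyError(key)

    def waveform(self, family: str, u, omega, s, phi) -> np.ndarray:
        """Unit-norm discrete waveform of any dictionary atom."""
        from .atoms import atom_waveform

        return atom_waveform(family, u, omega, s, phi, self.n)

    # -- the product-update formula -----------------------------------------

    def nonorthogonal_rows(self, atom_waveform: np.ndarray, entry_params: dict) -> dict:
        """Per-block row (position) subsets possibly non-orthogonal to an atom.

        Rows whose support windows do not overlap the atom's support have
        exactly zero products (envelope cutoff).  For Gabor-Gabor pairs the
        fast analytic orthogonality test prunes further.
        """
        nz = np.flatnonzero(atom_waveform)
        if nz.size == 0:
            return {}
        a_lo, a_hi = int(nz[0]), int(nz[-1])
        eps = self.dictionary.config.epsilon
        sel: dict = {}
        for key in self.dictionary.block_keys():
            fam = key[0]
            if fam in ("gabor", "gaussian"):
                blk = self.gabor_blocks[key[1]]
                t_hi = blk.t_lo + (blk.env != 0.0).sum(axis=1) - 1
                overlap = (blk.t_lo <= a_hi) & (t_hi >= a_lo)
                if fam == "gabor" and entry_params["family"] == "gabor":
                    s0 = entry_params["s"]
                    si = blk.info.s
                    zfac = 0.5 * math.sqrt(s0 * si / (s0 * s0 + si * si))
                    c = -math.pi * (blk.u - entry_params["u"]) ** 2 / (s0 * s0 + si * si)
                    z = zfac * np.exp(np.maximum(c, -745.0))
                    nonorth = 2.0 * math.sqrt(2.0) / (eps * eps) * z >= 1e-16
                    overlap &= nonorth
                rows = np.flatnonzero(overlap)
                if rows.size:
                    sel[key] = rows
            elif fam == "delta":
                sel[key] = np.arange(a_lo, a_hi + 1)
            elif fam == "harmonic":
                sel[key] = None  # full-support family: always recompute
        return sel

    def update_tables(
        self, tables: ProductTables, atom_waveform: np.ndarray, weight: float,
        entry_params: dict,
    ) -> None:
        """Apply the product-update formula in place:
        <R - w g, C_i> = <R, C_i> - w <g, C_i> for every atom i, with
        orthogonal cross-products replaced by zero (skipped)."""
        sel = self.nonorthogonal_rows(atom_waveform, entry_params)
        if not sel:
            return
        padded = self._pad(atom_waveform)
        for key, rows in sel.items():
            fam = key[0]
            cross = self._scan_block(key, atom_waveform, padded, rows)
            vals = tables.data[key]
            if fam == "gabor":
                vals[0][rows] -= weight * cross[0]
                vals[1][rows] -= weight * cross[1]
            elif fam == "harmonic":
                vals[0][:] -= weight * cross[0]
                vals[1][:] -= weight * cross[1]
            elif fam == "delta":
                vals[0][rows] -= weight * atom_waveform[rows]
            elif fam == "gaussian":
                vals[0][rows] -= weight * cross[0]

    def drift(self, tables: ProductTables, residual: np.ndarray, key, index) -> float:
        """|table - recomputed| at one atom, for the numerical-drift guard."""
        padded = self._pad(residual)
        fam = key[0]
        if fam == "gabor":
            iu, k = index
            xc, xs = self._scan_block(key, residual, padded, np.array([iu]))
            vals = tables.data[key]
            return max(abs(float(xc[0, k]) - vals[0][iu, k]), abs(float(xs[0, k]) - vals[1][iu, k]))
        fresh = self._scan_block(key, residual, padded, None)
        vals = tables.data[key]
        return float(max(abs(f - v).max() for f, v in zip(fresh, vals)))
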