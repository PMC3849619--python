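"""Multivariate matching pursuit across channels and trials.

All variants select, in each iteration, a single envelope class (u, omega, s)
fitted jointly to a set of signals, and differ in (a) which signals enter the
selection (raw channels/trials or their averages) and (b) whether the phase is
common to all signals or free per signal:

* MMP1 -- common phase, selection maximizes the sum of the *moduli* of the
  products over signals.
* MMP2 -- selection is plain monochannel MP on the across-signal average;
  per-signal weights are computed against the unaveraged residua.  Requires
  data not in the average reference (the channel mean must not vanish).
* MMP3 -- free phase per signal, selection maximizes the sum of *squared*
  products.

For channels x trials matrices the compositions MMPXY apply rule X across
channels and rule Y across trials: a "2" digit averages that dimension before
selection, the remaining digit (1 or 3) picks the selection objective, and a
"3" anywhere frees the phase per channel/trial at the weighting stage.
MMP13 and MMP31 are rejected, as in the reference engine.

The multivariate engines recompute product tables from the explicit residuals
each iteration; per-signal weights are exact dot products with the selected
waveform, so per-channel energy conservation holds by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .atoms import optimal_phase_from_moments, phase_split
from .dictionary import Dictionary
from .engine import Candidate, DictionaryScanner
from .mp import (
    BookEntry,
    Decomposition,
    StoppingRule,
    _empty_decomposition,
    _provenance,
)

__all__ = [
    "MMPVariantSpec",
    "mmp1_decompose",
    "mmp2_decompose",
    "mmp3_decompose",
    "mmpxy_decompose",
]

_ALLOWED_XY = {(1, 1), (1, 2), (2, 1), (2, 3), (3, 2), (3, 3)}

#: Number of coarse grid points for the common-phase 1-D objective.
_PHI_GRID = 64
#: Golden-section tolerance on the refined common phase (radians).
_PHI_TOL = 1e-10


@dataclass(frozen=True)
class MMPVariantSpec:
    """MMPXY composition: rule X across channels, rule Y across trials."""

    channel_rule: int
    trial_rule: int

    def __post_init__(self) -> None:
        pair = (self.channel_rule, self.trial_rule)
        if pair in ((1, 3), (3, 1)):
            raise ValueError(f"MMP{pair[0]}{pair[1]} not implemented in reference engine")
        if pair not in _ALLOWED_XY:
            raise ValueError(f"unknown MMP variant MMP{pair[0]}{pair[1]}")

    @property
    def name(self) -> str:
        return f"mmp{self.channel_rule}{self.trial_rule}"

    @property
    def free_phase(self) -> bool:
        return 3 in (self.channel_rule, self.trial_rule)

    @property
    def objective_rule(self) -> int:
        return 3 if self.free_phase else 1


# ---------------------------------------------------------------------------
# selection rules


def _golden_max(f, lo: float, hi: float, tol: float) -> tuple[float, float]:
    """Golden-section maximization of a unimodal scalar function."""
    inv = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - inv * (b - a)
    d = a + inv * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - inv * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + inv * (b - a)
            fd = f(d)
    x = 0.5 * (a + b)
    return x, f(x)


def _rule1_phase_objective(moms):
    """Sum over signals of |<x_m, g_phi>| as a function of phi.

    ``moms`` is (xc_list, xs_list, cc, ss, cs) for one atom.
    """
    xcs, xss, cc, ss, cs = moms

    def f(phi: float) -> float:
        cphi, sphi = math.cos(phi), math.sin(phi)
        den2 = cc * cphi * cphi - 2.0 * cs * cphi * sphi + ss * sphi * sphi
        if den2 <= 1e-20 * cc:
            return 0.0
        den = math.sqrt(den2)
        return sum(abs(xc * cphi - xs * sphi) for xc, xs in zip(xcs, xss)) / den

    return f


def _select_rule1(scanner: DictionaryScanner, tables_list) -> tuple[Candidate, float]:
    """Common-phase selection: argmax over atoms of max_phi sum_m |<x_m, g_phi>|.

    The 1-D phase objective is maximized on a coarse grid per atom
    (vectorized), candidate atoms whose per-signal upper bound
    sum_m sqrt(v_m' G^{-1} v_m) could beat the coarse winner are refined by
    golden section.
    """
    if len(tables_list) == 1:
        # single signal: the closed-form Gram maximization is exact
        cand = scanner.best_atom(tables_list[0])
        mom = scanner.moments_at(tables_list[0], cand.key, cand.index)
        if mom is None:
            return cand, 0.0
        phi, _ = optimal_phase_from_moments(*mom)
        return cand, phi

    phis = np.linspace(0.0, math.pi, _PHI_GRID, endpoint=False)
    best_coarse = -np.inf
    best = None
    ubs = {}
    for key in scanner.dictionary.block_keys():
        fam = key[0]
        if fam in ("delta", "gaussian"):
            score = sum(np.abs(t.data[key][0]) for t in tables_list)
            ub = score
        else:
            blk = scanner.gabor_blocks[key[1]] if fam == "gabor" else scanner.harmonic
            cc, ss, cs, fb = blk.cc, blk.ss, blk.cs, blk.fallback
            score = None
            score_fb = sum(np.abs(t.data[key][0]) for t in tables_list) / np.sqrt(cc)
            for phi in phis:
                cphi, sphi = math.cos(phi), math.sin(phi)
                den2 = cc * cphi * cphi - 2.0 * cs * cphi * sphi + ss * sphi * sphi
                valid = den2 > 1e-20 * cc
                num = sum(
                    np.abs(t.data[key][0] * cphi - t.data[key][1] * sphi)
                    for t in tables_list
                )
                val = np.where(valid, num / np.sqrt(np.where(valid, den2, 1.0)), 0.0)
                score = val if score is None else np.maximum(score, val)
            score = np.where(fb, score_fb, score)
            ub = sum(
                np.sqrt(np.maximum(scanner.block_scores2(t, key), 0.0))
                for t in tables_list
            )
        mask = scanner.dictionary.mask(key)
        if mask is not None:
            score = np.where(mask, score, -np.inf)
            ub = np.where(mask, ub, -np.inf)
        ubs[key] = (score, ub)
        flat = int(np.argmax(score))
        val = float(score.flat[flat])
        if val > best_coarse:
            best_coarse = val
            best = Candidate(key=key, index=np.unravel_index(flat, score.shape), score2=val**2)

    # refine every atom whose upper bound could beat the coarse winner
    best_val = best_coarse
    best_cand, best_phi = best, None
    for key, (score, ub) in ubs.items():
        fam = key[0]
        if fam in ("delta", "gaussian"):
            continue
        blk = scanner.gabor_blocks[key[1]] if fam == "gabor" else scanner.harmonic
        idxs = np.flatnonzero(ub.ravel() >= best_coarse)
        for flat in idxs:
            index = np.unravel_index(int(flat), ub.shape)
            if blk.fallback[index]:
                val, phi = float(score[index]), 0.0
            else:
                xcs = [float(t.data[key][0][index]) for t in tables_list]
                xss = [float(t.data[key][1][index]) for t in tables_list]
                moms = (xcs, xss, float(blk.cc[index]), float(blk.ss[index]), float(blk.cs[index]))
                f = _rule1_phase_objective(moms)
                phi0 = float(phis[int(np.argmax([f(p) for p in phis]))])
                step = math.pi / _PHI_GRID
                phi, val = _golden_max(f, phi0 - step, phi0 + step, _PHI_TOL)
            if val > best_val:
                best_val = val
                best_cand = Candidate(key=key, index=index, score2=val**2)
                best_phi = phi % (2.0 * math.pi)
    if best_phi is None:
        if best_cand.key[0] in ("delta", "gaussian"):
            best_phi = 0.0
        else:
            mom0 = scanner.moments_at(tables_list[0], best_cand.key, best_cand.index)
            blk = (
                scanner.gabor_blocks[best_cand.key[1]]
                if best_cand.key[0] == "gabor"
                else scanner.harmonic
            )
            if blk.fallback[best_cand.index]:
                best_phi = 0.0
            else:
                xcs = [float(t.data[best_cand.key][0][best_cand.index]) for t in tables_list]
                xss = [float(t.data[best_cand.key][1][best_cand.index]) for t in tables_list]
                moms = (xcs, xss, mom0[2], mom0[3], mom0[4])
                f = _rule1_phase_objective(moms)
                phi0 = float(phis[int(np.argmax([f(p) for p in phis]))])
                step = math.pi / _PHI_GRID
                best_phi, _ = _golden_max(f, phi0 - step, phi0 + step, _PHI_TOL)
                best_phi %= 2.0 * math.pi
    return best_cand, best_phi


def _select_rule3(scanner: DictionaryScanner, tables_list) -> Candidate:
    """Free-phase selection: argmax over atoms of sum_m <x_m, g^m>_max^2."""
    best = None
    for key in scanner.dictionary.block_keys():
        sc = sum(np.maximum(scanner.block_scores2(t, key), 0.0) for t in tables_list)
        mask = scanner.dictionary.mask(key)
        if mask is not None:
            sc = np.where(mask, sc, -np.inf)
        flat = int(np.argmax(sc))
        val = float(sc.flat[flat])
        if best is None or val > best.score2:
            best = Candidate(key=key, index=np.unravel_index(flat, sc.shape), score2=val)
    return best


# ---------------------------------------------------------------------------
# weighting


def _free_phase(residual: np.ndarray, params: dict, scanner: DictionaryScanner):
    """Optimal phase of one signal against a selected atom class."""
    fam = params["family"]
    if fam == "gabor":
        ps = phase_split(residual, params["u"], params["omega"], params["s"])
        return optimal_phase_from_moments(ps.xc, ps.xs, ps.cc, ps.ss, ps.cs)[0]
    if fam == "harmonic":
        t = np.arange(residual.size)
        cvec = np.cos(params["omega"] * t)
        svec = np.sin(params["omega"] * t)
        return optimal_phase_from_moments(
            float(residual @ cvec),
            float(residual @ svec),
            float(cvec @ cvec),
            float(svec @ svec),
            float(cvec @ svec),
        )[0]
    return 0.0


# ---------------------------------------------------------------------------
# the shared multivariate loop


def _mmp_loop(
    data: np.ndarray,  # (n_c, n_k, N)
    dictionary: Dictionary,
    stop: StoppingRule,
    *,
    selection: str,  # "rule1", "rule3", "average"
    average_axes: tuple[int, ...],  # axes of (c, k) averaged before selection
    free_phase: bool,
    variant: str,
    fs: float,
    calibration: float,
) -> Decomposition:
    n_c, n_k, n = data.shape
    if n != dictionary.config.n_samples:
        raise ValueError(
            f"epoch length {n} != dictionary n_samples {dictionary.config.n_samples}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("signal contains non-finite samples")
    scanner = dictionary.scanner
    stopng = stop
    e0 = float((data * data).sum())
    prov = _provenance(dictionary, stopng, variant)
    if e0 == 0.0:
        dec = _empty_decomposition(n, n_c, n_k, fs, calibration, e0, prov)
        dec.residual = data.copy()
        return dec

    residual = data.copy()
    entries: list[BookEntry] = []
    res_energy = [e0]

    for it in range(stopng.max_iterations):
        sel = residual
        for ax in sorted(average_axes, reverse=True):
            sel = sel.mean(axis=ax)
        sel_signals = sel.reshape(-1, n)
        tables_list = [scanner.scan(sig) for sig in sel_signals]
        common_phi = 0.0
        if selection == "average":
            cand = scanner.best_atom(tables_list[0])
            mom = scanner.moments_at(tables_list[0], cand.key, cand.index)
            if mom is not None:
                common_phi, _ = optimal_phase_from_moments(*mom)
        elif selection == "rule1":
            cand, common_phi = _select_rule1(scanner, tables_list)
        elif selection == "rule3":
            cand = _select_rule3(scanner, tables_list)
        else:
            raise ValueError(selection)
        if cand.score2 <= 0.0:
            break
        params = scanner.atom_params(cand.key, cand.index)

        weights = np.empty((n_c, n_k))
        phis = np.empty((n_c, n_k))
        common_wf = None
        if not free_phase:
            common_wf = scanner.waveform(
                params["family"], params["u"], params["omega"], params["s"], common_phi
            )
        for i in range(n_c):
            for k in range(n_k):
                r = residual[i, k]
                if free_phase:
                    phi = _free_phase(r, params, scanner)
                    wf = scanner.waveform(
                        params["family"], params["u"], params["omega"], params["s"], phi
                    )
                else:
                    phi, wf = common_phi, common_wf
                w = float(r @ wf)
                residual[i, k] = r - w * wf
                weights[i, k] = w
                phis[i, k] = phi
        entries.append(
            BookEntry(
                iteration=it,
                family=params["family"],
                u=params["u"],
                omega=params["omega"],
                s=params["s"],
                weights=weights,
                phases=phis,
            )
        )
        e_now = float((residual * residual).sum())
        res_energy.append(e_now)
        if 100.0 * (1.0 - e_now / e0) >= stopng.energy_percent:
            break

    return Decomposition(
        entries=entries,
        residual_energy=np.array(res_energy),
        signal_energy=e0,
        n_samples=n,
        n_channels=n_c,
        n_trials=n_k,
        fs=fs,
        calibration=calibration,
        provenance=prov,
        residual=residual,
    )


def _as_channels(channels: np.ndarray) -> np.ndarray:
    x = np.asarray(channels, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("expected a (n_channels, n_samples) array")
    return x


def mmp1_decompose(
    channels: np.ndarray,
    dictionary: Dictionary,
    stop: StoppingRule | None = None,
    *,
    fs: float = 1.0,
    calibration: float = 1.0,
) -> Decomposition:
    """MMP1: one atom per iteration with a single common phase, maximizing the
    sum of the moduli of the products over channels; per-channel real weights."""
    x = _as_channels(channels)
    return _mmp_loop(
        x[:, None, :],
        dictionary,
        stop or StoppingRule(),
        selection="rule1",
        average_axes=(),
        free_phase=False,
        variant="mmp1",
        fs=fs,
        calibration=calibration,
    )


def mmp2_decompose(
    channels: np.ndarray,
    dictionary: Dictionary,
    stop: StoppingRule | None = None,
    *,
    fs: float = 1.0,
    calibration: float = 1.0,
) -> Decomposition:
    """MMP2: selection by monochannel MP on the channel average, weights per
    channel against the unaveraged residua.

    Cannot be applied to data in the average reference: the channel mean
    vanishes there and carries no signal to decompose.
    """
    x = _as_channels(channels)
    mean = x.mean(axis=0)
    e_mean = float(mean @ mean)
    e_chan = float((x * x).sum()) / x.shape[0]
    if e_chan > 0.0:
        if e_mean <= 1e-15 * e_chan:
            raise ValueError(
                "channel average is numerically zero (average-reference data); "
                "MMP2 is not applicable"
            )
        if e_mean < 1e-10 * e_chan:
            warnings.warn(
                "channel average carries almost no energy; MMP2 selection will "
                "be driven by cancellation noise",
                stacklevel=2,
            )
    return _mmp_loop(
        x[:, None, :],
        dictionary,
        stop or StoppingRule(),
        selection="average",
        average_axes=(0,),
        free_phase=False,
        variant="mmp2",
        fs=fs,
        calibration=calibration,
    )


def mmp3_decompose(
    channels: np.ndarray,
    dictionary: Dictionary,
    stop: StoppingRule | None = None,
    *,
    fs: float = 1.0,
    calibration: float = 1.0,
) -> Decomposition:
    """MMP3: free phase per channel, selection maximizes the sum of squared
    products (never below MMP1's common-phase value for the same class)."""
    x = _as_channels(channels)
    return _mmp_loop(
        x[:, None, :],
        dictionary,
        stop or StoppingRule(),
        selection="rule3",
        average_axes=(),
        free_phase=True,
        variant="mmp3",
        fs=fs,
        calibration=calibration,
    )


def mmpxy_decompose(
    matrix,
    spec: MMPVariantSpec,
    dictionary: Dictionary,
    stop: StoppingRule | None = None,
) -> Decomposition:
    """MMPXY on a channels x trials x time block (a TrialMatrix or ndarray).

    Rule X acts across channels, rule Y across trials; "2" digits average the
    corresponding dimension before selection, and any "3" frees the phase per
    channel and trial at the weighting stage.  Weights are always computed
    against the unaveraged residua.
    """
    from .io import TrialMatrix

    if isinstance(matrix, TrialMatrix):
        data = matrix.data
        fs = matrix.fs
        calibration = matrix.calibration
    else:
        data = np.asarray(matrix, dtype=float)
        fs = 1.0
        calibration = 1.0
    if data.ndim != 3:
        raise ValueError("expected a (n_channels, n_trials, n_samples) block")
    average_axes = []
    if spec.channel_rule == 2:
        average_axes.append(0)
    if spec.trial_rule == 2:
        average_axes.append(1)
    selection = "rule3" if spec.objective_rule == 3 else "rule1"
    return _mmp_loop(
        data,
        dictionary,
        stop or StoppingRule(),
        selection=selection,
        average_axes=tuple(average_axes),
        free_phase=spec.free_phase,
        variant=spec.name,
        fs=fs,
        calibration=calibration,
    )
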