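"""Optimal Gabor dictionaries: product metric, neighbor products, sampling.

The dictionary is the finite, redundant atom set the pursuit selects from.
Its density is governed by a single parameter ``epsilon``: the inner-product
metric distance between any two *adjacent* atoms (scale-, frequency- or
position-neighbors) is bounded by epsilon, which in turn bounds the worst-case
one-step energy error of the greedy selection.  From epsilon follow the
dilation factor ``a`` between consecutive scales, and per-scale frequency and
position steps that are independent of frequency (chosen at the Nyquist end of
the band, where the steps are tightest).

Frequencies are snapped *down* to exact FFT-bin multiples 2*pi/fft_len so the
windowed-FFT product machinery applies bit-reproducibly; a finer grid can only
tighten the epsilon bound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .atoms import discrete_product, support_halfwidth, _cs_window

__all__ = [
    "MIN_SCALE",
    "FAMILIES",
    "DictionaryConfig",
    "ScaleInfo",
    "DictionaryLayout",
    "Dictionary",
    "metric_d0",
    "metric_d",
    "max_product_scale",
    "max_product_freq",
    "max_product_pos",
    "dilation_factor",
    "steps_for_scale",
    "build_dictionary",
    "dictionary_info",
]

#: Smallest Gabor scale (samples) admitted to the dictionary.  Below ~4
#: samples the discrete atom is an aliased rendition of its continuous parent
#: (the 2*omega term of the discrete self- and cross-products no longer
#: averages out near Nyquist) and the epsilon bound on neighbor distances
#: ceases to hold; see docs/methods.md.
MIN_SCALE = 4.0

#: Stable family enumeration order (part of the public API: the pursuit
#: tie-breaks argmax by this order, then scale, position, frequency).
FAMILIES = ("gabor", "harmonic", "delta", "gaussian")


# ---------------------------------------------------------------------------
# metric


def metric_d0(v0: np.ndarray, v1: np.ndarray) -> float:
    """Inner-product metric d0 = sqrt(1 - <g0|g1>) between unit-norm atoms.

    Zero for identical atoms, 1 for orthogonal ones, sqrt(2) for antipodal
    pairs (product -1).  Computed from the discrete product.
    """
    p = discrete_product(v0, v1)
    return math.sqrt(max(0.0, 1.0 - p))


def _class_basis(u: float, omega: float, s: float, n_samples: int) -> np.ndarray:
    """Stacked full-length C and S vectors spanning a phase class."""
    t_lo, cvec, svec = _cs_window(u, omega, s, n_samples)
    out = np.zeros((2, n_samples))
    out[0, t_lo : t_lo + cvec.size] = cvec
    out[1, t_lo : t_lo + svec.size] = svec
    return out


def _whitener(gram: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(gram)
    floor = 1e-14 * w.max()
    w = np.maximum(w, floor)
    return v @ np.diag(w**-0.5) @ v.T


def max_class_product(
    class0: tuple[float, float, float],
    class1: tuple[float, float, float],
    n_samples: int,
) -> float:
    """Maximal scalar product <G0|G1>_max over both phases, exactly.

    Each phase class spans the 2-D space {C, S}; the maximum of the normalized
    product over both phases is the largest singular value of the whitened
    cross-Gram of the two spans (a 2x2 problem), clamped to [0, 1].
    """
    b0 = _class_basis(*class0, n_samples)
    b1 = _class_basis(*class1, n_samples)
    g0 = b0 @ b0.T
    g1 = b1 @ b1.T
    m = b0 @ b1.T
    w = _whitener(g0) @ m @ _whitener(g1)
    smax = float(np.linalg.svd(w, compute_uv=False)[0])
    return min(smax, 1.0)


def metric_d(
    class0: tuple[float, float, float],
    class1: tuple[float, float, float],
    n_samples: int,
) -> float:
    """Phase-class metric d = sqrt(1 - <G0|G1>_max).

    Classes are identified by (u, omega, s); the product is maximized over
    both phases.
    """
    return math.sqrt(max(0.0, 1.0 - max_class_product(class0, class1, n_samples)))


# ---------------------------------------------------------------------------
# closed-form maximal products of adjacent atoms (continuous-time)


def max_product_scale(s: float, omega: float, a: float) -> float:
    """Maximal product between same-(u, omega) atoms at scales s and a*s.

    Two-branch closed form (phases both 0 or both pi/2); at omega ~ pi it
    reduces to sqrt(2a/(a^2+1)).
    """
    if a <= 1.0:
        raise ValueError("dilation factor a must be > 1")
    so2 = s * s * omega * omega
    e0 = math.exp(-so2 / (2.0 * math.pi))
    e1 = math.exp(-a * a * so2 / (2.0 * math.pi))
    ex = math.exp(-a * a * so2 / ((a * a + 1.0) * math.pi))
    pre = math.sqrt(2.0 * a / (a * a + 1.0))
    branch_sin = (1.0 - ex) / math.sqrt((1.0 - e0) * (1.0 - e1))
    branch_cos = (1.0 + ex) / math.sqrt((1.0 + e0) * (1.0 + e1))
    return pre * max(branch_sin, branch_cos)


def max_product_freq(s: float, omega: float, delta_omega: float) -> float:
    """Maximal product between same-(u, s) atoms at omega and omega+delta_omega.

    Near Nyquist this tends to exp(-delta_omega^2 s^2 / (8 pi)).
    """
    if delta_omega < 0.0:
        raise ValueError("delta_omega must be non-negative")
    if delta_omega == 0.0:
        return 1.0
    w1 = omega + delta_omega
    e0 = math.exp(-s * s * omega * omega / (2.0 * math.pi))
    e1 = math.exp(-s * s * w1 * w1 / (2.0 * math.pi))
    ex = math.exp(-s * s * omega * w1 / (2.0 * math.pi))
    pre = math.exp(-delta_omega * delta_omega * s * s / (8.0 * math.pi))
    branch_sin = (1.0 - ex) / math.sqrt((1.0 - e0) * (1.0 - e1))
    branch_cos = (1.0 + ex) / math.sqrt((1.0 + e0) * (1.0 + e1))
    return pre * max(branch_sin, branch_cos)


def max_product_pos(s: float, omega: float, delta_u: float) -> float:
    """Maximal product between same-(s, omega) atoms at positions delta_u apart.

    The inner maximization over phase of (cos(2 phi + omega du) + E) /
    (1 + cos(2 phi) E), E = exp(-s^2 omega^2 / (2 pi)), is solved in closed
    form; near Nyquist the result tends to exp(-pi delta_u^2 / (2 s^2)).
    """
    if delta_u < 0.0:
        raise ValueError("delta_u must be non-negative")
    if delta_u == 0.0:
        return 1.0
    e = math.exp(-s * s * omega * omega / (2.0 * math.pi))
    delta = omega * delta_u
    pre = math.exp(-math.pi * delta_u * delta_u / (2.0 * s * s))
    # stationary points of (cos th + E)/(1 + E cos(th - delta)) over th:
    # sin th - E^2 sin(th - delta) = -E sin delta, an R*sin(th + psi) = rhs form
    rc = 1.0 - e * e * math.cos(delta)
    rs = e * e * math.sin(delta)
    r = math.hypot(rc, rs)
    psi = math.atan2(rs, rc)
    rhs = -e * math.sin(delta)
    arg = max(-1.0, min(1.0, rhs / r)) if r > 0.0 else 0.0
    best = -np.inf
    for th in (math.asin(arg) - psi, math.pi - math.asin(arg) - psi):
        val = (math.cos(th) + e) / (1.0 + e * math.cos(th - delta))
        best = max(best, val)
    return pre * best


def dilation_factor(epsilon: float) -> float:
    """Dilation factor a between consecutive scales for a given epsilon.

    The > 1 root of 2a/(a^2+1) = (1 - epsilon^2)^2, in closed form.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    e2 = epsilon * epsilon
    num = 1.0 + epsilon * math.sqrt((2.0 - e2) * (e2 * e2 - 2.0 * e2 + 2.0))
    return num / (1.0 - e2) ** 2


def steps_for_scale(s: float, epsilon: float) -> tuple[float, float]:
    """Frequency step delta_omega and position step delta_u for scale s.

    delta_omega = (1/s) sqrt(-8 pi log(1-eps^2));
    delta_u     =  s    sqrt(-(2/pi) log(1-eps^2)).
    Both make the corresponding Nyquist-region neighbor product equal
    1 - epsilon^2.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    log_term = -math.log(1.0 - epsilon * epsilon)
    delta_omega = math.sqrt(8.0 * math.pi * log_term) / s
    delta_u = s * math.sqrt(2.0 / math.pi * log_term)
    return delta_omega, delta_u


# ---------------------------------------------------------------------------
# dictionary construction


@dataclass(frozen=True)
class DictionaryConfig:
    """User-facing dictionary parameters.

    epsilon ("energy error") bounds the metric distance between adjacent
    atoms; smaller epsilon means a denser dictionary.  ``dict_type``
    "stochastic" removes (100 - percentage_chosen)% of the atoms of the dense
    dictionary uniformly at random (reproducibly, from ``seed``).
    """

    epsilon: float
    n_samples: int
    dict_type: str = "fixed"
    percentage_chosen: float = 100.0
    seed: int | None = None
    include_families: tuple[str, ...] = ("gabor",)
    max_bytes: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.epsilon > 0.5:
            warnings.warn(
                f"epsilon={self.epsilon} is large; the one-step error bound is "
                "only meaningful for epsilon well below 1",
                stacklevel=2,
            )
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.dict_type not in ("fixed", "stochastic"):
            raise ValueError(f"unknown dict_type {self.dict_type!r}")
        if not 0.0 < self.percentage_chosen <= 100.0:
            raise ValueError("percentage_chosen must lie in (0, 100]")
        fams = tuple(self.include_families)
        for f in fams:
            if f not in FAMILIES:
                raise ValueError(f"unknown atom family {f!r}")
        if not fams:
            raise ValueError("include_families must not be empty")
        # normalize to canonical order
        object.__setattr__(
            self, "include_families", tuple(f for f in FAMILIES if f in fams)
        )
        if self.dict_type == "stochastic" and self.seed is None:
            raise ValueError("stochastic dictionaries require a seed")


def _next_pow2(x: float) -> int:
    return 1 << max(1, math.ceil(math.log2(x)))


@dataclass(frozen=True)
class ScaleInfo:
    """Discretization of one dictionary scale."""

    j: int  # scale index, s = a**j
    s: float
    delta_u: float
    n_u: int
    fft_len: int
    delta_omega: float  # realized step = 2*pi/fft_len (<= the optimal step)
    n_omega: int  # frequencies k*delta_omega, k = 1..n_omega (pi inclusive)

    @property
    def n_gabor(self) -> int:
        return self.n_u * self.n_omega


@dataclass(frozen=True)
class DictionaryLayout:
    """Derived geometry of an optimal dictionary (auditable)."""

    epsilon: float
    n_samples: int
    a: float
    n_scales: int  # floor(log_a N)
    j_min: int  # first scale index with s >= MIN_SCALE
    scales: tuple[ScaleInfo, ...]
    harmonic_fft_len: int
    harmonic_delta_omega: float
    n_harmonic: int
    n_delta: int

    def summary_table(self) -> str:
        """Per-scale structured text summary: s, delta_omega, delta_u, counts."""
        lines = [
            f"# optimal Gabor dictionary: epsilon={self.epsilon} N={self.n_samples} "
            f"a={self.a:.6f} scales j={self.j_min}..{self.n_scales}",
            f"{'j':>4} {'s':>12} {'delta_omega':>12} {'delta_u':>12} "
            f"{'n_u':>8} {'n_omega':>8} {'n_gabor':>10}",
        ]
        for sc in self.scales:
            lines.append(
                f"{sc.j:>4} {sc.s:>12.4f} {sc.delta_omega:>12.6f} "
                f"{sc.delta_u:>12.4f} {sc.n_u:>8} {sc.n_omega:>8} {sc.n_gabor:>10}"
            )
        return "\n".join(lines)


def _layout(config: DictionaryConfig) -> DictionaryLayout:
    n = config.n_samples
    eps = config.epsilon
    a = dilation_factor(eps)
    n_scales = int(math.floor(math.log(n) / math.log(a)))
    j_min = max(1, math.ceil(math.log(MIN_SCALE) / math.log(a) - 1e-12))
    scales = []
    for j in range(j_min, n_scales + 1):
        s = a**j
        dw_opt, du = steps_for_scale(s, eps)
        # window width on the clipped support
        width = min(n, 2 * math.floor(support_halfwidth(s)) + 1)
        fft_len = _next_pow2(max(2.0 * math.pi / dw_opt, float(width)))
        dw = 2.0 * math.pi / fft_len
        n_u = int(math.floor((n - 1) / du)) + 1
        n_omega = fft_len // 2
        scales.append(
            ScaleInfo(
                j=j, s=s, delta_u=du, n_u=n_u, fft_len=fft_len,
                delta_omega=dw, n_omega=n_omega,
            )
        )
    if not scales:
        raise ValueError(
            f"epoch of {n} samples admits no representable scale "
            f"(minimum scale {MIN_SCALE} samples)"
        )
    # harmonics: frequency step from the largest dictionary scale (the
    # natural infinite-window limit), snapped to FFT bins; transform must
    # cover the whole epoch
    s_max = scales[-1].s
    dw_h_opt, _ = steps_for_scale(s_max, eps)
    h_len = _next_pow2(max(2.0 * math.pi / dw_h_opt, float(n)))
    return DictionaryLayout(
        epsilon=eps,
        n_samples=n,
        a=a,
        n_scales=n_scales,
        j_min=j_min,
        scales=tuple(scales),
        harmonic_fft_len=h_len,
        harmonic_delta_omega=2.0 * math.pi / h_len,
        n_harmonic=h_len // 2,
        n_delta=n,
    )


class Dictionary:
    """A built dictionary: layout plus (for stochastic type) retention masks.

    Atom enumeration order is (family, scale asc, u asc, omega asc) with
    family order ``FAMILIES``; this order is stable and is the pursuit's
    argmax tie-break.
    """

    def __init__(
        self,
        config: DictionaryConfig,
        layout: DictionaryLayout,
        masks: dict | None,
    ) -> None:
        self.config = config
        self.layout = layout
        self.masks = masks  # block key -> bool array, or None for fixed/full
        self._scanner = None

    # -- block geometry ----------------------------------------------------

    def block_keys(self) -> list[tuple]:
        keys: list[tuple] = []
        fams = self.config.include_families
        if "gabor" in fams:
            keys += [("gabor", sc.j) for sc in self.layout.scales]
        if "harmonic" in fams:
            keys.append(("harmonic",))
        if "delta" in fams:
            keys.append(("delta",))
        if "gaussian" in fams:
            keys += [("gaussian", sc.j) for sc in self.layout.scales]
        return keys

    def block_shape(self, key: tuple) -> tuple[int, ...]:
        if key[0] == "gabor":
            sc = self.scale_info(key[1])
            return (sc.n_u, sc.n_omega)
        if key[0] == "harmonic":
            return (self.layout.n_harmonic,)
        if key[0] == "delta":
            return (self.layout.n_delta,)
        if key[0] == "gaussian":
            sc = self.scale_info(key[1])
            return (sc.n_u,)
        raise KeyError(key)

    def scale_info(self, j: int) -> ScaleInfo:
        sc = self.layout.scales[j - self.layout.j_min]
        assert sc.j == j
        return sc

    def mask(self, key: tuple) -> np.ndarray | None:
        if self.masks is None:
            return None
        return self.masks.get(key)

    # -- sizes -------------------------------------------------------------

    def n_atoms_dense(self) -> int:
        return sum(int(np.prod(self.block_shape(k))) for k in self.block_keys())

    def n_atoms(self) -> int:
        if self.masks is None:
            return self.n_atoms_dense()
        total = 0
        for key in self.block_keys():
            m = self.mask(key)
            total += int(m.sum()) if m is not None else int(np.prod(self.block_shape(key)))
        return total

    def nbytes_estimate(self) -> int:
        return _nbytes_estimate_from_layout(self.layout, self.config)

    @property
    def scanner(self):
        """Lazily built scan machinery (windows, Gram tables, FFT grids)."""
        if self._scanner is None:
            from .engine import DictionaryScanner

            self._scanner = DictionaryScanner(self)
        return self._scanner

    def provenance(self) -> dict:
        cfg = self.config
        return {
            "epsilon": cfg.epsilon,
            "n_samples": cfg.n_samples,
            "dict_type": cfg.dict_type,
            "percentage_chosen": cfg.percentage_chosen,
            "seed": cfg.seed,
            "include_families": list(cfg.include_families),
            "a": self.layout.a,
        }


def _nbytes_estimate_from_layout(layout: DictionaryLayout, config: DictionaryConfig) -> int:
    """Rough bytes needed by the scan tables (per analyzed signal)."""
    total = 0
    fams = config.include_families
    for sc in layout.scales:
        if "gabor" in fams:
            # xc, xs, cc, ss, cs (float64) + cached phase rotation (complex128)
            total += sc.n_u * sc.n_omega * 8 * 7
            total += sc.n_u * sc.fft_len * 8  # window/work arrays
        if "gaussian" in fams:
            total += sc.n_u * 8 * 2
    if "harmonic" in fams:
        total += layout.n_harmonic * 8 * 5
    if "delta" in fams:
        total += layout.n_delta * 8
    return total


def dictionary_info(config: DictionaryConfig) -> tuple[DictionaryLayout, int, int]:
    """Layout, atom count and memory estimate *before* building.

    Mirrors the reference GUI's RAM display: the estimate is reported so the
    user can abort before an oversized dictionary is materialized.
    """
    layout = _layout(config)
    n_atoms = 0
    fams = config.include_families
    for sc in layout.scales:
        if "gabor" in fams:
            n_atoms += sc.n_gabor
        if "gaussian" in fams:
            n_atoms += sc.n_u
    if "harmonic" in fams:
        n_atoms += layout.n_harmonic
    if "delta" in fams:
        n_atoms += layout.n_delta
    return layout, n_atoms, _nbytes_estimate_from_layout(layout, config)


def build_dictionary(config: DictionaryConfig) -> Dictionary:
    """Construct the optimal (or stochastic) dictionary for ``config``.

    Gabor atoms sit at scales a**j, positions on the per-scale delta_u grid
    and frequencies on the per-scale FFT-bin grid within (0, pi]; harmonics on
    the infinite-window frequency grid; Kronecker deltas at every sample;
    Gaussians on the (scale, delta_u) grid.  Stochastic dictionaries remove a
    seeded uniform subset of atoms (never jitter parameters).
    """
    layout, n_atoms, nbytes = dictionary_info(config)
    if config.max_bytes is not None and nbytes > config.max_bytes:
        raise MemoryError(
            f"dictionary of {n_atoms} atoms needs ~{nbytes} bytes, "
            f"exceeding the configured budget of {config.max_bytes}"
        )
    d = Dictionary(config, layout, masks=None)
    if config.dict_type == "stochastic" and config.percentage_chosen < 100.0:
        keys = d.block_keys()
        sizes = [int(np.prod(d.block_shape(k))) for k in keys]
        total = sum(sizes)
        n_remove = int(round(total * (100.0 - config.percentage_chosen) / 100.0))
        if n_remove >= total:
            raise ValueError("stochastic subsampling would empty the dictionary")
        rng = np.random.default_rng(config.seed)
        removed = rng.choice(total, size=n_remove, replace=False)
        keep = np.ones(total, dtype=bool)
        keep[removed] = False
        masks = {}
        offset = 0
        for key, size in zip(keys, sizes):
            blk = keep[offset : offset + size]
            offset += size
            if not blk.all():
                masks[key] = blk.reshape(d.block_shape(key)).copy()
        d.masks = masks if masks else None
    return d
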