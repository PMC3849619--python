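"""Real Gabor atoms: discrete synthesis, inner products, and optimal phase.

A real Gabor atom is a Gaussian-enveloped cosine

    g(t) = K * exp(-pi*((t - u)/s)**2) * cos(omega*(t - u) + phi)

parameterized by time center ``u`` (samples), angular frequency ``omega``
(radians/sample, 0 < omega <= pi), scale ``s`` (samples, s > 0) and phase
``phi`` (radians).  Atoms handed to the pursuit engines are normalized by
their *discrete* sample norm, so the unit-norm contract holds exactly on the
sampled vectors; the continuous-time normalization factor ``K(gamma)`` and the
closed-form continuous inner product are retained for fast screening and for
cross-checks against quadrature.

Waveform tables (cos, sin, Gaussian) are generated by one-step recurrences --
a complex rotation for the carrier and a multiplicative update for the
envelope -- so each synthesis costs a handful of transcendental calls
regardless of length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaborParams",
    "ProductConstants",
    "PhaseSplit",
    "ENVELOPE_CUTOFF",
    "synthesize_gabor",
    "atom_waveform",
    "gabor_window",
    "gabor_carrier",
    "product_constants",
    "continuous_norm_factor",
    "analytic_gabor_product",
    "discrete_product",
    "phase_split",
    "optimal_phase",
    "optimal_phase_from_moments",
    "windowed_fft_products",
    "is_orthogonal_fast",
    "orthogonality_factor_z",
    "integration_halfwidth",
    "gabor_pair_product",
    "OrthogonalPairError",
]

#: Envelope samples below this fraction of the peak are treated as exact zeros.
#: Matches the bounded-domain philosophy of the truncated product integrals and
#: makes far-apart atoms exactly orthogonal in discrete time.
ENVELOPE_CUTOFF = 1e-16

#: Support half-width in units of s implied by the cutoff:
#: exp(-pi*(h/s)^2) = ENVELOPE_CUTOFF.
_HALFWIDTH_FACTOR = math.sqrt(-math.log(ENVELOPE_CUTOFF) / math.pi)


@dataclass(frozen=True)
class GaborParams:
    """Parameters (u, omega, s, phi) of one real Gabor atom.

    u : time center in samples; omega : angular frequency in radians/sample,
    within (0, pi]; s : scale (Gaussian width) in samples; phi : phase in
    radians, stored in [0, 2*pi).
    """

    u: float
    omega: float
    s: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u", "omega", "s", "phi"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite Gabor parameter {name!r}")
        if not 0.0 < self.omega <= math.pi:
            raise ValueError(f"omega={self.omega} outside (0, pi]")
        if self.s <= 0.0:
            raise ValueError(f"scale s={self.s} must be positive")
        object.__setattr__(self, "phi", self.phi % (2.0 * math.pi))


@dataclass(frozen=True)
class ProductConstants:
    """Constants A, B, C of the Gaussian-product completion for an atom pair.

    A has units 1/samples^2, B is the center of mass of the two envelopes
    (samples), and C <= 0 is the log of the envelope-overlap attenuation.
    """

    A: float
    B: float
    C: float


class OrthogonalPairError(ValueError):
    """Raised when a pair is orthogonal to tolerance and no integration
    interval is needed."""


def support_halfwidth(s: float) -> float:
    """Half-width (samples) of the nonzero envelope support for scale ``s``."""
    return _HALFWIDTH_FACTOR * s


def gabor_window(u: float, s: float, n_samples: int) -> tuple[int, np.ndarray]:
    """Gaussian envelope samples exp(-pi*((t-u)/s)^2) on the clipped support.

    Returns ``(t_lo, env)`` where ``env[j]`` is the envelope at sample
    ``t_lo + j``.  Samples where the envelope falls below ``ENVELOPE_CUTOFF``
    of its peak are excluded.  The envelope is generated by the multiplicative
    recurrence e^{-a(t+1)^2} = e^{-a t^2} e^{-2at} e^{-a} (two cumulative
    products, three scalar exp calls).
    """
    h = support_halfwidth(s)
    t_lo = max(0, math.ceil(u - h))
    t_hi = min(n_samples - 1, math.floor(u + h))
    if t_hi < t_lo:
        return t_lo, np.zeros(0)
    w = t_hi - t_lo + 1
    alpha = math.pi / (s * s)
    tau0 = t_lo - u
    e0 = math.exp(-alpha * tau0 * tau0)
    if w == 1:
        return t_lo, np.array([e0])
    # ratio between consecutive samples: r_m = exp(-2*alpha*tau_m - alpha),
    # itself geometric with quotient exp(-2*alpha)
    q = math.exp(-2.0 * alpha)
    r0 = math.exp(-2.0 * alpha * tau0 - alpha)
    ratios = np.empty(w)
    ratios[0] = 1.0
    ratios[1] = r0
    ratios[2:] = q
    env = e0 * np.cumprod(np.cumprod(ratios)[: w])
    # guard against recurrence underflow drifting negative (cannot happen for
    # positive factors, but clamp denormals to the cutoff contract)
    env[env < ENVELOPE_CUTOFF] = 0.0
    return t_lo, env


def gabor_carrier(u: float, omega: float, t_lo: int, length: int) -> tuple[np.ndarray, np.ndarray]:
    """cos(omega*(t-u)) and sin(omega*(t-u)) for t = t_lo .. t_lo+length-1.

    Generated by the complex rotation recurrence z_{m+1} = z_m * e^{i*omega}
    (one cumulative product, one scalar cis call).
    """
    tau0 = t_lo - u
    z0 = complex(math.cos(omega * tau0), math.sin(omega * tau0))
    if length == 1:
        return np.array([z0.real]), np.array([z0.imag])
    step = complex(math.cos(omega), math.sin(omega))
    factors = np.empty(length, dtype=complex)
    factors[0] = z0
    factors[1:] = step
    z = np.cumprod(factors)
    return z.real, z.imag


def _cs_window(u: float, omega: float, s: float, n_samples: int):
    """Envelope-weighted cosine and sine components on the clipped support."""
    t_lo, env = gabor_window(u, s, n_samples)
    if env.size == 0:
        raise ValueError("degenerate atom: envelope underflows on the whole epoch")
    cos_t, sin_t = gabor_carrier(u, omega, t_lo, env.size)
    return t_lo, env * cos_t, env * sin_t


def synthesize_gabor(params: GaborParams, n_samples: int) -> np.ndarray:
    """Discrete real Gabor waveform of unit Euclidean norm.

    The returned vector has length ``n_samples`` and is exactly zero outside
    the envelope support.  Atoms clipped by the epoch border are renormalized
    on the clipped support, preserving the unit-norm contract.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    t_lo, cvec, svec = _cs_window(params.u, params.omega, params.s, n_samples)
    w = math.cos(params.phi) * cvec - math.sin(params.phi) * svec
    nrm = np.linalg.norm(w)
    if nrm == 0.0 or not np.isfinite(nrm):
        raise ValueError("degenerate atom: zero norm on the sampled support")
    out = np.zeros(n_samples)
    out[t_lo : t_lo + w.size] = w / nrm
    return out


def atom_waveform(
    family: str,
    u: float | None,
    omega: float | None,
    s: float | None,
    phi: float,
    n_samples: int,
) -> np.ndarray:
    """Unit-norm discrete waveform of any dictionary atom family.

    Families: "gabor" (enveloped cosine), "harmonic" (pure cosine, u = 0),
    "delta" (Kronecker delta at u), "gaussian" (pure envelope, no carrier).
    """
    if family == "gabor":
        return synthesize_gabor(GaborParams(u=u, omega=omega, s=s, phi=phi), n_samples)
    if family == "harmonic":
        t = np.arange(n_samples)
        w = np.cos(omega * t + phi)
        nrm = np.linalg.norm(w)
        if nrm == 0.0:
            raise ValueError("degenerate harmonic atom")
        return w / nrm
    if family == "delta":
        out = np.zeros(n_samples)
        out[int(round(u))] = 1.0
        return out
    if family == "gaussian":
        t_lo, env = gabor_window(u, s, n_samples)
        if env.size == 0:
            raise ValueError("degenerate atom: envelope underflows on the whole epoch")
        out = np.zeros(n_samples)
        out[t_lo : t_lo + env.size] = env
        return out / np.linalg.norm(out)
    raise ValueError(f"unknown atom family {family!r}")


def product_constants(g0: GaborParams, g1: GaborParams) -> ProductConstants:
    """Gaussian-product constants A, B, C for an atom pair.

    A = pi*(1/s0^2 + 1/s1^2);  B = (pi/A)*(u0/s0^2 + u1/s1^2);
    C = -pi*(u0-u1)^2/(s0^2+s1^2).
    """
    s0sq, s1sq = g0.s * g0.s, g1.s * g1.s
    a = math.pi * (1.0 / s0sq + 1.0 / s1sq)
    b = (math.pi / a) * (g0.u / s0sq + g1.u / s1sq)
    c = -math.pi * (g0.u - g1.u) ** 2 / (s0sq + s1sq)
    return ProductConstants(A=a, B=b, C=c)


def continuous_norm_factor(g: GaborParams) -> float:
    """Continuous-time normalization K(gamma) of a real Gabor atom.

    K = [ s/2^{3/2} * (1 + cos(2*phi) * exp(-s^2*omega^2/(2*pi))) ]^{-1/2}.
    """
    att = math.exp(-g.s * g.s * g.omega * g.omega / (2.0 * math.pi))
    val = g.s / (2.0 * math.sqrt(2.0)) * (1.0 + math.cos(2.0 * g.phi) * att)
    if val <= 0.0:
        raise ValueError("degenerate continuous normalization (omega ~ 0 with phi ~ pi/2)")
    return 1.0 / math.sqrt(val)


def _exp_safe(x: float) -> float:
    # exp underflowing to 0 is the desired overflow-safe behaviour
    return math.exp(x) if x > -745.0 else 0.0


def analytic_gabor_product(g0: GaborParams, g1: GaborParams) -> float:
    """Closed-form continuous inner product of two real Gabor atoms.

    Uses the continuous-time normalization; accurate for the discrete vectors
    only in the well-sampled regime (s >~ a few samples, omega away from 0 and
    pi).  Large s*omega underflows the Gaussian factors to zero rather than
    producing NaN.
    """
    con = product_constants(g0, g1)
    k0 = continuous_norm_factor(g0)
    k1 = continuous_norm_factor(g1)
    wsum = g0.omega + g1.omega
    wdif = g0.omega - g1.omega
    term_sum = math.cos(wsum * con.B + (g0.phi + g1.phi) - (g0.omega * g0.u + g1.omega * g1.u)) * _exp_safe(
        -wsum * wsum / (4.0 * con.A)
    )
    term_dif = math.cos(wdif * con.B + (g0.phi - g1.phi) - (g0.omega * g0.u - g1.omega * g1.u)) * _exp_safe(
        -wdif * wdif / (4.0 * con.A)
    )
    return k0 * k1 * 0.5 * math.sqrt(math.pi / con.A) * _exp_safe(con.C) * (term_sum + term_dif)


def discrete_product(v0: np.ndarray, v1: np.ndarray) -> float:
    """Euclidean dot product of two sample vectors (the authoritative product
    used by the pursuit engines)."""
    v0 = np.asarray(v0, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    if v0.shape != v1.shape:
        raise ValueError(f"length mismatch: {v0.shape} vs {v1.shape}")
    return float(v0 @ v1)


@dataclass(frozen=True)
class PhaseSplit:
    """Envelope-weighted cosine/sine components of an atom class against a
    signal, with the discrete Gram moments needed for phase optimization.

    In discrete time <C, S> is generally *not* zero; ``cs`` carries it so the
    phase solver can use the exact 2x2 Gram system.
    """

    t_lo: int
    C_vec: np.ndarray
    S_vec: np.ndarray
    xc: float
    xs: float
    cc: float
    ss: float
    cs: float


def phase_split(signal: np.ndarray, u: float, omega: float, s: float) -> PhaseSplit:
    """Compute the C/S components and all moments of ``signal`` against the
    Gabor class (u, omega, s)."""
    signal = np.asarray(signal, dtype=float)
    t_lo, cvec, svec = _cs_window(u, omega, s, signal.size)
    seg = signal[t_lo : t_lo + cvec.size]
    return PhaseSplit(
        t_lo=t_lo,
        C_vec=cvec,
        S_vec=svec,
        xc=float(seg @ cvec),
        xs=float(seg @ svec),
        cc=float(cvec @ cvec),
        ss=float(svec @ svec),
        cs=float(cvec @ svec),
    )


#: Relative determinant threshold below which the 2x2 Gram system is treated
#: as rank-1 and the solver falls back to the phi = 0 branch.
_GRAM_DET_RTOL = 1e-10
#: The sine component is treated as numerically absent when its energy falls
#: below this fraction of the cosine component's (e.g. Nyquist atoms centered
#: on integer samples, where S is pure rounding noise).
_GRAM_SS_RTOL = 1e-12


def optimal_phase_from_moments(
    xc: float, xs: float, cc: float, ss: float, cs: float
) -> tuple[float, float]:
    """Phase maximizing the product from the five scalar moments.

    Solves the exact 2x2 Gram system (Gram-corrected projection); reduces to
    the textbook closed form phi = arctan[(xs/ss)/(xc/cc)] (quadrant resolved,
    sign such that the product is maximal and non-negative) when <C,S> = 0.
    Returns ``(phi_max, product_max)`` with product_max >= 0.
    """
    det = cc * ss - cs * cs
    if cc <= 0.0:
        raise ValueError("degenerate atom class: <C,C> = 0")
    if ss <= _GRAM_SS_RTOL * cc or det <= _GRAM_DET_RTOL * cc * ss:
        # pure-Gaussian / rank-1 limit: only the phi = 0 component is resolvable
        prod = xc / math.sqrt(cc)
        if prod >= 0.0:
            return 0.0, prod
        return math.pi, -prod
    # the atom is b(w) = w1*C + w2*S with (w1, w2) = (cos phi, -sin phi);
    # maximizing (v.w)^2 / (w' G w) over the direction of w gives w* ~ G^{-1} v
    w1 = (ss * xc - cs * xs) / det
    w2 = (cc * xs - cs * xc) / det
    nrm = math.sqrt(w1 * w1 * cc + 2.0 * w1 * w2 * cs + w2 * w2 * ss)
    if nrm == 0.0:
        return 0.0, 0.0
    prod = (xc * w1 + xs * w2) / nrm
    phi = math.atan2(-w2, w1)
    if prod < 0.0:
        prod = -prod
        phi += math.pi
    return phi % (2.0 * math.pi), prod


def optimal_phase(signal: np.ndarray, u: float, omega: float, s: float) -> tuple[float, float]:
    """Phase phi that maximizes |<signal, g(u, omega, s, phi)>|.

    Returns ``(phi_max, product_max)`` with ``product_max >= 0`` equal to the
    product of the signal with the discretely normalized atom at phi_max.
    """
    ps = phase_split(signal, u, omega, s)
    return optimal_phase_from_moments(ps.xc, ps.xs, ps.cc, ps.ss, ps.cs)


def windowed_fft_products(
    signal: np.ndarray, u: float, s: float, delta_omega: float
) -> tuple[np.ndarray, np.ndarray]:
    """<x, C> and <x, S> for all grid frequencies omega_k = k*delta_omega.

    The grid step must correspond to an integer transform length,
    delta_omega = 2*pi/L for integer L (no silent regridding).  Returns the
    products for k = 0 .. floor(pi/delta_omega), computed as the real and
    negated imaginary parts of the discrete Fourier transform of the
    Gauss-windowed, u-centered signal.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    length = 2.0 * math.pi / delta_omega
    fft_len = int(round(length))
    if abs(length - fft_len) > 1e-9 * length:
        raise ValueError(
            f"delta_omega={delta_omega} incompatible with an integer transform "
            f"length (2*pi/delta_omega = {length})"
        )
    t_lo, env = gabor_window(u, s, n)
    if env.size == 0:
        raise ValueError("degenerate atom: envelope underflows on the whole epoch")
    if env.size > fft_len:
        raise ValueError(
            f"transform length {fft_len} shorter than envelope support {env.size}"
        )
    y = signal[t_lo : t_lo + env.size] * env
    spec = np.fft.rfft(y, n=fft_len)
    k_max = int(math.floor(math.pi / delta_omega + 1e-9))
    k_max = min(k_max, fft_len // 2)
    k = np.arange(k_max + 1)
    # shift the transform origin from t_lo to the atom center u
    phase = np.exp(1j * (u - t_lo) * delta_omega * k)
    g = spec[: k_max + 1] * phase
    return g.real.copy(), (-g.imag).copy()


def orthogonality_factor_z(g0: GaborParams, g1: GaborParams) -> float:
    """Envelope-overlap factor Z of the product factorization <g0,g1> = X*Y*Z."""
    con = product_constants(g0, g1)
    s0sq, s1sq = g0.s * g0.s, g1.s * g1.s
    return 0.5 * math.sqrt(g0.s * g1.s / (s0sq + s1sq)) * _exp_safe(con.C)


def is_orthogonal_fast(
    g0: GaborParams, g1: GaborParams, epsilon: float, eta: float = 1e-16
) -> bool:
    """Fast conservative test that two dictionary atoms are orthogonal.

    For atoms drawn from an epsilon-dictionary the normalization-dependent
    factor Y of the product is bounded by ~2/epsilon^2, and |X| < 2, so
    (2*sqrt(2)/epsilon^2)*Z < eta implies |<g0,g1>| < eta.  Default eta is the
    double-precision accuracy 1e-16.
    """
    return 2.0 * math.sqrt(2.0) / (epsilon * epsilon) * orthogonality_factor_z(g0, g1) < eta


def integration_halfwidth(
    g0: GaborParams, g1: GaborParams, eta: float, epsilon: float
) -> float:
    """Half-width Delta' of the truncated product-integration interval.

    Truncating the product integral to [B - Delta', B + Delta'] changes it by
    less than eta for any pair from an epsilon-dictionary.  Derived from the
    two-sided tail condition with the Gaussian tail bound; raises
    OrthogonalPairError when the pair is orthogonal at this tolerance and no
    interval is needed.
    """
    if is_orthogonal_fast(g0, g1, epsilon, eta):
        raise OrthogonalPairError("pair orthogonal to tolerance; no interval needed")
    con = product_constants(g0, g1)
    ratio = g0.s / g1.s + g1.s / g0.s
    arg = con.C - math.log(eta * epsilon * epsilon / 2.0 * math.sqrt(ratio))
    if arg <= 0.0:
        raise OrthogonalPairError("pair orthogonal to tolerance; no interval needed")
    return math.sqrt(arg / con.A)


def gabor_pair_product(
    g0: GaborParams,
    g1: GaborParams,
    n_samples: int,
    eta: float = 1e-12,
    epsilon: float = 0.1,
) -> float:
    """Discrete product of two atoms evaluated on the truncated interval
    [B - Delta', B + Delta'] (bounded-domain product).

    Returns 0.0 for pairs flagged orthogonal by the fast test.
    """
    try:
        halfwidth = integration_halfwidth(g0, g1, eta, epsilon)
    except OrthogonalPairError:
        return 0.0
    con = product_constants(g0, g1)
    lo = max(0, math.ceil(con.B - halfwidth))
    hi = min(n_samples - 1, math.floor(con.B + halfwidth))
    if hi < lo:
        return 0.0
    v0 = synthesize_gabor(g0, n_samples)
    v1 = synthesize_gabor(g1, n_samples)
    return float(v0[lo : hi + 1] @ v1[lo : hi + 1])
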