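"""Gabor atom synthesis, inner products, optimal phase, FFT products."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from gabormp import atoms
from gabormp.atoms import (
    GaborParams,
    OrthogonalPairError,
    analytic_gabor_product,
    atom_waveform,
    continuous_norm_factor,
    discrete_product,
    gabor_carrier,
    gabor_window,
    gabor_pair_product,
    integration_halfwidth,
    is_orthogonal_fast,
    optimal_phase,
    phase_split,
    product_constants,
    synthesize_gabor,
    windowed_fft_products,
)


def _random_params(rng, n=1024, s_range=(8.0, 128.0), om_range=(0.3, 2.8)):
    return GaborParams(
        u=float(rng.uniform(0.2 * n, 0.8 * n)),
        omega=float(rng.uniform(*om_range)),
        s=float(rng.uniform(*s_range)),
        phi=float(rng.uniform(0.0, 2.0 * math.pi)),
    )


# ---------------------------------------------------------------------------
# synthesis


@pytest.mark.parametrize(
    "u,omega,s,phi",
    [
        (512.0, math.pi, 256.0, 0.0),  # Nyquist carrier, wide envelope
        (100.25, 0.7, 12.0, 1.3),
        (5.0, 2.9, 40.0, 4.0),  # border-clipped
        (1000.0, 0.05, 3.0, 0.0),
    ],
)
def test_unit_norm_contract(u, omega, s, phi):
    v = synthesize_gabor(GaborParams(u, omega, s, phi), 1024)
    assert abs(np.linalg.norm(v) - 1.0) < 1e-12


@pytest.mark.parametrize("family", ["gabor", "harmonic", "delta", "gaussian"])
def test_unit_norm_all_families(family):
    v = atom_waveform(family, 60.0, 1.1, 20.0, 0.4, 128)
    assert abs(np.linalg.norm(v) - 1.0) < 1e-12


def test_nyquist_atom_alternates_sign():
    # omega = pi, phi = 0, center mid-epoch: consecutive nonzero samples flip sign
    n = 256
    v = synthesize_gabor(GaborParams(u=n / 2, omega=math.pi, s=n / 4, phi=0.0), n)
    core = v[n // 2 - 20 : n // 2 + 20]
    assert np.all(core[:-1] * core[1:] < 0)
    assert abs(np.linalg.norm(v) - 1.0) < 1e-12


def test_recurrence_tables_match_direct_transcendentals():
    # envelope and carrier recurrences vs per-sample library calls, N=4096
    n, u, s, omega = 4096, 1234.567, 900.0, 1.2345
    t_lo, env = gabor_window(u, s, n)
    t = np.arange(t_lo, t_lo + env.size, dtype=float)
    direct_env = np.exp(-math.pi * ((t - u) / s) ** 2)
    direct_env[direct_env < 1e-16] = 0.0
    assert np.abs(env - direct_env).max() < 1e-9
    c, s_ = gabor_carrier(u, omega, t_lo, env.size)
    assert np.abs(c - np.cos(omega * (t - u))).max() < 1e-9
    assert np.abs(s_ - np.sin(omega * (t - u))).max() < 1e-9


def test_phase_pi_shift_negates_waveform():
    g = GaborParams(200.0, 1.5, 30.0, 0.8)
    gpi = GaborParams(200.0, 1.5, 30.0, 0.8 + math.pi)
    v0 = synthesize_gabor(g, 512)
    v1 = synthesize_gabor(gpi, 512)
    np.testing.assert_allclose(v1, -v0, atol=1e-14)


def test_degenerate_atom_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        synthesize_gabor(GaborParams(u=500.0, omega=1.0, s=1e-3, phi=0.0), 64)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        GaborParams(0.0, 0.0, 10.0)  # omega = 0
    with pytest.raises(ValueError):
        GaborParams(0.0, 4.0, 10.0)  # above Nyquist
    with pytest.raises(ValueError):
        GaborParams(0.0, 1.0, -1.0)
    with pytest.raises(ValueError):
        GaborParams(float("nan"), 1.0, 1.0)


# ---------------------------------------------------------------------------
# product constants and analytic products


def test_product_constants_special_cases():
    s = 17.0
    g0 = GaborParams(0.0, 1.0, s)
    g1 = GaborParams(0.0, 2.0, s)
    con = product_constants(g0, g1)
    assert con.A == pytest.approx(2.0 * math.pi / s**2, rel=1e-14)
    assert con.B == pytest.approx(0.0, abs=1e-14)
    assert con.C == pytest.approx(0.0, abs=1e-14)

    du = 6.0
    con = product_constants(
        GaborParams(-du / 2 + 100, 1.0, s), GaborParams(du / 2 + 100, 1.0, s)
    )
    assert con.C == pytest.approx(-math.pi * du**2 / (2 * s**2), rel=1e-14)
    # B lies between the two centers
    assert 100 - du / 2 <= con.B <= 100 + du / 2

    con = product_constants(GaborParams(7.0, 1.0, 5.0), GaborParams(7.0, 2.0, 50.0))
    assert con.C == 0.0


def test_analytic_self_product_is_one():
    for g in (GaborParams(500.0, 1.1, 32.0, 0.3), GaborParams(100.0, 2.5, 80.0, 2.0)):
        assert analytic_gabor_product(g, g) == pytest.approx(1.0, abs=1e-6)


def test_analytic_product_matches_quadrature(rng):
    # closed form vs adaptive quadrature of the continuous integrand
    for _ in range(50):
        g0 = _random_params(rng, s_range=(16.0, 64.0))
        g1 = GaborParams(
            u=g0.u + rng.uniform(-30, 30),
            omega=float(rng.uniform(0.3, 2.8)),
            s=float(rng.uniform(16.0, 64.0)),
            phi=float(rng.uniform(0, 2 * math.pi)),
        )
        k0, k1 = continuous_norm_factor(g0), continuous_norm_factor(g1)

        def integrand(t):
            return (
                k0 * math.exp(-math.pi * ((t - g0.u) / g0.s) ** 2)
                * math.cos(g0.omega * (t - g0.u) + g0.phi)
                * k1 * math.exp(-math.pi * ((t - g1.u) / g1.s) ** 2)
                * math.cos(g1.omega * (t - g1.u) + g1.phi)
            )

        center = (g0.u + g1.u) / 2
        span = 6 * max(g0.s, g1.s)
        val, _ = quad(integrand, center - span, center + span, limit=400)
        assert abs(analytic_gabor_product(g0, g1) - val) < 1e-8


def test_analytic_product_symmetric(rng):
    for _ in range(100):
        g0, g1 = _random_params(rng), _random_params(rng)
        assert analytic_gabor_product(g0, g1) == analytic_gabor_product(g1, g0)


def test_analytic_product_overflow_safe():
    # huge s*omega underflows to 0, never NaN
    g0 = GaborParams(512.0, math.pi, 1e4, 0.0)
    g1 = GaborParams(900.0, math.pi, 1e4, 1.0)
    val = analytic_gabor_product(g0, g1)
    assert np.isfinite(val)


def test_discrete_product_matches_analytic_in_wellsampled_regime(rng):
    for _ in range(20):
        g0 = _random_params(rng, s_range=(16.0, 48.0), om_range=(0.5, 2.5))
        g1 = GaborParams(
            u=g0.u + rng.uniform(-20, 20),
            omega=float(np.clip(g0.omega + rng.uniform(-0.3, 0.3), 0.5, 2.5)),
            s=float(rng.uniform(16.0, 48.0)),
            phi=float(rng.uniform(0, 2 * math.pi)),
        )
        v0, v1 = synthesize_gabor(g0, 1024), synthesize_gabor(g1, 1024)
        assert discrete_product(v0, v1) == pytest.approx(
            analytic_gabor_product(g0, g1), abs=1e-4
        )


def test_discrete_product_basics():
    e1, e2 = np.zeros(16), np.zeros(16)
    e1[3] = 1.0
    e2[9] = 1.0
    assert discrete_product(e1, e1) == 1.0
    assert discrete_product(e1, e2) == 0.0
    with pytest.raises(ValueError, match="length mismatch"):
        discrete_product(np.zeros(4), np.zeros(5))


# ---------------------------------------------------------------------------
# optimal phase


def test_optimal_phase_on_aligned_component():
    ps = phase_split(np.zeros(512), 256.0, 1.3, 40.0)
    x = np.zeros(512)
    x[ps.t_lo : ps.t_lo + ps.C_vec.size] = ps.C_vec
    phi, prod = optimal_phase(x, 256.0, 1.3, 40.0)
    assert min(phi % math.pi, math.pi - phi % math.pi) < 1e-6
    assert prod == pytest.approx(np.linalg.norm(x) * math.sqrt(ps.cc) / math.sqrt(ps.cc))


def test_optimal_phase_recovers_planted_phase(rng):
    g = GaborParams(300.0, 1.1, 50.0, 1.1)
    x = 2.0 * synthesize_gabor(g, 1024)
    phi, prod = optimal_phase(x, g.u, g.omega, g.s)
    assert prod == pytest.approx(2.0, rel=1e-10)
    # recovered atom reproduces the signal direction
    v = synthesize_gabor(GaborParams(g.u, g.omega, g.s, phi), 1024)
    assert float(x @ v) == pytest.approx(2.0, rel=1e-10)


def test_optimal_phase_beats_dense_grid(rng):
    # closed form vs exhaustive phase grid on random signals
    grid = np.linspace(0.0, 2.0 * math.pi, 20000, endpoint=False)
    for _ in range(10):
        x = rng.standard_normal(1024)
        u = float(rng.uniform(200, 800))
        omega = float(rng.uniform(0.3, 2.9))
        s = float(rng.uniform(8, 100))
        ps = phase_split(x, u, omega, s)
        num = ps.xc * np.cos(grid) - ps.xs * np.sin(grid)
        den2 = (
            ps.cc * np.cos(grid) ** 2
            - 2 * ps.cs * np.cos(grid) * np.sin(grid)
            + ps.ss * np.sin(grid) ** 2
        )
        vals = num / np.sqrt(np.maximum(den2, 1e-300))
        best_grid = float(vals.max())
        phi, prod = optimal_phase(x, u, omega, s)
        assert prod >= best_grid * (1.0 - 1e-8)


def test_phase_minimum_root_gives_zero_product(rng):
    # substituting tan(phi) = <x,C>/<x,S> lands on the product's zero
    x = rng.standard_normal(1024)
    u, omega, s = 500.0, 1.0, 64.0  # <C,S> negligible here
    ps = phase_split(x, u, omega, s)
    phi1 = math.atan2(ps.xc, ps.xs)
    v = synthesize_gabor(GaborParams(u, omega, s, phi1), 1024)
    _, prod_max = optimal_phase(x, u, omega, s)
    assert abs(float(x @ v)) < 1e-8 * prod_max


def test_optimal_phase_pure_gaussian_limit():
    # ss ~ 0 branch: an integer-centered Nyquist atom has S identically zero
    x = np.zeros(256)
    x[100:140] = 1.0
    phi, prod = optimal_phase(x, 128.0, math.pi, 16.0)
    assert phi in (0.0, math.pi)
    assert np.isfinite(prod) and prod >= 0.0


# ---------------------------------------------------------------------------
# windowed FFT products


def test_windowed_fft_products_match_direct(rng):
    x = rng.standard_normal(1024)
    u, s = 421.7, 64.0
    dw = 2.0 * math.pi / 2048
    xc, xs = windowed_fft_products(x, u, s, dw)
    k_all = np.arange(1, xc.size)
    for k in [1, 17, 300, 701, 1024]:
        ps = phase_split(x, u, k * dw, s)
        assert abs(xc[k] - ps.xc) < 1e-9
        assert abs(xs[k] - ps.xs) < 1e-9


def test_windowed_fft_zero_signal():
    xc, xs = windowed_fft_products(np.zeros(256), 128.0, 16.0, 2 * math.pi / 512)
    assert np.all(xc == 0.0) and np.all(xs == 0.0)


def test_windowed_fft_pure_cosine_peak():
    n = 512
    dw = 2.0 * math.pi / 1024
    k0 = 100
    t = np.arange(n)
    u = 256.0  # antinode: cos(omega*(t-u)) peaks at t = u
    x = np.cos(k0 * dw * (t - u))
    xc, xs = windowed_fft_products(x, u, 40.0, dw)
    assert int(np.argmax(np.abs(xc))) == k0
    assert abs(xs[k0]) < 1e-9 * abs(xc[k0])


def test_windowed_fft_rejects_incompatible_grid():
    with pytest.raises(ValueError, match="incompatible"):
        windowed_fft_products(np.zeros(64), 32.0, 8.0, 0.1)


# ---------------------------------------------------------------------------
# orthogonality shortcut and bounded-domain products


def test_orthogonality_shortcut_is_conservative(rng):
    n = 4096
    flagged = 0
    for _ in range(200):
        g0 = _random_params(rng, n=n, s_range=(8.0, 64.0))
        g1 = _random_params(rng, n=n, s_range=(8.0, 64.0))
        if is_orthogonal_fast(g0, g1, epsilon=0.1):
            flagged += 1
            v0, v1 = synthesize_gabor(g0, n), synthesize_gabor(g1, n)
            assert abs(discrete_product(v0, v1)) < 1e-15
    assert flagged > 0  # the sample must exercise the shortcut


def test_orthogonality_far_separation_and_self():
    s = 10.0
    g0 = GaborParams(100.0, 2.0, s)
    g1 = GaborParams(100.0 + 40.0 * s, 2.0, s)
    assert is_orthogonal_fast(g0, g1, epsilon=0.1)
    assert not is_orthogonal_fast(g0, g0, epsilon=0.1)


def test_integration_halfwidth_truncation_error(rng):
    n = 2048
    for _ in range(50):
        s0 = float(rng.uniform(8, 64))
        g0 = GaborParams(float(rng.uniform(800, 1200)), float(rng.uniform(0.3, 2.8)), s0)
        g1 = GaborParams(
            g0.u + float(rng.uniform(-2 * s0, 2 * s0)),
            float(rng.uniform(0.3, 2.8)),
            float(rng.uniform(8, 64)),
            float(rng.uniform(0, 2 * math.pi)),
        )
        full = discrete_product(synthesize_gabor(g0, n), synthesize_gabor(g1, n))
        trunc = gabor_pair_product(g0, g1, n, eta=1e-12, epsilon=0.1)
        assert abs(full - trunc) < 1e-12


def test_integration_halfwidth_monotone_in_eta():
    g0 = GaborParams(500.0, 1.0, 30.0)
    g1 = GaborParams(520.0, 1.2, 40.0)
    d_strict = integration_halfwidth(g0, g1, eta=1e-12, epsilon=0.1)
    d_loose = integration_halfwidth(g0, g1, eta=1e-4, epsilon=0.1)
    assert d_loose < d_strict


def test_integration_halfwidth_identical_atoms_cover_bulk():
    g = GaborParams(500.0, 1.0, 30.0)
    d = integration_halfwidth(g, g, eta=1e-12, epsilon=0.1)
    assert np.isfinite(d)
    assert 2.0 * d >= 4.0 * g.s  # interval spans several scale units


def test_integration_halfwidth_orthogonal_pair_raises():
    g0 = GaborParams(100.0, 2.0, 10.0)
    g1 = GaborParams(100.0 + 400.0, 2.0, 10.0)
    with pytest.raises(OrthogonalPairError, match="no interval"):
        integration_halfwidth(g0, g1, eta=1e-16, epsilon=0.1)


# ---------------------------------------------------------------------------
# properties


@given(
    u=st.floats(100.0, 900.0),
    omega=st.floats(0.1, math.pi),
    s=st.floats(4.0, 200.0),
    phi=st.floats(0.0, 2.0 * math.pi),
)
def test_norm_property(u, omega, s, phi):
    v = synthesize_gabor(GaborParams(u, omega, s, phi), 1024)
    assert abs(np.linalg.norm(v) - 1.0) < 1e-12
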