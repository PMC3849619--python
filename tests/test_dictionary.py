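"""Metric, adjacent-atom products, and optimal dictionary construction."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from gabormp.atoms import GaborParams, synthesize_gabor
from gabormp.dictionary import (
    MIN_SCALE,
    Dictionary,
    DictionaryConfig,
    build_dictionary,
    dictionary_info,
    dilation_factor,
    max_class_product,
    max_product_freq,
    max_product_pos,
    max_product_scale,
    metric_d,
    metric_d0,
    steps_for_scale,
    _class_basis,
)


# ---------------------------------------------------------------------------
# the d0 metric


def test_d0_identity_orthogonal_antipodal():
    n = 1024
    g = GaborParams(300.0, 1.2, 32.0, 0.5)
    v = synthesize_gabor(g, n)
    assert metric_d0(v, v) == pytest.approx(0.0, abs=1e-7)
    # disjoint supports: exactly orthogonal
    v2 = synthesize_gabor(GaborParams(900.0, 1.2, 32.0, 0.5), n)
    assert metric_d0(v, v2) == 1.0
    # antipodal: product -1, distance sqrt(2) (the algebraic maximum; the
    # loose upper bound 2 is never exceeded)
    v3 = synthesize_gabor(GaborParams(300.0, 1.2, 32.0, 0.5 + math.pi), n)
    assert metric_d0(v, v3) == pytest.approx(math.sqrt(2.0), abs=1e-7)


def test_d0_triangle_inequality(rng):
    n = 512
    for _ in range(50):
        vs = [
            synthesize_gabor(
                GaborParams(
                    float(rng.uniform(100, 400)),
                    float(rng.uniform(0.2, 3.0)),
                    float(rng.uniform(4, 80)),
                    float(rng.uniform(0, 2 * math.pi)),
                ),
                n,
            )
            for _ in range(3)
        ]
        d01 = metric_d0(vs[0], vs[1])
        d12 = metric_d0(vs[1], vs[2])
        d02 = metric_d0(vs[0], vs[2])
        assert d02 <= d01 + d12 + 1e-12


# ---------------------------------------------------------------------------
# phase-class metric


def test_metric_d_identity_and_far_frequency():
    n = 512
    c0 = (256.0, 1.0, 30.0)
    assert metric_d(c0, c0, n) == pytest.approx(0.0, abs=1e-6)
    # widely separated frequencies: classes nearly orthogonal
    c1 = (256.0, 3.0, 30.0)
    assert metric_d(c0, c1, n) == pytest.approx(1.0, abs=1e-3)


def _grid_max_product(c0, c1, n, n_phi=360):
    """Brute-force maximal product over a phase grid (oracle)."""
    b0 = _class_basis(*c0, n)
    b1 = _class_basis(*c1, n)
    g0 = b0 @ b0.T
    g1 = b1 @ b1.T
    m = b0 @ b1.T
    phis = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    w = np.stack([np.cos(phis), -np.sin(phis)])  # (2, n_phi)
    num = w.T @ m @ w  # (n_phi, n_phi)
    n0 = np.sqrt(np.einsum("ij,jk,ki->i", w.T, g0, w))
    n1 = np.sqrt(np.einsum("ij,jk,ki->i", w.T, g1, w))
    return float((num / np.outer(n0, n1)).max())


def test_metric_d_matches_phase_grid_bruteforce(rng):
    n = 512
    for _ in range(10):
        s = float(rng.uniform(8, 40))
        u = float(rng.uniform(150, 350))
        om = float(rng.uniform(0.5, 2.6))
        c0 = (u, om, s)
        c1 = (
            u + float(rng.uniform(-s / 2, s / 2)),
            om + float(rng.uniform(-0.2, 0.2)),
            s * float(rng.uniform(0.8, 1.25)),
        )
        exact = max_class_product(c0, c1, n)
        grid = _grid_max_product(c0, c1, n)
        # the 360-point grid slightly undershoots the true maximum
        assert exact >= grid - 1e-9
        assert exact - grid < 1e-4
        assert metric_d(c0, c1, n) == pytest.approx(
            math.sqrt(1 - grid), abs=1e-3
        )


# ---------------------------------------------------------------------------
# closed-form neighbor products


def test_max_product_scale_limits():
    with pytest.raises(ValueError):
        max_product_scale(10.0, 1.0, 1.0)
    # Nyquist-region limit sqrt(2a/(a^2+1))
    a = 1.2
    val = max_product_scale(10.0, math.pi, a)
    assert val == pytest.approx(math.sqrt(2 * a / (a * a + 1)), abs=1e-10)
    # monotone decreasing in a at fixed (s, omega)
    vals = [max_product_scale(10.0, math.pi, aa) for aa in np.linspace(1.01, 3.0, 40)]
    assert all(x > y for x, y in zip(vals, vals[1:]))


def test_max_product_freq_values():
    assert max_product_freq(10.0, 1.0, 0.0) == 1.0
    s, om, dw = 10.0, math.pi, 0.05
    val = max_product_freq(s, om, dw)
    assert val == pytest.approx(math.exp(-(dw**2) * s * s / (8 * math.pi)), abs=1e-6)
    with pytest.raises(ValueError):
        max_product_freq(10.0, 1.0, -0.1)


def test_max_product_pos_values(rng):
    assert max_product_pos(10.0, 1.0, 0.0) == 1.0
    # near Nyquist the inner phase maximum attains 1 + exp(-s^2 om^2/(2 pi))
    s, om, du = 10.0, math.pi, 0.8
    e = math.exp(-s * s * om * om / (2 * math.pi))
    expected = math.exp(-math.pi * du * du / (2 * s * s)) * (1 + e) / math.sqrt(
        (1 + e) * (1 + e)
    )
    # compare the closed-form stationary solution against a dense phi grid
    phis = np.linspace(0, 2 * np.pi, 100000, endpoint=False)
    grid = (
        math.exp(-math.pi * du * du / (2 * s * s))
        * (np.cos(2 * phis + om * du) + e)
        / (1 + np.cos(2 * phis) * e)
    ).max()
    assert max_product_pos(s, om, du) == pytest.approx(float(grid), abs=1e-8)
    for _ in range(20):
        s = float(rng.uniform(5, 50))
        om = float(rng.uniform(0.3, math.pi))
        du = float(rng.uniform(0.0, s))
        e = math.exp(-s * s * om * om / (2 * math.pi))
        grid = float(
            (
                math.exp(-math.pi * du * du / (2 * s * s))
                * (np.cos(2 * phis + om * du) + e)
                / (1 + np.cos(2 * phis) * e)
            ).max()
        )
        val = max_product_pos(s, om, du)
        # stationary solution dominates the grid, to grid resolution
        assert val >= grid - 1e-12
        assert val - grid < 1e-6


# ---------------------------------------------------------------------------
# the optimal sampling


def test_dilation_factor_closed_form_vs_root():
    for eps in (0.02, 0.05, 0.1, 0.2, 0.4):
        e2 = eps * eps
        target = (1 - e2) ** 2

        def f(a):
            return 2 * a / (a * a + 1) - target

        root = brentq(f, 1.0 + 1e-12, 100.0)
        assert dilation_factor(eps) == pytest.approx(root, rel=1e-10)
    assert dilation_factor(0.1) == pytest.approx(1.22285, abs=5e-5)
    # epsilon -> 0+ gives a -> 1+
    assert dilation_factor(1e-4) == pytest.approx(1.0, abs=1e-2)
    with pytest.raises(ValueError):
        dilation_factor(1.5)


def test_steps_for_scale_values():
    dw, du = steps_for_scale(10.0, 0.1)
    assert dw * 10.0 == pytest.approx(0.50257, abs=2e-5)
    assert du / 10.0 == pytest.approx(0.08000, abs=2e-5)
    # the product delta_omega * delta_u is independent of s
    p1 = np.prod(steps_for_scale(5.0, 0.1))
    p2 = np.prod(steps_for_scale(200.0, 0.1))
    assert p1 == pytest.approx(p2, rel=1e-12)


@pytest.mark.parametrize("eps", [0.05, 0.1, 0.2])
def test_neighbor_metric_closes_the_loop(eps):
    # the optimal steps make the continuous neighbor products exactly 1-eps^2
    # at the Nyquist end, i.e. metric distance epsilon
    s = 24.0
    a = dilation_factor(eps)
    dw, du = steps_for_scale(s, eps)
    d_scale = math.sqrt(1 - max_product_scale(s, math.pi, a))
    d_freq = math.sqrt(1 - max_product_freq(s, math.pi - dw, dw))
    d_pos = math.sqrt(1 - max_product_pos(s, math.pi, du))
    for d in (d_scale, d_freq, d_pos):
        assert d == pytest.approx(eps, abs=1e-6)
    # the discretized classes never exceed the bound (aliasing near Nyquist
    # only increases similarity)
    n = 1024
    u, om = n / 2.0, math.pi * 0.98
    assert metric_d((u, om, s), (u, om, a * s), n) <= eps + 1e-6
    assert metric_d((u, om - dw, s), (u, om, s), n) <= eps + 1e-6
    assert metric_d((u, om, s), (u + du, om, s), n) <= eps + 1e-6


# ---------------------------------------------------------------------------
# construction


def test_atom_count_decreases_with_epsilon():
    counts = []
    for eps in (0.05, 0.1, 0.2):
        _, n_atoms, _ = dictionary_info(DictionaryConfig(epsilon=eps, n_samples=512))
        counts.append(n_atoms)
    assert counts[0] > counts[1] > counts[2]


def test_layout_scale_count_formula():
    for eps, n in ((0.1, 512), (0.2, 256), (0.3, 1000)):
        cfg = DictionaryConfig(epsilon=eps, n_samples=n)
        layout, _, _ = dictionary_info(cfg)
        a = dilation_factor(eps)
        assert layout.n_scales == int(math.floor(math.log(n) / math.log(a)))
        assert layout.scales[-1].j == layout.n_scales
        assert all(sc.s >= MIN_SCALE for sc in layout.scales)
        # realized frequency steps never exceed the optimal ones
        for sc in layout.scales:
            dw_opt, du_opt = steps_for_scale(sc.s, eps)
            assert sc.delta_omega <= dw_opt + 1e-12
            assert sc.delta_u == pytest.approx(du_opt)


def test_summary_table_lists_scales():
    layout, _, _ = dictionary_info(DictionaryConfig(epsilon=0.2, n_samples=256))
    table = layout.summary_table()
    assert "delta_omega" in table
    assert len(table.splitlines()) == 2 + len(layout.scales)


def test_stochastic_reproducible_and_percentage100():
    cfg = DictionaryConfig(
        epsilon=0.2, n_samples=256, dict_type="stochastic", percentage_chosen=50.0, seed=7
    )
    d1 = build_dictionary(cfg)
    d2 = build_dictionary(cfg)
    assert d1.masks.keys() == d2.masks.keys()
    for k in d1.masks:
        np.testing.assert_array_equal(d1.masks[k], d2.masks[k])
    n_dense = d1.n_atoms_dense()
    assert d1.n_atoms() == n_dense - int(round(n_dense * 0.5))
    # percentage 100: atom-for-atom the fixed dictionary
    full = build_dictionary(
        DictionaryConfig(
            epsilon=0.2, n_samples=256, dict_type="stochastic",
            percentage_chosen=100.0, seed=7,
        )
    )
    assert full.masks is None
    assert full.n_atoms() == n_dense


def test_stochastic_seeds_overlap_hypergeometric():
    # removal sets from different seeds overlap as for uniform draws
    cfg1 = DictionaryConfig(
        epsilon=0.2, n_samples=256, dict_type="stochastic", percentage_chosen=50.0, seed=1
    )
    cfg2 = DictionaryConfig(
        epsilon=0.2, n_samples=256, dict_type="stochastic", percentage_chosen=50.0, seed=2
    )
    d1, d2 = build_dictionary(cfg1), build_dictionary(cfg2)

    def removed(d: Dictionary) -> np.ndarray:
        bits = []
        for key in d.block_keys():
            m = d.mask(key)
            if m is None:
                bits.append(np.ones(int(np.prod(d.block_shape(key))), dtype=bool))
            else:
                bits.append(m.ravel())
        return ~np.concatenate(bits)

    r1, r2 = removed(d1), removed(d2)
    n = r1.size
    k = int(r1.sum())
    overlap = int((r1 & r2).sum())
    mean = k * k / n
    var = k * k / n * (n - k) / n * (n - k) / (n - 1)
    assert abs(overlap - mean) < 3.0 * math.sqrt(var)


def test_stochastic_requires_seed_and_nonempty():
    with pytest.raises(ValueError, match="seed"):
        DictionaryConfig(epsilon=0.2, n_samples=64, dict_type="stochastic")
    with pytest.raises(ValueError):
        DictionaryConfig(epsilon=0.2, n_samples=64, percentage_chosen=0.0)


def test_memory_budget_enforced():
    with pytest.raises(MemoryError, match="exceeding"):
        build_dictionary(DictionaryConfig(epsilon=0.05, n_samples=512, max_bytes=1000))


def test_epsilon_bounds_and_warning():
    with pytest.raises(ValueError):
        DictionaryConfig(epsilon=0.0, n_samples=64)
    with pytest.raises(ValueError):
        DictionaryConfig(epsilon=1.0, n_samples=64)
    with pytest.warns(UserWarning, match="large"):
        DictionaryConfig(epsilon=0.7, n_samples=64)


def _adjacent_pair_audit(eps: float, n: int, rng, n_pairs: int):
    """Sample adjacent dictionary pairs near Nyquist; return worst metric_d."""
    d = build_dictionary(DictionaryConfig(epsilon=eps, n_samples=n))
    scales = d.layout.scales
    worst = 0.0
    for _ in range(n_pairs):
        si = rng.integers(0, len(scales))
        sc = scales[si]
        # an omega within 10% of Nyquist on this scale's realized grid
        k_lo = int(math.ceil(0.9 * math.pi / sc.delta_omega))
        k = int(rng.integers(max(1, k_lo), sc.n_omega))
        om = (k + 1) * sc.delta_omega if k + 1 <= sc.n_omega else k * sc.delta_omega
        om = k * sc.delta_omega
        iu = int(rng.integers(0, max(1, sc.n_u - 1)))
        u = iu * sc.delta_u
        direction = rng.integers(0, 3)
        if direction == 0 and si + 1 < len(scales):
            other = (u, om, scales[si + 1].s)
        elif direction == 1 and k + 1 <= sc.n_omega:
            other = (u, (k + 1) * sc.delta_omega, sc.s)
        else:
            other = (u + sc.delta_u, om, sc.s)
        worst = max(worst, metric_d((u, om, sc.s), other, n))
    return worst


def test_epsilon_audit_small(rng):
    worst = _adjacent_pair_audit(0.1, 512, rng, 60)
    assert worst <= 0.1 + 1e-6
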