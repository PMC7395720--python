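"""Guided-wave dispersion: secular determinant, tracing, independent oracles.

Oracles used here are assembled independently of the package's layer
matrix: an isotropic-layer determinant built from Helmholtz potentials
(cosh/sinh form), a free-plate determinant built from the raw
(unreduced) partial-wave stress expressions, and a 3x3 water/half-space
determinant whose root is the Scholte interface speed that bounds the A0
mode at high frequency.
"""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from nitiwave.dispersion import (
    DispersionBranch,
    LayerSystem,
    TracingError,
    _trace_a0_fast,
    a0_high_freq_asymptote,
    isotropic_dispersion,
    secular_determinant,
    trace_a0,
    trace_modes,
)
from nitiwave.materials import make_material


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------


def iso_layer_det(mu, rho, cL, h, rho_w, cw, f, v):
    """Isotropic layer over water via Helmholtz potentials (cosh/sinh)."""
    om = 2 * np.pi * f
    k = om / v
    lam = rho * cL**2 - 2 * mu
    p = np.sqrt(complex(k**2 - (om / cL) ** 2))
    q = np.sqrt(complex(k**2 - om**2 * rho / mu))
    kw = np.sqrt(complex(k**2 - (om / cw) ** 2))
    if kw.real < 0:
        kw = -kw

    def rows(z):
        cp, sp = np.cosh(p * z), np.sinh(p * z)
        cq, sq = np.cosh(q * z), np.sinh(q * z)
        w = np.array([p * sp, p * cp, -1j * k * cq, -1j * k * sq])
        szz = np.array(
            [
                (lam * (p**2 - k**2) + 2 * mu * p**2) * cp,
                (lam * (p**2 - k**2) + 2 * mu * p**2) * sp,
                -2j * mu * k * q * sq,
                -2j * mu * k * q * cq,
            ]
        )
        sxz = mu * np.array(
            [2j * k * p * sp, 2j * k * p * cp, (q**2 + k**2) * cq, (q**2 + k**2) * sq]
        )
        return w, szz, sxz

    w0, szz0, sxz0 = rows(0.0)
    wh, szzh, sxzh = rows(h)
    M = np.zeros((5, 5), complex)
    M[0, :4] = szz0
    M[1, :4] = sxz0
    M[2, :4] = sxzh
    M[3, :4] = szzh
    M[3, 4] = rho_w * om**2
    M[4, :4] = wh
    M[4, 4] = kw
    s = np.abs(M).max(axis=1, keepdims=True)
    return np.linalg.det(M / s)


def iso_layer_root(mu, h, f, v_lo, v_hi, rho=1000.0, cL=1540.0, rho_w=1000.0, cw=1480.0):
    res = minimize_scalar(
        lambda v: abs(iso_layer_det(mu, rho, cL, h, rho_w, cw, f, v)),
        bounds=(v_lo, v_hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    assert res.fun < 1e-8, "oracle failed to localize a root"
    return res.x


def free_plate_det(mat, h, f, v):
    """4x4 free-plate determinant from raw partial-wave stress expressions."""
    lam, mu, G, rho = mat.lam, mat.mu, mat.G, mat.rho
    alpha, beta, gamma = lam + 2 * mu, G, lam + G
    om = 2 * np.pi * f
    k = om / v
    X = rho * v * v
    a = alpha * beta
    b = alpha**2 + beta**2 - X * (alpha + beta) - gamma**2
    c = (alpha - X) * (beta - X)
    disc = np.sqrt(complex(b * b - 4 * a * c))
    q2 = np.array([(-b + disc) / (2 * a), (-b - disc) / (2 * a)])
    qp = np.sqrt(q2)
    qp = np.where(qp.imag < 0, -qp, qp)
    qs = np.concatenate([qp, -qp])
    q2s = np.concatenate([q2, q2])
    U = gamma * qs
    W = -(alpha + beta * q2s - X)
    szz = lam * U + alpha * qs * W  # unreduced forms on purpose
    sxz = G * (qs * U + W)
    E0 = np.where(qs.imag >= 0, 1.0 + 0j, np.exp(-1j * k * qs * h))
    Eh = np.where(qs.imag >= 0, np.exp(1j * k * qs * h), 1.0 + 0j)
    M = np.stack([szz * E0, sxz * E0, szz * Eh, sxz * Eh])
    s = np.abs(M).max(axis=1, keepdims=True)
    return np.linalg.det(M / s)


def scholte_speed(mat, rho_w=1000.0, cw=1480.0):
    """Root of the 3x3 water/NITI half-space determinant (interface wave)."""
    lam, mu, G, rho = mat.lam, mat.mu, mat.G, mat.rho
    alpha, beta, gamma = lam + 2 * mu, G, lam + G

    def det(c):
        X = rho * c * c
        a = alpha * beta
        b = alpha**2 + beta**2 - X * (alpha + beta) - gamma**2
        cc = (alpha - X) * (beta - X)
        disc = np.sqrt(complex(b * b - 4 * a * cc))
        q2 = np.array([(-b + disc) / (2 * a), (-b - disc) / (2 * a)])
        q = np.sqrt(q2)
        q = np.where(q.imag < 0, -q, q)
        U = gamma * q
        W = -(alpha + beta * q2 - X)
        szz = lam * U + alpha * q * W
        sxz = q * U + W
        qw = np.sqrt(complex(c * c / cw**2 - 1))
        qw = qw if qw.imag >= 0 else -qw
        M = np.zeros((3, 3), complex)
        M[0, :2] = sxz
        M[1, :2] = szz
        M[1, 2] = -rho_w * c * c
        M[2, :2] = W
        M[2, 2] = qw
        s = np.abs(M).max(axis=1, keepdims=True)
        return abs(np.linalg.det(M / s))

    cb = mat.c_G
    grid = np.linspace(0.5 * cb, 0.9999 * cb, 800)
    vals = [det(c) for c in grid]
    i = int(np.argmin(vals))
    res = minimize_scalar(
        lambda c: det(c),
        bounds=(grid[max(i - 2, 0)], grid[min(i + 2, len(grid) - 1)]),
        method="bounded",
        options={"xatol": 1e-12},
    )
    assert res.fun < 1e-8
    return res.x


# --------------------------------------------------------------------------
# secular determinant
# --------------------------------------------------------------------------


class TestSecularDeterminant:
    def test_scaling_invariance(self, mat_aniso):
        # the determinant depends only on (phase velocity, k*h): expressing
        # the same physical point with rescaled units leaves it unchanged
        s1 = LayerSystem(mat_aniso, h=0.55e-3)
        s2 = LayerSystem(mat_aniso, h=0.55e-4)
        f, k = 1500.0, 3000.0
        d1 = secular_determinant(s1, f, k)
        d2 = secular_determinant(s2, 10 * f, 10 * k)
        assert d2 == pytest.approx(d1, rel=1e-10)

    def test_positive_inputs_required(self, sys_aniso):
        with pytest.raises(ValueError):
            secular_determinant(sys_aniso, -1.0, 100.0)
        with pytest.raises(ValueError):
            secular_determinant(sys_aniso, 100.0, 0.0)

    def test_grid_scan_minimum_is_a_root(self, sys_aniso):
        # brute-force 600x600 (f, k) scan, then local refinement: the
        # deepest |det| minimum must be a true zero of the secular equation
        f = np.linspace(200.0, 4000.0, 600)
        k = np.linspace(300.0, 7000.0, 600)
        F, K = np.meshgrid(f, k, indexing="ij")
        d = np.abs(secular_determinant(sys_aniso, F.ravel(), K.ravel()))
        i = int(np.argmin(d))
        f0, k0 = F.ravel()[i], K.ravel()[i]
        res = minimize_scalar(
            lambda kk: abs(secular_determinant(sys_aniso, f0, kk)),
            bounds=(k0 * 0.98, k0 * 1.02),
            method="bounded",
            options={"xatol": 1e-6},
        )
        assert res.fun < 1e-6

    def test_traced_roots_have_small_residual(self, a0_aniso):
        assert np.nanmax(a0_aniso.residuals) < 1e-6


# --------------------------------------------------------------------------
# mode tracing
# --------------------------------------------------------------------------


class TestTraceModes:
    def test_isotropic_layer_has_two_branches(self, sys_iso):
        branches = trace_modes(sys_iso, 200.0, 4000.0, 24)
        labels = [b.label for b in branches]
        assert "A0" in labels and "S0" in labels
        a0 = branches[labels.index("A0")]
        assert len(a0.freqs) >= 0.9 * 24
        assert np.all(np.diff(a0.phase_velocity) > 0)  # A0 speeds up with f

    def test_isotropic_a0_matches_potential_oracle(self, sys_iso):
        branches = trace_modes(sys_iso, 200.0, 4000.0, 24)
        a0 = next(b for b in branches if b.label == "A0")
        for f_chk in (1000.0, 4000.0):
            v_mine = a0.velocity_at(f_chk)
            v_oracle = iso_layer_root(20e3, 0.55e-3, f_chk, 0.8 * v_mine, 1.2 * v_mine)
            assert v_mine == pytest.approx(v_oracle, rel=1e-3)

    def test_a0_flexural_limit_at_low_frequency(self, sys_aniso):
        br = trace_a0(sys_aniso, np.linspace(40.0, 200.0, 9))
        assert np.all(np.diff(br.phase_velocity) > 0)  # decreasing toward f=0
        assert br.phase_velocity[0] < 1.0

    def test_s0_low_frequency_speed_increases_with_mu(self):
        speeds = []
        for mu in [20e3, 40e3, 100e3, 1000e3]:
            sys = LayerSystem(make_material(mu, 20e3, 1000.0, 1540.0), 0.55e-3)
            branches = trace_modes(sys, 200.0, 1000.0, 16)
            s0 = next(b for b in branches if b.label == "S0")
            speeds.append(s0.phase_velocity[0])
        assert np.all(np.diff(speeds) > 0)

    def test_free_plate_limit_matches_free_plate_oracle(self, mat_aniso):
        sys_free = LayerSystem(mat_aniso, h=0.55e-3, rho_f=0.0)
        br = trace_a0(sys_free, np.array([1000.0, 2000.0]))
        for f0, v0 in zip(br.freqs, br.phase_velocity):
            res = minimize_scalar(
                lambda v: abs(free_plate_det(mat_aniso, 0.55e-3, f0, v)),
                bounds=(0.98 * v0, 1.02 * v0),
                method="bounded",
                options={"xatol": 1e-9},
            )
            assert res.fun < 1e-8
            assert res.x == pytest.approx(v0, rel=1e-3)

    def test_nested_isotropic_equivalence(self, sys_iso):
        # the NITI secular with G = mu and the isotropic oracle locate the
        # same roots to 0.1% in wavenumber
        branches = isotropic_dispersion(mu=20e3, h=0.55e-3, f_min=300, f_max=3000, n_freq=16)
        a0 = next(b for b in branches if b.label == "A0")
        for f0, v0 in zip(a0.freqs[::5], a0.phase_velocity[::5]):
            v_oracle = iso_layer_root(20e3, 0.55e-3, f0, 0.9 * v0, 1.1 * v0)
            assert v0 == pytest.approx(v_oracle, rel=1e-3)

    def test_isotropic_dispersion_equals_g_equals_mu_trace(self):
        # nested-model identity: same call path, sample-for-sample
        b1 = isotropic_dispersion(mu=14.4e3, h=0.6e-3, f_min=200, f_max=4000, n_freq=16)
        sys = LayerSystem(make_material(14.4e3, 14.4e3, 1000.0, 1540.0), 0.6e-3)
        b2 = trace_modes(sys, 200, 4000, 16)
        assert len(b1) >= 2  # phantom-like layer supports two guided modes
        for x, y in zip(b1, b2):
            assert x.label == y.label
            assert np.allclose(x.wavenumbers, y.wavenumbers, rtol=1e-9)

    def test_tracing_error_carries_partial_results(self, mat_aniso):
        sys = LayerSystem(mat_aniso, h=0.55e-3)
        # velocity window excludes every root -> tracing must fail loudly
        with pytest.raises(TracingError):
            trace_modes(sys, 200.0, 400.0, 16, v_min=100.0, v_max=200.0, n_scan=50)

    def test_input_validation(self, sys_aniso):
        with pytest.raises(ValueError):
            trace_modes(sys_aniso, 0.0, 4000.0)
        with pytest.raises(ValueError):
            trace_modes(sys_aniso, 200.0, 4000.0, n_freq=8)


class TestA0Asymptote:
    def test_asymptote_approaches_scholte_oracle(self, mat_aniso):
        # water loading drags the high-frequency A0 limit to the Scholte
        # interface speed rather than the free-surface Rayleigh speed
        sys = LayerSystem(mat_aniso, h=0.55e-3)
        c_sch = scholte_speed(mat_aniso)
        br = trace_a0(sys, np.geomspace(8000.0, 30000.0, 8))
        assert br.phase_velocity[-1] == pytest.approx(c_sch, rel=0.02)

    def test_kh_scaling_contract(self, mat_aniso):
        # doubling h at fixed f*h leaves the asymptote nearly unchanged
        v1 = a0_high_freq_asymptote(LayerSystem(mat_aniso, 0.55e-3), 8000.0)
        v2 = a0_high_freq_asymptote(LayerSystem(mat_aniso, 1.10e-3), 4000.0)
        assert v2 == pytest.approx(v1, rel=0.01)

    def test_asymptote_monotone_in_G(self):
        vals = []
        for G in [10e3, 30e3, 100e3]:
            m = make_material(mu=200e3, G=G, rho=1000.0, cL=1540.0)
            sys = LayerSystem(m, 0.55e-3)
            f_eval = max(8000.0, 4 * m.c_G / sys.h)
            vals.append(a0_high_freq_asymptote(sys, f_eval))
        assert np.all(np.diff(vals) > 0)

    def test_short_wavelength_precondition(self, sys_aniso):
        with pytest.raises(ValueError, match="f_eval"):
            a0_high_freq_asymptote(sys_aniso, 500.0)


class TestFastTracer:
    def test_agrees_with_robust_tracer(self, sys_aniso):
        freqs = np.geomspace(300.0, 4000.0, 16)
        b_fast = _trace_a0_fast(sys_aniso, freqs)
        b_robust = trace_a0(sys_aniso, freqs)
        common = np.intersect1d(b_fast.freqs, b_robust.freqs)
        v_f = 2 * np.pi * common / b_fast.k_at(common)
        v_r = 2 * np.pi * common / b_robust.k_at(common)
        assert np.max(np.abs(v_f / v_r - 1)) < 1e-3


class TestDispersionBranch:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DispersionBranch("A0", np.array([1.0, 1.0]), np.array([2.0, 3.0]))
        with pytest.raises(ValueError):
            DispersionBranch("A0", np.array([1.0, 2.0]), np.array([-2.0, 3.0]))

    def test_unit_accessors(self):
        br = DispersionBranch("A0", np.array([1000.0, 2000.0]), np.array([2000.0, 3000.0]))
        assert np.allclose(br.k_cycles * 2 * np.pi, br.wavenumbers)
        assert br.phase_velocity[0] == pytest.approx(2 * np.pi * 1000.0 / 2000.0)
        assert br.velocity_at(1500.0) == pytest.approx(2 * np.pi * 1500.0 / 2500.0)
        with pytest.raises(ValueError):
            br.velocity_at(5000.0)
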