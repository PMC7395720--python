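"""Guided-wave dispersion for a NITI layer bounded by air and water.

The layer (thickness ``h``, symmetry axis normal to its faces) is
traction-free on top — air loading is negligible for soft tissue — and
loaded below by an inviscid fluid half-space (water).  Harmonic plane-wave
solutions in the layer are superpositions of four partial waves whose
vertical slowness ratios q solve a biquadratic; a single downgoing acoustic
wave lives in the fluid.  The five boundary conditions (zero traction on
top; zero shear traction, normal-stress/pressure balance and vertical
displacement continuity at the bottom) give a 5×5 determinant whose zeros
on the real (f, k) plane are the guided modes.  Water-loaded modes are
weakly leaky; roots are sought on the real-k axis as minima of the
normalized |determinant|, which matches how spectral ridges are fit.

Mode labels: the branch with the lowest low-frequency phase velocity is
A0 (quasi-antisymmetric, flexural), the next S0.  The asymmetric loading
makes the modes only quasi-(anti)symmetric, so labeling is by velocity
ordering rather than by polarization symmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .materials import NITIMaterial, make_material

__all__ = [
    "LayerSystem",
    "DispersionBranch",
    "TracingError",
    "secular_determinant",
    "trace_modes",
    "trace_a0",
    "a0_high_freq_asymptote",
    "isotropic_dispersion",
]

#: acceptance threshold on the normalized determinant at a stored root
ROOT_TOL = 1e-6
#: default fluid (water) properties
WATER_RHO = 1000.0
WATER_C = 1480.0


@dataclass(frozen=True)
class LayerSystem:
    """A NITI layer of thickness ``h`` over a fluid half-space.

    Parameters
    ----------
    material : NITIMaterial
        Layer constitutive parameters.
    h : float
        Layer thickness, m.
    rho_f : float
        Bounding-fluid density, kg/m³ (0 is allowed and means a free plate).
    c_f : float
        Bounding-fluid sound speed, m/s.
    """

    material: NITIMaterial
    h: float
    rho_f: float = WATER_RHO
    c_f: float = WATER_C

    def __post_init__(self) -> None:
        if not np.isfinite(self.h) or self.h <= 0:
            raise ValueError(f"h must be positive, got {self.h!r}")
        if self.rho_f < 0 or self.c_f <= 0:
            raise ValueError("fluid density must be >= 0 and sound speed > 0")


@dataclass(frozen=True)
class DispersionBranch:
    """A labeled guided mode as paired (frequency, wavenumber) samples."""

    label: str
    freqs: np.ndarray  # Hz, strictly increasing
    wavenumbers: np.ndarray  # rad/m
    residuals: np.ndarray = field(default=None)  # |det| at each sample

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        k = np.asarray(self.wavenumbers, dtype=float)
        if f.ndim != 1 or f.shape != k.shape:
            raise ValueError("freqs and wavenumbers must be 1-D and equal length")
        if len(f) and np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(k <= 0):
            raise ValueError("wavenumbers must be positive")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "wavenumbers", k)
        if self.residuals is None:
            object.__setattr__(self, "residuals", np.full_like(f, np.nan))

    @property
    def phase_velocity(self) -> np.ndarray:
        """Phase velocity ω/k at each sample, m/s."""
        return 2 * np.pi * self.freqs / self.wavenumbers

    @property
    def k_cycles(self) -> np.ndarray:
        """Wavenumbers in cycles/m."""
        return self.wavenumbers / (2 * np.pi)

    def k_at(self, f: np.ndarray) -> np.ndarray:
        """Interpolate k(f) in rad/m; NaN outside the branch's range."""
        f = np.asarray(f, dtype=float)
        return np.interp(f, self.freqs, self.wavenumbers, left=np.nan, right=np.nan)

    def velocity_at(self, f: float) -> float:
        """Interpolated phase velocity at frequency ``f``."""
        k = float(self.k_at(np.array([f]))[0])
        if np.isnan(k):
            raise ValueError(f"{f} Hz is outside branch {self.label} range")
        return 2 * np.pi * f / k


class TracingError(RuntimeError):
    """Mode tracing failed; partial results are attached as ``branches``."""

    def __init__(self, msg: str, branches: list[DispersionBranch]):
        super().__init__(msg)
        self.branches = branches


def _layer_matrix(sys: LayerSystem, f: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Stacked, row-normalized 5×5 boundary-condition matrices.

    ``f`` and ``k`` are broadcastable 1-D arrays; returns (N, 5, 5) complex.
    Exponential terms are referenced to the surface from which each partial
    wave decays, so all entries stay bounded at large kh; this rescales
    columns, which changes the determinant only by a nonzero factor.
    """
    m = sys.material
    lam, mu, G, rho = m.lam, m.mu, m.G, m.rho
    alpha, beta, gamma = lam + 2 * mu, G, lam + G
    f = np.atleast_1d(np.asarray(f, dtype=float))
    k = np.atleast_1d(np.asarray(k, dtype=float))
    f, k = np.broadcast_arrays(f, k)
    omega = 2 * np.pi * f
    c = omega / k
    X = rho * c * c

    a = alpha * beta
    b = alpha**2 + beta**2 - X * (alpha + beta) - gamma**2
    cq = (alpha - X) * (beta - X)
    disc = np.sqrt((b * b - 4 * a * cq).astype(complex))
    q2 = np.stack([(-b + disc) / (2 * a), (-b - disc) / (2 * a)], axis=-1)
    qp = np.sqrt(q2)
    qp = np.where(qp.imag < 0, -qp, qp)
    # four layer partial waves: +/-q1, +/-q2
    q = np.concatenate([qp, -qp], axis=-1)  # (N, 4)
    q2f = np.concatenate([q2, q2], axis=-1)

    Xc = X[..., None]
    Szz = q * (lam * (G - 4 * mu) - 4 * mu**2 - alpha * beta * q2f + alpha * Xc)
    Sxz = lam * (q2f - 1) - 2 * mu + Xc
    W = -(alpha + beta * q2f - Xc)

    phase = 1j * k[..., None] * q * sys.h
    decay_down = q.imag >= 0
    # E at z=0 and z=h with per-column referencing (|E| <= 1 everywhere);
    # the exponent is flipped before exp so its real part is never positive
    damp = np.exp(np.where(decay_down, phase, -phase))
    E0 = np.where(decay_down, 1.0 + 0j, damp)
    Eh = np.where(decay_down, damp, 1.0 + 0j)

    c2 = (c * c)[..., None]
    qf = np.sqrt((c * c / sys.c_f**2 - 1).astype(complex))[..., None]
    qf = np.where(qf.imag < 0, -qf, qf)

    N = f.shape
    M = np.zeros(N + (5, 5), dtype=complex)
    M[..., 0, :4] = Szz * E0
    M[..., 1, :4] = Sxz * E0
    M[..., 2, :4] = Sxz * Eh
    M[..., 3, :4] = Szz * Eh
    M[..., 4, :4] = W * Eh
    M[..., 3, 4] = (-sys.rho_f * c2)[..., 0]
    M[..., 4, 4] = -qf[..., 0]
    # scale rows to unit max modulus -> dimensionless O(1) determinant
    scale = np.max(np.abs(M), axis=-1, keepdims=True)
    scale = np.where(scale == 0, 1.0, scale)
    return M / scale


def secular_determinant(sys: LayerSystem, f, k):
    """Normalized secular determinant of the air/NITI-layer/water system.

    Accepts scalars or broadcastable arrays of frequency (Hz) and
    wavenumber (rad/m); returns complex determinant(s) of the 5×5
    row-normalized boundary-condition matrix.  Near a degenerate
    biquadratic (coincident partial-wave roots) the point is re-evaluated
    with k perturbed by 1 ppm.
    """
    scalar = np.isscalar(f) and np.isscalar(k)
    fa = np.atleast_1d(np.asarray(f, dtype=float))
    ka = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(fa <= 0) or np.any(ka <= 0):
        raise ValueError("f and k must be positive")
    M = _layer_matrix(sys, fa, ka)
    det = np.linalg.det(M)
    bad = ~np.isfinite(det)
    if np.any(bad):
        det = np.where(
            bad, np.linalg.det(_layer_matrix(sys, fa, ka * (1 + 1e-6))), det
        )
    return complex(det[0]) if scalar and det.size == 1 else det


def _abs_det_velocity(sys: LayerSystem, f: float, v: np.ndarray) -> np.ndarray:
    """|secular determinant| along a phase-velocity grid at fixed frequency."""
    k = 2 * np.pi * f / np.asarray(v, dtype=float)
    return np.abs(secular_determinant(sys, np.full_like(k, f), k))


def _is_degenerate(sys: LayerSystem, f: float, v: float, tol: float = 1e-6) -> bool:
    """True where the partial-wave biquadratic is (near-)degenerate.

    At isolated (f, k) points two of the four layer columns coincide —
    one pair's q² vanishes (a bulk-speed branch point, e.g. c = sqrt(G/ρ))
    or the two q² roots merge — and the determinant vanishes without a
    guided mode existing there.
    """
    m = sys.material
    alpha, beta, gamma = m.lam + 2 * m.mu, m.G, m.lam + m.G
    X = m.rho * v * v
    a = alpha * beta
    b = alpha**2 + beta**2 - X * (alpha + beta) - gamma**2
    c = (alpha - X) * (beta - X)
    disc = np.sqrt(complex(b * b - 4 * a * c))
    q2 = np.array([(-b + disc) / (2 * a), (-b - disc) / (2 * a)])
    scale = max(1.0, float(np.max(np.abs(q2))))
    return bool(
        np.min(np.abs(q2)) < tol * scale or abs(q2[0] - q2[1]) < tol * scale
    )


def _roots_at_frequency(
    sys: LayerSystem,
    f: float,
    v_min: float,
    v_max: float,
    n_scan: int = 800,
    tol: float = ROOT_TOL,
    rel_tol: float = 1e-4,
) -> list[tuple[float, float]]:
    """Phase velocities of all |det| roots at one frequency.

    Scans a log-spaced velocity grid and refines every local minimum by
    bounded golden-section search.  A minimum counts as a root only if the
    refined |det| is below ``tol`` absolutely *and* at least ``rel_tol``
    times smaller than the nearby scan background — at large λ/μ the
    determinant's background magnitude is itself small (near-parallel
    λ-dominated rows), so an absolute threshold alone admits spurious dips.
    Degenerate-quartic points are rejected outright.
    """
    v = np.geomspace(v_min, v_max, n_scan)
    d = _abs_det_velocity(sys, f, v)
    interior = np.nonzero((d[1:-1] < d[:-2]) & (d[1:-1] < d[2:]))[0] + 1
    roots = []
    for i in interior:
        lo, hi = max(0, i - 10), min(len(d), i + 11)
        background = float(np.median(d[lo:hi]))
        res = minimize_scalar(
            lambda vv: _abs_det_velocity(sys, f, np.array([vv]))[0],
            bounds=(v[i - 1], v[i + 1]),
            method="bounded",
            options={"xatol": 1e-9 * v[i]},
        )
        if res.fun < min(tol, rel_tol * background) and not _is_degenerate(
            sys, f, float(res.x)
        ):
            roots.append((float(res.x), float(res.fun)))
    # deduplicate near-coincident roots
    roots.sort()
    out: list[tuple[float, float]] = []
    for r, resid in roots:
        if not out or r / out[-1][0] > 1 + 1e-6:
            out.append((r, resid))
    return out


def _default_v_max(sys: LayerSystem) -> float:
    """Upper phase-velocity bound: just below the slower of the fluid sound
    speed and the layer quasi-longitudinal speed (faster roots are strongly
    leaky and outside the guided regime)."""
    return 0.999 * min(sys.c_f, sys.material.c_L)


def trace_modes(
    sys: LayerSystem,
    f_min: float = 200.0,
    f_max: float = 4000.0,
    n_freq: int = 32,
    max_modes: int = 4,
    v_min: float = 0.05,
    v_max: float | None = None,
    n_scan: int = 800,
) -> list[DispersionBranch]:
    """Trace guided-mode branches over a log-spaced frequency grid.

    Roots at successive frequencies are linked by nearest-phase-velocity
    continuation with linear extrapolation.  Branches are labeled 'A0'
    (lowest low-frequency phase velocity), 'S0', then 'H1', 'H2', ... in
    ascending velocity order.  Raises :class:`TracingError` (with partial
    results) if more than 25% of frequencies yield no root.
    """
    if not (0 < f_min < f_max):
        raise ValueError("require 0 < f_min < f_max")
    if n_freq < 16:
        raise ValueError("n_freq must be >= 16")
    if v_max is None:
        v_max = _default_v_max(sys)
    freqs = np.geomspace(f_min, f_max, n_freq)
    # each track: dict with lists f, v, resid
    tracks: list[dict] = []
    n_empty = 0
    for f in freqs:
        roots = _roots_at_frequency(sys, f, v_min, v_max, n_scan)
        if not roots:
            n_empty += 1
            continue
        # predict each live track's velocity at f
        preds = []
        for tr in tracks:
            fv, vv = tr["f"], tr["v"]
            if len(fv) >= 2:
                slope = (vv[-1] - vv[-2]) / (fv[-1] - fv[-2])
                preds.append(vv[-1] + slope * (f - fv[-1]))
            else:
                preds.append(vv[-1])
        used = set()
        for r, resid in roots:
            best, best_err = None, np.inf
            for j, p in enumerate(preds):
                if j in used or p <= 0:
                    continue
                err = abs(np.log(r / p))
                if err < best_err:
                    best, best_err = j, err
            if best is not None and best_err < np.log(1.35):
                tr = tracks[best]
                tr["f"].append(f)
                tr["v"].append(r)
                tr["resid"].append(resid)
                used.add(best)
            else:
                tracks.append({"f": [f], "v": [r], "resid": [resid]})
    # keep substantial tracks, ordered by low-frequency phase velocity
    tracks = [t for t in tracks if len(t["f"]) >= max(3, n_freq // 8)]
    tracks.sort(key=lambda t: (t["f"][0], t["v"][0]))
    tracks.sort(key=lambda t: t["v"][0] if t["f"][0] <= freqs[len(freqs) // 4] else np.inf)
    tracks = tracks[:max_modes]
    labels = ["A0", "S0"] + [f"H{i}" for i in range(1, max(1, len(tracks) - 1))]
    branches = []
    for label, tr in zip(labels, tracks):
        farr = np.array(tr["f"])
        varr = np.array(tr["v"])
        branches.append(
            DispersionBranch(
                label=label,
                freqs=farr,
                wavenumbers=2 * np.pi * farr / varr,
                residuals=np.array(tr["resid"]),
            )
        )
    if n_empty > 0.25 * n_freq:
        raise TracingError(
            f"no guided-mode root found at {n_empty}/{n_freq} frequencies",
            branches,
        )
    if not branches:
        raise TracingError("no branch persisted across the frequency grid", [])
    return branches


def trace_a0(
    sys: LayerSystem,
    freqs: np.ndarray,
    v_min: float = 0.05,
    n_scan: int = 400,
) -> DispersionBranch:
    """Trace only the A0 (slowest) branch by low-to-high continuation.

    Much faster than :func:`trace_modes` for inversion loops: the velocity
    scan is capped near sqrt(G/ρ), which bounds the A0 phase velocity, and
    at each frequency the root nearest the extrapolated previous velocity
    is kept (starting from the slowest root at the lowest frequency, where
    A0 is unambiguous).
    """
    freqs = np.sort(np.asarray(freqs, dtype=float))
    v_cap = min(1.25 * sys.material.c_G, _default_v_max(sys))
    fs, vs, rs = [], [], []
    for f in freqs:
        roots = _roots_at_frequency(sys, f, v_min, v_cap, n_scan)
        if not roots:
            continue
        if len(fs) >= 2:
            slope = (vs[-1] - vs[-2]) / (fs[-1] - fs[-2])
            pred = vs[-1] + slope * (f - fs[-1])
        elif fs:
            pred = vs[-1]
        else:
            pred = None
        if pred is None:
            r, resid = roots[0]  # slowest root at the lowest frequency
        else:
            r, resid = min(roots, key=lambda t: abs(t[0] - pred))
        fs.append(f)
        vs.append(r)
        rs.append(resid)
    if len(fs) < max(2, len(freqs) // 2):
        raise TracingError(
            f"A0 root found at only {len(fs)}/{len(freqs)} frequencies", []
        )
    fs = np.array(fs)
    return DispersionBranch(
        label="A0",
        freqs=fs,
        wavenumbers=2 * np.pi * fs / np.array(vs),
        residuals=np.array(rs),
    )


def _trace_a0_fast(
    sys: LayerSystem,
    freqs: np.ndarray,
    v_min: float = 0.05,
    v_cap_frac: float = 0.995,
    n_stage: tuple[int, int, int] = (240, 21, 21),
) -> DispersionBranch:
    """Batched A0 tracer for inversion loops.

    Within (0, ~sqrt(G/ρ)) the A0 branch is the only guided root (S0 and
    higher modes are faster; the c = sqrt(G/ρ) branch point is excluded by
    the cap), so per frequency the deepest interior |det| minimum of a
    coarse scan is the A0 root, refined by two batched local grid stages.
    Accuracy ~2e-4 relative in phase velocity — far below a spectral bin —
    at a few batched determinant evaluations per frequency.
    """
    freqs = np.sort(np.asarray(freqs, dtype=float))
    v_max = min(v_cap_frac * sys.material.c_G, _default_v_max(sys))
    nf = freqs.size
    v = np.broadcast_to(np.geomspace(v_min, v_max, n_stage[0]), (nf, n_stage[0]))
    fcol = freqs[:, None]

    def absdet(vgrid):
        k = 2 * np.pi * fcol / vgrid
        return np.abs(secular_determinant(sys, np.broadcast_to(fcol, k.shape), k))

    d = absdet(v)
    interior = (d[:, 1:-1] < d[:, :-2]) & (d[:, 1:-1] < d[:, 2:])
    dmask = np.where(interior, d[:, 1:-1], np.inf)
    idx = np.argmin(dmask, axis=1) + 1
    found = np.isfinite(dmask[np.arange(nf), idx - 1])
    lo = v[np.arange(nf), np.maximum(idx - 1, 0)]
    hi = v[np.arange(nf), np.minimum(idx + 1, n_stage[0] - 1)]
    for n in n_stage[1:]:
        v = lo[:, None] + (hi - lo)[:, None] * np.linspace(0, 1, n)[None, :]
        d = absdet(v)
        idx = np.argmin(d, axis=1)
        lo = v[np.arange(nf), np.maximum(idx - 1, 0)]
        hi = v[np.arange(nf), np.minimum(idx + 1, n - 1)]
    v_root = 0.5 * (lo + hi)
    resid = d[np.arange(nf), idx]
    keep = found & (resid < ROOT_TOL)
    if keep.sum() < max(2, nf // 2):
        raise TracingError(
            f"A0 root found at only {int(keep.sum())}/{nf} frequencies", []
        )
    fs = freqs[keep]
    return DispersionBranch(
        label="A0",
        freqs=fs,
        wavenumbers=2 * np.pi * fs / v_root[keep],
        residuals=resid[keep],
    )


def a0_high_freq_asymptote(sys: LayerSystem, f_eval: float = 4000.0) -> float:
    """A0 phase velocity at ``f_eval``, the high-frequency (Rayleigh-like)
    asymptote governed primarily by G.

    Requires f_eval·h ≳ 0.3·sqrt(G/ρ), i.e. the layer at least a third of
    a wavelength thick, so the mode is approaching its plateau.  (Full
    convergence to the Scholte-bounded limit needs f·h several times
    sqrt(G/ρ); at OCE-like bands the returned value is the practical
    high-frequency velocity rather than the infinite-frequency limit.)
    """
    if f_eval * sys.h < 0.3 * sys.material.c_G:
        raise ValueError(
            "f_eval*h too small for the short-wavelength regime; need "
            f"f_eval >= {0.3 * sys.material.c_G / sys.h:.0f} Hz"
        )
    freqs = np.geomspace(f_eval / 8, f_eval, 12)
    branch = trace_a0(sys, freqs)
    return branch.velocity_at(f_eval)


def isotropic_dispersion(
    mu: float,
    h: float,
    rho: float = 1000.0,
    cL: float = 1540.0,
    rho_f: float = WATER_RHO,
    c_f: float = WATER_C,
    f_min: float = 200.0,
    f_max: float = 4000.0,
    n_freq: int = 32,
    **kwargs,
) -> list[DispersionBranch]:
    """Dispersion branches of the isotropic layer: the nested G = μ case."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mat = make_material(mu=mu, G=mu, rho=rho, cL=cL)
    sys = LayerSystem(material=mat, h=h, rho_f=rho_f, c_f=c_f)
    return trace_modes(sys, f_min=f_min, f_max=f_max, n_freq=n_freq, **kwargs)
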