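"""Constitutive model for nearly-incompressible transversely isotropic (NITI) media.

A NITI material models soft layered tissue (e.g. corneal stroma) whose
microstructure — stacked collagen lamellae lying in the x–y plane — makes the
in-plane tensile/shear response (governed by ``mu``) independent of the
out-of-plane shear response (governed by ``G``).  The symmetry axis is z; the
x–y plane is the isotropy plane.  The first Lamé-like constant ``lam``
enforces near-incompressibility (lam >> mu) and is conventionally derived
from a fixed longitudinal wave speed rather than fitted.

In Voigt notation (11, 22, 33, 23, 13, 12) the stiffness matrix is::

    [ lam+2mu   lam      lam                      ]
    [ lam       lam+2mu  lam                      ]
    [ lam       lam      lam+2mu                  ]
    [                             G               ]
    [                                  G          ]
    [                                       mu    ]

so the longitudinal 3x3 block is formally isotropic (weak longitudinal
anisotropy) while the shear diagonal carries the two independent moduli.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "NITIMaterial",
    "BulkSpeeds",
    "ConvergenceError",
    "make_material",
    "stiffness_matrix",
    "bulk_speeds",
    "young_modulus",
    "rayleigh_speed",
]

#: lam/mu ratio below which the nearly-incompressible premise is questionable
NEARLY_INCOMPRESSIBLE_RATIO = 100.0


class ConvergenceError(RuntimeError):
    """A root search failed to bracket or refine a solution."""


@dataclass(frozen=True)
class NITIMaterial:
    """NITI constitutive parameters.

    Parameters
    ----------
    lam : float
        First Lamé-like constant λ in Pa; enforces near-incompressibility.
    mu : float
        In-plane shear modulus μ in Pa; sets the tensile response E = 3μ.
    G : float
        Out-of-plane shear modulus in Pa; sets surface/guided wave speeds.
    rho : float
        Mass density in kg/m³.
    """

    lam: float
    mu: float
    G: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("lam", "mu", "G", "rho"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if 3 * self.lam + 2 * self.mu <= 0:
            raise ValueError("longitudinal stiffness block is not positive definite")
        if self.lam / self.mu < NEARLY_INCOMPRESSIBLE_RATIO:
            warnings.warn(
                f"lam/mu = {self.lam / self.mu:.3g} < {NEARLY_INCOMPRESSIBLE_RATIO:g}: "
                "outside the nearly-incompressible regime the model targets",
                stacklevel=3,
            )
        if self.G > self.mu:
            warnings.warn(
                "G > mu: valid mathematically, but layered soft tissue is "
                "expected to have G <= mu",
                stacklevel=3,
            )

    @property
    def c_L(self) -> float:
        """Longitudinal wave speed sqrt((λ+2μ)/ρ) in m/s."""
        return float(np.sqrt((self.lam + 2 * self.mu) / self.rho))

    @property
    def c_G(self) -> float:
        """Out-of-plane shear speed sqrt(G/ρ) in m/s."""
        return float(np.sqrt(self.G / self.rho))


@dataclass(frozen=True)
class BulkSpeeds:
    """Bulk plane-wave speeds at propagation angle ``theta`` from the z axis."""

    c_qL: float
    c_qSV: float
    c_SH: float
    theta: float


def make_material(mu: float, G: float, rho: float, cL: float = 1540.0) -> NITIMaterial:
    """Build a NITI material with λ derived from the longitudinal speed.

    λ = ρ·cL² − 2μ, so the quasi-longitudinal speed matches ``cL`` exactly
    along the symmetry axis.  ``cL`` defaults to the soft-tissue value
    1540 m/s; λ is never treated as a free parameter elsewhere in the
    package.
    """
    for name, v in (("mu", mu), ("G", G), ("rho", rho), ("cL", cL)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite, got {v!r}")
    lam = rho * cL**2 - 2 * mu
    if lam <= 0:
        raise ValueError(
            f"rho*cL^2 = {rho * cL**2:.4g} Pa must exceed 2*mu = {2 * mu:.4g} Pa"
        )
    return NITIMaterial(lam=lam, mu=mu, G=G, rho=rho)


def stiffness_matrix(m: NITIMaterial) -> np.ndarray:
    """6×6 Voigt stiffness matrix (order 11, 22, 33, 23, 13, 12), in Pa."""
    C = np.zeros((6, 6))
    C[:3, :3] = m.lam
    C[0, 0] = C[1, 1] = C[2, 2] = m.lam + 2 * m.mu
    C[3, 3] = C[4, 4] = m.G
    C[5, 5] = m.mu
    return C


def bulk_speeds(m: NITIMaterial, theta: float) -> BulkSpeeds:
    """Christoffel bulk wave speeds for propagation at angle ``theta``.

    ``theta`` is measured from the symmetry (z) axis, in radians, and must
    lie in [0, π/2].  Returns the quasi-longitudinal, quasi-shear (sagittal
    polarization) and pure shear-horizontal speeds.  On the symmetry axis
    the two shear branches are degenerate at sqrt(G/ρ).
    """
    if not 0.0 <= theta <= np.pi / 2 + 1e-12:
        raise ValueError(f"theta must lie in [0, pi/2], got {theta!r}")
    s, c = np.sin(theta), np.cos(theta)
    lam, mu, G, rho = m.lam, m.mu, m.G, m.rho
    c11 = c33 = lam + 2 * mu
    c13 = lam
    # sagittal 2x2 Christoffel matrix for direction (sin, 0, cos)
    g11 = c11 * s**2 + G * c**2
    g33 = G * s**2 + c33 * c**2
    g13 = (c13 + G) * s * c
    half = 0.5 * (g11 + g33)
    rad = np.sqrt((0.5 * (g11 - g33)) ** 2 + g13**2)
    c_qL = np.sqrt((half + rad) / rho)
    c_qSV = np.sqrt((half - rad) / rho)
    c_SH = np.sqrt((mu * s**2 + G * c**2) / rho)
    return BulkSpeeds(c_qL=float(c_qL), c_qSV=float(c_qSV), c_SH=float(c_SH), theta=float(theta))


def young_modulus(m: NITIMaterial) -> float:
    """In-plane tensile Young's modulus from compliance inversion.

    Computed as 1/S₁₁ with S = C⁻¹; independent of G (the shear block is
    decoupled) and converging to 3μ as λ/μ → ∞, the incompressible limit.
    """
    C = stiffness_matrix(m)
    try:
        S = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by invariants
        raise RuntimeError(f"stiffness matrix is singular: {exc}") from exc
    return float(1.0 / S[0, 0])


def _sagittal_q_squared(alpha: float, beta: float, gamma: float, X: float) -> np.ndarray:
    """Roots q² of the partial-wave quartic for in-plane sagittal motion.

    For a plane wave exp(ik(x + q z − c t)) in the NITI medium, inserting
    the displacement ansatz into the elastodynamic equations gives a
    biquadratic in the vertical slowness ratio q::

        αβ q⁴ + (α² + β² − X(α+β) − γ²) q² + (α − X)(β − X) = 0

    with α = λ+2μ, β = G, γ = λ+G and X = ρc².
    """
    a = alpha * beta
    b = alpha**2 + beta**2 - X * (alpha + beta) - gamma**2
    c = (alpha - X) * (beta - X)
    disc = np.sqrt(complex(b * b - 4 * a * c))
    return np.array([(-b + disc) / (2 * a), (-b - disc) / (2 * a)], dtype=complex)


def _rayleigh_secular(m: NITIMaterial, c: float) -> complex:
    """Free-surface secular determinant for the NITI half-space, normalized.

    Two downward-decaying partial waves (Im q > 0) must jointly satisfy
    σ_zz = σ_xz = 0 on the surface; the 2×2 determinant of the stress rows
    vanishes at the Rayleigh speed.  Each partial wave's amplitude vector is
    taken as (U, W) = (γq, −(α + βq² − X)), which avoids dividing by q; the
    stress rows then reduce exactly (the O(λ²) terms cancel algebraically,
    which matters at λ/μ ≫ 1) to::

        σ_zz:  q·[λ(G − 4μ) − 4μ² − αβ q² + αX]
        σ_xz:  λ(q² − 1) − 2μ + X

    For subsonic speeds in the G ≤ μ regime both q² are real and negative,
    so the determinant is purely imaginary; its imaginary part serves as a
    real secular function with a sign change at the root.
    """
    lam, mu, G = m.lam, m.mu, m.G
    alpha, beta, gamma = lam + 2 * mu, G, lam + G
    X = m.rho * c * c
    q2 = _sagittal_q_squared(alpha, beta, gamma, X)
    q = np.sqrt(q2)
    q = np.where(q.imag < 0, -q, q)  # decay into the half-space
    row_zz = q * (lam * (G - 4 * mu) - 4 * mu**2 - alpha * beta * q2 + alpha * X)
    row_xz = lam * (q2 - 1) - 2 * mu + X
    det = row_zz[0] * row_xz[1] - row_zz[1] * row_xz[0]
    scale = max(np.max(np.abs(row_zz)), 1e-300) * max(np.max(np.abs(row_xz)), 1e-300)
    return det / scale


def rayleigh_speed(m: NITIMaterial, n_grid: int = 2000, rtol: float = 1e-9) -> float:
    """Surface (Rayleigh) wave speed on a traction-free NITI half-space, m/s.

    In-plane propagation; the root is subsonic relative to the
    vertically-polarized shear speed sqrt(G/ρ).  The secular function is
    evaluated on a dense speed grid, sign changes are bracketed and refined
    by bisection.  The ratio c_R/sqrt(G/ρ) runs from 0.9553 in the
    isotropic limit (G = μ) to 1 in the highly anisotropic limit (μ ≫ G).
    """
    c_bound = m.c_G
    # linear sweep plus a geometric tail toward the bound: at high mu/G the
    # root sits within 1e-7 of sqrt(G/rho)
    n_tail = n_grid // 4
    grid = np.concatenate(
        [
            np.linspace(1e-4 * c_bound, 0.99 * c_bound, n_grid - n_tail),
            c_bound * (1.0 - np.logspace(-2, -13, n_tail)),
        ]
    )
    vals = np.array([_rayleigh_secular(m, c).imag for c in grid])
    roots = []
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in idx:
        root = brentq(
            lambda c: _rayleigh_secular(m, c).imag,
            grid[i],
            grid[i + 1],
            xtol=rtol * c_bound,
            rtol=max(rtol, 1e-15),
        )
        roots.append(root)
    if not roots:
        # fall back to |det| minima (covers the G > mu complex-root regime)
        mags = np.array([abs(_rayleigh_secular(m, c)) for c in grid])
        k = int(np.argmin(mags))
        if not (0 < k < n_grid - 1) or mags[k] > 1e-4:
            raise ConvergenceError(
                "no Rayleigh root bracketed below the bulk shear speed"
            )
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda c: abs(_rayleigh_secular(m, c)),
            bounds=(grid[k - 1], grid[k + 1]),
            method="bounded",
            options={"xatol": rtol * c_bound},
        )
        roots.append(res.x)
    return float(max(roots))  # the Rayleigh root is the fastest subsonic root
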