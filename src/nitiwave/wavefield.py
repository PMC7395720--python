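"""Forward generation of surface wavefields for a NITI layer over water.

Two generators are provided:

* :func:`simulate_fd` — a 2D plane-strain, time-domain, staggered-grid
  velocity–stress finite-difference solver.  The layer follows the NITI
  constitutive law; the bounding water is modeled, as is standard for
  explicit elastic solvers, as an isotropic "solid" with zero shear
  modulus.  The push mimics an acoustic micro-tapping (AμT) excitation: a
  normal surface stress with a Gaussian profile in space and a
  super-Gaussian profile in time.

* :func:`synthesize_modal` — a fast spectral synthesizer that places
  energy exactly on prescribed dispersion branches.  It is the package's
  controlled test-fixture generator: unlike the FD solver it has no
  near-field, no grid dispersion and a known modal content.

The default space–time sampling mirrors an OCE scan: 512 time samples at
46.5 kHz and 256 lateral positions at dx = 54.7 μm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .dispersion import DispersionBranch, LayerSystem
from .fields import XTField

__all__ = ["SourceProfile", "simulate_fd", "synthesize_modal", "OCE_T_GRID", "OCE_X_GRID"]

#: default OCE-like sampling grids
OCE_T_GRID = np.arange(512) / 46500.0
OCE_X_GRID = np.arange(256) * 54.7e-6


@dataclass(frozen=True)
class SourceProfile:
    """AμT-like surface push: Gaussian in space, super-Gaussian in time.

    Defaults follow the acoustic micro-tapping geometry: 600 μm spatial
    FWHM and 100 μs temporal FWHM, producing mechanical bandwidths up to
    about 4 kHz in soft tissue.  ``peak_pressure`` sets an arbitrary
    amplitude scale (the problem is linear).
    """

    spatial_fwhm: float = 600e-6
    temporal_fwhm: float = 100e-6
    super_gaussian_order: int = 4
    peak_pressure: float = 1.0

    def __post_init__(self) -> None:
        if self.spatial_fwhm <= 0 or self.temporal_fwhm <= 0:
            raise ValueError("FWHMs must be positive")
        n = self.super_gaussian_order
        if n < 2 or n % 2:
            raise ValueError(f"super_gaussian_order must be even and >= 2, got {n}")

    def time_profile(self, t: np.ndarray, t0: float | None = None) -> np.ndarray:
        """Super-Gaussian pulse centered at ``t0`` (default 2 FWHM)."""
        if t0 is None:
            t0 = 2 * self.temporal_fwhm
        arg = 2 * (np.asarray(t, dtype=float) - t0) / self.temporal_fwhm
        return self.peak_pressure * np.exp(-np.log(2) * arg**self.super_gaussian_order)

    def space_profile(self, x: np.ndarray, x0: float) -> np.ndarray:
        """Gaussian lateral footprint centered at ``x0``."""
        arg = (np.asarray(x, dtype=float) - x0) / self.spatial_fwhm
        return np.exp(-4 * np.log(2) * arg**2)

    def spatial_k_response(self, k: np.ndarray) -> np.ndarray:
        """Magnitude response of the spatial Gaussian at wavenumber k (rad/m)."""
        sigma = self.spatial_fwhm / (2 * np.sqrt(2 * np.log(2)))
        return np.exp(-0.5 * (np.asarray(k, dtype=float) * sigma) ** 2)


def _sponge_taper(pos: np.ndarray, n_edge: float, width: int,
                  strength: float = 0.30, both: bool = True) -> np.ndarray:
    """Cerjan-style damping multipliers evaluated at arbitrary positions.

    ``pos`` are node positions in cell units (integers or half-integers —
    the staggered fields must each be damped at their own locations or the
    sponge becomes asymmetric by half a cell).  ``n_edge`` is the last
    position of the grid; damping ramps over ``width`` cells from each
    included edge.
    """
    d = np.minimum(pos, n_edge - pos) if both else pos
    arg = strength * np.maximum(width - d, 0.0) / width * 3.0
    return np.exp(-(arg**2))


@njit(cache=True)
def _fd_loop(
    txx, tzz, txz, vx, vz, C11, C13, C33, C55h, rho_inv, gxi, gxh, gzi, gzh,
    dtx, src_space, src_time, out_idx, rec
):  # pragma: no cover - exercised through simulate_fd
    """Explicit leapfrog velocity-stress update loop (staggered grid).

    Node layout (cell j, i): txx/tzz at (j, i); txz at (j+1/2, i+1/2);
    vx at (j, i+1/2); vz at (j+1/2, i).  The traction-free top surface
    lives on the tzz row j = 0, where the source's normal stress is
    imposed, with the antisymmetric image txz(-1/2) = -txz(+1/2).
    Returns -1 on success, or the step index where an instability (NaN)
    was first detected.
    """
    nz, nx = txx.shape
    nt = src_time.size
    j_out = 0
    for it in range(nt):
        # vx update: needs d(txx)/dx at (j, i+1/2) and d(txz)/dz
        for j in range(nz):
            ri = rho_inv[j] * dtx
            for i in range(nx - 1):
                if j == 0:
                    dtxz = 2.0 * txz[0, i]
                else:
                    dtxz = txz[j, i] - txz[j - 1, i]
                vx[j, i] += ri * (txx[j, i + 1] - txx[j, i] + dtxz)
        # vz update at (j+1/2, i)
        for j in range(nz - 1):
            ri = 0.5 * (rho_inv[j] + rho_inv[j + 1]) * dtx
            for i in range(nx):
                if i == 0:
                    dtxz = txz[j, 0]
                else:
                    dtxz = txz[j, i] - txz[j, i - 1]
                vz[j, i] += ri * (dtxz + tzz[j + 1, i] - tzz[j, i])
        # normal stresses; the surface row (j = 0) eliminates dvz/dz via the
        # traction condition sigma_zz = 0 => dvz/dz = -(C13/C33) dvx/dx
        a11s = (C11[0] - C13[0] * C13[0] / C33[0]) * dtx
        for i in range(nx):
            dvx = vx[0, i] - vx[0, i - 1] if i > 0 else vx[0, 0]
            txx[0, i] += a11s * dvx
        for j in range(1, nz):
            a11 = C11[j] * dtx
            a13 = C13[j] * dtx
            a33 = C33[j] * dtx
            for i in range(nx):
                dvx = vx[j, i] - vx[j, i - 1] if i > 0 else vx[j, 0]
                dvz = vz[j, i] - vz[j - 1, i]
                txx[j, i] += a11 * dvx + a13 * dvz
                tzz[j, i] += a13 * dvx + a33 * dvz
        # shear stress at (j+1/2, i+1/2); the last column (outside the
        # rightmost vz node) stays zero, mirroring the left edge convention
        for j in range(nz - 1):
            a55 = C55h[j] * dtx
            if a55 != 0.0:
                for i in range(nx - 1):
                    dvz = vz[j, i + 1] - vz[j, i]
                    txz[j, i] += a55 * (vx[j + 1, i] - vx[j, i] + dvz)
        # free surface: imposed normal stress (the surface push)
        for i in range(nx):
            tzz[0, i] = -src_time[it] * src_space[i]
        # absorbing strips; each field damped at its own stagger position
        if it % 2 == 0:
            for j in range(nz):
                dzi = gzi[j]
                dzh = gzh[j]
                for i in range(nx):
                    di = gxi[i]
                    dh = gxh[i]
                    if di != 1.0 or dh != 1.0 or dzi != 1.0 or dzh != 1.0:
                        txx[j, i] *= dzi * di
                        tzz[j, i] *= dzi * di
                        txz[j, i] *= dzh * dh
                        vx[j, i] *= dzi * dh
                        vz[j, i] *= dzh * di
        if j_out < out_idx.size and out_idx[j_out] == it:
            for i in range(nx):
                rec[j_out, i] = vz[0, i]
            j_out += 1
        if it % 500 == 0:
            probe = abs(vz[0, nx // 2]) + abs(vz[nz // 2, nx // 4])
            if not np.isfinite(probe) or probe > 1e20:
                return it
    return -1


def simulate_fd(
    sys: LayerSystem,
    src: SourceProfile | None = None,
    domain_length: float = 16e-3,
    fluid_depth: float | None = None,
    duration: float = 512 / 46500.0,
    points_per_wavelength: int = 40,
    cfl: float = 0.5,
    f_max: float = 4000.0,
    cL_numeric: float | None = 100.0,
    source_x: float | None = None,
    x_out: np.ndarray | None = None,
    t_out: np.ndarray | None = None,
) -> XTField:
    """Explicit staggered-grid simulation of the surface wavefield.

    Parameters
    ----------
    sys : LayerSystem
        Layer material/geometry and bounding fluid.
    src : SourceProfile
        Surface push applied as a normal stress on the traction-free top.
    domain_length, fluid_depth : float
        Physical extent, m; sponge strips are added outside.  Fluid depth
        defaults to 4 layer thicknesses.
    duration : float
        Simulated time, s.
    points_per_wavelength : int
        Cells per shortest guided wavelength (Scholte-bounded speed at
        ``f_max``); must be >= 20.
    cfl : float
        Fraction of the 2D stability limit, in (0, 0.9].
    cL_numeric : float or None
        Artificially reduced layer longitudinal speed used for the
        simulation stiffness (λ_sim = ρ·cL² − 2μ), keeping λ/μ >= 100.
        The explicit time step scales with the longitudinal speed while
        longitudinal terms barely affect the guided behavior, so a reduced
        value (default 100 m/s, auto-raised to preserve λ/μ >= 100) makes
        desk-scale runs feasible.  ``None`` uses the material's own λ.
    source_x : float or None
        Push center; default is the domain center.
    x_out, t_out : arrays or None
        Output grids; default: full interior at FD resolution in x, and
        times decimated to ~46.5 kHz.

    Returns
    -------
    XTField
        Surface vertical particle velocity on the output grids.
    """
    if src is None:
        src = SourceProfile()
    if points_per_wavelength < 20:
        raise ValueError("points_per_wavelength must be >= 20")
    if not 0 < cfl <= 0.9:
        raise ValueError("cfl must be in (0, 0.9]")
    m = sys.material
    if fluid_depth is None:
        fluid_depth = 4 * sys.h

    # simulation stiffness: optionally reduced longitudinal speed
    if cL_numeric is None:
        lam_sim = m.lam
    else:
        cl_floor = np.sqrt(102 * m.mu / m.rho)  # keeps lam_sim/mu >= 100
        cl = max(cL_numeric, float(cl_floor))
        lam_sim = m.rho * cl**2 - 2 * m.mu
    c11 = lam_sim + 2 * m.mu
    c13 = lam_sim
    c33 = lam_sim + 2 * m.mu
    c55 = m.G
    cL_sim = np.sqrt(c11 / m.rho)
    # fluid bulk modulus, sound speed matched to the (possibly reduced)
    # layer longitudinal speed so one CFL limit governs both media
    Kf = sys.rho_f * cL_sim**2 if sys.rho_f > 0 else 0.0

    # grid: shortest guided wavelength ~ Scholte-bounded speed / f_max
    c_min = 0.7 * m.c_G
    dx = c_min / f_max / points_per_wavelength
    dx = min(dx, sys.h / 8)  # resolve the layer thickness regardless
    n_sponge = max(20, int(round(0.2 * domain_length / dx)))
    nx_core = int(round(domain_length / dx)) + 1
    nx_core += (nx_core + 1) % 2  # odd core: a node sits exactly at center
    nx = nx_core + 2 * n_sponge
    nz_layer = int(round(sys.h / dx))
    nz_fluid = int(round(fluid_depth / dx))
    nz = nz_layer + nz_fluid + n_sponge
    x_grid = (np.arange(nx) - n_sponge) * dx

    dt = cfl * dx / (cL_sim * np.sqrt(2.0))
    nt = int(np.ceil(duration / dt)) + 1

    # depth-dependent moduli (z index 0 = surface)
    C11 = np.full(nz, c11)
    C13 = np.full(nz, c13)
    C33 = np.full(nz, c33)
    C55 = np.full(nz, c55)
    RHO = np.full(nz, m.rho)
    C11[nz_layer:] = Kf
    C13[nz_layer:] = Kf
    C33[nz_layer:] = Kf
    C55[nz_layer:] = 0.0
    RHO[nz_layer:] = max(sys.rho_f, 1e-3 * m.rho)
    # shear modulus at txz nodes (j+1/2): zero on/below the interface row
    C55h = np.minimum(C55, np.roll(C55, -1))
    C55h[-1] = 0.0

    # sponge multipliers at each staggered field's own x/z positions
    pos_x = np.arange(nx, dtype=float)
    pos_z = np.arange(nz, dtype=float)
    gxi = _sponge_taper(pos_x, nx - 1.0, n_sponge)
    gxh = _sponge_taper(pos_x + 0.5, nx - 1.0, n_sponge)
    gzi = _sponge_taper(nz - 1.0 - pos_z, 0.0, n_sponge, both=False)
    gzh = _sponge_taper(nz - 1.5 - pos_z, 0.0, n_sponge, both=False)

    txx = np.zeros((nz, nx))
    tzz = np.zeros((nz, nx))
    txz = np.zeros((nz, nx))  # node (j+1/2, i+1/2)
    vx = np.zeros((nz, nx))  # node (j, i+1/2)
    vz = np.zeros((nz, nx))  # node (j+1/2, i)

    if source_x is None:
        source_x = x_grid[n_sponge + (nx_core - 1) // 2]  # exact center node
    else:
        source_x = dx * round(source_x / dx)  # snap to a node (< dx/2 shift)
    src_space = src.space_profile(x_grid, source_x)
    t_steps = np.arange(nt) * dt
    src_time = src.time_profile(t_steps)

    if t_out is None:
        step_out = max(1, int(round((1 / 46500.0) / dt)))
        out_idx = np.arange(0, nt, step_out)
        t_out = t_steps[out_idx]
    else:
        t_out = np.asarray(t_out, dtype=float)
        if t_out[-1] > t_steps[-1] + dt:
            raise ValueError("t_out extends beyond the simulated duration")
        out_idx = np.clip(np.round(t_out / dt).astype(int), 0, nt - 1)
    if x_out is None:
        x_out = x_grid[n_sponge:-n_sponge]
    else:
        x_out = np.asarray(x_out, dtype=float)

    rec = np.zeros((len(out_idx), nx))
    step = _fd_loop(
        txx,
        tzz,
        txz,
        vx,
        vz,
        C11,
        C13,
        C33,
        C55h,
        1.0 / RHO,
        gxi,
        gxh,
        gzi,
        gzh,
        dt / dx,
        src_space,
        src_time,
        np.asarray(out_idx, dtype=np.int64),
        rec,
    )
    if step >= 0:
        raise FloatingPointError(f"instability detected at step {step}")

    # sample onto the requested lateral grid
    vz_out = np.empty((rec.shape[0], len(x_out)))
    for j in range(rec.shape[0]):
        vz_out[j] = np.interp(x_out, x_grid, rec[j])
    if not np.all(np.isfinite(vz_out)):
        raise FloatingPointError("non-finite samples in recorded field")
    return XTField(x=x_out, t=t_out, vz=vz_out)


def synthesize_modal(
    branches: list[DispersionBranch],
    src: SourceProfile | None = None,
    x: np.ndarray | None = None,
    t: np.ndarray | None = None,
    mode_amplitudes: np.ndarray | None = None,
    noise_rms: float = 0.0,
    seed: int | None = None,
    aperture_taper: float = 0.15,
) -> XTField:
    """Synthesize a surface wavefield with energy exactly on given branches.

    Each mode contributes Re Σ_ω a_m S(ω) exp(i(k_m(ω)x − ωt)), with S(ω)
    the spectrum of the source's temporal profile and the spatial
    footprint's wavenumber response evaluated on the branch.  A Tukey
    apodization over the outer ``aperture_taper`` fraction of the lateral
    aperture suppresses the sidelobes a hard truncation would smear across
    wavenumber (0 disables it).  Zero-mean Gaussian noise with RMS
    ``noise_rms`` × peak amplitude is added; the output is deterministic
    for a fixed ``seed``.
    """
    if not branches:
        raise ValueError("need at least one dispersion branch")
    if src is None:
        src = SourceProfile()
    x = OCE_X_GRID.copy() if x is None else np.asarray(x, dtype=float)
    t = OCE_T_GRID.copy() if t is None else np.asarray(t, dtype=float)
    if mode_amplitudes is None:
        mode_amplitudes = np.ones(len(branches))
    mode_amplitudes = np.asarray(mode_amplitudes, dtype=float)
    if mode_amplitudes.shape != (len(branches),):
        raise ValueError("mode_amplitudes must have one weight per branch")

    nt = t.size
    dt = t[1] - t[0]
    freqs = np.fft.rfftfreq(nt, dt)
    S = np.fft.rfft(src.time_profile(t))

    f_band = freqs[np.abs(S) > 0.1 * np.abs(S).max()]
    f_lo_need = 1.25 * f_band[f_band > 0].min() if np.any(f_band > 0) else 0.0
    f_hi_need = 0.8 * f_band.max() if f_band.size else np.inf
    spec = np.zeros((freqs.size, x.size), dtype=complex)
    for a, br in zip(mode_amplitudes, branches):
        if a == 0:
            continue
        if br.freqs[0] > f_lo_need or br.freqs[-1] < f_hi_need:
            warnings.warn(
                f"branch {br.label} covers {br.freqs[0]:.0f}-{br.freqs[-1]:.0f} Hz, "
                "narrower than the source bandwidth; synthesis is band-limited",
                stacklevel=2,
            )
        k = br.k_at(freqs)
        ok = np.isfinite(k)
        phase = np.exp(1j * np.outer(k[ok], x - x[0]))
        spec[ok, :] += (a * S[ok] * src.spatial_k_response(k[ok]))[:, None] * phase

    vz = np.fft.irfft(np.conj(spec), n=nt, axis=0)
    if aperture_taper > 0:
        n_tap = max(1, int(round(aperture_taper * x.size)))
        taper = np.ones(x.size)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_tap) / n_tap))
        taper[:n_tap] = ramp
        taper[-n_tap:] = ramp[::-1]
        vz = vz * taper[None, :]
    peak = np.abs(vz).max()
    if peak > 0:
        vz /= peak
    if noise_rms:
        rng = np.random.default_rng(seed)
        vz = vz + rng.normal(0.0, noise_rms, vz.shape)
    return XTField(x=x, t=t, vz=vz)
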