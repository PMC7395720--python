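"""OCE-style signal chain: phase to velocity, surface extraction, filtering,
and the 2D frequency–wavenumber spectrum.

The processing mirrors what a phase-sensitive OCT elastography system does
to raw data before dispersion fitting: convert inter-A-line optical phase
differences to vertical particle velocity, average a shallow depth window
below the detected surface with half-Gaussian weights, remove
counter-propagating energy and out-of-band noise, and Fourier-transform
the XT field into a per-frequency-normalized power spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .fields import Spectrum2D, XTField

__all__ = [
    "OCTParams",
    "phase_to_velocity",
    "extract_surface",
    "directional_filter",
    "bandpass_filter",
    "spectrum2d",
]


@dataclass(frozen=True)
class OCTParams:
    """Phase-sensitive OCT conversion constants.

    lambda_bar: center wavelength of the light source, m.
    n_bar: refractive index of the medium (1.38 for cornea-like tissue).
    fs: A-line sampling frequency, Hz.
    """

    lambda_bar: float = 1310e-9
    n_bar: float = 1.38
    fs: float = 46500.0

    def __post_init__(self) -> None:
        if self.lambda_bar <= 0 or self.fs <= 0:
            raise ValueError("lambda_bar and fs must be positive")
        if self.n_bar < 1:
            raise ValueError("n_bar must be >= 1")


def phase_to_velocity(dphi, p: OCTParams):
    """Vertical particle velocity from the inter-A-line phase difference.

    v_z = Δφ·λ̄·f_s / (4π·n̄) — the Doppler relation for phase-sensitive
    OCT with consecutive A-line scans.  Elementwise over arrays.
    """
    dphi = np.asarray(dphi, dtype=float)
    if not np.all(np.isfinite(dphi)):
        raise ValueError("dphi must be finite")
    out = dphi * p.lambda_bar * p.fs / (4 * np.pi * p.n_bar)
    return float(out) if out.ndim == 0 else out


def extract_surface(
    vz_volume: np.ndarray,
    surface_index,
    dz: float,
    x: np.ndarray,
    t: np.ndarray,
    window_depth: float = 183e-6,
    hwhm: float = 90e-6,
) -> XTField:
    """Collapse a velocity volume to a surface XT field by depth averaging.

    ``vz_volume`` is indexed [time, depth, position]; ``surface_index``
    gives the surface depth index per lateral position (scalar or array).
    Samples from the surface down to ``window_depth`` are averaged with
    half-Gaussian weights w(d) = exp(−ln2·(d/hwhm)²) normalized to unit
    sum, weighting the superficial signal most strongly.  If the window
    extends past the bottom of the volume it is truncated (with
    renormalized weights) and a warning is issued once.
    """
    vol = np.asarray(vz_volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("vz_volume must be [time, depth, position]")
    if window_depth <= 0 or hwhm <= 0 or dz <= 0:
        raise ValueError("window_depth, hwhm and dz must be positive")
    nt, ndepth, nx = vol.shape
    surface_index = np.broadcast_to(np.asarray(surface_index, dtype=int), (nx,))
    if np.any(surface_index < 0) or np.any(surface_index >= ndepth):
        raise ValueError("surface_index outside the depth range")
    n_win = int(np.floor(window_depth / dz)) + 1
    depths = np.arange(n_win) * dz
    weights = np.exp(-np.log(2) * (depths / hwhm) ** 2)
    out = np.empty((nt, nx))
    warned = False
    for i in range(nx):
        j0 = surface_index[i]
        j1 = min(j0 + n_win, ndepth)
        if j1 - j0 < n_win and not warned:
            warnings.warn(
                "depth window extends past the volume bottom; truncating "
                "with renormalized weights",
                stacklevel=2,
            )
            warned = True
        w = weights[: j1 - j0]
        out[:, i] = vol[:, j0:j1, i] @ (w / w.sum())
    return XTField(x=np.asarray(x, dtype=float), t=np.asarray(t, dtype=float), vz=out)


def directional_filter(xt: XTField, direction: str = "+x") -> XTField:
    """Keep only energy propagating in one lateral direction.

    In the 2D Fourier plane a wave exp(i(kx − ωt)) traveling toward +x
    occupies the quadrants where the (signed) temporal and spatial
    frequencies have opposite signs; the opposing quadrants are zeroed and
    the field inverse-transformed.  Zero-frequency lines are kept at half
    weight so that the two directions partition the energy.
    """
    if direction not in ("+x", "-x"):
        raise ValueError("direction must be '+x' or '-x'")
    F = np.fft.fft2(xt.vz)
    ft = np.fft.fftfreq(xt.t.size)[:, None]
    kx = np.fft.fftfreq(xt.x.size)[None, :]
    s = -1.0 if direction == "+x" else 1.0
    mask = np.where(ft * kx * s > 0, 1.0, np.where(ft * kx == 0, 0.5, 0.0))
    vz = np.fft.ifft2(F * mask).real
    return XTField(x=xt.x, t=xt.t, vz=vz)


def bandpass_filter(
    xt: XTField, f_lo: float = 100.0, f_hi: float = 4000.0, order: int = 4
) -> XTField:
    """Zero-phase (forward–backward) temporal Butterworth band-pass."""
    nyq = 0.5 / xt.dt
    if not 0 <= f_lo < f_hi <= nyq:
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz invalid for Nyquist {nyq:.0f} Hz")
    if f_lo == 0:
        sos = butter(order, f_hi / nyq, btype="low", output="sos")
    else:
        sos = butter(order, [f_lo / nyq, f_hi / nyq], btype="band", output="sos")
    vz = sosfiltfilt(sos, xt.vz, axis=0)
    return XTField(x=xt.x, t=xt.t, vz=vz)


def spectrum2d(xt: XTField, pad_factor: int = 2, noise_floor: float = 1e-3) -> Spectrum2D:
    """Normalized frequency–wavenumber power spectrum of an XT field.

    Magnitude-squared 2D FFT (zero-padded by ``pad_factor`` along both
    axes), restricted to positive frequencies and to the wavenumber
    half-plane carrying the propagating energy; wavenumbers are reported
    positive, in cycles/m.  Each frequency column whose maximum exceeds
    ``noise_floor`` times the global maximum is normalized to unit max,
    matching the ridge-fitting use and the usual 20 dB display convention;
    columns below the floor are zeroed.
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    nt, nx = xt.vz.shape
    if nt < 8 or nx < 8:
        raise ValueError("need at least 8 samples along each axis")
    nt_p, nx_p = pad_factor * nt, pad_factor * nx
    F = np.fft.fft2(xt.vz, s=(nt_p, nx_p))
    power = np.abs(F) ** 2 / (nt_p * nx_p)  # Parseval: sum equals XT energy
    n_fpos = nt_p // 2 + 1
    freqs = np.arange(n_fpos) / (nt_p * xt.dt)
    n_kpos = nx_p // 2 + 1
    k_cyc = np.arange(n_kpos) / (nx_p * xt.dx)
    # for f > 0: +x-going energy sits at negative spatial frequency bins
    pos_f = power[:n_fpos, :]
    half_neg = np.concatenate(
        [pos_f[:, :1], pos_f[:, : nx_p - n_kpos : -1]], axis=1
    )  # k bins 0, -1, -2, ... mapped to 0, 1, 2, ... cycles/m
    half_pos = pos_f[:, :n_kpos]
    raw = half_neg if half_neg.sum() >= half_pos.sum() else half_pos
    raw = raw.copy()

    col_max = raw.max(axis=1)
    floor = noise_floor * (raw.max() if raw.size else 0.0)
    norm = np.zeros_like(raw)
    keep = col_max > floor
    norm[keep] = raw[keep] / col_max[keep, None]
    return Spectrum2D(
        freqs=freqs,
        wavenumbers=k_cyc,
        power=norm,
        raw=raw,
        full_energy=float(power.sum()),
    )
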