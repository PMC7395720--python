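"""Array containers for surface wavefields and their 2D spectra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["XTField", "Spectrum2D"]


def _check_uniform(a: np.ndarray, name: str) -> float:
    """Return the grid step of a uniform, strictly increasing 1-D grid."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError(f"{name} must be a 1-D grid with >= 2 samples")
    d = np.diff(a)
    if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6, atol=0):
        raise ValueError(f"{name} grid must be uniform and strictly increasing")
    return float(d[0])


@dataclass(frozen=True)
class XTField:
    """Surface vertical-velocity field on uniform space-time grids.

    ``vz`` is indexed [time, position] in m/s; ``x`` in m, ``t`` in s.
    This is the "XT plot" of surface-wave elastography: what a
    phase-sensitive OCT system records along a line on the sample surface.
    """

    x: np.ndarray
    t: np.ndarray
    vz: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        t = np.asarray(self.t, dtype=float)
        vz = np.asarray(self.vz, dtype=float)
        _check_uniform(x, "x")
        _check_uniform(t, "t")
        if vz.shape != (t.size, x.size):
            raise ValueError(
                f"vz shape {vz.shape} does not match (len(t), len(x)) = "
                f"({t.size}, {x.size})"
            )
        if not np.all(np.isfinite(vz)):
            bad = np.argwhere(~np.isfinite(vz))[0]
            raise ValueError(f"vz contains a non-finite sample at [t={bad[0]}, x={bad[1]}]")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "vz", vz)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def energy(self) -> float:
        """Sum of squared samples (discrete signal energy)."""
        return float(np.sum(self.vz**2))


@dataclass(frozen=True)
class Spectrum2D:
    """Normalized frequency-wavenumber power spectrum of an XT field.

    ``power`` is indexed [frequency, wavenumber]; wavenumbers are in
    cycles/m (use :attr:`k_rad` for rad/m).  Each frequency column holding
    signal is normalized to unit maximum, matching how dispersion-curve
    ridges are fit; columns below the noise floor are zeroed.  ``raw``
    keeps the unnormalized power for energy bookkeeping.
    """

    freqs: np.ndarray
    wavenumbers: np.ndarray
    power: np.ndarray
    raw: np.ndarray = field(default=None, repr=False)
    #: total unnormalized power over the full 2D plane; equals the XT
    #: field's discrete energy by Parseval's theorem
    full_energy: float = None

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        k = np.asarray(self.wavenumbers, dtype=float)
        p = np.asarray(self.power, dtype=float)
        _check_uniform(f, "freqs")
        _check_uniform(k, "wavenumbers")
        if p.shape != (f.size, k.size):
            raise ValueError("power shape must be (len(freqs), len(wavenumbers))")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "wavenumbers", k)
        object.__setattr__(self, "power", p)
        if self.raw is not None:
            object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))

    @property
    def k_rad(self) -> np.ndarray:
        """Wavenumber axis in rad/m."""
        return 2 * np.pi * self.wavenumbers

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def dk(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])
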