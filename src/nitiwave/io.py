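"""File formats and run configuration.

XT fields and spectra persist either as HDF5 (exact round-trip) or as
plain-text CSV with a JSON sidecar carrying the grid metadata — there is
no community-standard container for OCE surface wavefields, so the
dialects are deliberately minimal and fully documented by their sidecars.
Dispersion branches use a flat CSV (mode, freq_hz, k_rad_per_m,
phase_velocity_m_per_s); wavenumbers are written in both rad/m and the
spectral convention cycles/m where relevant.  Every artifact embeds the
SHA-256 hash of the run configuration that produced it so a pipeline
cannot silently mix artifacts from different runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .fields import Spectrum2D, XTField
from .dispersion import DispersionBranch
from .inversion import FitResult

__all__ = [
    "FormatError",
    "RunConfig",
    "load_config",
    "config_hash",
    "read_xt",
    "write_xt",
    "read_spectrum",
    "write_spectrum",
    "read_branches",
    "write_branches",
    "write_fit_result",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_ALLOWED = {
    "material": {"mu_Pa", "G_Pa", "rho_kgm3", "cL_ms"},
    "geometry": {"h_m", "rho_f_kgm3", "c_f_ms"},
    "source": {"spatial_fwhm_m", "temporal_fwhm_s", "order"},
    "generate": {"kind", "noise_rms", "duration_s", "domain_length_m", "n_x", "n_t"},
    "processing": {"band_hz", "direction", "pad"},
    "fit": {"model", "init", "reg_weight", "seed"},
}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration.

    Blocks: material (mu_Pa, G_Pa, rho_kgm3, cL_ms), geometry (h_m,
    rho_f_kgm3, c_f_ms), source (spatial_fwhm_m, temporal_fwhm_s, order),
    generate (kind: synth|fd, noise_rms, ...), processing (band_hz,
    direction, pad), fit (model: niti|isotropic, init, reg_weight, seed).
    Unknown keys anywhere are rejected.
    """

    material: dict
    geometry: dict
    source: dict = field(default_factory=dict)
    generate: dict = field(default_factory=dict)
    processing: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for block, allowed in _ALLOWED.items():
            d = getattr(self, block)
            if not isinstance(d, dict):
                raise FormatError(f"config block '{block}' must be a mapping")
            unknown = set(d) - allowed
            if unknown:
                raise FormatError(
                    f"unknown key(s) {sorted(unknown)} in config block '{block}'"
                )
        for key in ("mu_Pa", "G_Pa", "rho_kgm3"):
            if key not in self.material:
                raise FormatError(f"material block missing required key '{key}'")
            if not self.material[key] > 0:
                raise FormatError(f"material.{key} must be positive")
        if "h_m" not in self.geometry:
            raise FormatError("geometry block missing required key 'h_m'")
        if not self.geometry["h_m"] > 0:
            raise FormatError("geometry.h_m must be positive")
        band = self.processing.get("band_hz")
        if band is not None and not (0 <= band[0] < band[1]):
            raise FormatError("processing.band_hz must be (lo, hi) with lo < hi")
        model = self.fit.get("model", "niti")
        if model not in ("niti", "isotropic"):
            raise FormatError("fit.model must be 'niti' or 'isotropic'")
        kind = self.generate.get("kind", "synth")
        if kind not in ("synth", "fd"):
            raise FormatError("generate.kind must be 'synth' or 'fd'")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(_ALLOWED)
        if unknown:
            raise FormatError(f"unknown config block(s): {sorted(unknown)}")
        return cls(**{k: d.get(k, {}) for k in _ALLOWED})

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Read a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path} does not contain a configuration mapping")
    return RunConfig.from_dict(data)


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 over the canonicalized configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# XT fields
# --------------------------------------------------------------------------


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5")


def write_xt(xt: XTField, path, meta: dict | None = None) -> Path:
    """Persist an XT field; the dialect follows the file extension.

    HDF5: datasets ``x``, ``t``, ``vz`` with unit attributes.  Text: a
    comma-delimited vz matrix (rows = time) with a ``<path>.json`` sidecar
    holding dx_m, dt_s, x0_m, t0_s and units.
    """
    path = Path(path)
    meta = dict(meta or {})
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            f.create_dataset("x", data=xt.x)
            f.create_dataset("t", data=xt.t)
            f.create_dataset("vz", data=xt.vz)
            f["x"].attrs["units"] = "m"
            f["t"].attrs["units"] = "s"
            f["vz"].attrs["units"] = "m/s"
            for k, v in meta.items():
                f.attrs[k] = v
    else:
        np.savetxt(path, xt.vz, delimiter=",")
        sidecar = {
            "dx_m": xt.dx,
            "dt_s": xt.dt,
            "x0_m": float(xt.x[0]),
            "t0_s": float(xt.t[0]),
            "units": {"x": "m", "t": "s", "vz": "m/s"},
            **meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )
    return path


def read_xt(path) -> XTField:
    """Load an XT field written by :func:`write_xt`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            for name in ("x", "t", "vz"):
                if name not in f:
                    raise FormatError(f"{path}: missing dataset '{name}'")
            x, t, vz = f["x"][:], f["t"][:], f["vz"][:]
    else:
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise FormatError(f"{path}: missing JSON sidecar {sidecar_path.name}")
        sidecar = json.loads(sidecar_path.read_text())
        for key in ("dx_m", "dt_s", "x0_m", "t0_s"):
            if key not in sidecar:
                raise FormatError(f"{sidecar_path.name}: missing field '{key}'")
        vz = np.loadtxt(path, delimiter=",", ndmin=2)
        x = sidecar["x0_m"] + sidecar["dx_m"] * np.arange(vz.shape[1])
        t = sidecar["t0_s"] + sidecar["dt_s"] * np.arange(vz.shape[0])
    bad = np.argwhere(~np.isfinite(vz))
    if bad.size:
        raise FormatError(
            f"{path}: non-finite vz sample at [t={bad[0][0]}, x={bad[0][1]}]"
        )
    try:
        return XTField(x=x, t=t, vz=vz)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_xt_meta(path) -> dict:
    """Metadata (attributes / sidecar extras) stored with an XT field."""
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            return dict(f.attrs)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        return json.loads(sidecar_path.read_text())
    return {}


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------


def write_spectrum(spec: Spectrum2D, path, meta: dict | None = None) -> Path:
    """Persist a spectrum as HDF5 (freqs/wavenumbers/power) or long CSV.

    Wavenumbers are stored in cycles/m (documented in the header/attrs).
    """
    path = Path(path)
    meta = dict(meta or {})
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            f.create_dataset("freqs", data=spec.freqs)
            f.create_dataset("wavenumbers", data=spec.wavenumbers)
            f.create_dataset("power", data=spec.power)
            f["freqs"].attrs["units"] = "Hz"
            f["wavenumbers"].attrs["units"] = "cycles/m"
            for k, v in meta.items():
                f.attrs[k] = v
    else:
        ff, kk = np.meshgrid(spec.freqs, spec.wavenumbers, indexing="ij")
        table = np.column_stack([ff.ravel(), kk.ravel(), spec.power.ravel()])
        header = "freq_hz,k_cycles_per_m,power"
        for k, v in meta.items():
            header = f"{k}={v}\n" + header
        np.savetxt(path, table, delimiter=",", header=header)
    return path


def read_spectrum(path) -> Spectrum2D:
    """Load a spectrum written by :func:`write_spectrum`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            for name in ("freqs", "wavenumbers", "power"):
                if name not in f:
                    raise FormatError(f"{path}: missing dataset '{name}'")
            return Spectrum2D(
                freqs=f["freqs"][:],
                wavenumbers=f["wavenumbers"][:],
                power=f["power"][:],
            )
    table = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    freqs = np.unique(table[:, 0])
    ks = np.unique(table[:, 1])
    if freqs.size * ks.size != table.shape[0]:
        raise FormatError(f"{path}: CSV triplet is not a complete grid")
    power = table[:, 2].reshape(freqs.size, ks.size)
    return Spectrum2D(freqs=freqs, wavenumbers=ks, power=power)


def read_spectrum_meta(path) -> dict:
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            return dict(f.attrs)
    meta = {}
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
    return meta


# --------------------------------------------------------------------------
# branches and fit results
# --------------------------------------------------------------------------


def write_branches(branches: list[DispersionBranch], path) -> Path:
    """Branch CSV: mode,freq_hz,k_rad_per_m,phase_velocity_m_per_s."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("mode,freq_hz,k_rad_per_m,phase_velocity_m_per_s\n")
        for br in branches:
            for fr, k, v in zip(br.freqs, br.wavenumbers, br.phase_velocity):
                f.write(f"{br.label},{fr:.9g},{k:.9g},{v:.9g}\n")
    return path


def read_branches(path) -> list[DispersionBranch]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    rows: dict[str, list] = {}
    with open(path) as f:
        header = f.readline().strip().split(",")
        if header[:3] != ["mode", "freq_hz", "k_rad_per_m"]:
            raise FormatError(f"{path}: unexpected branch CSV header {header}")
        for line in f:
            label, fr, k, *_ = line.strip().split(",")
            rows.setdefault(label, []).append((float(fr), float(k)))
    out = []
    for label, pts in rows.items():
        pts.sort()
        arr = np.array(pts)
        out.append(
            DispersionBranch(label=label, freqs=arr[:, 0], wavenumbers=arr[:, 1])
        )
    return out


def write_fit_result(result: FitResult, path, meta: dict | None = None) -> Path:
    path = Path(path)
    payload = asdict(result)
    payload.update(meta or {})
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=float))
    return path
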