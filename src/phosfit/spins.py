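"""Spin systems and noiseless frequency-domain basis-spectrum synthesis.

Each metabolite is a :class:`SpinSystem` — a list of resonances, each with a
chemical shift (ppm, PCr = 0), a relative amplitude and a fine-structure
pattern given as explicit (offset_hz, weight) lines.  Basis spectra are the
concentration-unit responses: every line is a unit-area pseudo-Voigt, and a
whole basis spectrum integrates (real part, Hz units) to
``nuclei_per_molecule × BASIS_AREA`` so that a fitted amplitude reads
directly as a concentration in the generator's units.

The complex lineshape pairs the absorption profile with its Hilbert-transform
dispersion (closed form for the Lorentzian, Dawson function for the
Gaussian), so time-domain and frequency-domain synthesis stay consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import dawsn

from .core import AcquisitionParams
from .errors import ParameterError, SpectralWindowError

__all__ = [
    "BASIS_AREA",
    "DEFAULT_METABOLITES",
    "Resonance",
    "SpinSystem",
    "Lineshape",
    "BasisSpectrum",
    "pseudo_voigt",
    "pseudo_voigt_complex",
    "simulate_basis",
    "build_default_basis",
    "load_spin_systems",
    "default_linewidths",
    "synthesize_profile",
]

#: Package-wide unit-concentration area constant (real-part integral in Hz
#: units contributed per ³¹P nucleus).
BASIS_AREA = 1.0

DEFAULT_METABOLITES = (
    "PCr", "aATP", "bATP", "gATP", "Pi_int", "Pi_ext", "PE", "PC",
    "GPC", "GPE", "MP", "UDPG", "NADH", "NAD+",
)

_GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Lineshape:
    """Pseudo-Voigt lineshape: ``η·Lorentzian + (1−η)·Gaussian``.

    Both components share the same nominal FWHM; η=1 is pure Lorentzian,
    η=0 pure Gaussian.
    """

    fwhm: float
    mixing_eta: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.fwhm) or self.fwhm <= 0:
            raise ParameterError(f"fwhm must be > 0 Hz, got {self.fwhm}")
        if not 0.0 <= self.mixing_eta <= 1.0:
            raise ParameterError(f"mixing_eta must lie in [0, 1], got {self.mixing_eta}")

    def scaled(self, factor: float) -> "Lineshape":
        return Lineshape(self.fwhm * factor, self.mixing_eta)


@dataclass(frozen=True)
class Resonance:
    """A resonance group: centre shift, relative amplitude and multiplet lines."""

    center_shift: float
    relative_amplitude: float
    multiplet_lines: tuple[tuple[float, float], ...] = ((0.0, 1.0),)

    def __post_init__(self) -> None:
        if self.relative_amplitude < 0:
            raise ParameterError("relative_amplitude must be >= 0")
        offsets = np.array([o for o, _ in self.multiplet_lines], dtype=float)
        weights = np.array([w for _, w in self.multiplet_lines], dtype=float)
        if not np.all(np.isfinite(offsets)):
            raise ParameterError("multiplet line offsets must be finite")
        if len(weights) == 0 or abs(weights.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"multiplet weights must sum to 1, got {weights.sum():.6g}"
            )


@dataclass(frozen=True)
class SpinSystem:
    name: str
    resonances: tuple[Resonance, ...]
    nuclei_per_molecule: int = 1

    def __post_init__(self) -> None:
        if self.nuclei_per_molecule < 1:
            raise ParameterError("nuclei_per_molecule must be >= 1")
        if not self.resonances:
            raise ParameterError(f"spin system '{self.name}' has no resonances")

    @property
    def total_relative_amplitude(self) -> float:
        return float(sum(r.relative_amplitude for r in self.resonances))


@dataclass
class BasisSpectrum:
    """Unit-concentration complex response of one metabolite on the ppm axis."""

    metabolite: str
    values: np.ndarray
    axis: np.ndarray
    lw_used: float
    system: SpinSystem
    acq: AcquisitionParams
    shape: Lineshape

    def scaled(self, factor: float) -> "BasisSpectrum":
        out = BasisSpectrum(
            self.metabolite, self.values * factor, self.axis,
            self.lw_used, self.system, self.acq, self.shape,
        )
        return out


def _lorentzian_complex(x: np.ndarray, fwhm: float) -> np.ndarray:
    """Unit-area complex Lorentzian: absorption + i·dispersion.

    The dispersion sign matches a causal decaying FID under the
    ``spectrum = fftshift(fft(fid))`` convention, so the inverse transform
    of a synthesized spectrum is a forward-decaying FID.
    """
    hw = fwhm / 2.0
    denom = np.pi * (hw * hw + x * x)
    return hw / denom - 1j * (x / denom)


def _gaussian_complex(x: np.ndarray, fwhm: float) -> np.ndarray:
    """Unit-area complex Gaussian; dispersion via the Dawson function
    (same causal sign convention as the Lorentzian)."""
    sigma = fwhm * _GAUSS_FWHM_TO_SIGMA
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    absorption = norm * np.exp(-0.5 * (x / sigma) ** 2)
    dispersion = norm * (2.0 / np.sqrt(np.pi)) * dawsn(x / (sigma * np.sqrt(2.0)))
    return absorption - 1j * dispersion


def pseudo_voigt_complex(axis_hz: np.ndarray, center: float, shape: Lineshape) -> np.ndarray:
    """Unit-area complex pseudo-Voigt evaluated at ``axis_hz`` (Hz)."""
    x = np.asarray(axis_hz, dtype=float) - center
    eta = shape.mixing_eta
    out = np.zeros(x.shape, dtype=complex)
    if eta > 0:
        out += eta * _lorentzian_complex(x, shape.fwhm)
    if eta < 1:
        out += (1.0 - eta) * _gaussian_complex(x, shape.fwhm)
    return out


def pseudo_voigt(axis_hz: np.ndarray, center: float, shape: Lineshape) -> np.ndarray:
    """Real (absorption) part of the unit-area pseudo-Voigt."""
    return pseudo_voigt_complex(axis_hz, center, shape).real


def synthesize_profile(
    system: SpinSystem,
    acq: AcquisitionParams,
    shape: Lineshape,
    hz_axis: np.ndarray,
    shift_ppm: float = 0.0,
    lw_scale: float = 1.0,
) -> np.ndarray:
    """Complex unit-concentration profile of ``system`` on a Hz-offset axis.

    ``shift_ppm`` displaces every resonance; ``lw_scale`` multiplies the
    FWHM — both are the free parameters of the linear-combination fitter.
    No spectral-window check is performed here (see :func:`simulate_basis`).
    """
    eff_shape = shape if lw_scale == 1.0 else shape.scaled(lw_scale)
    total = system.total_relative_amplitude
    if total <= 0:
        raise ParameterError(f"spin system '{system.name}' has zero total amplitude")
    scale = system.nuclei_per_molecule * BASIS_AREA / total
    out = np.zeros(np.shape(hz_axis), dtype=complex)
    for res in system.resonances:
        center_hz = acq.ppm_to_hz(res.center_shift + shift_ppm)
        for offset, weight in res.multiplet_lines:
            out += (scale * res.relative_amplitude * weight) * pseudo_voigt_complex(
                hz_axis, float(center_hz) + offset, eff_shape
            )
    return out


def simulate_basis(
    system: SpinSystem, acq: AcquisitionParams, shape: Lineshape
) -> BasisSpectrum:
    """Synthesize the noiseless unit-concentration basis spectrum of a metabolite.

    Raises :class:`SpectralWindowError` if any multiplet line falls outside
    the acquired bandwidth.
    """
    hz = acq.hz_axis()
    lo, hi = hz[0], hz[-1]
    for res in system.resonances:
        center_hz = float(acq.ppm_to_hz(res.center_shift))
        for offset, _ in res.multiplet_lines:
            line = center_hz + offset
            if not (lo <= line <= hi):
                raise SpectralWindowError(
                    f"{system.name}: line at {acq.hz_to_ppm(line):.2f} ppm "
                    f"({line:.1f} Hz) outside the spectral window "
                    f"[{acq.ppm_axis()[0]:.2f}, {acq.ppm_axis()[-1]:.2f}] ppm"
                )
    values = synthesize_profile(system, acq, shape, hz)
    return BasisSpectrum(system.name, values, acq.ppm_axis(), shape.fwhm, system, acq, shape)


# ---------------------------------------------------------------------------
# Default spin-parameter file handling


def _default_data(name: str) -> dict:
    with resources.files("phosfit.data").joinpath(name).open("r") as fh:
        return json.load(fh)


def load_spin_systems(path: str | Path | None = None) -> dict[str, SpinSystem]:
    """Load spin systems from a JSON spin-parameter file.

    Schema: ``{"systems": [{name, nuclei_per_molecule, resonances:
    [{shift_ppm, amplitude, lines: [{offset_hz, weight}]}]}]}``.
    With ``path=None`` the packaged literature-default file is used.
    """
    if path is None:
        raw = _default_data("spin_params.json")
    else:
        raw = json.loads(Path(path).read_text())
    systems: dict[str, SpinSystem] = {}
    for entry in raw["systems"]:
        name = entry["name"]
        if name in systems:
            raise ParameterError(f"duplicate spin system name '{name}'")
        resonances = tuple(
            Resonance(
                center_shift=float(r["shift_ppm"]),
                relative_amplitude=float(r["amplitude"]),
                multiplet_lines=tuple(
                    (float(l["offset_hz"]), float(l["weight"])) for l in r["lines"]
                ),
            )
            for r in entry["resonances"]
        )
        systems[name] = SpinSystem(name, resonances, int(entry["nuclei_per_molecule"]))
    return systems


def default_linewidths() -> dict[str, float]:
    """Packaged default per-metabolite linewidths in Hz (PCr = 13 Hz)."""
    return {k: float(v) for k, v in _default_data("invivo_profile.json")["linewidths_hz"].items()}


def build_default_basis(
    acq: AcquisitionParams | None = None,
    lw_table: Mapping[str, float] | None = None,
    eta: float | Mapping[str, float] = 1.0,
    spin_file: str | Path | None = None,
    names: Sequence[str] = DEFAULT_METABOLITES,
) -> list[BasisSpectrum]:
    """Build the 14-metabolite default basis set.

    ``lw_table`` must provide a FWHM (Hz) for every requested metabolite;
    ``eta`` may be a scalar mixing parameter or a per-metabolite mapping.
    """
    acq = acq or AcquisitionParams()
    if lw_table is None:
        lw_table = default_linewidths()
    missing = [n for n in names if n not in lw_table]
    if missing:
        raise ParameterError(f"lw_table missing linewidths for: {', '.join(missing)}")
    systems = load_spin_systems(spin_file)
    absent = [n for n in names if n not in systems]
    if absent:
        raise ParameterError(f"spin-parameter file missing systems: {', '.join(absent)}")
    basis = []
    for name in names:
        e = eta[name] if isinstance(eta, Mapping) else eta
        basis.append(simulate_basis(systems[name], acq, Lineshape(float(lw_table[name]), float(e))))
    return basis


def basis_by_name(basis: Iterable[BasisSpectrum]) -> dict[str, BasisSpectrum]:
    return {b.metabolite: b for b in basis}
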