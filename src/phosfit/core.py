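"""Core containers: acquisition geometry, ppm axes and FFT round trips.

Conventions
-----------
* The chemical-shift axis is in ppm with phosphocreatine (PCr) at 0 ppm and
  is stored strictly increasing.  Resonances downfield of PCr in the usual
  in vivo nomenclature (α-ATP at −7.6 ppm, β-ATP near −16 ppm, the NAD
  signals near −8.3 ppm) therefore sit at negative ppm.
* ppm ↔ Hz conversion uses the spectrometer frequency in MHz:
  ``hz = (ppm − transmitter_offset) × spectrometer_freq``.
* A spectrum and its FID are linked by the unitary pair
  ``spectrum = fftshift(fft(fid))`` / ``fid = ifft(ifftshift(spectrum))``,
  so the two synthesis routes (frequency-domain and time-domain) are exact
  inverses of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ParameterError

__all__ = ["AcquisitionParams", "Spectrum", "spectrum_from_fid", "fid_from_spectrum"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition geometry of a pulse-acquire ³¹P experiment.

    Parameters
    ----------
    spectrometer_freq : float
        ³¹P Larmor frequency in MHz (default 243.0, i.e. 14.1 T).
    spectral_width : float
        Acquisition bandwidth in Hz.
    n_points : int
        Number of complex points in the FID / spectrum.
    transmitter_offset : float
        Carrier position in ppm (default −8.3 ppm, on the NAD⁺ signal).
    reference_shift : float
        ppm of the chemical-shift reference (PCr, always 0).
    """

    spectrometer_freq: float = 243.0
    spectral_width: float = 12000.0
    n_points: int = 4096
    transmitter_offset: float = -8.3
    reference_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.spectrometer_freq <= 0:
            raise ParameterError("spectrometer_freq must be > 0 MHz")
        if self.spectral_width <= 0:
            raise ParameterError("spectral_width must be > 0 Hz")
        if self.n_points < 2:
            raise ParameterError("n_points must be >= 2")

    @property
    def dwell(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.spectral_width

    def time_axis(self) -> np.ndarray:
        """FID time axis in seconds, starting at t = 0."""
        return np.arange(self.n_points) * self.dwell

    def hz_axis(self) -> np.ndarray:
        """Frequency offsets from the carrier, strictly increasing, in Hz."""
        return (np.arange(self.n_points) - self.n_points // 2) * (
            self.spectral_width / self.n_points
        )

    def ppm_axis(self) -> np.ndarray:
        """Chemical-shift axis in ppm (PCr at 0), strictly increasing."""
        return self.transmitter_offset + self.hz_axis() / self.spectrometer_freq

    def ppm_to_hz(self, ppm: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(ppm, dtype=float) - self.transmitter_offset) * self.spectrometer_freq

    def hz_to_ppm(self, hz: float | np.ndarray) -> float | np.ndarray:
        return self.transmitter_offset + np.asarray(hz, dtype=float) / self.spectrometer_freq

    @property
    def hz_per_point(self) -> float:
        return self.spectral_width / self.n_points

    def to_dict(self) -> dict[str, Any]:
        return {
            "spectrometer_freq": self.spectrometer_freq,
            "spectral_width": self.spectral_width,
            "n_points": self.n_points,
            "transmitter_offset": self.transmitter_offset,
            "reference_shift": self.reference_shift,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AcquisitionParams":
        return cls(**d)


@dataclass
class Spectrum:
    """A complex frequency-domain spectrum on a ppm axis.

    ``meta`` carries provenance: seed, target SNR, ground-truth
    concentrations for synthetic data, and a log of applied corrections.
    """

    values: np.ndarray
    axis: np.ndarray
    acq: AcquisitionParams | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.values.shape != self.axis.shape:
            raise ParameterError("values and axis must have equal length")
        if not np.all(np.diff(self.axis) > 0):
            raise ParameterError("ppm axis must be strictly increasing")

    @property
    def real(self) -> np.ndarray:
        return self.values.real

    def window_mask(self, lo_ppm: float, hi_ppm: float) -> np.ndarray:
        """Boolean mask of points with lo_ppm <= axis <= hi_ppm."""
        if lo_ppm > hi_ppm:
            lo_ppm, hi_ppm = hi_ppm, lo_ppm
        if lo_ppm < self.axis[0] or hi_ppm > self.axis[-1]:
            raise ParameterError(
                f"window [{lo_ppm}, {hi_ppm}] ppm outside axis "
                f"[{self.axis[0]:.2f}, {self.axis[-1]:.2f}] ppm"
            )
        return (self.axis >= lo_ppm) & (self.axis <= hi_ppm)

    def copy(self) -> "Spectrum":
        return Spectrum(self.values.copy(), self.axis.copy(), self.acq, dict(self.meta))


def spectrum_from_fid(
    fid: np.ndarray, acq: AcquisitionParams, meta: dict[str, Any] | None = None
) -> Spectrum:
    """Fourier transform a complex FID to a Spectrum on the ppm axis."""
    fid = np.asarray(fid, dtype=complex)
    if fid.shape != (acq.n_points,):
        raise ParameterError(f"FID length {fid.shape} != n_points {acq.n_points}")
    values = np.fft.fftshift(np.fft.fft(fid))
    return Spectrum(values, acq.ppm_axis(), acq, dict(meta or {}))


def fid_from_spectrum(spec: Spectrum) -> np.ndarray:
    """Inverse transform; exact inverse of :func:`spectrum_from_fid`."""
    return np.fft.ifft(np.fft.ifftshift(spec.values))
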