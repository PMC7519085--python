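"""Synthetic ³¹P data generation: the stand-in for unavailable in vivo scans.

A synthetic spectrum is a concentration-weighted sum of basis spectra plus a
smooth broad baseline; complex Gaussian noise is injected in the time domain
and calibrated so that the realized SNR — α-ATP peak height at −7.6 ppm over
the real-part noise SD in the −20 to −25 ppm region — matches the requested
target in expectation.  Block series additionally carry per-block frequency
drift and zero-order phase variation, with the true offsets stored so the
drift/phase correction can be tested against ground truth.

Every stochastic operation takes a mandatory integer seed and uses a single
generator type (`numpy.random.default_rng`); the same seed reproduces the
output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AcquisitionParams, Spectrum, fid_from_spectrum, spectrum_from_fid
from .errors import ParameterError
from .spins import (
    DEFAULT_METABOLITES,
    BasisSpectrum,
    Lineshape,
    basis_by_name,
    load_spin_systems,
    simulate_basis,
    _default_data,
)

__all__ = [
    "ConcentrationProfile",
    "BaselineModel",
    "BlockSeries",
    "synthesize_spectrum",
    "make_block_series",
    "phantom_spectrum",
    "default_profile",
    "default_baseline",
    "make_developmental_table",
    "SNR_PEAK_PPM",
    "SNR_NOISE_RANGE",
]

#: α-ATP position (ppm) used in the SNR definition.
SNR_PEAK_PPM = -7.6
#: Signal-free region (ppm) whose real-part SD is the noise level.
SNR_NOISE_RANGE = (-25.0, -20.0)
#: Half-width (ppm) of the search window around the SNR peak.
SNR_PEAK_WINDOW = 0.5


@dataclass(frozen=True)
class ConcentrationProfile:
    """Per-metabolite concentrations in mM (all >= 0, names validated)."""

    conc: Mapping[str, float]
    allowed: tuple[str, ...] = DEFAULT_METABOLITES

    def __post_init__(self) -> None:
        for name, value in self.conc.items():
            if name not in self.allowed:
                raise ParameterError(f"unknown metabolite '{name}'")
            if not np.isfinite(value) or value < 0:
                raise ParameterError(f"concentration of '{name}' must be >= 0, got {value}")
        object.__setattr__(self, "conc", dict(self.conc))

    def __getitem__(self, name: str) -> float:
        return self.conc[name]

    def names(self) -> set[str]:
        return set(self.conc)

    def as_dict(self) -> dict[str, float]:
        return dict(self.conc)


@dataclass(frozen=True)
class BaselineModel:
    """Smooth broad baseline under the spectrum.

    kind:
      * ``"none"`` — zero baseline;
      * ``"polynomial"`` — coefficients (low→high order) of a polynomial in
        the axis normalized to [−1, 1];
      * ``"broad_peaks"`` — list of (center_ppm, fwhm_hz, height) broad
        Lorentzian humps, each with FWHM >= ``min_fwhm`` (no feature narrower
        than a genuine short-T₂* background component).
    """

    kind: str = "none"
    coefficients: tuple[float, ...] = ()
    peaks: tuple[tuple[float, float, float], ...] = ()
    min_fwhm: float = 200.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "polynomial", "broad_peaks"):
            raise ParameterError(f"unknown baseline kind '{self.kind}'")
        if self.kind == "broad_peaks":
            for center, fwhm, _height in self.peaks:
                if fwhm < self.min_fwhm:
                    raise ParameterError(
                        f"baseline peak at {center} ppm has FWHM {fwhm} Hz < "
                        f"minimum {self.min_fwhm} Hz — not a smooth baseline"
                    )
        object.__setattr__(self, "coefficients", tuple(self.coefficients))
        object.__setattr__(self, "peaks", tuple(tuple(p) for p in self.peaks))

    def evaluate(self, axis_ppm: np.ndarray, acq: AcquisitionParams) -> np.ndarray:
        axis_ppm = np.asarray(axis_ppm, dtype=float)
        if self.kind == "none":
            return np.zeros_like(axis_ppm)
        if self.kind == "polynomial":
            lo, hi = axis_ppm[0], axis_ppm[-1]
            x = 2.0 * (axis_ppm - lo) / (hi - lo) - 1.0
            return np.polynomial.polynomial.polyval(x, np.asarray(self.coefficients))
        out = np.zeros_like(axis_ppm)
        hz = np.asarray(acq.ppm_to_hz(axis_ppm))
        for center_ppm, fwhm, height in self.peaks:
            hw = fwhm / 2.0
            x = hz - float(acq.ppm_to_hz(center_ppm))
            out += height * hw * hw / (hw * hw + x * x)
        return out

    def describe(self) -> dict[str, Any]:
        return {"kind": self.kind, "coefficients": list(self.coefficients),
                "peaks": [list(p) for p in self.peaks]}


@dataclass
class BlockSeries:
    """A series of per-block FIDs with known injected drift/phase offsets."""

    blocks: list[np.ndarray]
    freq_offsets: np.ndarray
    phase_offsets: np.ndarray
    acq: AcquisitionParams
    seed: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = {len(b) for b in self.blocks}
        if len(n) != 1:
            raise ParameterError("all blocks must have equal length")
        if not (np.all(np.isfinite(self.freq_offsets)) and np.all(np.isfinite(self.phase_offsets))):
            raise ParameterError("block offsets must be finite")


def _noiseless_sum(
    profile: ConcentrationProfile,
    basis: Sequence[BasisSpectrum],
    baseline: BaselineModel | None,
) -> tuple[np.ndarray, AcquisitionParams]:
    bmap = basis_by_name(basis)
    missing = sorted(profile.names() - set(bmap))
    extra = sorted(set(bmap) - profile.names())
    if missing or extra:
        raise ParameterError(
            "profile/basis metabolite mismatch: "
            f"missing from basis: {missing or 'none'}; missing from profile: {extra or 'none'}"
        )
    acq = basis[0].acq
    values = np.zeros(acq.n_points, dtype=complex)
    for b in basis:  # basis order, so the sum is bit-reproducible
        values = values + profile[b.metabolite] * b.values
    if baseline is not None and baseline.kind != "none":
        values = values + baseline.evaluate(acq.ppm_axis(), acq)
    return values, acq


def _snr_reference_height(values: np.ndarray, acq: AcquisitionParams) -> float:
    axis = acq.ppm_axis()
    mask = (axis >= SNR_PEAK_PPM - SNR_PEAK_WINDOW) & (axis <= SNR_PEAK_PPM + SNR_PEAK_WINDOW)
    height = float(values.real[mask].max())
    if height <= 0:
        raise ParameterError(
            "no positive α-ATP reference peak near −7.6 ppm; cannot calibrate SNR"
        )
    return height


def noise_sd_for_snr(
    noiseless_values: np.ndarray, acq: AcquisitionParams, target_snr: float
) -> float:
    """Per-component time-domain noise SD giving the target spectral SNR.

    i.i.d. complex time-domain noise with per-component SD σ_t transforms to
    white frequency-domain noise with real-part SD σ_t·√N, so
    σ_t = peak_height / (target_snr · √N).
    """
    if target_snr <= 0:
        raise ParameterError(f"target_snr must be > 0, got {target_snr}")
    h = _snr_reference_height(noiseless_values, acq)
    return h / (target_snr * np.sqrt(acq.n_points))


def synthesize_spectrum(
    profile: ConcentrationProfile,
    basis: Sequence[BasisSpectrum],
    baseline: BaselineModel | None = None,
    target_snr: float | None = None,
    seed: int | None = None,
) -> Spectrum:
    """Synthesize one spectrum: Σ conc·basis (+ baseline) + calibrated noise.

    With ``target_snr=None`` the output is the exact noiseless sum.  The
    returned spectrum's ``meta`` records the seed, the nominal SNR, the
    injected time-domain noise SD and the ground-truth concentrations.
    """
    values, acq = _noiseless_sum(profile, basis, baseline)
    meta: dict[str, Any] = {
        "truth": profile.as_dict(),
        "target_snr": target_snr,
        "seed": seed,
        "baseline": (baseline or BaselineModel()).describe(),
    }
    if target_snr is None:
        return Spectrum(values.copy(), acq.ppm_axis(), acq, meta)
    if seed is None:
        raise ParameterError("seed is mandatory when injecting noise")
    sigma_t = noise_sd_for_snr(values, acq, target_snr)
    rng = np.random.default_rng(seed)
    fid = fid_from_spectrum(Spectrum(values, acq.ppm_axis(), acq))
    noise = rng.normal(0.0, sigma_t, acq.n_points) + 1j * rng.normal(0.0, sigma_t, acq.n_points)
    meta["noise_sd_time"] = sigma_t
    return spectrum_from_fid(fid + noise, acq, meta)


def make_block_series(
    profile: ConcentrationProfile,
    basis: Sequence[BasisSpectrum],
    drift_sd: float,
    phase_sd: float,
    n_blocks: int,
    seed: int,
    target_snr: float | None = None,
    baseline: BaselineModel | None = None,
) -> BlockSeries:
    """Generate ``n_blocks`` FIDs sharing one noiseless signal.

    Each block gets an independent frequency offset (SD ``drift_sd`` Hz,
    applied as time-domain modulation), a zero-order phase offset (SD
    ``phase_sd`` rad) and independent noise.  ``target_snr`` refers to the
    drift/phase-corrected *sum* of all blocks.  True offsets are stored for
    use as test oracles.
    """
    if n_blocks < 1:
        raise ParameterError(f"n_blocks must be >= 1, got {n_blocks}")
    if drift_sd < 0 or phase_sd < 0:
        raise ParameterError("drift_sd and phase_sd must be >= 0")
    values, acq = _noiseless_sum(profile, basis, baseline)
    fid0 = fid_from_spectrum(Spectrum(values, acq.ppm_axis(), acq))
    t = acq.time_axis()
    rng = np.random.default_rng(seed)
    freq_offsets = rng.normal(0.0, drift_sd, n_blocks) if drift_sd > 0 else np.zeros(n_blocks)
    phase_offsets = rng.normal(0.0, phase_sd, n_blocks) if phase_sd > 0 else np.zeros(n_blocks)
    sigma_t = 0.0
    if target_snr is not None:
        # per-block noise so that the corrected sum of n blocks hits target_snr
        sigma_t = np.sqrt(n_blocks) * noise_sd_for_snr(values, acq, target_snr)
    blocks = []
    for i in range(n_blocks):
        block = fid0 * np.exp(1j * (2.0 * np.pi * freq_offsets[i] * t + phase_offsets[i]))
        if sigma_t > 0:
            block = block + rng.normal(0.0, sigma_t, acq.n_points) \
                + 1j * rng.normal(0.0, sigma_t, acq.n_points)
        blocks.append(block)
    meta = {
        "truth": profile.as_dict(),
        "target_snr": target_snr,
        "drift_sd": drift_sd,
        "phase_sd": phase_sd,
        "noise_sd_time": sigma_t,
    }
    return BlockSeries(blocks, freq_offsets, phase_offsets, acq, seed, meta)


def phantom_spectrum(
    nad_conc: float,
    nadh_conc: float,
    pi_conc: float,
    acq: AcquisitionParams | None = None,
    seed: int | None = None,
    target_snr: float | None = None,
    lw: float = 8.0,
) -> Spectrum:
    """Three-component phantom spectrum (NAD⁺, NADH, Pi) with known truth.

    Emulates the validation solutions: NAD redox pair in phosphate-buffered
    saline with 9.57 mM inorganic phosphate as the internal reference.
    Solution linewidths are narrow (default 8 Hz).
    """
    for label, c in (("nad_conc", nad_conc), ("nadh_conc", nadh_conc), ("pi_conc", pi_conc)):
        if c < 0:
            raise ParameterError(f"{label} must be >= 0, got {c}")
    acq = acq or AcquisitionParams()
    systems = load_spin_systems()
    names = ("NAD+", "NADH", "Pi_int")
    basis = [simulate_basis(systems[n], acq, Lineshape(lw)) for n in names]
    profile = ConcentrationProfile(
        {"NAD+": nad_conc, "NADH": nadh_conc, "Pi_int": pi_conc}
    )
    if target_snr is not None and nad_conc == 0 and nadh_conc == 0 and pi_conc == 0:
        raise ParameterError("cannot set an SNR for an empty phantom")
    if target_snr is None:
        return synthesize_spectrum(profile, basis)
    # phantom SNR is referenced to its strongest peak rather than α-ATP
    values, _ = _noiseless_sum(profile, basis, None)
    sigma_t = float(values.real.max()) / (target_snr * np.sqrt(acq.n_points))
    rng = np.random.default_rng(seed)
    fid = fid_from_spectrum(Spectrum(values, acq.ppm_axis(), acq))
    noise = rng.normal(0.0, sigma_t, acq.n_points) + 1j * rng.normal(0.0, sigma_t, acq.n_points)
    meta = {"truth": profile.as_dict(), "target_snr": target_snr, "seed": seed,
            "noise_sd_time": sigma_t}
    return spectrum_from_fid(fid + noise, acq, meta)


def default_profile() -> ConcentrationProfile:
    """Packaged illustrative mouse-brain-like concentration profile (mM)."""
    return ConcentrationProfile(
        {k: float(v) for k, v in _default_data("invivo_profile.json")["concentrations_mM"].items()}
    )


def default_baseline() -> BaselineModel:
    """Packaged default broad-hump baseline model."""
    raw = _default_data("invivo_profile.json")["baseline"]
    return BaselineModel(kind=raw["kind"], peaks=tuple(tuple(p) for p in raw["peaks"]))


# ---------------------------------------------------------------------------
# Developmental group table for the statistics stage

_DEV_GROUPS = ("P20", "P40", "P90", "P250")
_DEV_AGES = {"P20": 20, "P40": 40, "P90": 90, "P250": 250}
_DEV_N = {"P20": 10, "P40": 9, "P90": 8, "P250": 5}
# group means emulating the developmental trajectory: stable NAD+, falling
# NADH (0.194 -> 0.043 mM), falling pH, rising free Mg2+, falling PME/PDE
_DEV_MEANS = {
    "NAD+": {"P20": 0.388, "P40": 0.385, "P90": 0.385, "P250": 0.383},
    "NADH": {"P20": 0.194, "P40": 0.140, "P90": 0.080, "P250": 0.043},
    "PME": {"P20": 3.2, "P40": 2.4, "P90": 1.9, "P250": 1.7},
    "PDE": {"P20": 0.9, "P40": 1.1, "P90": 1.3, "P250": 1.45},
    "pH": {"P20": 7.20, "P40": 7.17, "P90": 7.05, "P250": 7.06},
    "Mg_mM": {"P20": 0.18, "P40": 0.25, "P90": 0.27, "P250": 0.30},
}
_DEV_SDS = {"NAD+": 0.06, "NADH": 0.045, "PME": 0.35, "PDE": 0.20, "pH": 0.05, "Mg_mM": 0.04}


def make_developmental_table(
    seed: int, n_per_group: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Per-animal quantification table across postnatal ages P20–P250.

    Draws animal values around illustrative group means; derived columns
    (RR, tNAD, PME/PDE) are computed per animal.  Cohort sizes default to
    10/9/8/5 animals.
    """
    n_per_group = dict(n_per_group or _DEV_N)
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for group in _DEV_GROUPS:
        for _ in range(int(n_per_group[group])):
            row: dict[str, Any] = {
                "animal": f"m{idx:03d}", "group": group, "age_days": _DEV_AGES[group],
            }
            for q, means in _DEV_MEANS.items():
                row[q] = rng.normal(means[group], _DEV_SDS[q])
            row["NADH"] = max(row["NADH"], 0.005)
            row["NAD+"] = max(row["NAD+"], 0.01)
            row["RR"] = row["NAD+"] / row["NADH"]
            row["tNAD"] = row["NAD+"] + row["NADH"]
            row["PME_PDE"] = row["PME"] / row["PDE"]
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)
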