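"""Closed-form physiology from ³¹P chemical-shift differences.

Intracellular pH follows a Henderson–Hasselbalch-type relation in the
Pi–PCr shift difference δ_Pi (ppm):

    pH = pKa + log₁₀((δ_Pi − δ_a) / (δ_b − δ_Pi)),
    pKa = 6.73, δ_a = 3.275 ppm, δ_b = 5.685 ppm,

valid on the open interval (δ_a, δ_b); δ_Pi is the positive Pi−PCr
separation.  Free magnesium follows from the β-ATP–PCr shift difference δ
(ppm, negative):

    pMg = 4.24 − log₁₀[(δ + 18.58)^0.42 / (−15.74 − δ)^0.84],
    [Mg²⁺] = 10^(−pMg)  (molar),

valid on (−18.58, −15.74).  Shifts outside the open intervals raise a
domain error rather than clamping — a clamped value would fabricate
physiology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ParameterError

__all__ = ["PhysioConstants", "ph_from_shift", "mg_from_shift", "mg_log_argument"]


@dataclass(frozen=True)
class PhysioConstants:
    """Calibration constants of the pH and free-Mg²⁺ relations."""

    pka: float = 6.73
    delta_a: float = 3.275
    delta_b: float = 5.685
    mg_offset: float = 4.24
    mg_shift_low: float = -18.58
    mg_shift_high: float = -15.74
    mg_exp_num: float = 0.42
    mg_exp_den: float = 0.84

    def __post_init__(self) -> None:
        if not self.delta_a < self.delta_b:
            raise ParameterError("delta_a must be < delta_b")
        if not self.mg_shift_low < self.mg_shift_high:
            raise ParameterError("mg_shift_low must be < mg_shift_high")
        for name, v in self.__dict__.items():
            if not np.isfinite(v):
                raise ParameterError(f"constant {name} must be finite")


def ph_from_shift(delta_pi: float, constants: PhysioConstants | None = None) -> float:
    """Intracellular pH from the Pi–PCr chemical-shift difference (ppm)."""
    c = constants or PhysioConstants()
    if delta_pi <= c.delta_a:
        raise DomainError(
            f"delta_pi = {delta_pi} ppm is at or below the acid limit delta_a = {c.delta_a}"
        )
    if delta_pi >= c.delta_b:
        raise DomainError(
            f"delta_pi = {delta_pi} ppm is at or above the base limit delta_b = {c.delta_b}"
        )
    return c.pka + np.log10((delta_pi - c.delta_a) / (c.delta_b - delta_pi))


def mg_log_argument(delta: float, constants: PhysioConstants | None = None) -> float:
    """The base-10 log argument of the pMg relation (dimensionless)."""
    c = constants or PhysioConstants()
    return (delta - c.mg_shift_low) ** c.mg_exp_num / (c.mg_shift_high - delta) ** c.mg_exp_den


def mg_from_shift(
    delta_batp_pcr: float, constants: PhysioConstants | None = None
) -> tuple[float, float]:
    """(pMg, [Mg²⁺] in molar) from the β-ATP–PCr shift difference (ppm)."""
    c = constants or PhysioConstants()
    if delta_batp_pcr <= c.mg_shift_low:
        raise DomainError(
            f"delta = {delta_batp_pcr} ppm at or below the lower limit {c.mg_shift_low}"
        )
    if delta_batp_pcr >= c.mg_shift_high:
        raise DomainError(
            f"delta = {delta_batp_pcr} ppm at or above the upper limit {c.mg_shift_high}"
        )
    pmg = c.mg_offset - np.log10(mg_log_argument(delta_batp_pcr, c))
    return float(pmg), float(10.0 ** (-pmg))
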