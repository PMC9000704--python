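"""Binding thermodynamics: pKd ↔ ΔG conversion, ligand efficiency, ranking.

The Gibbs relation links the dissociation constant to the binding free
energy: ΔG = −2.303·R·T·pKd, with R = 1.9872 × 10⁻³ kcal/(mol·K). The
conversion constant c = 2.303·R·T (kcal/mol per pKd unit) can be supplied
directly, derived from a temperature, or calibrated from a table of
(pKd, ΔG) pairs by origin-constrained least squares. The packaged 27-ligand
binding table is internally consistent with a single constant c ≈ 1.3503
(T ≈ 295 K), which is the default.

Ligand (binding) efficiency normalizes affinity by molecular size:
LE = ΔG / n_heavy, kcal/mol per heavy atom; more negative is more efficient.
The torsional penalty entering docking-style scoring functions is the product
of a weight factor with the ligand's torsion count, ΔG_torsion = Wtor × Ntor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .compound_data import BindingRecord

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_CONVERSION_CONSTANT",
    "ThermoParams",
    "CalibrationResult",
    "delta_g_from_pkd",
    "pkd_from_delta_g",
    "calibrate_conversion",
    "ligand_efficiency",
    "torsional_energy",
    "rank_by_efficiency",
]

#: Gas constant in kcal/(mol·K).
GAS_CONSTANT_KCAL = 1.9872e-3

#: kcal/mol per pKd unit; calibrated on the packaged binding table (T ≈ 295 K).
DEFAULT_CONVERSION_CONSTANT = 1.3503


@dataclass(frozen=True)
class ThermoParams:
    """Conversion constant c = 2.303·R·T, parameterizable by c or by T (K)."""

    c: float | None = None
    temperature: float | None = None

    def __post_init__(self):
        if self.c is None and self.temperature is None:
            object.__setattr__(self, "c", DEFAULT_CONVERSION_CONSTANT)
        elif self.c is None:
            if self.temperature <= 0:
                raise ValueError("temperature must be positive (K)")
            object.__setattr__(self, "c", 2.303 * GAS_CONSTANT_KCAL * self.temperature)
        elif self.temperature is not None:
            expected = 2.303 * GAS_CONSTANT_KCAL * self.temperature
            if abs(self.c - expected) > 1e-6:
                raise ValueError(
                    f"inconsistent parameters: c={self.c} but 2.303·R·T={expected:.6f}"
                )
        if self.c <= 0:
            raise ValueError("conversion constant must be positive")


def delta_g_from_pkd(pkd: float, params: ThermoParams | None = None) -> float:
    """Binding free energy ΔG = −c·pKd, kcal/mol."""
    if not math.isfinite(pkd):
        raise ValueError("pKd must be finite")
    params = params or ThermoParams()
    return -params.c * pkd


def pkd_from_delta_g(delta_g: float, params: ThermoParams | None = None) -> float:
    """Inverse conversion, pKd = −ΔG / c."""
    if not math.isfinite(delta_g):
        raise ValueError("ΔG must be finite")
    params = params or ThermoParams()
    return -delta_g / params.c


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted conversion constant and per-ligand residuals ΔG + c·pKd."""

    c: float
    residuals: dict[str, float]

    @property
    def max_abs_residual(self) -> float:
        return max((abs(v) for v in self.residuals.values()), default=0.0)


def calibrate_conversion(records: list[BindingRecord]) -> CalibrationResult:
    """Least-squares slope of −ΔG on pKd through the origin.

    c = Σ(−ΔGᵢ·pKdᵢ) / Σ pKdᵢ²; residuals are ΔGᵢ − (−c·pKdᵢ) in kcal/mol.
    """
    if not records:
        raise ValueError("need at least one binding record")
    denom = sum(r.pkd**2 for r in records)
    if denom == 0:
        raise ValueError("degenerate fit: all pKd values are zero")
    c = sum(-r.delta_g * r.pkd for r in records) / denom
    residuals = {r.name: r.delta_g + c * r.pkd for r in records}
    return CalibrationResult(c=c, residuals=residuals)


def ligand_efficiency(delta_g: float, n_heavy: int) -> float:
    """ΔG per heavy atom, kcal/mol; preserves the sign of ΔG."""
    if n_heavy < 1:
        raise ValueError(f"heavy-atom count must be ≥ 1, got {n_heavy}")
    return delta_g / n_heavy


def torsional_energy(wtor: float, ntor: int) -> float:
    """Torsional penalty ΔG_torsion = Wtor × Ntor, kcal/mol."""
    if wtor < 0 or ntor < 0:
        raise ValueError("weight factor and torsion number must be non-negative")
    return wtor * ntor


def rank_by_efficiency(records: list[BindingRecord]) -> list[BindingRecord]:
    """Sort ascending by ligand efficiency (most negative = most efficient first).

    Ties break alphabetically by ligand name.
    """
    return sorted(records, key=lambda r: (r.ligand_efficiency, r.name))
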