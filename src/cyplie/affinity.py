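"""Conversions between IC50, Ki, binding free energy and pKi.

Experimental CYP inhibition data are usually reported as IC50 values from
competitive-inhibition assays.  For a competitive inhibitor the Cheng-Prusoff
relation ``Ki = IC50 / (1 + [S]/Km)`` recovers the inhibition constant, and
the binding free energy follows from ``dG_bind = R T ln(Ki)`` with Ki in
molar units (so dG is negative for sub-molar affinities).

When an assay is run with the probe substrate at its Km — the common design
for CYP screening — the Cheng-Prusoff factor is exactly 2, which is the
default convention used here when no substrate concentration is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GAS_CONSTANT_KJ",
    "DEFAULT_TEMPERATURE",
    "InhibitionMeasurement",
    "ki_from_ic50",
    "dg_from_ki",
    "ki_from_dg",
    "dg_from_ic50",
    "pki_delta_from_dg",
    "read_measurements",
    "write_measurements",
]

#: Molar gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT_KJ = 8.3145e-3

#: Temperature (K) used for all thermodynamic conversions unless overridden;
#: matches the temperature of the MD ensembles the LIE model consumes.
DEFAULT_TEMPERATURE = 300.0


def ki_from_ic50(
    ic50: float,
    substrate_conc: float | None = None,
    km: float | None = None,
) -> float:
    """Cheng-Prusoff conversion of a competitive-inhibition IC50 to Ki.

    Parameters
    ----------
    ic50 : float
        Half-maximal inhibitory concentration (M), > 0.
    substrate_conc, km : float, optional
        Probe-substrate concentration and its Michaelis constant (M).  If
        both are omitted the substrate-at-Km convention ``Ki = IC50/2`` is
        applied.  ``substrate_conc=0`` gives ``Ki = IC50``.

    Returns
    -------
    float
        Inhibition constant Ki in molar units.
    """
    if ic50 <= 0:
        raise ValueError(f"ic50 must be positive, got {ic50}")
    if substrate_conc is None and km is None:
        return ic50 / 2.0
    if substrate_conc is None:
        raise ValueError("substrate_conc required when km is given")
    if substrate_conc < 0:
        raise ValueError(f"substrate_conc must be non-negative, got {substrate_conc}")
    if substrate_conc == 0:
        return ic50
    if km is None or km <= 0:
        raise ValueError("km must be positive when substrate_conc > 0")
    return ic50 / (1.0 + substrate_conc / km)


def dg_from_ki(ki: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy dG_bind = R T ln(Ki), in kJ mol^-1 (Ki in M)."""
    if ki <= 0:
        raise ValueError(f"ki must be positive, got {ki}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT_KJ * temperature * math.log(ki)


def ki_from_dg(dg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`dg_from_ki`: Ki (M) from dG_bind (kJ mol^-1)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return math.exp(dg / (GAS_CONSTANT_KJ * temperature))


def dg_from_ic50(
    ic50: float,
    substrate_conc: float | None = None,
    km: float | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Convenience composition of Cheng-Prusoff and ``RT ln(Ki)``."""
    return dg_from_ki(ki_from_ic50(ic50, substrate_conc, km), temperature)


def pki_delta_from_dg(dg_delta: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Express a free-energy difference (kJ mol^-1) in pKi units.

    Since pKi = -log10(Ki) = -dG / (ln(10) R T), a difference of
    ``dg_delta`` kJ mol^-1 corresponds to ``dg_delta / (ln(10) R T)`` pKi
    units (about 0.8 pKi units for 4.6 kJ mol^-1 at 300 K).
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return dg_delta / (math.log(10.0) * GAS_CONSTANT_KJ * temperature)


@dataclass
class InhibitionMeasurement:
    """One compound's experimental inhibition data (concentrations in M)."""

    compound_id: str
    ic50: float | None = None
    ki: float | None = None
    substrate_conc: float | None = None
    km: float | None = None
    dg_obs: float | None = None

    def __post_init__(self) -> None:
        for name in ("ic50", "ki", "km"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.substrate_conc is not None and self.substrate_conc < 0:
            raise ValueError("substrate_conc must be non-negative")
        if self.ic50 is None and self.ki is None and self.dg_obs is None:
            raise ValueError(
                f"{self.compound_id}: need at least one of ic50, ki or dg_obs"
            )

    def binding_free_energy(self, temperature: float = DEFAULT_TEMPERATURE) -> float:
        """dG_bind (kJ mol^-1), preferring dg_obs > Ki > IC50."""
        if self.dg_obs is not None:
            return self.dg_obs
        if self.ki is not None:
            return dg_from_ki(self.ki, temperature)
        return dg_from_ki(
            ki_from_ic50(self.ic50, self.substrate_conc, self.km), temperature
        )


_COLUMNS = ["compound_id", "ic50_uM", "ki_uM", "substrate_uM", "km_uM", "dg_kjmol"]
_MICRO = 1e-6


def read_measurements(path) -> list[InhibitionMeasurement]:
    """Read a measurement table (CSV; concentrations in μM, dG in kJ/mol)."""
    frame = pd.read_csv(path)
    missing = [c for c in ("compound_id",) if c not in frame.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")

    def _get(row, column, scale=1.0):
        if column not in frame.columns or pd.isna(row[column]):
            return None
        return float(row[column]) * scale

    out = []
    for _, row in frame.iterrows():
        out.append(
            InhibitionMeasurement(
                compound_id=str(row["compound_id"]),
                ic50=_get(row, "ic50_uM", _MICRO),
                ki=_get(row, "ki_uM", _MICRO),
                substrate_conc=_get(row, "substrate_uM", _MICRO),
                km=_get(row, "km_uM", _MICRO),
                dg_obs=_get(row, "dg_kjmol"),
            )
        )
    return out


def write_measurements(measurements, path) -> None:
    """Write measurements to CSV in the same dialect read_measurements reads."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "compound_id": m.compound_id,
                "ic50_uM": None if m.ic50 is None else m.ic50 / _MICRO,
                "ki_uM": None if m.ki is None else m.ki / _MICRO,
                "substrate_uM": None
                if m.substrate_conc is None
                else m.substrate_conc / _MICRO,
                "km_uM": None if m.km is None else m.km / _MICRO,
                "dg_kjmol": m.dg_obs,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
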