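"""Conversion of experimental binding affinities to free energies.

An inhibition constant Ki relates to the standard binding free energy via
dG = RT ln(Ki / c0) with c0 the 1 M standard-state concentration, so the
free energy difference between two ligands measured at the same temperature
is ddG = RT ln(Ki_A / Ki_B), independent of the standard state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import C_STANDARD, R

#: Default assay temperature (K) when a record does not state one.
DEFAULT_ASSAY_TEMPERATURE = 298.15


@dataclass(frozen=True)
class AffinityRecord:
    """One experimental binding measurement.

    ``ki`` is in molar units.  Percent-inhibition results for weak binders
    carry no Ki and hence no free energy; store them with ``ki=None`` and a
    descriptive ``assay_note``.
    """

    compound_id: str
    ki: float | None
    temperature: float = DEFAULT_ASSAY_TEMPERATURE
    assay_note: str = ""

    def __post_init__(self) -> None:
        if self.ki is not None and self.ki <= 0:
            raise ValueError("Ki must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def ki_to_dg(record: AffinityRecord) -> float:
    """Standard binding free energy (kcal/mol) from Ki: dG = RT ln(Ki/1 M)."""
    if record.ki is None:
        raise ValueError(
            f"record '{record.compound_id}' has no Ki (qualitative assay only)"
        )
    return float(R * record.temperature * np.log(record.ki / C_STANDARD))


def ddg_from_ki(record_a: AffinityRecord, record_b: AffinityRecord) -> float:
    """Relative free energy ddG = RT ln(Ki_A / Ki_B), antisymmetric in A<->B."""
    if record_a.temperature != record_b.temperature:
        raise ValueError(
            f"temperature mismatch: {record_a.temperature} K vs "
            f"{record_b.temperature} K"
        )
    if record_a.ki is None or record_b.ki is None:
        raise ValueError("both records need a quantitative Ki")
    return float(R * record_a.temperature * np.log(record_a.ki / record_b.ki))
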