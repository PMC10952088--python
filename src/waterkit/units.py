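"""Physical constants and unit conversions.

All analysis code works in canonical internal units of Å (length) and ps
(time); conversions happen exactly once, at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Bohr radius in Å (CODATA).
BOHR_TO_ANGSTROM = 0.529177210903

#: One atomic unit of time in ps (CODATA: 2.4188843265857e-17 s).
AU_TIME_TO_PS = 2.4188843265857e-5

#: Boltzmann constant, J/K.
KB_J_PER_K = 1.380649e-23

#: Boltzmann constant in MD-friendly units: amu Å²/ps² per K
#: (1 amu Å²/ps² = 1.66053906660e-23 J).
KB_AMU_A2_PS2 = KB_J_PER_K / 1.66053906660e-23

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: 1 Å²/ps expressed in 1e-9 m²/s (1 Å²/ps = 1e-20 m² / 1e-12 s = 1e-8 m²/s).
A2_PER_PS_TO_1E9_M2_S = 10.0

#: Atomic masses (amu) used for centre-of-mass conventions.
MASS_O = 15.999
MASS_H = 1.008
MASS_D = 2.014

#: Molar mass of H2O and D2O, g/mol.
MOLAR_MASS_H2O = 18.015
MOLAR_MASS_D2O = 20.027

LENGTH_FACTORS = {"angstrom": 1.0, "bohr": BOHR_TO_ANGSTROM}
TIME_FACTORS = {"ps": 1.0, "fs": 1e-3, "au": AU_TIME_TO_PS}


@dataclass(frozen=True)
class UnitSystem:
    """Length/time unit tag attached to raw trajectory files.

    Conversion factors are applied exactly once on ingest; everything
    downstream sees Å and ps.
    """

    length: str = "angstrom"
    time: str = "ps"

    def __post_init__(self) -> None:
        if self.length not in LENGTH_FACTORS:
            raise ValueError(f"unknown length unit {self.length!r}")
        if self.time not in TIME_FACTORS:
            raise ValueError(f"unknown time unit {self.time!r}")

    @property
    def length_to_angstrom(self) -> float:
        return LENGTH_FACTORS[self.length]

    @property
    def time_to_ps(self) -> float:
        return TIME_FACTORS[self.time]
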