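"""Global reactivity descriptors from frontier-orbital energies.

Koopmans' theorem equates the ionization potential with −E_HOMO and the
electron affinity with −E_LUMO; from these the standard conceptual-DFT
descriptors follow:

    ΔE_HL = E_LUMO − E_HOMO        (gap; larger ⇒ kinetically more stable)
    η  = (I − A) / 2               (chemical hardness)
    S  = 1 / η                     (softness)
    χ  = (I + A) / 2               (electronegativity)
    μ  = −χ                        (chemical potential)
    ω  = μ² / (2η)                 (electrophilicity index, textbook form)

Published tables of these quantities sometimes follow a second
electrophilicity convention, ω = μ²·η/2; the two coincide only at η = 1 and
differ by a factor η² otherwise.  Both are computed and reported
(``electrophilicity_stated`` for μ²/(2η), ``electrophilicity_table`` for
μ²·η/2) so a caller can match either convention explicitly.

No unit conversion is performed: outputs are in whatever energy units the
orbital energies were supplied in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class OrbitalEnergies:
    """Frontier-orbital energies for one compound (same units for both)."""

    compound_id: str
    e_homo: float
    e_lumo: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.e_homo) and np.isfinite(self.e_lumo)):
            raise ValidationError("orbital energies must be finite")
        if self.e_homo >= self.e_lumo:
            warnings.warn(
                f"{self.compound_id}: E_HOMO >= E_LUMO (inverted orbitals?)", stacklevel=2
            )


@dataclass(frozen=True)
class ReactivityDescriptors:
    compound_id: str
    ionization_potential: float
    electron_affinity: float
    energy_gap: float
    hardness: float
    softness: float  # NaN when hardness is 0
    electronegativity: float
    chemical_potential: float
    electrophilicity_stated: float  # μ²/(2η); NaN when hardness is 0
    electrophilicity_table: float  # μ²·η/2
    undefined: bool  # True when hardness = 0 (softness/ω_stated undefined)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def koopmans(e: OrbitalEnergies) -> ReactivityDescriptors:
    """All global reactivity descriptors for one compound."""
    ip = -e.e_homo
    ea = -e.e_lumo
    gap = e.e_lumo - e.e_homo
    eta = (ip - ea) / 2.0
    chi = (ip + ea) / 2.0
    mu = -chi
    if eta == 0.0:
        warnings.warn(
            f"{e.compound_id}: hardness is 0; softness and stated electrophilicity undefined",
            stacklevel=2,
        )
        softness = np.nan
        omega_stated = np.nan
        undefined = True
    else:
        if eta < 0:
            warnings.warn(f"{e.compound_id}: negative hardness (inverted orbitals)", stacklevel=2)
        softness = 1.0 / eta
        omega_stated = mu**2 / (2.0 * eta)
        undefined = False
    omega_table = mu**2 * eta / 2.0
    return ReactivityDescriptors(
        compound_id=e.compound_id,
        ionization_potential=ip,
        electron_affinity=ea,
        energy_gap=gap,
        hardness=eta,
        softness=softness,
        electronegativity=chi,
        chemical_potential=mu,
        electrophilicity_stated=omega_stated,
        electrophilicity_table=omega_table,
        undefined=undefined,
    )


def reactivity_table(energies: list[OrbitalEnergies]) -> pd.DataFrame:
    """One row per compound, sorted by energy gap descending (ties by id)."""
    ids = [e.compound_id for e in energies]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate compound ids in reactivity input")
    rows = [koopmans(e).to_dict() for e in energies]
    columns = [
        "compound_id",
        "ionization_potential",
        "electron_affinity",
        "energy_gap",
        "hardness",
        "softness",
        "electronegativity",
        "chemical_potential",
        "electrophilicity_stated",
        "electrophilicity_table",
        "undefined",
    ]
    table = pd.DataFrame(rows, columns=columns)
    table = table.sort_values(
        ["energy_gap", "compound_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table.insert(1, "rank", np.arange(1, len(table) + 1))
    return table


def read_orbital_energies(path) -> list[OrbitalEnergies]:
    """CSV columns: compound_id, e_homo, e_lumo."""
    df = pd.read_csv(path)
    for col in ("compound_id", "e_homo", "e_lumo"):
        if col not in df.columns:
            raise ValidationError(f"orbital-energy CSV lacks column {col!r}")
    return [
        OrbitalEnergies(str(r.compound_id), float(r.e_homo), float(r.e_lumo))
        for r in df.itertuples()
    ]
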