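"""Binding-free-energy post-processing.

An MM-GBSA-style estimate of the binding free energy is the minimized energy
of the complex minus the sum of the minimized energies of the isolated
receptor and the unbound ligand:

    ΔG_bind = E_complex − (E_ligand + E_receptor)   [kcal/mol]

More negative is more favourable.  Given a table of ΔG_bind values and a
reference compound, ``rank_vs_reference`` sorts ascending by ΔG_bind and
adds ΔΔG = ΔG_bind(compound) − ΔG_bind(reference), which is invariant to
shifting every energy by a constant.  Any energy-decomposition columns are
carried through untouched; they are metadata, never re-summed to ΔG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import ID_COL

DG_COL = "dg_bind"
DDG_COL = "ddg_vs_reference"


@dataclass(frozen=True)
class EnergyTriple:
    """Minimized energies (kcal/mol) of complex, receptor and free ligand."""

    compound_id: str
    e_complex_minimized: float
    e_receptor_minimized: float
    e_ligand_minimized: float

    def __post_init__(self) -> None:
        values = (self.e_complex_minimized, self.e_receptor_minimized, self.e_ligand_minimized)
        if not all(np.isfinite(v) for v in values):
            raise ValidationError(f"{self.compound_id}: non-finite energy")


def dg_bind(t: EnergyTriple) -> float:
    """ΔG_bind = E_complex − (E_ligand + E_receptor), kcal/mol."""
    return t.e_complex_minimized - (t.e_ligand_minimized + t.e_receptor_minimized)


def binding_table(triples: list[EnergyTriple]) -> pd.DataFrame:
    ids = [t.compound_id for t in triples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate compound ids in binding input")
    return pd.DataFrame({ID_COL: ids, DG_COL: [dg_bind(t) for t in triples]})


def rank_vs_reference(table: pd.DataFrame, reference_id: str) -> pd.DataFrame:
    """Sort ascending by ΔG_bind (ties by id) and add ΔΔG vs the reference."""
    for col in (ID_COL, DG_COL):
        if col not in table.columns:
            raise ValidationError(f"binding table lacks column {col!r}")
    ref = table[table[ID_COL] == reference_id]
    if not len(ref):
        raise ValidationError(f"reference compound {reference_id!r} not in table")
    ref_dg = float(ref[DG_COL].iloc[0])
    out = table.copy()
    out[DDG_COL] = out[DG_COL] - ref_dg
    out = out.sort_values([DG_COL, ID_COL], kind="stable").reset_index(drop=True)
    out.insert(1, "rank", np.arange(1, len(out) + 1))
    return out
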