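"""Biomass reaction and RNA-seq-derived proteome allocation.

The cell-mass reaction converts ATP to ADP + Pi at a first-order rate and
deposits ``yield_g_per_mol_atp`` grams of biomass per mole of ATP consumed.
A fixed fraction of that biomass (63% by default) is protein, apportioned
among the methanogenic enzymes by RNA-seq-derived mass fractions, which
fixes a stoichiometry of micromoles of each enzyme produced per mole of
ATP.  Enzyme concentrations are an algebraic function of the current cell
mass (stoichiometry x mass / yield), which is exactly equivalent to
carrying each enzyme as a separate linearly-coupled ODE state and keeps the
initial enzyme levels consistent with the initial mass.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneExpressionTable",
    "ProteomeAllocation",
    "mass_fractions",
    "stoichiometry_from_fractions",
    "enzyme_concentrations",
    "cell_mass_rate",
    "load_allocation",
]

#: default growth parameters
PROTEIN_MASS_FRACTION = 0.63
YIELD_G_PER_MOL_ATP = 15.4
GROWTH_RATE_PER_HR = 0.125


@dataclass
class GeneExpressionTable:
    """Per-gene averaged RPKM values with molecular weights (kDa).

    ``table`` holds columns ``gene``, ``rpkm``, ``mw_kda``, ``enzyme``; the
    ``enzyme`` column assigns each gene to an enzyme complex of the kinetic
    model.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "rpkm", "mw_kda", "enzyme"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"expression table lacks columns {sorted(missing)}")
        if (self.table["rpkm"] < 0).any():
            raise ValueError("RPKM values must be non-negative")
        if (self.table["mw_kda"] <= 0).any():
            raise ValueError("molecular weights must be positive")

    @classmethod
    def from_tsv(cls, path: str) -> "GeneExpressionTable":
        return cls(pd.read_csv(path, sep="\t"))


def mass_fractions(expr: GeneExpressionTable) -> pd.Series:
    """RPKM-weighted protein mass fractions, one per enzyme complex.

    ``a_i = m_i * RPKM_i / sum_j m_j * RPKM_j`` per gene, summed within each
    enzyme complex; the fractions sum to 1.
    """
    df = expr.table
    if len(df) == 0:
        raise ValueError("expression table is empty")
    weight = df["mw_kda"].to_numpy() * df["rpkm"].to_numpy()
    total = weight.sum()
    if total <= 0:
        raise ValueError("all RPKM values are zero: mass fractions undefined")
    per_gene = pd.Series(weight / total, index=df["enzyme"].to_numpy())
    return per_gene.groupby(level=0).sum()


@dataclass
class ProteomeAllocation:
    """Per-enzyme stoichiometries in the cell-mass reaction.

    ``stoichiometries`` maps enzyme name to micromoles of enzyme produced
    per mole of ATP consumed by growth.
    """

    stoichiometries: dict[str, float]
    condition: str = "custom"
    protein_mass_fraction: float = PROTEIN_MASS_FRACTION
    yield_g_per_mol_atp: float = YIELD_G_PER_MOL_ATP
    growth_rate_per_hr: float = GROWTH_RATE_PER_HR
    molecular_weights_kda: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.stoichiometries.values()):
            raise ValueError("stoichiometries must be non-negative")
        if not 0 < self.protein_mass_fraction <= 1:
            raise ValueError("protein_mass_fraction must lie in (0, 1]")
        if self.yield_g_per_mol_atp <= 0:
            raise ValueError("yield must be positive")

    @property
    def growth_rate_per_s(self) -> float:
        return self.growth_rate_per_hr / 3600.0

    def enzyme_concentration(self, enzyme: str, cell_mass_mg: float,
                             volume_ml: float = 1.0) -> float:
        return enzyme_concentrations(cell_mass_mg, self, volume_ml)[enzyme]


def stoichiometry_from_fractions(
    fractions: Mapping[str, float],
    molecular_weights_kda: Mapping[str, float],
    protein_mass_fraction: float = PROTEIN_MASS_FRACTION,
    yield_g_per_mol_atp: float = YIELD_G_PER_MOL_ATP,
    condition: str = "custom",
) -> ProteomeAllocation:
    """Convert protein mass fractions to umol enzyme per mol ATP.

    Each mole of ATP routed through growth yields
    ``protein_mass_fraction * yield`` grams of protein, apportioned by mass
    fraction and divided by molecular weight (kDa -> g/mol via x1000):
    ``umol/mol = a_i * 0.63 * 15.4 / (mw_kda * 1000) * 1e6``.
    """
    total = float(sum(fractions.values()))
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"mass fractions must sum to 1 (got {total:.6g})")
    grams_protein = protein_mass_fraction * yield_g_per_mol_atp
    stoich = {}
    for enzyme, a in fractions.items():
        mw = molecular_weights_kda[enzyme]
        if mw <= 0:
            raise ValueError(f"non-positive molecular weight for {enzyme!r}")
        stoich[enzyme] = a * grams_protein / (mw * 1000.0) * 1e6
    return ProteomeAllocation(
        stoichiometries=stoich,
        condition=condition,
        protein_mass_fraction=protein_mass_fraction,
        yield_g_per_mol_atp=yield_g_per_mol_atp,
        molecular_weights_kda=dict(molecular_weights_kda),
    )


def enzyme_concentrations(
    cell_mass_mg: float, alloc: ProteomeAllocation, volume_ml: float = 1.0
) -> dict[str, float]:
    """Enzyme concentrations (mM) implied by the current cell mass.

    ATP-equivalents of the standing biomass are ``mass/yield``; each
    enzyme's moles are its stoichiometry times that, diluted in the culture
    volume.  In 1 mL this reduces to ``stoich_umol_per_mol * mass_mg /
    (yield * 1000)`` mM.
    """
    if cell_mass_mg < 0:
        raise ValueError("cell mass must be non-negative")
    mol_atp = cell_mass_mg * 1e-3 / alloc.yield_g_per_mol_atp
    out = {}
    for enzyme, stoich in alloc.stoichiometries.items():
        moles = stoich * 1e-6 * mol_atp
        out[enzyme] = moles / (volume_ml * 1e-3) * 1e3  # mol/L -> mM
    return out


def cell_mass_rate(
    atp_mM: float, alloc: ProteomeAllocation, volume_ml: float = 1.0
) -> tuple[float, float]:
    """Instantaneous biomass production from the first-order growth reaction.

    Returns ``(mass_rate_mg_per_s, atp_consumption_mM_per_s)``.  The ATP
    flux is ``k*[ATP]`` with ``k = 0.125/hr``; each mM/s of ATP in
    ``volume_ml`` is ``volume_ml`` umol/s, yielding
    ``flux * yield * volume_ml * 1e-3`` mg/s of biomass.
    """
    if atp_mM < 0:
        raise ValueError("ATP concentration must be non-negative")
    flux = alloc.growth_rate_per_s * atp_mM  # mM/s
    mass_rate = flux * volume_ml * alloc.yield_g_per_mol_atp * 1e-3  # mg/s
    return mass_rate, flux


def load_allocation(condition_or_path: str) -> ProteomeAllocation:
    """Load a packaged (``"methanol"``/``"acetate"``) or custom allocation TSV."""
    if condition_or_path in ("methanol", "acetate"):
        resource = f"table2_{condition_or_path}.tsv"
        with importlib.resources.as_file(
            importlib.resources.files("methanokin.data") / resource
        ) as path:
            df = pd.read_csv(path, sep="\t")
        condition = condition_or_path
    else:
        df = pd.read_csv(condition_or_path, sep="\t")
        condition = "custom"
    stoich = dict(zip(df["enzyme"], df["umol_per_mol_atp"].astype(float)))
    return ProteomeAllocation(stoichiometries=stoich, condition=condition)
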