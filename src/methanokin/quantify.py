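"""Copy-number arithmetic for single-molecule pulldown (SiMPull) data.

SiMPull counts fluorescent spots of an antibody-captured protein on a
slide; a linear calibration maps spot counts to lysate concentration, and
dividing by the culture's cell density gives mean copies per cell.  An
independent estimate comes from the proteome route: dry mass x protein
fraction x the enzyme's proteome mass fraction, converted through its
molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AVOGADRO",
    "Calibration",
    "CopyNumberEstimate",
    "calibrate",
    "copies_per_cell",
    "proteome_fraction_estimate",
]

# Avogadro constant fixed at the rounded 6.023e23/mol: the published
# per-cell counts (10038 and 18135 for the ribosome rows) reproduce
# exactly only with this value.
AVOGADRO = 6.023e23


@dataclass
class Calibration:
    """Least-squares line mapping lysate concentration (nM) to spot count."""

    slope: float  # spots per nM
    intercept: float  # spots
    r_squared: float = float("nan")
    stderr_slope: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def predict_spots(self, conc_nM: float) -> float:
        return self.slope * conc_nM + self.intercept

    def concentration(self, spots: float) -> float:
        """Invert the line: concentration (nM) for an observed spot count."""
        return (spots - self.intercept) / self.slope


def calibrate(spot_counts: Sequence[tuple[float, float]]) -> Calibration:
    """Fit the spots-vs-concentration line with a free intercept.

    ``spot_counts`` is an iterable of ``(concentration_nM, spots)`` pairs
    covering at least two distinct concentrations.
    """
    arr = np.asarray(list(spot_counts), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (concentration, spots) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct concentrations")
    res = stats.linregress(x, y)
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr_slope=float(res.stderr),
        n_points=len(x),
    )


@dataclass
class CopyNumberEstimate:
    """Per-cell copy number with uncertainty propagated in quadrature."""

    conc_nM: float
    conc_sd_nM: float
    cells_per_ml: float
    cells_sd_per_ml: float
    copies: float
    copies_sd: float

    def __post_init__(self) -> None:
        if min(self.conc_nM, self.cells_per_ml, self.copies) < 0:
            raise ValueError("central values must be non-negative")
        if min(self.conc_sd_nM, self.cells_sd_per_ml, self.copies_sd) < 0:
            raise ValueError("uncertainties must be non-negative")


def copies_per_cell(
    conc_nM: float,
    cells_per_ml: float,
    conc_sd_nM: float = 0.0,
    cells_sd_per_ml: float = 0.0,
) -> CopyNumberEstimate:
    """Mean copies per cell from lysate concentration and cell density.

    ``copies = conc * 1e-9 mol/L * N_A * 1e-3 L / cells_per_mL``; relative
    uncertainties of the two inputs combine in quadrature.
    """
    if conc_nM < 0:
        raise ValueError("concentration must be non-negative")
    if cells_per_ml <= 0:
        raise ValueError("cell density must be positive")
    copies = conc_nM * 1e-9 * AVOGADRO * 1e-3 / cells_per_ml
    rel = 0.0
    if conc_nM > 0 and conc_sd_nM > 0:
        rel += (conc_sd_nM / conc_nM) ** 2
    if cells_sd_per_ml > 0:
        rel += (cells_sd_per_ml / cells_per_ml) ** 2
    return CopyNumberEstimate(
        conc_nM=conc_nM,
        conc_sd_nM=conc_sd_nM,
        cells_per_ml=cells_per_ml,
        cells_sd_per_ml=cells_sd_per_ml,
        copies=copies,
        copies_sd=copies * np.sqrt(rel),
    )


def proteome_fraction_estimate(
    dry_mass_mg_per_ml: float,
    protein_fraction: float,
    enzyme_mass_fraction: float,
    mw_kda: float,
    cells_per_ml: float,
) -> tuple[float, float, float]:
    """Copy number from the proteome-mass route.

    Returns ``(ug_per_ml, pmol_per_ml, copies_per_cell)``:
    ``ug/mL = dry_mass * protein_fraction * enzyme_fraction * 1000``;
    ``pmol/mL = ug/mL / mw_kda * 1000``; copies via Avogadro and the cell
    density.
    """
    for name, v in [("dry_mass_mg_per_ml", dry_mass_mg_per_ml),
                    ("protein_fraction", protein_fraction),
                    ("mw_kda", mw_kda), ("cells_per_ml", cells_per_ml)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if enzyme_mass_fraction < 0:
        raise ValueError("enzyme_mass_fraction must be non-negative")
    ug_per_ml = dry_mass_mg_per_ml * protein_fraction * enzyme_mass_fraction * 1e3
    pmol_per_ml = ug_per_ml / (mw_kda * 1e3) * 1e6
    copies = pmol_per_ml * 1e-12 * AVOGADRO / cells_per_ml
    return ug_per_ml, pmol_per_ml, copies
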