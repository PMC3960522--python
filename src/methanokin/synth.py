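"""Seed-deterministic synthetic data with the structure each stage assumes.

Four generators stand in for the study's raw data so the entire pipeline
is testable offline: RPKM expression tables, noisy substrate/cell-mass
growth curves (simulated from the kinetic model itself, with ground-truth
parameters recorded), SiMPull spot-count tables around a known calibration
line, and DIC-like phantom images of ellipsoidal cells.  Every generator
emits ground truth alongside the data and is reproducible from its seed.

The DIC appearance model renders each cell as the directional derivative
of a blurred ellipse-indicator (optical path length) field along the shear
axis — the minimal model under which Hilbert enhancement is the correct
inverse — plus white Gaussian noise at a stated SNR.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .growth import GeneExpressionTable, load_allocation
from .network import ReactionNetwork
from .simulate import KineticGrowthModel, Scenario

__all__ = [
    "gen_rpkm",
    "gen_growth_curve",
    "gen_simpull",
    "gen_dic_phantom",
]

#: default cell-size distributions (um): means from DIC morphometry of
#: methanol- and acetate-grown cells; SDs chosen as ~15% of the mean,
#: typical of single-cell size scatter
CELL_SIZE_DEFAULTS = {
    "methanol": dict(length=(2.9, 0.4), width=(2.3, 0.3)),
    "acetate": dict(length=(2.3, 0.32), width=(1.7, 0.24)),
}


def gen_rpkm(
    n_genes: int,
    dispersion: float = 1.0,
    seed: int = 0,
    median_rpkm: float = 100.0,
) -> GeneExpressionTable:
    """Log-normal RPKM table with molecular weights and enzyme assignments.

    RPKM ~ LogNormal(log(median), dispersion); molecular weights uniform
    in [20, 600] kDa; genes are assigned round-robin to the enzyme
    complexes of the packaged allocation table.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    enzymes = sorted(load_allocation("methanol").stoichiometries)
    rpkm = np.exp(rng.normal(np.log(median_rpkm), dispersion, n_genes))
    mw = rng.uniform(20.0, 600.0, n_genes)
    df = pd.DataFrame(
        {
            "gene": [f"gene{i:04d}" for i in range(n_genes)],
            "rpkm": rpkm,
            "mw_kda": mw,
            "enzyme": [enzymes[i % len(enzymes)] for i in range(n_genes)],
        }
    )
    return GeneExpressionTable(df)


def gen_growth_curve(
    scenario: Scenario,
    params: Mapping[str, float] | None,
    noise_sd: float,
    n_points: int,
    seed: int = 0,
    network: ReactionNetwork | None = None,
) -> pd.DataFrame:
    """Noisy substrate/cell-mass observations simulated from the model.

    ``params`` optionally overrides reaction ``k_cat`` values (these are
    the recorded ground truth for recovery experiments).  ``noise_sd`` is
    the additive Gaussian noise sd expressed as a fraction of each series'
    maximum; observations are clipped at zero.  Returns a DataFrame with
    columns ``time_h``, ``substrate_mM``, ``mass_mg_per_ml`` plus the
    truth in ``df.attrs``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_points < 2:
        raise ValueError("need at least two observation times")
    from .fitcal import _network_with_kcats
    from .network import default_network

    net = network if network is not None else default_network()
    if params:
        net = _network_with_kcats(net, params)
    scen = scenario.replace(stop_at_exhaustion=False)
    model = KineticGrowthModel(net, None, scen)
    t_obs = np.linspace(0.0, scen.duration_h, n_points + 1)[1:]
    tc = model.simulate(t_eval=np.concatenate([[0.0], t_obs]))
    sim = tc.data.set_index("time_h")
    sub = np.interp(t_obs, sim.index, sim[scen.substrate].to_numpy())
    mass = np.interp(t_obs, sim.index, sim["cell_mass_mg"].to_numpy())

    rng = np.random.default_rng(seed)
    sub_noisy = sub + rng.normal(0.0, noise_sd * np.max(np.abs(sub)),
                                 len(sub)) if noise_sd else sub.copy()
    mass_noisy = mass + rng.normal(0.0, noise_sd * np.max(np.abs(mass)),
                                   len(mass)) if noise_sd else mass.copy()
    df = pd.DataFrame(
        {
            "time_h": t_obs,
            "substrate_mM": np.maximum(sub_noisy, 0.0),
            "mass_mg_per_ml": np.maximum(mass_noisy, 0.0),
        }
    )
    df.attrs["truth"] = dict(params or {})
    df.attrs["noise_sd"] = noise_sd
    df.attrs["seed"] = seed
    return df


def gen_simpull(
    true_conc_nM: float | Sequence[float],
    calibration: tuple[float, float],
    n_fields: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson spot counts per imaging field around a calibration line.

    ``calibration`` is ``(slope_spots_per_nM, intercept_spots)``; each of
    ``n_fields`` fields per concentration draws
    ``Poisson(slope*conc + intercept)``.  Returns columns ``conc_nM``,
    ``field``, ``spots``.
    """
    slope, intercept = calibration
    concs = np.atleast_1d(np.asarray(true_conc_nM, dtype=float))
    if np.any(concs < 0):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for c in concs:
        lam = max(slope * c + intercept, 0.0)
        counts = rng.poisson(lam, n_fields)
        for f, k in enumerate(counts):
            rows.append(dict(conc_nM=c, field=f, spots=int(k)))
    df = pd.DataFrame(rows)
    df.attrs["truth"] = dict(slope=slope, intercept=intercept)
    return df


def _sample_cells(rng, n_cells, length_mean_sd, width_mean_sd,
                  shape, pixel_size_um, margin_px):
    """Rejection-sample non-overlapping cell centres and sizes."""
    cells = []
    attempts = 0
    while len(cells) < n_cells and attempts < 200 * max(n_cells, 1):
        attempts += 1
        L = rng.normal(*length_mean_sd)
        W = rng.normal(*width_mean_sd)
        if L <= 0.5 or W <= 0.3:
            continue
        if W > L:
            L, W = W, L
        theta = rng.uniform(0, np.pi)
        r = rng.uniform(margin_px, shape[0] - margin_px)
        c = rng.uniform(margin_px, shape[1] - margin_px)
        rad = L / 2 / pixel_size_um
        if any(np.hypot(r - r0, c - c0) < rad + L0 / 2 / pixel_size_um + 4
               for r0, c0, L0 in ((x["row"], x["col"], x["length_um"])
                                  for x in cells)):
            continue
        cells.append(dict(row=r, col=c, length_um=L, width_um=W,
                          orientation_rad=theta))
    return cells


def gen_dic_phantom(
    n_cells: int,
    length_mean_sd: tuple[float, float] = CELL_SIZE_DEFAULTS["methanol"]["length"],
    width_mean_sd: tuple[float, float] = CELL_SIZE_DEFAULTS["methanol"]["width"],
    shear_axis_degrees: float = 45.0,
    snr: float = 10.0,
    image_size: int = 512,
    seed: int = 0,
    pixel_size_um: float = 0.1,
    blur_sigma_px: float = 1.5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """DIC-like phantom image of ellipsoidal cells with ground truth.

    The optical-path field is a sum of ellipse indicators blurred by
    ``blur_sigma_px`` (optical resolution); the image is its directional
    derivative along the shear axis plus Gaussian noise with sd =
    (signal RMS)/snr.  The truth table lists each cell's centre, axes and
    orientation.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    shape = (image_size, image_size)
    margin = int(np.ceil((length_mean_sd[0] + 4 * length_mean_sd[1])
                         / pixel_size_um / 2)) + 2
    cells = _sample_cells(rng, n_cells, length_mean_sd, width_mean_sd,
                          shape, pixel_size_um, margin)

    field = np.zeros(shape)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for cell in cells:
        a = cell["length_um"] / 2 / pixel_size_um
        b = cell["width_um"] / 2 / pixel_size_um
        th = cell["orientation_rad"]
        dr = rr - cell["row"]
        dc = cc - cell["col"]
        u = dc * np.cos(th) + dr * np.sin(th)
        v = -dc * np.sin(th) + dr * np.cos(th)
        field[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = 1.0
    field = ndimage.gaussian_filter(field, blur_sigma_px)

    gr, gc = np.gradient(field)
    phi = np.deg2rad(shear_axis_degrees)
    image = gc * np.cos(phi) + gr * np.sin(phi)
    signal_rms = np.sqrt(np.mean(image**2))
    noise_scale = (signal_rms / snr) if signal_rms > 0 else (1.0 / snr)
    image = image + rng.normal(0.0, noise_scale, shape)

    truth = pd.DataFrame(cells, columns=["row", "col", "length_um",
                                         "width_um", "orientation_rad"])
    truth.attrs["pixel_size_um"] = pixel_size_um
    truth.attrs["shear_axis_degrees"] = shear_axis_degrees
    truth.attrs["snr"] = snr
    return image, truth
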