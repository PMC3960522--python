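"""Assemble and integrate the biomass-coupled methanogenesis ODE system.

The state vector holds the concentrations (mM) of every dynamic species in
a fixed 1 mL compartment plus the cell mass (mg).  Enzyme concentrations
are computed algebraically from the current cell mass at every right-hand-
side evaluation, so enzymes accumulate as the culture grows; the cell-mass
reaction consumes ATP first order and deposits biomass at the fixed yield.

The entry points follow a model/results pattern: a
:class:`KineticGrowthModel` is built from a network, a proteome allocation,
and a :class:`Scenario`; ``simulate()`` returns a :class:`TimeCourse` from
which the observables (peak methane production rate, cumulative
CH4:CO2 efflux ratio, peak specific growth rate) are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .growth import ProteomeAllocation, load_allocation
from .network import (
    CONSERVED_POOLS,
    ReactionNetwork,
    default_network,
)

__all__ = [
    "Scenario",
    "TimeCourse",
    "KineticGrowthModel",
    "IntegrationError",
    "assemble",
    "run",
    "methane_rate",
    "efflux_ratio",
]

#: species initialised at the carrier pool concentration ("base" mode):
#: the free/oxidised member of each conserved pool
_BASE_CARRIERS = ("CoM", "CoB", "CoA", "H4SPT", "F420", "Fd_ox", "Mphen", "Mfr")

#: numerical depletion guard half-point (mM) applied to non-kinetic
#: reactants so that a constant-flux side reaction shuts off smoothly as
#: its supply vanishes instead of driving the pool negative
_GUARD_EPS = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid state."""

    def __init__(self, message: str, last_time: float | None = None,
                 last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


class ConfigurationError(ValueError):
    """Raised when network, allocation and scenario are inconsistent."""


@dataclass
class Scenario:
    """Initial conditions and solver settings for one growth simulation.

    Defaults follow the study conditions: growth on 125 mM methanol (or
    120 mM acetate via :meth:`acetate`), 0.1 mg initial cell mass in 1 mL,
    ATP/ADP/Pi at 10/1/10 mM, each carrier pool at 0.009 mM, extracellular
    pH 7.  ``h_per_atp`` is the number of translocated ions consumed per
    ATP by ATP synthase (4 by default; 3.5 is the variant stoichiometry).
    ``pool_translocated_ions`` routes pumped Na+ into the same
    extracellular ion pool that drives ATP synthase (a chemiosmotic
    equivalence; see the methods note) — without it the sodium gradient
    built by Rnf and Mtr is wasted and acetoclastic growth is
    energetically impossible.
    """

    substrate: str = "MeOH"
    substrate_mM: float = 125.0
    condition: str = "methanol"
    initial_cell_mass_mg: float = 0.1
    atp_mM: float = 10.0
    adp_mM: float = 1.0
    pi_mM: float = 10.0
    carrier_mM: float = 0.009
    carrier_init: str = "base"  # "base": free forms only; "all": every carrier
    extracellular_pH: float = 7.0
    duration_h: float = 150.0
    h_per_atp: float = 4.0
    pool_translocated_ions: bool = True
    stop_at_exhaustion: bool = True
    exhaustion_mM: float = 1e-3
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    sample_h: float = 0.01

    def __post_init__(self) -> None:
        for name in ("substrate_mM", "initial_cell_mass_mg", "atp_mM",
                     "adp_mM", "pi_mM", "carrier_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.carrier_init not in ("base", "all"):
            raise ValueError("carrier_init must be 'base' or 'all'")

    @classmethod
    def methanol(cls, **kwargs) -> "Scenario":
        return cls(**kwargs)

    @classmethod
    def acetate(cls, **kwargs) -> "Scenario":
        defaults = dict(substrate="Ac", substrate_mM=120.0, condition="acetate")
        defaults.update(kwargs)
        return cls(**defaults)

    def replace(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


class TimeCourse:
    """Solution of one growth simulation.

    ``data`` is a DataFrame with columns ``time_h``, one column per dynamic
    species (mM), ``cell_mass_mg``, ``ch4_cum_umol`` and ``co2_cum_umol``
    (net gas amounts in the 1 mL compartment).
    """

    def __init__(self, data: pd.DataFrame, scenario: Scenario,
                 species: Sequence[str]):
        if not np.all(np.diff(data["time_h"].to_numpy()) > 0):
            raise ValueError("time grid must be strictly increasing")
        self.data = data
        self.scenario = scenario
        self.species = list(species)

    @property
    def time_h(self) -> np.ndarray:
        return self.data["time_h"].to_numpy()

    @property
    def cell_mass_mg(self) -> np.ndarray:
        return self.data["cell_mass_mg"].to_numpy()

    def concentration(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def pool_totals(self) -> pd.DataFrame:
        """Totals of each conserved carrier pool along the trajectory."""
        cols = {}
        for pool, members in CONSERVED_POOLS.items():
            present = [m for m in members if m in self.data.columns]
            cols[pool] = self.data[present].sum(axis=1)
        return pd.DataFrame(cols, index=self.data.index)

    def specific_growth_rate(self) -> np.ndarray:
        """d(ln mass)/dt in 1/h along the time grid."""
        mass = np.maximum(self.cell_mass_mg, 1e-12)
        return np.gradient(np.log(mass), self.time_h)

    def peak_specific_growth_rate(self) -> float:
        return float(np.max(self.specific_growth_rate()))

    def methane_rate(self) -> float:
        return methane_rate(self)

    def efflux_ratio(self) -> float:
        return efflux_ratio(self)

    def to_csv(self, path: str) -> None:
        self.data.to_csv(path, index=False)

    def plot(self, ax=None):
        """Substrate, cumulative gases and cell mass against time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.time_h
        ax.plot(t, self.concentration(self.scenario.substrate),
                label=f"{self.scenario.substrate} (mM)")
        ax.plot(t, self.data["ch4_cum_umol"], label="CH4 (umol)")
        ax.plot(t, self.data["co2_cum_umol"], label="CO2 (umol)")
        ax2 = ax.twinx()
        ax2.plot(t, self.cell_mass_mg, color="k", ls="--", label="mass (mg)")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("mM / umol")
        ax2.set_ylabel("cell mass (mg)")
        ax.legend(loc="best")
        return ax


def methane_rate(tc: TimeCourse) -> float:
    """Peak methane production rate in nmol/mL/min.

    Central differences of cumulative CH4 on the solver's dense output; no
    further smoothing.  The maximum over the trajectory is the
    exponential-phase peak.
    """
    t = tc.time_h
    if len(t) < 3:
        raise ValueError("too few samples to resolve a methane rate")
    ch4 = tc.data["ch4_cum_umol"].to_numpy()
    rate_umol_per_h = np.gradient(ch4, t)
    return float(np.max(rate_umol_per_h) * 1000.0 / 60.0)


def efflux_ratio(tc: TimeCourse) -> float:
    """Cumulative CH4 / cumulative CO2 at the final time."""
    ch4 = float(tc.data["ch4_cum_umol"].iloc[-1])
    co2 = float(tc.data["co2_cum_umol"].iloc[-1])
    if co2 <= 0:
        raise ZeroDivisionError("no CO2 effluxed: ratio undefined")
    return ch4 / co2


class KineticGrowthModel:
    """Biomass-coupled kinetic model of methanogenesis.

    Parameters
    ----------
    network :
        validated :class:`~methanokin.network.ReactionNetwork`; defaults to
        the packaged reaction table.
    allocation :
        :class:`~methanokin.growth.ProteomeAllocation` covering every
        enzyme in the network; defaults to the packaged table for the
        scenario's condition.
    scenario :
        :class:`Scenario` with initial conditions and solver settings.
    """

    def __init__(self, network: ReactionNetwork | None = None,
                 allocation: ProteomeAllocation | None = None,
                 scenario: Scenario | None = None):
        self.scenario = scenario if scenario is not None else Scenario()
        self.network = network if network is not None else default_network()
        if allocation is None:
            allocation = load_allocation(self.scenario.condition)
        self.allocation = allocation
        self._compile()

    # -- assembly -----------------------------------------------------

    def _compile(self) -> None:
        net, alloc, scen = self.network, self.allocation, self.scenario
        missing = [e for e in net.enzymes() if e not in alloc.stoichiometries]
        if missing:
            raise ConfigurationError(
                f"allocation lacks enzymes required by the network: {missing}"
            )
        dyn = [sp.name for sp in net.species
               if net.species_role(sp.name) not in ("constant", "biomass")]
        if scen.substrate not in dyn:
            raise ConfigurationError(
                f"substrate {scen.substrate!r} is not a dynamic species"
            )
        self.dynamic_species = dyn
        index = {name: i for i, name in enumerate(dyn)}
        n = len(dyn)

        compiled = []
        self._cell_mass_rxn = None
        n_rxn = len(net.reactions)
        # vectorised kinetics: indices point into the state vector extended
        # by one slot frozen at 1.0, so absent/constant factors multiply by 1
        dummy = n
        P = np.full((n_rxn, 2), dummy, dtype=int)   # primary substrate slots
        KM = np.zeros((n_rxn, 2))
        G = np.full((n_rxn, 2), dummy, dtype=int)   # depletion-guard slots
        EPS = np.zeros((n_rxn, 2))
        coef = np.zeros(n_rxn)                      # k_cat * alloc / (Y*1e3)
        S = np.zeros((n + 1, n_rxn))                # last row: cell mass (mg)
        for j, rxn in enumerate(net.reactions):
            def remap(name: str) -> str | None:
                if scen.pool_translocated_ions and name == "Na_e":
                    return "He"
                if net.species_role(name) in ("constant", "biomass"):
                    return None
                return name

            stoich = np.zeros(n)
            guard_idx = []
            for name, nu in rxn.reactant_stoich.items():
                eff_nu = nu
                if rxn.enzyme == "ATPS" and name == "He":
                    eff_nu = scen.h_per_atp
                mapped = remap(name)
                if mapped is None:
                    continue
                stoich[index[mapped]] -= eff_nu
                if name not in rxn.primary_substrates:
                    guard_idx.append(index[mapped])
            for name, nu in rxn.product_stoich.items():
                mapped = remap(name)
                if mapped is None:
                    continue
                stoich[index[mapped]] += nu

            primary_idx = [index[p] for p in rxn.primary_substrates
                           if net.species_role(p) != "constant"]
            guard_idx = sorted(set(guard_idx))
            if len(guard_idx) > 2:
                raise ConfigurationError(
                    f"reaction {rxn.rid!r} has more than two guarded reactants"
                )
            entry = dict(
                rid=rxn.rid,
                mechanism=rxn.mechanism,
                k_cat=rxn.k_cat,
                k_m=rxn.k_m,
                primary=np.array(primary_idx, dtype=int),
                guards=np.array(guard_idx, dtype=int),
                stoich=stoich,
                enzyme_stoich=(None if rxn.mechanism == "F"
                               else alloc.stoichiometries[rxn.enzyme]),
            )
            compiled.append(entry)
            S[:n, j] = stoich
            if rxn.mechanism == "F":
                if "Biomass" in rxn.product_stoich:
                    self._cell_mass_rxn = entry
                    self._cm_j = j
                    S[n, j] = alloc.yield_g_per_mol_atp * 1e-3 * net.volume
            else:
                coef[j] = rxn.k_cat * alloc.stoichiometries[rxn.enzyme] / (
                    alloc.yield_g_per_mol_atp * 1e3 * net.volume
                )
                for slot, i in enumerate(primary_idx[:2]):
                    P[j, slot] = i
                    KM[j, slot] = rxn.k_m
                for slot, i in enumerate(guard_idx):
                    G[j, slot] = i
                    EPS[j, slot] = _GUARD_EPS
        self._compiled = compiled
        self._index = index
        f_rows = [j for j, rxn in enumerate(net.reactions)
                  if rxn.mechanism == "F"]
        f_k = np.array([
            alloc.growth_rate_per_s
            if (self._cell_mass_rxn is not None and j == self._cm_j)
            else net.reactions[j].k_cat
            for j in f_rows
        ])
        f_p = np.array([index[net.reactions[j].primary_substrates[0]]
                        for j in f_rows], dtype=int)
        self._vec = dict(P=P, KM=KM, G=G, EPS=EPS, coef=coef, S=S,
                         F_j=np.array(f_rows, dtype=int), F_k=f_k, F_p=f_p)

    def initial_state(self) -> np.ndarray:
        scen = self.scenario
        net = self.network
        y0 = np.zeros(len(self.dynamic_species) + 1)
        idx = self._index

        def set_if_present(name: str, value: float) -> None:
            if name in idx:
                y0[idx[name]] = value

        set_if_present(scen.substrate, scen.substrate_mM)
        set_if_present("ATP", scen.atp_mM)
        set_if_present("ADP", scen.adp_mM)
        set_if_present("Pi", scen.pi_mM)
        carriers = (_BASE_CARRIERS if scen.carrier_init == "base" else
                    [s for s in self.dynamic_species
                     if net.species_role(s) == "carrier"])
        for name in carriers:
            set_if_present(name, scen.carrier_mM)
        # extracellular pH 7 -> 1e-7 M = 1e-4 mM
        set_if_present("He", 10.0 ** (-scen.extracellular_pH) * 1e3)
        y0[-1] = scen.initial_cell_mass_mg
        return y0

    def rhs(self) -> Callable[[float, np.ndarray], np.ndarray]:
        """The derivative function (t, state) -> d(state)/dt.

        Rate laws are evaluated on non-negatively clipped concentrations;
        a smooth depletion guard ``s/(s+eps)`` throttles each reaction as
        any of its non-kinetic reactants approaches zero, so constant-flux
        side reactions cannot drive a pool negative.  Stoichiometry is
        untouched by the guard, so all conservation laws hold exactly.
        """
        v = self._vec
        P, KM, G, EPS, coef, S = (v["P"], v["KM"], v["G"], v["EPS"],
                                  v["coef"], v["S"])
        F_j, F_k, F_p = v["F_j"], v["F_k"], v["F_p"]
        n = len(self.dynamic_species)

        def f(t: float, y: np.ndarray) -> np.ndarray:
            ce = np.empty(n + 1)
            np.maximum(y[:n], 0.0, out=ce[:n])
            ce[n] = 1.0
            m = y[n] if y[n] > 0.0 else 0.0
            sp = ce[P]
            gp = ce[G]
            flux = (coef * m
                    * (sp[:, 0] / (KM[:, 0] + sp[:, 0]))
                    * (sp[:, 1] / (KM[:, 1] + sp[:, 1]))
                    * (gp[:, 0] / (EPS[:, 0] + gp[:, 0]))
                    * (gp[:, 1] / (EPS[:, 1] + gp[:, 1])))
            if len(F_j):
                flux[F_j] = F_k * ce[F_p]
            return S @ flux

        return f

    def reaction_fluxes(self, state: np.ndarray) -> dict[str, float]:
        """Per-reaction fluxes (mM/s) at one state vector, keyed by rid."""
        v = self._vec
        n = len(self.dynamic_species)
        ce = np.append(np.maximum(state[:n], 0.0), 1.0)
        m = max(state[n], 0.0)
        sp, gp = ce[v["P"]], ce[v["G"]]
        flux = (v["coef"] * m
                * (sp[:, 0] / (v["KM"][:, 0] + sp[:, 0]))
                * (sp[:, 1] / (v["KM"][:, 1] + sp[:, 1]))
                * (gp[:, 0] / (v["EPS"][:, 0] + gp[:, 0]))
                * (gp[:, 1] / (v["EPS"][:, 1] + gp[:, 1])))
        if len(v["F_j"]):
            flux[v["F_j"]] = v["F_k"] * ce[v["F_p"]]
        return {rx["rid"]: float(flux[j])
                for j, rx in enumerate(self._compiled)}

    # -- integration --------------------------------------------------

    def simulate(self, duration_h: float | None = None,
                 t_eval: np.ndarray | None = None) -> TimeCourse:
        """Integrate the model and return a :class:`TimeCourse`.

        Time is integrated in seconds with an adaptive stiff-capable
        solver; output is sampled on a dense grid (``scenario.sample_h``).
        Integration stops early at substrate exhaustion when
        ``scenario.stop_at_exhaustion`` is set.
        """
        scen = self.scenario
        T = float(duration_h if duration_h is not None else scen.duration_h)
        y0 = self.initial_state()
        f = self.rhs()
        if t_eval is None:
            t_eval = np.arange(0.0, T + scen.sample_h / 2, scen.sample_h)
        t_eval_s = np.asarray(t_eval) * 3600.0

        events = []
        sub_i = self._index[scen.substrate]
        if scen.stop_at_exhaustion and y0[sub_i] > scen.exhaustion_mM:
            def exhausted(t, y):
                return y[sub_i] - scen.exhaustion_mM
            exhausted.terminal = True
            exhausted.direction = -1
            events.append(exhausted)

        sol = solve_ivp(
            f, (0.0, T * 3600.0), y0, method=scen.method,
            rtol=scen.rtol, atol=scen.atol, t_eval=t_eval_s,
            events=events or None, dense_output=False,
        )
        if not sol.success:
            last_t = sol.t[-1] if len(sol.t) else None
            last_y = sol.y[:, -1] if sol.y.size else None
            raise IntegrationError(
                f"integration failed: {sol.message}", last_t, last_y
            )
        t_h = sol.t / 3600.0
        if sol.t_events and len(sol.t_events[0]):
            # append the exact event state so observables see exhaustion
            te = sol.t_events[0][0]
            if len(t_h) == 0 or te / 3600.0 > t_h[-1] + 1e-12:
                t_h = np.append(t_h, te / 3600.0)
                sol_y = np.column_stack([sol.y, sol.y_events[0][0]])
            else:
                sol_y = sol.y
        else:
            sol_y = sol.y
        data = pd.DataFrame(sol_y[:-1].T, columns=self.dynamic_species)
        data.insert(0, "time_h", t_h)
        data["cell_mass_mg"] = sol_y[-1]
        vol = self.network.volume
        data["ch4_cum_umol"] = data.get("CH4", 0.0) * vol
        data["co2_cum_umol"] = data.get("CO2", 0.0) * vol
        return TimeCourse(data, scen, self.dynamic_species)

    def fit(self, observations, free_params, bounds=None, seed=0,
            n_starts=8, **kwargs):
        """Fit free rate constants to growth observations.

        Thin delegate to :func:`methanokin.fitcal.fit`; returns a
        :class:`~methanokin.fitcal.FitResult`.
        """
        from . import fitcal

        return fitcal.fit(free_params, observations, self.scenario,
                          bounds=bounds, seed=seed, n_starts=n_starts,
                          network=self.network, allocation=self.allocation,
                          **kwargs)


def assemble(network: ReactionNetwork, allocation: ProteomeAllocation,
             scenario: Scenario) -> Callable[[float, np.ndarray], np.ndarray]:
    """Return the ODE right-hand side for the given configuration."""
    return KineticGrowthModel(network, allocation, scenario).rhs()


def run(scenario: Scenario, network: ReactionNetwork | None = None,
        allocation: ProteomeAllocation | None = None) -> TimeCourse:
    """Simulate a growth scenario with the packaged defaults."""
    return KineticGrowthModel(network, allocation, scenario).simulate()
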