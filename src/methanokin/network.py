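"""Methanogenesis reaction network: parsing, validation, and rate laws.

The network couples the acetoclastic, methylotrophic, electron-transport,
and cell-growth reactions of *Methanosarcina acetivorans*.  Every reaction
is irreversible; reversible enzymes appear as two independent rows.  Four
rate-law mechanisms are supported:

``M``
    irreversible unimolecular Michaelis-Menten, ``kcat*E*s/(Km+s)``;
``B``
    irreversible bimolecular Michaelis-Menten with a shared ``kcat``/``Km``
    for both substrates, taken as the product of the two saturation factors;
``BC``
    bimolecular Michaelis-Menten on the two designated (primary) reactants,
    with the remaining co-reactants converted at the same flux by an implied
    constant-flux side reaction;
``F``
    first order, ``k*s``.

Water and the intracellular proton are carried in the stoichiometry for
completeness but held constant: they are never updated by any flux, and when
one of them is designated a kinetic substrate its saturation factor is taken
as 1 (its activity is folded into ``kcat``).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SpeciesPool",
    "KineticReaction",
    "ReactionNetwork",
    "NetworkValidationError",
    "load_network",
    "default_network",
    "rate_uni_mm",
    "rate_bi_mm",
    "rate_first_order",
    "species_derivatives",
    "SPECIES_ROLES",
    "CONSERVED_POOLS",
    "CARBON_WEIGHTS",
]

#: canonical role of every species in the packaged network
SPECIES_ROLES: dict[str, str] = {
    "MeOH": "substrate",
    "Ac": "substrate",
    "CH4": "product",
    "CO2": "product",
    "CO": "product",
    "AcP": "intermediate",
    "AcCoA": "carrier",
    "CoA": "carrier",
    "CoM": "carrier",
    "MeCoM": "carrier",
    "CoB": "carrier",
    "CoBCoM": "carrier",
    "H4SPT": "carrier",
    "MeH4SPT": "carrier",
    "MethyleneH4SPT": "carrier",
    "MethenylH4SPT": "carrier",
    "FormylH4SPT": "carrier",
    "Mfr": "carrier",
    "FormylMfr": "carrier",
    "F420": "carrier",
    "F420H2": "carrier",
    "Fd_ox": "carrier",
    "Fd_red": "carrier",
    "Mphen": "carrier",
    "MphenH2": "carrier",
    "ATP": "energy",
    "ADP": "energy",
    "Pi": "energy",
    "He": "ion",
    "H2O": "constant",
    "H": "constant",
    "Na_c": "constant",
    "Na_e": "constant",
    "Biomass": "biomass",
}

#: conserved moiety pools (with the cell-mass reaction disabled)
CONSERVED_POOLS: dict[str, tuple[str, ...]] = {
    "CoM": ("CoM", "MeCoM", "CoBCoM"),
    "CoB": ("CoB", "CoBCoM"),
    "CoA": ("CoA", "AcCoA"),
    "Fd": ("Fd_ox", "Fd_red"),
    "F420": ("F420", "F420H2"),
    "Mphen": ("Mphen", "MphenH2"),
    "Mfr": ("Mfr", "FormylMfr"),
    "H4SPT": (
        "H4SPT",
        "MeH4SPT",
        "MethyleneH4SPT",
        "MethenylH4SPT",
        "FormylH4SPT",
    ),
}

#: carbon atoms carried by each carbon-bearing species
CARBON_WEIGHTS: dict[str, int] = {
    "MeOH": 1,
    "Ac": 2,
    "AcP": 2,
    "AcCoA": 2,
    "CO": 1,
    "CO2": 1,
    "CH4": 1,
    "MeCoM": 1,
    "MeH4SPT": 1,
    "MethyleneH4SPT": 1,
    "MethenylH4SPT": 1,
    "FormylH4SPT": 1,
    "FormylMfr": 1,
}

_MECHANISMS = ("M", "B", "BC", "F")


class NetworkValidationError(ValueError):
    """Raised when a reaction table row fails validation."""


@dataclass
class SpeciesPool:
    """A chemical species with its concentration (mM) and network role.

    Species with role ``constant`` (water, the intracellular proton, and by
    default the sodium pools) are never updated by any flux.
    """

    name: str
    concentration: float = 0.0
    role: str = "intermediate"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"negative concentration for species {self.name!r}")


@dataclass
class KineticReaction:
    """One irreversible reaction row of the kinetic model.

    ``primary_substrates`` are the kinetic substrates of the rate law: one
    species for mechanisms M and F, two for B and BC (the underlined
    reactants of a B/C row).
    """

    enzyme: str
    reactant_stoich: dict[str, float]
    product_stoich: dict[str, float]
    mechanism: str
    k_cat: float
    k_m: float | None
    primary_substrates: tuple[str, ...]
    citation: str = ""
    rid: str = ""

    def validate(self) -> None:
        if self.mechanism not in _MECHANISMS:
            raise NetworkValidationError(
                f"reaction {self.rid!r}: unknown mechanism {self.mechanism!r}"
            )
        n_primary = len(self.primary_substrates)
        if self.mechanism in ("M", "F") and n_primary != 1:
            raise NetworkValidationError(
                f"reaction {self.rid!r}: mechanism {self.mechanism} requires "
                f"exactly 1 primary substrate, got {n_primary}"
            )
        if self.mechanism in ("B", "BC") and n_primary != 2:
            raise NetworkValidationError(
                f"reaction {self.rid!r}: mechanism {self.mechanism} requires "
                f"exactly 2 primary substrates, got {n_primary}"
            )
        if self.mechanism == "F" and self.k_m is not None:
            raise NetworkValidationError(
                f"reaction {self.rid!r}: first-order reactions take no K_M"
            )
        if self.mechanism != "F" and (self.k_m is None or self.k_m <= 0):
            raise NetworkValidationError(
                f"reaction {self.rid!r}: K_M must be positive for Michaelis-"
                f"Menten mechanisms"
            )
        for sp in self.primary_substrates:
            if sp not in self.reactant_stoich:
                raise NetworkValidationError(
                    f"reaction {self.rid!r}: primary substrate {sp!r} does not "
                    f"appear among the reactants"
                )


def rate_uni_mm(k_cat: float, enzyme_conc: float, s: float, k_m: float) -> float:
    """Irreversible unimolecular Michaelis-Menten flux, mM/s.

    ``kcat*E*s/(Km+s)``; all concentrations in mM, ``k_cat`` per second.
    """
    if min(k_cat, enzyme_conc, s) < 0 or k_m <= 0:
        raise ValueError("rate_uni_mm requires non-negative inputs and K_M > 0")
    return k_cat * enzyme_conc * s / (k_m + s)


def rate_bi_mm(
    k_cat: float, enzyme_conc: float, s1: float, s2: float, k_m: float
) -> float:
    """Irreversible bimolecular Michaelis-Menten flux, mM/s.

    Both substrates share ``k_cat`` and ``K_M``; the rate is the product of
    the two saturation factors, ``kcat*E*[s1/(Km+s1)]*[s2/(Km+s2)]``, which
    preserves per-substrate half-saturation and the ``kcat*E`` ceiling.
    """
    if min(k_cat, enzyme_conc, s1, s2) < 0 or k_m <= 0:
        raise ValueError("rate_bi_mm requires non-negative inputs and K_M > 0")
    return k_cat * enzyme_conc * (s1 / (k_m + s1)) * (s2 / (k_m + s2))


def rate_first_order(k: float, s: float) -> float:
    """First-order flux ``k*s`` in mM/s (``k`` per second, ``s`` in mM)."""
    if k < 0 or s < 0:
        raise ValueError("rate_first_order requires non-negative inputs")
    return k * s


def species_derivatives(
    reaction: KineticReaction, flux: float
) -> dict[str, float]:
    """Per-species concentration rates (mM/s) produced by one reaction flux.

    Every reactant is decremented and every product incremented by
    stoichiometry x flux.  For B/C reactions this drives the non-primary
    co-reactants at the same flux, which is exactly the constant-flux side
    reaction of the model.  Species with role ``constant`` receive rate 0.
    """
    if flux < 0:
        raise ValueError("flux must be non-negative")
    rates: dict[str, float] = {}
    for sp, nu in reaction.reactant_stoich.items():
        rates[sp] = rates.get(sp, 0.0) - nu * flux
    for sp, nu in reaction.product_stoich.items():
        rates[sp] = rates.get(sp, 0.0) + nu * flux
    for sp in rates:
        if SPECIES_ROLES.get(sp) == "constant":
            rates[sp] = 0.0
    return rates


@dataclass
class ReactionNetwork:
    """A validated collection of species and kinetic reactions in 1 mL."""

    species: list[SpeciesPool] = field(default_factory=list)
    reactions: list[KineticReaction] = field(default_factory=list)
    volume: float = 1.0  # mL; 1 mM in 1 mL is 1 umol

    def __post_init__(self) -> None:
        self.validate()

    @property
    def species_names(self) -> list[str]:
        return [sp.name for sp in self.species]

    def species_role(self, name: str) -> str:
        return SPECIES_ROLES.get(name, "intermediate")

    def validate(self) -> None:
        known = set(self.species_names)
        for rxn in self.reactions:
            rxn.validate()
            for sp in list(rxn.reactant_stoich) + list(rxn.product_stoich):
                if sp not in known:
                    raise NetworkValidationError(
                        f"reaction {rxn.rid!r} references unknown species {sp!r}"
                    )

    def enzymes(self) -> list[str]:
        """Enzyme names that require an allocation entry (all but cell mass)."""
        return sorted(
            {r.enzyme for r in self.reactions if r.mechanism != "F"}
        )

    def reaction_flux(
        self, rxn: KineticReaction, conc: Mapping[str, float], enzyme_conc: float
    ) -> float:
        """Evaluate one reaction's rate law at the given concentrations.

        A primary substrate with role ``constant`` contributes a saturation
        factor of 1 (its activity is implicit in ``k_cat``).
        """
        if rxn.mechanism == "F":
            return rate_first_order(rxn.k_cat, conc[rxn.primary_substrates[0]])
        sats = []
        for sp in rxn.primary_substrates:
            if self.species_role(sp) == "constant":
                continue
            sats.append(conc[sp] / (rxn.k_m + conc[sp]))
        out = rxn.k_cat * enzyme_conc
        for f in sats:
            out *= f
        return out


_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_side(side: str, rid: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    side = side.strip()
    if not side:
        return stoich
    for term in side.split(" + "):
        m = _TERM_RE.match(term)
        if m is None:
            raise NetworkValidationError(
                f"reaction {rid!r}: unparseable term {term!r}"
            )
        coeff = float(m.group(1)) if m.group(1) else 1.0
        name = m.group(2)
        stoich[name] = stoich.get(name, 0.0) + coeff
    return stoich


def parse_reaction(text: str, rid: str = "") -> tuple[dict[str, float], dict[str, float]]:
    """Split a ``"A + 2 B → C"`` reaction string into stoichiometry maps."""
    for arrow in ("→", "->"):
        if arrow in text:
            lhs, rhs = text.split(arrow, 1)
            return _parse_side(lhs, rid), _parse_side(rhs, rid)
    raise NetworkValidationError(f"reaction {rid!r}: no arrow in {text!r}")


def load_network(table: str | pd.DataFrame) -> ReactionNetwork:
    """Build a :class:`ReactionNetwork` from a reaction-parameter table.

    ``table`` is a path to a UTF-8 TSV (columns ``enzyme``, ``reaction``,
    ``kcat_per_s``, ``km_mM``, ``type``, ``primary_substrates``,
    ``citation``) or an equivalent DataFrame.  Reversible enzyme pairs
    appear as two independent irreversible rows; duplicate enzyme names get
    ``_fwd``/``_rev``-style suffixed reaction ids.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    required = {"enzyme", "reaction", "kcat_per_s", "km_mM", "type"}
    missing = required - set(df.columns)
    if missing:
        raise NetworkValidationError(f"reaction table lacks columns {sorted(missing)}")

    reactions: list[KineticReaction] = []
    seen: dict[str, int] = {}
    for i, row in df.iterrows():
        enzyme = str(row["enzyme"]).strip()
        n = seen.get(enzyme, 0)
        seen[enzyme] = n + 1
        rid = enzyme if n == 0 else f"{enzyme}_rev" if n == 1 else f"{enzyme}_{n}"
        try:
            reactants, products = parse_reaction(str(row["reaction"]), rid)
            km_raw = str(row["km_mM"]).strip()
            km = None if km_raw in ("", "-", "—", "nan") else float(km_raw)
            primary_raw = str(row.get("primary_substrates", "")).strip()
            primary = tuple(p.strip() for p in primary_raw.split(";") if p.strip())
            rxn = KineticReaction(
                enzyme=enzyme,
                reactant_stoich=reactants,
                product_stoich=products,
                mechanism=str(row["type"]).strip(),
                k_cat=float(row["kcat_per_s"]),
                k_m=km,
                primary_substrates=primary,
                citation=str(row.get("citation", "")).strip(),
                rid=rid,
            )
            rxn.validate()
        except NetworkValidationError as err:
            raise NetworkValidationError(f"row {i} ({enzyme}): {err}") from err
        reactions.append(rxn)

    names: list[str] = []
    for rxn in reactions:
        for sp in list(rxn.reactant_stoich) + list(rxn.product_stoich):
            if sp not in names:
                names.append(sp)
    species = [
        SpeciesPool(name=sp, role=SPECIES_ROLES.get(sp, "intermediate"))
        for sp in names
    ]
    return ReactionNetwork(species=species, reactions=reactions)


def default_network() -> ReactionNetwork:
    """The packaged 27-reaction network (26 pathway rows + cell mass)."""
    with importlib.resources.as_file(
        importlib.resources.files("methanokin.data") / "table1.tsv"
    ) as path:
        return load_network(str(path))
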