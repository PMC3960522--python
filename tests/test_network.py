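"""Reaction-table parsing, validation, and rate-law behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methanokin.network import (
    NetworkValidationError,
    load_network,
    rate_bi_mm,
    rate_first_order,
    rate_uni_mm,
    species_derivatives,
)


class TestDefaultTable:
    def test_reaction_count(self, network):
        # 26 pathway rows (incl. ATP synthase) + the cell-mass reaction
        assert len(network.reactions) == 27

    def test_all_enzymes_covered_by_allocation(self, network, methanol_alloc):
        assert set(network.enzymes()) <= set(methanol_alloc.stoichiometries)

    def test_mcr_row(self, network):
        mcr = next(r for r in network.reactions if r.rid == "Mcr")
        assert mcr.mechanism == "B"
        assert mcr.k_cat == 5.0
        assert mcr.k_m == 2.0
        assert mcr.primary_substrates == ("MeCoM", "CoB")
        assert mcr.reactant_stoich == {"MeCoM": 1, "CoB": 1}
        assert mcr.product_stoich == {"CoBCoM": 1, "CH4": 1}

    def test_mer_reverse_forward_ratio(self, network):
        by_rid = {r.rid: r for r in network.reactions}
        ratio = by_rid["Mer_rev"].k_cat / by_rid["Mer"].k_cat
        assert round(ratio, 1) == 6.8

    def test_mtr_primary_pairs(self, network):
        by_rid = {r.rid: r for r in network.reactions}
        assert by_rid["Mtr"].primary_substrates == ("MeH4SPT", "CoM")
        assert by_rid["Mtr_rev"].primary_substrates == ("MeCoM", "H4SPT")

    def test_reversible_pairs_are_independent_rows(self, network):
        from collections import Counter

        counts = Counter(r.enzyme for r in network.reactions)
        for enzyme in ("Ack", "Pta", "Cdh", "Mer", "Mtd", "Mch", "Ftr",
                       "FmdFwd", "Mtr"):
            assert counts[enzyme] == 2


class TestLoadNetwork:
    def test_empty_table(self):
        df = pd.DataFrame(columns=["enzyme", "reaction", "kcat_per_s",
                                   "km_mM", "type", "primary_substrates",
                                   "citation"])
        net = load_network(df)
        assert net.reactions == [] and net.species == []

    def test_single_row_example(self):
        df = pd.DataFrame([
            dict(enzyme="Mcr", reaction="MeCoM + CoB → CoBCoM + CH4",
                 kcat_per_s="5.0", km_mM="2", type="B",
                 primary_substrates="MeCoM;CoB", citation="x")
        ])
        net = load_network(df)
        rxn = net.reactions[0]
        assert rxn.mechanism == "B"
        assert rxn.primary_substrates == ("MeCoM", "CoB")
        assert set(net.species_names) == {"MeCoM", "CoB", "CoBCoM", "CH4"}

    @pytest.mark.parametrize(
        "row, match",
        [
            (dict(type="Q", primary_substrates="A"), "mechanism"),
            (dict(reaction="A B C", type="M", primary_substrates="A"),
             "arrow"),
            (dict(primary_substrates="Z", type="M"), "primary substrate"),
            (dict(primary_substrates="A;B;C", type="B"), "exactly 2"),
            (dict(type="F", primary_substrates="A", km_mM="2"), "no K_M"),
        ],
    )
    def test_validation_failures_name_the_row(self, row, match):
        base = dict(enzyme="Enz", reaction="A + B → C", kcat_per_s="1",
                    km_mM="1", type="B", primary_substrates="A;B",
                    citation="")
        base.update(row)
        with pytest.raises(NetworkValidationError, match=match):
            load_network(pd.DataFrame([base]))


class TestRateLaws:
    def test_uni_mm_zero_substrate(self):
        assert rate_uni_mm(17.0, 1e-3, 0.0, 50.0) == 0.0

    def test_uni_mm_half_saturation(self):
        assert rate_uni_mm(17.0, 1e-3, 50.0, 50.0) == pytest.approx(
            17.0 * 1e-3 / 2
        )

    def test_uni_mm_mta_row_value(self):
        # k_cat and K_M of the highest-affinity methanol methyltransferase
        assert rate_uni_mm(17.0, 1e-3, 50.0, 50.0) == pytest.approx(8.5e-3)

    def test_bi_mm_zero_and_quarter(self):
        assert rate_bi_mm(5.0, 1.0, 0.0, 3.0, 2.0) == 0.0
        assert rate_bi_mm(5.0, 1.0, 2.0, 2.0, 2.0) == pytest.approx(5.0 / 4)

    def test_bi_mm_saturation_bound(self):
        assert rate_bi_mm(5.0, 2.0, 1e9, 1e9, 2.0) == pytest.approx(
            10.0, rel=1e-6
        )

    def test_first_order(self):
        assert rate_first_order(3.4722e-5, 0.0) == 0.0
        assert rate_first_order(3.4722e-5, 10.0) == pytest.approx(3.4722e-4)

    def test_first_order_doubling_time(self):
        # pure exponential at the printed growth constant
        assert np.log(2) / 0.125 == pytest.approx(5.545, abs=5e-3)

    @pytest.mark.parametrize("fn, args", [
        (rate_uni_mm, (1.0, -1.0, 1.0, 1.0)),
        (rate_uni_mm, (1.0, 1.0, 1.0, 0.0)),
        (rate_bi_mm, (1.0, 1.0, -1.0, 1.0, 1.0)),
        (rate_first_order, (-1.0, 1.0)),
    ])
    def test_negative_inputs_raise(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        kcat=st.floats(0.01, 1e3),
        e=st.floats(0.0, 10.0),
        s1=st.floats(0.0, 1e3),
        s2=st.floats(0.0, 1e3),
        km=st.floats(1e-3, 1e2),
        ds=st.floats(1e-6, 10.0),
    )
    def test_bi_mm_nonneg_monotone_bounded(self, kcat, e, s1, s2, km, ds):
        v = rate_bi_mm(kcat, e, s1, s2, km)
        assert 0.0 <= v <= kcat * e + 1e-12
        assert rate_bi_mm(kcat, e, s1 + ds, s2, km) >= v - 1e-12
        assert rate_bi_mm(kcat, e, s1, s2 + ds, km) >= v - 1e-12


class TestSpeciesDerivatives:
    def test_mcr_flux_routing(self, network):
        mcr = next(r for r in network.reactions if r.rid == "Mcr")
        rates = species_derivatives(mcr, 2.0)
        assert rates == {"MeCoM": -2.0, "CoB": -2.0, "CoBCoM": 2.0,
                         "CH4": 2.0}

    def test_cdh_constant_flux_coupling(self, network):
        cdh = next(r for r in network.reactions if r.rid == "Cdh")
        rates = species_derivatives(cdh, 1.5)
        # non-primary reactants ride along at stoichiometry x flux
        assert rates["Fd_ox"] == pytest.approx(-3.0)
        assert rates["H4SPT"] == pytest.approx(-1.5)
        assert rates["MeH4SPT"] == pytest.approx(1.5)
        # constant species are never updated
        assert rates["H2O"] == 0.0 and rates["H"] == 0.0

    def test_zero_flux(self, network):
        cdh = next(r for r in network.reactions if r.rid == "Cdh")
        assert all(v == 0.0 for v in species_derivatives(cdh, 0.0).values())

    def test_negative_flux_rejected(self, network):
        with pytest.raises(ValueError):
            species_derivatives(network.reactions[0], -1.0)
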