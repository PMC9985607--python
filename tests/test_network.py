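"""Deterministic reaction-network construction and integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from autocyclase import (RateParams, build_network, crossover_concentration,
                         product_fractions, run_to_completion,
                         simulate_deterministic)


class TestBuildNetwork:
    def test_monomer_only_truncation(self):
        rp = RateParams(k_uni=0.01, k_bi=130.0, k_hyd=0.002)
        net = build_network(1, rp, "drop")
        assert set(net.species) == {"A1", "C1", "L1", "E", "Ainact", "leakU"}
        names = sorted(r.name for r in net.reactions)
        assert names == ["A1->C1+E", "A1->L1+E"]  # no bimolecular representable

    def test_mechanistic_dimer_path_present(self):
        rp = RateParams(mode="mechanistic", k_act=1.0, k_cyc=1.0,
                        k_poly=1e4, k_hyd=0.0)
        net = build_network(2, rp)
        names = {r.name for r in net.reactions}
        assert "T1+A1->" in names          # tandem formation
        assert "A2->T2" in names and "T2->C2+E" in names

    def test_reaction_count_matches_exhaustive_enumeration(self):
        rp = RateParams(k_uni=0.01, k_bi=130.0, k_hyd=0.002)
        N = 4
        net = build_network(N, rp, "drop")
        # oracle: brute-force enumeration over unordered pairs n <= m <= N
        pairs = [(n, m) for n in range(1, N + 1) for m in range(n, N + 1)
                 if n + m <= N]
        expected = 2 * N + len(pairs)      # cyclisation + hydrolysis + tandem
        assert len(net.reactions) == expected

    def test_absorb_routes_to_cap_with_unit_leak(self):
        rp = RateParams(k_uni=0.01, k_bi=130.0)
        net = build_network(2, rp, "absorb")
        over = [r for r in net.reactions if r.name == "A1+A2->"]
        assert len(over) == 1
        s = over[0].stoich
        assert s[net.index["A2"]] == 0     # -1 reactant +1 absorbed product
        assert s[net.index["leakU"]] == 1  # one surplus target unit booked

    def test_order_below_one_rejected(self):
        with pytest.raises(ValueError):
            build_network(0, RateParams())


class TestDeterministic:
    def test_first_order_closed_form(self):
        rp = RateParams(k_uni=0.01, k_bi=0.0, k_hyd=0.0)
        net = build_network(1, rp)
        t = np.linspace(0.0, 300.0, 80)
        tc = simulate_deterministic(net, rp, 5e-6, t)
        expected = 5e-6 * (1.0 - np.exp(-0.01 * t))
        assert np.max(np.abs(tc["C1"] - expected)) < 1e-12
        # at t = 1/k the conversion is 63.21%
        tc2 = simulate_deterministic(net, rp, 5e-6, np.linspace(0, 100.0, 11))
        assert tc2["C1"][-1] / 5e-6 == pytest.approx(0.6321, abs=2e-4)

    def test_monomer_yield_matches_branching_quadrature(self, study_params):
        """With only cyclisation vs homodimerisation draining the monomer,
        the final monomer-cyclic fraction equals
        (1/C0) * int_0^C0 k_uni / (k_uni + 2 k_bi a) da."""
        c0 = 5e-6
        net = build_network(2, study_params, "drop")
        tc = run_to_completion(net, study_params, c0, unreacted_tol=1e-7)
        val, _ = quad(lambda a: study_params.k_uni
                      / (study_params.k_uni + 2 * study_params.k_bi * a), 0, c0)
        oracle = val / c0
        assert product_fractions(tc)["monomer_cyclic"] == pytest.approx(
            oracle, rel=1e-4)

    def test_full_network_close_to_quadrature(self, study_params, study_network):
        # higher-order recapture of monomer shifts the yield only slightly
        tc = run_to_completion(study_network, study_params, 5e-6)
        val, _ = quad(lambda a: 0.01 / (0.01 + 260.0 * a), 0, 5e-6)
        assert product_fractions(tc)["monomer_cyclic"] == pytest.approx(
            val / 5e-6, rel=2e-3)

    def test_inactive_fraction_bookkeeping(self):
        rp = RateParams(k_uni=0.01, k_bi=0.0, f_inactive=0.05)
        net = build_network(1, rp)
        tc = run_to_completion(net, rp, 5e-6)
        fr = product_fractions(tc)
        assert fr["unreacted"] == pytest.approx(0.05, abs=1e-4)
        assert fr["monomer_cyclic"] == pytest.approx(0.95, abs=1e-4)

    def test_oligomer_fraction_above_crossover(self, study_params, study_network):
        # at 80 uM the bimolecular channel rivals the unimolecular one
        fr = product_fractions(run_to_completion(study_network, study_params, 80e-6))
        assert fr["oligomer_cyclic"] > 0.25

    def test_empty_timecourse_rejected(self, study_params, study_network):
        tc = simulate_deterministic(study_network, study_params, 5e-6,
                                    np.linspace(0, 1, 5))
        tc.network = None
        with pytest.raises(ValueError):
            product_fractions(tc)

    def test_decreasing_grid_rejected(self, study_params, study_network):
        with pytest.raises(ValueError):
            simulate_deterministic(study_network, study_params, 5e-6,
                                   np.array([0.0, 2.0, 1.0]))


class TestInvariants:
    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(k_uni=st.floats(1e-3, 1.0), k_bi=st.floats(0.0, 1e4),
           k_hyd=st.floats(0.0, 0.1), c0=st.floats(1e-6, 2e-4),
           policy=st.sampled_from(["drop", "absorb"]))
    def test_conservation_all_runs(self, k_uni, k_bi, k_hyd, c0, policy):
        rp = RateParams(k_uni=k_uni, k_bi=k_bi, k_hyd=k_hyd)
        net = build_network(3, rp, policy)
        tc = simulate_deterministic(net, rp, c0, np.linspace(0, 50, 25))
        errs = tc.conservation_errors()
        assert errs["target_units"] <= 1e-6
        assert errs["enzyme_units"] <= 1e-6

    def test_monotonicity_in_c0(self, study_params, study_network):
        fracs = [product_fractions(
            run_to_completion(study_network, study_params, c0))
            for c0 in (50e-6, 100e-6, 200e-6)]
        olig = [f["oligomer_cyclic"] for f in fracs]
        mono = [f["monomer_cyclic"] for f in fracs]
        assert olig[0] < olig[1] < olig[2]
        assert mono[0] > mono[1] > mono[2]

    def test_monotonicity_in_k_bi(self):
        oligs = []
        for k_bi in (30.0, 130.0, 500.0):
            rp = RateParams(k_uni=0.01, k_bi=k_bi)
            net = build_network(4, rp, "drop")
            oligs.append(product_fractions(
                run_to_completion(net, rp, 50e-6))["oligomer_cyclic"])
        assert oligs[0] < oligs[1] < oligs[2]

    def test_crossover_concentration(self, study_params):
        assert crossover_concentration(study_params) == pytest.approx(
            7.692e-5, rel=1e-3)
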