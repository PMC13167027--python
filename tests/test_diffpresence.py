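import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_oracle, fisher_oracle
from symprof import coverage as cov
from symprof import diffpresence as dp
from symprof import simulate as sim
from symprof.io import GROUP_LOTTI, GROUP_LUNA, ParameterError


class TestAssignGroups:
    def test_dominance_labels_map_to_groups(self):
        groups = dp.assign_groups(
            {"s1": "T_lotti", "s2": "T_luna_var1", "s3": "T_luna_var2"}
        )
        assert groups == {"s1": GROUP_LOTTI, "s2": GROUP_LUNA, "s3": GROUP_LUNA}

    def test_no_focal_symbiont_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="symprof"):
            groups = dp.assign_groups({"s1": "T_lotti", "s2": "none"})
        assert groups == {"s1": GROUP_LOTTI}
        assert "excluded" in caplog.text


class TestClassification:
    thresholds = dp.ClassificationThresholds()

    @pytest.mark.parametrize(
        "breadth,depth,group,expected",
        [
            (0.70, 25, GROUP_LUNA, "present"),
            (0.70, 3, GROUP_LOTTI, "present"),
            (0.70, 3, GROUP_LUNA, "unknown"),  # group-specific depth threshold
            (0.65, 20, GROUP_LUNA, "present"),  # thresholds are inclusive
            (0.05, 0.2, GROUP_LUNA, "absent"),
            (0.05, 0.2, GROUP_LOTTI, "absent"),
            (0.64, 100, GROUP_LUNA, "unknown"),  # high depth cannot rescue breadth
            (0.05, 5, GROUP_LOTTI, "unknown"),  # low breadth but depth above absence cutoff
        ],
    )
    def test_state_fixtures(self, breadth, depth, group, expected):
        assert dp.classify_gene_state(breadth, depth, group, self.thresholds) == expected

    def test_unknown_group_rejected(self):
        with pytest.raises(ParameterError):
            dp.classify_gene_state(0.9, 30, "mystery", self.thresholds)

    def test_threshold_invariants_enforced(self):
        with pytest.raises(ParameterError):
            dp.ClassificationThresholds(breadth_absent=0.8)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        breadth=st.floats(0, 1), depth=st.floats(0, 200),
        group=st.sampled_from([GROUP_LUNA, GROUP_LOTTI]),
    )
    def test_classification_total(self, breadth, depth, group):
        """Every valid (breadth, depth) maps to exactly one of three states."""
        state = dp.classify_gene_state(breadth, depth, group, self.thresholds)
        assert state in ("present", "absent", "unknown")


class TestContingency:
    def _states(self):
        states = pd.DataFrame(
            {
                "l1": ["present", "unknown"],
                "l2": ["present", "unknown"],
                "l3": ["unknown", "unknown"],
                "o1": ["absent", "unknown"],
                "o2": ["absent", "unknown"],
                "o3": ["present", "unknown"],
            },
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        groups = {s: (GROUP_LUNA if s.startswith("l") else GROUP_LOTTI) for s in states}
        return states, groups

    def test_counts_and_unknown_exclusion(self):
        states, groups = self._states()
        assert dp.gene_contingency(states, groups, "g1") == (2, 0, 1, 2)
        assert dp.gene_contingency(states, groups, "g2") == (0, 0, 0, 0)

    def test_invariant_to_sample_order(self):
        states, groups = self._states()
        shuffled = states[list(reversed(states.columns))]
        assert dp.gene_contingency(shuffled, groups, "g1") == (2, 0, 1, 2)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((5, 0, 0, 5), 2 / 252),
            ((2, 2, 2, 2), 1.0),
            ((10, 0, 0, 10), 2 / 184756),
            ((0, 0, 3, 3), 1.0),  # zero margin -> untestable convention
        ],
    )
    def test_enumerated_fixtures(self, table, expected):
        p, _ = dp.fisher_exact_two_sided(*table)
        assert p == pytest.approx(expected, abs=1e-15)

    def test_odds_ratio_conventions(self):
        assert dp.fisher_exact_two_sided(5, 0, 0, 5)[1] == math.inf
        assert dp.fisher_exact_two_sided(0, 5, 5, 0)[1] == 0.0
        assert dp.fisher_exact_two_sided(2, 1, 1, 2)[1] == 4.0
        assert math.isnan(dp.fisher_exact_two_sided(0, 0, 3, 3)[1])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_matches_exact_enumeration_and_scipy(self, table):
        a, b, c, d = table
        p, _ = dp.fisher_exact_two_sided(a, b, c, d)
        assert abs(p - float(fisher_oracle(a, b, c, d))) < 1e-12
        if min(a + b, c + d, a + c, b + d) > 0:
            _, p_scipy = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert p == pytest.approx(p_scipy, rel=1e-6)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 20)] * 4))
    def test_symmetries(self, table):
        a, b, c, d = table
        p = dp.fisher_exact_two_sided(a, b, c, d)[0]
        assert p == dp.fisher_exact_two_sided(c, d, a, b)[0]
        assert p == dp.fisher_exact_two_sided(b, a, d, c)[0]


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.001, 0.01, 0.03, 0.05], [0.004, 0.02, 0.04, 0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.42], [0.42]),
        ],
    )
    def test_step_up_by_hand(self, p, expected):
        assert dp.bh_fdr(p) == pytest.approx(expected)

    def test_empty_input(self):
        assert dp.bh_fdr([]).size == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=120))
    def test_matches_oracle_and_invariants(self, p):
        q = dp.bh_fdr(p)
        assert q == pytest.approx(bh_oracle(p), abs=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert ((0 <= q) & (q <= 1)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()  # monotone along ascending p


def _simulated_results(n_a, n_b, n_genes, n_specific, seed, alpha=0.05):
    _, genes, truth = sim.simulate_reference(
        n_genes, n_specific, gene_length=150, intergenic_length=20, seed=seed
    )
    ref_len = n_genes * 150 + (n_genes + 1) * 20
    profiles, truth = sim.simulate_cohort_depths(
        n_a, n_b, genes, truth, sim.ReadSimParams(), ref_len, seed=seed + 1
    )
    coverage, _ = cov.coverage_table_from_profiles(profiles, genes)
    states = dp.classify_states(coverage, truth.sample_groups)
    return dp.differential_presence(states, truth.sample_groups, fdr_alpha=alpha), truth


class TestDifferentialPresence:
    def test_planted_recovery_small_cohort(self):
        results, truth = _simulated_results(12, 12, 60, 6, seed=21)
        called = set(results.loc[results["call"] == dp.CALL_A, "gene_id"])
        assert called == truth.specific_genes
        assert (results["call"] != dp.CALL_B).all()

    def test_one_vs_one_cohort_yields_no_calls(self):
        """Margins (1, 1) cannot reach significance: max evidence p = 0.5."""
        results, _ = _simulated_results(1, 1, 20, 3, seed=4)
        assert (results.loc[results["call"] != dp.CALL_UNTESTABLE, "p_value"] >= 0.5).all()
        assert set(results["call"]) <= {dp.CALL_NS, dp.CALL_UNTESTABLE}

    def test_refuses_single_group(self):
        states = pd.DataFrame({"s1": ["present"], "s2": ["absent"]},
                              index=pd.Index(["g1"], name="gene_id"))
        with pytest.raises(ParameterError):
            dp.differential_presence(states, {"s1": GROUP_LUNA, "s2": GROUP_LUNA})

    def test_untestable_genes_excluded_from_m_and_reported(self):
        states = pd.DataFrame(
            {
                "l1": ["present", "unknown"],
                "l2": ["absent", "unknown"],
                "o1": ["present", "present"],
                "o2": ["absent", "absent"],
            },
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        groups = {"l1": GROUP_LUNA, "l2": GROUP_LUNA,
                  "o1": GROUP_LOTTI, "o2": GROUP_LOTTI}
        results = dp.differential_presence(states, groups).set_index("gene_id")
        assert results.loc["g2", "call"] == dp.CALL_UNTESTABLE
        assert math.isnan(results.loc["g2", "q_value"])
        # g1 is the only testable gene, so its q equals its p (m = 1)
        assert results.loc["g1", "q_value"] == results.loc["g1", "p_value"]

    def test_q_not_below_p(self):
        results, _ = _simulated_results(6, 6, 40, 4, seed=33)
        testable = results["call"] != dp.CALL_UNTESTABLE
        assert (
            results.loc[testable, "q_value"] >= results.loc[testable, "p_value"] - 1e-15
        ).all()
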