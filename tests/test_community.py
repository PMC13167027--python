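import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symprof import community as comm
from symprof import simulate as sim
from symprof.community import ASVTable, CooccurrenceCategory
from symprof.io import ParameterError, SymprofError


class TestFiltering:
    def test_library_size_filter_is_strict(self, tiny_asv_table):
        # totals: s1=100, s2=1000, s3=1000 -> with threshold 1000 only s1 drops
        filtered = comm.filter_samples(tiny_asv_table, 1000)
        assert filtered.sample_ids == ["s2", "s3"]

    def test_threshold_zero_is_identity(self, tiny_asv_table):
        assert comm.filter_samples(tiny_asv_table, 0).sample_ids == ["s1", "s2", "s3"]

    def test_all_removed_is_error(self, tiny_asv_table):
        with pytest.raises(SymprofError):
            comm.filter_samples(tiny_asv_table, 10_000)

    def test_organelle_taxa_removed_unclassified_kept(self, tiny_asv_table):
        filtered = comm.filter_taxa(tiny_asv_table)
        assert filtered.asv_ids == ["ASV_a", "ASV_c"]  # chloroplast ASV_b removed

    @pytest.mark.parametrize("marker", ["Mitochondria", "CHLOROPLAST", "Eukaryota"])
    def test_markers_match_case_insensitive(self, tiny_asv_table, marker):
        table = tiny_asv_table
        table.taxonomy["ASV_c"] = f"Something;{marker};tail"
        assert "ASV_c" not in comm.filter_taxa(table).asv_ids


class TestCSS:
    def test_worked_example(self):
        counts = np.array([0, 2, 4, 6, 8])
        assert comm.css_scaling_factor(counts, 0.5) == 6.0
        table = ASVTable(
            counts=pd.DataFrame([counts], index=["s"], columns=list("abcde")),
            taxonomy=pd.Series({c: "Bacteria" for c in "abcde"}),
            metadata=pd.DataFrame({"site": ["x"], "date": ["d"], "compartment": ["gill"]},
                                  index=pd.Index(["s"], name="sample_id")),
        )
        normalized, factors = comm.css_normalize(table, 0.5, 1000.0)
        assert factors["s"] == 6.0
        assert normalized.loc["s"].tolist() == pytest.approx(
            [0.0, 1000 * 2 / 6, 1000 * 4 / 6, 1000.0, 1000 * 8 / 6]
        )

    def test_single_asv_sample_normalizes_to_scale(self):
        assert comm.css_scaling_factor(np.array([17]), 0.5) == 17.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 500), min_size=2, max_size=30).filter(
            lambda c: sum(c) > 0
        ),
        factor=st.integers(2, 50),
        quantile=st.floats(0.05, 0.95),
    )
    def test_scale_invariance(self, counts, factor, quantile):
        """Multiplying a sample's counts by c > 0 leaves CSS output unchanged."""
        raw = np.array(counts)
        s1 = comm.css_scaling_factor(raw, quantile)
        s2 = comm.css_scaling_factor(raw * factor, quantile)
        np.testing.assert_allclose(raw / s1, raw * factor / s2)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ParameterError):
            comm.css_scaling_factor(np.zeros(5, dtype=int), 0.5)


class TestRelativeAbundance:
    def test_rows_sum_to_one(self, tiny_asv_table):
        rel = comm.relative_abundance(tiny_asv_table.counts)
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-12)
        assert rel.loc["s1"].tolist() == pytest.approx([0.5, 0.3, 0.2])

    def test_zero_total_sample_rejected(self, tiny_asv_table):
        counts = tiny_asv_table.counts.copy()
        counts.loc["s1"] = 0
        with pytest.raises(ParameterError):
            comm.relative_abundance(counts)


def _gill_table(count_rows, focal=("ASV_lotti", "ASV_v1", "ASV_v2")):
    samples = [f"s{i}" for i in range(len(count_rows))]
    counts = pd.DataFrame(count_rows, index=samples, columns=list(focal) + ["ASV_bg"])
    taxonomy = pd.Series({a: "Bacteria;Ca_Thiodiazotropha" for a in focal}
                         | {"ASV_bg": "Bacteria;Other"})
    metadata = pd.DataFrame(
        {"site": "x", "date": "d", "compartment": "gill"},
        index=pd.Index(samples, name="sample_id"),
    )
    return ASVTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


FOCAL = {"ASV_lotti": "T_lotti", "ASV_v1": "T_luna_var1", "ASV_v2": "T_luna_var2"}


class TestDominance:
    def test_dominant_by_relative_abundance(self):
        table = _gill_table([[60, 25, 10, 5], [30, 35, 30, 5], [0, 0, 0, 10]])
        dom = comm.dominant_symbiont(table, FOCAL)
        assert dom.loc["s0", "dominant_type"] == "T_lotti"
        assert dom.loc["s0", "dominant_rel_abundance"] == pytest.approx(0.6)
        assert dom.loc["s1", "dominant_type"] == "T_luna_var1"
        assert dom.loc["s2", "dominant_type"] == "none"

    def test_exact_tie_breaks_to_smallest_id(self):
        table = _gill_table([[0, 40, 40, 20]])
        dom = comm.dominant_symbiont(table, FOCAL)
        assert dom.loc["s0", "dominant_asv"] == "ASV_v1"  # "ASV_v1" < "ASV_v2"

    def test_dominance_invariant_to_per_sample_rescaling(self):
        rows = [[60, 25, 10, 5], [3, 35, 30, 5]]
        table = _gill_table(rows)
        scaled = _gill_table([[x * 7 for x in rows[0]], rows[1]])
        a = comm.dominant_symbiont(table, FOCAL)["dominant_asv"]
        b = comm.dominant_symbiont(scaled, FOCAL)["dominant_asv"]
        assert a.equals(b)

    def test_detection_threshold_applies_to_raw_counts(self):
        table = _gill_table([[2, 0, 0, 98]])
        assert comm.dominant_symbiont(table, FOCAL, detection_min_count=5).loc[
            "s0", "dominant_type"
        ] == "none"


class TestCooccurrence:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ((True, False, False), CooccurrenceCategory.LOTTI_ONLY),
            ((True, True, False), CooccurrenceCategory.LOTTI_PLUS_ONE_VARIANT),
            ((True, False, True), CooccurrenceCategory.LOTTI_PLUS_ONE_VARIANT),
            ((True, True, True), CooccurrenceCategory.ALL_THREE),
            ((False, True, True), CooccurrenceCategory.VARIANTS_ONLY),
            ((False, True, False), CooccurrenceCategory.SINGLE_VARIANT_ONLY),
            ((False, False, True), CooccurrenceCategory.SINGLE_VARIANT_ONLY),
            ((False, False, False), CooccurrenceCategory.NONE_DETECTED),
        ],
    )
    def test_all_eight_patterns(self, flags, expected):
        assert comm.cooccurrence_category(*flags) is expected

    def test_partition_is_total(self):
        """The six categories partition the 8 detection patterns."""
        seen = [comm.cooccurrence_category(*f)
                for f in itertools.product([False, True], repeat=3)]
        assert len(seen) == 8
        assert set(seen) == set(CooccurrenceCategory)

    def test_summary_counts_and_percentages(self):
        cats = [CooccurrenceCategory.LOTTI_ONLY, CooccurrenceCategory.ALL_THREE,
                CooccurrenceCategory.VARIANTS_ONLY,
                CooccurrenceCategory.LOTTI_PLUS_ONE_VARIANT]
        summary = comm.cooccurrence_summary(cats)
        assert summary["count"].sum() == 4
        assert (summary.loc[[c.value for c in cats], "percent"] == 25.0).all()

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            comm.cooccurrence_summary([])

    def test_categorize_matches_planted_truth(self):
        gill, _, truth = sim.simulate_asv_dataset(sim.ASVSimParams(n_hosts=150), seed=13)
        observed = comm.categorize_samples(gill)
        planted = pd.Series(truth.sample_categories)
        agreement = (observed.loc[planted.index] == planted).mean()
        assert agreement > 0.97


class TestRichness:
    def test_observed_count_and_threshold(self):
        table = _gill_table([[3, 0, 1, 0]])
        assert comm.richness(table).loc["s0"] == 2
        assert comm.richness(table, detection_min_count=5).loc["s0"] == 0

    def test_taxon_scope(self):
        table = _gill_table([[3, 2, 1, 50]])
        assert comm.richness(table, taxon_prefix="Thiodiazotropha").loc["s0"] == 3
        assert comm.richness(table).loc["s0"] == 4


class TestSharedASVs:
    def test_planted_shared_set_recovered(self):
        gill, env, truth = sim.simulate_asv_dataset(sim.ASVSimParams(n_hosts=60), seed=17)
        gill, env = comm.filter_taxa(gill), comm.filter_taxa(env)
        report = comm.shared_asvs(gill, env)
        assert set(report["asv_id"]) == truth.shared_asv_ids

    def test_blade_and_rhizome_only_asv_has_zero_prevalence_elsewhere(self):
        gill, env, _ = sim.simulate_asv_dataset(sim.ASVSimParams(n_hosts=60), seed=17)
        report = comm.shared_asvs(gill, env).set_index("asv_id")
        assert report.loc[sim.ASV_SHARED2, "sediment_prevalence"] == 0.0
        assert report.loc[sim.ASV_SHARED2, "seawater_prevalence"] == 0.0
        assert report.loc[sim.ASV_SHARED2, "root_rhizome_prevalence"] > 0.0

    def test_gill_only_asv_excluded_and_disjoint_spaces_error(self, tiny_asv_table):
        gill, env, _ = sim.simulate_asv_dataset(sim.ASVSimParams(n_hosts=30), seed=3)
        report = comm.shared_asvs(gill, env)
        assert sim.ASV_LOTTI not in set(report["asv_id"])  # never planted in env
        with pytest.raises(SymprofError, match="id space"):
            comm.shared_asvs(gill, tiny_asv_table)

    def test_rhizome_abundance_ordering_matches_planting(self):
        """ASV_1n2_n6n is planted at ~0.04% on the rhizome, twice luna
        variant 1's ~0.02%; the report should reflect that ordering."""
        gill, env, _ = sim.simulate_asv_dataset(sim.ASVSimParams(n_hosts=30), seed=23)
        report = comm.shared_asvs(gill, env).set_index("asv_id")
        assert (
            report.loc[sim.ASV_SHARED2, "root_rhizome_mean_rel_abundance"]
            > report.loc[sim.ASV_LUNA1, "root_rhizome_mean_rel_abundance"]
        )


class TestASVTableIO:
    def test_tsv_round_trip(self, tmp_path, tiny_asv_table):
        tiny_asv_table.write(tmp_path, prefix="t")
        back = ASVTable.read(tmp_path, prefix="t")
        assert back.counts.equals(tiny_asv_table.counts)
        assert back.taxonomy.sort_index().equals(tiny_asv_table.taxonomy.sort_index())
        assert back.metadata.equals(tiny_asv_table.metadata)
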