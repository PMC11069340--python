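import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from isocat import (
    ConfigError,
    FormatError,
    ScreenCriteria,
    candidate_table,
    classify_candidates,
    find_hotspots,
    fisher_exact_2x2,
    trait_enrichment,
)
from isocat.conservation import ConservationMatrix
from isocat.core import PhenotypeRecord
from isocat.simulate import SimulationConfig, simulate_counts, simulate_panel
from isocat.expression import fold_change_table
from isocat import conservation_matrix
from isocat.screen import flags_by_replicon
from oracles import fisher_two_sided_exact


def tiny_matrix(identity: dict, coverage=None) -> ConservationMatrix:
    """Build a ConservationMatrix from {strain: {gene: identity}} literals."""
    ident = pd.DataFrame(identity)
    cov = pd.DataFrame(coverage) if coverage is not None else ident.notna() * 100.0
    hits = ident.apply(lambda col: col.map(lambda v: None if pd.isna(v) else "hit"))
    return ConservationMatrix(identity=ident, coverage=cov, best_hit=hits, min_coverage=50)


def fc_frame(log2fc: dict, threshold=1.0) -> pd.DataFrame:
    s = pd.Series(log2fc)
    return pd.DataFrame(
        {"mean_cpm_control": 1.0, "mean_cpm_treated": 1.0, "log2fc": s,
         "upregulated": s >= threshold}
    )


PHENO = {
    "D1": PhenotypeRecord("D1", True, "legume"),
    "N1": PhenotypeRecord("N1", False, "soil"),
}


class TestClassifyCandidates:
    def test_conserved_in_degraders_absent_in_nondegraders(self):
        fc = fc_frame({"g1": 2.5})
        cons = tiny_matrix({"D1": {"g1": 100.0}, "N1": {"g1": np.nan}})
        assert classify_candidates(fc, cons, PHENO, ScreenCriteria()) == {"g1": True}

    def test_not_upregulated_is_never_a_candidate(self):
        fc = fc_frame({"g1": 0.0})
        cons = tiny_matrix({"D1": {"g1": 100.0}, "N1": {"g1": np.nan}})
        assert classify_candidates(fc, cons, PHENO, ScreenCriteria()) == {"g1": False}

    def test_conserved_in_nondegrader_disqualifies(self):
        fc = fc_frame({"g1": 2.5})
        cons = tiny_matrix({"D1": {"g1": 100.0}, "N1": {"g1": 80.0}})
        assert classify_candidates(fc, cons, PHENO, ScreenCriteria()) == {"g1": False}

    def test_criteria_validation(self):
        with pytest.raises(ConfigError):
            ScreenCriteria(conserved_identity_min=30, nonconserved_identity_max=40)

    def test_requires_both_phenotype_classes(self):
        fc = fc_frame({"g1": 2.0})
        cons = tiny_matrix({"D1": {"g1": 100.0}})
        with pytest.raises(FormatError):
            classify_candidates(fc, cons, {"D1": PHENO["D1"]}, ScreenCriteria())

    def test_relaxing_fc_threshold_never_shrinks_candidate_set(self):
        cfg = SimulationConfig(
            seed=5, n_degraders=2, n_nondegraders=2, genes_per_strain=24,
            cluster_size=4, cluster_start_rank=11, protein_length=40,
        )
        panel, truth = simulate_panel(cfg)
        fc = fold_change_table(simulate_counts(panel, cfg, truth))
        cons = conservation_matrix(panel)
        previous = set()
        for threshold in (3.0, 2.0, 1.0, 0.0, -2.0):
            crit = ScreenCriteria(log2fc_threshold=threshold)
            called = {
                g for g, v in classify_candidates(
                    fc, cons, panel.phenotypes, crit, panel.reference_strain_id
                ).items() if v
            }
            assert previous <= called
            previous = called

    def test_noiseless_panel_recovers_exactly_the_planted_cluster(self):
        cfg = SimulationConfig(
            seed=8, n_degraders=2, n_nondegraders=2, genes_per_strain=24,
            cluster_size=4, cluster_start_rank=11, protein_length=40,
            background_divergence=0.0, cluster_divergence_in_degraders=0.0,
            nb_dispersion=0.0,
        )
        panel, truth = simulate_panel(cfg)
        fc = fold_change_table(simulate_counts(panel, cfg, truth))
        cons = conservation_matrix(panel)
        called = classify_candidates(
            fc, cons, panel.phenotypes, ScreenCriteria(), panel.reference_strain_id
        )
        assert {g for g, v in called.items() if v} == set(truth.cluster_locus_ids)


class TestFindHotspots:
    def test_all_candidates_one_hotspot(self):
        hs = find_hotspots([True] * 6, min_run=2, max_gap=1)
        assert len(hs) == 1
        assert (hs[0].start_rank, hs[0].end_rank, hs[0].n_candidates) == (1, 6, 6)

    def test_no_candidates_no_hotspots(self):
        assert find_hotspots([False] * 9, min_run=2, max_gap=1) == []

    def test_gap_tolerant_run_with_trailing_singleton(self):
        flags = [1, 1, 0, 1, 1, 0, 0, 0, 1]
        hs = find_hotspots([bool(f) for f in flags], min_run=3, max_gap=1)
        assert len(hs) == 1
        h = hs[0]
        assert (h.start_rank, h.end_rank, h.n_candidates, h.span) == (1, 5, 4, 5)
        assert h.locus_ids == ("1", "2", "4", "5")

    def test_min_run_must_be_positive(self):
        with pytest.raises(ConfigError):
            find_hotspots([True], min_run=0, max_gap=1)

    @given(st.lists(st.booleans(), min_size=1, max_size=40),
           st.integers(1, 4), st.integers(0, 3))
    @settings(deadline=None, max_examples=200)
    def test_reversal_mirrors_hotspots(self, flags, min_run, max_gap):
        fwd = find_hotspots(flags, min_run=min_run, max_gap=max_gap)
        rev = find_hotspots(flags[::-1], min_run=min_run, max_gap=max_gap)
        n = len(flags)
        mirrored = sorted(
            (n + 1 - h.end_rank, n + 1 - h.start_rank, h.n_candidates) for h in fwd
        )
        assert sorted((h.start_rank, h.end_rank, h.n_candidates) for h in rev) == mirrored

    def test_multiple_replicons_sorted_by_score(self):
        flags = {
            "p1": [("a", True), ("b", True), ("c", True)],
            "c1": [("x", True), ("y", True), ("z", True), ("w", True)],
        }
        hs = find_hotspots(flags, min_run=2, max_gap=0)
        assert [h.replicon_id for h in hs] == ["c1", "p1"]


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]).p_two_sided == 1.0

    def test_three_vs_three_diagonal(self):
        assert fisher_exact_2x2([[3, 0], [0, 3]]).p_two_sided == pytest.approx(0.1, rel=1e-12)

    def test_five_vs_five_diagonal(self):
        res = fisher_exact_2x2([[5, 0], [0, 5]])
        assert res.p_two_sided == pytest.approx(2 / 252, rel=1e-12)
        assert res.odds_ratio == float("inf")

    def test_negative_entry_rejected(self):
        with pytest.raises(FormatError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    @given(st.tuples(st.integers(0, 10), st.integers(0, 10),
                     st.integers(0, 10), st.integers(0, 10)).filter(lambda t: sum(t) > 0))
    @settings(deadline=None, max_examples=300)
    def test_matches_exact_enumeration_and_scipy(self, cells):
        a, b, c, d = cells
        p = fisher_exact_2x2([[a, b], [c, d]]).p_two_sided
        exact = float(fisher_two_sided_exact([[a, b], [c, d]]))
        assert p == pytest.approx(exact, rel=1e-9, abs=1e-12)
        assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], rel=1e-7, abs=1e-12)

    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)).filter(lambda t: sum(t) > 0))
    @settings(deadline=None, max_examples=150)
    def test_transpose_and_double_swap_invariance(self, cells):
        a, b, c, d = cells
        p = fisher_exact_2x2([[a, b], [c, d]]).p_two_sided
        assert fisher_exact_2x2([[a, c], [b, d]]).p_two_sided == pytest.approx(p, rel=1e-12)
        assert fisher_exact_2x2([[d, c], [b, a]]).p_two_sided == pytest.approx(p, rel=1e-12)


class TestTraitEnrichment:
    def test_perfect_cooccurrence(self):
        presence = {f"s{i}": i < 5 for i in range(10)}
        trait = dict(presence)
        res = trait_enrichment(presence, trait)
        assert res.contingency == ((5, 0), (0, 5))
        assert res.p_two_sided == pytest.approx(2 / 252, rel=1e-12)

    def test_universal_trait_is_uninformative(self):
        presence = {"a": True, "b": True, "c": False}
        trait = {"a": True, "b": True, "c": True}
        assert trait_enrichment(presence, trait).p_two_sided == 1.0

    def test_mismatched_universes_rejected(self):
        with pytest.raises(FormatError):
            trait_enrichment({"a": True}, {"b": True})

    def test_null_pvalues_are_not_small(self):
        # independent balanced presence/trait over 50 strains: the median
        # two-sided p over replicates should be comfortably non-significant
        rng = np.random.default_rng(123)
        strains = [f"s{i}" for i in range(50)]
        ps = []
        for _ in range(200):
            presence = dict(zip(strains, rng.permutation([True] * 25 + [False] * 25)))
            trait = dict(zip(strains, rng.permutation([True] * 25 + [False] * 25)))
            ps.append(trait_enrichment(presence, trait).p_two_sided)
        assert np.median(ps) >= 0.3


class TestEndToEndScreen:
    def test_hotspot_flags_follow_coordinate_order(self):
        cfg = SimulationConfig(
            seed=9, n_degraders=1, n_nondegraders=1, genes_per_strain=12,
            cluster_size=3, cluster_start_rank=5, protein_length=30,
        )
        panel, truth = simulate_panel(cfg)
        cand = {g.locus_id: g.locus_id in truth.cluster_locus_ids
                for g in panel.reference_genes()}
        flags = flags_by_replicon(panel.reference_genes(), cand)
        hs = find_hotspots(flags, min_run=3, max_gap=0)
        assert len(hs) == 1
        assert hs[0].locus_ids == truth.cluster_locus_ids
        assert hs[0].replicon_id == truth.replicon_id
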