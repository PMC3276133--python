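"""Multiplicative-model epistasis: ε arithmetic, filtering, clustering."""

import numpy as np
import pandas as pd
import pytest

from chemscreen import (
    NoiseModel,
    SyntheticCohortSpec,
    average_orientations,
    classify_sign,
    cluster_profiles,
    condition_contrast,
    epistasis_table,
    epsilon,
    epsilon_matrix,
    expected_fitness,
    linked_pairs,
    preset_cohort,
    random_genome_layout,
    reciprocal_correlation,
    reciprocal_filter,
    simulate_epistasis_cohort,
)
from oracles import average_linkage_oracle


class TestArithmetic:
    @pytest.mark.parametrize("wx,wy,expect", [(1.0, 1.0, 1.0), (0.8, 0.5, 0.4), (0.0, 0.9, 0.0)])
    def test_expected_fitness_is_product(self, wx, wy, expect):
        assert expected_fitness(wx, wy) == pytest.approx(expect)

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            expected_fitness(-0.1, 1.0)

    @pytest.mark.parametrize(
        "wxy,wx,wy,expect",
        [(0.4, 0.8, 0.5, 0.0), (0.1, 0.8, 0.5, -0.3), (0.7, 0.8, 0.5, 0.3)],
    )
    def test_epsilon_deviation(self, wxy, wx, wy, expect):
        assert epsilon(wxy, wx, wy) == pytest.approx(expect)

    @pytest.mark.parametrize(
        "wa,wb,keep", [(0.9, 0.9, True), (1.0, 0.5, False), (0.9, 0.5, True)]
    )
    def test_reciprocal_filter_including_exact_boundary(self, wa, wb, keep):
        assert reciprocal_filter(wa, wb) is keep

    @pytest.mark.parametrize("ea,eb,expect", [(-0.2, -0.4, -0.3), (0.1, -0.1, 0.0)])
    def test_orientation_average(self, ea, eb, expect):
        assert average_orientations(ea, eb) == pytest.approx(expect)

    def test_sign_classes_with_deadzone(self):
        assert classify_sign(-0.3) == "aggravating"
        assert classify_sign(0.3) == "alleviating"
        assert classify_sign(0.05) == "none"
        assert classify_sign(-0.08) == "aggravating"  # boundary is classified


class TestReciprocalCorrelation:
    def test_identical_vectors(self):
        assert reciprocal_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_anticorrelation_still_r2_one(self):
        assert reciprocal_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_correlation([1, 1, 1], [1, 2, 3])

    def test_high_r2_at_assay_noise_and_cohort_scale(self):
        """At orientation noise SD 0.05 over ~800 pairs spanning fitness
        0.2–1.0, reciprocal R^2 lands near the assay's reported
        reproducibility (≈0.9)."""
        ok = 0
        for seed in range(50):
            g = np.random.default_rng(seed)
            w = g.uniform(0.2, 1.0, 800)
            a = np.clip(w + g.normal(0, 0.05, 800), 0, None)
            b = np.clip(w + g.normal(0, 0.05, 800), 0, None)
            ok += reciprocal_correlation(a, b) >= 0.9
        assert ok >= 45


class TestEpistasisTable:
    def cohort(self, **kw):
        spec = preset_cohort("epistasis", seed=kw.pop("seed", 0))
        if kw:
            spec = SyntheticCohortSpec(
                strain_ids=spec.strain_ids,
                true_fitness=spec.true_fitness,
                pathway=spec.pathway,
                epsilon_rules=kw.pop("epsilon_rules", spec.epsilon_rules),
                noise=kw.pop("noise", spec.noise),
                seed=spec.seed,
            )
        return spec

    def test_multiplicative_zero_noise_cohort_gives_exact_zero_epsilon(self):
        spec = self.cohort(epsilon_rules={}, noise=NoiseModel(fitness_sd=0.0))
        doubles, singles, _ = simulate_epistasis_cohort(spec, ["treatment"])
        rec = epistasis_table(singles, doubles)
        assert (rec["mean_eps"] == 0.0).all()
        assert not rec["filtered"].any()
        assert (rec["sign_class"] == "none").all()

    def test_zero_noise_clustering_is_degenerate_not_fabricated(self):
        spec = self.cohort(epsilon_rules={}, noise=NoiseModel(fitness_sd=0.0))
        doubles, singles, _ = simulate_epistasis_cohort(spec, ["treatment"])
        mat = epsilon_matrix(epistasis_table(singles, doubles), "treatment")
        with pytest.raises(ValueError, match="usable"):
            cluster_profiles(mat)

    def test_injected_disagreement_is_filtered(self):
        spec = self.cohort(noise=NoiseModel(fitness_sd=0.0))
        genes = [g for g in spec.strain_ids if g != "WT"]
        bad = (genes[0], genes[1])
        doubles, singles, _ = simulate_epistasis_cohort(
            spec, ["treatment"], orientation_disagreement={bad: 0.5}
        )
        rec = epistasis_table(singles, doubles)
        rec = rec.set_index(["gene_x", "gene_y"])
        assert rec.loc[bad, "filtered"]
        assert not rec.drop(index=[bad])["filtered"].any()

    def test_filter_rate_monotone_in_disagreement(self):
        spec = self.cohort(noise=NoiseModel(fitness_sd=0.05))
        genes = [g for g in spec.strain_ids if g != "WT"]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        rates = []
        for delta in (0.0, 0.3, 0.6):
            doubles, singles, _ = simulate_epistasis_cohort(
                spec,
                ["treatment"],
                orientation_disagreement={p: delta for p in pairs},
            )
            rec = epistasis_table(singles, doubles)
            rates.append(rec["filtered"].mean())
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]

    def test_within_pathway_epsilon_recovered(self):
        """Planted ε = +0.15 within one pathway, noise SD 0.02, 10 pairs:
        the mean estimated ε lands in [0.10, 0.20]."""
        spec = preset_cohort("epistasis", seed=3)
        genes = [g for g in spec.strain_ids if g != "WT"][:5]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        doubles, singles, _ = simulate_epistasis_cohort(spec, ["treatment"], pairs=pairs)
        rec = epistasis_table(singles, doubles)
        assert len(rec) == 10
        assert 0.10 <= rec["mean_eps"].mean() <= 0.20

    def test_single_orientation_kept_but_flagged(self):
        singles = pd.DataFrame(
            {"gene": ["a", "b"], "condition": ["c", "c"], "W": [0.8, 0.5]}
        )
        doubles = pd.DataFrame(
            {
                "gene_x": ["a"],
                "gene_y": ["b"],
                "orientation": ["KanNat"],
                "condition": ["c"],
                "W": [0.7],
            }
        )
        rec = epistasis_table(singles, doubles)
        assert rec.loc[0, "single_orientation"]
        assert rec.loc[0, "mean_eps"] == pytest.approx(0.3)

    def test_mean_eps_invariant_to_orientation_label_swap(self):
        spec = self.cohort(seed=4)
        doubles, singles, _ = simulate_epistasis_cohort(spec, ["treatment"])
        swapped = doubles.copy()
        swapped["orientation"] = swapped["orientation"].map(
            {"KanNat": "NatKan", "NatKan": "KanNat"}
        )
        a = epistasis_table(singles, doubles)["mean_eps"]
        b = epistasis_table(singles, swapped)["mean_eps"]
        pd.testing.assert_series_equal(a, b)


class TestClustering:
    def test_identical_profiles_merge_first_at_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=6)
        mat = pd.DataFrame(
            [base, base, rng.normal(size=6), rng.normal(size=6)],
            index=list("abcd"),
        )
        res = cluster_profiles(mat, min_finite_frac=0.0)
        first = res.linkage_matrix[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_profile_and_negation_merge_last_at_two(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=8)
        mat = pd.DataFrame([base, base * 1.5, -base], index=list("abc"))
        res = cluster_profiles(mat, min_finite_frac=0.0)
        assert res.linkage_matrix[-1, 2] == pytest.approx(2.0, abs=1e-9)

    def test_merge_tree_matches_bruteforce_agglomeration(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 9)), index=list("abcde"))
        res = cluster_profiles(mat, min_finite_frac=0.0)
        from chemscreen.epistasis import _pairwise_complete_correlation_distance

        dist = _pairwise_complete_correlation_distance(mat)
        oracle = average_linkage_oracle(dist)
        # reconstruct leaf sets per merge from the scipy linkage matrix
        n = 5
        members = {i: frozenset([i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(res.linkage_matrix):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            exp_set, exp_h = oracle[step]
            assert merged == exp_set
            assert h == pytest.approx(exp_h, abs=1e-9)

    def test_sparse_profile_dropped_with_log(self, caplog):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(4, 8)), index=list("abcd"))
        mat.iloc[3, :7] = np.nan
        res = cluster_profiles(mat, min_finite_frac=0.0)
        assert res.dropped == ["d"]

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"))
        nwk = cluster_profiles(mat, min_finite_frac=0.0).to_newick()
        assert nwk.endswith(";")
        for g in "abcd":
            assert g in nwk

    def test_planted_two_pathway_structure_recovered(self):
        hits = 0
        for seed in range(20):
            spec = preset_cohort("epistasis", seed=seed)
            doubles, singles, _ = simulate_epistasis_cohort(
                spec, ["treatment"]
            )
            mat = epsilon_matrix(epistasis_table(singles, doubles), "treatment")
            labels = cluster_profiles(mat).cut(2)
            part = frozenset(
                frozenset(g for g in labels if labels[g] == c)
                for c in set(labels.values())
            )
            truth = frozenset(
                frozenset(g for g in labels if spec.pathway[g] == p)
                for p in ("A", "B")
            )
            hits += part == truth
        assert hits == 20


class TestConditionContrast:
    def test_identical_conditions_give_zero_delta(self):
        spec = preset_cohort("epistasis", seed=0)
        spec.noise = NoiseModel(fitness_sd=0.0)
        # YPD and control both map to unstressed fitness in this cohort
        doubles, singles, _ = simulate_epistasis_cohort(spec, ["control", "YPD"])
        rec = epistasis_table(singles, doubles)
        table, _ = condition_contrast(rec, control="control", treatment="YPD")
        assert np.allclose(table["delta_eps"], 0.0)

    def test_stress_only_interactions_counted_in_treatment(self):
        spec = preset_cohort("epistasis", seed=1)
        spec.noise = NoiseModel(fitness_sd=0.0)
        doubles, singles, _ = simulate_epistasis_cohort(spec, ["control", "treatment"])
        rec = epistasis_table(singles, doubles)
        _, counts = condition_contrast(rec, control="control", treatment="treatment")
        assert counts["treatment"] > counts["control"]
        assert counts["control"] == 0

    def test_spiked_delta_recovered(self):
        spec = preset_cohort("epistasis", seed=6)
        spec.epsilon_rules = {"treatment": {("A", "A"): 0.3}}
        doubles, singles, _ = simulate_epistasis_cohort(spec, ["control", "treatment"])
        rec = epistasis_table(singles, doubles)
        table, _ = condition_contrast(rec, control="control", treatment="treatment")
        pw = spec.pathway
        spiked = table[
            (table["gene_x"].map(pw) == "A") & (table["gene_y"].map(pw) == "A")
        ]
        assert np.all(np.abs(spiked["delta_eps"] - 0.3) <= 0.05)


class TestLinkedPairs:
    def test_same_chromosome_proximity_flagged(self):
        genes = [f"g{i}" for i in range(6)]
        layout = random_genome_layout(genes, n_chromosomes=2)
        pairs = [("g0", "g1"), ("g0", "g5")]
        flagged = linked_pairs(layout, pairs, max_bp=5000)
        assert ("g0", "g1") in flagged
        assert ("g0", "g5") not in flagged
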