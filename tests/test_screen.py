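"""Pooled-screen scoring: normalization, fold change, tags, rank product."""

import numpy as np
import pandas as pd
import pytest

from chemscreen import (
    ArraySample,
    NoiseModel,
    SyntheticCohortSpec,
    TagMap,
    call_resistant,
    call_sensitive,
    combine_tags,
    default_tag_map,
    log2_fold_change,
    normalize_arrays,
    rank_product,
    score_pooled_screen,
    simulate_screen_arrays,
)
from oracles import rank_product_pfp_oracle


def arr(array_id, role, values, tags=None):
    tags = tags or [f"t{i}" for i in range(len(values))]
    return ArraySample(array_id, role, pd.Series(values, index=tags))


class TestNormalization:
    def test_two_array_toy_means_meet_at_grand_mean(self):
        a = arr("a", "control", [50.0, 150.0])
        b = arr("b", "treatment", [200.0, 400.0])
        out = normalize_arrays([a, b])
        assert out[0].intensities.mean() == pytest.approx(200.0)
        assert out[1].intensities.mean() == pytest.approx(200.0)

    def test_array_at_grand_mean_unchanged(self):
        a = arr("a", "control", [100.0, 300.0])
        b = arr("b", "treatment", [150.0, 250.0])
        out = normalize_arrays([a, b])
        pd.testing.assert_series_equal(out[0].intensities, a.intensities)

    def test_global_array_scaling_cancels_downstream(self):
        ctrl = arr("c", "control", [100.0, 400.0, 900.0])
        trt = arr("t", "treatment", [50.0, 400.0, 1800.0])
        base = log2_fold_change(*[[s for s in normalize_arrays([ctrl, trt]) if s.role == "control"],
                                  [s for s in normalize_arrays([ctrl, trt]) if s.role == "treatment"][0]])
        scaled_trt = arr("t", "treatment", [x * 7.5 for x in [50.0, 400.0, 1800.0]])
        normed = normalize_arrays([ctrl, scaled_trt])
        scaled = log2_fold_change([normed[0]], normed[1])
        pd.testing.assert_series_equal(base["score"], scaled["score"])

    def test_zero_array_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_arrays([arr("a", "control", [0.0, 0.0])])


class TestFoldChange:
    def test_equal_arrays_score_zero(self):
        c = arr("c", "control", [500.0, 800.0])
        t = arr("t", "treatment", [500.0, 800.0])
        assert (log2_fold_change([c], t)["score"] == 0).all()

    def test_fourfold_depletion_scores_two(self):
        c = arr("c", "control", [4000.0, 100.0])
        t = arr("t", "treatment", [1000.0, 100.0])
        assert log2_fold_change([c], t)["score"]["t0"] == pytest.approx(2.0)

    def test_enriched_strain_scores_negative(self):
        c = arr("c", "control", [1000.0, 1000.0])
        t = arr("t", "treatment", [4000.0, 1000.0])
        assert log2_fold_change([c], t)["score"]["t0"] < 0

    def test_zero_treatment_intensity_floored_and_flagged(self):
        c = arr("c", "control", [1000.0, 1000.0])
        t = arr("t", "treatment", [0.0, 500.0])
        out = log2_fold_change([c], t)
        assert out["floored"]["t0"]
        assert np.isfinite(out["score"]["t0"])
        # floor = half the smallest positive treatment intensity
        assert out["score"]["t0"] == pytest.approx(np.log2(1000.0 / 250.0))


class TestCombineTags:
    tm = TagMap({"s1": ("u1", "d1"), "s2": ("u2", "d2"), "s3": ("u3", "d3")})

    def test_mean_and_single_tag_flag(self):
        scores = pd.Series({"u1": 2.0, "d1": 3.0, "u2": 2.0})
        out = combine_tags(scores, self.tm)
        assert out.loc["s1", "score"] == pytest.approx(2.5)
        assert not out.loc["s1", "single_tag"]
        assert out.loc["s2", "score"] == pytest.approx(2.0)
        assert out.loc["s2", "single_tag"]

    def test_strain_with_no_tags_dropped(self):
        scores = pd.Series({"u1": 2.0, "d1": 3.0})
        out = combine_tags(scores, self.tm)
        assert "s3" not in out.index

    def test_matches_per_strain_mean_oracle(self, rng):
        strains = [f"s{i}" for i in range(20)]
        tm = TagMap({s: (f"{s}u", f"{s}d") for s in strains})
        vals = {t: rng.normal() for s in strains for t in (f"{s}u", f"{s}d")}
        out = combine_tags(pd.Series(vals), tm)
        for s in strains:
            assert out.loc[s, "score"] == pytest.approx(
                (vals[f"{s}u"] + vals[f"{s}d"]) / 2
            )

    def test_duplicate_tag_rejected(self):
        with pytest.raises(ValueError, match="tag"):
            TagMap({"s1": ("u", "d"), "s2": ("u", "e")})


class TestRankProduct:
    def test_top_ranked_strain_has_rp_one(self):
        m = pd.DataFrame({"r1": [5.0, 1.0, 0.5], "r2": [9.0, 2.0, 1.0]})
        out = rank_product(m, seed=0)
        assert out.loc[0, "rp"] == pytest.approx(1.0)

    def test_constant_replicate_rejected(self):
        m = pd.DataFrame({"r1": [1.0, 1.0, 1.0], "r2": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            rank_product(m)

    @pytest.mark.parametrize("shape", [(2, 2), (3, 2), (4, 2), (3, 3), (4, 3)])
    def test_pfp_matches_exhaustive_enumeration(self, shape, rng):
        x = rng.normal(size=shape)
        got = rank_product(pd.DataFrame(x), method="exhaustive")
        rp_e, pfp_e = rank_product_pfp_oracle(x)
        np.testing.assert_allclose(got["rp"].to_numpy(), rp_e, rtol=1e-9)
        np.testing.assert_allclose(got["pfp"].to_numpy(), pfp_e, rtol=1e-9)

    def test_invariant_to_monotone_transform(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 2)))
        base = rank_product(x, method="exhaustive")
        warped = rank_product(np.arctan(x) * 3 + 1, method="exhaustive")
        pd.testing.assert_frame_equal(base, warped)


class TestCalls:
    def frame(self, pfp, mean, intensity=1000.0):
        return pd.DataFrame(
            {
                "pfp": pfp,
                "mean_score": mean,
                "rp": np.arange(1, len(pfp) + 1, dtype=float),
                "treatment_intensity": intensity,
            },
            index=[f"s{i}" for i in range(len(pfp))],
        )

    def test_cutoff_selects_significant_depleted(self):
        out = call_sensitive(self.frame([0.01, 0.04, 0.2], [1.0, 2.0, 3.0]), 0.05)
        assert out == ["s0", "s1"]

    def test_no_calls_above_cutoff(self):
        assert call_sensitive(self.frame([0.3, 0.6], [1.0, 1.0]), 0.05) == []

    def test_cutoff_monotonicity(self, rng):
        f = self.frame(rng.uniform(0, 0.2, 10).tolist(), rng.normal(1, 1, 10).tolist())
        assert set(call_sensitive(f, 0.01)) <= set(call_sensitive(f, 0.05))

    def test_resistant_requires_enrichment_and_signal_above_floor(self):
        f = self.frame([0.5, 0.5], [-3.0, -3.0], intensity=[1000.0, 64.0])
        out = call_resistant(f, resistance_threshold=1.0, background_floor=64.0)
        assert out == ["s0"]


class TestEndToEnd:
    def test_zero_noise_resistance_round_trip_recovers_spikes_exactly(self):
        strains = [f"s{i:02d}" for i in range(60)]
        resistant = set(strains[:6])
        fitness = {
            s: {"control": 1.0, "treatment": 1.2 if s in resistant else 0.4}
            for s in strains
        }
        spec = SyntheticCohortSpec(
            strain_ids=strains,
            true_fitness=fitness,
            noise=NoiseModel(intensity_cv=0.0, od_sd=0.0, fitness_sd=0.0),
            seed=5,
        )
        samples = simulate_screen_arrays(spec, "treatment")
        scores = score_pooled_screen(
            samples,
            default_tag_map(strains),
            mode="resistance",
            n_permutations=100,
            seed=5,
        )
        assert set(scores.index[scores["call"] == "resistant"]) == resistant

    def test_scores_invariant_to_scaling_one_array(self):
        strains = [f"s{i}" for i in range(10)]
        fitness = {s: {"control": 1.0, "treatment": 1.0} for s in strains}
        spec = SyntheticCohortSpec(
            strain_ids=strains, true_fitness=fitness, seed=2
        )
        samples = simulate_screen_arrays(spec, "treatment")
        base = score_pooled_screen(
            samples, default_tag_map(strains), n_permutations=50, seed=1
        )
        samples[0].intensities = samples[0].intensities * 13.7
        scaled = score_pooled_screen(
            samples, default_tag_map(strains), n_permutations=50, seed=1
        )
        # scores, significance and calls are scale-free; the reported raw
        # treatment intensity legitimately shifts with the grand mean
        cols = [c for c in base.columns if c != "treatment_intensity"]
        pd.testing.assert_frame_equal(base[cols], scaled[cols])
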