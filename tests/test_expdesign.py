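import itertools

import numpy as np
import pytest

from ordfit.data import RegionMap
from ordfit.expdesign import (
    _canonical_intervals,
    enumerate_conditions,
    enumerate_experiments,
    expected_prediction,
    objective_expected_variance,
    objective_jaccard,
    objective_prediction_variance,
    qualitative_discretize,
    quantitative_design,
    rank_table,
)
from ordfit.scaling import ScalingConfig, model_scale, total_variation


class TestEnumeration:
    def test_paper_scale_count(self):
        conds = enumerate_conditions()
        assert len(conds) == 210         # 21 singles + 189 pairs

    def test_single_species_single_kind(self):
        assert len(enumerate_conditions(["Bam"], ["null"])) == 1

    def test_two_by_two(self):
        conds = enumerate_conditions(["Bam", "Nos"], ["null", "doubled"])
        assert len(conds) == 4 + 4

    def test_pairs_have_distinct_species(self):
        for c in enumerate_conditions(["Bam", "Nos", "Dpp"],
                                      ["null", "heterozygous"]):
            species = [s for s, _ in c.perturbations]
            assert len(species) == len(set(species))

    def test_experiments_cross_measurements(self):
        exps = enumerate_experiments(["Bam"], ["null"], ["pMad", "Nos"])
        assert len(exps) == 2

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            enumerate_conditions([], ["null"])


class TestDiscretize:
    def _oracle(self, y, rm, cfg):
        """Exhaustive-minimum labeling against the same canonical intervals,
        evaluated by direct formula."""
        lo, hi = _canonical_intervals(y, 2, cfg)
        denom = total_variation(y) + cfg.epsilon_fraction * model_scale(y)
        best = None
        for bits in itertools.product((0, 1), repeat=4):
            err = 0.0
            for b, r in zip(bits, rm.germline_regions):
                seg = y[rm.slice0(r)]
                s = np.clip(seg, lo[b], hi[b])
                err += float((((seg - s) / denom) ** 2).mean())
            key = (round(err, 12), sum(bits), bits)
            if best is None or key < best:
                best = key
        return np.asarray(best[2])

    def test_anterior_high_output(self, region_map):
        y = np.concatenate([[1.0, 0.95], np.full(7, 0.1), np.full(8, 0.05)])
        lab = qualitative_discretize(y, region_map)
        assert lab.tolist() == [1, 1, 0, 0]

    def test_flat_output_is_uniform_low(self, region_map):
        lab = qualitative_discretize(np.full(17, 2.0), region_map)
        assert lab.tolist() == [0, 0, 0, 0]

    def test_matches_exhaustive_minimum(self, region_map, rng):
        cfg = ScalingConfig()
        for _ in range(25):
            y = rng.uniform(0, 1, 17)
            lab = qualitative_discretize(y, region_map, cfg)
            assert lab.tolist() == self._oracle(y, region_map, cfg).tolist()


class TestExpectedPrediction:
    @pytest.mark.parametrize("preds,expected", [
        ([[0], [0], [1]], [0]),
        ([[1], [1]], [1]),
        ([[0], [1]], [0]),                # tie goes low
        ([[1, 0, 1, 0]], [1, 0, 1, 0]),   # single representative: identity
    ])
    def test_median_rule(self, preds, expected):
        assert expected_prediction(np.array(preds)).tolist() == expected


class TestDiscriminationObjectives:
    def test_agreement_gives_zero(self):
        P = np.array([[0, 1, 0, 1], [0, 1, 0, 1]])
        ens = {"a": P, "b": P.copy(), "c": P.copy()}
        assert objective_expected_variance(ens) == 0.0
        assert objective_jaccard(ens) == 0.0

    def test_opposite_uniform_predictions_maximal(self):
        ens = {"a": np.zeros((3, 4), int), "b": np.ones((3, 4), int)}
        # Bernoulli variance 0.25 per region, 4 regions
        assert objective_expected_variance(ens) == pytest.approx(1.0)
        assert objective_jaccard(ens) == pytest.approx(1.0)   # one pair

    def test_mutually_exclusive_sets_equal_number_of_pairs(self):
        ens = {"a": np.array([[0, 0, 0, 0]]), "b": np.array([[1, 0, 0, 0]]),
               "c": np.array([[0, 1, 0, 0]])}
        assert objective_jaccard(ens) == pytest.approx(3.0)

    def test_duplicate_representative_does_not_change_jaccard(self):
        a = np.array([[0, 0, 1, 1], [1, 1, 0, 0]])
        b = np.array([[0, 0, 1, 1], [0, 1, 0, 1]])
        before = objective_jaccard({"a": a, "b": b})
        a_dup = np.vstack([a, a[0]])
        assert objective_jaccard({"a": a_dup, "b": b}) == before

    def test_jaccard_matches_hand_count(self):
        # |A|=2, |B|=2, overlap 1: J = 2*1/(2+2) = 0.5 -> dissimilarity 0.5
        a = np.array([[0, 0, 1, 1], [1, 1, 0, 0]])
        b = np.array([[0, 0, 1, 1], [0, 1, 0, 1]])
        assert objective_jaccard({"a": a, "b": b}) == pytest.approx(0.5)

    def test_expected_variance_matches_direct_formula(self, rng):
        ens = {f"m{i}": rng.integers(0, 2, (5, 4)) for i in range(4)}
        direct = sum(
            np.var([float(np.mean(P[:, r]) > 0.5) for P in ens.values()])
            for r in range(4))
        assert objective_expected_variance(ens) == pytest.approx(direct)

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            objective_expected_variance({"a": np.zeros((2, 4))})


class TestPredictionVariance:
    def test_within_model_agreement_gives_zero(self):
        ens = {"a": np.tile([0, 1, 0, 1], (4, 1)),
               "b": np.tile([1, 1, 1, 1], (3, 1))}
        assert objective_prediction_variance(ens) == 0.0

    def test_only_split_models_contribute(self):
        split = np.array([[0, 0, 0, 0], [1, 0, 0, 0]])
        agree = np.zeros((2, 4), int)
        one = objective_prediction_variance({"a": split, "b": agree})
        assert one == objective_prediction_variance({"a": split})

    def test_matches_direct_recomputation(self, rng):
        ens = {f"m{i}": rng.integers(0, 2, (6, 4)) for i in range(3)}
        direct = sum(float(P.var(axis=0).sum()) for P in ens.values())
        assert objective_prediction_variance(ens) == pytest.approx(direct)

    def test_permutation_invariance(self, rng):
        P = rng.integers(0, 2, (6, 4))
        ens1 = {"a": P, "b": rng.integers(0, 2, (4, 4))}
        ens2 = {"a": P[::-1], "b": ens1["b"][::-1]}
        assert objective_prediction_variance(ens1) == \
            objective_prediction_variance(ens2)


class TestQuantitativeDesign:
    def _tables(self, rng, n_models=3, n_reps=4):
        return {f"m{i}": rng.normal(size=(n_reps, 2, 3, 17))
                for i in range(n_models)}

    def test_identical_tables_give_zero_discrimination(self, rng):
        t = rng.normal(size=(4, 2, 3, 17))
        tables = {"a": t, "b": t.copy()}
        df = quantitative_design(tables, ["p1", "p2"], ["s1", "s2", "s3"],
                                 "discriminate")
        assert np.allclose(df["score"], 0.0)

    def test_single_representative_gives_zero_refinement(self, rng):
        tables = {"a": rng.normal(size=(1, 2, 3, 17)),
                  "b": rng.normal(size=(1, 2, 3, 17))}
        df = quantitative_design(tables, ["p1", "p2"], ["s1", "s2", "s3"],
                                 "refine")
        assert np.allclose(df["score"], 0.0)

    def test_matches_bruteforce_recomputation(self, rng, region_map):
        tables = self._tables(rng)
        for mode in ("discriminate", "refine"):
            df = quantitative_design(tables, ["p1", "p2"], ["s1", "s2", "s3"],
                                     mode)
            for _, row in df.iterrows():
                j = ["p1", "p2"].index(row["experiment"])
                k = ["s1", "s2", "s3"].index(row["measured"])
                per_cell = []
                for c in range(17):
                    vals = {m: t[:, j, k, c] for m, t in tables.items()}
                    if mode == "discriminate":
                        per_cell.append(np.var([v.mean() for v in vals.values()]))
                    else:
                        per_cell.append(sum(v.var() for v in vals.values()))
                per_cell = np.asarray(per_cell)
                expect = sum(per_cell[region_map.slice0(r)].mean()
                             for r in region_map.germline_regions)
                assert row["score"] == pytest.approx(expect)

    def test_axis_mismatch_rejected(self, rng):
        tables = {"a": rng.normal(size=(2, 2, 3, 17)),
                  "b": rng.normal(size=(2, 2, 2, 17))}
        with pytest.raises(ValueError):
            quantitative_design(tables, ["p1", "p2"], ["s1", "s2", "s3"],
                                "discriminate")


class TestRankTable:
    def test_normalization_and_order(self):
        import pandas as pd
        df = pd.DataFrame(dict(experiment=list("abcd"), measured=["x"] * 4,
                               objective=["o"] * 4, score=[1.0, 3.0, 2.0, 4.0]))
        ranked = rank_table(df)
        assert ranked["normalized"].iloc[0] == 1.0
        assert ranked["normalized"].iloc[-1] == 0.0
        assert list(ranked["experiment"]) == ["d", "b", "c", "a"]

    def test_constant_scores_normalize_to_zero(self):
        import pandas as pd
        df = pd.DataFrame(dict(experiment=list("ab"), measured=["x"] * 2,
                               objective=["o"] * 2, score=[2.0, 2.0]))
        assert np.allclose(rank_table(df)["normalized"], 0.0)

    def test_top_k(self):
        import pandas as pd
        df = pd.DataFrame(dict(experiment=list("abcd"), measured=["x"] * 4,
                               objective=["o"] * 4, score=[1, 3, 2, 4]))
        assert len(rank_table(df, top_k=2)) == 2
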