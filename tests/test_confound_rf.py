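import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codonsig.cog_enrich import NO, YES, PhenotypeMatrix
from codonsig.confound_rf import (
    CogDataset,
    UntestableDataset,
    build_cog_dataset,
    cv_auc,
    randomization_test,
    shuffle_feature,
)
from codonsig.he_predict import ClassifierConfig

FAST_RF = ClassifierConfig(n_estimators=40)


def separable_dataset(n=60, seed=0, informative=True):
    """Labels determined by feature 'f0' (or independent of everything)."""
    rng = np.random.default_rng(seed)
    genomes = np.array([f"g{i:03d}" for i in range(n)])
    f0 = rng.random(n) < 0.5
    y = f0.astype(int) if informative else (rng.random(n) < 0.5).astype(int)
    features = pd.DataFrame(
        {
            "f0": np.where(f0, YES, NO),
            "f1": np.where(rng.random(n) < 0.5, YES, NO),
            "f2": np.where(rng.random(n) < 0.5, YES, NO),
        }
    )
    return CogDataset("COGX", features, y, genomes)


def matrix_from(df: pd.DataFrame) -> PhenotypeMatrix:
    return PhenotypeMatrix(df)


class TestBuildDataset:
    def test_paralogs_are_separate_instances(self):
        m = matrix_from(pd.DataFrame({"p": [YES, NO, YES]}, index=["a", "b", "c"]))
        cogs = {"c1": [("a", "x1"), ("a", "x2"), ("b", "y1"), ("c", "z1")]}
        he = {"x1": True, "x2": False, "y1": False, "z1": True}
        ds = build_cog_dataset("c1", cogs, he, m)
        assert len(ds.y) == 4
        # instances of one genome share feature values
        assert (ds.features.iloc[0] == ds.features.iloc[1]).all()

    def test_missing_phenotype_instances_retained(self):
        m = matrix_from(pd.DataFrame({"p": [YES, None]}, index=["a", "b"]))
        cogs = {"c1": [("a", "x"), ("b", "y")]}
        ds = build_cog_dataset("c1", cogs, {"x": True, "y": False}, m)
        assert len(ds.y) == 2
        enc = ds.encoded()
        assert enc[1, 0] == 2  # missing encoded as its own category

    def test_empty_cog_is_error(self):
        m = matrix_from(pd.DataFrame({"p": [YES]}, index=["a"]))
        with pytest.raises(ValueError):
            build_cog_dataset("c1", {"c1": []}, {}, m)
        with pytest.raises(KeyError):
            build_cog_dataset("nope", {"c1": []}, {}, m)

    def test_single_class_flagged_untestable(self):
        m = matrix_from(pd.DataFrame({"p": [YES, NO]}, index=["a", "b"]))
        ds = build_cog_dataset(
            "c1", {"c1": [("a", "x"), ("b", "y")]}, {"x": True, "y": True}, m
        )
        assert not ds.testable
        with pytest.raises(UntestableDataset):
            cv_auc(ds, seed=0, classifier=FAST_RF)


class TestCvAuc:
    def test_separable_signal(self):
        ds = separable_dataset(n=60, seed=1)
        assert cv_auc(ds, n_folds=5, seed=0, classifier=FAST_RF) >= 0.95

    def test_null_signal(self):
        aucs = [
            cv_auc(separable_dataset(n=60, seed=s, informative=False),
                   n_folds=5, seed=s, classifier=FAST_RF)
            for s in range(5)
        ]
        assert all(0.3 <= a <= 0.7 for a in aucs)

    def test_deterministic_under_seed(self):
        ds = separable_dataset(n=40, seed=2)
        a = cv_auc(ds, n_folds=5, seed=3, classifier=FAST_RF)
        b = cv_auc(ds, n_folds=5, seed=3, classifier=FAST_RF)
        assert a == b


class TestShuffle:
    def test_multiset_preserved_and_others_untouched(self):
        ds = separable_dataset(n=30, seed=4)
        sh = shuffle_feature(ds, "f0", seed=9)
        assert sorted(sh.features["f0"]) == sorted(ds.features["f0"])
        assert (sh.features["f1"] == ds.features["f1"]).all()
        assert (sh.features["f2"] == ds.features["f2"]).all()
        assert np.array_equal(sh.y, ds.y)

    def test_genome_wise_permutation_keeps_paralogs_tied(self):
        m = matrix_from(
            pd.DataFrame({"p": [YES, NO, YES, NO]}, index=list("abcd"))
        )
        cogs = {"c1": [(g, f"{g}{i}") for g in "abcd" for i in range(3)]}
        he = {f"{g}{i}": (i == 0) for g in "abcd" for i in range(3)}
        ds = build_cog_dataset("c1", cogs, he, m)
        for seed in range(5):
            sh = shuffle_feature(ds, "p", seed=seed)
            for g in "abcd":
                vals = sh.features["p"][sh.genome_ids == g]
                assert len(set(vals)) == 1


class TestRandomization:
    def test_z_and_p_formula(self):
        # verdict arithmetic on a held-fixed AUC configuration:
        # z = (0.9 - 0.5)/0.1 = 4 -> p = Phi_tail(4) ~ 3.17e-5
        z = (0.9 - 0.5) / 0.1
        assert stats.norm.sf(z) == pytest.approx(3.167e-5, rel=1e-3)

    def test_informative_feature_declared_independent(self):
        ds = separable_dataset(n=60, seed=6)
        v = randomization_test(ds, "f0", n_shuffles=10, n_folds=5, seed=1,
                               classifier=FAST_RF)
        assert v.auc_original > np.mean(v.auc_shuffled)
        assert v.independent

    def test_uninformative_feature_rejected(self):
        ds = separable_dataset(n=60, seed=7)
        v = randomization_test(ds, "f1", n_shuffles=10, n_folds=5, seed=2,
                               classifier=FAST_RF)
        assert not v.independent

    def test_duplicate_feature_is_confounded(self):
        # f_dup carries no unique information beyond f0
        ds = separable_dataset(n=60, seed=8)
        ds.features["f_dup"] = ds.features["f0"]
        v = randomization_test(ds, "f_dup", n_shuffles=10, n_folds=5, seed=3,
                               classifier=FAST_RF)
        assert not v.independent

    def test_duplicate_feature_p_values_uniform(self):
        # a column duplicating another carries no unique information, so its
        # randomization-test P values over replicates should look uniform
        from scipy import stats

        rng_clf = ClassifierConfig(n_estimators=20)
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 40
            f0 = rng.random(n) < 0.5
            y = f0.astype(int)
            flip = rng.random(n) < 0.2  # label noise keeps folds non-degenerate
            y = np.where(flip, 1 - y, y)
            feats = pd.DataFrame(
                {
                    "f0": np.where(f0, YES, NO),
                    "f_dup": np.where(f0, YES, NO),
                    "f1": np.where(rng.random(n) < 0.5, YES, NO),
                }
            )
            ds = CogDataset("C", feats, y, np.array([f"g{i}" for i in range(n)]))
            v = randomization_test(
                ds, "f_dup", n_shuffles=15, n_folds=3, seed=seed + 5000,
                classifier=rng_clf,
            )
            ps.append(v.p_one_tailed)
        assert stats.kstest(np.array(ps), "uniform").pvalue > 0.01

    def test_bitwise_reproducible(self):
        ds = separable_dataset(n=40, seed=9)
        a = randomization_test(ds, "f0", n_shuffles=5, n_folds=4, seed=11,
                               classifier=FAST_RF)
        b = randomization_test(ds, "f0", n_shuffles=5, n_folds=4, seed=11,
                               classifier=FAST_RF)
        assert a.auc_original == b.auc_original
        assert np.array_equal(a.auc_shuffled, b.auc_shuffled)
        assert a.p_one_tailed == b.p_one_tailed
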