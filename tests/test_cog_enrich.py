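import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from codonsig.cog_enrich import (
    NO,
    YES,
    PhenotypeMatrix,
    assemble_features,
    descriptor_features,
    discretize,
    estimate_screen_fdr,
    filter_cogs,
    fisher_two_tailed,
    screen_phenotype,
)


def fisher_oracle(a, b, c, d):
    """Exact two-tailed Fisher P by rational-arithmetic enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = {
        k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), math.comb(n, c1))
        for k in range(lo, hi + 1)
    }
    obs = pmf[a]
    total = sum(p for p in pmf.values() if p <= obs * (1 + Fraction(1, 10**7)))
    return float(total)


class TestFisher:
    def test_stated_table(self):
        assert fisher_two_tailed(8, 2, 2, 8) == pytest.approx(0.0230, abs=5e-5)

    def test_symmetric_table_is_one(self):
        assert fisher_two_tailed(5, 5, 5, 5) == pytest.approx(1.0)

    def test_degenerate_margin_convention(self):
        assert fisher_two_tailed(0, 0, 3, 7) == 1.0
        assert fisher_two_tailed(3, 7, 0, 0) == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
            assert fisher_two_tailed(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-9
            )

    def test_matches_scipy_cross_check(self, rng):
        # independent second route: scipy's own implementation
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 21, 4))
            if (a + b) and (c + d) and (a + c) and (b + d):
                assert fisher_two_tailed(a, b, c, d) == pytest.approx(
                    fisher_exact([[a, b], [c, d]])[1], rel=1e-7, abs=1e-12
                )

    def test_polarity_swap_leaves_p_unchanged(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 12, 4))
            assert fisher_two_tailed(a, b, c, d) == pytest.approx(
                fisher_two_tailed(c, d, a, b), rel=1e-12
            )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_tailed(-1, 2, 3, 4)


class TestScreenFdr:
    @pytest.mark.parametrize(
        "tested,significant,expected",
        [
            (2847, 295, 9.65),
            (1887, 160, 11.8),
            (2287, 346, 6.61),
            (1863, 55, 33.9),
            (100, 1, 100.0),
        ],
    )
    def test_expected_false_positive_estimate(self, tested, significant, expected):
        assert estimate_screen_fdr(tested, significant, 0.01) == pytest.approx(
            expected, abs=0.05
        )

    def test_scale_invariance(self):
        assert estimate_screen_fdr(500, 40, 0.01) == pytest.approx(
            estimate_screen_fdr(1000, 80, 0.01)
        )

    def test_zero_significant_undefined(self):
        with pytest.raises(ValueError):
            estimate_screen_fdr(100, 0, 0.01)


class TestDescriptors:
    def test_cumulative_indicators(self):
        q = (1.0, 2.0, 3.0)
        assert discretize(0.5, q) == (False, False, False)
        assert discretize(3.5, q) == (True, True, True)
        assert discretize(2.0, q) == (True, True, False)

    def test_six_features_emitted(self):
        idx = [f"g{i}" for i in range(8)]
        gc = pd.Series(np.linspace(0.3, 0.7, 8), index=idx)
        size = pd.Series(np.linspace(1e6, 8e6, 8), index=idx)
        df = descriptor_features(gc, size)
        assert df.shape == (8, 6)
        assert set(df.stack().unique()) <= {YES, NO}

    def test_feature_total_is_one_hundred(self, rng):
        # 24 phenotypes + 6 descriptors + 70 taxonomy indicators
        idx = [f"g{i}" for i in range(10)]
        phen = pd.DataFrame(
            {f"phen_{i:02d}": [YES] * 10 for i in range(24)}, index=idx
        )
        tax = pd.DataFrame(
            {f"tax_{i:03d}": [NO] * 10 for i in range(70)}, index=idx
        )
        gc = pd.Series(rng.uniform(0.3, 0.7, 10), index=idx)
        size = pd.Series(rng.uniform(1e6, 9e6, 10), index=idx)
        matrix = assemble_features(phen, gc, size, tax)
        assert len(matrix.features) == 100


class TestFilterCogs:
    def test_boundaries(self):
        cogs = {
            "small": ["x"] * 19,
            "lo": ["x"] * 20,
            "hi": ["x"] * 10_000,
            "big": ["x"] * 10_001,
        }
        assert set(filter_cogs(cogs)) == {"lo", "hi"}


def build_matrix(values: dict[str, str | None]) -> PhenotypeMatrix:
    df = pd.DataFrame({"phen": pd.Series(values, dtype=object)})
    return PhenotypeMatrix(df)


class TestScreen:
    def test_identical_fractions_fail(self):
        matrix = build_matrix({"gp": YES, "gn": NO})
        cogs = {"c": [("gp", f"p{i}") for i in range(10)] + [("gn", f"n{i}") for i in range(10)]}
        he = {f"p{i}": i < 5 for i in range(10)} | {f"n{i}": i < 5 for i in range(10)}
        records, summary = screen_phenotype(cogs, he, matrix, "phen")
        assert records[0].fold == pytest.approx(1.0)
        assert not records[0].passes
        assert summary.n_tested == 1 and summary.n_significant == 0

    def test_planted_enrichment_passes(self):
        matrix = build_matrix({"gp": YES, "gn": NO})
        cogs = {"c": [("gp", f"p{i}") for i in range(40)] + [("gn", f"n{i}") for i in range(40)]}
        he = {f"p{i}": i < 32 for i in range(40)} | {f"n{i}": i < 4 for i in range(40)}
        records, summary = screen_phenotype(cogs, he, matrix, "phen")
        r = records[0]
        assert r.fold == pytest.approx((32 / 40) / (4 / 40))
        assert r.passes and summary.n_significant == 1

    def test_empty_group_not_tested(self):
        # catalase-like case: no representatives in negatives
        matrix = build_matrix({"gp": YES, "gn": NO})
        cogs = {"c": [("gp", f"p{i}") for i in range(25)]}
        he = {f"p{i}": i < 20 for i in range(25)}
        records, summary = screen_phenotype(cogs, he, matrix, "phen")
        assert records == [] and summary.n_tested == 0

    def test_zero_he_in_negatives_gives_infinite_fold(self):
        matrix = build_matrix({"gp": YES, "gn": NO})
        cogs = {"c": [("gp", f"p{i}") for i in range(20)] + [("gn", f"n{i}") for i in range(20)]}
        he = {f"p{i}": i < 15 for i in range(20)} | {f"n{i}": False for i in range(20)}
        records, _ = screen_phenotype(cogs, he, matrix, "phen")
        assert records[0].fold == math.inf and records[0].passes

    def test_missing_phenotype_organisms_excluded(self):
        matrix = build_matrix({"gp": YES, "gn": NO, "gm": None})
        cogs = {
            "c": [("gp", "p0"), ("gn", "n0"), ("gm", "m0")],
        }
        he = {"p0": True, "n0": False, "m0": True}
        records, _ = screen_phenotype(cogs, he, matrix, "phen")
        r = records[0]
        assert (r.a + r.b + r.c + r.d) == 2  # gm not counted

    def test_unknown_phenotype_hard_error(self):
        matrix = build_matrix({"gp": YES})
        with pytest.raises(KeyError):
            screen_phenotype({}, {}, matrix, "nope")

    def test_polarity_swap_inverts_fold(self):
        pos = build_matrix({"gp": YES, "gn": NO})
        neg = build_matrix({"gp": NO, "gn": YES})
        cogs = {"c": [("gp", f"p{i}") for i in range(30)] + [("gn", f"n{i}") for i in range(30)]}
        he = {f"p{i}": i < 18 for i in range(30)} | {f"n{i}": i < 6 for i in range(30)}
        r1, _ = screen_phenotype(cogs, he, pos, "phen")
        r2, _ = screen_phenotype(cogs, he, neg, "phen")
        assert r1[0].fold == pytest.approx(1 / r2[0].fold)
        assert r1[0].p_two_tailed == pytest.approx(r2[0].p_two_tailed, rel=1e-9)


class TestPhenotypeMatrix:
    def test_tsv_round_trip(self, tmp_path, tiny_world):
        m = tiny_world.matrix
        m.to_tsv(tmp_path / "m.tsv")
        back = PhenotypeMatrix.from_tsv(tmp_path / "m.tsv")
        assert back.features == m.features
        assert back.df.fillna("_").equals(m.df.fillna("_"))

    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeMatrix(pd.DataFrame({"f": ["maybe"]}, index=["g"]))
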