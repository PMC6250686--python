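"""Normalization, abundance units and the NB differential-expression test."""

import numpy as np
import pandas as pd
import pytest

from heterophylly.expression import (
    CONTRAST_LABELS,
    CountMatrix,
    TranscriptStructure,
    abundance,
    de_test,
    estimate_dispersion,
    filter_lncrna_candidates,
    normalize_counts,
    pairwise_contrasts,
    presence_sets,
    size_factors,
    stage_means,
)


def _matrix(counts, groups, rna_class="mRNA"):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    return CountMatrix(counts=df, groups=pd.Series(groups), rna_class=rna_class)


def _two_group_matrix(rng, mean_a, mean_b, alpha, n_genes=1, n=3):
    """NB counts for a Li-vs-Bo design with the given group means."""

    def draw(mean):
        if alpha == 0:
            return rng.poisson(mean, size=(n_genes, n))
        r = 1 / alpha
        return rng.negative_binomial(r, r / (r + mean), size=(n_genes, n))

    counts = np.hstack([draw(mean_a), draw(mean_b)])
    cols = [f"Li{i+1}" for i in range(n)] + [f"Bo{i+1}" for i in range(n)]
    df = pd.DataFrame(counts, columns=cols, index=[f"g{i}" for i in range(n_genes)])
    groups = pd.Series({c: c[:2] for c in cols})
    return CountMatrix(counts=df, groups=groups)


class TestSizeFactors:
    def test_proportional_columns(self):
        m = _matrix({"a": [10, 20, 5], "b": [20, 40, 10]}, {"a": "Li", "b": "Bo"})
        f = size_factors(m)
        assert f["a"] == pytest.approx(1 / np.sqrt(2))
        assert f["b"] == pytest.approx(np.sqrt(2))

    def test_identical_columns(self):
        m = _matrix({"a": [3, 7], "b": [3, 7]}, {"a": "Li", "b": "Bo"})
        assert size_factors(m).tolist() == pytest.approx([1.0, 1.0])

    def test_zero_rows_excluded(self):
        m = _matrix({"a": [0, 10], "b": [5, 10]}, {"a": "Li", "b": "Bo"})
        assert size_factors(m).tolist() == pytest.approx([1.0, 1.0])

    def test_no_all_positive_row_raises(self):
        m = _matrix({"a": [0, 10], "b": [5, 0]}, {"a": "Li", "b": "Bo"})
        with pytest.raises(ValueError, match="median-of-ratios"):
            size_factors(m)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scaling_one_sample_scales_its_relative_factor(self, c):
        """Scaling a sample's counts by c scales its factor by c relative to
        the others (factors are defined against the geometric-mean
        pseudo-reference, so only ratios are identifiable) and leaves the
        normalized profile unchanged up to one global constant."""
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(50, size=(100, 4)),
            columns=list("abcd"),
            index=[f"g{i}" for i in range(100)],
        ).astype(float)
        f0 = size_factors(counts)
        scaled = counts.copy()
        scaled["b"] *= c
        f1 = size_factors(scaled)
        assert (f1["b"] / f1["a"]) / (f0["b"] / f0["a"]) == pytest.approx(c, rel=1e-9)
        ratio = normalize_counts(scaled, f1) / normalize_counts(counts, f0)
        assert float(ratio.max().max()) == pytest.approx(float(ratio.min().min()))


class TestNormalization:
    def test_division_by_factor(self):
        m = _matrix({"a": [10], "b": [10]}, {"a": "Li", "b": "Bo"})
        out = normalize_counts(m, pd.Series({"a": 2.0, "b": 1.0}))
        assert out.loc["g0", "a"] == 5.0
        assert out.loc["g0", "b"] == 10.0

    def test_nonpositive_factor_rejected(self):
        m = _matrix({"a": [10], "b": [10]}, {"a": "Li", "b": "Bo"})
        with pytest.raises(ValueError):
            normalize_counts(m, pd.Series({"a": 0.0, "b": 1.0}))

    def test_stage_means_of_proportional_columns(self):
        profile = [10.0, 20.0, 5.0]
        m = _matrix(
            {"Li1": profile, "Li2": [2 * x for x in profile]},
            {"Li1": "Li", "Li2": "Li"},
        )
        normalized = normalize_counts(m, size_factors(m))
        means = stage_means(normalized, m.groups)
        expected = np.sqrt(2) * np.array(profile)  # shared profile, geomean scale
        assert means["Li"].to_numpy() == pytest.approx(expected)


class TestAbundance:
    def test_fpkm_definition(self):
        counts = pd.DataFrame({"s": [1000, 999000]}, index=["g", "rest"])
        out = abundance(counts, "FPKM", lengths={"g": 1000, "rest": 1000})
        assert out.loc["g", "s"] == pytest.approx(1000.0)

    def test_tpm_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(30, size=(50, 3)), index=[f"g{i}" for i in range(50)]
        )
        lengths = pd.Series(
            rng.integers(200, 2000, size=50), index=counts.index
        )
        out = abundance(counts, "TPM", lengths=lengths)
        assert out.sum(axis=0).to_numpy() == pytest.approx([1e6] * 3, rel=1e-6)

    def test_rpm_definition_and_linearity(self):
        counts = pd.DataFrame({"s": [250, 4999750]}, index=["g", "rest"])
        out = abundance(counts, "RPM")
        assert out.loc["g", "s"] == pytest.approx(50.0)
        doubled = abundance(counts * 2, "RPM")  # totals double too
        pd.testing.assert_frame_equal(out, doubled)

    def test_missing_length_rejected(self):
        counts = pd.DataFrame({"s": [10]}, index=["g"])
        with pytest.raises(ValueError, match="length"):
            abundance(counts, "FPKM", lengths={})


class TestDispersion:
    def test_moment_formula(self):
        # two stages, each with within-group mean 100 and variance 600
        a = np.array([100 - 24.494897, 100, 100 + 24.494897])  # var = 600
        df = pd.DataFrame(
            [np.concatenate([a, a])],
            columns=["Li1", "Li2", "Li3", "Bo1", "Bo2", "Bo3"],
            index=["g0"],
        )
        groups = pd.Series({c: c[:2] for c in df.columns})
        alpha = estimate_dispersion(df, groups, ("Li", "Bo"))
        assert alpha["g0"] == pytest.approx((600 - 100) / 100**2, rel=1e-4)

    def test_underdispersed_hits_floor(self):
        df = pd.DataFrame(
            [[100, 100, 100, 100, 100, 100]],
            columns=["Li1", "Li2", "Li3", "Bo1", "Bo2", "Bo3"],
            index=["g0"],
        )
        groups = pd.Series({c: c[:2] for c in df.columns})
        assert estimate_dispersion(df, groups, ("Li", "Bo"))["g0"] == 1e-8

    def test_single_replicate_rejected(self):
        df = pd.DataFrame([[1, 2]], columns=["Li1", "Bo1"], index=["g0"])
        groups = pd.Series({"Li1": "Li", "Bo1": "Bo"})
        with pytest.raises(ValueError, match="replicate"):
            estimate_dispersion(df, groups, ("Li", "Bo"))

    def test_poisson_data_mostly_at_floor(self):
        rng = np.random.default_rng(5)
        m = _two_group_matrix(rng, 100, 100, alpha=0, n_genes=500)
        normalized = normalize_counts(m, size_factors(m))
        alpha = estimate_dispersion(normalized, m.groups, ("Li", "Bo"))
        # for Poisson data the MoM estimate is negative about half the time
        assert (alpha == 1e-8).mean() > 0.3
        assert alpha.median() < 0.02


class TestDeTest:
    def test_identical_groups_are_null(self):
        df = pd.DataFrame(
            [[50] * 6],
            columns=["Li1", "Li2", "Li3", "Bo1", "Bo2", "Bo3"],
            index=["g0"],
        )
        m = CountMatrix(counts=df, groups=pd.Series({c: c[:2] for c in df.columns}))
        res = de_test(m, "Li", "Bo")
        assert res.loc["g0", "log2fc"] == 0.0
        assert res.loc["g0", "pvalue"] >= 0.99

    def test_null_type_i_error_near_nominal(self):
        rng = np.random.default_rng(42)
        m = _two_group_matrix(rng, 100, 100, alpha=0.05, n_genes=2000)
        res = de_test(m, "Li", "Bo")
        assert 0.03 <= res["significant"].mean() <= 0.07

    def test_strong_signal_detected(self):
        # unit size factors: every gene carries the same planted signal, so
        # the mostly-null assumption behind median-of-ratios does not apply
        rng = np.random.default_rng(7)
        m = _two_group_matrix(rng, 10, 1000, alpha=0.01, n_genes=20)
        ones = pd.Series(1.0, index=m.counts.columns)
        res = de_test(m, "Li", "Bo", factors=ones)
        assert (res["pvalue"] < 1e-3).all()
        assert (res["log2fc"] > 5).all()

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        m = _two_group_matrix(rng, 80, 150, alpha=0.05, n_genes=50)
        fwd = de_test(m, "Li", "Bo")
        rev = de_test(m, "Bo", "Li")
        assert fwd["log2fc"].to_numpy() == pytest.approx(-rev["log2fc"].to_numpy())
        assert fwd["pvalue"].to_numpy() == pytest.approx(rev["pvalue"].to_numpy())

    def test_missing_stage_rejected(self):
        m = _two_group_matrix(np.random.default_rng(0), 10, 10, 0.05, n_genes=2)
        with pytest.raises(ValueError, match="Ov"):
            de_test(m, "Li", "Ov")


class TestPairwiseContrasts:
    def test_six_contrasts_in_conventional_order(self, small_dataset):
        tables = pairwise_contrasts(small_dataset.counts["miRNA"])
        assert list(tables) == ["A", "B", "C", "D", "E", "F"]
        expected = ["La/Li", "Ov/Li", "Bo/Li", "Ov/La", "Bo/La", "Bo/Ov"]
        assert [t["contrast"].iloc[0] for t in tables.values()] == expected

    def test_two_stage_matrix_rejected(self):
        m = _two_group_matrix(np.random.default_rng(0), 10, 10, 0.05, n_genes=2)
        with pytest.raises(ValueError, match="Ov"):
            pairwise_contrasts(m)


class TestLncrnaFilter:
    @pytest.mark.parametrize(
        "length,exons,kept",
        [
            (150, 3, False),  # too short
            (250, 1, False),  # too few exons
            (200, 2, True),  # both boundaries inclusive
            (1000, 5, True),
        ],
    )
    def test_structural_rules(self, length, exons, kept):
        out = filter_lncrna_candidates([TranscriptStructure("t", length, exons)])
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        assert filter_lncrna_candidates([]) == []


class TestPresenceSets:
    def test_toy_matrix_matches_hand_enumeration(self):
        cols = ["Li1", "Li2", "La1", "La2", "Ov1", "Ov2", "Bo1", "Bo2"]
        rows = {
            "only_li": [5, 3, 0, 0, 0, 0, 0, 0],
            "everywhere": [1, 1, 1, 1, 1, 1, 1, 1],
            "li_and_bo": [2, 0, 0, 0, 0, 0, 0, 4],
            "zero": [0, 0, 0, 0, 0, 0, 0, 0],
            "only_bo": [0, 0, 0, 0, 0, 0, 9, 9],
            "ov_only_strict": [0, 0, 0, 0, 3, 3, 0, 0],
        }
        df = pd.DataFrame(rows, index=cols).T
        m = CountMatrix(counts=df, groups=pd.Series({c: c[:2] for c in cols}))
        out = presence_sets(m, min_count=1, min_samples=1)
        assert out["exclusive"] == {"Li": 1, "La": 0, "Ov": 1, "Bo": 1}
        assert out["expressed"]["Li"] == {"only_li", "everywhere", "li_and_bo"}
        assert out["intersections"][frozenset({"Li", "Bo"})] == 1
        assert "zero" not in set().union(*out["expressed"].values())

    def test_min_samples_threshold(self):
        cols = ["Li1", "Li2", "Bo1", "Bo2"]
        df = pd.DataFrame({"g": [3, 0, 0, 0]}, index=cols).T
        m = CountMatrix(counts=df, groups=pd.Series({c: c[:2] for c in cols}))
        strict = presence_sets(m, min_count=1, min_samples=2)
        assert strict["expressed"]["Li"] == set()
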