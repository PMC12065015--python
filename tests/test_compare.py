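"""Pairwise comparison: R2, characteristic exclusion, strength, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyosig.compare import (
    NOT_COMPUTABLE,
    STRENGTH_INSIGNIFICANT,
    STRENGTH_MODERATE,
    STRENGTH_STRONG,
    ComparisonConfig,
    classify_strength,
    compare_pair,
    cutoff_sensitivity,
    exclude_characteristic,
    pairwise_matrix,
    r_squared,
    results_to_long_frame,
    results_to_triangle,
    strength_summary,
)
from karyosig.iscn import TranslocationType
from karyosig.spectrum import N_TYPES
from conftest import make_spectrum


def ols_r2(x, y):
    """Independent least-squares oracle: 1 - SSres/SStot of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_res = np.sum((y - A @ coef) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1 - ss_res / ss_tot


class TestRSquared:
    def test_identical_vectors(self):
        assert r_squared([1, 2, 5], [1, 2, 5]) == pytest.approx(1.0)

    def test_sign_blind(self):
        assert r_squared([1, 2, 3], [3, 2, 1]) == pytest.approx(1.0)

    def test_matches_least_squares_oracle(self):
        x, y = [1, 2, 3, 4], [1, 2, 2, 4]
        assert r_squared(x, y) == pytest.approx(ols_r2(x, y), abs=1e-12)

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(3, 300))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + rng.uniform(-2, 2) * x
            worst = max(worst, abs(r_squared(x, y) - ols_r2(x, y)))
        assert worst < 1e-12

    @pytest.mark.parametrize(
        "x, y, message",
        [
            ([1, 2], [1, 2], "at least 3"),
            ([1, 1, 1], [1, 2, 3], "degenerate"),
            ([1, 2, 3], [5, 5, 5], "degenerate"),
            ([1, 2, 3], [1, 2], "length mismatch"),
        ],
    )
    def test_invalid_inputs(self, x, y, message):
        with pytest.raises(ValueError, match=message):
            r_squared(x, y)


class TestExcludeCharacteristic:
    def test_spiked_type_is_excluded(self, uniform_spectrum):
        # CML-like: t(9;22) at 60%
        cml = make_spectrum({i: 1 for i in range(200)} | {200: 300}, label="CML")
        excluded = exclude_characteristic(cml, uniform_spectrum, 10.0)
        assert len(excluded) == 1
        (only,) = excluded
        from karyosig.spectrum import enumerate_types

        assert only == enumerate_types()[200]

    def test_uniform_spectra_exclude_nothing(self, uniform_spectrum):
        assert exclude_characteristic(uniform_spectrum, uniform_spectrum, 10.0) == frozenset()

    def test_boundary_is_strict(self, uniform_spectrum):
        # one type at exactly 10.0% of 1000
        at_ten = make_spectrum({0: 100} | {i: 1 for i in range(1, 201)} | {201: 700})
        excluded = exclude_characteristic(at_ten, uniform_spectrum, 10.0)
        assert at_ten.pct_freq[0] == 10.0
        assert not any(t.label == "t(1;2)" for t in excluded)  # index 0 retained
        # nudge above the cutoff: now excluded
        above = make_spectrum({0: 101} | {i: 1 for i in range(1, 201)} | {201: 699})
        assert above.pct_freq[0] > 10.0
        assert any(t.label == "t(1;2)" for t in exclude_characteristic(above, uniform_spectrum, 10.0))

    def test_union_over_both_spectra(self, uniform_spectrum):
        spiked = make_spectrum({5: 60, 6: 40})
        excluded = exclude_characteristic(uniform_spectrum, spiked, 10.0)
        from karyosig.spectrum import enumerate_types

        assert excluded == frozenset(enumerate_types()[i] for i in (5, 6))

    def test_zero_observation_spectrum_is_an_error(self, uniform_spectrum):
        empty = make_spectrum({}, n_cases=10)
        with pytest.raises(ValueError, match="no observations"):
            exclude_characteristic(uniform_spectrum, empty, 10.0)


class TestStrengthClassification:
    @pytest.mark.parametrize(
        "r2, expected",
        [
            (0.0, STRENGTH_INSIGNIFICANT),
            (0.31, STRENGTH_INSIGNIFICANT),  # rounds to 0.3
            (0.36, STRENGTH_MODERATE),       # rounds to 0.4
            (0.599, STRENGTH_MODERATE),      # rounds to 0.6
            (0.66, STRENGTH_STRONG),         # rounds to 0.7
            (0.880, STRENGTH_STRONG),
            (1.0, STRENGTH_STRONG),
        ],
    )
    def test_bins_on_rounded_value(self, r2, expected):
        assert classify_strength(r2) == expected

    def test_cutoff_config_validation(self):
        with pytest.raises(ValueError, match="cutoff_pct"):
            ComparisonConfig(cutoff_pct=0)


class TestComparePair:
    def test_self_comparison_is_perfect(self, uniform_spectrum):
        varied = make_spectrum({i: i % 7 + 1 for i in range(100)})
        res = compare_pair(varied, varied)
        assert res.r2 == pytest.approx(1.0)
        assert res.strength == STRENGTH_STRONG
        assert res.excluded_types == frozenset()
        assert res.n_retained == N_TYPES

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = make_spectrum(rng.integers(0, 30, N_TYPES), label="a")
        b = make_spectrum(rng.integers(0, 30, N_TYPES), label="b")
        ab, ba = compare_pair(a, b), compare_pair(b, a)
        assert ab.r2 == pytest.approx(ba.r2, abs=1e-15)
        assert ab.excluded_types == ba.excluded_types
        assert ab.strength == ba.strength

    def test_retained_plus_excluded_is_253(self):
        a = make_spectrum({0: 60, 1: 20} | {i: 1 for i in range(10, 30)}, label="a")
        b = make_spectrum({i: 1 for i in range(50)}, label="b")
        res = compare_pair(a, b)
        assert len(res.excluded_types) == 2
        assert res.n_retained + len(res.excluded_types) == N_TYPES

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=40, derandomize=True)
    def test_renormalization_invariance(self, scale):
        """Rescaling either percentage vector by any positive constant leaves
        R2 unchanged, so re-percentaging after exclusion cannot matter."""
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 5, 60)
        y = rng.uniform(0, 5, 60)
        assert r_squared(x * scale, y) == pytest.approx(r_squared(x, y), abs=1e-12)
        assert r_squared(x, y * scale) == pytest.approx(r_squared(x, y), abs=1e-12)

    def test_too_few_retained_coordinates_is_an_error(self, uniform_spectrum):
        # at a very strict cutoff every uniform coordinate is excluded
        cfg = ComparisonConfig(cutoff_pct=0.1)
        with pytest.raises(ValueError, match="at least 3"):
            compare_pair(uniform_spectrum, uniform_spectrum, cfg)


class TestPairwiseMatrix:
    @pytest.mark.parametrize("n, expected", [(12, 66), (16, 120), (11, 55)])
    def test_comparison_counts(self, n, expected):
        rng = np.random.default_rng(n)
        spectra = [
            make_spectrum(rng.integers(0, 20, N_TYPES), label=f"s{i}")
            for i in range(n)
        ]
        results = pairwise_matrix(spectra)
        assert len(results) == expected == n * (n - 1) // 2

    def test_total_across_three_panels_is_241(self):
        assert 66 + 120 + 55 == 241

    def test_degenerate_pair_is_flagged_not_fatal(self):
        rng = np.random.default_rng(5)
        good_a = make_spectrum(rng.integers(1, 20, N_TYPES), label="a")
        good_b = make_spectrum(rng.integers(1, 20, N_TYPES), label="b")
        constant = make_spectrum(np.full(N_TYPES, 2), label="flat")
        results = pairwise_matrix([good_a, good_b, constant])
        assert len(results) == 3
        flagged = [r for r in results if r.strength == NOT_COMPUTABLE]
        assert len(flagged) == 2
        assert all(r.r2 is None and r.error for r in flagged)

    def test_triangle_layout(self):
        rng = np.random.default_rng(9)
        spectra = [
            make_spectrum(rng.integers(0, 20, N_TYPES), label=f"s{i}")
            for i in range(4)
        ]
        tri = results_to_triangle(pairwise_matrix(spectra))
        assert list(tri.index) == ["s0", "s1", "s2"]
        assert list(tri.columns) == ["s1", "s2", "s3"]
        assert tri.loc["s2", "s1"] == ""  # lower triangle stays empty


class TestStrengthSummary:
    def test_all_perfect(self):
        varied = make_spectrum({i: i % 5 + 1 for i in range(50)})
        results = pairwise_matrix([varied, varied, varied])
        summ = strength_summary(results)
        assert summ.by_class[STRENGTH_STRONG] == summ.n_total == 3

    def test_reported_fraction_rounds_to_98(self):
        """65 of 66 weak comparisons report as 98%."""
        from dataclasses import replace

        varied = make_spectrum({i: i % 5 + 1 for i in range(50)}, label="v")
        base = compare_pair(varied, varied)

        results = [replace(base, r2=0.05, strength=STRENGTH_INSIGNIFICANT)] * 65
        results.append(replace(base, r2=0.45, strength=STRENGTH_MODERATE))
        summ = strength_summary(results)
        assert (summ.n_total, summ.n_le_03) == (66, 65)
        assert summ.pct_le_03 == 98

    def test_tallies_match_recount_oracle(self):
        rng = np.random.default_rng(21)
        spectra = [
            make_spectrum(rng.integers(0, 15, N_TYPES), label=f"s{i}")
            for i in range(10)
        ]
        results = pairwise_matrix(spectra)
        summ = strength_summary(results)
        r2s = [r.r2 for r in results if r.r2 is not None]
        assert summ.n_le_03 == sum(1 for v in r2s if v <= 0.3)
        assert summ.n_lt_01 == sum(1 for v in r2s if v < 0.1)
        assert sum(summ.by_class.values()) == len(results) == 45


class TestCutoffSensitivity:
    def test_no_type_above_one_percent_gives_identical_r2(self):
        rng = np.random.default_rng(13)
        # 253 types, all counts 95..105 of ~25000: every pct ~0.4%
        a = make_spectrum(rng.integers(95, 106, N_TYPES), label="a")
        b = make_spectrum(rng.integers(95, 106, N_TYPES), label="b")
        rows = cutoff_sensitivity(a, b, [10, 5, 2, 1])
        r2s = {r.r2 for r in rows}
        assert len(r2s) == 1
        assert all(r.n_retained == N_TYPES for r in rows)

    def test_retained_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(17)
        a = make_spectrum(rng.integers(0, 60, N_TYPES), label="a")
        b = make_spectrum(rng.integers(0, 60, N_TYPES), label="b")
        rows = cutoff_sensitivity(a, b, [10, 5, 2, 1])
        retained = [r.n_retained for r in rows]
        assert retained == sorted(retained, reverse=True)

    def test_single_spike_excluded_at_every_cutoff(self):
        rng = np.random.default_rng(19)
        spiked = make_spectrum({0: 600} | {i: 4 for i in range(1, 101)}, label="spiked")
        # near-uniform partner, every type well below 1%
        other = make_spectrum(rng.integers(95, 106, N_TYPES), label="other")
        rows = cutoff_sensitivity(spiked, other, [10, 5, 2, 1])
        assert all(r.n_retained == N_TYPES - 1 for r in rows)


def test_long_frame_rounding_and_columns():
    rng = np.random.default_rng(2)
    a = make_spectrum(rng.integers(0, 20, N_TYPES), label="a")
    b = make_spectrum(rng.integers(0, 20, N_TYPES), label="b")
    df = results_to_long_frame(pairwise_matrix([a, b]))
    assert list(df.columns) == [
        "label_a", "label_b", "cutoff_pct", "n_retained",
        "excluded", "r2", "strength", "error",
    ]
    assert df.loc[0, "r2"] == round(compare_pair(a, b).r2, 3)
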