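import numpy as np
import pytest

from irnv.criteria import (
    ProbabilityIntervals,
    WeightedClassCounts,
    anpim_intervals,
    conditional_entropy,
    idm_intervals,
    imprecise_gain,
    info_gain,
    info_gain_ratio,
    max_entropy_binary,
    max_entropy_distribution,
    shannon_entropy,
)
from irnv.synthetic import make_fixture

from helpers import bruteforce_max_entropy, random_interval_system, tiny_dataset


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "dist, expected",
        [((0.5, 0.5), 1.0), ((1.0, 0.0), 0.0), ((0.25, 0.75), 0.811278124459)],
    )
    def test_known_values(self, dist, expected):
        assert shannon_entropy(dist) == pytest.approx(expected, abs=1e-9)

    def test_rejects_unnormalised_input(self):
        with pytest.raises(ValueError):
            shannon_entropy((0.5, 0.6))


class TestPreciseCriteria:
    def test_conditional_entropy_of_perfect_predictor_is_zero(self):
        ds = make_fixture("pure_split")
        assert conditional_entropy(ds, "X1") == pytest.approx(0.0, abs=1e-12)

    def test_conditional_entropy_of_independent_predictor(self):
        ds = make_fixture("forced_root")  # X2 independent of a balanced class
        assert conditional_entropy(ds, "X2") == pytest.approx(1.0, abs=1e-12)

    def test_conditional_entropy_two_41_branches(self, iig_negative):
        # two 5-record branches with class counts (4,1): H = H(0.8, 0.2)
        expected = shannon_entropy((0.8, 0.2))
        assert conditional_entropy(iig_negative, "X") == pytest.approx(expected)
        assert expected == pytest.approx(0.721928, abs=1e-6)

    def test_igr_of_class_copy_is_one(self):
        ds = make_fixture("pure_split")
        assert info_gain_ratio(ds, "X1").value == pytest.approx(1.0)

    def test_igr_of_independent_predictor_is_zero(self):
        ds = make_fixture("forced_root")
        assert info_gain_ratio(ds, "X2").value == pytest.approx(0.0, abs=1e-12)

    def test_igr_zero_gain_fixture(self, iig_negative):
        # class (8,2) split into two (4,1) branches: IG = 0.7219 - 0.7219
        assert info_gain(iig_negative, "X") == pytest.approx(0.0, abs=1e-12)
        assert info_gain_ratio(iig_negative, "X").value == pytest.approx(0.0, abs=1e-12)

    def test_igr_undefined_for_constant_predictor(self):
        ds = tiny_dataset({"X": [1, 1, 1, 1]}, [1, 1, 2, 1])
        assert not info_gain_ratio(ds, "X").defined


class TestCredalIntervals:
    def test_idm_substitution(self):
        iv = idm_intervals(WeightedClassCounts((3, 6)), s=1)
        assert iv.lower == pytest.approx((0.3, 0.6))
        assert iv.upper == pytest.approx((0.4, 0.7))

    def test_idm_zero_count_class(self):
        iv = idm_intervals(WeightedClassCounts((0, 10)), s=1)
        assert iv.lower == pytest.approx((0.0, 10 / 11))
        assert iv.upper == pytest.approx((1 / 11, 1.0))

    def test_idm_width_identity(self, rng):
        """Every class interval has width s/(N+s)."""
        for _ in range(20):
            counts = WeightedClassCounts(tuple(rng.uniform(0.1, 20, size=3)))
            s = rng.uniform(0.5, 2)
            iv = idm_intervals(counts, s)
            widths = np.subtract(iv.upper, iv.lower)
            assert widths == pytest.approx(s / (counts.total + s))

    def test_anpim_substitution(self):
        iv = anpim_intervals(WeightedClassCounts((3, 6)))
        assert iv.lower == pytest.approx((2 / 9, 5 / 9))
        assert iv.upper == pytest.approx((4 / 9, 7 / 9))

    def test_anpim_clamps(self):
        iv = anpim_intervals(WeightedClassCounts((0, 9)))
        assert iv.lower == pytest.approx((0.0, 8 / 9))
        assert iv.upper == pytest.approx((1 / 9, 1.0))
        iv = anpim_intervals(WeightedClassCounts((9, 0)))
        assert iv.upper[0] == 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            idm_intervals(WeightedClassCounts((0.0, 0.0)))
        with pytest.raises(ValueError):
            anpim_intervals(WeightedClassCounts((0.0, 0.0)))


class TestMaxEntropy:
    def test_two_class_example(self):
        iv = ProbabilityIntervals((0.3, 0.6), (0.4, 0.7))
        p, h = max_entropy_distribution(iv)
        assert p == pytest.approx((0.4, 0.6), abs=1e-9)
        assert h == pytest.approx(0.970951, abs=1e-6)

    def test_degenerate_point_set(self):
        iv = ProbabilityIntervals((0.2, 0.8), (0.2, 0.8))
        p, h = max_entropy_distribution(iv)
        assert p == pytest.approx((0.2, 0.8), abs=1e-9)

    def test_idm_three_class_example(self):
        iv = idm_intervals(WeightedClassCounts((1, 1, 8)), s=1)
        p, h = max_entropy_distribution(iv)
        assert p == pytest.approx((1.5 / 11, 1.5 / 11, 8 / 11), abs=1e-9)
        assert h == pytest.approx(shannon_entropy((1.5 / 11, 1.5 / 11, 8 / 11)), abs=1e-9)
        assert h == pytest.approx(1.1181, abs=1e-3)

    def test_infeasible_intervals_rejected(self):
        with pytest.raises(ValueError):
            max_entropy_distribution(ProbabilityIntervals((0.6, 0.6), (0.7, 0.7)))

    def test_matches_bruteforce_on_random_systems(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 5))
            iv, p0 = random_interval_system(rng, k)
            _, h = max_entropy_distribution(iv)
            h_ref = bruteforce_max_entropy(iv, p0)
            assert h == pytest.approx(h_ref, abs=1e-4)

    def test_binary_fast_path_agrees_with_water_filling(self, rng):
        for _ in range(50):
            n1, n2 = rng.uniform(0, 30, size=2)
            if n1 + n2 <= 0:
                continue
            counts = WeightedClassCounts((n1, n2))
            for model, iv in (
                ("idm", idm_intervals(counts, 1.0)),
                ("npi", anpim_intervals(counts)),
            ):
                _, h = max_entropy_distribution(iv)
                h_fast = float(max_entropy_binary(n1, n2, model, 1.0))
                assert h_fast == pytest.approx(h, abs=1e-9)

    def test_containment_empirical_within_intervals(self, rng):
        """The empirical frequency vector lies in both credal sets, so
        H* is at least the empirical entropy and at most log2(k)."""
        for _ in range(40):
            k = int(rng.integers(2, 5))
            n = rng.uniform(0.2, 15, size=k)
            counts = WeightedClassCounts(tuple(n))
            emp = n / n.sum()
            for iv in (idm_intervals(counts, 1.0), anpim_intervals(counts)):
                assert (np.asarray(iv.lower) <= emp + 1e-12).all()
                assert (emp <= np.asarray(iv.upper) + 1e-12).all()
                _, h = max_entropy_distribution(iv)
                assert h >= shannon_entropy(emp) - 1e-9
                assert h <= np.log2(k) + 1e-9


class TestImpreciseGain:
    def test_constant_predictor_scores_zero(self):
        ds = tiny_dataset({"X": [1, 1, 1, 1, 1]}, [1, 1, 1, 2, 2])
        assert imprecise_gain(ds, "X", "idm", 1.0).value == pytest.approx(0.0, abs=1e-12)

    def test_negative_on_uninformative_balanced_split(self, iig_negative):
        score = imprecise_gain(iig_negative, "X", "idm", 1.0)
        assert score.value == pytest.approx(-0.0730, abs=1e-3)

    def test_positive_for_class_copy(self):
        ds = make_fixture("pure_split")
        assert imprecise_gain(ds, "X1", "idm", 1.0).value > 0
        assert imprecise_gain(ds, "X1", "npi").value > 0

    def test_small_s_limit_recovers_info_gain(self, rng):
        """As s -> 0 the IDM credal set collapses to the empirical point."""
        for _ in range(10):
            n = 24
            ds = tiny_dataset(
                {"X": rng.integers(1, 4, size=n).tolist()},
                rng.choice([1, 2], size=n, p=[0.7, 0.3]).tolist(),
                weights=rng.uniform(0.5, 2.0, size=n),
            )
            iig = imprecise_gain(ds, "X", "idm", s=1e-8).value
            assert iig == pytest.approx(info_gain(ds, "X"), abs=1e-6)
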