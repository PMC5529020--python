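"""Signal processing: replicate medians, re-incubation correction, smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimap import (
    ArrayLayout,
    correct_signal,
    estimate_reincubation,
    map_to_toxins,
    replicate_median,
    running_median,
)

from conftest import make_toxin


def layout_from(fields):
    return ArrayLayout(list(fields), corner_field_count=sum(1 for f in fields if f[2]))

class TestReplicateMedian:
    def make(self, values, peptide="P" * 15):
        fields = [(i, peptide, False) for i in range(len(values))]
        table = pd.DataFrame(
            {
                "field_id": range(len(values)),
                "peptide": peptide,
                "intensity": values,
            }
        )
        return layout_from(fields), table

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4, 100], 3),  # outlier robustness
            ([7], 7),
            ([1, 2, 3, 4], 2.5),  # a replicate lost: sort-and-average oracle
        ],
    )
    def test_median_of_replicates(self, values, expected):
        layout, table = self.make(values)
        medians, corners = replicate_median(table, layout)
        assert medians["P" * 15] == pytest.approx(expected)
        assert corners.size == 0

    def test_missing_peptide_rejected_by_name(self):
        layout, table = self.make([1, 2, 3])
        with pytest.raises(ValueError, match="PPP"):
            replicate_median(table.iloc[:0], layout)

    def test_corner_fields_split_out(self):
        fields = [(0, "A" * 15, False), (1, "K" * 15, True), (2, "K" * 15, True)]
        table = pd.DataFrame(
            {"field_id": [0, 1, 2], "peptide": ["A" * 15, "K" * 15, "K" * 15],
             "intensity": [5.0, 100.0, 200.0]}
        )
        medians, corners = replicate_median(table, layout_from(fields))
        assert list(medians.index) == ["A" * 15]
        assert sorted(corners) == [100.0, 200.0]


class TestReincubation:
    def test_reference_scale_ratio(self):
        # channel medians 50 and 215 give the 4.3-fold effect
        assert estimate_reincubation(np.array([50.0]), np.array([215.0])) == 4.3

    def test_identical_distributions_give_unity(self, rng):
        x = rng.lognormal(4, 0.5, size=500)
        assert estimate_reincubation(x, x) == 1.0

    def test_empty_or_zero_background_rejected(self):
        with pytest.raises(ValueError):
            estimate_reincubation(np.array([]), np.array([1.0]))
        with pytest.raises(ValueError):
            estimate_reincubation(np.array([0.0]), np.array([1.0]))

    @pytest.mark.parametrize("true_factor", [2.0, 3.0, 6.0])
    def test_monte_carlo_recovery(self, true_factor, rng):
        """Mean estimate over seeds is within 5% of the generating factor."""
        estimates = []
        for _ in range(25):
            bg = rng.lognormal(5.0, 0.8, size=852)
            av = true_factor * rng.lognormal(5.0, 0.8, size=852)
            estimates.append(estimate_reincubation(bg, av))
        assert np.mean(estimates) == pytest.approx(true_factor, rel=0.05)

    def test_scale_equivariance(self, rng):
        bg = rng.lognormal(4, 0.5, size=200)
        av = rng.lognormal(5, 0.5, size=200)
        base = estimate_reincubation(bg, av)
        assert estimate_reincubation(bg, 3 * av) == pytest.approx(3 * base)
        assert estimate_reincubation(2 * bg, av) == pytest.approx(base / 2)


class TestCorrectSignal:
    @pytest.mark.parametrize(
        "av, bg, factor, expected",
        [(100, 10, 4.3, 57), (43, 10, 4.3, 0), (10, 10, 4.3, -33)],
    )
    def test_arithmetic(self, av, bg, factor, expected):
        assert correct_signal(av, bg, factor) == pytest.approx(expected)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            correct_signal(1.0, 1.0, 0.0)


def brute_running_median(x):
    """Windowed-median oracle including the terminal two-value rule."""
    out = []
    for i in range(len(x)):
        window = x[max(0, i - 1) : i + 2]
        out.append(np.median(window))
    return np.array(out)


class TestRunningMedian:
    def test_three_point_example(self):
        assert running_median([10, 50, 20]) == pytest.approx([30, 20, 35])

    def test_constant_profile_fixed_point(self):
        assert running_median([3.5] * 4) == pytest.approx([3.5] * 4)

    def test_length_one_identity(self):
        assert running_median([42.0]) == pytest.approx([42.0])

    def test_matches_brute_oracle_on_random_profiles(self, rng):
        for _ in range(1000):
            x = rng.normal(size=rng.integers(1, 40))
            assert np.allclose(running_median(x), brute_running_median(x))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_oracle_property(self, values):
        x = np.array(values)
        assert np.allclose(running_median(x), brute_running_median(x))


class TestMapToToxins:
    def test_profile_length_is_l_minus_14(self):
        toxin = make_toxin("T", "ACDEFGHIKLMNPQRSTVWYACDEFGHIK")  # 29 residues
        scores = {toxin.sequence[i : i + 15]: float(i) for i in range(15)}
        profiles = map_to_toxins(scores, [toxin])
        assert len(profiles) == 1
        assert len(profiles[0]) == 15

    def test_identical_toxins_share_profiles(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        a, b = make_toxin("A", seq), make_toxin("B", seq)
        scores = {seq[i : i + 15]: float(10 * i) for i in range(6)}
        pa, pb = map_to_toxins(scores, [a, b])
        assert np.allclose(pa.scores, pb.scores)

    def test_hand_built_profile_matches_manual_medians(self):
        seq = "ACDEFGHIKLMNPQRSTVW"  # 19 residues -> 5 windows
        toxin = make_toxin("T", seq)
        raw = [10.0, 50.0, 20.0, 80.0, 40.0]
        scores = {seq[i : i + 15]: raw[i] for i in range(5)}
        (profile,) = map_to_toxins(scores, [toxin])
        # manual oracle: [mean(10,50), med(10,50,20), med(50,20,80),
        #                 med(20,80,40), mean(80,40)]
        assert profile.scores == pytest.approx([30, 20, 50, 40, 60])
        assert profile.raw == pytest.approx(raw)
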