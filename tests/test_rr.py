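import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cephrr.exceptions import ValidationError
from cephrr.geometry import subject_frames
from cephrr.rr import (
    bland_altman,
    classify_reliability,
    rr_by,
    rr_components,
    rr_table,
    sample_size,
)
from cephrr.simulate import simulate

from conftest import make_truth


# -- independent oracle --------------------------------------------------------


def anova_oracle(values: pd.DataFrame):
    """Brute-force balanced gauge R&R via per-subject one-way ANOVA mean
    squares: s_r^2 = pooled MS_within, s_L^2 = (mean_j MS_between,j - s_r^2)/n.

    Written independently of the production estimator (explicit loops over
    sums of squares)."""
    subjects = sorted(values["subject"].unique())
    operators = sorted(values["operator"].unique())
    p = len(operators)
    ss_within, df_within = 0.0, 0
    ms_between = []
    n = None
    for j in subjects:
        cell_means = []
        for i in operators:
            y = values[(values["subject"] == j) & (values["operator"] == i)][
                "value"
            ].to_numpy()
            n = len(y)
            m = y.mean()
            cell_means.append(m)
            ss_within += ((y - m) ** 2).sum()
            df_within += len(y) - 1
        grand = float(np.mean(cell_means))
        ss_between = n * sum((m - grand) ** 2 for m in cell_means)
        ms_between.append(ss_between / (p - 1))
    s_r_sq = ss_within / df_within
    s_L_sq = max(0.0, (float(np.mean(ms_between)) - s_r_sq) / n)
    return np.sqrt(s_r_sq), np.sqrt(s_L_sq), np.sqrt(s_r_sq + s_L_sq)


def balanced_table(rng, p, q, n, sigma_r=0.5, sigma_L=0.3):
    rows = []
    bias = rng.normal(0, sigma_L, p)
    for j in range(q):
        level = rng.normal(0, 5)
        for i in range(p):
            for k in range(n):
                rows.append(
                    (f"s{j}", f"o{i}", str(k), level + bias[i] + rng.normal(0, sigma_r))
                )
    return pd.DataFrame(rows, columns=["subject", "operator", "session", "value"])


class TestRRComponents:
    def test_identical_values_give_zero(self):
        df = balanced_table(np.random.default_rng(0), 3, 4, 2, 0, 0)
        df["value"] = 7.0
        comp = rr_components(df)
        assert comp.s_r == comp.s_L == comp.s_R == 0.0

    def test_single_operator_two_sessions(self):
        """Two subjects each measured {0, 2} by one operator: pooled cell
        variance is 2, so s_r = sqrt(2) and s_R = s_r."""
        df = pd.DataFrame(
            {
                "subject": ["a", "a", "b", "b"],
                "operator": ["o1"] * 4,
                "value": [0.0, 2.0, 0.0, 2.0],
            }
        )
        comp = rr_components(df)
        assert comp.s_r == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert comp.s_L == 0.0
        assert comp.s_R == pytest.approx(comp.s_r, abs=1e-12)

    def test_matches_anova_oracle_on_balanced_data(self, rng):
        for _ in range(20):
            p, q, n = rng.integers(2, 4), rng.integers(2, 7), rng.integers(2, 4)
            df = balanced_table(rng, int(p), int(q), int(n))
            comp = rr_components(df)
            s_r, s_L, s_R = anova_oracle(df)
            assert comp.s_r == pytest.approx(s_r, abs=1e-10)
            assert comp.s_L == pytest.approx(s_L, abs=1e-10)
            assert comp.s_R == pytest.approx(s_R, abs=1e-10)

    def test_label_permutation_invariance(self, rng):
        df = balanced_table(rng, 3, 5, 2)
        base = rr_components(df)
        shuffled = df.sample(frac=1.0, random_state=0)
        relabel = df.replace(
            {"operator": {"o0": "zz", "o1": "aa", "o2": "mm"},
             "subject": {f"s{j}": f"t{9 - j}" for j in range(5)}}
        )
        for variant in (shuffled, relabel):
            comp = rr_components(variant)
            assert comp.s_r == pytest.approx(base.s_r, abs=1e-12)
            assert comp.s_R == pytest.approx(base.s_R, abs=1e-12)

    def test_per_subject_location_invariance(self, rng):
        df = balanced_table(rng, 3, 5, 2)
        shifted = df.copy()
        offsets = {f"s{j}": 100.0 * j for j in range(5)}
        shifted["value"] += shifted["subject"].map(offsets)
        a, b = rr_components(df), rr_components(shifted)
        assert b.s_r == pytest.approx(a.s_r, abs=1e-9)
        assert b.s_L == pytest.approx(a.s_L, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25)
    def test_s_R_at_least_s_r(self, seed):
        rng = np.random.default_rng(seed)
        df = balanced_table(rng, 2 + seed % 2, 3, 2)
        comp = rr_components(df)
        assert comp.s_R >= comp.s_r >= 0.0
        assert comp.s_R**2 == pytest.approx(comp.s_r**2 + comp.s_L**2, abs=1e-10)

    def test_all_singleton_cells_rejected(self):
        df = pd.DataFrame(
            {"subject": ["a", "a", "b"], "operator": ["o1", "o2", "o1"],
             "value": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValidationError, match="single replicate"):
            rr_components(df)

    def test_rr_by_matches_componentwise(self, rng):
        frames = []
        for lm in ("Na", "Me"):
            for ax in ("x", "y"):
                df = balanced_table(rng, 3, 4, 2)
                df["landmark"], df["axis"] = lm, ax
                frames.append(df)
        long = pd.concat(frames, ignore_index=True)
        vec = rr_by(long, ["landmark", "axis"])
        for _, row in vec.iterrows():
            stratum = long[(long["landmark"] == row["landmark"])
                           & (long["axis"] == row["axis"])]
            comp = rr_components(stratum)
            assert row["s_r"] == pytest.approx(comp.s_r, abs=1e-12)
            assert row["s_R"] == pytest.approx(comp.s_R, abs=1e-12)


class TestSampleSize:
    def test_study_design_value(self):
        assert sample_size(0.15, 6) == 17

    def test_two_repetitions(self):
        # 1.96^2 / (2 * 0.15^2 * 1) = 85.37 -> 85
        assert sample_size(0.15, 2) == 85

    def test_doubling_repetitions_minus_one_halves_requirement(self):
        a = 1.96**2 / (2 * 0.15**2 * (6 - 1))
        b = 1.96**2 / (2 * 0.15**2 * (11 - 1))
        assert b == pytest.approx(a / 2)

    @pytest.mark.parametrize("bad", [(-0.1, 6), (0.0, 6), (1.5, 6), (0.15, 1)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValidationError):
            sample_size(*bad)


class TestClassifyReliability:
    @pytest.mark.parametrize(
        "ci_repeat,ci_repro,expected",
        [
            (2.05, 3.40, "caution"),
            (0.24, 0.35, "acceptable"),
            (1.27, 1.51, "useful"),
            (1.0, 1.0, "acceptable"),  # boundary: <= 1 mm
            (1.0, 2.0, "useful"),      # boundary: <= 2 mm
            (0.1, 2.01, "caution"),
        ],
    )
    def test_classes(self, ci_repeat, ci_repro, expected):
        assert classify_reliability(ci_repeat, ci_repro) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            classify_reliability(-0.1, 0.5)


class TestRRTable:
    def test_noise_free_dataset_all_zero(self, noise_free_dataset):
        frames = subject_frames(noise_free_dataset)
        table = rr_table(noise_free_dataset, frames)
        assert len(table) == 33 * 3
        assert (table.records["repet_2sd"] == 0).all()
        assert (table.records["repro_2sd"] == 0).all()
        assert (table.records["reliability_class"] == "acceptable").all()

    def test_isotropic_recovery(self):
        """With sigma_r = 0.25 mm isotropic and no operator effect, the mean
        estimated repeatability CI over 200 simulated studies is within 5%
        of 2 x 0.25 = 0.50 mm."""
        total, count = 0.0, 0
        for rep in range(200):
            truth = make_truth(sigma_r_default=0.25, seed=50_000 + rep)
            dataset, _ = simulate(truth, n_subjects=5, n_operators=3, n_sessions=2)
            table = rr_table(dataset, subject_frames(dataset))
            total += table.records["repet_2sd"].mean()
            count += 1
        assert total / count == pytest.approx(0.50, rel=0.05)


class TestBlandAltman:
    def test_deviations_sum_to_zero_per_subject(self, quiet_dataset):
        frames = subject_frames(quiet_dataset)
        series = bland_altman(quiet_dataset, "Na", "y", frames)
        sums = series.deviations.groupby("subject")["deviation"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 0.0, atol=1e-10)

    def test_noise_free_all_zero(self, noise_free_dataset):
        frames = subject_frames(noise_free_dataset)
        series = bland_altman(noise_free_dataset, "Me", "z", frames)
        np.testing.assert_allclose(series.deviations["deviation"], 0.0, atol=1e-10)
        assert series.limit == pytest.approx(0.0, abs=1e-10)

    def test_about_95_percent_within_limits(self):
        truth = make_truth(sigma_r_default=0.3, sigma_L_default=0.2, seed=99)
        dataset, _ = simulate(truth, n_subjects=40, n_operators=3, n_sessions=2)
        frames = subject_frames(dataset)
        inside = total = 0
        for lm in ("Na", "Me", "Or-L"):
            series = bland_altman(dataset, lm, "x", frames)
            d = series.deviations["deviation"].to_numpy()
            inside += (np.abs(d) <= series.limit).sum()
            total += len(d)
        # binomial tolerance around 0.95 (deviation-from-mean slightly
        # shrinks the spread, so coverage runs high, never low)
        assert 0.90 <= inside / total <= 1.0
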