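"""Filtering, correction, grouping and baseline-subtraction contracts."""

import numpy as np
import pandas as pd
import pytest

from metabodcv import preprocess as pp
from metabodcv.errors import (
    AlignmentError,
    ConfigurationError,
    PairingError,
    PreconditionError,
)
from metabodcv.synthetic import ISOTOPE_SPACING
from metabodcv.tables import BLANK, QC_POOL, SAMPLE

from conftest import make_table, simple_samples


def _uniform_table(features, n_value=100.0, samples=None):
    samples = samples or simple_samples()
    inten = np.full((len(features), len(samples)), n_value)
    return make_table(features, inten, samples)


class TestBlankFilter:
    def _fixture(self):
        samples = simple_samples(n_subjects=4, n_blanks=2)
        feats = [(f"F{i}", 100.0 + i, 5.0, "positive") for i in range(10)]
        rng = np.random.default_rng(0)
        inten = rng.uniform(900, 1100, (10, len(samples)))
        blank_cols = [0, 1]
        # features 0-2 planted above the presence rule, the rest near zero
        for i in range(10):
            for c in blank_cols:
                inten[i, c] = 1000.0 if i < 3 else 1.0
        return make_table(feats, inten, samples)

    def test_planted_blank_features_removed_exactly(self):
        table = self._fixture()
        out, report = pp.filter_blank_features(table, 0.5)
        assert sorted(report.removed_ids) == ["F0", "F1", "F2"]
        assert report.n_before == 10 and report.n_after == 7

    def test_ratio_threshold_is_strict(self):
        samples = simple_samples(n_subjects=2, n_blanks=1)
        feats = [("clean", 100.0, 5.0, "positive"), ("equal", 200.0, 5.0, "positive")]
        inten = np.full((2, len(samples)), 1000.0)
        inten[0, 0] = 0.0  # blank column
        table = make_table(feats, inten, samples)
        out, report = pp.filter_blank_features(table, 0.5)
        assert "clean" in out.features.index  # blank mean 0 -> retained
        assert "equal" in report.removed_ids  # ratio 1.0 > 0.5 -> removed

    def test_requires_blank_samples(self):
        samples = [r for r in simple_samples() if r[4] != BLANK]
        table = _uniform_table([("F0", 100.0, 5.0, "positive")], samples=samples)
        with pytest.raises(PreconditionError):
            pp.filter_blank_features(table)


class TestRtWindow:
    @pytest.mark.parametrize(
        "rt,kept",
        [(0.25, False), (0.3, True), (0.69, True), (8.31, True), (9.42, True), (9.43, False)],
    )
    def test_closed_interval(self, rt, kept):
        table = _uniform_table([("F0", 500.0, rt, "positive")])
        out, _ = pp.filter_rt_window(table)
        assert ("F0" in out.features.index) is kept

    def test_inverted_window_rejected(self):
        table = _uniform_table([("F0", 500.0, 5.0, "positive")])
        with pytest.raises(ConfigurationError):
            pp.filter_rt_window(table, rt_min=2.0, rt_max=1.0)


class TestEarlyMassDefect:
    @pytest.mark.parametrize(
        "mz,rt,kept",
        [
            (187.0588, 0.69, True),   # first decimal 0 -> plausible
            (150.45, 0.5, False),     # first decimal 4 inside the window
            (155.0697, 6.28, True),   # outside 0.3-0.8 min
            (200.9, 0.8, False),      # boundary rt, first decimal 9
            (200.39, 0.5, True),      # first decimal 3
        ],
    )
    def test_rule(self, mz, rt, kept):
        table = _uniform_table([("F0", mz, rt, "positive")])
        out, _ = pp.filter_early_mass_defect(table)
        assert ("F0" in out.features.index) is kept


class TestIsotopesDuplicates:
    def _fixture(self):
        """4 parents + 4 isotope satellites + 2 duplicate pairs = 6 removals."""
        samples = simple_samples(n_subjects=6)
        rng = np.random.default_rng(1)
        feats, rows = [], []
        for i in range(4):
            base = rng.uniform(500, 1500, len(samples))
            feats.append((f"P{i}", 200.0 + 50 * i, 2.0 + i, "positive"))
            rows.append(base)
            feats.append((f"I{i}", 200.0 + 50 * i + ISOTOPE_SPACING, 2.0 + i, "positive"))
            rows.append(0.3 * base)
        for i in range(2):
            base = rng.uniform(500, 1500, len(samples))
            feats.append((f"D{i}a", 600.0 + i, 6.0 + i, "positive"))
            rows.append(base)
            feats.append((f"D{i}b", 600.0 + i + 0.002, 6.0 + i + 0.004, "positive"))
            rows.append(0.8 * base + rng.normal(0, 1, len(samples)))
        return make_table(feats, np.array(rows), samples)

    def test_exact_removals_and_categories(self):
        table = self._fixture()
        out, report = pp.remove_isotopes_duplicates(table)
        assert report.n_before - report.n_after == 6
        assert sorted(i for i in report.removed_ids if i.startswith("I")) == [
            "I0", "I1", "I2", "I3"]
        assert sorted(i for i in report.removed_ids if i.startswith("D")) == ["D0b", "D1b"]
        assert all(report.detail[i] == "isotope" for i in report.removed_ids if i[0] == "I")
        assert all(report.detail[i] == "duplicate" for i in report.removed_ids if i[0] == "D")

    def test_uncorrelated_satellite_spacing_kept(self):
        samples = simple_samples(n_subjects=6)
        rng = np.random.default_rng(2)
        feats = [("A", 300.0, 4.0, "positive"), ("B", 300.0 + ISOTOPE_SPACING, 4.0, "positive")]
        inten = rng.uniform(100, 2000, (2, len(samples)))  # independent -> low correlation
        table = make_table(feats, inten, samples)
        out, report = pp.remove_isotopes_duplicates(table)
        assert len(report.removed_ids) == 0


class TestBatchCorrect:
    def _two_batch_table(self):
        samples = []
        for b, subjects in ((1, ["S0"]), (2, ["S1"])):
            for i, (sid, visit) in enumerate(
                [(s, v) for s in subjects for v in ("baseline", "week8")]
            ):
                samples.append((f"{sid}_{visit}", sid, "C", visit, SAMPLE, b, i))
        feats = [("F0", 100.0, 5.0, "positive")]
        inten = np.array([[10.0, 20.0, 30.0, 40.0]])
        return make_table(feats, inten, samples)

    def test_default_mode_hand_computation(self):
        out = pp.batch_correct(self._two_batch_table())
        np.testing.assert_allclose(
            out.intensities.iloc[0].to_numpy(),
            [10 * 25 / 15, 20 * 25 / 15, 30 * 25 / 35, 40 * 25 / 35],
        )
        vals = out.intensities.iloc[0]
        assert vals.iloc[:2].mean() == pytest.approx(25.0)
        assert vals.iloc[2:].mean() == pytest.approx(25.0)

    def test_verbatim_mode_hand_computation(self):
        out = pp.batch_correct(self._two_batch_table(), mode="verbatim")
        np.testing.assert_allclose(out.intensities.iloc[0, :2].to_numpy(), [6.0, 12.0])

    def test_single_batch_identity_both_modes(self, small_study):
        _, table, _, _ = small_study
        one_batch = table.copy()
        one_batch.samples["batch"] = 1
        for mode in ("default", "verbatim"):
            out = pp.batch_correct(one_batch, mode=mode)
            np.testing.assert_allclose(out.intensities.to_numpy(), table.intensities.to_numpy())

    def test_conservation_on_random_data(self):
        rng = np.random.default_rng(3)
        samples = []
        k = 0
        for b in (1, 2, 3):
            for s in range(4):
                for visit in ("baseline", "week8"):
                    samples.append((f"B{b}S{s}_{visit}", f"B{b}S{s}", "C", visit, SAMPLE, b, k))
                    k += 1
        feats = [(f"F{i}", 100.0 + i, 5.0, "positive") for i in range(6)]
        table = make_table(feats, rng.uniform(10, 1000, (6, len(samples))), samples)
        out = pp.batch_correct(table)
        np.testing.assert_allclose(
            out.intensities.mean(axis=1), table.intensities.mean(axis=1), rtol=1e-10
        )
        meta = table.samples
        for b in (1, 2, 3):
            cols = meta.index[meta["batch"] == b]
            np.testing.assert_allclose(
                out.intensities[cols].mean(axis=1), table.intensities.mean(axis=1), rtol=1e-10
            )


class TestDriftCorrect:
    def test_no_drift_is_near_identity(self, small_study):
        _, table, _, _ = small_study
        out = pp.drift_correct(table)
        # QC intensities are iid noise around a constant: LOWESS trend ~ flat
        ratio = out.intensities.to_numpy() / table.intensities.to_numpy()
        assert np.abs(np.log(ratio)).mean() < 0.2

    def test_linear_drift_removed_from_qc_trend(self):
        from metabodcv.synthetic import SimConfig, generate_study, inject_batch_and_drift

        cfg = SimConfig(n_subjects_per_arm=20, n_features_per_mode=(10, 10),
                        n_discriminating=0, n_blank_features=0, n_isotope_pairs=0,
                        n_batches=1, batch_sd=0.0, drift_amplitude=0.2,
                        noise_sd=0.05, rng_seed=4)
        clean, _, _ = generate_study(cfg)
        drifted = inject_batch_and_drift(clean, cfg)
        corrected = pp.drift_correct(drifted, span=0.75)
        meta = clean.samples
        qc = meta.index[meta["sample_type"] == QC_POOL]
        order = meta.loc[qc, "injection_order"].to_numpy(float)

        def mean_qc_slope(t):
            logs = np.log(t.intensities[qc].to_numpy())
            return np.mean([np.polyfit(order, row, 1)[0] for row in logs])

        assert mean_qc_slope(drifted) > 5 * abs(mean_qc_slope(corrected))

    def test_constant_trend_normalizes_to_identity(self):
        samples = simple_samples(n_subjects=3, n_qc=4)
        feats = [("F0", 100.0, 5.0, "positive")]
        inten = np.full((1, len(samples)), 7.0)
        table = make_table(feats, inten, samples)
        out = pp.drift_correct(table)
        np.testing.assert_allclose(out.intensities.to_numpy(), table.intensities.to_numpy())

    def test_too_few_qcs_leaves_batch_uncorrected(self, caplog):
        samples = simple_samples(n_subjects=3, n_qc=2)
        feats = [("F0", 100.0, 5.0, "positive")]
        rng = np.random.default_rng(5)
        table = make_table(feats, rng.uniform(10, 20, (1, len(samples))), samples)
        with caplog.at_level("WARNING"):
            out = pp.drift_correct(table)
        np.testing.assert_allclose(out.intensities.to_numpy(), table.intensities.to_numpy())
        assert "QC pools" in caplog.text


class TestGroupFeatures:
    def _corr_pair_table(self, rt_a, rt_b, noise=0.0, seed=6):
        samples = simple_samples(n_subjects=6)
        rng = np.random.default_rng(seed)
        base = rng.uniform(100, 1000, len(samples))
        feats = [("A", 300.0, rt_a, "positive"), ("B", 410.0, rt_b, "positive"),
                 ("C", 520.0, 8.9, "positive")]
        rows = [base * 1.5, base + rng.normal(0, noise * base.std() + 1e-9, len(samples)),
                rng.uniform(100, 1000, len(samples))]
        return make_table(feats, np.abs(np.array(rows)), samples)

    def test_coeluting_correlated_features_grouped(self):
        table = self._corr_pair_table(5.770, 5.775)
        out, report = pp.group_features(table)
        assert len(out.features) == 2
        assert "A" in out.features.index  # most intense representative kept
        assert "B" in report.removed_ids

    def test_separated_isomers_stay_distinct(self):
        # e.g. two isomeric phosphatidylcholines at RT 8.14 vs 8.25 share m/z
        # and correlate, but elute outside the 0.01-min window
        table = self._corr_pair_table(8.14, 8.25)
        out, _ = pp.group_features(table)
        assert {"A", "B"} <= set(out.features.index)

    def test_low_correlation_not_grouped(self):
        table = self._corr_pair_table(5.770, 5.775, noise=3.0)
        out, _ = pp.group_features(table)
        assert {"A", "B"} <= set(out.features.index)

    def test_never_increases_and_rows_are_subset(self, small_study):
        _, table, _, _ = small_study
        out, _ = pp.group_features(table, rt_window=0.5, corr_min=0.3)
        assert len(out.features) <= len(table.features)
        for fid in out.features.index:
            np.testing.assert_array_equal(
                out.intensities.loc[fid].to_numpy(), table.intensities.loc[fid].to_numpy()
            )


class TestConcatenateModes:
    def test_counts_add_and_modes_kept(self, small_study):
        _, table, _, _ = small_study
        pos = table.subset_features(table.features.index[table.features["mode"] == "positive"])
        neg = table.subset_features(table.features.index[table.features["mode"] == "negative"])
        out = pp.concatenate_modes(pos, neg)
        assert len(out.features) == len(pos.features) + len(neg.features)
        assert set(out.features["mode"]) == {"positive", "negative"}

    def test_empty_negative_returns_positive(self, small_study):
        _, table, _, _ = small_study
        pos = table.subset_features(table.features.index[table.features["mode"] == "positive"])
        neg = table.subset_features([])
        out = pp.concatenate_modes(pos, neg)
        pd.testing.assert_frame_equal(out.intensities, pos.intensities)

    def test_alignment_by_id_not_position(self, small_study):
        _, table, _, _ = small_study
        pos = table.subset_features(table.features.index[table.features["mode"] == "positive"])
        neg = table.subset_features(table.features.index[table.features["mode"] == "negative"])
        shuffled = neg.copy()
        cols = list(shuffled.intensities.columns)[::-1]
        shuffled.intensities = shuffled.intensities[cols]
        out = pp.concatenate_modes(pos, shuffled)
        fid = neg.features.index[0]
        pd.testing.assert_series_equal(out.intensities.loc[fid], neg.intensities.loc[fid])

    def test_sample_mismatch_names_offenders(self, small_study):
        _, table, _, _ = small_study
        pos = table.subset_features(table.features.index[table.features["mode"] == "positive"])
        neg = table.subset_features(table.features.index[table.features["mode"] == "negative"])
        clipped = neg.copy()
        dropped = clipped.study_sample_ids[0]
        clipped.intensities = clipped.intensities.drop(columns=[dropped])
        with pytest.raises(AlignmentError, match=dropped):
            pp.concatenate_modes(pos, clipped)


class TestBaselineSubtract:
    def test_simple_difference(self):
        samples = simple_samples(n_subjects=2)
        feats = [("F0", 100.0, 5.0, "positive")]
        table = _uniform_table(feats, samples=samples)
        t = table.copy()
        t.intensities.loc["F0", "S0_baseline"] = 100.0
        t.intensities.loc["F0", "S0_week8"] = 150.0
        out = pp.baseline_subtract(t)
        assert out.intensities.loc["F0", "S0"] == 50.0
        assert set(out.samples["sample_type"]) == {SAMPLE}

    def test_identical_visits_give_zero(self, small_study):
        _, table, _, _ = small_study
        t = table.copy()
        meta = t.samples
        for subject, grp in meta[meta["sample_type"] == SAMPLE].groupby("subject"):
            b = grp.index[grp["visit"] == "baseline"][0]
            w = grp.index[grp["visit"] == "week8"][0]
            t.intensities[w] = t.intensities[b]
        out = pp.baseline_subtract(t)
        assert (out.intensities.to_numpy() == 0).all()

    def test_unpaired_subject_named_in_error(self, small_study):
        _, table, _, _ = small_study
        t = table.copy()
        victim = t.samples[t.samples["sample_type"] == SAMPLE]["subject"].iloc[0]
        drop_col = t.samples.index[
            (t.samples["subject"] == victim) & (t.samples["visit"] == "week8")
        ][0]
        t.intensities = t.intensities.drop(columns=[drop_col])
        t.samples = t.samples.drop(index=[drop_col])
        with pytest.raises(PairingError, match=victim):
            pp.baseline_subtract(t)

    def test_arm_labels_carry_over(self, small_study):
        _, table, _, _ = small_study
        out = pp.baseline_subtract(table)
        meta = table.samples
        for subject in out.samples.index:
            expected = meta[meta["subject"] == subject]["arm"].iloc[0]
            assert out.samples.loc[subject, "arm"] == expected


def test_filters_are_idempotent(artifact_study):
    _, table, _, _ = artifact_study
    stages = [
        lambda t: pp.filter_blank_features(t)[0],
        lambda t: pp.filter_rt_window(t)[0],
        lambda t: pp.filter_early_mass_defect(t)[0],
        lambda t: pp.remove_isotopes_duplicates(t)[0],
    ]
    current = table
    for stage in stages:
        once = stage(current)
        twice = stage(once)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)
        current = once
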