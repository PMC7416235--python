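import numpy as np
import pytest

from circleemd.errors import InvalidConfigError, InvalidInputError
from circleemd.preprocess import (
    PreprocConfig,
    RawStudy,
    StudyDataset,
    detrend_runs,
    normalize_by_baseline,
    reduce_outliers,
    run_preprocessing,
    select_channels_by_tvalue,
    select_roi_channels,
    select_task_conditions,
    shift_data,
    znorm_spatial,
)

from oracles import linear_detrend_oracle


def toy_study(n_runs=2, t=12, c=4, seed=0, baseline=10.0):
    rng = np.random.default_rng(seed)
    runs = [baseline + rng.normal(size=(t, c)) for _ in range(n_runs)]
    conds = [np.tile([1, 2, 3, 4], t // 4)[:t] for _ in range(n_runs)]
    roi = np.array(["A", "A", "B", "B"][:c])
    return RawStudy(runs=runs, channel_roi=roi, conditions=conds)


class TestShiftData:
    def test_zero_shift_is_identity(self):
        s = toy_study()
        out = shift_data(s, 0)
        assert all(np.array_equal(a, b) for a, b in zip(out.runs, s.runs))

    def test_pairing_on_labeled_toy_run(self):
        mat = np.arange(5, dtype=float)[:, None]
        study = RawStudy(
            runs=[mat],
            channel_roi=np.array(["A"]),
            conditions=[np.array([1, 2, 3, 4, 1])],
        )
        out = shift_data(study, 1)
        # volume t+1's signal is paired with the condition of volume t
        assert out.runs[0].ravel().tolist() == [1, 2, 3, 4]
        assert out.conditions[0].tolist() == [1, 2, 3, 4]

    def test_label_counts_preserved_across_runs(self):
        s = toy_study(n_runs=3)
        out = shift_data(s, 2)
        assert all(len(c) == r.shape[0] for c, r in zip(out.conditions, out.runs))

    def test_excessive_shift_rejected(self):
        with pytest.raises(InvalidConfigError):
            shift_data(toy_study(t=4), 4)


class TestSelectRoi:
    def test_all_rois_keep_everything(self):
        s = toy_study()
        out = select_roi_channels(s, ["A", "B"])
        assert out.n_channels == s.n_channels

    def test_single_roi_preserves_order(self):
        s = toy_study()
        out = select_roi_channels(s, ["B"])
        assert out.n_channels == 2
        assert np.array_equal(out.runs[0], s.runs[0][:, 2:])

    def test_empty_or_unknown_rejected(self):
        with pytest.raises(InvalidConfigError):
            select_roi_channels(toy_study(), [])
        with pytest.raises(InvalidConfigError):
            select_roi_channels(toy_study(), ["Z"])


class TestSelectByTvalue:
    def test_hand_computed_ordering(self):
        # channel 0: huge task effect, tiny variance -> ranks first
        t = 8
        conds = [np.array([1, 1, 1, 1, 2, 2, 2, 2])]
        rng = np.random.default_rng(1)
        mat = np.zeros((t, 3))
        mat[4:, 0] = 5.0
        mat[:, 0] += 0.01 * rng.normal(size=t)
        mat[4:, 1] = 1.0
        mat[:, 1] += 1.0 * rng.normal(size=t)
        mat[:, 2] = rng.normal(size=t)
        study = RawStudy(runs=[mat], channel_roi=np.array(["A"] * 3), conditions=conds)
        cfg = PreprocConfig(tval_min=-np.inf, n_channels_keep=3)
        _, tvals = select_channels_by_tvalue(study, cfg)
        # verify channel 0 against a hand-computed pooled two-sample t
        a, b = mat[4:, 0], mat[:4, 0]
        sp = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp * (1 / a.size + 1 / b.size))
        assert tvals[0] == pytest.approx(t_hand, rel=1e-12)
        assert np.argmax(tvals) == 0

    def test_threshold_then_top_k(self):
        # 6 channels above threshold, keep top 4 of them, original order kept
        t = 40
        rng = np.random.default_rng(3)
        conds = [np.array(([1] * 20) + ([2] * 20))]
        effects = np.array([0.0, 3.0, 5.0, 0.1, 4.0, 6.0, 2.0, 7.0])
        mat = rng.normal(size=(t, 8)) * 0.5
        mat[20:, :] += effects
        study = RawStudy(runs=[mat], channel_roi=np.array(["A"] * 8), conditions=conds)
        out, tvals = select_channels_by_tvalue(
            study, PreprocConfig(tval_min=3.2, n_channels_keep=4)
        )
        passing = np.flatnonzero(tvals >= 3.2)
        top4 = sorted(passing[np.argsort(tvals[passing])[::-1]][:4])
        assert out.n_channels == 4
        assert np.array_equal(out.runs[0], mat[:, top4])

    def test_nothing_passes_warns_and_keeps_none(self):
        study = toy_study(seed=5)
        with pytest.warns(UserWarning):
            out, _ = select_channels_by_tvalue(study, PreprocConfig(tval_min=50.0))
        assert out.n_channels == 0

    def test_selection_stable_under_nonselected_permutation(self):
        t = 40
        rng = np.random.default_rng(7)
        conds = [np.array(([1] * 20) + ([2] * 20))]
        mat = rng.normal(size=(t, 6)) * 0.5
        mat[20:, [1, 4]] += 8.0  # only channels 1 and 4 respond
        roi = np.array(["A"] * 6)
        cfg = PreprocConfig(tval_min=3.2, n_channels_keep=2)
        out1, _ = select_channels_by_tvalue(
            RawStudy(runs=[mat], channel_roi=roi, conditions=conds), cfg
        )
        perm = mat.copy()
        perm[:, [0, 5]] = perm[:, [5, 0]]  # permute non-selected channels
        out2, _ = select_channels_by_tvalue(
            RawStudy(runs=[perm], channel_roi=roi, conditions=conds), cfg
        )
        assert np.array_equal(out1.runs[0], out2.runs[0])


class TestReduceOutliers:
    def test_clean_data_unchanged(self):
        rng = np.random.default_rng(11)
        mat = rng.uniform(-1, 1, size=(20, 2))
        study = RawStudy(
            runs=[mat], channel_roi=np.array(["A", "A"]), conditions=[np.ones(20, int)]
        )
        out = reduce_outliers(study, std_thres=4.0, num_its=2)
        assert np.allclose(out.runs[0], mat)

    def test_spike_clipped_in_two_passes(self):
        vals = np.zeros(20)
        vals[:19] = np.linspace(-1, 1, 19)
        vals[19] = 50.0  # ~10 SD spike
        # hand-run the two clipping passes
        x = vals.copy()
        for _ in range(2):
            lo, hi = x.mean() - 4 * x.std(), x.mean() + 4 * x.std()
            x = np.clip(x, lo, hi)
        study = RawStudy(
            runs=[vals[:, None]], channel_roi=np.array(["A"]), conditions=[np.ones(20, int)]
        )
        out = reduce_outliers(study, std_thres=4.0, num_its=2)
        assert np.allclose(out.runs[0].ravel(), x)
        assert out.runs[0].max() < 50.0

    def test_range_never_grows(self):
        rng = np.random.default_rng(13)
        mat = rng.standard_t(df=2, size=(50, 3))
        study = RawStudy(
            runs=[mat], channel_roi=np.array(["A"] * 3), conditions=[np.ones(50, int)]
        )
        out = reduce_outliers(study, 2.0, 3)
        assert np.all(out.runs[0].max(0) <= mat.max(0) + 1e-12)
        assert np.all(out.runs[0].min(0) >= mat.min(0) - 1e-12)


class TestDetrend:
    def test_pure_ramp_becomes_its_mean(self):
        ramp = np.linspace(0, 9, 10)[:, None]
        study = RawStudy(
            runs=[ramp], channel_roi=np.array(["A"]), conditions=[np.ones(10, int)]
        )
        out = detrend_runs(study)
        assert np.allclose(out.runs[0], ramp.mean())

    def test_idempotent(self):
        study = toy_study(seed=17)
        once = detrend_runs(study)
        twice = detrend_runs(once)
        assert np.allclose(once.runs[0], twice.runs[0], atol=1e-10)

    def test_matches_least_squares_oracle(self):
        t = np.arange(30, dtype=float)
        series = 0.3 * t + np.sin(2 * np.pi * t / 7) + 5.0
        study = RawStudy(
            runs=[series[:, None]], channel_roi=np.array(["A"]), conditions=[np.ones(30, int)]
        )
        out = detrend_runs(study)
        assert np.allclose(out.runs[0].ravel(), linear_detrend_oracle(series), atol=1e-10)


class TestNormalizeByBaseline:
    def test_baseline_equal_signal_gives_zero(self):
        mat = np.full((8, 2), 7.0)
        study = RawStudy(
            runs=[mat], channel_roi=np.array(["A", "A"]), conditions=[np.ones(8, int)]
        )
        out = normalize_by_baseline(study, frozenset({1}))
        assert np.allclose(out.runs[0], 0.0)

    def test_percent_change_arithmetic(self):
        mat = np.array([[10.0], [11.0]])
        study = RawStudy(
            runs=[mat], channel_roi=np.array(["A"]), conditions=[np.array([1, 2])]
        )
        out = normalize_by_baseline(study, frozenset({1}))
        assert out.runs[0].ravel().tolist() == [0.0, pytest.approx(10.0)]

    def test_scale_invariance(self):
        study = toy_study(seed=19)
        scaled = RawStudy(
            runs=[r * 3.0 for r in study.runs],
            channel_roi=study.channel_roi,
            conditions=study.conditions,
        )
        a = normalize_by_baseline(study, frozenset({1, 2, 3, 4}))
        b = normalize_by_baseline(scaled, frozenset({1, 2, 3, 4}))
        assert np.allclose(a.runs[0], b.runs[0], atol=1e-10)

    def test_zero_baseline_rejected(self):
        mat = np.zeros((4, 1))
        study = RawStudy(
            runs=[mat], channel_roi=np.array(["A"]), conditions=[np.ones(4, int)]
        )
        with pytest.raises(InvalidInputError):
            normalize_by_baseline(study, frozenset({1}))


class TestZnorm:
    def test_population_sd_convention(self):
        ds = StudyDataset(
            samples=np.array([[1.0, 3.0]]),
            labels=np.array([0]),
            run_id=np.array([0]),
            condition=np.array([2]),
        )
        out = znorm_spatial(ds)
        assert out.samples.ravel().tolist() == [-1.0, 1.0]

    def test_defining_property_and_affine_removal(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=(5, 40))
        ds = StudyDataset(
            samples=x,
            labels=np.zeros(5, int),
            run_id=np.zeros(5, int),
            condition=np.full(5, 2),
        )
        out = znorm_spatial(ds)
        assert np.allclose(out.samples.mean(1), 0, atol=1e-12)
        assert np.allclose(out.samples.std(1), 1, atol=1e-12)
        affine = StudyDataset(
            samples=3.0 * x + 2.0,
            labels=ds.labels,
            run_id=ds.run_id,
            condition=ds.condition,
        )
        assert np.allclose(znorm_spatial(affine).samples, out.samples, atol=1e-10)


class TestSelectTaskConditions:
    def test_emulated_design_yields_240_balanced(self, default_dataset):
        dataset, _, _ = default_dataset
        assert dataset.samples.shape == (240, 200)
        assert np.bincount(dataset.labels).tolist() == [80, 80, 80]

    def test_selecting_all_conditions_returns_every_state(self):
        s = toy_study()
        ds = select_task_conditions(s, frozenset({1, 2, 3, 4}))
        assert ds.n_samples == sum(r.shape[0] for r in s.runs)


class TestFullFlow:
    def test_shape_contract_on_emulated_study(self, default_dataset):
        dataset, tvals, _ = default_dataset
        assert dataset.samples.shape == (240, 200)
        assert np.unique(dataset.run_id).size == 10
        assert int(np.sum(tvals >= 3.2)) >= 200

    def test_deterministic(self):
        from circleemd.synthetic import EmulatedStudySpec, make_emulated_study

        spec = EmulatedStudySpec(seed=42, n_runs=3, n_channels_raw=40, n_channels_signal=30)
        cfg = PreprocConfig(n_channels_keep=20)
        a, _ = run_preprocessing(make_emulated_study(spec)[0], cfg)
        b, _ = run_preprocessing(make_emulated_study(spec)[0], cfg)
        assert np.array_equal(a.samples, b.samples)
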