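import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnts.timeseries import (
    BinarizedDataset,
    PerturbationDataset,
    binarize,
    clamping,
    normalize,
    qc_repair,
    read_long,
    read_midas,
    write_midas,
)


def make_ds(series, nodes=("r1",), timepoints=None, perts=None,
            stimuli=("s1",), inhibitors=()):
    series = tuple(np.asarray(m, dtype=float) for m in series)
    k = series[0].shape[0]
    timepoints = timepoints or tuple(range(k))
    perts = perts or tuple({"s1": 1} for _ in series)
    return PerturbationDataset(nodes, timepoints, perts, series, stimuli, inhibitors)


class TestNormalize:
    def test_divides_by_global_maximum(self):
        ds = make_ds([[[0.2], [0.4]]])
        out = normalize(ds)
        assert np.allclose(out.series[0], [[0.5], [1.0]])

    def test_constant_positive_node_becomes_one(self):
        ds = make_ds([[[0.3], [0.3]]])
        assert np.allclose(normalize(ds).series[0], 1.0)

    def test_all_zero_node_raises_with_name(self):
        ds = make_ds([[[0.0], [0.0]]])
        with pytest.raises(ValueError, match="r1"):
            normalize(ds)

    def test_maximum_is_global_across_perturbations(self):
        ds = make_ds([[[0.2], [0.4]], [[0.8], [0.4]]])
        out = normalize(ds)
        assert np.allclose(out.series[0], [[0.25], [0.5]])
        assert np.allclose(out.series[1], [[1.0], [0.5]])

    def test_idempotent(self):
        ds = make_ds([[[0.2, 0.7], [0.4, 0.1]]], nodes=("r1", "r2"))
        once = normalize(ds)
        twice = normalize(once)
        for a, b in zip(once.series, twice.series):
            assert np.allclose(a, b)

    def test_missing_entries_stay_missing(self):
        ds = make_ds([[[np.nan], [0.4]]])
        out = normalize(ds)
        assert np.isnan(out.series[0][0, 0]) and out.series[0][1, 0] == 1.0


class TestBinarize:
    def test_threshold_and_tie_rule(self):
        ds = make_ds([[[0.2], [0.8], [0.5]]])
        out = binarize(ds, 0.5)
        assert out.series[0][:, 0].tolist() == [0.0, 1.0, 1.0]

    def test_subthreshold_row_all_zero(self):
        ds = make_ds([[[0.49], [0.49]]])
        assert binarize(ds).series[0].sum() == 0

    def test_missing_entry_locates_point(self):
        ds = make_ds([[[np.nan], [0.4]]], timepoints=(0, 5))
        with pytest.raises(ValueError, match=r"perturbation 0.*time 0.*'r1'"):
            binarize(ds)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0), st.integers(0, 2**16))
    def test_commutes_with_positive_rescaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(0.01, 1.0, size=(3, 2))
        a = binarize(normalize(make_ds([raw], nodes=("r1", "r2"))))
        b = binarize(normalize(make_ds([raw * scale], nodes=("r1", "r2"))))
        assert np.array_equal(a.series[0], b.series[0])


class TestQCRepair:
    def test_step2_fills_missing_t0_from_control(self):
        ds = make_ds([[[np.nan], [0.4], [0.6]]])
        clean, report = qc_repair(ds, control={"r1": 0.3})
        assert clean.series[0][0, 0] == 0.3
        (entry,) = report.by_rule("step-2")
        assert entry["node"] == "r1" and entry["value"] == 0.3

    def test_step3_collapses_duplicate_timepoint_keeping_first(self):
        ds = make_ds(
            [[[0.1], [0.2], [0.9], [0.3]]], timepoints=(0, 5, 5, 15)
        )
        clean, report = qc_repair(ds)
        assert clean.timepoints == (0, 5, 15)
        assert clean.series[0][:, 0].tolist() == [0.1, 0.2, 0.3]
        assert report.by_rule("step-3")[0]["dropped_rows"] == [2]

    def test_step4_drops_dynamic_inhibited_readout(self):
        series = [[[0.9], [0.1], [0.9]], [[0.2], [0.2], [0.2]]]
        ds = PerturbationDataset(
            ("x",), (0, 5, 15),
            ({"x": 1}, {"x": 0}),
            tuple(np.asarray(s, float) for s in series),
            (), ("x",),
        )
        clean, report = qc_repair(ds, tolerance=0.2)
        assert clean.n_perturbations == 1
        (entry,) = report.by_rule("step-4")
        assert entry["perturbation"] == 0 and entry["node"] == "x"

    def test_step4_tolerates_static_inhibited_readout(self):
        ds = PerturbationDataset(
            ("x",), (0, 5), ({"x": 1},),
            (np.array([[0.15], [0.2]]),), (), ("x",),
        )
        clean, report = qc_repair(ds, tolerance=0.2)
        assert clean.n_perturbations == 1 and not report.by_rule("step-4")

    def test_step5_drops_incomplete_perturbations(self):
        ds = make_ds([[[0.1], [np.nan]], [[0.2], [0.3]]])
        clean, report = qc_repair(ds)
        assert clean.n_perturbations == 1
        assert report.by_rule("step-5")[0]["perturbation"] == 0

    def test_clean_dataset_is_fixpoint(self):
        ds = make_ds([[[0.1], [0.4]]])
        clean, report = qc_repair(ds)
        assert not report
        assert np.array_equal(clean.series[0], ds.series[0])

    def test_replay_reconstructs_output(self):
        series = [
            [[np.nan], [0.2], [0.25], [0.3]],
            [[0.1], [np.nan], [np.nan], [0.3]],
        ]
        ds = make_ds(series, timepoints=(0, 5, 5, 15))
        clean, report = qc_repair(ds, control={"r1": 0.5})
        replayed = report.replay(ds)
        assert replayed.timepoints == clean.timepoints
        assert replayed.perturbations == clean.perturbations
        for a, b in zip(replayed.series, clean.series):
            assert np.array_equal(a, b, equal_nan=True)

    def test_surviving_set_is_subset(self):
        ds = make_ds([[[0.1], [np.nan]], [[0.2], [0.3]]])
        clean, _ = qc_repair(ds)
        assert set(map(tuple, (p.items() for p in clean.perturbations))) <= set(
            map(tuple, (p.items() for p in ds.perturbations))
        )

    def test_empty_survivor_reported_not_raised(self):
        ds = make_ds([[[0.1], [np.nan]]])
        clean, report = qc_repair(ds)
        assert clean.n_perturbations == 0
        assert report.by_rule("empty-dataset")


class TestClamping:
    def test_stimuli_clamped_to_treatment_inhibitors_to_zero(self):
        clamp = clamping({"s1": 1, "s2": 0, "i1": 1, "i2": 0},
                         ("s1", "s2"), ("i1", "i2"))
        assert clamp == {"s1": 1, "s2": 0, "i1": 0}


class TestFormats:
    def test_midas_roundtrip(self, tmp_path):
        ds = PerturbationDataset(
            ("r1", "r2"), (0, 5),
            ({"s1": 1, "i1": 0}, {"s1": 0, "i1": 1}),
            (np.array([[0.1, 0.9], [0.2, 0.8]]),
             np.array([[0.3, 0.7], [0.4, np.nan]])),
            ("s1",), ("i1",),
        )
        path = tmp_path / "data.csv"
        write_midas(ds, path)
        back = read_midas(path)
        assert back.observed_nodes == ds.observed_nodes
        assert back.stimuli == ("s1",) and back.inhibitors == ("i1",)
        assert back.perturbations == ds.perturbations
        for a, b in zip(back.series, ds.series):
            assert np.array_equal(a, b, equal_nan=True)

    def test_long_format_matches_midas(self, tmp_path):
        vals = tmp_path / "vals.csv"
        perts = tmp_path / "perts.csv"
        vals.write_text(
            "perturbation_id,time,node,value\n"
            "p1,0,r1,0.1\np1,5,r1,0.9\np2,0,r1,0.2\np2,5,r1,0.8\n"
        )
        perts.write_text(
            "perturbation_id,node,kind,value\n"
            "p1,s1,stimulus,1\np2,s1,stimulus,0\n"
        )
        ds = read_long(vals, perts)
        assert ds.observed_nodes == ("r1",)
        assert ds.perturbations == ({"s1": 1}, {"s1": 0})
        assert np.allclose(ds.series[1], [[0.2], [0.8]])

    def test_binarized_flip(self):
        b = BinarizedDataset(("r1",), (0, 5), ({"s1": 1},),
                             (np.array([[0.0], [1.0]]),), ("s1",), ())
        flipped = b.flip([(0, 0, "r1")])
        assert flipped.series[0][:, 0].tolist() == [1.0, 1.0]
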