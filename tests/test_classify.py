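import numpy as np
import pytest

from capturestress.classify import (CutoffCriteria, IntensityClassifier,
                                    classify_amplitude_cycle,
                                    exercise_metrics, label_event,
                                    level_proportions)
from capturestress.features import FeatureWindow, VSTrace

# one case per rule branch plus every boundary (boundaries fall to medium)
RULE_CASES = [
    (0.30, 3.0, "high"),    # large, fast cycling
    (0.26, 4.9, "high"),    # just over both cutoffs
    (0.30, 8.0, "med"),     # large but slow: medium
    (0.30, 5.0, "med"),     # cycle exactly at cutoff
    (0.25, 3.0, "med"),     # amplitude exactly at the high cutoff
    (0.249, 2.1, "med"),    # mid-band amplitude, fast
    (0.10, 2.0, "med"),     # mid-band amplitude
    (0.051, 8.0, "med"),    # just above the low cutoff
    (0.05, 3.0, "med"),     # amplitude exactly at the low cutoff
    (0.049, 12.0, "low"),   # just below the low cutoff
    (0.03, 3.0, "low"),     # small and fast is still low
    (0.001, 30.0, "low"),   # near-static
]


@pytest.mark.parametrize("amp,cycle,expected", RULE_CASES)
def test_cutoff_rule_branches(amp, cycle, expected):
    assert classify_amplitude_cycle(amp, cycle) == expected


def test_level_monotone_in_amplitude():
    """Raising amplitude at fixed cycle never demotes the level."""
    order = {"low": 0, "med": 1, "high": 2}
    for cycle in (2.0, 4.9, 5.0, 8.0):
        levels = [order[classify_amplitude_cycle(a, cycle)]
                  for a in np.linspace(0.0, 0.6, 400)]
        assert all(b >= a for a, b in zip(levels, levels[1:]))


def _windows(amps, cycles):
    return [FeatureWindow(10.0 * i, 10.0 * (i + 1), a, c, 10, True)
            for i, (a, c) in enumerate(zip(amps, cycles))]


def _blob_features(rng, centers=(0.02, 0.12, 0.50), cycles=(8.0, 3.5, 3.0),
                   n_each=30, amp_sd=0.005, cycle_sd=0.3):
    amps, cycs, labels = [], [], []
    for k, (c, cy) in enumerate(zip(centers, cycles)):
        amps += list(np.maximum(rng.normal(c, amp_sd, n_each), 1e-4))
        cycs += list(np.maximum(rng.normal(cy, cycle_sd, n_each), 2.0))
        labels += [k] * n_each
    return np.column_stack([amps, cycs]), np.array(labels)


def test_three_blob_partition_matches_membership(rng):
    """Well-separated amplitude blobs are recovered exactly, and the result
    is a nearest-centre fixed point in the clustering feature space."""
    X, blob = _blob_features(rng)
    clf = IntensityClassifier(random_state=0).fit(X)
    assert clf.n_clusters_ == 3
    # canonical ordering is ascending amplitude, so ids match blob indices
    np.testing.assert_array_equal(clf.cluster_ids_, blob)
    # independent oracle: brute-force nearest-centre assignment on the
    # standardised log-amplitude feature the classifier clusters on
    z = np.log(X[:, :1] + 0.05)
    z = (z - z.mean()) / z.std()
    centers = np.array([z[clf.cluster_ids_ == c].mean() for c in range(3)])
    nearest = np.argmin(np.abs(z - centers[None, :]), axis=1)
    np.testing.assert_array_equal(nearest, clf.cluster_ids_)


def test_blob_levels_follow_cutoffs(rng):
    X, blob = _blob_features(rng)
    clf = IntensityClassifier(random_state=0).fit(X)
    assert [clf.cluster_levels_[c] for c in range(3)] == ["low", "med",
                                                          "high"]


def test_identical_windows_collapse_to_single_cluster(caplog):
    X = np.tile([[0.1, 3.0]], (20, 1))
    clf = IntensityClassifier(random_state=0).fit(X)
    assert clf.n_clusters_ == 1
    assert set(clf.labels_) == {"med"}


def test_seeded_determinism(rng):
    X, _ = _blob_features(rng, amp_sd=0.02)
    a = IntensityClassifier(random_state=7).fit(X).cluster_ids_
    b = IntensityClassifier(random_state=7).fit(X).cluster_ids_
    np.testing.assert_array_equal(a, b)


def test_output_invariant_to_input_permutation(rng):
    X, _ = _blob_features(rng)
    perm = rng.permutation(len(X))
    base = IntensityClassifier(random_state=0).fit(X).labels_
    shuffled = IntensityClassifier(random_state=0).fit(X[perm]).labels_
    np.testing.assert_array_equal(shuffled, base[perm])


def test_sklearn_estimator_api():
    from sklearn.base import clone
    clf = IntensityClassifier(n_clusters=3, random_state=1)
    params = clf.get_params()
    assert params["random_state"] == 1
    clone(clf)  # must be cloneable for pipelines/model selection
    clf.set_params(level_mode="window")
    assert clf.level_mode == "window"


def _labeled_constant_vs(levels, vs_value=0.5):
    n = len(levels)
    vst = VSTrace("e", np.arange(n, dtype=float), np.full(n, vs_value))
    wins = _windows([0.1] * (n // 10), [3.0] * (n // 10))
    from capturestress.classify import LabeledEvent
    return LabeledEvent("e", wins, np.array(["med"] * len(wins)),
                        np.array(levels), np.zeros(len(wins), int),
                        {0: "med"}, 1), vst


def test_proportions_and_fight_intensity():
    levels = ["low"] * 50 + ["high"] * 50
    labeled, vst = _labeled_constant_vs(levels)
    m = exercise_metrics(labeled, vst, capture_duration_min=2.0)
    assert (m.p_low, m.p_med, m.p_high) == (0.5, 0.0, 0.5)
    assert m.p_low + m.p_med + m.p_high == 1.0  # exact, not approximate
    # 100 samples of 0.5 g over 2 min -> 25 g·min⁻¹
    assert m.mean_fight_intensity_g_min == pytest.approx(25.0)


def test_fight_intensity_printed_definition():
    labeled, vst = _labeled_constant_vs(["low"] * 120)
    m = exercise_metrics(labeled, vst, capture_duration_min=2.0)
    assert m.mean_fight_intensity_g_min == pytest.approx(30.0)
    assert m.p_low == 1.0


def test_empty_label_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        level_proportions(np.array([], dtype=str))


def test_label_event_covers_every_second(rng):
    from capturestress.synthetic import BoutModelConfig, simulate_capture_event
    from capturestress.features import vectorial_sum, window_features
    tr, truth = simulate_capture_event(BoutModelConfig(), rng,
                                       duration_min=6.0)
    vst = vectorial_sum(tr)
    lab = label_event(vst, window_features(vst), seed=0)
    assert len(lab.second_levels) == len(vst.vs)
    assert set(lab.second_levels) <= {"low", "med", "high"}
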