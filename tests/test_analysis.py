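"""CA membership thresholds, ignition detection against a brute-force
oracle, ASI trial averaging and baseline alignment."""

import numpy as np
import pytest

from hebbca import (
    AnalysisParams,
    align_baseline,
    ca_size_table,
    detect_ignitions,
    extract_asi,
    identify_ca_cells,
)
from hebbca.analysis import ASI, IgnitionEvent, active_fraction, events_table

N_AREAS, A = 6, 16  # toy layout: 6 areas of 4x4 cells
N = N_AREAS * A


def profile_with_peaks(peaks):
    """One-pattern profile with given {cell: value} and zeros elsewhere."""
    prof = np.zeros((1, N))
    for c, v in peaks.items():
        prof[0, c] = v
    return prof


class TestMembership:
    def test_gamma_one_keeps_only_argmax_cells(self):
        rng = np.random.default_rng(0)
        prof = rng.random((3, N))
        m = identify_ca_cells(prof, gamma=1.0)
        for w in range(3):
            per_area = prof[w].reshape(N_AREAS, A)
            for a in range(N_AREAS):
                members = m.members[w].reshape(N_AREAS, A)[a]
                assert members.sum() == np.count_nonzero(
                    per_area[a] == per_area[a].max()
                )

    def test_threshold_is_gamma_times_area_max(self):
        prof = profile_with_peaks({0: 0.8, 1: 0.5, 16: 0.4})
        m = identify_ca_cells(prof, gamma=0.5)
        assert m.thresholds[0, 0] == pytest.approx(0.4)
        assert m.thresholds[0, 1] == pytest.approx(0.2)
        got = set(m.member_indices(0).tolist())
        assert {0, 1, 16} <= got

    def test_membership_nested_in_gamma(self):
        rng = np.random.default_rng(1)
        prof = rng.random((2, N))
        m_lo = identify_ca_cells(prof, gamma=0.3)
        m_hi = identify_ca_cells(prof, gamma=0.7)
        for w in range(2):
            assert set(m_hi.member_indices(w)) <= set(m_lo.member_indices(w))

    def test_all_zero_area_flagged_empty_with_no_members(self):
        prof = profile_with_peaks({0: 0.8})  # only P1 responds
        m = identify_ca_cells(prof, gamma=0.5)
        assert m.empty[0]
        assert set(m.member_indices(0)) == {0}

    def test_size_table_bounds_and_single_case(self):
        prof = profile_with_peaks({0: 0.8, 1: 0.8, 16: 0.4})
        table = ca_size_table(prof, gammas=(0.5,))
        sizes = identify_ca_cells(prof, 0.5).size_per_area(0)
        assert np.array_equal(table[0.5].to_numpy(), sizes)
        assert (table.to_numpy() <= A).all()

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            identify_ca_cells(np.zeros((1, N)), gamma=1.5)


def brute_force_events(recording, membership, w, fraction=0.5):
    """Per-step set-intersection oracle for ignition detection."""
    cells = membership.member_indices(w)
    theta = membership.cell_thresholds(w)[cells]
    active_steps = []
    for t in range(recording.shape[0]):
        firing = {int(c) for c, th in zip(cells, theta)
                  if recording[t, c] >= th}
        if len(firing) >= fraction * len(cells):
            active_steps.append(t)
    events = []
    for t in active_steps:
        if events and t == events[-1][1] + 1:
            events[-1][1] = t
        else:
            events.append([t, t])
    return [(s, e) for s, e in events]


@pytest.fixture()
def two_ca_membership():
    prof = np.zeros((2, N))
    prof[0, [0, 1, 16, 17]] = 1.0        # CA 1: cells in P1 and HP
    prof[1, [32, 33, 48, 49]] = 1.0      # CA 2: cells in PA and PF
    return identify_ca_cells(prof, gamma=0.5)


class TestDetection:
    def test_agrees_with_brute_force_oracle_on_random_recordings(
        self, two_ca_membership
    ):
        rng = np.random.default_rng(3)
        rec = rng.random((60, N))
        events = detect_ignitions(rec, two_ca_membership)
        for w in range(2):
            got = [(e.onset, e.offset) for e in events if e.ca_id == w + 1]
            assert got == brute_force_events(rec, two_ca_membership, w)

    def test_all_zero_recording_has_no_events(self, two_ca_membership):
        assert detect_ignitions(np.zeros((50, N)), two_ca_membership) == []

    def test_exact_half_active_for_one_step_is_one_event(self, two_ca_membership):
        """Boundary: exactly 50% of CA cells at threshold for one step."""
        rec = np.zeros((20, N))
        rec[7, [0, 16]] = 0.5   # 2 of 4 cells exactly at theta = 0.5
        events = detect_ignitions(rec, two_ca_membership)
        assert [(e.ca_id, e.onset, e.offset) for e in events] == [(1, 7, 7)]
        # just below threshold: no event
        rec[7, [0, 16]] = 0.4999
        assert detect_ignitions(rec, two_ca_membership) == []

    def test_two_cas_in_disjoint_windows(self, two_ca_membership):
        rec = np.zeros((40, N))
        rec[5:9, [0, 1, 16]] = 1.0
        rec[20:26, [32, 33, 48]] = 1.0
        events = detect_ignitions(rec, two_ca_membership)
        assert [(e.ca_id, e.onset, e.offset) for e in events] == [
            (1, 5, 8), (2, 20, 25),
        ]

    def test_detection_idempotent(self, two_ca_membership):
        rng = np.random.default_rng(4)
        rec = rng.random((80, N))
        a = detect_ignitions(rec, two_ca_membership)
        b = detect_ignitions(rec, two_ca_membership)
        assert events_table(a).equals(events_table(b))

    def test_gap_merging(self, two_ca_membership):
        rec = np.zeros((30, N))
        rec[5:8, [0, 1, 16, 17]] = 1.0
        rec[10:12, [0, 1, 16, 17]] = 1.0
        strict = detect_ignitions(rec, two_ca_membership, AnalysisParams(min_gap=0))
        merged = detect_ignitions(rec, two_ca_membership, AnalysisParams(min_gap=2))
        assert len(strict) == 2
        assert len(merged) == 1 and (merged[0].onset, merged[0].offset) == (5, 11)

    def test_peak_fraction_recorded(self, two_ca_membership):
        rec = np.zeros((20, N))
        rec[4, [0, 16]] = 1.0
        rec[5, [0, 1, 16, 17]] = 1.0
        ev = detect_ignitions(rec, two_ca_membership)[0]
        assert ev.peak_fraction == pytest.approx(1.0)
        assert ev.duration == 2


class TestASI:
    params = AnalysisParams(pre_onset=5, trial_len=15)

    def synthetic_recording(self, onsets):
        rec = np.zeros((80, N))
        for t in onsets:
            rec[t:t + 4, [0, 1, 16]] = 1.0   # 3 of 4 cells: above 50%
        return rec

    def test_single_event_asi_equals_the_trial(self, two_ca_membership):
        rec = self.synthetic_recording([20])
        events = detect_ignitions(rec, two_ca_membership, self.params)
        asis = extract_asi(rec, events, two_ca_membership, self.params)
        asi = asis[1]
        assert asi.n_trials == 1
        # P1 area trace: zeros before onset-aligned step 5, then 2 cells
        expected = np.zeros(15)
        expected[5:9] = 2
        assert np.array_equal(asi.counts[0], expected)

    def test_duplicated_trials_average_to_the_common_trial(self, two_ca_membership):
        rec = self.synthetic_recording([20, 50])
        events = detect_ignitions(rec, two_ca_membership, self.params)
        asis = extract_asi(rec, events, two_ca_membership, self.params)
        single = extract_asi(
            rec, [e for e in events if e.onset == 20], two_ca_membership, self.params
        )
        assert asis[1].n_trials == 2
        assert np.array_equal(asis[1].counts, single[1].counts)

    def test_normalized_in_unit_interval(self, two_ca_membership):
        rec = self.synthetic_recording([20, 50])
        events = detect_ignitions(rec, two_ca_membership, self.params)
        asis = extract_asi(rec, events, two_ca_membership, self.params)
        norm = asis[1].normalized
        valid = ~np.isnan(norm)
        assert (norm[valid] >= 0).all() and (norm[valid] <= 1).all()
        # areas with no members are NaN
        assert np.isnan(norm[2]).all()

    def test_events_too_close_to_edges_dropped(self, two_ca_membership):
        rec = self.synthetic_recording([2, 76])   # windows overrun both ends
        events = detect_ignitions(rec, two_ca_membership, self.params)
        asis = extract_asi(rec, events, two_ca_membership, self.params)
        assert asis == {}

    def test_ca_without_events_excluded(self, two_ca_membership):
        rec = self.synthetic_recording([20])
        events = detect_ignitions(rec, two_ca_membership, self.params)
        asis = extract_asi(rec, events, two_ca_membership, self.params)
        assert 2 not in asis


class TestAlignment:
    def make_asi(self, lead_zeros, ca_id=1, pre_onset=10, length=40):
        counts = np.zeros((N_AREAS, length))
        counts[2, lead_zeros:] = 3.0   # PA rises first
        counts[1, lead_zeros + 1:] = 2.0
        norm = counts / 4.0
        return ASI(ca_id=ca_id, counts=counts, normalized=norm,
                   n_trials=2, pre_onset=pre_onset)

    def test_origin_is_step_before_first_nonzero(self):
        asi = self.make_asi(6)
        windows, kept, origins = align_baseline({1: asi}, AnalysisParams())
        assert kept == [1] and origins == [5]
        assert windows.shape == (1, N_AREAS, 6)
        assert np.all(windows[0, :, 0] == 0.0)
        assert windows[0, 2, 1] > 0

    def test_translation_equivariance(self):
        w1, _, o1 = align_baseline({1: self.make_asi(4)}, AnalysisParams())
        w2, _, o2 = align_baseline({1: self.make_asi(7)}, AnalysisParams())
        assert o2[0] - o1[0] == 3
        assert np.array_equal(w1, w2)

    def test_no_all_zero_step_excludes_ca(self):
        asi = self.make_asi(0)   # active from the very first step
        windows, kept, _ = align_baseline({1: asi}, AnalysisParams())
        assert kept == [] and windows.shape[0] == 0

    def test_critical_window_length_default_six(self):
        windows, _, _ = align_baseline({1: self.make_asi(6)}, AnalysisParams())
        assert windows.shape[-1] == 6


def test_active_fraction_empty_ca_is_zero():
    prof = np.zeros((1, N))
    m = identify_ca_cells(prof, gamma=0.5)
    assert np.all(active_fraction(np.ones((5, N)), m, 0) == 0.0)
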