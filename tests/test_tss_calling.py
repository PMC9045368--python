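import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sigmacall.tss_calling import (
    InvalidInputError,
    ReadStartProfile,
    TssCandidate,
    TssCallingConfig,
    cluster_positions,
    compute_rrs,
    format_tss_name,
    merge_replicates,
    score_candidates,
)
from sigmacall.io_formats import parse_tss_name

from _oracles import brute_force_cluster


def make_profile(counts, total=10**6):
    return ReadStartProfile(replicon_id="CP000352", strand="+", counts=counts,
                            total_reads=total)


class TestComputeRrs:
    @pytest.mark.parametrize(
        "counts,total,expected",
        [
            ({100: 50}, 10**7, {100: 5.0}),
            ({}, 10**6, {}),
            ({1: 1, 2: 2}, 10**6, {1: 1.0, 2: 2.0}),
        ],
    )
    def test_reads_per_million(self, counts, total, expected):
        assert compute_rrs(make_profile(counts, total)) == pytest.approx(expected)

    def test_zero_total_reads_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_rrs(make_profile({1: 1}, total=0))

    def test_zero_counts_absent(self):
        assert compute_rrs(make_profile({5: 0, 6: 3})) == pytest.approx({6: 3.0})


class TestClustering:
    def test_pooling_into_highest(self):
        peaks = cluster_positions({100: 10.0, 103: 2.0, 120: 1.0}, radius=5)
        assert {(p.position, p.rrs) for p in peaks} == {(100, 12.0), (120, 1.0)}

    def test_radius_zero_is_identity(self):
        peaks = cluster_positions({100: 10.0}, radius=0)
        assert [(p.position, p.rrs) for p in peaks] == [(100, 10.0)]

    def test_tie_broken_to_smaller_coordinate(self):
        peaks = cluster_positions({100: 5.0, 105: 5.0}, radius=5)
        assert [(p.position, p.rrs) for p in peaks] == [(100, 10.0)]

    def test_empty_input(self):
        assert cluster_positions({}, radius=5) == []

    @given(
        data=st.dictionaries(
            st.integers(min_value=1, max_value=200),
            st.floats(min_value=0.01, max_value=100, allow_nan=False),
            max_size=40,
        ),
        radius=st.integers(min_value=0, max_value=10),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_conserves_mass(self, data, radius):
        peaks = cluster_positions(data, radius)
        expected = brute_force_cluster(data, radius)
        assert [p.position for p in peaks] == [q[0] for q in expected]
        np.testing.assert_allclose(
            [p.rrs for p in peaks], [q[1] for q in expected], rtol=1e-9
        )
        assert sum(p.rrs for p in peaks) == pytest.approx(sum(data.values()))
        positions = [p.position for p in peaks]
        assert all(b - a > radius for a, b in zip(positions, positions[1:]))


class TestScoring:
    def cfg(self, **kw):
        return TssCallingConfig(**kw)

    def cand(self, rrs, pos=100):
        return TssCandidate(replicon_id="CP000352", strand="+", position=pos, rrs=rrs)

    def test_ratio_mode(self):
        out = score_candidates([self.cand(50.0)], {100: 2.0}, self.cfg(control_mode="ratio"))
        assert out[0].score == pytest.approx(25.0)

    def test_control_free_mode(self):
        out = score_candidates([self.cand(50.0)], None, self.cfg())
        assert out[0].score == pytest.approx(50.0)

    def test_rrs_cutoff_drops_candidate(self):
        assert score_candidates([self.cand(4.0)], None, self.cfg()) == []

    def test_per_replicate_cutoff_is_strict(self):
        assert score_candidates([self.cand(5.0)], None, self.cfg()) == []
        kept = score_candidates([self.cand(5.01)], None, self.cfg())
        assert len(kept) == 1

    def test_zero_control_uses_floor_and_flags(self):
        control = {500: 0.5, 700: 4.0}  # nothing near the peak
        out = score_candidates([self.cand(50.0)], control, self.cfg(control_mode="ratio"))
        assert out[0].control_floored
        assert out[0].score == pytest.approx(50.0 / 0.5)

    def test_control_pooled_with_same_radius(self):
        control = {98: 1.0, 104: 1.0, 110: 7.0}
        out = score_candidates([self.cand(50.0)], control, self.cfg(control_mode="ratio"))
        assert out[0].rrs_control == pytest.approx(2.0)

    def test_ratio_mode_requires_control(self):
        with pytest.raises(InvalidInputError):
            score_candidates([self.cand(50.0)], None, self.cfg(control_mode="ratio"))


class TestMergeReplicates:
    def cand(self, pos, score, strand="-"):
        return TssCandidate(replicon_id="CP000352", strand=strand, position=pos,
                            rrs=score, score=score)

    def test_consensus_of_three_replicates(self):
        reps = [
            [self.cand(769713, 38130.0)],
            [self.cand(769713, 21698.0)],
            [self.cand(769713, 29914.0)],
        ]
        records = merge_replicates(reps, TssCallingConfig())
        assert len(records) == 1
        rec = records[0]
        assert (rec.position, rec.strand, rec.name) == (769713, "-", "TSS_769713-2")
        assert rec.mean_score == pytest.approx(np.mean([38130, 21698, 29914]))
        assert rec.score_sd == pytest.approx(np.std([38130, 21698, 29914], ddof=1))

    def test_peak_missing_in_one_replicate_dropped(self):
        reps = [[self.cand(100, 50.0)], [self.cand(100, 60.0)], []]
        assert merge_replicates(reps, TssCallingConfig()) == []

    def test_consensus_cutoff_is_strict(self):
        assert merge_replicates([[self.cand(10, 9.9)]], TssCallingConfig()) == []
        assert merge_replicates([[self.cand(10, 10.0)]], TssCallingConfig()) == []
        assert len(merge_replicates([[self.cand(10, 10.1)]], TssCallingConfig())) == 1

    def test_empty_replicate_list_rejected(self):
        with pytest.raises(InvalidInputError):
            merge_replicates([], TssCallingConfig())

    def test_sorted_by_descending_mean_score(self):
        reps = [[self.cand(100, 50.0), self.cand(300, 500.0), self.cand(200, 99.0)]]
        records = merge_replicates(reps, TssCallingConfig())
        assert [r.position for r in records] == [300, 200, 100]

    @given(scores=st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=1, max_size=8),
           cutoff_lo=st.floats(min_value=0, max_value=100),
           delta=st.floats(min_value=0, max_value=100))
    @settings(max_examples=100, deadline=None)
    def test_raising_cutoff_never_adds_records(self, scores, cutoff_lo, delta):
        reps = [[self.cand(10 * (i + 1), s) for i, s in enumerate(scores)]]
        low = merge_replicates(reps, TssCallingConfig(consensus_score_cutoff=cutoff_lo))
        high = merge_replicates(
            reps, TssCallingConfig(consensus_score_cutoff=cutoff_lo + delta)
        )
        assert {r.name for r in high} <= {r.name for r in low}


@given(pos=st.integers(min_value=1, max_value=10**7),
       strand=st.sampled_from("+-"),
       digit=st.integers(min_value=0, max_value=9))
@settings(max_examples=50, deadline=None)
def test_tss_name_round_trip(pos, strand, digit):
    assert parse_tss_name(format_tss_name(pos, strand, digit)) == (pos, strand, digit)
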