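import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from uvmtk import PipelineConfig, SegmentedProfile
from uvmtk.cn import (
    call_arm_events,
    filter_changes,
    gene_copy_status,
    to_log2,
)


def _profile(rows, sample="S1"):
    return SegmentedProfile(
        sample=sample,
        segments=pd.DataFrame(rows, columns=["chrom", "start", "end", "log2"]),
    )


class TestToLog2:
    def test_diploid_maps_to_zero(self):
        assert to_log2([2.0])[0] == 0.0

    def test_four_copies_maps_to_one(self):
        assert to_log2([4.0])[0] == 1.0

    def test_zero_replaced_by_min_nonzero_before_transform(self):
        # {0, 1, 4}: the zero becomes 1, giving log2 {-1, -1, +1}
        np.testing.assert_allclose(to_log2([0, 1, 4]), [-1.0, -1.0, 1.0])

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError, match="all copy values are zero"):
            to_log2([0.0, 0.0])


class TestGeneCopyStatus:
    def test_single_overlap_returns_segment_value(self, toy_genes):
        prof = _profile([("1", 0, 50_000_000, 0.4)])
        status = gene_copy_status(prof, toy_genes)
        assert status["gA"] == pytest.approx(0.4)

    def test_max_abs_log2_keeps_sign(self, toy_genes):
        # gene gB spans the segment boundary at 45-55 Mb: {+0.3, -0.5} -> -0.5
        prof = _profile(
            [("1", 0, 50_000_000, 0.3), ("1", 50_000_000, 120_000_000, -0.5)]
        )
        status = gene_copy_status(prof, toy_genes)
        assert status["gB"] == pytest.approx(-0.5)
        # brute-force oracle over overlapping segments
        overlaps = [0.3, -0.5]
        assert status["gB"] == max(overlaps, key=abs)

    def test_no_overlap_is_missing(self, toy_genes):
        prof = _profile([("1", 0, 50_000_000, 0.4)])
        status = gene_copy_status(prof, toy_genes)
        assert np.isnan(status["gC"]) and np.isnan(status["gD"])

    def test_exact_tie_broken_toward_loss(self, toy_genes):
        prof = _profile(
            [("1", 0, 50_000_000, 0.4), ("1", 50_000_000, 120_000_000, -0.4)]
        )
        status = gene_copy_status(prof, toy_genes)
        assert status["gB"] == pytest.approx(-0.4)

    def test_permutation_invariant_in_segment_order(self, toy_genes):
        rows = [
            ("1", 0, 30_000_000, 0.2),
            ("1", 30_000_000, 50_000_000, 0.5),
            ("1", 50_000_000, 120_000_000, -0.3),
            ("2", 0, 80_000_000, -0.8),
        ]
        s1 = gene_copy_status(_profile(rows), toy_genes)
        s2 = gene_copy_status(_profile(rows[::-1]), toy_genes)
        pd.testing.assert_series_equal(s1, s2)


class TestFilterChanges:
    def test_shallow_change_removed(self, genome, config):
        prof = _profile([("1", 0, 125_000_000, 0.1)])
        assert len(filter_changes(prof, genome, config)) == 0

    def test_narrow_change_removed(self, genome, config):
        # 0.4 x shortest arm < the 0.5 threshold
        width = int(0.4 * genome.shortest_arm_length())
        prof = _profile([("1", 0, width, 0.5)])
        assert len(filter_changes(prof, genome, config)) == 0

    def test_qualifying_change_retained(self, genome, config):
        width = int(0.6 * genome.shortest_arm_length())
        prof = _profile([("1", 0, width, 0.25)])
        assert len(filter_changes(prof, genome, config)) == 1

    def test_idempotent(self, genome, config):
        prof = _profile(
            [("1", 0, 125_000_000, 0.5), ("1", 125_000_000, 126_000_000, 0.9),
             ("2", 0, 90_000_000, 0.05)]
        )
        once = filter_changes(prof, genome, config)
        again = filter_changes(
            SegmentedProfile("S1", once), genome, config
        )
        pd.testing.assert_frame_equal(once, again)


class TestCallArmEvents:
    def test_whole_arm_gain_called(self, genome, config):
        chrom, start, end = genome.arm_interval("8q")
        prof = _profile([("8", start, end, 0.6)])
        events = call_arm_events([prof], genome, config)
        assert events.loc["S1", ("8q", "gain")]
        assert not events.loc["S1", ("8q", "loss")]

    def test_no_changes_gives_all_false(self, genome, config):
        prof = _profile([("1", 0, 249_000_000, 0.0)])
        events = call_arm_events([prof], genome, config)
        assert not events.loc["S1"].any()

    def test_chromosome_3_is_single_unit(self, genome, config):
        prof = _profile([("3", 0, 198_022_430, -0.8)])
        events = call_arm_events([prof], genome, config)
        assert events.loc["S1", ("3", "loss")]
        assert ("3p", "loss") not in events.columns

    def test_exact_recovery_of_planted_whole_arm_events(self, genome, config):
        from uvmtk.simulate import CohortSpec, simulate_cn_expression

        spec = CohortSpec(n_a=10, n_b=10, n_genes_per_arm=2)
        cohort = simulate_cn_expression(spec, seed=11)
        events = call_arm_events(cohort.profiles_a, genome, config)
        truth = cohort.truth_events.query("cohort == 'A'")
        planted = {
            (r.sample, r.arm, r.direction) for r in truth.itertuples()
        }
        called = {
            (s, arm, d)
            for s in events.index
            for (arm, d) in events.columns
            if events.loc[s, (arm, d)]
        }
        assert called == planted


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    values=st.lists(
        st.floats(min_value=0.0, max_value=16.0, allow_nan=False),
        min_size=1, max_size=20,
    ).filter(lambda v: any(x > 0 for x in v))
)
def test_to_log2_matches_manual_rule(values):
    out = to_log2(values)
    floor = min(v for v in values if v > 0)
    expected = [np.log2((v if v > 0 else floor) / 2) for v in values]
    np.testing.assert_allclose(out, expected)


class TestRecenter:
    def test_offset_shifts_all_log2_values(self, toy_profile):
        from uvmtk.cn import recenter

        shifted = recenter(toy_profile, 0.1)
        np.testing.assert_allclose(
            shifted.segments["log2"], toy_profile.segments["log2"] - 0.1
        )
        assert shifted.sample == toy_profile.sample
        # original untouched
        assert toy_profile.segments["log2"].iloc[0] == pytest.approx(0.4)
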