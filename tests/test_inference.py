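"""Transmission inference: window states, segmentation, crossover calls,
aneuploidy detection and sample classification."""

import numpy as np
import pandas as pd
import pytest

from polyhap.core import GenomeLayout, ValidationError
from polyhap.inference import (
    InferenceParams,
    TransmissionModel,
    call_crossovers,
    classify_window_state,
    detect_aneuploidy,
    segment_states,
    StateSegment,
)
from polyhap.pipelines import simulate_sample, two_way_marker_pipeline
from polyhap.sim import SimulationConfig, TruncationSpec, rng_from, simulate_founders
from polyhap.windows import WindowProfile

PARAMS = InferenceParams()


def synthetic_profile(af_values, cov_values=None, step=50_000, window=1_000_000,
                      chrom="chr1"):
    n = len(af_values)
    starts = np.arange(n) * step
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + window,
                       "n_markers": 50, "mean_af": af_values})
    if cov_values is not None:
        df["mean_norm_cov"] = cov_values
    return WindowProfile(df, window, step)


class TestWindowState:
    @pytest.mark.parametrize("af,ploidy,expect", [
        (0.50, 2, 1),      # balanced heterozygous
        (0.02, 2, 0),      # homozygous reference side
        (0.97, 2, 2),
        (0.25, 2, None),   # ambiguous band between hom and het for diploid
        (0.68, 4, 3),      # nearest grid point 0.75 within t_dose
        (0.50, 4, 2),
        (0.66, 4, None),   # 2/3 falls between tetraploid dosage states
        (np.nan, 2, None),
    ])
    def test_state_grid(self, af, ploidy, expect):
        assert classify_window_state(af, ploidy, PARAMS) == expect

    def test_invalid_ploidy(self):
        with pytest.raises(ValidationError):
            classify_window_state(0.5, 3, PARAMS)


class TestSegmentation:
    def test_uniform_het_single_segment(self):
        prof = synthetic_profile([0.5] * 100)
        segs = segment_states(prof, 2, PARAMS)
        assert len(segs) == 1
        assert segs[0].state == 1 and segs[0].n_windows == 100
        assert segs[0].start == 0

    def test_two_state_profile_one_transition(self):
        prof = synthetic_profile([0.5] * 40 + [0.97] * 60)
        segs = segment_states(prof, 2, PARAMS)
        assert [s.state for s in segs] == [1, 2]
        calls = call_crossovers(segs)
        assert len(calls) == 1
        assert calls[0].left_state == 1 and calls[0].right_state == 2

    def test_isolated_window_absorbed(self):
        af = [0.5] * 50
        af[25] = 0.97  # single-window blip, below min_run
        segs = segment_states(synthetic_profile(af), 2, PARAMS)
        assert len(segs) == 1 and segs[0].state == 1

    def test_ambiguous_gap_between_same_state_merged(self):
        af = [0.5] * 30 + [0.3] * 3 + [0.5] * 30  # 0.3 is ambiguous for diploid
        segs = segment_states(synthetic_profile(af), 2, PARAMS)
        assert len(segs) == 1 and segs[0].n_windows == 63


class TestCrossoverCalls:
    def test_call_interval_contains_midpoint(self):
        segs = [StateSegment("chr1", 0, 11_950_000, 1, 220, 0.5),
                StateSegment("chr1", 12_050_000, 30_000_000, 2, 360, 0.98)]
        (call,) = call_crossovers(segs)
        assert call.lo == 11_950_000 and call.hi == 12_050_000
        assert call.midpoint == 12_000_000

    def test_single_segment_no_calls(self):
        segs = [StateSegment("chr1", 0, 30_000_000, 1, 600, 0.5)]
        assert call_crossovers(segs) == []

    def test_breakpoint_recovery_simulation(self, two_founder_panel, two_founder_config):
        # simulated meiotic recombinants: every call within W/2 + s of a true
        # breakpoint, every sample labelled recombinant
        panel, cfg = two_founder_panel, two_founder_config
        markers = two_way_marker_pipeline(panel, "B", exclusion=None)
        positions = markers.positions_frame()
        tol = 1_000_000 // 2 + 50_000
        n_calls = n_good = 0
        for i in range(12):
            rng = rng_from(100 + i, 10)
            s = simulate_sample(panel, "f2", ("A", "B"), f"F2_{i}", cfg, rng)
            res = TransmissionModel(s.counts, positions, panel.layout, ploidy=2).fit()
            assert res.label == "recombinant"
            truth = s.offspring.truth.all_breakpoints()
            for call in res.crossovers:
                n_calls += 1
                d = min(abs(call.midpoint - bp) for c, bp in truth if c == call.chrom)
                n_good += d <= tol
        assert n_calls > 0
        assert n_good / n_calls >= 0.95


class TestAneuploidy:
    def test_and_rule_requires_both_signals(self):
        # AF shifted but coverage normal: no call (e.g. allelic bias)
        prof = synthetic_profile([0.67] * 60, [1.0] * 60)
        assert detect_aneuploidy(prof, 4, PARAMS) == []
        # coverage shifted but AF normal: no call either
        prof = synthetic_profile([0.5] * 60, [0.75] * 60)
        assert detect_aneuploidy(prof, 4, PARAMS) == []

    def test_no_deviation_empty(self):
        prof = synthetic_profile([0.5] * 60, [1.0] * 60)
        assert detect_aneuploidy(prof, 4, PARAMS) == []

    def test_joint_deviation_called_with_direction_and_lost_hap(self):
        af = [0.5] * 30 + [2 / 3] * 30
        cov = [1.0] * 30 + [0.75] * 30
        prof = synthetic_profile(af, cov)
        (seg,) = detect_aneuploidy(prof, 4, PARAMS, haplotype_labels=("A", "B"))
        assert seg.direction == "loss"
        assert seg.inferred_lost_haplotype == "A"  # AF rose: low-allele copy lost
        assert abs(seg.af_shift - 1 / 6) < 1e-9
        assert abs(seg.cov_ratio - 0.75) < 1e-9

    def test_threshold_monotonicity(self, two_founder_panel, two_founder_config):
        panel, cfg = two_founder_panel, two_founder_config
        markers = two_way_marker_pipeline(panel, "B", exclusion=None)
        rng = rng_from(55, 10)
        tr = TruncationSpec(forced=(("chr01", "A", "right", 8_000_000),))
        s = simulate_sample(panel, "clonal_tetraploid", ("A", "B"), "T", cfg, rng,
                            truncation=tr)
        from polyhap.windows import profile_sample
        prof = profile_sample(s.counts, markers.positions_frame(), panel.layout)
        last = None
        for t in [0.02, 0.05, 0.10, 0.14, 0.30]:
            p = InferenceParams(t_af=t, t_cov=t)
            n = len(detect_aneuploidy(prof, 4, p))
            if last is not None:
                assert n <= last
            last = n


class TestSampleClassification:
    def test_clonal_tetraploid_clonal_zero_crossovers(self, two_founder_panel,
                                                      two_founder_config):
        panel, cfg = two_founder_panel, two_founder_config
        markers = two_way_marker_pipeline(panel, "B", exclusion=None)
        rng = rng_from(60, 10)
        s = simulate_sample(panel, "clonal_tetraploid", ("A", "B"), "M1", cfg, rng)
        res = TransmissionModel.from_markers(s.counts, markers, panel.layout,
                                             ploidy=4).fit()
        assert res.label == "clonal"
        assert res.n_crossovers == 0
        assert res.classification.n_aneuploid_segments == 0

    def test_truncated_clonal_is_clonal_plus_anomaly(self, two_founder_panel,
                                                     two_founder_config):
        panel, cfg = two_founder_panel, two_founder_config
        markers = two_way_marker_pipeline(panel, "B", exclusion=None)
        rng = rng_from(61, 10)
        tr = TruncationSpec(forced=(("chr02", "A", "right", 9_000_000),))
        s = simulate_sample(panel, "clonal_tetraploid", ("A", "B"), "M2", cfg, rng,
                            truncation=tr)
        res = TransmissionModel.from_markers(s.counts, markers, panel.layout,
                                             ploidy=4, haplotype_labels=("A", "B")).fit()
        assert res.label == "clonal"
        assert res.n_crossovers == 0
        assert res.classification.n_aneuploid_segments >= 1
        assert res.aneuploidy[0].inferred_lost_haplotype == "A"

    def test_f1_diploid_clonal_pattern(self, two_founder_panel, two_founder_config):
        panel, cfg = two_founder_panel, two_founder_config
        markers = two_way_marker_pipeline(panel, "B", exclusion=None)
        rng = rng_from(62, 10)
        s = simulate_sample(panel, "f1", ("A", "B"), "F1", cfg, rng)
        res = TransmissionModel.from_markers(s.counts, markers, panel.layout,
                                             ploidy=2).fit()
        assert res.label == "clonal"
        assert abs(res.profile.genome_mean_af() - 0.5) < 0.02

    def test_summary_mentions_key_fields(self, two_founder_panel, two_founder_config):
        panel, cfg = two_founder_panel, two_founder_config
        markers = two_way_marker_pipeline(panel, "B", exclusion=None)
        rng = rng_from(63, 10)
        s = simulate_sample(panel, "f1", ("A", "B"), "F1s", cfg, rng)
        res = TransmissionModel.from_markers(s.counts, markers, panel.layout,
                                             ploidy=2).fit()
        text = res.summary()
        for token in ("F1s", "clonal", "crossover", "genome mean AF"):
            assert token in text
        d = res.to_dict()
        assert d["label"] == "clonal" and d["n_crossovers"] == 0


class TestRecoveryRates:
    def test_clonal_recovery_over_many_seeds(self, two_founder_panel, two_founder_config):
        # every clonal tetraploid (no truncation) must come back clonal, 0 CO
        panel, cfg = two_founder_panel, two_founder_config
        markers = two_way_marker_pipeline(panel, "B", exclusion=None)
        positions = markers.positions_frame()
        for i in range(20):
            rng = rng_from(200 + i, 10)
            s = simulate_sample(panel, "clonal_tetraploid", ("A", "B"), f"M{i}",
                                cfg, rng)
            res = TransmissionModel(s.counts, positions, panel.layout, ploidy=4).fit()
            assert res.label == "clonal" and res.n_crossovers == 0

    def test_truncation_sensitivity_and_specificity(self, two_founder_panel,
                                                    two_founder_config):
        # injected >= 3 Mb terminal losses are found; untouched chromosomes clean
        panel, cfg = two_founder_panel, two_founder_config
        markers = two_way_marker_pipeline(panel, "B", exclusion=None)
        positions = markers.positions_frame()
        found = 0
        for i in range(10):
            rng = rng_from(300 + i, 10)
            size = 3_000_000 + 700_000 * i
            tr = TruncationSpec(forced=(("chr01", "A", "right", size),))
            s = simulate_sample(panel, "clonal_tetraploid", ("A", "B"), f"T{i}",
                                cfg, rng, truncation=tr)
            res = TransmissionModel(s.counts, positions, panel.layout, ploidy=4).fit()
            on_target = [a for a in res.aneuploidy if a.chrom == "chr01"]
            off_target = [a for a in res.aneuploidy if a.chrom != "chr01"]
            assert not off_target
            found += bool(on_target)
        assert found >= 10 * 0.95 - 1e-9
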