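"""Synthetic study generator: determinism, planted structure, ground truth."""
import numpy as np
import pytest

from oriskew.ergodic import estimate_loading_rate
from oriskew.intervals import IntervalSet
from oriskew.permtest import count_overlapping, permutation_enrichment
from oriskew.seqprops import base_composition, gc_skew
from oriskew.synthetic import (
    CELL_LINES,
    KO_LINES,
    SyntheticConfig,
    TruthRecord,
    default_gate,
    expected_ergodic,
    generate_annotations,
    generate_flow_sample,
    generate_genome,
    generate_liftover_pairs,
    generate_peaksets,
    generate_timing_track,
    make_layout,
    simulate_origins,
    simulate_study,
)

SMALL = dict(n_chroms=2, chrom_length=200_000, n_core_origins=40,
             n_planted_up=5, n_planted_down=5)


class TestConfigValidation:
    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError, match="mask_fraction"):
            SyntheticConfig(mask_fraction=1.5)

    def test_nonpositive_length(self):
        with pytest.raises(ValueError, match="chrom_length"):
            SyntheticConfig(chrom_length=0)

    def test_planted_exceeding_core(self):
        with pytest.raises(ValueError, match="planted"):
            SyntheticConfig(n_core_origins=10, n_planted_up=8, n_planted_down=8)

    def test_g1_plus_s_must_leave_g2(self):
        with pytest.raises(ValueError):
            SyntheticConfig(g1_fraction=0.6, s_fraction=0.5)

    def test_origin_footprint_exceeding_genome(self):
        cfg = SyntheticConfig(n_chroms=1, chrom_length=1_000, n_core_origins=50,
                              n_planted_up=0, n_planted_down=0)
        with pytest.raises(ValueError, match="footprint|gap"):
            simulate_origins(cfg)


class TestGenome:
    def test_at_only_when_gc_zero(self):
        cfg = SyntheticConfig(seed=3, gc_content_bg=0.0, planted_gc_skew=0.0,
                              planted_repeat_copies=0, **SMALL)
        seqs, layout = generate_genome(cfg)
        comp = base_composition("".join(seqs.values()))
        assert comp["G"] == 0 and comp["C"] == 0
        assert comp["A"] > 0 and comp["T"] > 0

    def test_extreme_skew_window_has_g_but_no_c(self):
        cfg = SyntheticConfig(seed=4, planted_gc_skew=1.0,
                              planted_repeat_copies=0, **SMALL)
        layout = make_layout(cfg)
        truth = simulate_origins(cfg, layout)
        seqs, _ = generate_genome(cfg, truth, layout)
        ups = truth.origins.query("label == 'planted_up'")
        for row in ups.itertuples():
            window = seqs[row.chrom][row.start:row.end]
            comp = base_composition(window)
            assert comp["C"] == 0 and comp["G"] > 0
            assert gc_skew(window) == 1.0

    def test_repeat_planted_at_up_origins(self):
        cfg = SyntheticConfig(seed=5, **SMALL)
        layout = make_layout(cfg)
        truth = simulate_origins(cfg, layout)
        seqs, _ = generate_genome(cfg, truth, layout)
        motif = cfg.planted_repeat * cfg.planted_repeat_copies
        for row in truth.origins.query("label == 'planted_up'").itertuples():
            assert motif in seqs[row.chrom][row.start:row.end]

    def test_fasta_determinism(self):
        cfg = SyntheticConfig(seed=1, **SMALL)
        a, _ = generate_genome(cfg)
        b, _ = generate_genome(cfg)
        assert a == b

    def test_masked_regions_are_n(self):
        cfg = SyntheticConfig(seed=6, **SMALL)
        seqs, layout = generate_genome(cfg)
        iv = layout.masked[0]
        assert set(seqs[iv.chrom][iv.start:iv.end]) == {"N"}


class TestPeaksets:
    def test_conservation_per_line(self):
        cfg = SyntheticConfig(seed=7, **SMALL)
        peaksets, counts, libs, truth = generate_peaksets(cfg)
        n_spec = int(round(cfg.frac_line_specific * cfg.n_core_origins))
        for line in CELL_LINES:
            expected = cfg.n_core_origins if line == "WT" else cfg.n_core_origins
            if line != "WT":
                expected = cfg.n_core_origins - n_spec + n_spec  # losses + gains
            assert len(peaksets[line][0]) == expected
            assert truth.origins[f"in_{line}"].sum() == expected

    def test_every_origin_has_exactly_one_label(self):
        cfg = SyntheticConfig(seed=8, **SMALL)
        truth = simulate_origins(cfg)
        labels = set(truth.origins["label"])
        allowed = {"shared", "planted_up", "planted_down"} | {
            f"specific_{line}" for line in KO_LINES
        }
        assert labels <= allowed

    def test_no_line_specific_no_jitter_identical_sets(self):
        cfg = SyntheticConfig(seed=9, frac_line_specific=0.0,
                              boundary_jitter_sd=0.0, **SMALL)
        peaksets, *_ = generate_peaksets(cfg)
        wt = [(iv.chrom, iv.start, iv.end) for iv in peaksets["WT"][0]]
        for line in CELL_LINES:
            for rep in peaksets[line]:
                assert [(iv.chrom, iv.start, iv.end) for iv in rep] == wt

    def test_zero_jitter_replicate_intersection_recovers_origins(self):
        from oriskew.intervals import intersect_replicates

        cfg = SyntheticConfig(seed=10, boundary_jitter_sd=0.0, **SMALL)
        peaksets, *_, truth = generate_peaksets(cfg)
        wt = peaksets["WT"]
        got = intersect_replicates(wt[0], wt[1])
        expected = truth.origin_set()  # restrict to WT members
        wt_truth = [
            (r.chrom, int(r.start), int(r.end))
            for r in truth.origins.query("in_WT").itertuples()
        ]
        assert [(iv.chrom, iv.start, iv.end) for iv in got] == wt_truth

    def test_planted_counts_scale_with_fold(self):
        cfg = SyntheticConfig(seed=11, reads_per_origin_mean=500, **SMALL)
        _, counts, _, truth = generate_peaksets(cfg)
        up = truth.origins["label"] == "planted_up"
        wt = counts.loc[up.values, ["WT_rep1", "WT_rep2"]].sum(axis=1)
        for ko in KO_LINES:
            koc = counts.loc[up.values, [f"{ko}_rep1", f"{ko}_rep2"]].sum(axis=1)
            assert (koc / wt).median() > 1.5

    def test_truth_round_trips_through_json(self, tmp_path):
        cfg = SyntheticConfig(seed=12, **SMALL)
        truth = simulate_origins(cfg)
        truth.expected_mean_rate = 0.61
        path = tmp_path / "truth.json"
        truth.to_json(path)
        again = TruthRecord.from_json(path)
        assert again.origins.astype(str).equals(truth.origins.astype(str))
        assert again.mcm_load_rate == truth.mcm_load_rate


class TestAnnotations:
    def test_infinite_odds_every_interval_on_origin(self):
        cfg = SyntheticConfig(seed=13, annotation_enrichment=np.inf,
                              n_annotations=100, **SMALL)
        layout = make_layout(cfg)
        origins = simulate_origins(cfg, layout).origin_set()
        track = generate_annotations(cfg, layout, origins)["annotation"]
        assert count_overlapping(track, origins) == len(track)

    def test_empty_origin_set_gives_uniform_background(self, rng):
        cfg = SyntheticConfig(seed=14, n_annotations=100, **SMALL)
        layout = make_layout(cfg)
        track = generate_annotations(cfg, layout, IntervalSet())["annotation"]
        assert len(track) == 100
        for iv in track:
            for m in layout.masked:
                assert not iv.overlaps(m)

    def test_neutral_odds_is_calibrated_null(self):
        # enrichment fold ~ 1 under odds = 1 (single-seed sanity check; the
        # full calibration sweep lives in the acceptance suite)
        cfg = SyntheticConfig(seed=15, annotation_enrichment=1.0, **SMALL)
        layout = make_layout(cfg)
        origins = simulate_origins(cfg, layout).origin_set()
        track = generate_annotations(cfg, layout, origins)["annotation"]
        res = permutation_enrichment(origins, track, layout, n_perm=100, seed=0)
        assert 0.7 < res.fold < 1.3


class TestTimingTrack:
    def test_null_shift_small_ks(self):
        cfg = SyntheticConfig(seed=16, timing_shift=0.0, **SMALL)
        layout = make_layout(cfg)
        origins = simulate_origins(cfg, layout).origin_set()
        track = generate_timing_track(cfg, layout, origins)
        assert len(track) > 0

    def test_shift_recovered_as_wasserstein(self):
        from oriskew.timing import assign_origin_timing, compare_timing

        shift = 1.5
        cfg = SyntheticConfig(seed=17, timing_shift=shift, n_chroms=4,
                              chrom_length=500_000, n_core_origins=150,
                              n_planted_up=0, n_planted_down=0,
                              probe_spacing=2_000)
        layout = make_layout(cfg)
        origins = simulate_origins(cfg, layout).origin_set()
        track = generate_timing_track(cfg, layout, origins)
        ori_vals = assign_origin_timing(origins, track)
        probes = track.probes
        hit = np.zeros(len(probes), dtype=bool)
        omap = origins.by_chrom()
        for i, row in enumerate(probes.itertuples()):
            if row.chrom in omap:
                s, e = omap[row.chrom]
                hit[i] = bool(((s < row.end) & (e > row.start)).any())
        bg_vals = probes.loc[~hit, "value"].to_numpy()
        res = compare_timing(ori_vals, bg_vals)
        assert res.wasserstein == pytest.approx(shift, rel=0.25)

    def test_empty_probe_grid_errors(self):
        cfg = SyntheticConfig(seed=18, **SMALL)
        layout = make_layout(SyntheticConfig(seed=18, **SMALL))
        layout.chrom_sizes = {"chrSim1": 100}  # shorter than probe spacing
        layout.masked = IntervalSet()
        with pytest.raises(ValueError, match="probe"):
            generate_timing_track(cfg, layout, IntervalSet())

    def test_liftover_pairs_mix_good_and_bad(self):
        from oriskew.timing import filter_size_change

        cfg = SyntheticConfig(seed=19, **SMALL)
        origins = simulate_origins(cfg).origin_set()
        pairs = generate_liftover_pairs(cfg, origins, frac_bad=0.3)
        kept = sum(filter_size_change(o, l) for o, l in pairs)
        assert 0 < kept < len(pairs)


class TestFlowSample:
    def test_determinism(self):
        cfg = SyntheticConfig(seed=20, n_events=5_000)
        a, b = generate_flow_sample(cfg), generate_flow_sample(cfg)
        np.testing.assert_array_equal(a.mcm, b.mcm)
        np.testing.assert_array_equal(a.dapi, b.dapi)

    def test_zero_rate_estimates_zero(self):
        cfg = SyntheticConfig(seed=21, mcm_load_rate=0.0, n_events=20_000)
        flow = generate_flow_sample(cfg)
        res = estimate_loading_rate(flow, default_gate(cfg))
        assert res.mean_rate == 0.0

    def test_invalid_g1_fraction(self):
        with pytest.raises(ValueError):
            SyntheticConfig(g1_fraction=0.0)

    def test_age_distribution_matches_exponential_growth(self):
        cfg = SyntheticConfig(seed=22, n_events=100_000, dapi_cv=0.0)
        flow = generate_flow_sample(cfg)
        # noise-free DAPI is exactly 4N only in G2: P(age >= (g1+s) T) under
        # the steady-state density equals 2(2^-(g1+s) - 1/2)
        g1, s = cfg.g1_fraction, cfg.s_fraction
        frac_g2_expected = 2 * (2 ** (-(g1 + s)) - 0.5)
        frac_g2 = np.mean(flow.dapi == 2 * cfg.dapi_g1)
        assert frac_g2 == pytest.approx(frac_g2_expected, abs=0.01)

    def test_estimator_matches_analytic_truth(self):
        cfg = SyntheticConfig(seed=23, n_events=50_000)
        flow = generate_flow_sample(cfg)
        gate = default_gate(cfg)
        est = estimate_loading_rate(flow, gate).mean_rate
        truth = expected_ergodic(cfg, gate).mean_rate
        assert est == pytest.approx(truth, rel=0.15)


class TestStudyBundle:
    def test_simulate_study_deterministic_and_complete(self):
        cfg = SyntheticConfig(seed=24, **SMALL, n_events=2_000)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        assert a.sequences == b.sequences
        assert a.counts.equals(b.counts)
        assert set(a.peaksets) == set(CELL_LINES)
        assert a.truth.expected_mean_rate is not None

    def test_write_study_round_trip(self, tmp_path):
        from oriskew.intervals import read_bed, read_chrom_sizes
        from oriskew.synthetic import write_study

        cfg = SyntheticConfig(seed=25, **SMALL, n_events=1_000)
        study = simulate_study(cfg)
        write_study(study, tmp_path)
        sizes = read_chrom_sizes(tmp_path / "genome.chrom.sizes")
        assert sizes == study.layout.chrom_sizes
        wt = read_bed(tmp_path / "peaks_WT_rep1.bed")
        assert len(wt) == len(study.peaksets["WT"][0])
        again = TruthRecord.from_json(tmp_path / "truth.json")
        assert len(again.origins) == len(study.truth.origins)
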