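import numpy as np
import pytest

from longamp.io_formats import AlignmentRecord, SequenceRecord
from longamp.profiler import (
    Event,
    classify_events,
    gc_bias,
    position_slope,
    profile,
    read_length_stats,
)
from longamp.simulate import SimConfig, make_panel, simulate_reads, truth_to_alignment


def counts_of(events):
    out = {e: 0 for e in Event}
    for ev in events:
        out[ev.event] += 1
    return out


class TestClassifyEvents:
    def test_single_mismatch(self):
        ref = "ACGTACGTAC"
        read = "ACGTCCGTAC"
        aln = AlignmentRecord("r", "c", 0, False, [("M", 10)], read)
        c = counts_of(classify_events(aln, ref))
        assert c[Event.MATCH] == 9 and c[Event.MISMATCH] == 1
        assert c[Event.INSERTION] == c[Event.DELETION] == 0

    def test_cigar_arithmetic(self):
        # 4M 2I 4M 1D 2M over matching sequence
        ref = "ACGTACGTACGTA"
        read = ref[:4] + "TT" + ref[4:8] + ref[9:11]
        aln = AlignmentRecord(
            "r", "c", 0, False, [("M", 4), ("I", 2), ("M", 4), ("D", 1), ("M", 2)], read
        )
        c = counts_of(classify_events(aln, ref))
        assert c[Event.INSERTION] == 2 and c[Event.DELETION] == 1

    def test_reverse_strand_cycles_reindexed(self):
        ref = "ACGTACGTAC"
        aln = AlignmentRecord("r", "c", 0, True, [("M", 10)], ref)
        cycles = [ev.cycle for ev in classify_events(aln, ref)]
        assert cycles == list(range(9, -1, -1))

    def test_truth_walk_equals_classification(self, study_sim):
        cfg, panel, sample, truth, reads, truths = study_sim
        refs = {a.name: a.bases for a in panel.amplicons}
        for t, r in zip(truths[:150], reads[:150]):
            aln = truth_to_alignment(t, r)
            c = counts_of(classify_events(aln, refs[t.amplicon]))
            assert c[Event.INSERTION] == t.events.count("I")
            assert c[Event.DELETION] == t.events.count("D")
            # mismatches vs reference can exceed the walk's X count only at
            # planted het positions carried by the source haplotype
            assert c[Event.MISMATCH] >= 0


class TestProfile:
    def test_study_rates_recovered_through_alignment(self, study_alignments):
        alignments, _, _, refs = study_alignments
        prof = profile(alignments, refs)
        assert prof.n_aligned_bases >= 100_000
        assert 100 * prof.rates["insertion"] == pytest.approx(12.0, abs=0.5)
        assert 100 * prof.rates["deletion"] == pytest.approx(2.0, abs=0.5)
        assert 100 * prof.rates["mismatch"] == pytest.approx(1.0, abs=0.5)

    def test_error_free_rates_zero(self):
        cfg = SimConfig(seed=6, p_ins=0, p_del=0, p_mis=0, depth=3, n_true_sites=0, n_artifact_sites=0)
        panel, sample, _ = make_panel(cfg, n_amplicons=1)
        reads, truths = simulate_reads(panel, sample, cfg)
        refs = {a.name: a.bases for a in panel.amplicons}
        prof = profile([truth_to_alignment(t, r) for t, r in zip(truths, reads)], refs)
        assert prof.total_rate == 0.0

    def test_per_position_sums_match_aggregates(self, study_alignments):
        alignments, _, _, refs = study_alignments
        prof = profile(alignments, refs, max_position=10_000)
        assert prof.per_position["events"].sum() == sum(prof.counts.values())
        obs = prof.per_position["observations"].to_numpy()
        assert (np.diff(obs) <= 0).all()  # non-increasing in position

    def test_known_site_exclusion_switch(self, study_sim, study_alignments):
        cfg, panel, sample, truth, reads, truths = study_sim
        alignments, _, _, refs = study_alignments
        known = {}
        for v in truth:
            known.setdefault(v.contig, set()).add(v.pos)
        incl = profile(alignments, refs)
        excl = profile(alignments, refs, known_sites=known, exclude_known=True)
        # het alleles look like mismatches when included
        assert excl.counts["mismatch"] < incl.counts["mismatch"]

    def test_no_alignments_rejected(self):
        with pytest.raises(ValueError):
            profile([], {})


class TestReadLengthStats:
    def test_constant_lengths(self):
        reads = [SequenceRecord(f"r{i}", "A" * 700, None) for i in range(3)]
        st = read_length_stats(reads)
        assert st.mean == 700 and st.frac_gt_2500 == 0.0

    def test_threshold_is_strict(self):
        assert read_length_stats([SequenceRecord("r", "A" * 2501)]).frac_gt_2500 == 1.0
        assert read_length_stats([SequenceRecord("r", "A" * 2500)]).frac_gt_2500 == 0.0

    def test_default_config_targets_recovered(self):
        # long contig so fragment truncation is negligible; n ~ 1e4 reads
        cfg = SimConfig(seed=33, depth=42, n_true_sites=0, n_artifact_sites=0)
        panel, sample, _ = make_panel(cfg, n_amplicons=1, amplicon_len=150_000)
        reads, _ = simulate_reads(panel, sample, cfg)
        assert len(reads) >= 10_000
        st = read_length_stats(reads)
        assert st.mean == pytest.approx(700, rel=0.05)
        assert st.frac_gt_2500 == pytest.approx(0.05, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            read_length_stats([])


class TestGCBias:
    def _uniform_panel(self, seed=0, n=60_000):
        rng = np.random.default_rng(seed)
        bases = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        return {"g": bases}

    def _tiled_alignments(self, refs, step=50, read_len=200):
        alns = []
        for name, seq in refs.items():
            for s in range(0, len(seq) - read_len, step):
                alns.append(
                    AlignmentRecord(
                        f"{name}_{s}", name, s, False, [("M", read_len)], seq[s : s + read_len]
                    )
                )
        return alns

    def test_uniform_coverage_flat_curve(self):
        refs = self._uniform_panel()
        curve = gc_bias(self._tiled_alignments(refs), refs)
        populated = curve.bins[(curve.bins.n_windows >= 5)]
        inner = populated[
            (populated.gc_low > 0.25) & (populated.gc_high < 0.75)
        ]
        assert (abs(inner.relative_coverage - 1.0) < 0.05).all()

    def test_constructed_bias_recovered(self):
        refs = self._uniform_panel(seed=1)
        seq = refs["g"]

        def win_gc(w):
            block = seq[w * 100 : (w + 1) * 100]
            return (block.count("G") + block.count("C")) / 100

        # window-aligned reads, 10 per window; keep 5 where GC > 0.6
        alns = []
        for w in range(len(seq) // 100):
            copies = 5 if win_gc(w) > 0.6 else 10
            for c in range(copies):
                alns.append(
                    AlignmentRecord(
                        f"w{w}_{c}", "g", w * 100, False, [("M", 100)], seq[w * 100 : w * 100 + 100]
                    )
                )
        curve = gc_bias(alns, refs)
        high = curve.bins[(curve.bins.gc_low >= 0.6) & (curve.bins.n_windows >= 5)]
        low = curve.bins[(curve.bins.gc_high <= 0.6) & (curve.bins.n_windows >= 5)]
        assert len(high) > 0
        ratio = high.mean_coverage.mean() / low.mean_coverage.mean()
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_weighted_mean_is_one(self, study_alignments):
        alignments, _, _, refs = study_alignments
        curve = gc_bias(alignments, refs)
        assert curve.weighted_mean_relative() == pytest.approx(1.0, abs=1e-9)

    def test_empty_bin_flagged(self):
        refs = {"g": "AT" * 200}  # all windows GC ~ 0
        curve = gc_bias(self._tiled_alignments(refs, step=100, read_len=100), refs)
        zero = curve.bins[curve.bins.n_windows == 0]
        assert (zero.relative_coverage == 0).all() and zero.low_confidence.all()

    def test_window_larger_than_contig_rejected(self):
        with pytest.raises(ValueError):
            gc_bias([], {"g": "ACGT" * 10}, window_size=1000)


class TestPositionSlope:
    def test_flat_on_study_data(self, study_alignments):
        alignments, _, true_alns, refs = study_alignments
        prof = profile(true_alns, refs, max_position=4000)
        assert abs(position_slope(prof)) < 2e-5
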