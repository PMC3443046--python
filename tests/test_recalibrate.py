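import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longamp.io_formats import AlignmentRecord, SequenceRecord
from longamp.recalibrate import (
    build_table,
    empirical_quality,
    recalibrate_alignment,
    recalibrate_read,
)


def make_reads_with_mismatch_rate(
    rng, ref, n_reads, rate_fn, quality=20, reverse_every=0
):
    """Identity-aligned reads over ``ref`` with per-cycle mismatch rate rate_fn."""
    from longamp.io_formats import reverse_complement

    L = len(ref)
    alns = []
    for r in range(n_reads):
        bases = list(ref)
        for i in range(L):
            if rng.random() < rate_fn(i):
                bases[i] = "ACGT"[("ACGT".index(bases[i]) + 1 + rng.integers(3)) % 4]
        is_rev = reverse_every and r % reverse_every == 0
        seq = "".join(bases)
        alns.append(
            AlignmentRecord(
                f"r{r}", "c", 0, bool(is_rev), [("M", L)], seq, [quality] * L
            )
        )
    return alns


class TestEmpiricalQuality:
    @pytest.mark.parametrize(
        "n,m,expect",
        [
            (98, 0, -10 * math.log10(1 / 100)),  # = 20.0 by the closed form
            (998, 9, 20.0),
            (0, 0, -10 * math.log10(0.5)),  # ~3.01, uninformative
        ],
    )
    def test_closed_form(self, n, m, expect):
        assert empirical_quality(n, m) == pytest.approx(expect, abs=1e-9)

    def test_cap_at_60(self):
        assert empirical_quality(10**8, 0) == 60.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=10_000), st.data())
    def test_monotone_in_mismatches(self, n, data):
        m = data.draw(st.integers(min_value=0, max_value=n - 1))
        assert empirical_quality(n, m + 1) <= empirical_quality(n, m)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            empirical_quality(5, 6)


class TestBuildTable:
    def test_read_group_quality_near_q20_at_one_percent(self):
        rng = np.random.default_rng(0)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        alns = make_reads_with_mismatch_rate(rng, ref, 300, lambda i: 0.01)
        table = build_table(alns, {"c": ref})
        n, m = table.read_group["RG1"]
        assert n == 150_000
        assert empirical_quality(n, m) == pytest.approx(20.0, abs=0.5)

    def test_error_free_hits_cap(self):
        rng = np.random.default_rng(1)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        alns = make_reads_with_mismatch_rate(rng, ref, 50, lambda i: 0.0)
        table = build_table(alns, {"c": ref})
        n, m = table.read_group["RG1"]
        assert m == 0 and empirical_quality(n, m) > 40

    def test_known_site_exclusion(self):
        # a planted het-like site must not shift the empirical quality
        rng = np.random.default_rng(2)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        alns = make_reads_with_mismatch_rate(rng, ref, 100, lambda i: 0.0)
        # half the reads carry an alt at position 150
        for a in alns[:50]:
            b = list(a.bases)
            b[150] = "ACGT"[("ACGT".index(b[150]) + 1) % 4]
            a.bases = "".join(b)
        with_site = build_table(alns, {"c": ref})
        without = build_table(alns, {"c": ref}, known_sites={"c": {150}})
        assert with_site.read_group["RG1"][1] == 50
        assert without.read_group["RG1"][1] == 0
        assert without.read_group["RG1"][0] == with_site.read_group["RG1"][0] - 100

    def test_child_counts_sum_to_parent(self):
        rng = np.random.default_rng(3)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        alns = make_reads_with_mismatch_rate(rng, ref, 40, lambda i: 0.02, reverse_every=3)
        table = build_table(alns, {"c": ref})
        rg_n, rg_m = table.read_group["RG1"]
        for child in (table.quality, table.cycle, table.dinucleotide):
            assert sum(v[0] for v in child.values()) == rg_n
            assert sum(v[1] for v in child.values()) == rg_m

    def test_indels_excluded_from_counts(self):
        ref = "ACGTACGTACGT"
        aln = AlignmentRecord(
            "r", "c", 0, False, [("M", 4), ("I", 3), ("M", 4), ("D", 2), ("M", 2)],
            ref[:4] + "TTT" + ref[4:8] + ref[10:12], [20] * 13,
        )
        table = build_table([aln], {"c": ref})
        assert table.read_group["RG1"] == [10, 0]


class TestRecalibrateRead:
    def test_covariate_free_data_collapses_to_read_group_quality(self):
        rng = np.random.default_rng(4)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        alns = make_reads_with_mismatch_rate(rng, ref, 400, lambda i: 0.01)
        table = build_table(alns, {"c": ref})
        n, m = table.read_group["RG1"]
        q_rg = empirical_quality(n, m)
        rec = recalibrate_read(SequenceRecord("r", ref, [20] * len(ref)), table)
        assert abs(np.mean(rec.qualities) - q_rg) <= 1.0

    def test_late_cycle_doubled_error_gives_three_point_delta(self):
        rng = np.random.default_rng(5)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        alns = make_reads_with_mismatch_rate(
            rng, ref, 600, lambda i: 0.01 if i < 500 else 0.02
        )
        table = build_table(alns, {"c": ref})
        rec = recalibrate_alignment(alns[0], table)
        early = np.mean(rec.qualities[:500])
        late = np.mean(rec.qualities[500:])
        assert early - late == pytest.approx(10 * math.log10(2), abs=1.0)

    def test_sparse_bin_falls_back_to_parent(self):
        rng = np.random.default_rng(6)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        alns = make_reads_with_mismatch_rate(rng, ref, 4, lambda i: 0.0)  # 200 obs total
        table = build_table(alns, {"c": ref})
        n, m = table.read_group["RG1"]
        q_rg = round(empirical_quality(n, m))
        rec = recalibrate_read(SequenceRecord("r", ref, [20] * 50), table, min_obs=100)
        # per-cycle bins hold only 4 observations each -> all deltas vanish
        assert set(rec.qualities) == {min(60, max(2, q_rg))}

    def test_clamped_to_valid_range(self):
        rng = np.random.default_rng(7)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        alns = make_reads_with_mismatch_rate(rng, ref, 100, lambda i: 0.9)
        table = build_table(alns, {"c": ref})
        rec = recalibrate_read(SequenceRecord("r", ref, [20] * 100), table)
        assert min(rec.qualities) >= 2 and max(rec.qualities) <= 60


class TestCalibrationProperty:
    def test_recalibrated_quality_matches_observed_error(self):
        """For well-populated quality values, |Q - (-10 log10 r)| <= 1.

        Reads start at random offsets so the cycle and dinucleotide
        covariates decorrelate, as they do for real panel data.
        """
        rng = np.random.default_rng(8)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        L = 100
        alns = []
        for r in range(5000):
            s = int(rng.integers(0, len(ref) - L))
            bases = list(ref[s : s + L])
            for i in range(L):
                if rng.random() < 0.01:
                    bases[i] = "ACGT"[("ACGT".index(bases[i]) + 1 + rng.integers(3)) % 4]
            alns.append(
                AlignmentRecord(f"r{r}", "c", s, False, [("M", L)], "".join(bases), [20] * L)
            )
        table = build_table(alns, {"c": ref})
        recal = [recalibrate_alignment(a, table) for a in alns[:3000]]
        by_q: dict[int, list[int]] = {}
        for a in recal:
            for i, q in enumerate(a.qualities):
                by_q.setdefault(q, []).append(int(a.bases[i] != ref[a.start + i]))
        checked = 0
        for q, flags in by_q.items():
            if len(flags) >= 10_000:
                checked += 1
                r = np.mean(flags)
                assert abs(-10 * math.log10(r) - q) <= 1.0
        assert checked >= 1

    def test_fixed_point_on_covariate_free_data(self):
        rng = np.random.default_rng(9)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        alns = make_reads_with_mismatch_rate(rng, ref, 300, lambda i: 0.01)
        table1 = build_table(alns, {"c": ref})
        recal = [recalibrate_alignment(a, table1) for a in alns]
        table2 = build_table(recal, {"c": ref})
        q1 = empirical_quality(*table1.read_group["RG1"])
        q2 = empirical_quality(*table2.read_group["RG1"])
        assert abs(q1 - q2) <= 1.0
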