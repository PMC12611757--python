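"""Stripe caller, repeat overlap and read-support scoring against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecdnakit import DataError
from ecdnakit import synthetic_data as sd
from ecdnakit.eie_discovery import (
    ContactMatrix,
    call_trans_stripes,
    ecdna_support_counts,
    genome_class_fraction,
    merge_intervals,
    overlap_fractions,
    stripe_bin_stats,
)

AMP = [("chr8", 0, 5000)]  # 5 bins of 1 kb


def _cm(pairs):
    return ContactMatrix(
        bin_size=1000,
        pairs=pd.DataFrame(pairs, columns=["chrom1", "start1", "chrom2", "start2", "count"]),
    )


def _background(chrom="chr3", n_bins=40, count=2):
    """Flat trans background so the per-chromosome median is well defined."""
    return [
        ("chr8", a, chrom, b * 1000, count) for a in range(0, 5000, 1000) for b in range(n_bins)
    ]


class TestContactMatrix:
    def test_orientation_canonicalized(self):
        cm = _cm([("chr8", 0, "chr3", 2000, 5), ("chr3", 1000, "chr8", 0, 4)])
        assert (cm.pairs["chrom1"] == "chr3").all()

    def test_conflicting_mirror_counts_rejected(self):
        with pytest.raises(DataError):
            _cm([("chr8", 0, "chr3", 2000, 5), ("chr3", 2000, "chr8", 0, 4)])

    def test_offgrid_start_rejected(self):
        with pytest.raises(DataError):
            _cm([("chr8", 500, "chr3", 0, 1)])


class TestStripeCaller:
    def test_full_stripe_called_with_unit_coverage(self):
        pairs = _background() + [("chr8", a, "chr3", 100_000, 30) for a in range(0, 5000, 1000)]
        calls = call_trans_stripes(_cm(pairs), AMP)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert row["coverage_fraction"] == 1.0
        assert (row["chrom"], row["start"], row["end"]) == ("chr3", 100_000, 101_000)

    def test_zero_contact_bin_not_called(self):
        calls = call_trans_stripes(_cm(_background(count=1)), AMP, min_enrichment=3.0)
        assert len(calls) == 0

    def test_empty_amplicon_rejected(self):
        with pytest.raises(DataError):
            call_trans_stripes(_cm(_background()), [])

    def test_storage_order_and_zero_bins_do_not_change_calls(self):
        pairs = _background() + [("chr8", a, "chr3", 50_000, 40) for a in range(0, 5000, 1000)]
        base = call_trans_stripes(_cm(pairs), AMP)
        rng = np.random.default_rng(0)
        shuffled = [pairs[i] for i in rng.permutation(len(pairs))]
        # flip orientation of half the stored pairs and append zero-count bins
        shuffled = [
            (c2, s2, c1, s1, n) if i % 2 else (c1, s1, c2, s2, n)
            for i, (c1, s1, c2, s2, n) in enumerate(shuffled)
        ]
        shuffled += [("chr8", 0, "chr3", 90_000 + 1000 * i, 0) for i in range(10)]
        again = call_trans_stripes(_cm(shuffled), AMP)
        pd.testing.assert_frame_equal(base, again)

    def test_adjacent_passing_bins_merge_to_anchor(self):
        # bin 2000 contacts 3/5 amplicon bins, bin 3000 contacts all 5
        stripe = [("chr8", a, "chr3", 50_000, 25) for a in (0, 1000, 2000)] + [
            ("chr8", a, "chr3", 51_000, 40) for a in range(0, 5000, 1000)
        ]
        calls = call_trans_stripes(_cm(_background() + stripe), AMP)
        assert len(calls) == 1
        assert calls.iloc[0]["n_bins"] == 2
        assert calls.iloc[0]["start"] == 51_000  # higher-coverage bin anchors
        assert calls.iloc[0]["run_start"] == 50_000

    def test_planted_stripes_recovered_exactly(self, genome_bundle):
        amp = [tuple(r) for r in genome_bundle["ecdna"].itertuples(index=False, name=None)]
        calls = call_trans_stripes(genome_bundle["contacts"], amp)
        got = set(zip(calls["chrom"], calls["start"]))
        want = set(zip(genome_bundle["eie_truth"]["chrom"], genome_bundle["eie_truth"]["start"]))
        assert got == want

    def test_detection_improves_with_contrast(self):
        """Separation between planted and background bins (rank AUC of the
        enrichment score) grows monotonically with stripe/background ratio."""
        aucs = []
        for rate in (2.0, 5.0, 20.0):
            bundle = sd.simulate_genome_and_contacts(
                sd.GenomeSimConfig(stripe_contact_rate=rate, seed=21)
            )
            amp = [tuple(r) for r in bundle["ecdna"].itertuples(index=False, name=None)]
            scored = stripe_bin_stats(bundle["contacts"], amp)
            truth = set(zip(bundle["eie_truth"]["chrom"], bundle["eie_truth"]["start"]))
            is_pos = np.array([(c, s) in truth for c, s in zip(scored["chrom"], scored["start"])])
            score = scored["enrichment"].to_numpy()
            pos, neg = score[is_pos], score[~is_pos]
            auc = (pos[:, None] > neg[None, :]).mean()
            aucs.append(auc)
        assert aucs[0] <= aucs[1] <= aucs[2]
        assert aucs[2] == 1.0


def brute_force_class_fraction(intervals, start, end):
    """Per-base boolean mask oracle."""
    mask = np.zeros(end - start, dtype=bool)
    for s, e in intervals:
        lo, hi = max(s, start), min(e, end)
        if hi > lo:
            mask[lo - start : hi - start] = True
    return mask.mean()


interval_list = st.lists(
    st.tuples(st.integers(0, 950), st.integers(1, 80)).map(lambda t: (t[0], t[0] + t[1])),
    max_size=12,
)


class TestOverlapFractions:
    def test_simple_cases(self):
        eies = pd.DataFrame([("chr1", 0, 1000)], columns=["chrom", "start", "end"])
        rep = pd.DataFrame(
            [("chr1", 0, 1000, "LINE/L1")], columns=["chrom", "start", "end", "name"]
        )
        out = overlap_fractions(eies, rep)
        assert out.loc[0, "LINE"] == 1.0 and out.loc[0, "SINE"] == 0.0 and out.loc[0, "LTR"] == 0.0

    def test_overlapping_annotations_merged_before_counting(self):
        eies = pd.DataFrame([("chr1", 0, 1000)], columns=["chrom", "start", "end"])
        rep = pd.DataFrame(
            [("chr1", 0, 300, "LINE/L1"), ("chr1", 200, 600, "LINE/L2")],
            columns=["chrom", "start", "end", "name"],
        )
        assert overlap_fractions(eies, rep).loc[0, "LINE"] == pytest.approx(0.6)

    def test_zero_length_interval_rejected(self):
        eies = pd.DataFrame([("chr1", 5, 5)], columns=["chrom", "start", "end"])
        with pytest.raises(DataError):
            overlap_fractions(eies, pd.DataFrame(columns=["chrom", "start", "end", "name"]))

    @settings(max_examples=40, deadline=None)
    @given(lines=interval_list, sines=interval_list)
    def test_matches_per_base_mask_oracle(self, lines, sines):
        eies = pd.DataFrame([("c", 0, 1000)], columns=["chrom", "start", "end"])
        rep = pd.DataFrame(
            [("c", s, e, "LINE/L1") for s, e in lines]
            + [("c", s, e, "SINE/Alu") for s, e in sines],
            columns=["chrom", "start", "end", "name"],
        )
        out = overlap_fractions(eies, rep)
        assert out.loc[0, "LINE"] == pytest.approx(brute_force_class_fraction(lines, 0, 1000))
        assert out.loc[0, "SINE"] == pytest.approx(brute_force_class_fraction(sines, 0, 1000))

    @settings(max_examples=25, deadline=None)
    @given(lines=interval_list, extra=interval_list)
    def test_monotone_under_added_annotation(self, lines, extra):
        eies = pd.DataFrame([("c", 0, 1000)], columns=["chrom", "start", "end"])
        mk = lambda iv: pd.DataFrame(
            [("c", s, e, "LINE/L1") for s, e in iv], columns=["chrom", "start", "end", "name"]
        )
        before = overlap_fractions(eies, mk(lines)).loc[0, "LINE"]
        after = overlap_fractions(eies, mk(lines + extra)).loc[0, "LINE"]
        assert after >= before - 1e-12

    def test_disjoint_class_fractions_sum_below_one(self, genome_bundle):
        truth = genome_bundle["eie_truth"][["chrom", "start", "end"]]
        out = overlap_fractions(truth, genome_bundle["repeats"])
        assert ((out[["LINE", "SINE", "LTR"]].sum(axis=1)) <= 1.0 + 1e-12).all()


class TestGenomeClassFraction:
    def test_half_genome_single_class(self):
        rep = pd.DataFrame(
            [("c1", 0, 1_000_000, "LINE/L1")], columns=["chrom", "start", "end", "name"]
        )
        out = genome_class_fraction(rep, {"c1": 1_000_000, "c2": 1_000_000})
        assert out["LINE"] == 0.5 and out["SINE"] == 0.0

    def test_empty_annotation_all_zero(self):
        rep = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        assert set(genome_class_fraction(rep, {"c": 100}).values()) == {0.0}

    def test_interval_beyond_chromosome_rejected(self):
        rep = pd.DataFrame([("c", 50, 200, "LINE/L1")], columns=["chrom", "start", "end", "name"])
        with pytest.raises(DataError):
            genome_class_fraction(rep, {"c": 100})

    @settings(max_examples=30, deadline=None)
    @given(lines=interval_list)
    def test_matches_mask_oracle(self, lines):
        rep = pd.DataFrame(
            [("c", s, e, "LINE/L1") for s, e in lines], columns=["chrom", "start", "end", "name"]
        )
        out = genome_class_fraction(rep, {"c": 2000})
        assert out["LINE"] == pytest.approx(brute_force_class_fraction(lines, 0, 2000))


class TestMergeIntervals:
    @settings(max_examples=40, deadline=None)
    @given(iv=interval_list)
    def test_merge_is_disjoint_and_covers_same_bases(self, iv):
        s, e = merge_intervals([a for a, _ in iv], [b for _, b in iv])
        assert (s[1:] > e[:-1]).all() if len(s) > 1 else True
        mask = np.zeros(1100, dtype=bool)
        for a, b in iv:
            mask[a:b] = True
        assert int((e - s).sum()) == int(mask.sum())


class TestSupportCounts:
    EIES = pd.DataFrame([("chr3", 100, 200), ("chr3", 500, 600)], columns=["chrom", "start", "end"])
    EC = pd.DataFrame([("chr8", 0, 10_000)], columns=["chrom", "start", "end"])

    def test_no_reads(self):
        reads = pd.DataFrame(columns=["read_id", "chrom", "start", "end"])
        out = ecdna_support_counts(reads, self.EIES, self.EC)
        assert (out["raw_count"] == 0).all() and (out["log10_count"] == 0.0).all()

    def test_nine_reads_give_log_one(self):
        rows = []
        for i in range(9):
            rows += [(f"r{i}", "chr3", 150, 160), (f"r{i}", "chr8", 100, 200)]
        out = ecdna_support_counts(
            pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end"]), self.EIES, self.EC
        )
        assert out.loc[0, "raw_count"] == 9
        assert out.loc[0, "log10_count"] == pytest.approx(1.0)
        assert out.loc[1, "raw_count"] == 0

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_matches_set_intersection_oracle(self, data):
        n_reads = data.draw(st.integers(1, 25))
        rows = []
        for i in range(n_reads):
            for _ in range(data.draw(st.integers(1, 3))):
                chrom = data.draw(st.sampled_from(["chr3", "chr8"]))
                s = data.draw(st.integers(0, 900))
                rows.append((f"r{i}", chrom, s, s + data.draw(st.integers(1, 150))))
        reads = pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end"])
        ec = pd.DataFrame([("chr8", 200, 700)], columns=["chrom", "start", "end"])
        eies = pd.DataFrame([("chr3", 300, 400)], columns=["chrom", "start", "end"])
        out = ecdna_support_counts(reads, eies, ec)

        def hits(chrom, lo, hi):
            return {
                r for r, c, s, e in reads.itertuples(index=False) if c == chrom and s < hi and lo < e
            }

        want = len(hits("chr3", 300, 400) & hits("chr8", 200, 700))
        assert out.loc[0, "raw_count"] == want
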