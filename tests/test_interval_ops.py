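"""Interval-kernel tests against hand computations and O(n^2) oracles."""

import numpy as np
import pandas as pd
import pytest

from statepipe import interval_ops as iv


def make_peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def random_peakset(rng, n, chrom_len=1_000_000, n_chroms=2, max_len=5_000):
    chroms = [f"c{j}" for j in rng.integers(1, n_chroms + 1, n)]
    starts = rng.integers(0, chrom_len - max_len, n)
    lengths = rng.integers(1, max_len, n)
    return make_peaks(
        {"chrom": chroms, "start": starts, "end": starts + lengths}
    ).sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------- brute-force oracles

def merge_oracle(peaks):
    """Quadratic union-of-intervals merge."""
    rows = sorted(peaks[["chrom", "start", "end"]].itertuples(index=False))
    out = []
    for chrom, start, end in rows:
        for reg in out:
            if reg[0] == chrom and start <= reg[2] and end >= reg[1]:
                reg[1], reg[2] = min(reg[1], start), max(reg[2], end)
                break
        else:
            out.append([chrom, start, end])
    # repeated passes until stable (chains of overlaps)
    changed = True
    while changed:
        changed = False
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                a, b = out[i], out[j]
                if a and b and a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]:
                    a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                    out[j] = None
                    changed = True
        out = [r for r in out if r]
    return sorted(map(tuple, out))


def reciprocal_oracle(set_a, set_b, min_frac, either):
    """All-pairs qualification check."""
    mask = np.zeros(len(set_a), dtype=bool)
    for i, a in enumerate(set_a.itertuples(index=False)):
        for b in set_b.itertuples(index=False):
            if a.chrom != b.chrom:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov <= 0:
                continue
            fa = ov / (a.end - a.start)
            fb = ov / (b.end - b.start)
            ok = (fa >= min_frac or fb >= min_frac) if either else (
                fa >= min_frac and fb >= min_frac
            )
            if ok:
                mask[i] = True
                break
    return mask


# ---------------------------------------------------------------------------- merge

class TestMerge:
    def test_overlapping_intervals_merge(self):
        peaks = make_peaks([("c1", 100, 200), ("c1", 150, 300)])
        out = iv.merge_overlapping(peaks)
        assert out[["chrom", "start", "end"]].values.tolist() == [["c1", 100, 300]]

    def test_book_ended_intervals_merge(self):
        peaks = make_peaks([("c1", 100, 200), ("c1", 200, 300)])
        out = iv.merge_overlapping(peaks)
        assert out[["start", "end"]].values.tolist() == [[100, 300]]

    def test_disjoint_intervals_unchanged(self):
        peaks = make_peaks([("c1", 0, 10), ("c1", 20, 30)])
        out = iv.merge_overlapping(peaks)
        assert out[["start", "end"]].values.tolist() == [[0, 10], [20, 30]]

    def test_merge_is_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(7)
        peaks = random_peakset(rng, 200)
        once = iv.merge_overlapping(peaks)
        twice = iv.merge_overlapping(once)
        pd.testing.assert_frame_equal(
            once[["chrom", "start", "end"]], twice[["chrom", "start", "end"]]
        )
        shuffled = peaks.sample(frac=1.0, random_state=1).reset_index(drop=True)
        again = iv.merge_overlapping(shuffled)
        pd.testing.assert_frame_equal(
            once[["chrom", "start", "end"]], again[["chrom", "start", "end"]]
        )

    def test_merge_conserves_covered_bases(self):
        rng = np.random.default_rng(11)
        peaks = random_peakset(rng, 300)
        merged = iv.merge_overlapping(peaks)
        covered = set()
        for row in peaks.itertuples(index=False):
            covered.update((row.chrom, p) for p in range(row.start, row.end, 97))
        for chrom, pos in covered:
            sub = merged[merged["chrom"] == chrom]
            assert ((sub["start"] <= pos) & (pos < sub["end"])).any()
        assert (merged["end"] - merged["start"]).sum() <= (
            peaks["end"] - peaks["start"]
        ).sum()

    def test_merge_matches_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            peaks = random_peakset(rng, int(rng.integers(1, 120)))
            merged = iv.merge_overlapping(peaks)
            got = sorted(merged[["chrom", "start", "end"]].itertuples(index=False))
            assert [tuple(r) for r in got] == merge_oracle(peaks)

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            iv.merge_overlapping(make_peaks([("c1", 50, 50)]))


# ---------------------------------------------------------------- reciprocal overlap

class TestReciprocalOverlap:
    def test_either_vs_both_semantics(self):
        # overlap 50: 50% of a (qualifies), 20% of b (fails both-mode)
        a = make_peaks([("c1", 100, 200)])
        b = make_peaks([("c1", 150, 400)])
        assert iv.reciprocal_overlap_mask(a, b, 0.25, either=True)[0]
        assert not iv.reciprocal_overlap_mask(a, b, 0.25, either=False)[0]

    def test_identical_intervals_qualify_in_both_modes(self):
        a = make_peaks([("c1", 10, 60)])
        assert iv.reciprocal_overlap_mask(a, a, 0.25, either=False)[0]

    def test_disjoint_never_qualify(self):
        a = make_peaks([("c1", 0, 100)])
        b = make_peaks([("c1", 100, 200)])  # book-ended: zero shared bases
        assert not iv.reciprocal_overlap_mask(a, b, 0.25, either=True)[0]

    def test_invalid_fraction_rejected(self):
        a = make_peaks([("c1", 0, 10)])
        with pytest.raises(ValueError):
            iv.reciprocal_overlap(a, a, min_frac=0.0)

    @pytest.mark.parametrize("either", [True, False])
    def test_matches_all_pairs_oracle(self, either):
        rng = np.random.default_rng(17 if either else 23)
        for _ in range(15):
            a = iv.merge_overlapping(random_peakset(rng, int(rng.integers(5, 150))))
            b = iv.merge_overlapping(random_peakset(rng, int(rng.integers(5, 150))))
            got = iv.reciprocal_overlap_mask(a, b, 0.25, either=either)
            want = reciprocal_oracle(a, b, 0.25, either=either)
            assert (got == want).all()

    def test_either_mode_is_symmetric(self):
        rng = np.random.default_rng(29)
        a = iv.merge_overlapping(random_peakset(rng, 80))
        b = iv.merge_overlapping(random_peakset(rng, 80))
        # a pairs with b somewhere iff b pairs with a somewhere on the same bases
        mask_ab = reciprocal_oracle(a, b, 0.25, True)
        mask_ba = reciprocal_oracle(b, a, 0.25, True)
        assert mask_ab.any() == mask_ba.any()


# ------------------------------------------------------------------ shared counting

class TestSharedPeakCount:
    def test_identical_sets_fully_shared(self):
        rng = np.random.default_rng(31)
        a = iv.merge_overlapping(random_peakset(rng, 50))
        res = iv.shared_peak_count(a, a)
        assert res.n_shared == len(a)
        assert res.n_a_only == res.n_b_only == 0

    def test_disjoint_sets_share_nothing(self):
        a = make_peaks([("c1", 0, 100)])
        b = make_peaks([("c2", 0, 100)])
        res = iv.shared_peak_count(a, b)
        assert res.n_shared == 0
        assert (res.n_a_only, res.n_b_only) == (1, 1)

    def test_union_identity_on_random_sets(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            a = iv.merge_overlapping(random_peakset(rng, int(rng.integers(10, 200))))
            b = iv.merge_overlapping(random_peakset(rng, int(rng.integers(10, 200))))
            res = iv.shared_peak_count(a, b)
            union = iv.union_count(len(a), len(b), res.n_shared)
            assert union >= max(len(a), len(b)) - res.n_shared
            # qualifying counts bounded by set sizes
            assert res.n_a_qualifying + res.n_a_only == len(a)
            assert res.n_b_qualifying + res.n_b_only == len(b)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            a = iv.merge_overlapping(random_peakset(rng, 100))
            b = iv.merge_overlapping(random_peakset(rng, 100))
            res = iv.shared_peak_count(a, b)
            mask_a = reciprocal_oracle(a, b, 0.25, True)
            mask_b = reciprocal_oracle(b, a, 0.25, True)
            qual = pd.concat([a[mask_a], b[mask_b]])
            n_shared = len(iv.merge_overlapping(qual)) if len(qual) else 0
            assert res.n_shared == n_shared
            assert res.n_a_only == (~mask_a).sum()
            assert res.n_b_only == (~mask_b).sum()


# ------------------------------------------------------------- fractions and unions

class TestPrintedArithmetic:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (26_428, 49_846, 53.0),
            (15_463, 17_413, 88.8),
            (0, 10, 0.0),
        ],
    )
    def test_overlap_fraction(self, num, den, expected):
        assert iv.overlap_fraction(num, den) == expected

    def test_overlap_fraction_rounds_half_up(self):
        assert iv.overlap_fraction(575, 1000) == 57.5
        assert iv.overlap_fraction(5745, 10000) == 57.5  # 57.45 -> 57.5 half-up
        with pytest.raises(ValueError):
            iv.overlap_fraction(1, 0)

    def test_union_count(self):
        assert iv.union_count(49_846, 45_589, 26_428) == 69_007
        assert iv.union_count(10, 10, 10) == 10
        assert iv.union_count(5, 7, 0) == 12
        with pytest.raises(ValueError):
            iv.union_count(1, 1, 5)


# ---------------------------------------------------------------- target assignment

class TestAssignTargetGene:
    def make_tss(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss_position", "strand"])

    def test_distance_strictly_below_threshold_assigned(self):
        tss = self.make_tss([("g1", "c1", 21_499, "+")])
        # midpoint 1500, distance 19,999
        assert iv.assign_target_gene(("c1", 1000, 2000), tss) == "g1"

    def test_distance_at_threshold_unassigned(self):
        tss = self.make_tss([("g1", "c1", 21_500, "+")])
        assert iv.assign_target_gene(("c1", 1000, 2000), tss) is None

    def test_nearest_gene_wins(self):
        tss = self.make_tss([("far", "c1", 16_500, "+"), ("near", "c1", 6_500, "-")])
        assert iv.assign_target_gene(("c1", 1000, 2000), tss) == "near"

    def test_tie_breaks_lexicographically(self):
        tss = self.make_tss([("zeta", "c1", 2_500, "+"), ("alpha", "c1", 500, "-")])
        assert iv.assign_target_gene(("c1", 1000, 2000), tss) == "alpha"

    def test_missing_chromosome_returns_none(self):
        tss = self.make_tss([("g1", "c2", 100, "+")])
        assert iv.assign_target_gene(("c1", 1000, 2000), tss) is None

    def test_nearest_matches_exhaustive_scan(self):
        rng = np.random.default_rng(43)
        tss = self.make_tss(
            [(f"g{i}", "c1", int(p), "+") for i, p in enumerate(rng.integers(0, 500_000, 200))]
        )
        for _ in range(50):
            start = int(rng.integers(0, 480_000))
            end = start + int(rng.integers(100, 2_000))
            mid = (start + end) // 2
            dists = (tss["tss_position"] - mid).abs()
            best = dists.min()
            want = sorted(tss.loc[dists == best, "gene_id"])[0] if best < 20_000 else None
            assert iv.assign_target_gene(("c1", start, end), tss) == want


# -------------------------------------------------------------------------- fisher

def fisher_greater_oracle(n11, n12, n21, n22):
    """Hypergeometric tail enumeration."""
    from math import comb

    row1, col1, n = n11 + n12, n11 + n21, n11 + n12 + n21 + n22
    denom = comb(n, col1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(comb(row1, k) * comb(n - row1, col1 - k) for k in range(n11, hi + 1)) / denom


class TestFisherOverlap:
    @pytest.mark.parametrize(
        "table", [(10, 0, 0, 10), (5, 5, 5, 5), (0, 5, 5, 5), (3, 1, 2, 8), (0, 0, 4, 4)]
    )
    def test_matches_enumeration_oracle(self, table):
        assert iv.fisher_overlap_test(*table) == pytest.approx(
            fisher_greater_oracle(*table), rel=1e-9
        )

    def test_perfect_overlap_value(self):
        from math import comb

        assert iv.fisher_overlap_test(10, 0, 0, 10) == pytest.approx(1 / comb(20, 10))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            iv.fisher_overlap_test(-1, 0, 0, 0)
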