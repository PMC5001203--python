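"""Promoter annotation and background-region construction."""

import numpy as np
import pandas as pd
import pytest

from mbdcapdm.annotation import (
    GenomeLayout,
    Promoter,
    Window,
    build_background,
    compute_tpm,
    construct_candidates,
    filter_windows,
    finalize_background,
    load_refflat,
    tile_genome,
)


def refflat_line(gene, chrom, strand, tx_start, tx_end):
    return "\t".join(
        [
            gene, f"{gene}_tx", chrom, strand, str(tx_start), str(tx_end),
            str(tx_start), str(tx_end), "1", f"{tx_start},", f"{tx_end},",
        ]
    )


class TestLoadRefflat:
    def test_shared_tss_collapses(self, tmp_path):
        path = tmp_path / "genes.refFlat"
        path.write_text(
            "\n".join(
                [
                    refflat_line("GENE1", "chr1", "+", 10000, 15000),
                    refflat_line("GENE1", "chr1", "+", 10000, 18000),
                    refflat_line("GENE2", "chr1", "+", 30000, 35000),
                ]
            )
            + "\n"
        )
        promoters = load_refflat(path)
        assert len(promoters) == 2

    def test_plus_strand_interval(self, tmp_path):
        path = tmp_path / "g.refFlat"
        path.write_text(refflat_line("G", "chr1", "+", 10000, 15000) + "\n")
        (p,) = load_refflat(path)
        assert (p.tss, p.start, p.end) == (10000, 8000, 12000)

    def test_minus_strand_interval(self, tmp_path):
        """- strand TSS is txEnd - 1 (half-open refFlat coordinates)."""
        path = tmp_path / "g.refFlat"
        path.write_text(refflat_line("G", "chr1", "-", 4000, 10000) + "\n")
        (p,) = load_refflat(path)
        assert (p.tss, p.start, p.end) == (9999, 7999, 11999)

    def test_malformed_rows_skipped_and_clipping(self, tmp_path):
        path = tmp_path / "g.refFlat"
        path.write_text(
            "not\ta\tvalid\trow\n"
            + refflat_line("NEAREDGE", "chr1", "+", 500, 3000)
            + "\n"
        )
        layout = GenomeLayout({"chr1": 3000})
        (p,) = load_refflat(path, layout)
        assert p.clipped and p.start == 0 and p.end == 2500


class TestTiling:
    def test_window_counts(self):
        layout = GenomeLayout({"chr1": 1000})
        assert len(list(tile_genome(layout))) == 10

    def test_trailing_partial_dropped(self):
        layout = GenomeLayout({"chr1": 1050})
        windows = list(tile_genome(layout))
        assert len(windows) == 10
        assert windows[-1].end == 1000

    def test_gc_fraction_from_sequence(self):
        layout = GenomeLayout({"chr1": 300})
        windows = list(tile_genome(layout, {"chr1": "G" * 300}))
        assert all(w.gc_fraction == 1.0 for w in windows)

    def test_ambiguous_base_flagged(self):
        layout = GenomeLayout({"chr1": 200})
        seq = "A" * 100 + "A" * 50 + "N" + "A" * 49
        w0, w1 = tile_genome(layout, {"chr1": seq})
        assert not w0.has_ambiguous_base
        assert w1.has_ambiguous_base


def toy_windows(n=30, chrom="chr1", gc=0.3):
    return [Window(chrom, i * 100, (i + 1) * 100, gc) for i in range(n)]


class TestFiltering:
    def test_exclusions_match_brute_force(self):
        windows = toy_windows(30)
        promoter = Promoter("G", "chr1", "+", 650, 500, 900)  # windows 5-8
        cpg = {"chr1": [(2000, 2100)]}  # window 20
        eligible = filter_windows(windows, [promoter], cpg_islands=cpg)
        # brute force: any >=1 bp overlap excludes
        expected = [
            w
            for w in windows
            if not (w.start < 900 and w.end > 500)
            and not (w.start < 2100 and w.end > 2000)
        ]
        assert len(eligible) == 25
        assert [w.id for w in eligible] == [w.id for w in expected]

    def test_no_exclusions_keeps_all(self):
        windows = toy_windows(10)
        assert len(filter_windows(windows, [])) == 10

    def test_ambiguous_window_excluded(self):
        w = Window("chr1", 0, 100, 0.3, has_ambiguous_base=True)
        assert filter_windows([w], []) == []


class TestCandidates:
    def test_exactly_80_low_gc_selected(self):
        windows = toy_windows(80)
        promoter = Promoter("G", "chr1", "+", 4000, 2000, 6000)
        cand, flags = construct_candidates(promoter, windows)
        assert len(cand) == 80 and not flags

    def test_nearest_by_midpoint_matches_sort_oracle(self, rng):
        starts = rng.choice(np.arange(0, 100000, 100), size=100, replace=False)
        windows = [Window("chr1", int(s), int(s) + 100, 0.2) for s in starts]
        promoter = Promoter("G", "chr1", "+", 41234, 39234, 43234)
        cand, _ = construct_candidates(promoter, windows)
        oracle = sorted(windows, key=lambda w: (abs(w.midpoint - 41234), w.start))[:80]
        assert [w.id for w in cand] == [w.id for w in oracle]

    def test_high_gc_only_flags_no_background(self):
        windows = toy_windows(30, gc=0.55)
        promoter = Promoter("G", "chr1", "+", 1500, 0, 3000)
        cand, flags = construct_candidates(promoter, windows)
        assert cand == [] and "no_background" in flags

    def test_other_chromosome_ignored(self):
        windows = toy_windows(10, chrom="chr2")
        promoter = Promoter("G", "chr1", "+", 500, 0, 2500)
        cand, flags = construct_candidates(promoter, windows)
        assert cand == []


class TestTPM:
    def test_single_window_collapses_to_million(self):
        assert compute_tpm([7], read_length=50)[0] == pytest.approx(1e6)

    def test_equal_counts_split_evenly(self):
        tpm = compute_tpm([3, 3], read_length=50)
        assert np.allclose(tpm, [5e5, 5e5])

    def test_hand_computed_values(self):
        tpm = compute_tpm([1, 3], read_length=50)
        assert np.allclose(tpm, [2.5e5, 7.5e5])

    def test_normalization_sums_to_million(self, rng):
        counts = rng.integers(0, 500, size=200)
        counts[0] = 3  # ensure nonzero
        tpm = compute_tpm(counts, read_length=50)
        assert tpm.sum() == pytest.approx(1e6, rel=1e-6)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            compute_tpm([0, 0], read_length=50)


class TestFinalize:
    def _promoter(self):
        return Promoter("G", "chr1", "+", 4000, 2000, 6000)

    def test_lowest_40_of_80_matches_sort_oracle(self, rng):
        windows = toy_windows(80)
        tpm = pd.Series(rng.permutation(80).astype(float), index=[w.id for w in windows])
        final, flags = finalize_background(self._promoter(), windows, tpm)
        oracle = sorted(windows, key=lambda w: tpm[w.id])[:40]
        assert [w.id for w in final] == [w.id for w in oracle]
        assert not flags

    def test_shortfall_retains_all_with_flag(self):
        windows = toy_windows(30)
        tpm = pd.Series(1.0, index=[w.id for w in windows])
        final, flags = finalize_background(self._promoter(), windows, tpm)
        assert len(final) == 30 and "short_final" in flags

    def test_tpm_ties_break_by_proximity(self):
        windows = toy_windows(80)
        tpm = pd.Series(0.0, index=[w.id for w in windows])
        final, _ = finalize_background(self._promoter(), windows, tpm)
        oracle = sorted(windows, key=lambda w: (abs(w.midpoint - 4000), w.start))[:40]
        assert [w.id for w in final] == [w.id for w in oracle]


class TestBuildBackground:
    def test_pipeline_invariants(self, rng):
        """Every finalized window is eligible, low-GC and within bounds."""
        n_windows = 400
        layout = GenomeLayout(
            {"chr1": n_windows * 100},
            gaps={"chr1": [(30000, 30300)]},
            cpg_islands={"chr1": [(10000, 10200)]},
        )
        gc = rng.uniform(0.2, 0.6, size=n_windows)
        windows = [
            Window("chr1", i * 100, (i + 1) * 100, float(gc[i]))
            for i in range(n_windows)
        ]
        promoters = [
            Promoter("G1", "chr1", "+", 5000, 3000, 7000),
            Promoter("G2", "chr1", "-", 25000, 23000, 27000),
        ]
        counts = pd.DataFrame(
            {"s1": rng.integers(0, 50, n_windows)},
            index=[w.id for w in windows],
        )
        ann = build_background(layout, promoters, counts, read_length=50, windows=windows)
        for p in promoters:
            final = ann.windows[p.id]
            assert len(final) <= 40
            assert len(ann.candidates[p.id]) <= 80
            assert len(final) <= len(ann.candidates[p.id])
            for w in final:
                assert w.gc_fraction < 0.40
                assert not (w.start < 7000 and w.end > 3000)
                assert not (w.start < 27000 and w.end > 23000)
                assert not (w.start < 10200 and w.end > 10000)
                assert not (w.start < 30300 and w.end > 30000)

    def test_deterministic(self, rng):
        layout = GenomeLayout({"chr1": 30000})
        gc = rng.uniform(0.1, 0.5, 300)
        windows = [
            Window("chr1", i * 100, (i + 1) * 100, float(gc[i])) for i in range(300)
        ]
        promoters = [Promoter("G", "chr1", "+", 15000, 13000, 17000)]
        counts = pd.DataFrame(
            {"s1": rng.integers(0, 20, 300)}, index=[w.id for w in windows]
        )
        a1 = build_background(layout, promoters, counts, 50, windows=windows)
        a2 = build_background(layout, promoters, counts, 50, windows=windows)
        assert a1.window_ids("G") == a2.window_ids("G")
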