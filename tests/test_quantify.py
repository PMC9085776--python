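import math

import pytest

from doubletap import (
    IndelSpec,
    LocusSequence,
    OutcomeDistribution,
    SimConfig,
    apply_indel,
    build_indel_table,
    classify_read,
    compare_conditions,
    genotype_clones,
    simulate_reads,
)
from doubletap.quantify import DISCARD, HDR_PERFECT, INDEL, WT, IndelTable, Stat


def _reads(sim_reads):
    return [r.as_pair() for r in sim_reads]


def _table_from_stats(locus_id, hdr, indel, wt, discard=0.0, sd=0.0, alleles=()):
    from doubletap import IndelAllele

    entries = [
        IndelAllele(key=k, seq="", spec=None, provenance="observed",
                    frequency=f, frequency_sd=0.0, n_replicates=3)
        for k, f in alleles
    ]
    return IndelTable(
        locus_id=locus_id, cut_index=50, total_reads=1000, n_replicates=3,
        alleles=entries,
        wt_pct=Stat(wt, sd, 3), hdr_pct=Stat(hdr, sd, 3),
        total_indel_pct=Stat(indel, sd, 3), discard_pct=Stat(discard, 0, 3),
    )


class TestClassifyRead:
    def test_exact_reference_read_is_wt(self, locus_and_primary, hdr_allele):
        locus, primary = locus_and_primary
        cls = classify_read(
            locus.seq, None, locus, hdr_allele, primary.cut_index
        )
        assert cls.category == WT

    def test_exact_hdr_read_is_hdr_perfect(self, locus_and_primary, hdr_allele):
        locus, primary = locus_and_primary
        cls = classify_read(
            hdr_allele.seq, None, locus, hdr_allele, primary.cut_index
        )
        assert cls.category == HDR_PERFECT

    def test_insertion_at_cut_detected_with_key(self, locus_and_primary, hdr_allele):
        locus, primary = locus_and_primary
        cut = primary.cut_index
        # pick a base that cannot left-shift out of the cut position
        base = next(b for b in "ACGT" if b != locus.seq[cut - 1])
        read = locus.seq[:cut] + base + locus.seq[cut:]
        cls = classify_read(read, None, locus, hdr_allele, cut)
        assert cls.category == INDEL
        assert cls.indel_keys == (f"ins:1:0:{base}",)

    def test_hdr_read_with_additional_indel_is_indel(
        self, locus_and_primary, hdr_allele
    ):
        locus, primary = locus_and_primary
        cut = primary.cut_index
        read = hdr_allele.seq[: cut - 6] + hdr_allele.seq[cut - 4 :]
        cls = classify_read(read, None, locus, hdr_allele, cut)
        assert cls.category == INDEL

    def test_without_hdr_amplicon_hdr_never_assigned(
        self, locus_and_primary, hdr_allele
    ):
        locus, primary = locus_and_primary
        cls = classify_read(
            hdr_allele.seq, None, locus, None, primary.cut_index
        )
        assert cls.category != HDR_PERFECT

    def test_low_quality_read_discarded(self, locus_and_primary):
        locus, primary = locus_and_primary
        qual = chr(33 + 5) * len(locus.seq)  # mean Phred 5
        cls = classify_read(
            locus.seq, qual, locus, None, primary.cut_index
        )
        assert cls.category == DISCARD

    def test_short_read_discarded(self, locus_and_primary):
        locus, primary = locus_and_primary
        cls = classify_read(
            locus.seq[: len(locus.seq) // 2], None, locus, None,
            primary.cut_index,
        )
        assert cls.category == DISCARD

    def test_mismatches_outside_window_tolerated(self, locus_and_primary):
        locus, primary = locus_and_primary
        read = "T" + locus.seq[1:-1] + "A"
        read = read[:5] + "N" + read[6:]  # N also stays outside the window
        cls = classify_read(read, None, locus, None, primary.cut_index)
        assert cls.category == WT


class TestBuildIndelTable:
    def test_error_free_mixture_recovered_exactly(
        self, locus_and_primary, hdr_allele
    ):
        locus, primary = locus_and_primary
        base = next(b for b in "ACGT" if b != locus.seq[primary.cut_index - 1])
        key = f"ins:1:0:{base}"
        dist = OutcomeDistribution(0.5, 0.2, {key: 0.3})
        reads = simulate_reads(
            locus, primary, hdr_allele, dist,
            SimConfig(seed=7, n_reads=1000, error_rate=0.0, exact_counts=True),
        )
        table = build_indel_table(
            [_reads(reads)], locus, hdr_allele, primary.cut_index
        )
        assert table.allele_frequencies()[key] == pytest.approx(30.0)
        assert table.wt_pct.mean == pytest.approx(50.0)
        assert table.hdr_pct.mean == pytest.approx(20.0)
        assert table.discard_pct.mean == pytest.approx(0.0)

    def test_replicate_means_within_binomial_bounds(
        self, locus_and_primary, hdr_allele
    ):
        locus, primary = locus_and_primary
        base = next(b for b in "ACGT" if b != locus.seq[primary.cut_index - 1])
        key = f"ins:1:0:{base}"
        dist = OutcomeDistribution(0.5, 0.2, {key: 0.3})
        n = 1500
        reps = [
            _reads(
                simulate_reads(
                    locus, primary, hdr_allele, dist,
                    SimConfig(seed=100 + i, n_reads=n, error_rate=0.002),
                )
            )
            for i in range(3)
        ]
        table = build_indel_table(reps, locus, hdr_allele, primary.cut_index)
        sigma = 100 * math.sqrt(0.3 * 0.7 / (3 * n))
        assert abs(table.allele_frequencies()[key] - 30.0) < 3 * sigma

    def test_pure_wt_hdr_mixture_has_no_indels(
        self, locus_and_primary, hdr_allele
    ):
        locus, primary = locus_and_primary
        dist = OutcomeDistribution(0.5, 0.5, {})
        reads = simulate_reads(
            locus, primary, hdr_allele, dist,
            SimConfig(seed=9, n_reads=400, error_rate=0.0, exact_counts=True),
        )
        table = build_indel_table(
            [_reads(reads)], locus, hdr_allele, primary.cut_index
        )
        assert table.total_indel_pct.mean == 0.0

    def test_category_percentages_sum_to_100(self, locus_and_primary, hdr_allele):
        locus, primary = locus_and_primary
        base = locus.seq[primary.cut_index - 1]
        dist = OutcomeDistribution(0.4, 0.3, {f"ins:1:0:{base}": 0.3})
        reads = simulate_reads(
            locus, primary, hdr_allele, dist,
            SimConfig(seed=13, n_reads=800, error_rate=0.005),
        )
        table = build_indel_table(
            [_reads(reads)], locus, hdr_allele, primary.cut_index
        )
        total = (
            table.wt_pct.mean + table.hdr_pct.mean
            + table.total_indel_pct.mean + table.discard_pct.mean
        )
        assert total == pytest.approx(100.0, abs=0.01)

    def test_all_discard_raises(self, locus_and_primary):
        locus, primary = locus_and_primary
        junk = [("ACGT" * (len(locus) // 4), None)] * 5
        with pytest.raises(ValueError, match="classifiable"):
            build_indel_table(
                [[(s, chr(33 + 2) * len(s)) for s, _ in junk]],
                locus, None, primary.cut_index,
            )

    def test_empty_replicate_rejected(self, locus_and_primary):
        locus, primary = locus_and_primary
        with pytest.raises(ValueError):
            build_indel_table([[]], locus, None, primary.cut_index)

    def test_tsv_round_trip_schema(self, tmp_path, locus_and_primary, hdr_allele):
        import pandas as pd

        locus, primary = locus_and_primary
        base = locus.seq[primary.cut_index - 1]
        dist = OutcomeDistribution(0.6, 0.0, {f"ins:1:0:{base}": 0.4})
        reads = simulate_reads(
            locus, primary, None, dist,
            SimConfig(seed=3, n_reads=500, error_rate=0.0, exact_counts=True),
        )
        table = build_indel_table([_reads(reads)], locus, None, primary.cut_index)
        out = tmp_path / "table.tsv"
        table.to_tsv(out)
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == [
            "key", "kind", "length", "offset", "bases",
            "frequency_pct", "sd_pct", "n", "provenance",
        ]
        assert df["frequency_pct"].iloc[0] == pytest.approx(40.0)


class TestCompareConditions:
    def test_exact_fold_change(self):
        nt = _table_from_stats("L", hdr=10.0, indel=40.0, wt=50.0)
        dt = _table_from_stats("L", hdr=20.0, indel=30.0, wt=50.0)
        stats = compare_conditions(nt, dt)
        assert stats.fold_change == pytest.approx(2.0)
        assert stats.fold_change_sd == pytest.approx(0.0)
        assert stats.percent_decrease_indels == pytest.approx(25.0)

    def test_percent_decrease_on_reported_scale(self):
        nt = _table_from_stats("L", hdr=10.0, indel=38.6, wt=51.4)
        dt = _table_from_stats("L", hdr=17.0, indel=6.9, wt=76.1)
        stats = compare_conditions(nt, dt)
        assert stats.percent_decrease_indels == pytest.approx(82.1, abs=0.05)

    def test_quotient_error_propagation(self):
        nt = _table_from_stats("L", hdr=10.0, indel=40.0, wt=50.0, sd=1.0)
        dt = _table_from_stats("L", hdr=20.0, indel=30.0, wt=50.0, sd=1.0)
        stats = compare_conditions(nt, dt)
        expected = 2.0 * math.sqrt((1 / 10) ** 2 + (1 / 20) ** 2)
        assert stats.fold_change_sd == pytest.approx(expected)

    def test_zero_nt_hdr_flags_fold_undefined(self):
        nt = _table_from_stats("L", hdr=0.0, indel=40.0, wt=60.0)
        dt = _table_from_stats("L", hdr=20.0, indel=30.0, wt=50.0)
        stats = compare_conditions(nt, dt)
        assert stats.fold_undefined and stats.fold_change is None

    def test_targeted_key_rates_summed(self):
        nt = _table_from_stats(
            "L", hdr=10.0, indel=40.0, wt=50.0,
            alleles=[("del:2:0", 25.0), ("ins:1:0:A", 10.0)],
        )
        dt = _table_from_stats(
            "L", hdr=20.0, indel=10.0, wt=70.0,
            alleles=[("del:2:0", 3.0), ("ins:1:0:A", 2.0)],
        )
        stats = compare_conditions(nt, dt, ["del:2:0", "ins:1:0:A"])
        assert stats.targeted_rate_nt == pytest.approx(35.0)
        assert stats.targeted_rate_dt == pytest.approx(5.0)

    def test_different_loci_rejected(self):
        nt = _table_from_stats("L1", hdr=10.0, indel=40.0, wt=50.0)
        dt = _table_from_stats("L2", hdr=20.0, indel=30.0, wt=50.0)
        with pytest.raises(ValueError):
            compare_conditions(nt, dt)

    def test_fold_change_invariant_to_depth(
        self, locus_and_primary, hdr_allele
    ):
        locus, primary = locus_and_primary
        base = locus.seq[primary.cut_index - 1]
        dist_nt = OutcomeDistribution(0.5, 0.1, {f"ins:1:0:{base}": 0.4})
        dist_dt = OutcomeDistribution(0.5, 0.3, {f"ins:1:0:{base}": 0.2})
        folds = []
        for n in (500, 2000):
            tables = []
            for i, dist in enumerate((dist_nt, dist_dt)):
                reads = simulate_reads(
                    locus, primary, hdr_allele, dist,
                    SimConfig(seed=50 + i, n_reads=n, error_rate=0.0,
                              exact_counts=True),
                )
                tables.append(
                    build_indel_table(
                        [_reads(reads)], locus, hdr_allele, primary.cut_index
                    )
                )
            folds.append(compare_conditions(*tables).fold_change)
        assert folds[0] == pytest.approx(folds[1])


class TestGenotypeClones:
    def _clone(self, locus, primary, hdr, dist, seed, n=150):
        reads = simulate_reads(
            locus, primary, hdr, dist,
            SimConfig(seed=seed, n_reads=n, error_rate=0.001),
        )
        return _reads(reads)

    def test_pure_hdr_clone_is_homozygous(self, locus_and_primary, hdr_allele):
        locus, primary = locus_and_primary
        clone = self._clone(
            locus, primary, hdr_allele, OutcomeDistribution(0.0, 1.0, {}), 1
        )
        calls, _ = genotype_clones(
            [("c1", clone)], locus, hdr_allele, primary.cut_index
        )
        assert calls[0].category == "homozygous"

    def test_wt_hdr_mixture_is_heterozygous(self, locus_and_primary, hdr_allele):
        locus, primary = locus_and_primary
        clone = self._clone(
            locus, primary, hdr_allele,
            OutcomeDistribution(1 / 3, 2 / 3, {}), 2,
        )
        calls, _ = genotype_clones(
            [("c1", clone)], locus, hdr_allele, primary.cut_index
        )
        assert calls[0].category == "heterozygous"

    def test_category_mapping_across_mixtures(self, locus_and_primary, hdr_allele):
        locus, primary = locus_and_primary
        base = locus.seq[primary.cut_index - 1]
        key = f"ins:1:0:{base}"
        cases = [
            (OutcomeDistribution(0.0, 1 / 3, {key: 2 / 3}), "HDR_indel"),
            (OutcomeDistribution(0.0, 0.0, {key: 1.0}), "indel_mixture"),
            (OutcomeDistribution(2 / 3, 0.0, {key: 1 / 3}), "WT_indel"),
            (OutcomeDistribution(1.0, 0.0, {}), "WT"),
        ]
        clones = [
            (f"c{i}", self._clone(locus, primary, hdr_allele, dist, 10 + i))
            for i, (dist, _) in enumerate(cases)
        ]
        calls, summary = genotype_clones(
            clones, locus, hdr_allele, primary.cut_index
        )
        assert [c.category for c in calls] == [cat for _, cat in cases]
        assert summary["HDR_indel"] == 25

    def test_low_coverage_clone_excluded(self, locus_and_primary, hdr_allele):
        locus, primary = locus_and_primary
        clone = self._clone(
            locus, primary, hdr_allele, OutcomeDistribution(0.0, 1.0, {}),
            seed=5, n=20,
        )
        calls, _ = genotype_clones(
            [("tiny", clone)], locus, hdr_allele, primary.cut_index,
            min_reads=100,
        )
        assert calls == []
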