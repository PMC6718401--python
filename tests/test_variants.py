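"""Paired Fisher calling, spectrum classes, repeat context, timing, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from msiburst.variants import (
    GT_MISMATCH_CLASSES,
    PILEUP_COLUMNS,
    VariantRecord,
    annotate_repeat_context,
    assign_timing,
    call_somatic,
    classify_substitution,
    count_repeat_context,
    fisher_exact_pvalues,
    records_to_dataframe,
    region_enrichment,
    timing_split,
    vaf_band_fraction,
    write_minimal_vcf,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def make_pileup(rows):
    """rows: list of dicts with chrom/pos/ref and per-allele counts (rest 0)."""
    data = []
    for row in rows:
        full = {c: 0 for c in PILEUP_COLUMNS}
        full.update({"chrom": "chr1", "indel_seq": ""})
        full.update(row)
        data.append(full)
    return pd.DataFrame(data, columns=PILEUP_COLUMNS)


class TestFisher:
    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        tables = rng.integers(0, 120, size=(500, 4))
        ours = fisher_exact_pvalues(tables)
        scipys = np.array([stats.fisher_exact(t.reshape(2, 2))[1] for t in tables])
        np.testing.assert_allclose(ours, scipys, rtol=1e-9, atol=1e-300)

    def test_matches_enumeration_on_small_tables(self):
        # independent oracle: sum hypergeometric pmf over the support directly
        rng = np.random.default_rng(1)
        tables = rng.integers(0, 15, size=(200, 4))
        for a, b, c, d in tables:
            n, row1, col1 = a + b + c + d, a + b, a + c
            lo, hi = max(0, row1 + col1 - n), min(row1, col1)
            support = np.arange(lo, hi + 1)
            pmf = stats.hypergeom.pmf(support, n, col1, row1)
            obs = stats.hypergeom.pmf(a, n, col1, row1)
            expected = pmf[pmf <= obs * (1 + 1e-7)].sum()
            got = fisher_exact_pvalues([[a, b, c, d]])[0]
            assert got == pytest.approx(min(expected, 1.0), rel=1e-9)

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError):
            fisher_exact_pvalues([[1, -1, 2, 3]])


class TestCallSomatic:
    def test_shallow_site_excluded_regardless_of_signal(self):
        sites = make_pileup(
            [
                {"pos": 10, "ref": "A", "A_control": 9, "A_case": 50, "T_case": 50},
            ]
        )
        assert call_somatic(sites, min_depth=10) == []

    def test_identical_samples_never_called(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(50):
            counts = rng.integers(0, 40, size=4)
            row = {"pos": i + 1, "ref": "C"}
            for b, c in zip("ACGT", counts):
                row[f"{b}_control"] = int(c)
                row[f"{b}_case"] = int(c)
            rows.append(row)
        assert call_somatic(make_pileup(rows), p_threshold=0.999) == []

    def test_clear_somatic_site_called_with_exact_pvalue(self):
        sites = make_pileup(
            [{"pos": 5, "ref": "G", "G_control": 50, "G_case": 25, "A_case": 25}]
        )
        records = call_somatic(sites)
        assert len(records) == 1
        rec = records[0]
        assert (rec.ref, rec.alt, rec.vtype) == ("G", "A", "substitution")
        assert rec.case_fraction == pytest.approx(0.5)
        # oracle: exhaustive hypergeometric enumeration of the observed margins
        expected = stats.fisher_exact([[50, 0], [25, 25]])[1]
        assert rec.p_value == pytest.approx(expected, rel=1e-9)
        assert rec.p_value < 0.001

    def test_deletion_candidate_reported_with_unit(self):
        sites = make_pileup(
            [
                {
                    "pos": 7,
                    "ref": "T",
                    "T_control": 60,
                    "T_case": 30,
                    "del_case": 30,
                    "indel_seq": "A",
                }
            ]
        )
        (rec,) = call_somatic(sites)
        assert rec.vtype == "deletion"
        assert rec.alt == "A"

    def test_malformed_pileup_rejected(self):
        sites = make_pileup([{"pos": 1, "ref": "A", "A_control": -3, "A_case": 10}])
        with pytest.raises(ValueError):
            call_somatic(sites)
        with pytest.raises(ValueError):
            call_somatic(pd.DataFrame({"pos": [1]}))

    def test_benjamini_hochberg_mode_runs(self):
        sites = make_pileup(
            [
                {"pos": 5, "ref": "G", "G_control": 50, "G_case": 25, "A_case": 25},
                {"pos": 9, "ref": "C", "C_control": 40, "C_case": 38, "T_case": 2},
            ]
        )
        fixed = call_somatic(sites)
        bh = call_somatic(sites, benjamini_hochberg=True)
        assert {r.position for r in bh} <= {5, 9}
        assert {r.position for r in fixed} == {5}


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "ref, alt, cls, flag",
        [
            ("G", "A", "C>T", True),
            ("C", "T", "C>T", True),
            ("T", "C", "T>C", True),
            ("A", "G", "T>C", True),
            ("C", "G", "C>G", False),
            ("C", "A", "C>A", False),
            ("G", "T", "C>A", False),
            ("T", "A", "T>A", False),
            ("A", "T", "T>A", False),
            ("T", "G", "T>G", False),
            ("A", "C", "T>G", False),
            ("G", "C", "C>G", False),
        ],
    )
    def test_all_twelve_changes(self, ref, alt, cls, flag):
        assert classify_substitution(ref, alt) == (cls, flag)

    @given(
        st.sampled_from("ACGT"),
        st.sampled_from("ACGT"),
    )
    def test_reverse_complement_invariance(self, ref, alt):
        if ref == alt:
            return
        assert classify_substitution(ref, alt) == classify_substitution(
            _COMP[ref], _COMP[alt]
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_substitution("N", "A")
        with pytest.raises(ValueError):
            classify_substitution("A", "A")

    def test_gt_class_table_is_configurable(self):
        cls, flag = classify_substitution("C", "T", gt_classes=frozenset())
        assert cls == "C>T" and flag is False
        assert GT_MISMATCH_CLASSES == {"C>T", "T>C"}


class TestVafBand:
    def test_all_zero_fractions(self):
        assert vaf_band_fraction([0.0, 0.0, 0.0]) == 0.0

    def test_band_is_closed_at_both_ends(self):
        assert vaf_band_fraction([0.30, 0.60, 0.29, 0.61]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vaf_band_fraction([])

    def test_accepts_records(self):
        recs = [
            VariantRecord("chr1", 1, "A", "T", "substitution", 0.0, f, 1e-5)
            for f in (0.45, 0.10)
        ]
        assert vaf_band_fraction(recs) == 0.5


class TestRepeatContext:
    def test_mononucleotide_run_counted_from_any_copy(self):
        seq = "GGAAAAAGG"  # run of five A at 2..7
        for pos in range(2, 7):
            assert count_repeat_context(seq, pos, "A") == 5

    def test_dinucleotide_insertion_adjacent_to_run(self):
        assert count_repeat_context("TTCACACATT", 2, "CA") == 3

    def test_no_flanking_repeat_is_zero(self):
        assert count_repeat_context("AGCA", 2, "T") == 0

    @pytest.mark.parametrize("pos", [3, 5, 7])
    def test_invariant_to_deleted_copy_in_run(self, pos):
        seq = "TTTACACACACGG"  # ACACACAC: four AC copies at 3..11
        assert count_repeat_context(seq, pos, "AC") == 4

    def test_record_annotation_uses_anchor_convention(self):
        seq = "GGAAAAAGG"
        rec = VariantRecord("chr1", 2, "G", "A", "deletion", 0.0, 0.3, 1e-5)
        assert annotate_repeat_context(seq, rec).repeat_context == 5

    def test_substitution_rejected(self):
        rec = VariantRecord("chr1", 2, "G", "A", "substitution", 0.0, 0.3, 1e-5)
        with pytest.raises(ValueError):
            annotate_repeat_context("GGAA", rec)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            count_repeat_context("ACGT", 9, "A")


class TestTiming:
    def test_constant_track_splits_half_early(self):
        track = pd.DataFrame(
            {"start": [0, 10, 20, 30], "end": [10, 20, 30, 40], "value": [1.0] * 4}
        )
        labels = timing_split(track)["label"]
        assert (labels == "early").sum() == 2
        # deterministic tie-break: earlier intervals first
        assert list(labels[:2]) == ["early", "early"]

    def test_higher_value_is_earlier(self):
        track = pd.DataFrame({"start": [0, 10], "end": [10, 20], "value": [1.0, 2.0]})
        rec = VariantRecord("chr1", 15, "A", "T", "substitution", 0.0, 0.5, 1e-5)
        (out,) = assign_timing([rec], track)
        assert out.timing == "early"

    def test_flippable_convention(self):
        track = pd.DataFrame({"start": [0, 10], "end": [10, 20], "value": [1.0, 2.0]})
        rec = VariantRecord("chr1", 15, "A", "T", "substitution", 0.0, 0.5, 1e-5)
        (out,) = assign_timing([rec], track, early_is_high=False)
        assert out.timing == "late"

    @pytest.mark.parametrize("n_intervals", [1, 2, 5, 8, 31])
    def test_split_is_always_fifty_fifty(self, n_intervals):
        rng = np.random.default_rng(n_intervals)
        starts = np.arange(n_intervals) * 10
        track = pd.DataFrame(
            {"start": starts, "end": starts + 10, "value": rng.random(n_intervals)}
        )
        labels = timing_split(track)["label"]
        assert (labels == "early").sum() == (n_intervals + 1) // 2

    def test_uncovered_position_unassigned(self):
        track = pd.DataFrame({"start": [0, 10], "end": [10, 20], "value": [1.0, 2.0]})
        rec = VariantRecord("chr1", 99, "A", "T", "substitution", 0.0, 0.5, 1e-5)
        (out,) = assign_timing([rec], track)
        assert out.timing == "unassigned"

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            timing_split(pd.DataFrame(columns=["start", "end", "value"]))


def _indel(pos):
    return VariantRecord("chr1", pos, "A", "T", "deletion", 0.0, 0.4, 1e-5)


class TestRegionEnrichment:
    def test_equal_densities_give_null_result(self):
        exons = [(0, 1000)]
        introns = [(1000, 11000)]
        # density 1/100 in both regions
        records = [_indel(p) for p in range(1, 1001, 100)]  # 10 exonic
        records += [_indel(p) for p in range(1001, 11001, 100)]  # 100 intronic
        res = region_enrichment(records, exons, introns)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self):
        # intron: 90 indels / 1e6 bases, exon: 10 / 1e6
        exons = [(0, 10**6)]
        introns = [(10**6, 2 * 10**6)]
        records = [_indel(10**6 + 1 + 10 * i) for i in range(90)]
        records += [_indel(1 + 10 * i) for i in range(10)]
        res = region_enrichment(records, exons, introns)
        table = np.array([[90, 10**6 - 90], [10, 10**6 - 10]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        np.testing.assert_array_equal(res.table, table.astype(np.int64))

    def test_biased_generator_reaches_significance(self):
        rng = np.random.default_rng(5)
        exons = [(0, 50_000)]
        introns = [(50_000, 100_000)]
        # tenfold intronic density, enough counts for p < 0.001
        positions = np.concatenate(
            [
                rng.integers(1, 50_000, size=20),
                rng.integers(50_001, 100_000, size=200),
            ]
        )
        res = region_enrichment([_indel(int(p)) for p in positions], exons, introns)
        assert res.p_value < 0.001

    def test_zero_base_totals_rejected(self):
        with pytest.raises(ValueError):
            region_enrichment([], [], [(0, 10)])

    def test_substitutions_ignored(self):
        subs = [VariantRecord("chr1", 5, "A", "T", "substitution", 0.0, 0.5, 1e-5)]
        res = region_enrichment(subs, [(0, 100)], [(100, 200)])
        assert res.table[:, 0].sum() == 0 and res.p_value == 1.0


class TestOutput:
    def test_minimal_vcf_is_parseable_by_pysam(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        records = [
            VariantRecord("chr1", 10, "A", "T", "substitution", 0.0, 0.5, 1e-5,
                          region="exon", timing="early"),
            VariantRecord("chr1", 20, "C", "AG", "insertion", 0.0, 0.4, 1e-6,
                          repeat_context=3),
            VariantRecord("chr1", 30, "G", "TT", "deletion", 0.0, 0.3, 1e-7,
                          repeat_context=0),
        ]
        path = tmp_path / "out.vcf"
        write_minimal_vcf(records, path, contigs={"chr1": 1000})
        parsed = list(pysam.VariantFile(str(path)))
        assert len(parsed) == 3
        assert parsed[0].info["TYPE"] == "substitution"
        assert parsed[1].alts == ("CAG",)
        assert parsed[2].ref == "GTT"

    def test_records_dataframe_columns(self):
        df = records_to_dataframe(
            [VariantRecord("chr1", 1, "A", "T", "substitution", 0.0, 0.5, 1e-5)]
        )
        assert list(df.columns)[:5] == ["chrom", "position", "ref", "alt", "vtype"]
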