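import random

import numpy as np
import pytest

from teasv import (DetectionThresholds, GenomeInterval, InsertionPlan,
                   ReferenceGenome, SequenceRecord, ab_initio_scan,
                   cluster_calls, evaluate_against_truth,
                   filter_genomic_reads, find_reference_copies,
                   plant_insertions, targeted_scan, verify_locus_construct)
from teasv.detect import BreakpointSignature, ConcordanceResult, InsertionCall

from conftest import random_dna


def test_thresholds_validation():
    DetectionThresholds()
    with pytest.raises(ValueError):
        DetectionThresholds(hsp_sum_frac_low=0.8, hsp_sum_frac_high=0.7)
    with pytest.raises(ValueError):
        DetectionThresholds(min_te_len=0)


# ---------------------------------------------------------------------------
# Shared noiseless planted-insertion scenario
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def scenario(small_genome, small_genome_indexes, ltr_te, scoring, thresholds):
    """One TE planted at chr1:25000 (TSD 5) in the 50-kb genome, with
    error-free reads of known geometry cut from the mutated sequence."""
    plan = InsertionPlan(ltr_te.family, "chr1", 25_000, "sense", tsd_length=5)
    mutated, truth = plant_insertions(small_genome, [ltr_te], [plan])
    mut = mutated.records[0].residues
    te_end = 25_000 + 5_300 + 5  # TE + TSD in mutated coordinates
    reads = [
        # 1 kb flank + entire TE + TSD + 1 kb flank
        SequenceRecord("full_span", mut[24_000:te_end + 1_000]),
        # 2.5 kb flank then the first 1.5 kb of the TE
        SequenceRecord("split_left", mut[22_500:26_500]),
        # last 1.5 kb of the TE, TSD, then 2.5 kb flank
        SequenceRecord("split_right", mut[28_800:te_end + 2_500]),
        # the element alone
        SequenceRecord("pure_te", mut[25_000:30_300]),
        # plain genomic sequence far from the insertion
        SequenceRecord("genomic", mut[5_000:9_000]),
        # genomic block followed by non-TE junk: a breakpoint with no TE
        SequenceRecord("junk_break",
                       small_genome.records[0].residues[40_000:40_600]
                       + random_dna(np.random.default_rng(55), 300)),
    ]
    kept = filter_genomic_reads(reads, small_genome, scoring,
                                thresholds.min_genomic_frac,
                                small_genome_indexes)
    return {"mutated": mutated, "truth": truth, "reads": reads, "kept": kept,
            "te": ltr_te, "genome": small_genome,
            "indexes": small_genome_indexes}


@pytest.fixture(scope="module")
def targeted(scenario, scoring, thresholds):
    funnel = {}
    classes, sigs = targeted_scan(scenario["te"], scenario["reads"],
                                  scenario["genome"], scoring, thresholds,
                                  scenario["indexes"], funnel=funnel)
    return classes, sigs, funnel


@pytest.fixture(scope="module")
def abinitio(scenario, scoring, thresholds):
    funnel = {}
    sigs = ab_initio_scan(scenario["kept"], scenario["genome"],
                          [scenario["te"]], scoring, thresholds,
                          funnel=funnel)
    return sigs, funnel


# ---------------------------------------------------------------------------
# Targeted mode
# ---------------------------------------------------------------------------

def test_targeted_read_classification(targeted):
    classes, _, _ = targeted
    by_id = {c.read_id: c.category for c in classes}
    assert by_id["full_span"] == "full_span"
    assert by_id["split_left"] == "split"
    assert by_id["split_right"] == "split"
    assert by_id["pure_te"] == "full_TE"
    assert "genomic" not in by_id      # never hits the TE query
    assert "junk_break" not in by_id


def test_targeted_signatures_validated_at_the_planted_site(targeted):
    _, sigs, _ = targeted
    assert {s.read_id for s in sigs} == {"full_span", "split_left",
                                         "split_right"}
    for s in sigs:
        assert s.validated
        assert s.chrom == "chr1"
        assert abs(s.breakpoint - 25_000) <= 50
        assert s.orientation == "sense"


def test_targeted_funnel_counts(targeted):
    _, sigs, funnel = targeted
    assert funnel["reads_in"] == 6
    assert funnel["te_hit"] == 4          # full_TE read hits but yields no site
    assert funnel["candidates"] == 3
    assert funnel["validated"] == len(sigs) == 3
    assert (funnel["reads_in"] >= funnel["te_hit"]
            >= funnel["candidates"] >= funnel["validated"])


def test_targeted_single_call_with_full_support(targeted, scenario,
                                                thresholds, scoring):
    _, sigs, _ = targeted
    calls = cluster_calls(sigs, [scenario["te"]], scenario["genome"],
                          thresholds, scoring,
                          reference_copies={scenario["te"].family: []})
    assert len(calls) == 1
    call = calls[0]
    assert call.status == "validated"
    assert call.orientation == "sense"
    assert sorted(r for r, _ in call.support) == ["full_span", "split_left",
                                                  "split_right"]
    assert dict(call.support)["full_span"] == "full_span"
    report = evaluate_against_truth(calls, scenario["truth"])
    assert (report.precision, report.recall) == (1.0, 1.0)
    assert abs(report.offsets[0]) <= 50  # within the evaluation match window


# ---------------------------------------------------------------------------
# Ab initio mode
# ---------------------------------------------------------------------------

def test_abinitio_finds_the_same_junctions(abinitio):
    sigs, _ = abinitio
    assert {s.read_id for s in sigs} == {"full_span", "split_left",
                                         "split_right"}
    for s in sigs:
        assert s.validated and abs(s.breakpoint - 25_000) <= 50
    by_id = {s.read_id: s.category for s in sigs}
    assert by_id["full_span"] == "full_span"  # promoted from split
    assert by_id["split_left"] == "split"


def test_abinitio_rejects_non_te_breakpoints_and_full_blocks(abinitio):
    """Soundness: the fully genomic read (block covers ~100% of it) and the
    junk-breakpoint read (remainder matches no library TE) yield nothing."""
    sigs, funnel = abinitio
    ids = {s.read_id for s in sigs}
    assert "genomic" not in ids and "junk_break" not in ids
    # genomic read fails the <=75%-block filter; junk read passes it but
    # fails the TE-remainder filter
    assert funnel["breakpoint_candidates"] == 4
    assert funnel["te_hit"] == 3
    assert (funnel["reads_in"] >= funnel["breakpoint_candidates"]
            >= funnel["te_hit"] >= funnel["validated"])


def test_abinitio_threshold_monotonicity(scenario, scoring, thresholds):
    """Raising min_te_len or min_block_len never increases signatures."""
    def count(**kw):
        th = DetectionThresholds(**kw)
        return len(ab_initio_scan(scenario["kept"], scenario["genome"],
                                  [scenario["te"]], scoring, th))
    te_counts = [count(min_te_len=v) for v in (200, 1_600, 5_400)]
    assert te_counts == sorted(te_counts, reverse=True)
    block_counts = [count(min_block_len=v) for v in (400, 1_200, 2_600)]
    assert block_counts == sorted(block_counts, reverse=True)


def test_abinitio_requires_te_library(scenario, scoring):
    with pytest.raises(ValueError):
        ab_initio_scan(scenario["kept"], scenario["genome"], [], scoring)


# ---------------------------------------------------------------------------
# Locus-construct validation
# ---------------------------------------------------------------------------

def test_verify_full_span_waiver(targeted, scenario, scoring, thresholds):
    """A full-span read aligns over ~100% of its length; that passes as
    full_span but would fail the 75% cap if treated as a split read."""
    import dataclasses
    _, sigs, _ = targeted
    fs = next(s for s in sigs if s.read_id == "full_span")
    read = next(r for r in scenario["reads"] if r.id == "full_span")
    as_full = verify_locus_construct(fs, scenario["te"], scenario["genome"],
                                     read, scoring, thresholds)
    assert as_full.passed and as_full.two_sided_junction
    assert as_full.fraction_of_read > thresholds.hsp_sum_frac_high
    demoted = dataclasses.replace(fs, category="split", concordance=None)
    as_split = verify_locus_construct(demoted, scenario["te"],
                                      scenario["genome"], read, scoring,
                                      thresholds)
    assert not as_split.passed


def test_verify_respects_min_hsp_sum(targeted, scenario, scoring):
    _, sigs, _ = targeted
    sig = next(s for s in sigs if s.read_id == "split_left")
    read = next(r for r in scenario["reads"] if r.id == "split_left")
    strict = DetectionThresholds(min_hsp_sum=5_000, hsp_sum_frac_high=1.0)
    res = verify_locus_construct(sig, scenario["te"], scenario["genome"],
                                 read, scoring, strict)
    assert not res.passed
    normal = verify_locus_construct(sig, scenario["te"], scenario["genome"],
                                    read, scoring)
    assert normal.passed
    assert normal.hsp_sum > 300
    assert 0.33 <= normal.fraction_of_read <= 0.75


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _sig(bp, read_id, chrom="chr1", family="famX", orientation="sense",
         passed=True):
    return BreakpointSignature(
        read_id=read_id, chrom=chrom, breakpoint=bp, te_family=family,
        te_read_interval=(0, 500), te_aligned_len=500,
        orientation=orientation, junction_side="right", block_qstart=0,
        block_qend=1_000, block_strand="+", remainder=(1_000, 1_500),
        concordance=ConcordanceResult(read_id, 1_000, 0.5, passed, True))


def _empty_env(small_genome):
    return dict(te_library=[], genome=small_genome,
                reference_copies={"famX": []})


def test_cluster_single_linkage_groups(small_genome, thresholds):
    positions = [100, 150, 400, 2_000, 2_050, 2_100, 5_000,
                 9_000, 9_050, 12_000, 20_000]
    sigs = [_sig(bp, f"r{i}") for i, bp in enumerate(positions)]
    calls = cluster_calls(sigs, thresholds=thresholds, **_empty_env(small_genome))
    assert len(calls) == 7
    assert sum(len(c.support) for c in calls) == 11
    # two breakpoints 150 apart stay separate calls
    two = cluster_calls([_sig(1_000, "a"), _sig(1_150, "b")],
                        thresholds=thresholds, **_empty_env(small_genome))
    assert len(two) == 2
    # exactly at the tolerance they merge
    one = cluster_calls([_sig(1_000, "a"), _sig(1_100, "b")],
                        thresholds=thresholds, **_empty_env(small_genome))
    assert len(one) == 1


def test_cluster_permutation_invariance(small_genome, thresholds):
    rand = random.Random(17)
    positions = [100, 130, 180, 5_000, 5_020, 9_999]
    sigs = [_sig(bp, f"r{i}") for i, bp in enumerate(positions)]
    base = cluster_calls(sigs, thresholds=thresholds, **_empty_env(small_genome))
    for _ in range(5):
        shuffled = sigs[:]
        rand.shuffle(shuffled)
        again = cluster_calls(shuffled, thresholds=thresholds,
                              **_empty_env(small_genome))
        assert again == base


def test_cluster_separates_chrom_and_family(small_genome, thresholds):
    sigs = [_sig(1_000, "a"), _sig(1_010, "b", family="famY"),
            _sig(1_000, "c", chrom="chr2")]
    calls = cluster_calls(sigs, thresholds=thresholds, **_empty_env(small_genome))
    assert len(calls) == 3


def test_cluster_orientation_majority_and_status(small_genome, thresholds):
    sigs = [_sig(1_000, "a", orientation="antisense"),
            _sig(1_010, "b", orientation="antisense"),
            _sig(1_020, "c", orientation="sense")]
    call = cluster_calls(sigs, thresholds=thresholds,
                         **_empty_env(small_genome))[0]
    assert call.orientation == "antisense"
    assert call.status == "validated"
    tie = cluster_calls([_sig(1_000, "a", orientation="sense"),
                         _sig(1_010, "b", orientation="antisense")],
                        thresholds=thresholds, **_empty_env(small_genome))[0]
    assert tie.orientation == "unknown"
    mixed = cluster_calls([_sig(1_000, "a"), _sig(1_010, "b", passed=False)],
                          thresholds=thresholds, **_empty_env(small_genome))[0]
    assert mixed.status == "candidate"


# ---------------------------------------------------------------------------
# Reference copies
# ---------------------------------------------------------------------------

def test_find_reference_copies_and_flagging(ltr_te, scoring, thresholds, rng):
    flank_a = random_dna(rng, 10_000)
    flank_b = random_dna(rng, 10_000)
    genome = ReferenceGenome([SequenceRecord(
        "chrR", flank_a + ltr_te.sequence.residues + flank_b)])
    copies = find_reference_copies([ltr_te], genome, scoring)
    loci = copies[ltr_te.family]
    assert len(loci) == 1
    assert abs(loci[0].start - 10_000) <= 10
    assert abs(loci[0].end - 15_300) <= 10
    # a signature at the donor locus is flagged and excluded from scoring
    sig = _sig(10_000, "r0", chrom="chrR", family=ltr_te.family)
    calls = cluster_calls([sig], [ltr_te], genome, thresholds, scoring,
                          reference_copies=copies)
    assert calls[0].is_reference_copy
    report = evaluate_against_truth(calls, [])
    assert report.n_calls == 0 and report.false_positives == 0


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _call(bp, family="famX", chrom="chr1"):
    return InsertionCall(locus=GenomeInterval(chrom, bp, bp + 1),
                         te_family=family, orientation="sense",
                         support=[("r", "split")], status="validated")


def _truth(bp, family="famX", chrom="chr1"):
    from teasv import TruthRecord
    return TruthRecord(chrom, bp, bp, family, "sense", 5, 5_300)


def test_evaluate_exact_and_windowed_matches():
    report = evaluate_against_truth([_call(1_000), _call(5_030)],
                                    [_truth(1_000), _truth(5_000)],
                                    match_window=50)
    assert report.true_positives == 2
    assert (report.precision, report.recall) == (1.0, 1.0)
    assert sorted(report.offsets) == [0, 30]
    assert report.mean_abs_offset == pytest.approx(15.0)


def test_evaluate_window_family_and_chrom_must_match():
    report = evaluate_against_truth(
        [_call(1_060), _call(2_000, family="famY"), _call(3_000, chrom="chr2")],
        [_truth(1_000), _truth(2_000), _truth(3_000)], match_window=50)
    assert report.true_positives == 0
    assert report.false_positives == 3
    assert report.false_negatives == 3


def test_evaluate_each_truth_matches_once_nearest_first():
    report = evaluate_against_truth([_call(1_010), _call(1_040)],
                                    [_truth(1_000)], match_window=50)
    assert report.true_positives == 1
    assert report.false_positives == 1
    assert report.offsets == [10]  # the nearer call wins


def test_evaluate_empty_edge_cases():
    empty = evaluate_against_truth([], [])
    assert (empty.precision, empty.recall) == (1.0, 1.0)
    miss = evaluate_against_truth([], [_truth(1_000)])
    assert miss.recall == 0.0
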