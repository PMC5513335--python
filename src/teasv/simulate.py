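"""Synthetic genomes, planted TE insertions, and nanopore-like noisy reads.

The generator emulates the regime the detection method was designed for:
single-molecule reads with ~13% total error (half mismatches, a quarter
insertions, a quarter deletions), log-normal lengths with a 4.6 kb median,
drawn from a genome carrying planted insertions of a 5.3-kb LTR-
retrotransposon-like element with terminal repeats and a short target-site
duplication.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import (GenomeInterval, ReferenceGenome, SequenceRecord,
                      TELibraryEntry, revcomp)

logger = logging.getLogger("teasv.simulate")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulatedGenomeSpec:
    """I.i.d. random genome: chromosome lengths, GC content, seed."""

    chrom_lengths: tuple = (1_000_000,)
    gc_fraction: float = 0.36
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc_fraction < 1):
            raise ValueError("gc_fraction must be in (0, 1)")
        if any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")


@dataclass(frozen=True)
class InsertionPlan:
    """One planned TE insertion (or cut-and-paste move)."""

    te_family: str
    chrom: str
    position: int                    # insertion point, 0-based, pre-insertion
    orientation: str = "sense"       # {"sense", "antisense"}
    tsd_length: int = 5
    mechanism: str = "copy_paste"    # {"copy_paste", "cut_paste"}
    donor: Optional[GenomeInterval] = None  # excised for cut_paste

    def __post_init__(self) -> None:
        if self.orientation not in ("sense", "antisense"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.mechanism not in ("copy_paste", "cut_paste"):
            raise ValueError(f"bad mechanism {self.mechanism!r}")
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        if self.position < self.tsd_length:
            raise ValueError("position must leave room for the TSD")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one executed insertion.

    ``position`` is the first base of the TE in post-insertion (mutated)
    coordinates; ``ref_position`` is the insertion point in the original
    reference, the space in which calls are made.
    """

    chrom: str
    position: int
    ref_position: int
    te_family: str
    orientation: str
    tsd_length: int
    te_length: int


@dataclass(frozen=True)
class ReadErrorModel:
    """Per-base error process and read-length distribution.

    Lengths are log-normal, parameterized by the median and the log-scale
    spread sigma.  The default spread (0.6) keeps the mean near the
    median, matching a run whose usable reads cluster around 4.6 kb
    without a heavy tail of very long molecules; sub-500-bp junk reads of
    a real flow cell are not emulated.
    """

    total_error: float = 0.13
    mismatch_share: float = 0.5
    insertion_share: float = 0.25
    deletion_share: float = 0.25
    median_length: float = 4_600.0
    sigma: float = 0.6
    min_length: int = 100
    max_length: int = 50_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.total_error <= 0.3):
            raise ValueError("total_error must be in [0, 0.3]")
        shares = self.mismatch_share + self.insertion_share + self.deletion_share
        if abs(shares - 1.0) > 1e-9:
            raise ValueError("error shares must sum to 1")


@dataclass(frozen=True)
class CoverageTarget:
    """Stop condition for read simulation: total coverage or read count."""

    mode: str = "coverage_x"  # {"coverage_x", "n_reads"}
    value: float = 0.8

    def __post_init__(self) -> None:
        if self.mode not in ("coverage_x", "n_reads"):
            raise ValueError(f"bad coverage mode {self.mode!r}")
        if self.value <= 0:
            raise ValueError("coverage target must be positive")


# ---------------------------------------------------------------------------
# Genome and TE generation
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1 - gc) / 2
    p = np.array([at, gc / 2, gc / 2, at])
    return "".join(rng.choice(_BASES, size=length, p=p))


def simulate_genome(spec: SimulatedGenomeSpec) -> ReferenceGenome:
    """Random i.i.d. genome; identical spec + seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    records = [
        SequenceRecord(f"chr{i + 1}", _random_dna(rng, L, spec.gc_fraction))
        for i, L in enumerate(spec.chrom_lengths)
    ]
    return ReferenceGenome(records)


def make_synthetic_ltr_te(seed: int, family: str = "simLTR1",
                          length: int = 5_300, ltr_length: int = 400,
                          gc: float = 0.36) -> TELibraryEntry:
    """A synthetic LTR-retrotransposon-like element.

    Random internal sequence bracketed by two identical terminal repeats,
    mimicking the structure of an active COPIA-family element.  The
    sequence is generated, not taken from any real TE.
    """
    rng = np.random.default_rng(seed)
    ltr = _random_dna(rng, ltr_length, gc)
    internal = _random_dna(rng, length - 2 * ltr_length, gc)
    seq = ltr + internal + ltr
    return TELibraryEntry(family, "LTR_retrotransposon",
                          SequenceRecord(family, seq), ltr_length)


def make_synthetic_dna_te(seed: int, family: str = "simCACTA1",
                          length: int = 4_000, gc: float = 0.36
                          ) -> TELibraryEntry:
    """A synthetic cut-and-paste DNA-transposon-like element."""
    rng = np.random.default_rng(seed)
    return TELibraryEntry(family, "DNA_transposon",
                          SequenceRecord(family, _random_dna(rng, length, gc)))


# ---------------------------------------------------------------------------
# Insertion planting
# ---------------------------------------------------------------------------

def plant_insertions(genome: ReferenceGenome,
                     te_library: Sequence[TELibraryEntry],
                     plans: Sequence[InsertionPlan]
                     ) -> tuple[ReferenceGenome, list[TruthRecord]]:
    """Apply insertion plans, returning the mutated genome and truth.

    At each target the TE sequence (reverse complemented for antisense)
    is inserted with the ``tsd_length`` bases preceding the site
    duplicated after the element.  copy_paste leaves any donor intact;
    cut_paste also excises the stated donor interval.  Truth positions
    are expressed in mutated-genome space (plus the reference-space
    insertion point for evaluation).
    """
    by_family = {t.family: t for t in te_library}
    per_chrom: dict[str, list[InsertionPlan]] = {}
    for p in plans:
        if p.te_family not in by_family:
            raise ValueError(f"unknown TE family {p.te_family!r}")
        if p.chrom not in genome:
            raise KeyError(f"unknown chromosome {p.chrom!r}")
        per_chrom.setdefault(p.chrom, []).append(p)
    excisions: dict[str, list[GenomeInterval]] = {}
    for p in plans:
        if p.mechanism == "cut_paste" and p.donor is not None:
            excisions.setdefault(p.donor.chrom, []).append(p.donor)
    new_records: list[SequenceRecord] = []
    for rec in genome:
        chrom_plans = sorted(per_chrom.get(rec.id, []),
                             key=lambda p: p.position)
        for a, b in zip(chrom_plans, chrom_plans[1:]):
            if a.position == b.position:
                raise ValueError(f"overlapping plans at {rec.id}:{a.position}")
        cuts = sorted(excisions.get(rec.id, []), key=lambda iv: iv.start)
        # edit list: (pos, kind, plan-or-interval), applied left to right
        edits: list[tuple[int, str, object]] = (
            [(p.position, "ins", p) for p in chrom_plans]
            + [(iv.start, "del", iv) for iv in cuts])
        edits.sort(key=lambda e: e[0])
        seq = rec.residues
        parts: list[str] = []
        cursor = 0
        for pos, kind, obj in edits:
            if pos < cursor:
                raise ValueError("overlapping edits")
            parts.append(seq[cursor:pos])
            if kind == "ins":
                plan = obj
                te_seq = by_family[plan.te_family].sequence.residues
                if plan.orientation == "antisense":
                    te_seq = revcomp(te_seq)
                tsd = seq[pos - plan.tsd_length: pos] if plan.tsd_length else ""
                parts.append(te_seq + tsd)
                cursor = pos
            else:
                cursor = obj.end
        parts.append(seq[cursor:])
        new_records.append(SequenceRecord(rec.id, "".join(parts), rec.description))
    truth = _recompute_truth_positions(genome, plans, by_family)
    truth.sort(key=lambda t: (t.chrom, t.ref_position))
    return ReferenceGenome(new_records), truth


def _recompute_truth_positions(genome, plans, by_family) -> list[TruthRecord]:
    """Mutated-space coordinates of each planted TE.

    Walks the edits per chromosome in order, accumulating length offsets;
    kept separate from the sequence assembly so the bookkeeping can be
    cross-checked against junction extraction in tests.
    """
    truth: list[TruthRecord] = []
    per_chrom: dict[str, list[InsertionPlan]] = {}
    for p in plans:
        per_chrom.setdefault(p.chrom, []).append(p)
    excisions: dict[str, list[GenomeInterval]] = {}
    for p in plans:
        if p.mechanism == "cut_paste" and p.donor is not None:
            excisions.setdefault(p.donor.chrom, []).append(p.donor)
    for chrom, chrom_plans in per_chrom.items():
        edits: list[tuple[int, str, object]] = (
            [(p.position, "ins", p) for p in chrom_plans]
            + [(iv.start, "del", iv) for iv in excisions.get(chrom, [])])
        edits.sort(key=lambda e: e[0])
        offset = 0
        for pos, kind, obj in edits:
            if kind == "ins":
                plan = obj
                te_len = len(by_family[plan.te_family].sequence)
                truth.append(TruthRecord(
                    chrom=chrom, position=pos + offset, ref_position=pos,
                    te_family=plan.te_family, orientation=plan.orientation,
                    tsd_length=plan.tsd_length, te_length=te_len))
                offset += te_len + plan.tsd_length
            else:
                offset -= obj.length()
    return truth


def random_insertion_plans(genome: ReferenceGenome, te: TELibraryEntry,
                           n: int, seed: int, min_separation: int = 20_000,
                           edge_margin: int = 10_000,
                           tsd_length: Optional[int] = None
                           ) -> list[InsertionPlan]:
    """n well-separated random insertion sites for one TE family.

    Sites are kept >= min_separation apart (about twice the read-length
    scale) so junctions are separable, and away from chromosome ends.
    """
    if tsd_length is None:
        tsd_length = 5 if te.te_class == "LTR_retrotransposon" else 3
    rng = np.random.default_rng(seed)
    chroms = [(r.id, len(r)) for r in genome]
    total = sum(L for _, L in chroms)
    plans: list[InsertionPlan] = []
    attempts = 0
    while len(plans) < n:
        attempts += 1
        if attempts > 10_000 * n:
            raise RuntimeError("cannot place insertions with the requested "
                               "separation; genome too small")
        x = rng.integers(0, total)
        for chrom, L in chroms:
            if x < L:
                break
            x -= L
        pos = int(x)
        if pos < edge_margin or pos > L - edge_margin:
            continue
        if any(p.chrom == chrom and abs(p.position - pos) < min_separation
               for p in plans):
            continue
        orientation = "sense" if rng.random() < 0.5 else "antisense"
        plans.append(InsertionPlan(te.family, chrom, pos, orientation,
                                   tsd_length))
    plans.sort(key=lambda p: (p.chrom, p.position))
    return plans


def write_truth_bed(truth: Sequence[TruthRecord], path) -> None:
    """Truth as BED6 in reference coordinates; the mutated-space position
    travels in the name field."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for t in truth:
            strand = "+" if t.orientation == "sense" else "-"
            name = (f"{t.te_family};mut_pos={t.position};"
                    f"tsd={t.tsd_length};te_len={t.te_length}")
            fh.write(f"{t.chrom}\t{t.ref_position}\t{t.ref_position + 1}\t"
                     f"{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, model: ReadErrorModel,
                  rng: np.random.Generator) -> str:
    if model.total_error == 0.0 or not seq:
        return seq
    p_mis = model.total_error * model.mismatch_share
    p_ins = model.total_error * model.insertion_share
    p_del = model.total_error * model.deletion_share
    u = rng.random(len(seq))
    out: list[str] = []
    bases = "ACGT"
    for i, c in enumerate(seq):
        x = u[i]
        if x < p_mis:
            choices = [b for b in bases if b != c] if c in bases else list(bases)
            out.append(choices[int(rng.integers(0, len(choices)))])
        elif x < p_mis + p_ins:
            out.append(c)
            out.append(bases[int(rng.integers(0, 4))])
        elif x < p_mis + p_ins + p_del:
            continue
        else:
            out.append(c)
    return "".join(out)


def parse_read_origin(read_id: str) -> tuple[str, int, int, str]:
    """Decode (chrom, start, end, strand) from a simulated read id."""
    _, chrom, span, strand = read_id.split(":")
    start, end = span.split("-")
    return chrom, int(start), int(end), strand


def simulate_reads(genome: ReferenceGenome, target: CoverageTarget,
                   model: ReadErrorModel, seed: int
                   ) -> list[SequenceRecord]:
    """Noisy long reads from a genome, uniform start positions.

    Read ids encode the true error-free origin as
    ``sim_<i>:<chrom>:<start>-<end>:<strand>`` (coordinates on the input
    genome), so evaluation can recover which junctions each read spans.
    """
    rng = np.random.default_rng(seed)
    chroms = [(r.id, r.residues) for r in genome]
    lengths = np.array([len(s) for _, s in chroms], dtype=np.int64)
    total = int(lengths.sum())
    if total < model.min_length:
        raise ValueError("genome shorter than the minimum read length")
    probs = lengths / total
    if target.mode == "coverage_x":
        target_bases = target.value * total
        max_reads = None
    else:
        target_bases = None
        max_reads = int(target.value)
    mu = np.log(model.median_length)
    reads: list[SequenceRecord] = []
    drawn_bases = 0
    i = 0
    while True:
        if max_reads is not None and len(reads) >= max_reads:
            break
        if target_bases is not None and drawn_bases >= target_bases:
            break
        ci = int(rng.choice(len(chroms), p=probs))
        chrom, seq = chroms[ci]
        L = int(np.exp(rng.normal(mu, model.sigma)))
        L = max(model.min_length, min(L, model.max_length))
        if L >= len(seq):
            start = 0
        else:
            start = int(rng.integers(0, len(seq) - L + 1))
        end = min(start + L, len(seq))
        fragment = seq[start:end]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = revcomp(fragment)
        noisy = _apply_errors(fragment, model, rng)
        if len(noisy) == 0:
            continue
        rid = f"sim_{i}:{chrom}:{start}-{end}:{strand}"
        reads.append(SequenceRecord(rid, noisy))
        drawn_bases += end - start
        i += 1
    logger.info("simulated %d reads, %d source bases (%.2fX of %d bp)",
                len(reads), drawn_bases, drawn_bases / total, total)
    return reads


# ---------------------------------------------------------------------------
# Qualifying-junction analysis (read-origin truth)
# ---------------------------------------------------------------------------

def read_is_detectable(t: TruthRecord, rs: int, re_: int,
                       thresholds=None,
                       noise_margin: float = 0.1,
                       noise_pad: int = 25) -> bool:
    """Would this read's error-free geometry survive the detection filters?

    Judged purely from the read's origin interval [rs, re_) on the mutated
    genome against one planted insertion: the best genomic block is the
    longer flank, the TE portion is the overlap with the element, and the
    concordance fraction is predicted from the +/-1 kb locus window.  The
    deterministic thresholds (minimum block, block-fraction cap, minimum
    TE length, HSP-sum window, full-span waiver) are applied with a small
    allowance for error-induced alignment-endpoint noise.
    """
    from .detect import DetectionThresholds

    th = thresholds or DetectionThresholds()
    te_lo = t.position
    te_hi = t.position + t.te_length
    L = re_ - rs
    a = min(max(0, te_lo - rs), L)          # left genomic flank in the read
    b = min(max(0, re_ - te_hi), L)         # right genomic flank
    te_cov = max(0, min(re_, te_hi) - max(rs, te_lo))
    min_flank = th.min_block_len * (1 + noise_margin) + noise_pad
    min_te = th.min_te_len * (1 + noise_margin) + noise_pad
    if te_cov < min_te or max(a, b) < min_flank:
        return False
    block = max(a, b)
    if block > (th.max_block_frac - 0.02) * L:
        return False
    # predicted HSP sum against the locus-window + TE construct
    min_hsp = 40
    sum_pred = te_cov
    for flank in (a, b):
        if flank >= min_hsp:
            sum_pred += min(flank, th.flank_pad)
    if sum_pred <= th.min_hsp_sum * (1 + noise_margin) + noise_pad:
        return False
    frac = sum_pred / L
    full_span = (te_cov >= t.te_length and a >= th.full_span_min_flank * 2
                 and b >= th.full_span_min_flank * 2)
    if frac < th.hsp_sum_frac_low + 0.02:
        return False
    if not full_span and frac > th.hsp_sum_frac_high - 0.02:
        return False
    return True


def qualifying_insertions(truth: Sequence[TruthRecord],
                          reads: Sequence[SequenceRecord],
                          thresholds=None) -> list[int]:
    """Indices of truth records with at least one detectable read.

    Detectability is decided from read-origin truth alone via
    :func:`read_is_detectable`; no alignment is involved.
    """
    out: list[int] = []
    for ti, t in enumerate(truth):
        found = False
        for r in reads:
            chrom, rs, re_, _ = parse_read_origin(r.id)
            if chrom != t.chrom:
                continue
            if read_is_detectable(t, rs, re_, thresholds):
                found = True
                break
        if found:
            out.append(ti)
    return out


# ---------------------------------------------------------------------------
# End-to-end benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkConfig:
    """One fully seeded end-to-end experiment."""

    chrom_lengths: tuple = (1_000_000,)
    gc_fraction: float = 0.36
    n_insertions: int = 10
    te_length: int = 5_300
    ltr_length: int = 400
    tsd_length: int = 5
    coverage: CoverageTarget = field(default_factory=CoverageTarget)
    error_model: ReadErrorModel = field(default_factory=ReadErrorModel)
    seed: int = 0
    match_window: int = 50
    run_targeted: bool = False


def run_benchmark(config: BenchmarkConfig) -> dict:
    """simulate -> plant -> read -> qc -> detect -> evaluate, fully seeded.

    Returns a JSON-serializable report with funnel counts, qc summary,
    precision, recall and per-insertion breakpoint offsets.
    """
    from .align import ScoringScheme, build_genome_indexes
    from .detect import (DetectionThresholds, ab_initio_scan, cluster_calls,
                         evaluate_against_truth, targeted_scan)
    from .qc import filter_genomic_reads, summarize_reads

    seed = int(config.seed) % (2 ** 31)
    scoring = ScoringScheme()
    thresholds = DetectionThresholds()
    spec = SimulatedGenomeSpec(tuple(config.chrom_lengths),
                               config.gc_fraction, seed)
    genome = simulate_genome(spec)
    te = make_synthetic_ltr_te(seed + 1009, length=config.te_length,
                               ltr_length=config.ltr_length,
                               gc=config.gc_fraction)
    library = [te]
    plans = random_insertion_plans(genome, te, config.n_insertions,
                                   seed + 2003, tsd_length=config.tsd_length)
    mutated, truth = plant_insertions(genome, library, plans)
    reads = simulate_reads(mutated, config.coverage, config.error_model,
                           seed + 3001)
    indexes = build_genome_indexes(genome, scoring)
    kept = filter_genomic_reads(reads, genome, scoring,
                                thresholds.min_genomic_frac, indexes)
    qc_summary = summarize_reads(kept, genome, n_total=len(reads))
    funnel: dict = {}
    signatures = ab_initio_scan(kept, genome, library, scoring, thresholds,
                                funnel=funnel)
    calls = cluster_calls(signatures, library, genome, thresholds, scoring,
                          reference_copies={te.family: []})
    report_eval = evaluate_against_truth(calls, truth, config.match_window)
    qualifying = qualifying_insertions(truth, reads, thresholds)
    report = {
        "seed": seed,
        "n_reads": len(reads),
        "n_kept": len(kept),
        "coverage_x": qc_summary.coverage_x,
        "median_read_length": qc_summary.median_length,
        "mean_identity_pct": qc_summary.mean_identity_pct,
        "funnel": funnel,
        "n_truth": len(truth),
        "n_calls": report_eval.n_calls,
        "precision": report_eval.precision,
        "recall": report_eval.recall,
        "mean_abs_offset": report_eval.mean_abs_offset,
        "offsets": report_eval.offsets,
        "n_qualifying_insertions": len(qualifying),
        "qualifying_recall": (
            len(set(report_eval.matched_truth_ids) & set(qualifying))
            / len(qualifying) if qualifying else 1.0),
    }
    if config.run_targeted:
        tf: dict = {}
        _, tsigs = targeted_scan(te, [f.read for f in kept], genome, scoring,
                                 thresholds, indexes, funnel=tf)
        tcalls = cluster_calls(tsigs, library, genome, thresholds, scoring,
                               reference_copies={te.family: []})
        teval = evaluate_against_truth(tcalls, truth, config.match_window)
        report["targeted"] = {
            "funnel": tf,
            "n_calls": teval.n_calls,
            "precision": teval.precision,
            "recall": teval.recall,
        }
        report["targeted_loci"] = sorted(
            (c.locus.chrom, c.locus.start) for c in tcalls)
        report["abinitio_loci"] = sorted(
            (c.locus.chrom, c.locus.start) for c in calls
            if c.te_family == te.family)
    return report
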