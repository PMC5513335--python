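"""Split-read detection of TE insertion polymorphisms from long reads.

Two modes mirror the two strategies of the underlying method:

* **targeted**: a known TE query is searched against the reads; TE-hit
  reads are classified (fully-TE / split / full-span), split and
  full-span reads are located on the reference, and each candidate locus
  is re-validated against a flank+TE construct.
* **ab initio**: every read is aligned to the reference; reads whose best
  contiguous genomic block covers at least ``min_block_len`` bases but at
  most ``max_block_frac`` of the read are similarity-breakpoint
  candidates.  The unaligned remainder is searched against a TE library,
  and candidates with >= ``min_te_len`` TE sequence are re-validated the
  same way.

Validation replaces the manual dot-plot inspection of the original
workflow with a quantitative concordance score: the read is re-aligned to
the concatenation of the +/-1 kb insertion-locus window and the TE
sequence, and must align over more than ``min_hsp_sum`` bases amounting
to 33-75% of its length (full-span reads are exempt from the upper
bound, since flank+TE+flank reads legitimately align almost entirely).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import (BlockChain, HSP, ScoringScheme, align_to_genome,
                    build_genome_indexes, chain_blocks,
                    interval_union_length, local_align)
from .core_io import (GenomeInterval, ReferenceGenome, SequenceRecord,
                      TELibraryEntry, extract_window)

logger = logging.getLogger("teasv.detect")


@dataclass(frozen=True)
class DetectionThresholds:
    """All tunable cutoffs of the detection pipelines (lengths in bp)."""

    min_block_len: int = 400       # minimum contiguous genomic block
    max_block_frac: float = 0.75   # genomic block may cover at most this read fraction
    min_te_len: int = 200          # minimum TE alignment in the remainder
    locus_window: int = 2_000      # re-validation window spanning the site
    min_hsp_sum: int = 300         # strict lower bound on summed HSP length
    hsp_sum_frac_low: float = 0.33
    hsp_sum_frac_high: float = 0.75
    flank_pad: int = 1_000         # +/- flank extracted around the breakpoint
    cluster_tolerance: int = 100   # breakpoints this close merge into one call
    min_genomic_frac: float = 0.20
    chain_max_gap: int = 50        # HSP chaining gap defining "contiguous"
    full_te_frac: float = 0.95     # TE coverage above which a read is fully-TE
    full_span_min_flank: int = 50  # minimal genomic flank on each side

    def __post_init__(self) -> None:
        if not (0 < self.hsp_sum_frac_low < self.hsp_sum_frac_high <= 1):
            raise ValueError("need 0 < frac_low < frac_high <= 1")
        for name in ("min_block_len", "min_te_len", "locus_window",
                     "min_hsp_sum", "flank_pad", "cluster_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ConcordanceResult:
    """Outcome of re-aligning a read to the locus+TE construct."""

    read_id: str
    hsp_sum: int
    fraction_of_read: float
    passed: bool
    two_sided_junction: bool
    window_clipped: bool = False


@dataclass
class BreakpointSignature:
    """Per-read evidence for one insertion junction."""

    read_id: str
    chrom: str
    breakpoint: int              # reference coordinate of the junction
    te_family: str
    te_read_interval: tuple      # (start, end) of the TE segment on the read
    te_aligned_len: int
    orientation: str             # {"sense", "antisense", "unknown"}
    junction_side: str           # {"left", "right", "both"}
    block_qstart: int
    block_qend: int
    block_strand: str
    remainder: tuple             # (start, end) of the unaligned remainder
    category: str = "split"      # {"split", "full_span"}
    concordance: Optional[ConcordanceResult] = None

    @property
    def validated(self) -> bool:
        return self.concordance is not None and self.concordance.passed


@dataclass
class ReadTEClass:
    """Classification of one TE-hit read."""

    read_id: str
    category: str  # {"full_TE", "split", "full_span", "none"}
    te_segments: list = field(default_factory=list)
    flank_segments: list = field(default_factory=list)


@dataclass
class InsertionCall:
    """Clustered, validated TE insertion locus."""

    locus: GenomeInterval
    te_family: str
    orientation: str             # {"sense", "antisense", "unknown"}
    support: list                # [(read_id, category), ...]
    status: str = "candidate"    # {"candidate", "validated"}
    is_reference_copy: bool = False

    @property
    def breakpoint(self) -> int:
        return (self.locus.start + self.locus.end - 1) // 2


@dataclass
class EvaluationReport:
    """Precision/recall of calls against planted-insertion truth."""

    n_calls: int
    n_truth: int
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    mean_abs_offset: float
    offsets: list = field(default_factory=list)
    matched_truth_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _te_union(hsps: Sequence[HSP]) -> int:
    return interval_union_length([(h.qstart, h.qend) for h in hsps])


def _best_te_family(segment: SequenceRecord, te_library, scoring,
                    min_te_len: int):
    """Best TE-library match of a read segment.

    Returns (family, union_len, strand, (qstart, qend)) in segment
    coordinates, or None when no family reaches ``min_te_len``.
    """
    best = None
    for entry in te_library:
        hsps = local_align(segment, entry.sequence, scoring)
        if not hsps:
            continue
        union = _te_union(hsps)
        if union < min_te_len:
            continue
        score = sum(h.score for h in hsps)
        plus = sum(h.score for h in hsps if h.strand == "+")
        strand = "+" if plus * 2 >= score else "-"
        span = (min(h.qstart for h in hsps), max(h.qend for h in hsps))
        if best is None or score > best[4]:
            best = (entry.family, union, strand, span, score)
    if best is None:
        return None
    return best[:4]


def _breakpoint_from_chain(chain: BlockChain, side: str) -> int:
    """Reference coordinate of the junction at one end of a genomic block.

    ``side`` is the read-coordinate side ("left" = junction before the
    block, "right" = after).  A reverse-strand block swaps the mapping.
    """
    if chain.strand == "+":
        return chain.sstart if side == "left" else chain.send
    return chain.send if side == "left" else chain.sstart


def _orientation(block_strand: str, te_strand: str) -> str:
    return "sense" if block_strand == te_strand else "antisense"


# ---------------------------------------------------------------------------
# Locus re-validation
# ---------------------------------------------------------------------------

def verify_locus_construct(signature: BreakpointSignature,
                           te: TELibraryEntry,
                           genome: ReferenceGenome,
                           read: SequenceRecord,
                           scoring: Optional[ScoringScheme] = None,
                           thresholds: Optional[DetectionThresholds] = None
                           ) -> ConcordanceResult:
    """Re-align a read to the flank+TE construct and score concordance.

    The construct is the +/- flank_pad window around the breakpoint
    concatenated with the TE sequence.  The HSP-length sum is the union
    of the read's aligned intervals against the construct.
    """
    scoring = scoring or ScoringScheme()
    thresholds = thresholds or DetectionThresholds()
    chrom_len = genome.chrom_length(signature.chrom)
    bp = signature.breakpoint
    lo = max(0, bp - thresholds.flank_pad)
    hi = min(chrom_len, bp + thresholds.flank_pad)
    clipped = (lo != bp - thresholds.flank_pad) or (hi != bp + thresholds.flank_pad)
    window = extract_window(
        genome, GenomeInterval(signature.chrom, max(lo, 0), max(hi, lo + 1)), 0)
    construct = SequenceRecord(
        f"construct_{signature.chrom}_{bp}_{te.family}",
        window.residues + te.sequence.residues)
    hsps = local_align(read, construct, scoring)
    hsp_sum = interval_union_length([(h.qstart, h.qend) for h in hsps])
    frac = hsp_sum / len(read)
    # junction coverage on the read: genomic-window HSPs on one side of the
    # read breakpoint, TE-part HSPs on the other, each within 50 bp
    window_len = len(window.residues)
    qbp = (signature.block_qend
           if signature.junction_side in ("right", "both")
           else signature.block_qstart)
    win_hsps = [h for h in hsps if h.sstart < window_len]
    te_hsps = [h for h in hsps if h.send > window_len]
    near = 50
    win_near = any(h.qstart - near <= qbp <= h.qend + near for h in win_hsps)
    te_near = any(h.qstart - near <= qbp <= h.qend + near for h in te_hsps)
    two_sided = bool(win_near and te_near)
    frac_ok = frac >= thresholds.hsp_sum_frac_low and (
        signature.category == "full_span"
        or frac <= thresholds.hsp_sum_frac_high)
    passed = hsp_sum > thresholds.min_hsp_sum and frac_ok
    if signature.category == "full_span":
        passed = passed and two_sided
    return ConcordanceResult(read_id=read.id, hsp_sum=hsp_sum,
                             fraction_of_read=frac, passed=passed,
                             two_sided_junction=two_sided,
                             window_clipped=clipped)


# ---------------------------------------------------------------------------
# Targeted mode
# ---------------------------------------------------------------------------

def targeted_scan(te: TELibraryEntry,
                  reads: Sequence[SequenceRecord],
                  genome: ReferenceGenome,
                  scoring: Optional[ScoringScheme] = None,
                  thresholds: Optional[DetectionThresholds] = None,
                  indexes: Optional[dict] = None,
                  funnel: Optional[dict] = None
                  ) -> tuple[list[ReadTEClass], list[BreakpointSignature]]:
    """Search a known TE against the reads and map its new insertions.

    Each TE-hit read is classified full_TE / split / full_span; split and
    full-span reads yield BreakpointSignatures which are re-validated
    against the locus construct.  Only validated signatures are returned.
    """
    scoring = scoring or ScoringScheme()
    thresholds = thresholds or DetectionThresholds()
    if indexes is None:
        indexes = build_genome_indexes(genome, scoring)
    classes: list[ReadTEClass] = []
    signatures: list[BreakpointSignature] = []
    n_hit = n_candidate = 0
    for read in reads:
        te_hsps = local_align(read, te.sequence, scoring)
        if not te_hsps:
            continue
        n_hit += 1
        te_cov = _te_union(te_hsps)
        te_lo = min(h.qstart for h in te_hsps)
        te_hi = max(h.qend for h in te_hsps)
        te_segments = [(te_lo, te_hi)]
        if te_cov >= thresholds.full_te_frac * len(read):
            classes.append(ReadTEClass(read.id, "full_TE", te_segments, []))
            continue
        plus = sum(h.score for h in te_hsps if h.strand == "+")
        total = sum(h.score for h in te_hsps)
        te_strand = "+" if plus * 2 >= total else "-"
        genomic = align_to_genome(read, genome, scoring, indexes)
        chains = chain_blocks(genomic, thresholds.chain_max_gap) if genomic else []
        min_flank = thresholds.full_span_min_flank
        left = [c for c in chains
                if c.qend <= te_lo + _SEG_TOL and te_lo - c.qstart >= min_flank]
        right = [c for c in chains
                 if c.qstart >= te_hi - _SEG_TOL and c.qend - te_hi >= min_flank]
        sig = None
        if left and right:
            lbest = max(left, key=lambda c: c.total_score)
            rbest = max(right, key=lambda c: c.total_score)
            if _same_locus(lbest, rbest, thresholds):
                n_candidate += 1
                bp = _breakpoint_from_chain(lbest, "right")
                sig = BreakpointSignature(
                    read_id=read.id, chrom=lbest.subject_id, breakpoint=bp,
                    te_family=te.family, te_read_interval=(te_lo, te_hi),
                    te_aligned_len=te_cov,
                    orientation=_orientation(lbest.strand, te_strand),
                    junction_side="both",
                    block_qstart=lbest.qstart, block_qend=lbest.qend,
                    block_strand=lbest.strand,
                    remainder=(te_lo, te_hi), category="full_span")
                classes.append(ReadTEClass(
                    read.id, "full_span", te_segments,
                    [(lbest.qstart, lbest.qend), (rbest.qstart, rbest.qend)]))
        if sig is None:
            split = _split_signature(read, chains, te.family, te_strand,
                                     te_lo, te_hi, te_cov, thresholds)
            if split is not None:
                n_candidate += 1
                sig = split
                classes.append(ReadTEClass(
                    read.id, "split", te_segments,
                    [(sig.block_qstart, sig.block_qend)]))
            else:
                classes.append(ReadTEClass(read.id, "none", te_segments, []))
        if sig is not None:
            sig.concordance = verify_locus_construct(
                sig, te, genome, read, scoring, thresholds)
            if sig.validated:
                signatures.append(sig)
    if funnel is not None:
        funnel.update({"reads_in": len(reads), "te_hit": n_hit,
                       "candidates": n_candidate,
                       "validated": len(signatures)})
    logger.info("targeted %s: %d reads, %d TE-hit, %d candidates, "
                "%d validated", te.family, len(reads), n_hit, n_candidate,
                len(signatures))
    return classes, signatures


_SEG_TOL = 100  # tolerated overlap between TE and flank segments on the read


def _same_locus(left: BlockChain, right: BlockChain,
                thresholds: DetectionThresholds) -> bool:
    """Do two flank blocks bracket one insertion site on the reference?"""
    if left.subject_id != right.subject_id or left.strand != right.strand:
        return False
    gap_tol = 2 * thresholds.cluster_tolerance
    if left.strand == "+":
        return abs(right.sstart - left.send) <= gap_tol
    return abs(left.sstart - right.send) <= gap_tol


def _split_signature(read, chains, family, te_strand, te_lo, te_hi, te_cov,
                     thresholds) -> Optional[BreakpointSignature]:
    """Signature for a read with a TE segment on one side of a genomic block."""
    left = [c for c in chains if c.qend <= te_lo + _SEG_TOL
            and c.joined_query_span >= thresholds.full_span_min_flank]
    right = [c for c in chains if c.qstart >= te_hi - _SEG_TOL
             and c.joined_query_span >= thresholds.full_span_min_flank]
    candidates = []
    for c in left:
        candidates.append((c, "right"))   # junction after the block
    for c in right:
        candidates.append((c, "left"))    # junction before the block
    if not candidates:
        return None
    chain, side = max(candidates, key=lambda cs: cs[0].total_score)
    bp = _breakpoint_from_chain(chain, "right" if side == "right" else "left")
    remainder = ((chain.qend, te_hi) if side == "right" else (te_lo, chain.qstart))
    return BreakpointSignature(
        read_id=read.id, chrom=chain.subject_id, breakpoint=bp,
        te_family=family, te_read_interval=(te_lo, te_hi),
        te_aligned_len=te_cov,
        orientation=_orientation(chain.strand, te_strand),
        junction_side=side,
        block_qstart=chain.qstart, block_qend=chain.qend,
        block_strand=chain.strand, remainder=remainder, category="split")


# ---------------------------------------------------------------------------
# Ab initio mode
# ---------------------------------------------------------------------------

def ab_initio_scan(kept_reads,
                   genome: ReferenceGenome,
                   te_library: Sequence[TELibraryEntry],
                   scoring: Optional[ScoringScheme] = None,
                   thresholds: Optional[DetectionThresholds] = None,
                   funnel: Optional[dict] = None
                   ) -> list[BreakpointSignature]:
    """Discover insertions of any library TE from similarity breakpoints.

    ``kept_reads`` is the output of qc.filter_genomic_reads (FilteredRead
    objects carrying their genomic HSPs).  Per read: (1) the best
    contiguous genomic block must span >= min_block_len bases and at most
    max_block_frac of the read; (2) the remainder must align to some
    library TE over >= min_te_len bases; (3) the locus construct must
    pass concordance.  Only passing signatures are returned.
    """
    scoring = scoring or ScoringScheme()
    thresholds = thresholds or DetectionThresholds()
    if not te_library:
        raise ValueError("ab initio detection requires a non-empty TE library")
    te_by_family = {t.family: t for t in te_library}
    signatures: list[BreakpointSignature] = []
    n_block = n_tehit = 0
    for fr in kept_reads:
        read = fr.read
        if not fr.hsps:
            continue
        chains = chain_blocks(fr.hsps, thresholds.chain_max_gap)
        best = chains[0]
        span = best.joined_query_span
        if span < thresholds.min_block_len:
            continue
        if span > thresholds.max_block_frac * len(read):
            continue
        n_block += 1
        sig = _remainder_signature(read, best, te_library, scoring, thresholds)
        if sig is None:
            continue
        n_tehit += 1
        _promote_full_span(sig, chains, thresholds)
        sig.concordance = verify_locus_construct(
            sig, te_by_family[sig.te_family], genome, read, scoring, thresholds)
        if sig.validated:
            signatures.append(sig)
    if funnel is not None:
        funnel.update({"reads_in": len(kept_reads),
                       "breakpoint_candidates": n_block,
                       "te_hit": n_tehit, "validated": len(signatures)})
    logger.info("ab initio: %d reads, %d breakpoint candidates, %d TE-hit, "
                "%d validated", len(kept_reads), n_block, n_tehit,
                len(signatures))
    return signatures


def _remainder_signature(read, chain: BlockChain, te_library, scoring,
                         thresholds) -> Optional[BreakpointSignature]:
    """Align the read's non-block remainder to the TE library."""
    pieces = []
    if chain.qstart > 0:
        pieces.append(("left", 0, chain.qstart))
    if chain.qend < len(read):
        pieces.append(("right", chain.qend, len(read)))
    best = None
    for side, lo, hi in pieces:
        if hi - lo < thresholds.min_te_len:
            continue
        segment = SequenceRecord(read.id, read.residues[lo:hi])
        hit = _best_te_family(segment, te_library, scoring,
                              thresholds.min_te_len)
        if hit is None:
            continue
        family, union, strand, (sq_lo, sq_hi) = hit
        if best is None or union > best[1]:
            best = (family, union, strand, (lo + sq_lo, lo + sq_hi), side, (lo, hi))
    if best is None:
        return None
    family, union, te_strand, te_iv, side, remainder = best
    # junction sits at the block edge facing the TE segment
    junction_side = "right" if side == "right" else "left"
    bp = _breakpoint_from_chain(chain, junction_side)
    return BreakpointSignature(
        read_id=read.id, chrom=chain.subject_id, breakpoint=bp,
        te_family=family, te_read_interval=te_iv, te_aligned_len=union,
        orientation=_orientation(chain.strand, te_strand),
        junction_side=junction_side,
        block_qstart=chain.qstart, block_qend=chain.qend,
        block_strand=chain.strand, remainder=remainder, category="split")


def _promote_full_span(sig: BreakpointSignature, chains, thresholds) -> None:
    """Reclassify a split signature as full_span when a second genomic
    chain brackets the TE segment on the opposite side at the same locus.

    A full-span read (flank + entire TE + flank) legitimately aligns over
    almost all of its length to the locus construct, so validation treats
    the category differently.
    """
    te_lo, te_hi = sig.te_read_interval
    min_flank = thresholds.full_span_min_flank
    for c in chains:
        if c.subject_id != sig.chrom or c.strand != sig.block_strand:
            continue
        if sig.junction_side == "right":
            # block is left of the TE; look for a chain right of it
            opposite = (c.qstart >= te_hi - _SEG_TOL
                        and c.qend - te_hi >= min_flank)
            ref_gap = (abs(c.sstart - sig.breakpoint) if sig.block_strand == "+"
                       else abs(sig.breakpoint - c.send))
        else:
            opposite = (c.qend <= te_lo + _SEG_TOL
                        and te_lo - c.qstart >= min_flank)
            ref_gap = (abs(sig.breakpoint - c.send) if sig.block_strand == "+"
                       else abs(c.sstart - sig.breakpoint))
        if opposite and ref_gap <= 2 * thresholds.cluster_tolerance:
            sig.category = "full_span"
            return


# ---------------------------------------------------------------------------
# Clustering and evaluation
# ---------------------------------------------------------------------------

def find_reference_copies(te_library, genome: ReferenceGenome,
                          scoring: Optional[ScoringScheme] = None,
                          min_cover_frac: float = 0.5) -> dict:
    """Self-detect pre-existing library TE copies in the reference.

    Returns {family: [GenomeInterval, ...]} for loci where a chain of the
    TE-vs-genome alignment covers at least ``min_cover_frac`` of the
    element.
    """
    scoring = scoring or ScoringScheme()
    out: dict[str, list[GenomeInterval]] = {}
    for entry in te_library:
        loci: list[GenomeInterval] = []
        for rec in genome:
            hsps = local_align(entry.sequence, rec, scoring)
            for chain in chain_blocks(hsps, max_gap=200):
                if chain.joined_query_span >= min_cover_frac * len(entry.sequence):
                    loci.append(GenomeInterval(rec.id, chain.sstart, chain.send))
        out[entry.family] = loci
    return out


def cluster_calls(signatures: Sequence[BreakpointSignature],
                  te_library: Sequence[TELibraryEntry],
                  genome: ReferenceGenome,
                  thresholds: Optional[DetectionThresholds] = None,
                  scoring: Optional[ScoringScheme] = None,
                  reference_copies: Optional[dict] = None
                  ) -> list[InsertionCall]:
    """Merge validated signatures into insertion calls.

    Signatures on the same chromosome, for the same family, whose
    breakpoints lie within ``cluster_tolerance`` of their neighbours
    (single linkage on sorted positions) form one call.  Calls at a
    library TE's pre-existing reference locus are flagged.
    """
    thresholds = thresholds or DetectionThresholds()
    if reference_copies is None:
        reference_copies = find_reference_copies(te_library, genome, scoring)
    ordered = sorted(signatures,
                     key=lambda s: (s.chrom, s.te_family, s.breakpoint, s.read_id))
    calls: list[InsertionCall] = []
    group: list[BreakpointSignature] = []

    def flush(group):
        if not group:
            return
        bps = [s.breakpoint for s in group]
        chrom = group[0].chrom
        locus = GenomeInterval(chrom, min(bps), max(bps) + 1)
        orients = [s.orientation for s in group]
        n_sense = orients.count("sense")
        n_anti = orients.count("antisense")
        if n_sense > n_anti:
            orientation = "sense"
        elif n_anti > n_sense:
            orientation = "antisense"
        else:
            orientation = "unknown"
        family = group[0].te_family
        is_ref = any(
            locus.overlaps(ref, slop=thresholds.cluster_tolerance)
            for ref in reference_copies.get(family, []))
        calls.append(InsertionCall(
            locus=locus, te_family=family, orientation=orientation,
            support=sorted((s.read_id, s.category) for s in group),
            status="validated" if all(s.validated for s in group) else "candidate",
            is_reference_copy=is_ref))

    for sig in ordered:
        if (group and sig.chrom == group[-1].chrom
                and sig.te_family == group[-1].te_family
                and sig.breakpoint - group[-1].breakpoint
                <= thresholds.cluster_tolerance):
            group.append(sig)
        else:
            flush(group)
            group = [sig]
    flush(group)
    calls.sort(key=lambda c: (c.locus.chrom, c.locus.start, c.te_family))
    return calls


def evaluate_against_truth(calls: Sequence[InsertionCall],
                           truth,
                           match_window: int = 50) -> EvaluationReport:
    """Score calls against planted-insertion ground truth.

    A call is a true positive when a truth record on the same chromosome
    and family lies within ``match_window`` of its breakpoint (reference
    coordinates); each truth record matches at most once, nearest first.
    Calls flagged as reference copies are not neo-insertions and are
    excluded from scoring.
    """
    neo = [c for c in calls if not c.is_reference_copy]
    pairs = []
    for ci, c in enumerate(neo):
        for ti, t in enumerate(truth):
            if c.locus.chrom != t.chrom or c.te_family != t.te_family:
                continue
            off = c.breakpoint - t.ref_position
            if abs(off) <= match_window:
                pairs.append((abs(off), ci, ti, off))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    offsets = []
    matched_truth = []
    for _, ci, ti, off in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        offsets.append(off)
        matched_truth.append(ti)
    tp = len(used_c)
    fp = len(neo) - tp
    fn = len(truth) - len(used_t)
    return EvaluationReport(
        n_calls=len(neo), n_truth=len(truth),
        true_positives=tp, false_positives=fp, false_negatives=fn,
        precision=tp / len(neo) if neo else 1.0,
        recall=tp / len(truth) if truth else 1.0,
        mean_abs_offset=(sum(abs(o) for o in offsets) / len(offsets)
                         if offsets else 0.0),
        offsets=offsets, matched_truth_ids=sorted(matched_truth))
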