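"""Read-set characterization and the relative copy-number (ddCt) utility.

A read set is characterized against a reference genome the way a noisy
long-read pilot run would be: keep reads whose genomic alignments cover at
least 20% of their length, then summarize lengths, identity and effective
genome coverage from the kept alignments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .align import (HSP, ScoringScheme, align_to_genome,
                    build_genome_indexes, interval_union_length,
                    mean_identity)
from .core_io import ReferenceGenome, SequenceRecord

logger = logging.getLogger("teasv.qc")


@dataclass
class ReadQCSummary:
    """Summary statistics of a genomically filtered read set."""

    n_reads: int
    n_kept: int
    total_bases: int
    median_length: int
    fraction_in_range: float  # fraction of kept reads in [500, 15000]
    mean_identity_pct: float
    coverage_x: float

    RANGE = (500, 15_000)


@dataclass(frozen=True)
class QPCRMeasurement:
    """Raw Ct values for the relative-quantification arithmetic.

    The calibrator sample is assumed to carry ``calibrator_copies`` copies
    of the target (the wild type's two copies by default).
    """

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float
    calibrator_copies: float = 2.0

    def __post_init__(self) -> None:
        for v in (self.ct_target_sample, self.ct_reference_sample,
                  self.ct_target_calibrator, self.ct_reference_calibrator):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"Ct values must be finite and positive, got {v}")


@dataclass
class FilteredRead:
    """A kept read with its genomic alignment evidence."""

    read: SequenceRecord
    hsps: list
    aligned_fraction: float

    @property
    def aligned_bases(self) -> int:
        return interval_union_length([(h.qstart, h.qend) for h in self.hsps])


def filter_genomic_reads(reads: Sequence[SequenceRecord],
                         genome: ReferenceGenome,
                         scoring: Optional[ScoringScheme] = None,
                         min_fraction: float = 0.20,
                         indexes: Optional[dict] = None) -> list[FilteredRead]:
    """Keep reads whose genomic HSPs cover >= min_fraction of their length.

    Coverage of a read is the union of its HSP query intervals over all
    chromosomes and both strands; the boundary is inclusive ("at least").
    """
    if scoring is None:
        scoring = ScoringScheme()
    if indexes is None:
        indexes = build_genome_indexes(genome, scoring)
    kept: list[FilteredRead] = []
    for read in reads:
        hsps = align_to_genome(read, genome, scoring, indexes)
        frac = interval_union_length(
            [(h.qstart, h.qend) for h in hsps]) / len(read)
        if frac >= min_fraction:
            kept.append(FilteredRead(read=read, hsps=hsps,
                                     aligned_fraction=frac))
    logger.info("genomic filter: %d/%d reads kept (min_fraction=%.2f)",
                len(kept), len(reads), min_fraction)
    return kept


def median_lower(values: Sequence[int]) -> int:
    """Median without interpolation: the lower of the two central values
    for even n.  Deterministic across platforms."""
    if not values:
        return 0
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def summarize_reads(kept: Sequence[FilteredRead],
                    genome: ReferenceGenome,
                    n_total: Optional[int] = None) -> ReadQCSummary:
    """Characterize a filtered read set against its reference genome.

    Coverage is estimated from aligned bases of kept reads over the genome
    length; identity is the unweighted mean over all genomic HSPs.
    """
    if genome.total_length <= 0:
        raise ValueError("genome length must be positive")
    n_total = n_total if n_total is not None else len(kept)
    if not kept:
        return ReadQCSummary(n_total, 0, 0, 0, 0.0, 0.0, 0.0)
    lengths = [len(f.read) for f in kept]
    lo, hi = ReadQCSummary.RANGE
    in_range = sum(1 for L in lengths if lo <= L <= hi)
    all_hsps = [h for f in kept for h in f.hsps]
    aligned = sum(f.aligned_bases for f in kept)
    return ReadQCSummary(
        n_reads=n_total,
        n_kept=len(kept),
        total_bases=sum(lengths),
        median_length=median_lower(lengths),
        fraction_in_range=in_range / len(kept),
        mean_identity_pct=mean_identity(all_hsps) if all_hsps else 0.0,
        coverage_x=aligned / genome.total_length,
    )


def gene_presence_check(genes: Sequence[SequenceRecord],
                        kept: Sequence[FilteredRead],
                        scoring: Optional[ScoringScheme] = None) -> dict:
    """Which of a set of unique genes are touched by at least one read.

    A gene counts as present when any kept read produces an HSP of at
    least ``min_hsp_length`` against it.  Returns
    {gene_id: (present, [supporting read ids])}.
    """
    from .align import local_align

    if scoring is None:
        scoring = ScoringScheme()
    result: dict[str, tuple[bool, list[str]]] = {}
    for gene in genes:
        support: list[str] = []
        for f in kept:
            hsps = local_align(f.read, gene, scoring)
            if any(h.aligned_columns >= scoring.min_hsp_length for h in hsps):
                support.append(f.read.id)
        result[gene.id] = (bool(support), support)
    return result


def ddct_copy_number(m: QPCRMeasurement) -> float:
    """Relative copy number by the 2^-ddCt method.

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator);
    the result is calibrator_copies * 2^-ddCt, so a sample identical to
    the calibrator reports exactly the calibrator's copy count.
    """
    ddct = ((m.ct_target_sample - m.ct_reference_sample)
            - (m.ct_target_calibrator - m.ct_reference_calibrator))
    return m.calibrator_copies * 2.0 ** (-ddct)
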