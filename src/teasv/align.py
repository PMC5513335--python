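"""Seeded, affine-gap local alignment producing HSPs, plus block chaining.

The aligner mirrors a nucleotide BLAST-style search tuned for noisy long
reads: reward +2, mismatch -3, gap open 5, gap extend 2 (a gap of length L
costs 5 + 2L).  Small problems are solved exactly over the full dynamic-
programming matrix; large ones are seeded with exact k-mers, bucketed by
diagonal, and extended with a banded Gotoh kernel, so the same recurrence
underlies both paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from numba import njit

from .core_io import SequenceRecord, revcomp

NEG_INF = -(10 ** 9)
MASK_SCORE = -(10 ** 6)  # substitution score against a masked position

# base codes: A=0 C=1 G=2 T=3 N=4, mask=5
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as int8 codes (anything odd becomes N)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring and HSP-reporting parameters.

    Penalties are positive costs.  ``min_hsp_score`` / ``min_hsp_length``
    replace E-value significance with deterministic, database-size-
    independent cutoffs.
    """

    match_reward: int = 2
    mismatch_penalty: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    min_hsp_score: int = 50
    min_hsp_length: int = 40
    # seeding / extension parameters
    seed_k: int = 11
    band: int = 100
    xdrop: int = 100
    min_seeds: int = 4
    seed_diag_gap: int = 20
    max_band_width: int = 800
    exact_cells: int = 2_000_000  # below this, solve the full matrix exactly
    max_exact_hsps: int = 16

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if min(self.mismatch_penalty, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties are positive costs")
        if self.min_hsp_length < self.seed_k:
            raise ValueError("min_hsp_length must be >= seed length")


@dataclass(frozen=True)
class HSP:
    """One gapped local-alignment segment (high-scoring segment pair).

    Query and subject intervals are 0-based half-open.  For strand '-',
    the query interval is given on the original (forward) query sequence
    and the subject interval is ascending as usual.
    """

    query_id: str
    subject_id: str
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str
    score: int
    aligned_columns: int
    matches: int
    gaps: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.aligned_columns

    @property
    def qlength(self) -> int:
        return self.qend - self.qstart

    @property
    def slength(self) -> int:
        return self.send - self.sstart


@dataclass
class BlockChain:
    """Co-linear, same-strand HSPs joined into one contiguous block."""

    hsps: list
    max_internal_gap: int

    @property
    def subject_id(self) -> str:
        return self.hsps[0].subject_id

    @property
    def strand(self) -> str:
        return self.hsps[0].strand

    @property
    def qstart(self) -> int:
        return min(h.qstart for h in self.hsps)

    @property
    def qend(self) -> int:
        return max(h.qend for h in self.hsps)

    @property
    def sstart(self) -> int:
        return min(h.sstart for h in self.hsps)

    @property
    def send(self) -> int:
        return max(h.send for h in self.hsps)

    @property
    def total_score(self) -> int:
        return sum(h.score for h in self.hsps)

    @property
    def joined_query_span(self) -> int:
        """Union length of member query intervals."""
        return interval_union_length([(h.qstart, h.qend) for h in self.hsps])


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length covered by a set of half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_lo: Optional[int] = None
    cur_hi = 0
    for lo, hi in ivs:
        if cur_lo is None or lo > cur_hi:
            if cur_lo is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_lo is not None:
        total += cur_hi - cur_lo
    return total


# ---------------------------------------------------------------------------
# Gotoh kernels
# ---------------------------------------------------------------------------
# Banded local alignment over diagonals d = j - i in [dlo, dhi], where i
# indexes the query and j the subject.  Band coordinate w = j - i - dlo.
# Pointer codes for H: 0 stop, 1 diagonal, 2 from E (gap consuming subject),
# 3 from F (gap consuming query).  E/F pointers: 0 opened from H, 1 extended.

@njit(cache=True)
def _gotoh_banded(q, s, dlo, dhi, match, mismatch, gopen, gext, xdrop):
    m = q.size
    n = s.size
    W = dhi - dlo + 1
    # pointer packing: bits 0-1 H move (0 stop, 1 diag, 2 from E, 3 from F),
    # bit 2 E extended, bit 3 F extended
    P = np.zeros((m, W), dtype=np.uint8)
    prevH = np.full(W, NEG_INF, dtype=np.int64)
    prevF = np.full(W, NEG_INF, dtype=np.int64)
    curH = np.full(W, NEG_INF, dtype=np.int64)
    curF = np.full(W, NEG_INF, dtype=np.int64)
    best = 0
    bi = -1
    bj = -1
    for i in range(m):
        jlo = max(0, i + dlo)
        jhi = min(n - 1, i + dhi)
        row_best = NEG_INF
        if jlo > jhi:
            continue
        h_left = NEG_INF  # H(i, j-1)
        e_left = NEG_INF  # E(i, j-1)
        a = q[i]
        for j in range(jlo, jhi + 1):
            w = j - i - dlo
            b = s[j]
            if a >= 5 or b >= 5:
                sub = MASK_SCORE
            elif a == 4 or b == 4 or a != b:
                sub = -mismatch
            else:
                sub = match
            if i == 0 or j == 0:
                diag = sub  # alignment may start here (baseline 0)
            else:
                ph = prevH[w]
                diag = ph + sub if ph > NEG_INF else NEG_INF
            ptr = np.uint8(0)
            # E: gap consuming subject (left move), same row
            e_val = NEG_INF
            if w > 0 and j > jlo:
                open_e = h_left - gopen - gext if h_left > NEG_INF else NEG_INF
                ext_e = e_left - gext if e_left > NEG_INF else NEG_INF
                if ext_e > open_e:
                    e_val = ext_e
                    ptr |= np.uint8(4)
                else:
                    e_val = open_e
            # F: gap consuming query (up move), previous row, w+1
            f_val = NEG_INF
            if i > 0 and w + 1 < W:
                ph_up = prevH[w + 1]
                pf_up = prevF[w + 1]
                open_f = ph_up - gopen - gext if ph_up > NEG_INF else NEG_INF
                ext_f = pf_up - gext if pf_up > NEG_INF else NEG_INF
                if ext_f > open_f:
                    f_val = ext_f
                    ptr |= np.uint8(8)
                else:
                    f_val = open_f
            h = 0
            move = np.uint8(0)
            if diag > h:
                h = diag
                move = np.uint8(1)
            if e_val > h:
                h = e_val
                move = np.uint8(2)
            if f_val > h:
                h = f_val
                move = np.uint8(3)
            curH[w] = h
            curF[w] = f_val
            P[i, w] = ptr | move
            h_left = h
            e_left = e_val
            if h > row_best:
                row_best = h
            if h > best:
                best = h
                bi = i
                bj = j
        # out-of-range band cells must not leak into the next row
        if jlo > i + dlo:
            for w in range(0, jlo - i - dlo):
                curH[w] = NEG_INF
                curF[w] = NEG_INF
        if jhi < i + dhi:
            for w in range(jhi - i - dlo + 1, W):
                curH[w] = NEG_INF
                curF[w] = NEG_INF
        prevH, curH = curH, prevH
        prevF, curF = curF, prevF
        if best > 0 and row_best < best - xdrop and i > bi:
            break
    return best, bi, bj, P


def _traceback(bi, bj, dlo, q, s, P):
    """Pointer walk from the best cell (H state) to the local start."""
    i, j = bi, bj
    cols = matches = gaps = 0
    state = 0  # 0=H, 1=E, 2=F
    while True:
        w = j - i - dlo
        p = P[i, w]
        if state == 0:
            move = p & 3
            if move == 1:
                cols += 1
                if q[i] == s[j] and q[i] < 4:
                    matches += 1
                i -= 1
                j -= 1
                if i < 0 or j < 0:
                    break
            elif move == 2:
                state = 1
            elif move == 3:
                state = 2
            else:  # stop
                return i + 1, bi + 1, j + 1, bj + 1, cols, matches, gaps
        elif state == 1:  # E, consumed subject base
            cols += 1
            gaps += 1
            if not (p & 4):
                state = 0
            j -= 1
        else:  # F, consumed query base
            cols += 1
            gaps += 1
            if not (p & 8):
                state = 0
            i -= 1
    return i + 1, bi + 1, j + 1, bj + 1, cols, matches, gaps


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

class SeedIndex:
    """Exact k-mer index of one subject sequence.

    Build once per subject (e.g. the reference genome) and reuse across
    queries.  k-mers containing N are never indexed, so ambiguity
    characters cannot seed an alignment.
    """

    def __init__(self, subject: SequenceRecord, k: int = 11):
        self.subject = subject
        self.k = k
        self.codes = encode(subject.residues)
        self._index: dict[int, list[int]] = {}
        kmers = _rolling_kmers(self.codes, k)
        for pos, km in enumerate(kmers):
            if km >= 0:
                self._index.setdefault(km, []).append(pos)

    def hits(self, query_codes: np.ndarray) -> list[tuple[int, int]]:
        """(query_pos, subject_pos) pairs of exact k-mer matches."""
        out: list[tuple[int, int]] = []
        for qpos, km in enumerate(_rolling_kmers(query_codes, self.k)):
            if km < 0:
                continue
            positions = self._index.get(km)
            if positions:
                for spos in positions:
                    out.append((qpos, spos))
        return out


def _rolling_kmers(codes: np.ndarray, k: int) -> list[int]:
    """2-bit rolling k-mer codes; -1 where the window contains N."""
    n = codes.size
    if n < k:
        return []
    out = [-1] * (n - k + 1)
    mask = (1 << (2 * k)) - 1
    km = 0
    valid = 0  # run length of non-N bases ending here
    for i in range(n):
        c = int(codes[i])
        if c >= 4:
            valid = 0
            km = 0
            continue
        km = ((km << 2) | c) & mask
        valid += 1
        if valid >= k:
            out[i - k + 1] = km
    return out


def _nonoverlapping_seeds(cluster: Sequence[tuple[int, int]], k: int) -> int:
    """Seeds covering distinct query k-mers (a single exact match of
    length k+t produces t+1 overlapping hits; those count once)."""
    count = 0
    last = -(10 ** 9)
    for qpos, _ in sorted(cluster):
        if qpos >= last + k:
            count += 1
            last = qpos
    return count


def _cluster_seeds(hits: Sequence[tuple[int, int]], diag_gap: int,
                   query_gap: int) -> list[list[tuple[int, int]]]:
    """Group seed hits into diagonal buckets.

    Hits are first grouped by diagonal (d = spos - qpos) allowing drift up
    to ``diag_gap`` between consecutive diagonals, then split where the
    query positions jump by more than ``query_gap``.
    """
    if not hits:
        return []
    by_diag = sorted(hits, key=lambda h: (h[1] - h[0], h[0]))
    groups: list[list[tuple[int, int]]] = []
    cur = [by_diag[0]]
    for h in by_diag[1:]:
        if (h[1] - h[0]) - (cur[-1][1] - cur[-1][0]) <= diag_gap:
            cur.append(h)
        else:
            groups.append(cur)
            cur = [h]
    groups.append(cur)
    out: list[list[tuple[int, int]]] = []
    for g in groups:
        g.sort(key=lambda h: h[0])
        run = [g[0]]
        for h in g[1:]:
            if h[0] - run[-1][0] <= query_gap:
                run.append(h)
            else:
                out.append(run)
                run = [h]
        out.append(run)
    return out


# ---------------------------------------------------------------------------
# local_align
# ---------------------------------------------------------------------------

_EXT_MARGIN = 500  # extension allowance beyond the outermost seeds


def _align_one_strand(q_codes, s_codes, query_id, subject_id, strand,
                      scoring: ScoringScheme, index: Optional[SeedIndex],
                      orig_qlen: int) -> list[HSP]:
    m, n = q_codes.size, s_codes.size
    hsps: list[HSP] = []
    if m == 0 or n == 0:
        return hsps
    if m * n <= scoring.exact_cells:
        hsps.extend(_exact_hsps(q_codes, s_codes, query_id, subject_id,
                                strand, scoring, orig_qlen))
        return hsps
    if index is None:
        index = SeedIndex(SequenceRecord(subject_id, _decode(s_codes)),
                          scoring.seed_k)
    hits = index.hits(q_codes)
    clusters = _cluster_seeds(hits, diag_gap=scoring.seed_diag_gap,
                              query_gap=1000)
    for cluster in clusters:
        if _nonoverlapping_seeds(cluster, scoring.seed_k) < scoring.min_seeds:
            continue
        qpos = [h[0] for h in cluster]
        diags = [h[1] - h[0] for h in cluster]
        qlo = max(0, min(qpos) - _EXT_MARGIN)
        qhi = min(m, max(qpos) + scoring.seed_k + _EXT_MARGIN)
        dlo = min(diags) - scoring.band
        dhi = max(diags) + scoring.band
        if dhi - dlo + 1 > scoring.max_band_width:
            # clip a runaway band around the median seed diagonal
            dmed = sorted(diags)[len(diags) // 2]
            half = scoring.max_band_width // 2
            dlo = dmed - half
            dhi = dmed + half
        slo = max(0, qlo + dlo)
        shi = min(n, qhi + dhi)
        if shi <= slo:
            continue
        sub_q = q_codes[qlo:qhi]
        sub_s = s_codes[slo:shi]
        # band diagonals in sub-coordinates
        b_dlo = dlo - slo + qlo
        b_dhi = dhi - slo + qlo
        b_dlo = max(b_dlo, -(sub_q.size - 1))
        b_dhi = min(b_dhi, sub_s.size - 1)
        if b_dhi < b_dlo:
            continue
        best, bi, bj, P = _gotoh_banded(
            sub_q, sub_s, b_dlo, b_dhi,
            scoring.match_reward, scoring.mismatch_penalty,
            scoring.gap_open, scoring.gap_extend, scoring.xdrop)
        if best < scoring.min_hsp_score or bi < 0:
            continue
        qs, qe, ss, se, cols, matches, gaps = _traceback(
            bi, bj, b_dlo, sub_q, sub_s, P)
        if cols < scoring.min_hsp_length:
            continue
        hsps.append(_make_hsp(query_id, subject_id, strand,
                              qlo + qs, qlo + qe, slo + ss, slo + se,
                              best, cols, matches, gaps, orig_qlen))
    return _dedup(hsps)


def _exact_hsps(q_codes, s_codes, query_id, subject_id, strand,
                scoring: ScoringScheme, orig_qlen: int) -> list[HSP]:
    """Full-matrix search; repeated best-HSP extraction with masking."""
    s_work = s_codes.copy()
    m = q_codes.size
    out: list[HSP] = []
    full_dlo = -(m - 1)
    full_dhi = s_codes.size - 1
    for _ in range(scoring.max_exact_hsps):
        best, bi, bj, P = _gotoh_banded(
            q_codes, s_work, full_dlo, full_dhi,
            scoring.match_reward, scoring.mismatch_penalty,
            scoring.gap_open, scoring.gap_extend, 10 ** 9)
        if best < scoring.min_hsp_score or bi < 0:
            break
        qs, qe, ss, se, cols, matches, gaps = _traceback(
            bi, bj, full_dlo, q_codes, s_work, P)
        if cols >= scoring.min_hsp_length:
            out.append(_make_hsp(query_id, subject_id, strand, qs, qe, ss, se,
                                 best, cols, matches, gaps, orig_qlen))
        s_work[ss:se] = 5  # mask and search for the next HSP
        if se <= ss:
            break
    return out


def _make_hsp(query_id, subject_id, strand, qs, qe, ss, se, score,
              cols, matches, gaps, orig_qlen) -> HSP:
    if strand == "-":
        qs, qe = orig_qlen - qe, orig_qlen - qs
    return HSP(query_id=query_id, subject_id=subject_id,
               qstart=qs, qend=qe, sstart=ss, send=se, strand=strand,
               score=int(score), aligned_columns=cols, matches=matches,
               gaps=gaps)


def _dedup(hsps: list[HSP]) -> list[HSP]:
    seen = set()
    out = []
    for h in sorted(hsps, key=lambda x: (-x.score, x.qstart, x.sstart)):
        key = (h.qstart, h.qend, h.sstart, h.send, h.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(h)
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join("ACGTNN"[c] for c in codes)


def local_align(query: SequenceRecord, subject: SequenceRecord,
                scoring: Optional[ScoringScheme] = None,
                index: Optional[SeedIndex] = None,
                strands: str = "+-") -> list[HSP]:
    """All HSPs of query vs subject above the reporting thresholds.

    Both strands are searched by default (the reverse complement of the
    query against the forward subject).  Results are sorted by descending
    score, ties broken by query then subject start; deterministic for
    fixed inputs.
    """
    if scoring is None:
        scoring = ScoringScheme()
    if len(query) == 0 or len(subject) == 0:
        raise ValueError("query and subject must be non-empty")
    s_codes = index.codes if index is not None else encode(subject.residues)
    orig_qlen = len(query)
    hsps: list[HSP] = []
    if "+" in strands:
        q_codes = encode(query.residues)
        hsps.extend(_align_one_strand(q_codes, s_codes, query.id, subject.id,
                                      "+", scoring, index, orig_qlen))
    if "-" in strands:
        rc_codes = encode(revcomp(query.residues))
        hsps.extend(_align_one_strand(rc_codes, s_codes, query.id, subject.id,
                                      "-", scoring, index, orig_qlen))
    hsps.sort(key=lambda h: (-h.score, h.qstart, h.sstart))
    return hsps


def align_to_genome(query: SequenceRecord, genome, scoring: ScoringScheme,
                    indexes: Optional[dict] = None) -> list[HSP]:
    """Align one read against every chromosome of a ReferenceGenome.

    ``indexes`` maps chromosome id -> SeedIndex, built once by the caller
    for repeated queries.
    """
    out: list[HSP] = []
    for rec in genome:
        idx = indexes.get(rec.id) if indexes else None
        out.extend(local_align(query, rec, scoring, index=idx))
    out.sort(key=lambda h: (-h.score, h.subject_id, h.qstart, h.sstart))
    return out


def build_genome_indexes(genome, scoring: ScoringScheme) -> dict:
    """SeedIndex per chromosome, keyed by chromosome id."""
    return {rec.id: SeedIndex(rec, scoring.seed_k) for rec in genome}


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

_CHAIN_OVERLAP_TOL = 25  # allowed overlap between successive HSPs


def chain_blocks(hsps: Sequence[HSP], max_gap: int = 50) -> list[BlockChain]:
    """Greedy score-ordered chaining of co-linear same-strand HSPs.

    Every input HSP is assigned to exactly one chain.  Two successive
    HSPs chain when their query gap and subject gap are each <= max_gap
    (small overlaps are tolerated) and their subject order agrees with
    the query order for the shared strand.
    """
    if not hsps:
        return []
    qid = hsps[0].query_id
    if any(h.query_id != qid for h in hsps):
        raise ValueError("chain_blocks expects HSPs from a single query")
    order = sorted(hsps, key=lambda h: (-h.score, h.qstart, h.sstart))
    chains: list[list[HSP]] = []
    for h in order:
        placed = False
        for chain in chains:
            if _fits_chain(chain, h, max_gap):
                chain.append(h)
                chain.sort(key=lambda x: x.qstart)
                placed = True
                break
        if not placed:
            chains.append([h])
    result = [BlockChain(hsps=c, max_internal_gap=max_gap) for c in chains]
    result.sort(key=lambda c: (-c.total_score, c.qstart, c.sstart))
    return result


def _fits_chain(chain: list[HSP], h: HSP, max_gap: int) -> bool:
    first = chain[0]
    if h.subject_id != first.subject_id or h.strand != first.strand:
        return False
    members = sorted(chain + [h], key=lambda x: x.qstart)
    pos = members.index(h)
    for other, lower_is_prev in ((members[pos - 1], True) if pos > 0 else (None, True),
                                 (members[pos + 1], False) if pos + 1 < len(members) else (None, False)):
        if other is None:
            continue
        prev, nxt = (other, h) if lower_is_prev else (h, other)
        qgap = nxt.qstart - prev.qend
        if qgap > max_gap or qgap < -_CHAIN_OVERLAP_TOL:
            return False
        if h.strand == "+":
            sgap = nxt.sstart - prev.send
        else:
            sgap = prev.sstart - nxt.send
        if sgap > max_gap or sgap < -_CHAIN_OVERLAP_TOL:
            return False
    return True


# ---------------------------------------------------------------------------
# Identity statistics / HSP table
# ---------------------------------------------------------------------------

def mean_identity(hsps: Sequence[HSP], weighted: bool = False) -> float:
    """Mean percent identity over HSPs.

    Unweighted arithmetic mean by default; ``weighted=True`` weights each
    HSP by its aligned columns.
    """
    if not hsps:
        raise ValueError("mean_identity of an empty HSP set is undefined")
    if weighted:
        total_cols = sum(h.aligned_columns for h in hsps)
        return 100.0 * sum(h.matches for h in hsps) / total_cols
    return sum(h.identity_pct for h in hsps) / len(hsps)


def write_hsps_tsv(hsps: Sequence[HSP], path) -> None:
    """12-column tabular dump (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for h in hsps:
            mismatches = h.aligned_columns - h.matches - h.gaps
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.subject_id, f"{h.identity_pct:.2f}",
                h.aligned_columns, mismatches, h.gaps,
                h.qstart + 1, h.qend, h.sstart + 1, h.send,
                h.strand, h.score)) + "\n")
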