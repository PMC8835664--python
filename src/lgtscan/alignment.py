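"""Deterministic seed-and-extend local alignment and read-pair fate logic.

The pipeline's two-pass extraction (align to host, keep half-mapped pairs,
realign to bacterial references) only needs, per mate, the best local
alignment against a reference set and a mapped/unmapped verdict. The
aligner here provides exactly that: exact k-mer seeding on both strands,
followed by affine-gap Smith-Waterman extension in a window around each
seeded diagonal. Only a single primary hit is reported per mate;
supplementary or secondary alignments are never produced or consulted.

Scoring: a gap of length g scores ``gap_open + g * gap_extend`` (both
negative). Ties between equal-scoring hits are broken deterministically:
lexicographically smallest reference id, then smallest start, then the
forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from numba import njit

from .io_formats import ReadPairRecord, SequenceRecord

__all__ = [
    "AlignerParams",
    "AlignmentHit",
    "PairFate",
    "ReferenceIndex",
    "align_mate",
    "classify_pair_fate",
    "extract_half_mapped",
    "revcomp",
    "iter_half_mapped_sam",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignerParams:
    """Seeding and affine-gap scoring parameters.

    Defaults mirror bwa-mem's scoring (match +1, mismatch -4, gap open -6,
    gap extend -1, minimum reported score 30, 15-mer seeds) so behaviour on
    synthetic reads is familiar.
    """

    seed_k: int = 15
    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_score: int = 30

    def __post_init__(self) -> None:
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive and mismatch negative")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


@dataclass(frozen=True)
class AlignmentHit:
    """Primary local alignment of one mate against one reference set.

    ``aligned_read_bases`` counts read bases in match/mismatch columns,
    the numerator of the alignment-coverage filter.
    """

    read_id: str
    mate_index: int
    ref_id: str
    start: int
    end: int
    strand: str
    aligned_read_bases: int
    score: int
    is_primary: bool = True


class PairFate:
    """Mapping fate of a pair against one reference set."""

    BOTH = "BOTH"
    MATE1_ONLY = "MATE1_ONLY"
    MATE2_ONLY = "MATE2_ONLY"
    NEITHER = "NEITHER"


# base encoding: ACGT -> 1..4; anything else (incl. N) -> codes that never
# compare equal between query and reference, so N is always a mismatch
_Q_LUT = np.zeros(256, dtype=np.uint8) + 5
_R_LUT = np.zeros(256, dtype=np.uint8) + 6
for _i, _b in enumerate("ACGT", start=1):
    _Q_LUT[ord(_b)] = _i
    _R_LUT[ord(_b)] = _i


def _encode(seq: str, lut: np.ndarray) -> np.ndarray:
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_extend(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Affine-gap local DP with traceback.

    Returns (score, r_beg, r_end, q_beg, q_end, aligned_read_bases) of the
    best local alignment, preferring (on score ties during traceback-cell
    selection) the smallest reference end then smallest query end.
    """
    m = q.shape[0]
    n = r.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -10**9, dtype=np.int32)  # gap consumes query
    F = np.full((m + 1, n + 1), -10**9, dtype=np.int32)  # gap consumes ref
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop,1 diag,2 up,3 left
    pe = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 if E extends E
    pf = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 if F extends F

    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = match if qi == r[j - 1] else mismatch
            e_open = H[i - 1, j] + gap_open + gap_extend
            e_ext = E[i - 1, j] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                pe[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i, j - 1] + gap_open + gap_extend
            f_ext = F[i, j - 1] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                pf[i, j] = 1
            else:
                F[i, j] = f_open
            h = H[i - 1, j - 1] + s
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0
    # traceback
    i, j = bi, bj
    aligned = 0
    state = 0  # 0 in H, 2 in E, 3 in F
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                aligned += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            if pe[i, j] == 0:
                state = 0
            i -= 1
        else:
            if pf[i, j] == 0:
                state = 0
            j -= 1
    return best, j, bj, i, bi, aligned


class ReferenceIndex:
    """Exact k-mer index over a set of reference sequences.

    References are indexed independently, so a reported alignment interval
    can never cross a reference boundary.
    """

    def __init__(self, references: Sequence[SequenceRecord], seed_k: int = 15):
        refs = list(references)
        if not refs:
            raise ValueError("empty reference set")
        ids = [r.id for r in refs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference ids")
        self.seed_k = seed_k
        self.sequences: dict[str, str] = {r.id: r.sequence for r in refs}
        self.encoded: dict[str, np.ndarray] = {
            r.id: _encode(r.sequence, _R_LUT) for r in refs
        }
        index: dict[str, list[tuple[str, int]]] = {}
        for r in refs:
            seq = r.sequence
            for pos in range(0, len(seq) - seed_k + 1):
                index.setdefault(seq[pos : pos + seed_k], []).append((r.id, pos))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, ())


_MAX_CLUSTERS = 64
_DIAG_BAND = 12
_WINDOW_PAD = 16


def _seed_clusters(query: str, index: ReferenceIndex):
    """Collect seeded diagonals, clustered per reference.

    Yields (ref_id, min_diag, max_diag, n_seeds) in deterministic order.
    """
    k = index.seed_k
    hits: dict[str, list[int]] = {}
    for off in range(0, len(query) - k + 1):
        for ref_id, pos in index.lookup(query[off : off + k]):
            hits.setdefault(ref_id, []).append(pos - off)
    clusters = []
    for ref_id in sorted(hits):
        diags = sorted(hits[ref_id])
        lo = hi = diags[0]
        count = 1
        for d in diags[1:]:
            if d - hi <= _DIAG_BAND:
                hi = d
                count += 1
            else:
                clusters.append((ref_id, lo, hi, count))
                lo = hi = d
                count = 1
        clusters.append((ref_id, lo, hi, count))
    if len(clusters) > _MAX_CLUSTERS:
        clusters.sort(key=lambda c: (-c[3], c[0], c[1]))
        clusters = sorted(clusters[:_MAX_CLUSTERS], key=lambda c: (c[0], c[1]))
    return clusters


def _align_strand(query: str, query_enc: np.ndarray, index: ReferenceIndex,
                  params: AlignerParams):
    """Best candidate per seeded cluster on one strand of the query."""
    L = len(query)
    results = []
    for ref_id, lo, hi, _count in _seed_clusters(query, index):
        ref_seq = index.sequences[ref_id]
        # fast path: exact full-length match on a single diagonal
        if lo == hi and lo >= 0 and lo + L <= len(ref_seq) \
                and ref_seq[lo : lo + L] == query:
            results.append((L * params.match, ref_id, lo, lo + L, L))
            continue
        w_start = max(0, lo - _WINDOW_PAD)
        w_end = min(len(ref_seq), hi + L + _WINDOW_PAD)
        score, r_beg, r_end, _q_beg, _q_end, aligned = _sw_extend(
            query_enc,
            index.encoded[ref_id][w_start:w_end],
            params.match, params.mismatch,
            params.gap_open, params.gap_extend,
        )
        if score > 0:
            results.append(
                (score, ref_id, w_start + r_beg, w_start + r_end, aligned)
            )
    return results


def align_mate(sequence: str, index: ReferenceIndex,
               params: AlignerParams | None = None, *,
               read_id: str = "", mate_index: int = 1) -> AlignmentHit | None:
    """Align one mate to a reference set; return the primary hit or None.

    A mate shorter than ``seed_k`` is unmapped by definition. The hit with
    the highest score wins; ties prefer the smallest reference id, then
    the smallest start, then the forward strand.
    """
    params = params or AlignerParams()
    if index.seed_k != params.seed_k:
        raise ValueError("index seed_k does not match params.seed_k")
    sequence = sequence.upper()
    if len(sequence) < params.seed_k:
        return None
    candidates = []  # (-score, ref_id, start, strand_rank, end, aligned)
    for strand, query in (("+", sequence), ("-", revcomp(sequence))):
        enc = _encode(query, _Q_LUT)
        for score, ref_id, start, end, aligned in _align_strand(
            query, enc, index, params
        ):
            candidates.append(
                (-score, ref_id, start, 0 if strand == "+" else 1, end, aligned)
            )
    if not candidates:
        return None
    neg_score, ref_id, start, strand_rank, end, aligned = min(candidates)
    score = -neg_score
    if score < params.min_score:
        return None
    return AlignmentHit(
        read_id=read_id,
        mate_index=mate_index,
        ref_id=ref_id,
        start=start,
        end=end,
        strand="+" if strand_rank == 0 else "-",
        aligned_read_bases=aligned,
        score=score,
    )


def classify_pair_fate(hit1: AlignmentHit | None,
                       hit2: AlignmentHit | None) -> str:
    """Partition a pair by the primary mapped status of its two mates."""
    if hit1 is not None and hit2 is not None:
        return PairFate.BOTH
    if hit1 is not None:
        return PairFate.MATE1_ONLY
    if hit2 is not None:
        return PairFate.MATE2_ONLY
    return PairFate.NEITHER


def extract_half_mapped(
    pairs: Iterable[ReadPairRecord],
    host_index: ReferenceIndex,
    params: AlignerParams | None = None,
) -> Iterator[tuple[ReadPairRecord, AlignmentHit, int]]:
    """First-pass extraction: keep pairs with exactly one host-mapped mate.

    Yields (pair, host-side hit, host-mapped mate index). Pairs with both
    or neither mate mapped to the host are discarded.
    """
    params = params or AlignerParams()
    for pair in pairs:
        hit1 = align_mate(pair.seq1, host_index, params,
                          read_id=pair.pair_id, mate_index=1)
        hit2 = align_mate(pair.seq2, host_index, params,
                          read_id=pair.pair_id, mate_index=2)
        fate = classify_pair_fate(hit1, hit2)
        if fate == PairFate.MATE1_ONLY:
            yield pair, hit1, 1
        elif fate == PairFate.MATE2_ONLY:
            yield pair, hit2, 2


# ---------------------------------------------------------------------------
# Optional SAM import path

_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_MATE_UNMAPPED = 0x8
_FLAG_FIRST = 0x40
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


def iter_half_mapped_sam(path) -> Iterator[tuple[str, int, AlignmentHit, str]]:
    """Read half-mapped pairs from SAM produced by an external aligner.

    Secondary (0x100) and supplementary (0x800) records are discarded; a
    pair passes iff its primary records show exactly one mapped mate (the
    flag-4/flag-8 extraction semantics). Yields (pair_id, host-mapped mate
    index, host hit, sequence of the unmapped mate).
    """
    import pysam

    by_pair: dict[str, dict[int, object]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.flag & (_FLAG_SECONDARY | _FLAG_SUPPLEMENTARY):
                continue
            if not rec.flag & _FLAG_PAIRED:
                continue
            mate = 1 if rec.flag & _FLAG_FIRST else 2
            by_pair.setdefault(rec.query_name, {})[mate] = rec
    for pair_id in sorted(by_pair):
        mates = by_pair[pair_id]
        if set(mates) != {1, 2}:
            continue
        unmapped = {m: bool(mates[m].flag & _FLAG_UNMAPPED) for m in (1, 2)}
        if sum(unmapped.values()) != 1:
            continue
        mapped_mate = 1 if not unmapped[1] else 2
        rec = mates[mapped_mate]
        aligned = sum(
            length for op, length in (rec.cigartuples or []) if op in (0, 7, 8)
        )
        hit = AlignmentHit(
            read_id=pair_id,
            mate_index=mapped_mate,
            ref_id=rec.reference_name,
            start=rec.reference_start,
            end=rec.reference_end or rec.reference_start + aligned,
            strand="-" if rec.is_reverse else "+",
            aligned_read_bases=aligned,
            score=int(rec.get_tag("AS")) if rec.has_tag("AS") else aligned,
        )
        free_rec = mates[3 - mapped_mate]
        seq = free_rec.query_sequence or ""
        if free_rec.is_reverse:
            seq = revcomp(seq)
        yield pair_id, mapped_mate, hit, seq
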