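"""LGT candidate calling, the filtering cascade and junction deduplication.

A read pair supports lateral gene transfer when one mate maps exclusively
to the host genome and the other maps exclusively to a bacterial
reference; the integration junction then lies between the two mates,
inside the unsequenced insert. Candidates from the realignment pass are
filtered for alignment coverage (both mates >= 90% of read bases aligned
by default), read-level low complexity (long poly-A/T/G/C runs), and
repeat overlap of the host-side interval, then deduplicated on the exact
(host position, bacterial position) junction key.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .alignment import (
    AlignerParams,
    AlignmentHit,
    ReferenceIndex,
    align_mate,
    extract_half_mapped,
)
from .io_formats import EVENT_COLUMNS, GenomicInterval, ReadPairRecord

__all__ = [
    "LgtCandidate",
    "LgtEvent",
    "FilterReport",
    "detect_candidates",
    "filter_coverage",
    "filter_low_complexity",
    "filter_repeat_overlap",
    "dedup_junctions",
    "run_detection",
    "events_to_dataframe",
    "DEFAULT_MIN_COVERAGE",
    "HOMOPOLYMER_RUN",
    "COMPOSITION_FRACTION",
]

DEFAULT_MIN_COVERAGE = 0.90
HOMOPOLYMER_RUN = 20
COMPOSITION_FRACTION = 0.80


@dataclass(frozen=True)
class LgtCandidate:
    """A read pair supporting LGT, before filtering.

    The host hit and the bacterial hit belong to different mates of the
    same pair; mate sequences are retained for the read-level filters.
    """

    sample_id: str
    pair_id: str
    host_hit: AlignmentHit
    bact_hit: AlignmentHit
    bact_genus: str
    host_mate_seq: str
    bact_mate_seq: str

    def __post_init__(self) -> None:
        if self.host_hit.mate_index == self.bact_hit.mate_index:
            raise ValueError(
                f"pair {self.pair_id}: host and bacterial hits on same mate"
            )


@dataclass
class LgtEvent:
    """A deduplicated integration junction for one sample."""

    sample_id: str
    pair_id: str
    host_chrom: str
    host_start: int
    host_end: int
    host_strand: str
    bact_accession: str
    bact_genus: str
    bact_start: int
    bact_end: int
    gene_name: str = "."
    region_class: str = ""

    @property
    def junction_key(self) -> tuple[str, int, str, int]:
        return (self.host_chrom, self.host_start,
                self.bact_accession, self.bact_start)

    @property
    def host_interval(self) -> GenomicInterval:
        return GenomicInterval(self.host_chrom, self.host_start,
                               self.host_end, self.host_strand)


@dataclass
class FilterReport:
    """Per-stage survivor counts along the cascade (weakly decreasing
    from ``half_mapped`` on; ``bacterial_mapped`` and ``exclusive`` count
    the two halves of the candidate definition)."""

    input_pairs: int = 0
    half_mapped: int = 0
    bacterial_mapped: int = 0
    exclusive: int = 0
    coverage_pass: int = 0
    complexity_pass: int = 0
    repeat_pass: int = 0
    deduplicated: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def detect_candidates(
    half_mapped: Iterable[tuple[ReadPairRecord, AlignmentHit, int]],
    bact_index: ReferenceIndex,
    genus_map: dict[str, str],
    params: AlignerParams | None = None,
    report: FilterReport | None = None,
) -> list[LgtCandidate]:
    """Realign half-mapped pairs to bacterial references and apply the
    exclusivity rule.

    A candidate is emitted iff the host-unmapped mate maps to a bacterial
    reference AND the host-mapped mate does not map to any bacterial
    reference. The host-unmapped status of the bacterial mate comes from
    the first pass; cross-reference exclusivity is checked by realigning
    the host mate here.
    """
    params = params or AlignerParams()
    candidates = []
    for pair, host_hit, host_mate in half_mapped:
        free_mate = 3 - host_mate
        free_seq = pair.seq2 if host_mate == 1 else pair.seq1
        host_seq = pair.seq1 if host_mate == 1 else pair.seq2
        bact_hit = align_mate(free_seq, bact_index, params,
                              read_id=pair.pair_id, mate_index=free_mate)
        if bact_hit is None:
            continue
        if report is not None:
            report.bacterial_mapped += 1
        if align_mate(host_seq, bact_index, params) is not None:
            continue  # host mate also bacterial: not exclusive
        if report is not None:
            report.exclusive += 1
        try:
            genus = genus_map[bact_hit.ref_id]
        except KeyError:
            raise ValueError(
                f"accession {bact_hit.ref_id!r} missing from genus metadata"
            ) from None
        candidates.append(
            LgtCandidate(
                sample_id="",
                pair_id=pair.pair_id,
                host_hit=host_hit,
                bact_hit=bact_hit,
                bact_genus=genus,
                host_mate_seq=host_seq,
                bact_mate_seq=free_seq,
            )
        )
    return candidates


def filter_coverage(candidate: LgtCandidate,
                    min_coverage: float = DEFAULT_MIN_COVERAGE) -> bool:
    """Keep iff aligned_read_bases / read_length >= min_coverage for both
    the host-side and the bacterial-side mate."""
    host_cov = candidate.host_hit.aligned_read_bases / len(candidate.host_mate_seq)
    bact_cov = candidate.bact_hit.aligned_read_bases / len(candidate.bact_mate_seq)
    return host_cov >= min_coverage and bact_cov >= min_coverage


def _max_homopolymer_run(seq: str) -> int:
    best = run = 1
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > best:
            best = run
    return best if seq else 0


def _is_low_complexity(seq: str, max_run: int, max_fraction: float) -> bool:
    if not seq:
        return False
    if _max_homopolymer_run(seq) >= max_run:
        return True
    counts = {b: seq.count(b) for b in set(seq)}
    return max(counts.values()) / len(seq) > max_fraction


def filter_low_complexity(candidate: LgtCandidate,
                          max_run: int = HOMOPOLYMER_RUN,
                          max_fraction: float = COMPOSITION_FRACTION) -> bool:
    """Keep unless either mate has a homopolymer run >= ``max_run`` bp or
    a single base making up more than ``max_fraction`` of the mate."""
    return not (
        _is_low_complexity(candidate.host_mate_seq, max_run, max_fraction)
        or _is_low_complexity(candidate.bact_mate_seq, max_run, max_fraction)
    )


def filter_repeat_overlap(candidate: LgtCandidate,
                          repeats: Sequence[GenomicInterval]) -> bool:
    """Return True (flagged) iff the host-side interval overlaps any
    repeat interval by at least one base (half-open semantics)."""
    hit = candidate.host_hit
    for iv in repeats:
        if iv.chrom == hit.ref_id and hit.start < iv.end and iv.start < hit.end:
            return True
    return False


def dedup_junctions(candidates: Sequence[LgtCandidate],
                    sample_id: str = "") -> list[LgtEvent]:
    """Collapse candidates to one event per unique junction key.

    The key is (host_chrom, host_start, bact_accession, bact_start); the
    representative is the candidate with the lexicographically smallest
    pair_id. Output sorted by key. Idempotent.
    """
    chosen: dict[tuple, LgtCandidate] = {}
    for cand in sorted(candidates, key=lambda c: c.pair_id):
        key = (cand.host_hit.ref_id, cand.host_hit.start,
               cand.bact_hit.ref_id, cand.bact_hit.start)
        if key not in chosen:
            chosen[key] = cand
    events = []
    for key in sorted(chosen):
        cand = chosen[key]
        events.append(
            LgtEvent(
                sample_id=sample_id or cand.sample_id,
                pair_id=cand.pair_id,
                host_chrom=cand.host_hit.ref_id,
                host_start=cand.host_hit.start,
                host_end=cand.host_hit.end,
                host_strand=cand.host_hit.strand,
                bact_accession=cand.bact_hit.ref_id,
                bact_genus=cand.bact_genus,
                bact_start=cand.bact_hit.start,
                bact_end=cand.bact_hit.end,
            )
        )
    return events


def run_detection(
    pairs: Iterable[ReadPairRecord],
    host_index: ReferenceIndex,
    bact_index: ReferenceIndex,
    genus_map: dict[str, str],
    repeats: Sequence[GenomicInterval] = (),
    *,
    sample_id: str = "",
    params: AlignerParams | None = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    exclude_repeats: bool = True,
) -> tuple[list[LgtEvent], FilterReport]:
    """Full per-sample cascade: extraction, realignment, filters, dedup.

    With ``exclude_repeats`` (the default) repeat-flagged candidates are
    dropped; otherwise they are merely counted. Returns the deduplicated
    events and the per-stage filter report.
    """
    params = params or AlignerParams()
    report = FilterReport()

    def counted(stream):
        for pair in stream:
            report.input_pairs += 1
            yield pair

    half_mapped = []
    for item in extract_half_mapped(counted(pairs), host_index, params):
        report.half_mapped += 1
        half_mapped.append(item)

    candidates = detect_candidates(half_mapped, bact_index, genus_map,
                                   params, report)
    kept = [c for c in candidates if filter_coverage(c, min_coverage)]
    report.coverage_pass = len(kept)
    kept = [c for c in kept if filter_low_complexity(c)]
    report.complexity_pass = len(kept)
    if exclude_repeats:
        kept = [c for c in kept if not filter_repeat_overlap(c, repeats)]
    report.repeat_pass = len(kept)
    events = dedup_junctions(kept, sample_id=sample_id)
    report.deduplicated = len(events)
    return events, report


def events_to_dataframe(events: Sequence[LgtEvent]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": e.sample_id,
            "pair_id": e.pair_id,
            "host_chrom": e.host_chrom,
            "host_start": e.host_start,
            "host_end": e.host_end,
            "host_strand": e.host_strand,
            "bact_accession": e.bact_accession,
            "bact_genus": e.bact_genus,
            "bact_start": e.bact_start,
            "bact_end": e.bact_end,
            "gene_name": e.gene_name,
            "region_class": e.region_class,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
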