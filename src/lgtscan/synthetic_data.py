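"""Synthetic cohorts with planted bacterial-human integration junctions.

Real inputs for this analysis are patient-scale RNA-seq datasets aligned
against hg19 and RefSeq bacterial references. This module emulates their
statistical structure at desk scale: a random host "genome" with a gene
model table and repeat intervals, a set of bacterial references with genus
metadata, and paired-end reads of five truth classes:

* ``host`` - both mates from one host transcript fragment,
* ``bacterial`` - both mates from one bacterial fragment (microbiome),
* ``lgt`` - mate 1 host-derived and mate 2 bacteria-derived, flanking a
  planted integration junction that lies inside the unsequenced insert,
* ``lowcomplex`` - one mate a pure homopolymer (poly-A/T/G/C artifact),
* ``duplicate`` - a byte-copy of an earlier lgt pair (library artifact).

Every emitted pair carries a truth record, so detection sensitivity and
specificity can be measured exactly. Reads are emulated as unspliced
transcript copies: each mate is contiguous on its reference, integration
junctions fall inside gene spans, and insert sizes are resampled until
they exceed twice the read length so the junction always lies between the
two mates. Base qualities are constant 'I' (the pipeline ignores quality).
Identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    GenomicInterval,
    ReadPairRecord,
    SequenceRecord,
    write_bed,
    write_fasta,
    write_fastq_pairs,
    write_gene_models,
    write_genus_map,
)

__all__ = [
    "SimConfig",
    "References",
    "TRUTH_COLUMNS",
    "generate_references",
    "simulate_sample",
    "simulate_cohort",
    "simulate_cohort_burdens",
    "simulate_clinical",
    "HOST_CHROM",
]

HOST_CHROM = "chrH"

# genera observed repeatedly in host-microbe integration surveys; used to
# label the synthetic bacterial references
_GENERA = (
    "Mesorhizobium", "Pseudomonas", "Acinetobacter", "Escherichia",
    "Staphylococcus", "Streptococcus", "Bacillus", "Klebsiella",
    "Enterococcus", "Lactobacillus", "Sphingomonas", "Bradyrhizobium",
)

_DEFAULT_MARKER_PROBS = {
    "ighv_mutated": 0.55,
    "del11q": 0.18,
    "del17q": 0.08,
    "tri12": 0.15,
    "del13q": 0.55,
    "cd38_high": 0.30,
}
_RAI_STAGES = ("0", "I", "II", "III", "IV")
_DEFAULT_RAI_PROBS = (0.25, 0.25, 0.20, 0.15, 0.15)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Rates are fractions of all read pairs; their sum must not exceed 1
    (the remainder are plain host pairs). ``insert_mean`` must be at
    least twice ``read_length`` so a planted junction can sit in the
    unsequenced insert between the two mates. ``seed`` fully determines
    every output.
    """

    seed: int = 0
    host_length: int = 100_000
    n_host_genes: int = 30
    n_bacterial_refs: int = 20
    bacterial_length: int = 5_000
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    n_pairs_per_sample: int = 100_000
    lgt_rate: float = 1e-3
    microbiome_rate: float = 5e-3
    duplicate_rate: float = 1e-4
    lowcomplexity_rate: float = 1e-4
    error_rate: float = 1e-3
    n_samples_group1: int = 20
    n_samples_group2: int = 20
    group2_lgt_fold: float = 2.0
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # clinical model: exponential event times (per-month hazards), uniform
    # censoring, group-wise marker prevalences (equal by default, i.e. no
    # configured marker/group association)
    os_hazard: float = 0.012
    pfs_hazard: float = 0.025
    hazard_ratio_group2: float = 1.0
    censor_time_max: float = 96.0
    marker_probs_group1: dict = field(
        default_factory=lambda: dict(_DEFAULT_MARKER_PROBS)
    )
    marker_probs_group2: dict = field(
        default_factory=lambda: dict(_DEFAULT_MARKER_PROBS)
    )
    rai_probs: tuple = _DEFAULT_RAI_PROBS

    def __post_init__(self) -> None:
        rates = (self.lgt_rate, self.microbiome_rate, self.duplicate_rate,
                 self.lowcomplexity_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all class rates must lie in [0, 1]")
        if sum(rates) > 1.0:
            raise ValueError("class rates must sum to <= 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must be >= 2 * read_length")
        if self.group2_lgt_fold * self.lgt_rate > 1.0:
            raise ValueError("group2 lgt rate exceeds 1")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if self.bacterial_length < 2 * self.read_length + 1:
            raise ValueError("bacterial references shorter than one fragment")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class References:
    """Everything a detection run needs besides the reads."""

    host: SequenceRecord
    bacterial: tuple[SequenceRecord, ...]
    gene_models: tuple[GeneModel, ...]
    repeats: tuple[GenomicInterval, ...]
    genus_map: dict[str, str]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "host_fasta": out / "host.fasta",
            "bacterial_fasta": out / "bacterial.fasta",
            "gene_models": out / "gene_models.tsv",
            "repeats": out / "repeats.bed",
            "genus_map": out / "genus_map.tsv",
        }
        write_fasta([self.host], paths["host_fasta"])
        write_fasta(self.bacterial, paths["bacterial_fasta"])
        write_gene_models(self.gene_models, paths["gene_models"])
        write_bed(self.repeats, paths["repeats"])
        write_genus_map(self.genus_map, paths["genus_map"])
        return paths


TRUTH_COLUMNS = [
    "pair_id", "truth_class", "duplicate_of",
    "host_chrom", "host_pos", "bact_accession", "bact_pos",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int,
                base_probs) -> str:
    draw = rng.choice(_BASES, size=length, p=list(base_probs))
    return draw.tobytes().decode("ascii")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# references

def _make_gene_models(rng: np.random.Generator,
                      config: SimConfig) -> tuple[GeneModel, ...]:
    n = config.n_host_genes
    if n == 0:
        return ()
    span_lengths = rng.integers(1500, 3501, size=n)
    min_gap = 100
    needed = int(span_lengths.sum()) + (n + 1) * min_gap
    if needed > config.host_length:
        raise ValueError(
            f"cannot place {n} non-overlapping genes in {config.host_length} bp"
        )
    slack = config.host_length - needed
    cuts = np.sort(rng.integers(0, slack + 1, size=n + 1))
    extra_gaps = np.diff(np.concatenate(([0], cuts)))  # sums to <= slack
    models = []
    pos = 0
    for i in range(n):
        pos += min_gap + int(extra_gaps[i])
        tx_start = pos
        tx_end = pos + int(span_lengths[i])
        pos = tx_end
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 6))
        n_pieces = 2 * n_exons - 1  # exons and introns alternate
        length = tx_end - tx_start
        min_piece = 60
        free = length - n_pieces * min_piece
        inner = np.sort(rng.integers(0, free + 1, size=n_pieces - 1))
        pieces = np.diff(np.concatenate(([0], inner, [free]))) + min_piece
        bounds = tx_start + np.concatenate(([0], np.cumsum(pieces)))
        exon_starts = tuple(int(b) for b in bounds[0:-1:2])
        exon_ends = tuple(int(b) for b in bounds[1::2])
        coding = rng.random() < 0.8
        if coding:
            # CDS begins mid-first-exon and ends mid-last-exon so both
            # UTRs are non-empty
            cds_start = exon_starts[0] + int(
                rng.integers(10, exon_ends[0] - exon_starts[0] - 9)
            )
            cds_end = exon_starts[-1] + int(
                rng.integers(10, exon_ends[-1] - exon_starts[-1] - 9)
            )
        else:
            cds_start = cds_end = tx_start
        prefix = "NCG" if not coding else "GENE"
        models.append(
            GeneModel(
                gene_name=f"{prefix}{i + 1:04d}",
                chrom=HOST_CHROM,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                cds_end=cds_end,
                exon_starts=exon_starts,
                exon_ends=exon_ends,
            )
        )
    return tuple(models)


def generate_references(config: SimConfig) -> References:
    """Deterministically generate host and bacterial references.

    The host is one uniform-composition chromosome carrying
    ``n_host_genes`` non-overlapping gene models (>= 2 exons each, coding
    genes with both UTRs); each bacterial record gets a distinct accession
    and a genus label; a repeat BED with at least one interval stands in
    for a RepeatMasker annotation.
    """
    rng = np.random.default_rng((config.seed, 1))
    host = SequenceRecord(
        HOST_CHROM, _random_seq(rng, config.host_length, config.base_probs)
    )
    gene_models = _make_gene_models(rng, config)
    bacterial = []
    genus_map = {}
    for i in range(config.n_bacterial_refs):
        acc = f"NZ_SYN{i + 1:04d}"
        bacterial.append(
            SequenceRecord(
                acc, _random_seq(rng, config.bacterial_length, config.base_probs)
            )
        )
        genus_map[acc] = _GENERA[i % len(_GENERA)]
    n_repeats = max(1, config.host_length // 20_000)
    repeats = []
    for _ in range(n_repeats):
        length = int(rng.integers(200, 1001))
        start = int(rng.integers(0, max(1, config.host_length - length)))
        repeats.append(GenomicInterval(HOST_CHROM, start, start + length))
    repeats.sort(key=lambda iv: iv.start)
    return References(host, tuple(bacterial), gene_models, tuple(repeats),
                      genus_map)


# ---------------------------------------------------------------------------
# reads

def _draw_insert(rng: np.random.Generator, config: SimConfig,
                 upper: int) -> int:
    """Truncated-normal insert size, resampled until feasible.

    The lower truncation at 2x read length guarantees the junction of an
    lgt pair lies strictly inside the unsequenced insert.
    """
    lo = 2 * config.read_length
    if upper < lo:
        raise ValueError("reference too short for the configured insert size")
    for _ in range(1000):
        s = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        if lo <= s <= upper:
            return s
    return lo


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _fragment_reads(frag: str, strand: str, read_length: int) -> tuple[str, str]:
    """FR mates from a fragment: mate 1 leads, mate 2 is the reverse
    complement of the trailing end."""
    if strand == "-":
        frag = _revcomp(frag)
    return frag[:read_length], _revcomp(frag[-read_length:])


def _gene_fragment_start(rng: np.random.Generator, genes, insert: int,
                         host_len: int) -> int:
    """Fragment start inside a gene span (an unspliced transcript copy)."""
    if genes:
        g = genes[int(rng.integers(0, len(genes)))]
        hi = min(g.tx_end - insert, host_len - insert)
        lo = g.tx_start
        if hi < lo:
            lo, hi = 0, host_len - insert
    else:
        lo, hi = 0, host_len - insert
    return int(rng.integers(lo, hi + 1))


def simulate_sample(
    config: SimConfig,
    references: References,
    sample_id: str,
    *,
    lgt_rate: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadPairRecord], pd.DataFrame]:
    """Simulate one sample's read pairs plus their truth table.

    Class counts are a multinomial draw over the configured rates;
    duplicates are byte-copies of previously emitted lgt pairs (reassigned
    to the host class if no lgt pair exists to copy). Returns the pairs in
    a seeded random order and a truth DataFrame with one row per pair.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 2, _stable_tag(sample_id)))
    rate_lgt = config.lgt_rate if lgt_rate is None else lgt_rate
    probs = [rate_lgt, config.microbiome_rate, config.lowcomplexity_rate,
             config.duplicate_rate]
    probs.append(1.0 - sum(probs))
    n_lgt, n_micro, n_low, n_dup, n_host = rng.multinomial(
        config.n_pairs_per_sample, probs
    )
    if n_lgt == 0:
        n_host += n_dup
        n_dup = 0

    host_seq = references.host.sequence
    host_len = len(host_seq)
    genes = references.gene_models
    rl = config.read_length
    accs = [b.id for b in references.bacterial]
    bact_seqs = {b.id: b.sequence for b in references.bacterial}

    pairs: list[tuple[str, str, str, str, int | None, str | None, int | None]] = []
    # each entry: (class, seq1, seq2, dup_src, host_pos, acc, bact_pos)

    lgt_entries = []
    for _ in range(int(n_lgt)):
        insert = _draw_insert(rng, config, min(host_len, config.bacterial_length))
        h_len = int(rng.integers(rl, insert - rl + 1))
        b_len = insert - h_len
        # junction inside a gene span (transcript-borne integration),
        # clipped so the host-side fragment stays on the chromosome
        if genes:
            g = genes[int(rng.integers(0, len(genes)))]
            hp = int(rng.integers(max(g.tx_start, h_len),
                                  max(g.tx_end, h_len + 1)))
        else:
            hp = int(rng.integers(h_len, host_len + 1))
        acc = accs[int(rng.integers(0, len(accs)))]
        bp = int(rng.integers(0, config.bacterial_length - b_len + 1))
        seq1 = host_seq[hp - h_len : hp - h_len + rl]
        seq2 = _revcomp(bact_seqs[acc][bp + b_len - rl : bp + b_len])
        seq1 = _apply_errors(rng, seq1, config.error_rate)
        seq2 = _apply_errors(rng, seq2, config.error_rate)
        lgt_entries.append(("lgt", seq1, seq2, None, hp, acc, bp))
    pairs.extend(lgt_entries)

    for _ in range(int(n_dup)):
        src_idx = int(rng.integers(0, len(lgt_entries)))
        src = lgt_entries[src_idx]
        pairs.append(("duplicate", src[1], src[2], src_idx, src[4], src[5],
                      src[6]))

    for _ in range(int(n_micro)):
        insert = _draw_insert(rng, config, config.bacterial_length)
        acc = accs[int(rng.integers(0, len(accs)))]
        start = int(rng.integers(0, config.bacterial_length - insert + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        s1, s2 = _fragment_reads(bact_seqs[acc][start : start + insert],
                                 strand, rl)
        pairs.append(("bacterial", _apply_errors(rng, s1, config.error_rate),
                      _apply_errors(rng, s2, config.error_rate),
                      None, None, None, None))

    for _ in range(int(n_low)):
        insert = _draw_insert(rng, config, host_len)
        fs = _gene_fragment_start(rng, genes, insert, host_len)
        s1 = host_seq[fs : fs + rl]
        base = "ACGT"[int(rng.integers(0, 4))]
        pairs.append(("lowcomplex", _apply_errors(rng, s1, config.error_rate),
                      base * rl, None, None, None, None))

    for _ in range(int(n_host)):
        insert = _draw_insert(rng, config, host_len)
        fs = _gene_fragment_start(rng, genes, insert, host_len)
        strand = "+" if rng.random() < 0.5 else "-"
        s1, s2 = _fragment_reads(host_seq[fs : fs + insert], strand, rl)
        pairs.append(("host", _apply_errors(rng, s1, config.error_rate),
                      _apply_errors(rng, s2, config.error_rate),
                      None, None, None, None))

    order = rng.permutation(len(pairs))
    ids = [f"{sample_id}:{i:07d}" for i in range(len(pairs))]
    # map original lgt-entry index -> final pair id, for duplicate_of
    lgt_final_id = {}
    for new_pos, old_idx in enumerate(order):
        if old_idx < len(lgt_entries):
            lgt_final_id[int(old_idx)] = ids[new_pos]

    records: list[ReadPairRecord] = []
    truth_rows = []
    for new_pos, old_idx in enumerate(order):
        cls, s1, s2, dup_src, hp, acc, bp = pairs[old_idx]
        pid = ids[new_pos]
        records.append(ReadPairRecord(pid, s1, s2, truth_class=cls))
        truth_rows.append(
            {
                "pair_id": pid,
                "truth_class": cls,
                "duplicate_of": lgt_final_id[dup_src] if dup_src is not None
                else "",
                "host_chrom": HOST_CHROM if hp is not None else "",
                "host_pos": hp if hp is not None else -1,
                "bact_accession": acc or "",
                "bact_pos": bp if bp is not None else -1,
            }
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return records, truth


def _stable_tag(s: str) -> int:
    """Deterministic small integer from a string (hash() is salted)."""
    tag = 0
    for ch in s:
        tag = (tag * 131 + ord(ch)) % (2**31 - 1)
    return tag


# ---------------------------------------------------------------------------
# cohort

def simulate_clinical(config: SimConfig, sample_ids: list[str],
                      groups: list[int]) -> pd.DataFrame:
    """Clinical table: exponential survival with a configurable group
    hazard ratio, uniform censoring, and categorical markers drawn with
    group-wise prevalences (equal by default)."""
    rng = np.random.default_rng((config.seed, 3))
    rows = []
    for sid, grp in zip(sample_ids, groups):
        hr = config.hazard_ratio_group2 if grp == 2 else 1.0
        row = {"sample_id": sid, "group": grp}
        for prefix, hazard in (("os", config.os_hazard),
                               ("pfs", config.pfs_hazard)):
            t_event = rng.exponential(1.0 / (hazard * hr))
            t_censor = rng.uniform(0.0, config.censor_time_max)
            row[f"{prefix}_time"] = round(min(t_event, t_censor), 3)
            row[f"{prefix}_event"] = int(t_event <= t_censor)
        probs = (config.marker_probs_group2 if grp == 2
                 else config.marker_probs_group1)
        for marker, p in probs.items():
            if marker == "cd38_high":
                row["cd38"] = "high" if rng.random() < p else "low"
            else:
                row[marker] = "yes" if rng.random() < p else "no"
        row["rai_stage"] = _RAI_STAGES[
            int(rng.choice(len(_RAI_STAGES), p=list(config.rai_probs)))
        ]
        rows.append(row)
    return pd.DataFrame(rows)


def _cohort_layout(config: SimConfig) -> tuple[list[str], list[int]]:
    ids, groups = [], []
    for g, n in ((1, config.n_samples_group1), (2, config.n_samples_group2)):
        for i in range(n):
            ids.append(f"G{g}S{i + 1:03d}")
            groups.append(g)
    return ids, groups


def simulate_cohort(config: SimConfig, references: References,
                    out_dir: str | Path) -> pd.DataFrame:
    """Write per-sample FASTQ pairs, truth tables and the clinical TSV.

    Group 2 samples use ``lgt_rate * group2_lgt_fold``. Returns the
    clinical table (also written to ``clinical.tsv``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids, groups = _cohort_layout(config)
    for sid, grp in zip(ids, groups):
        rate = config.lgt_rate * (config.group2_lgt_fold if grp == 2 else 1.0)
        pairs, truth = simulate_sample(config, references, sid, lgt_rate=rate)
        write_fastq_pairs(pairs, out / f"{sid}_R1.fastq", out / f"{sid}_R2.fastq")
        truth.to_csv(out / f"{sid}_truth.tsv", sep="\t", index=False)
    clinical = simulate_clinical(config, ids, groups)
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    return clinical


def simulate_cohort_burdens(config: SimConfig) -> pd.DataFrame:
    """Per-sample true LGT burden without emitting reads.

    Draws each sample's planted-junction count from the same binomial law
    the read-level simulator uses (junctions are almost surely distinct,
    so unique events equal planted pairs). Columns: sample_id, group,
    n_events, total_pairs. Fast enough for replicate-based power and null
    calibration studies.
    """
    rng = np.random.default_rng((config.seed, 4))
    ids, groups = _cohort_layout(config)
    rows = []
    for sid, grp in zip(ids, groups):
        rate = config.lgt_rate * (config.group2_lgt_fold if grp == 2 else 1.0)
        n_events = int(rng.binomial(config.n_pairs_per_sample, rate))
        rows.append(
            {"sample_id": sid, "group": grp, "n_events": n_events,
             "total_pairs": config.n_pairs_per_sample}
        )
    return pd.DataFrame(rows)
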