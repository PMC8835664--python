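"""Gene and gene-structure annotation of integration sites.

Each event's host-side interval is classified by its midpoint against a
gene model table, following the familiar variant-annotator convention:
exonic / splicing / UTR5 / UTR3 / intronic for coding genes, ncRNA_exonic
/ ncRNA_intronic for genes without a CDS, upstream / downstream within a
1 kb window around the transcript, intergenic otherwise. When several
genes overlap the position, precedence (exonic > splicing > UTR5 > UTR3 >
intronic > ncRNA_exonic > ncRNA_intronic > upstream > downstream >
intergenic) then alphabetical gene name break the tie.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .io_formats import GeneModel
from .lgt_detection import LgtEvent

__all__ = [
    "REGION_CLASSES",
    "UPSTREAM_WINDOW",
    "SPLICING_WINDOW",
    "classify_position",
    "annotate_event",
    "annotate_events",
    "region_distribution",
    "gene_recurrence",
]

REGION_CLASSES = (
    "exonic", "splicing", "UTR5", "UTR3", "intronic",
    "ncRNA_exonic", "ncRNA_intronic", "upstream", "downstream", "intergenic",
)
_PRECEDENCE = {cls: rank for rank, cls in enumerate(REGION_CLASSES)}

UPSTREAM_WINDOW = 1000  # bp up/downstream of the transcript span
SPLICING_WINDOW = 2  # intronic bases adjacent to each exon boundary


def _classify_in_gene(pos: int, gene: GeneModel) -> str | None:
    """Region class of ``pos`` with respect to one gene, or None if the
    position is outside the gene and its flanking windows."""
    if gene.tx_start <= pos < gene.tx_end:
        in_exon = any(s <= pos < e for s, e in gene.exons())
        if in_exon:
            if not gene.is_coding:
                return "ncRNA_exonic"
            if pos < gene.cds_start:
                return "UTR5" if gene.strand == "+" else "UTR3"
            if pos >= gene.cds_end:
                return "UTR3" if gene.strand == "+" else "UTR5"
            return "exonic"
        # intronic; near-boundary positions are splice-site proximal
        for s, e in gene.exons():
            if 0 <= pos - e < SPLICING_WINDOW or 0 < s - pos <= SPLICING_WINDOW:
                return "splicing"
        return "intronic" if gene.is_coding else "ncRNA_intronic"
    if gene.tx_start - UPSTREAM_WINDOW <= pos < gene.tx_start:
        return "upstream" if gene.strand == "+" else "downstream"
    if gene.tx_end <= pos < gene.tx_end + UPSTREAM_WINDOW:
        return "downstream" if gene.strand == "+" else "upstream"
    return None


def classify_position(chrom: str, pos: int,
                      gene_models: Sequence[GeneModel]) -> tuple[str, str]:
    """(gene_name, region_class) for a single genomic position.

    Precedence then alphabetical gene name resolve overlaps; positions
    assigned to no gene are intergenic with gene name ".".
    """
    hits = []
    for gene in gene_models:
        if gene.chrom != chrom:
            continue
        cls = _classify_in_gene(pos, gene)
        if cls is not None:
            hits.append((_PRECEDENCE[cls], gene.gene_name, cls))
    if not hits:
        return ".", "intergenic"
    _, gene_name, cls = min(hits)
    return gene_name, cls


def annotate_event(event: LgtEvent,
                   gene_models: Sequence[GeneModel]) -> LgtEvent:
    """Fill gene_name and region_class from the host interval midpoint."""
    midpoint = (event.host_start + event.host_end) // 2
    event.gene_name, event.region_class = classify_position(
        event.host_chrom, midpoint, gene_models
    )
    return event


def annotate_events(events: Iterable[LgtEvent],
                    gene_models: Sequence[GeneModel]) -> list[LgtEvent]:
    return [annotate_event(e, gene_models) for e in events]


def region_distribution(events: Sequence[LgtEvent] | pd.DataFrame) -> dict[str, float]:
    """Fraction of events per region class (sums to 1; empty input gives
    an empty distribution)."""
    if isinstance(events, pd.DataFrame):
        classes = list(events["region_class"])
    else:
        classes = [e.region_class for e in events]
    if not classes:
        return {}
    counts: dict[str, int] = {}
    for cls in classes:
        if not cls:
            raise ValueError("unannotated event in region_distribution")
        counts[cls] = counts.get(cls, 0) + 1
    total = len(classes)
    return {cls: counts[cls] / total
            for cls in REGION_CLASSES if cls in counts}


def gene_recurrence(events: pd.DataFrame, cohorts: dict[str, str],
                    cohort_sizes: dict[str, int],
                    top_n: int | None = 30) -> pd.DataFrame:
    """Percentage of patients per cohort with >= 1 event in each gene.

    ``cohorts`` maps sample_id to a cohort label, ``cohort_sizes`` gives
    each cohort's patient count (a patient counts once per gene no matter
    how many events hit it). Intergenic events (gene name ".") are
    excluded. Rows sorted by descending percentage in the first cohort
    label (sorted order), ties alphabetical by gene; the top ``top_n``
    rows are returned.
    """
    df = events[events["gene_name"] != "."].copy()
    df["cohort"] = df["sample_id"].map(cohorts)
    if df["cohort"].isna().any():
        missing = sorted(df.loc[df["cohort"].isna(), "sample_id"].unique())
        raise ValueError(f"samples without cohort label: {missing}")
    labels = sorted(cohort_sizes)
    rows = []
    for gene, sub in df.groupby("gene_name"):
        row = {"gene_name": gene}
        for label in labels:
            n_patients = sub.loc[sub["cohort"] == label, "sample_id"].nunique()
            row[f"pct_{label}"] = 100.0 * n_patients / cohort_sizes[label]
        rows.append(row)
    out = pd.DataFrame(rows, columns=["gene_name"] + [f"pct_{l}" for l in labels])
    if out.empty:
        return out
    primary = f"pct_{labels[0]}"
    out = out.sort_values(
        [primary, "gene_name"], ascending=[False, True]
    ).reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n).reset_index(drop=True)
    return out
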