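"""Independent brute-force oracles shared by the unit and acceptance
tests. Each recomputes a quantity from first principles, with no calls
into the pipeline's own code paths."""

import numpy as np
from Bio import Align

from lgtscan.annotation import REGION_CLASSES, SPLICING_WINDOW, UPSTREAM_WINDOW


def biopython_sw_score(ref, read, params):
    """Full Smith-Waterman score under the same affine gap model (a gap
    of length g costs |gap_open| + g * |gap_extend|)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner.score(ref, read)


def logrank_oracle(times, events, labels):
    """Two-group log-rank statistic: sum over event times of O - E for
    group one, squared, over the hypergeometric variance."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (labels == groups[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (labels == groups[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def oracle_classify(chrom, pos, genes):
    """Exhaustive interval-containment region classification."""
    candidates = []
    for g in genes:
        if g.chrom != chrom:
            continue
        in_exon = any(
            s <= pos < e for s, e in zip(g.exon_starts, g.exon_ends)
        )
        coding = g.cds_start != g.cds_end
        if g.tx_start <= pos < g.tx_end:
            if in_exon:
                if not coding:
                    candidates.append(("ncRNA_exonic", g.gene_name))
                elif g.cds_start <= pos < g.cds_end:
                    candidates.append(("exonic", g.gene_name))
                elif pos < g.cds_start:
                    candidates.append(
                        ("UTR5" if g.strand == "+" else "UTR3", g.gene_name)
                    )
                else:
                    candidates.append(
                        ("UTR3" if g.strand == "+" else "UTR5", g.gene_name)
                    )
            else:
                near = any(
                    e <= pos < e + SPLICING_WINDOW
                    or s - SPLICING_WINDOW <= pos < s
                    for s, e in zip(g.exon_starts, g.exon_ends)
                )
                if near:
                    candidates.append(("splicing", g.gene_name))
                elif coding:
                    candidates.append(("intronic", g.gene_name))
                else:
                    candidates.append(("ncRNA_intronic", g.gene_name))
        elif g.tx_start - UPSTREAM_WINDOW <= pos < g.tx_start:
            candidates.append(
                ("upstream" if g.strand == "+" else "downstream", g.gene_name)
            )
        elif g.tx_end <= pos < g.tx_end + UPSTREAM_WINDOW:
            candidates.append(
                ("downstream" if g.strand == "+" else "upstream", g.gene_name)
            )
    if not candidates:
        return ".", "intergenic"
    rank = {c: i for i, c in enumerate(REGION_CLASSES)}
    cls, name = min(candidates, key=lambda t: (rank[t[0]], t[1]))
    return name, cls
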