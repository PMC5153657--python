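"""Genomic feature classification and summary statistics for circRNAs.

Each circle is placed relative to its host transcript's 5'UTR/CDS/3'UTR
partition, the splice-accepting exon index is reported in transcript order
(strand-aware), and per-gene circle counts, within-circle exon counts and
cross-tissue overlap (Venn) tables summarise the annotation.  The host
transcript is the one with the longest CDS (ties broken by transcript_id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .genome import GeneModel, GenomeBundle, Transcript
from .junctionquant import CircJunction

log = logging.getLogger(__name__)

CATEGORIES = ("CDS-CDS", "5'UTR-CDS", "CDS-3'UTR", "5'UTR-5'UTR",
              "3'UTR-3'UTR", "5'UTR-3'UTR", "intergenic", "other")


@dataclass(frozen=True)
class CircFeatureRecord:
    circ_id: str
    host_gene: str
    category: str
    acceptor_exon_index: int      # 1-based, transcript order; 0 if intergenic
    acceptor_exact: bool
    exons_within: int
    host_transcript_exons: int


def _host(circ: CircJunction, bundle: GenomeBundle
          ) -> tuple[GeneModel, Transcript] | None:
    if circ.host_gene and circ.host_gene != "intergenic":
        g = bundle.gene(circ.host_gene)
        return g, g.principal_transcript()
    cands = bundle.genes_overlapping(circ.chrom, circ.start, circ.end)
    if not cands:
        return None
    # prefer a gene whose exons match both boundaries
    def matches(g: GeneModel) -> int:
        t = g.principal_transcript()
        s_hit = any(s == circ.start for s, _ in t.exons)
        e_hit = any(e == circ.end for _, e in t.exons)
        return s_hit + e_hit
    g = min(cands, key=lambda g: (-matches(g), g.gene_id))
    return g, g.principal_transcript()


def _region_of(pos: int, tx: Transcript, strand: str) -> str | None:
    """5'UTR / CDS / 3'UTR label of a genomic position, None if intronic
    or outside the transcript."""
    in_exon = any(s <= pos < e for s, e in tx.exons)
    if not in_exon:
        return None
    if tx.cds is None:
        return "other"
    cs, ce = tx.cds
    if cs <= pos < ce:
        return "CDS"
    left = pos < cs
    if strand == "+":
        return "5'UTR" if left else "3'UTR"
    return "3'UTR" if left else "5'UTR"


def classify_region(circ: CircJunction, bundle: GenomeBundle) -> str:
    """Region category from the circle's first and last bases relative to
    the host transcript's UTR/CDS partition, ordered 5'->3' in transcript
    orientation."""
    host = _host(circ, bundle)
    if host is None:
        return "intergenic"
    gene, tx = host
    r_start = _region_of(circ.start, tx, gene.strand)
    r_end = _region_of(circ.end - 1, tx, gene.strand)
    if r_start is None or r_end is None or "other" in (r_start, r_end):
        log.debug("%s: boundary outside host exons -> other", circ.circ_id)
        return "other"
    first, last = (r_start, r_end) if gene.strand == "+" else (r_end, r_start)
    if first == last:
        return f"{first}-{last}" if first != "CDS" else "CDS-CDS"
    if first == "5'UTR":
        return f"5'UTR-{last}"
    if last == "3'UTR":
        return f"{first}-3'UTR"
    return "other"  # 3'UTR before CDS in transcript order: not a valid layout


def acceptor_exon_index(circ: CircJunction, bundle: GenomeBundle
                        ) -> tuple[int, bool]:
    """1-based transcript-order index of the splice-accepting exon: the host
    exon whose start coincides with the circle start (plus strand) or whose
    end coincides with the circle end (minus strand).  Falls back to the
    nearest containing exon, flagged inexact."""
    host = _host(circ, bundle)
    if host is None:
        raise ValueError(f"{circ.circ_id} is intergenic")
    gene, tx = host
    exons = tx.exons if gene.strand == "+" else tx.exons[::-1]  # transcript order
    if gene.strand == "+":
        target, boundary = circ.start, "start"
    else:
        target, boundary = circ.end, "end"
    for i, (s, e) in enumerate(exons, start=1):
        if (boundary == "start" and s == target) or \
           (boundary == "end" and e == target):
            return i, True
    pos = circ.start if gene.strand == "+" else circ.end - 1
    best, dist = 1, None
    for i, (s, e) in enumerate(exons, start=1):
        d = 0 if s <= pos < e else min(abs(pos - s), abs(pos - (e - 1)))
        if dist is None or d < dist:
            best, dist = i, d
    return best, False


def exons_within(circ: CircJunction, bundle: GenomeBundle) -> int:
    """Number of host-transcript exons fully contained in [start, end)."""
    host = _host(circ, bundle)
    if host is None:
        raise ValueError(f"{circ.circ_id} is intergenic")
    _, tx = host
    return sum(1 for s, e in tx.exons if circ.start <= s and e <= circ.end)


def per_gene_counts(circs: list[CircJunction]) -> pd.DataFrame:
    """gene_id -> number of circles (genic circles only)."""
    genic = [c.host_gene for c in circs
             if c.host_gene and c.host_gene != "intergenic"]
    if not genic:
        return pd.DataFrame(columns=["gene_id", "n_circles"])
    counts = pd.Series(genic).value_counts().sort_index()
    return (counts.rename_axis("gene_id").reset_index(name="n_circles")
            .sort_values(["n_circles", "gene_id"], ascending=[False, True])
            .reset_index(drop=True))


def feature_table(circs: list[CircJunction], bundle: GenomeBundle
                  ) -> pd.DataFrame:
    rows = []
    for c in circs:
        cat = classify_region(c, bundle)
        if cat == "intergenic":
            rows.append(dict(circ_id=c.circ_id, host_gene="intergenic",
                             category=cat, acceptor_exon_index=0,
                             acceptor_exact=False, exons_within=0,
                             host_transcript_exons=0))
            continue
        host = _host(c, bundle)
        gene, tx = host
        idx, exact = acceptor_exon_index(c, bundle)
        rows.append(dict(circ_id=c.circ_id, host_gene=gene.gene_id,
                         category=cat, acceptor_exon_index=idx,
                         acceptor_exact=exact,
                         exons_within=exons_within(c, bundle),
                         host_transcript_exons=len(tx.exons)))
    return pd.DataFrame(rows, columns=["circ_id", "host_gene", "category",
                                       "acceptor_exon_index", "acceptor_exact",
                                       "exons_within", "host_transcript_exons"])


def tissue_overlap(retained: dict[str, list[str] | set[str]]) -> pd.DataFrame:
    """All 2^k - 1 exclusive region counts of the k-set Venn diagram."""
    tissues = sorted(retained)
    sets = {t: set(retained[t]) for t in tissues}
    rows = []
    for r in range(1, len(tissues) + 1):
        for combo in combinations(tissues, r):
            inside = set.intersection(*(sets[t] for t in combo))
            outside = set.union(set(), *(sets[t] for t in tissues
                                         if t not in combo))
            exclusive = inside - outside
            rows.append(dict(tissues="&".join(combo), n=len(exclusive)))
    return pd.DataFrame(rows, columns=["tissues", "n"])
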