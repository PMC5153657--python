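"""Genome and gene-model containers.

All coordinates are 0-based half-open on the forward genomic strand.  GTF
input/output converts to 1-based inclusive at the boundary.  A gene's CDS is
stored as a single genomic interval (BED thickStart/thickEnd style); the
coding sequence is its intersection with the exon union, and UTR spans are
the exonic sequence outside it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

from ._seq import revcomp

Interval = tuple[int, int]


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[Interval, ...]  # genomic ascending, non-overlapping
    cds: Interval | None = None  # genomic interval; coding = intersection with exons

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_exonic_length(self) -> int:
        if self.cds is None:
            return 0
        cs, ce = self.cds
        return sum(max(0, min(e, ce) - max(s, cs)) for s, e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    transcripts: list[Transcript]

    @property
    def span(self) -> Interval:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)

    def exon_union(self) -> list[Interval]:
        """Merged exon intervals over all transcripts."""
        ivs = sorted(e for t in self.transcripts for e in t.exons)
        merged: list[Interval] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def exon_union_length(self) -> int:
        return sum(e - s for s, e in self.exon_union())

    def principal_transcript(self) -> Transcript:
        """The transcript with the longest CDS (ties by transcript_id)."""
        return min(
            self.transcripts,
            key=lambda t: (-t.cds_exonic_length(), t.transcript_id),
        )


class GenomeBundle:
    """A genome's sequences plus its gene models — the coordinate frame for
    everything downstream."""

    def __init__(self, sequences: dict[str, str], genes: list[GeneModel]):
        self.sequences = sequences
        self.genes = genes
        self._by_id = {g.gene_id: g for g in genes}
        self._validate()
        # per-chromosome genes sorted by span start, for interval queries
        self._chrom_genes: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._chrom_genes.setdefault(g.chrom, []).append(g)
        for lst in self._chrom_genes.values():
            lst.sort(key=lambda g: g.span[0])

    def _validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.sequences:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            clen = len(self.sequences[g.chrom])
            for t in g.transcripts:
                prev = 0
                for s, e in t.exons:
                    if not (0 <= s < e <= clen):
                        raise ValueError(
                            f"gene {g.gene_id}: exon ({s},{e}) outside {g.chrom}"
                        )
                    if s < prev:
                        raise ValueError(
                            f"gene {g.gene_id}: overlapping/unsorted exons"
                        )
                    prev = e

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        out = []
        for g in self._chrom_genes.get(chrom, []):
            gs, ge = g.span
            if gs < end and start < ge:
                out.append(g)
        return out

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][max(0, start):end]

    def spliced_sequence(self, gene: GeneModel, transcript: Transcript) -> str:
        """Mature mRNA sequence in transcript (5'->3') orientation."""
        chrom = self.sequences[gene.chrom]
        seq = "".join(chrom[s:e] for s, e in transcript.exons)
        return revcomp(seq) if gene.strand == "-" else seq

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_gtf(self, path: str | Path, source: str = "circage") -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                gs, ge = g.span
                attrs = f'gene_id "{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\t{source}\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                for t in g.transcripts:
                    ts, te = t.span
                    ta = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                    fh.write(
                        f"{g.chrom}\t{source}\ttranscript\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t{ta}\n"
                    )
                    for s, e in t.exons:
                        fh.write(
                            f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{ta}\n"
                        )
                    if t.cds is not None:
                        cs, ce = t.cds
                        for s, e in t.exons:
                            a, b = max(s, cs), min(e, ce)
                            if a < b:
                                fh.write(
                                    f"{g.chrom}\t{source}\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t0\t{ta}\n"
                                )

    @classmethod
    def read(cls, fasta_path: str | Path, gtf_path: str | Path) -> "GenomeBundle":
        sequences = _read_fasta(fasta_path)
        genes = read_gtf_genes(gtf_path)
        return cls(sequences, genes)

    def serialize(self) -> str:
        """Canonical text form (FASTA + GTF), used for determinism checks."""
        buf = io.StringIO()
        for name in sorted(self.sequences):
            buf.write(f">{name}\n{self.sequences[name]}\n")
        for g in self.genes:
            for t in g.transcripts:
                buf.write(
                    f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{t.transcript_id}"
                    f"\t{t.exons}\t{t.cds}\n"
                )
        return buf.getvalue()


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip('"')
    return None


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GTF file (gene/transcript/exon/CDS features)."""
    exons: dict[tuple[str, str], list[Interval]] = {}
    cds: dict[tuple[str, str], list[Interval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene_id -> (chrom, strand)
    tx_order: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, feature, start, end, strand, attrs = f[0], f[2], f[3], f[4], f[6], f[8]
            gid = _attr(attrs, "gene_id")
            if gid is None:
                continue
            meta.setdefault(gid, (chrom, strand))
            if feature in ("exon", "CDS"):
                tid = _attr(attrs, "transcript_id")
                key = (gid, tid)
                if feature == "exon":
                    if tid not in tx_order.setdefault(gid, []):
                        tx_order[gid].append(tid)
                    exons.setdefault(key, []).append((int(start) - 1, int(end)))
                else:
                    cds.setdefault(key, []).append((int(start) - 1, int(end)))
    genes = []
    for gid, (chrom, strand) in meta.items():
        txs = []
        for tid in tx_order.get(gid, []):
            ex = tuple(sorted(exons[(gid, tid)]))
            c = cds.get((gid, tid))
            interval = (min(s for s, _ in c), max(e for _, e in c)) if c else None
            txs.append(Transcript(tid, ex, interval))
        if txs:
            genes.append(GeneModel(gid, chrom, strand, txs))
    return genes
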