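"""Junction-scaffold quantification of circRNAs.

For every unique back-spliced junction, a reference scaffold of up to
200 nt is built from the genomic sequence flanking the junction — the last
100 nt before the donor end followed by the first 100 nt after the acceptor
start, reverse-complemented for minus-strand circles so the scaffold reads
5'->3' in transcript orientation.  Flanks are genomic (not spliced), which
faithfully mirrors a getfasta-style sequence extraction; scaffolds whose
flanks would run into intronic sequence (terminal exons shorter than the
flank) and short circles whose two flanks overlap are flagged.

Individual mates are aligned end-to-end against the scaffolds, PCR
duplicates are collapsed on alignment start coordinates, junction-spanning
mates are counted per circRNA and library, and the per-tissue expression
filter (>= 6 deduplicated reads summed over a tissue's six libraries) and
the multi-gene filter (junction boundaries in exons of two different genes,
a signature of duplicated paralogs rather than back-splicing) are applied.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._seq import revcomp
from .genome import GenomeBundle

log = logging.getLogger(__name__)

DEFAULT_FLANK = 100
DEFAULT_SCORE_THRESHOLD = -15
MISMATCH_PENALTY = 6
GAP_OPEN = 5
GAP_EXTEND = 3
DEFAULT_MIN_OVERHANG = 10
DEFAULT_MIN_TOTAL = 6


@dataclass(frozen=True)
class CircJunction:
    """One back-spliced junction locus: the unit of annotation."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    source: str = "de-novo"  # known / de-novo / both
    host_gene: str = ""

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class JunctionScaffold:
    circ_id: str
    sequence: str
    offset: int  # donor-side flank length = acceptor first-base position
    source: str
    short_circle_overlap: bool = False
    intronic_flank: bool = False


@dataclass(frozen=True)
class JunctionAlignment:
    read_id: str
    circ_id: str
    start: int
    strand: str
    score: int
    mismatches: int
    library: str = ""


@dataclass
class JunctionCountMatrix:
    counts: pd.DataFrame            # circ_id x library, deduplicated
    library_totals: dict[str, int]  # linearly aligned + junction reads


def merge_annotations(known: list[CircJunction],
                      de_novo: list[CircJunction]) -> list[CircJunction]:
    """Merge on identical (chrom, start, end, strand); remember provenance."""
    merged: dict[tuple, CircJunction] = {}
    for c in known:
        merged[c.key] = CircJunction(c.circ_id, *c.key, source="known",
                                     host_gene=c.host_gene)
    for i, c in enumerate(de_novo):
        if c.key in merged:
            m = merged[c.key]
            merged[c.key] = CircJunction(m.circ_id, *m.key, source="both",
                                         host_gene=m.host_gene)
        else:
            cid = c.circ_id or f"denovo{i + 1:05d}"
            merged[c.key] = CircJunction(cid, *c.key, source="de-novo")
    return [merged[k] for k in sorted(merged)]


def build_scaffolds(circs: list[CircJunction], bundle: GenomeBundle,
                    flank: int = DEFAULT_FLANK) -> list[JunctionScaffold]:
    """One scaffold per unique junction, genomic flanks of
    ``min(flank, span)`` nt on each side of the back-spliced junction."""
    out = []
    for c in circs:
        span = c.end - c.start
        if span < 1:
            raise ValueError(f"{c.circ_id}: circle span < 1 nt")
        fl = min(flank, span)
        chrom = bundle.sequences[c.chrom]
        donor_g = chrom[c.end - fl:c.end]
        acceptor_g = chrom[c.start:c.start + fl]
        if c.strand == "-":
            donor_flank = revcomp(acceptor_g)
            acceptor_flank = revcomp(donor_g)
        else:
            donor_flank = donor_g
            acceptor_flank = acceptor_g
        seq = (donor_flank + acceptor_flank).upper()
        intronic = _flank_leaves_terminal_exons(c, bundle, fl)
        out.append(JunctionScaffold(
            c.circ_id, seq, fl, c.source,
            short_circle_overlap=span < 2 * flank,
            intronic_flank=intronic))
    return out


def _flank_leaves_terminal_exons(c: CircJunction, bundle: GenomeBundle,
                                 fl: int) -> bool:
    """True when a genomic flank extends beyond the terminal exon whose
    boundary defines the junction (possible intronic content)."""
    for g in bundle.genes_overlapping(c.chrom, c.start, c.end):
        for t in g.transcripts:
            first = next((e for e in t.exons if e[0] == c.start), None)
            last = next((e for e in t.exons if e[1] == c.end), None)
            if first and last:
                return (first[1] - first[0] < fl) or (last[1] - last[0] < fl)
    return False


def align_to_scaffolds(mates, scaffolds: list[JunctionScaffold],
                       score_threshold: int = DEFAULT_SCORE_THRESHOLD,
                       min_overhang: int = DEFAULT_MIN_OVERHANG,
                       library: str = "") -> list[JunctionAlignment]:
    """End-to-end alignment of each mate against the scaffold set.

    ``mates`` yields (read_id, sequence) pairs.  Substitution-only
    end-to-end placements are scored at -6 per mismatch (the score budget of
    -15 therefore admits at most two mismatches); alignments must cover the
    junction with at least ``min_overhang`` nt on each side, and a mate
    whose best score is reached on more than one scaffold is discarded as
    ambiguous.
    """
    max_mm = (-score_threshold) // MISMATCH_PENALTY
    k = 20
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    seqs = [s.sequence for s in scaffolds]
    for si, seq in enumerate(seqs):
        for i in range(len(seq) - k + 1):
            index[seq[i:i + k]].append((si, i))
    out = []
    for read_id, seq in mates:
        L = len(seq)
        if L < k:
            continue
        seed_offs = (0, (L - k) // 2, L - k)
        best: list[tuple[int, int, int, str, int]] = []  # score desc
        best_score = None
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            cands: set[tuple[int, int]] = set()
            for off in seed_offs:
                for si, pos in index.get(oriented[off:off + k], ()):
                    start = pos - off
                    if 0 <= start and start + L <= len(seqs[si]):
                        cands.add((si, start))
            for si, start in cands:
                ref = seqs[si][start:start + L]
                mm = sum(a != b for a, b in zip(oriented, ref))
                if mm > max_mm:
                    continue
                score = -MISMATCH_PENALTY * mm
                off_j = scaffolds[si].offset
                if not (start <= off_j - min_overhang
                        and start + L >= off_j + min_overhang):
                    continue
                if best_score is None or score > best_score:
                    best = [(score, si, start, strand, mm)]
                    best_score = score
                elif score == best_score:
                    best.append((score, si, start, strand, mm))
        if not best:
            continue
        circ_ids = {scaffolds[b[1]].circ_id for b in best}
        if len(circ_ids) > 1:
            continue  # ambiguous multi-scaffold mate
        score, si, start, strand, mm = best[0]
        out.append(JunctionAlignment(read_id, scaffolds[si].circ_id,
                                     start, strand, score, mm, library))
    return out


def dedupe(alignments: list[JunctionAlignment]) -> list[JunctionAlignment]:
    """Collapse likely PCR duplicates within a library: alignments sharing
    (circ_id, start, strand) keep the highest score (ties: smallest
    read_id).  Idempotent."""
    kept: dict[tuple, JunctionAlignment] = {}
    for a in alignments:
        key = (a.library, a.circ_id, a.start, a.strand)
        prev = kept.get(key)
        if prev is None or (a.score, _neg(a.read_id)) > (prev.score, _neg(prev.read_id)):
            kept[key] = a
    return [kept[k] for k in sorted(kept)]


class _neg:
    """Reverses string ordering so max-by-score prefers the lexicographically
    smallest read_id on ties."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_neg") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_neg") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg) and self.s == other.s


def count_junctions(alignments_by_library: dict[str, list[JunctionAlignment]],
                    scaffolds: list[JunctionScaffold],
                    libraries: list[str],
                    linear_reads: dict[str, int] | None = None,
                    fragment_of=lambda read_id: read_id
                    ) -> JunctionCountMatrix:
    """Deduplicated junction read counts per circRNA and library.

    Fragments whose two mates align to *different* scaffolds are excluded
    entirely (no-chimera rule); ``fragment_of`` maps a read identifier to
    its fragment so the two mates of a pair can be recognised.
    """
    circ_ids = [s.circ_id for s in scaffolds]
    counts = pd.DataFrame(0, index=circ_ids, columns=list(libraries), dtype=int)
    totals = {}
    for lib in libraries:
        alns = alignments_by_library.get(lib, [])
        if not alns:
            log.warning("library %s has zero junction alignments", lib)
        frag_circ: dict[str, set[str]] = defaultdict(set)
        for a in alns:
            frag_circ[fragment_of(a.read_id)].add(a.circ_id)
        chimeric = {f for f, cs in frag_circ.items() if len(cs) > 1}
        n_junc = 0
        for a in alns:
            if fragment_of(a.read_id) in chimeric:
                continue
            counts.loc[a.circ_id, lib] += 1
            n_junc += 1
        totals[lib] = (linear_reads or {}).get(lib, 0) + n_junc
    return JunctionCountMatrix(counts, totals)


def expression_filter(matrix: JunctionCountMatrix,
                      design: pd.DataFrame,
                      min_total: int = DEFAULT_MIN_TOTAL,
                      strict: bool = True
                      ) -> tuple[JunctionCountMatrix, dict[str, list[str]]]:
    """Per-tissue expression cutoff: a circRNA is retained for a tissue iff
    its summed deduplicated count across that tissue's six libraries (three
    young + three old) reaches ``min_total`` — an average of one read per
    replicate.  Returns the matrix restricted to circles retained in at
    least one tissue plus per-tissue retained-set membership.

    With ``strict`` a tissue must have exactly six libraries; otherwise the
    threshold is scaled proportionally to the library count.
    """
    retained: dict[str, list[str]] = {}
    keep_any: set[str] = set()
    for tissue, sub in design.groupby("tissue", sort=True):
        libs = list(sub["library"])
        if len(libs) != 6:
            if strict:
                raise ValueError(
                    f"tissue {tissue} has {len(libs)} libraries, expected 6")
            threshold = min_total * len(libs) / 6.0
        else:
            threshold = float(min_total)
        sums = matrix.counts[libs].sum(axis=1)
        ids = sorted(sums.index[sums >= threshold])
        retained[tissue] = ids
        keep_any |= set(ids)
    keep = [c for c in matrix.counts.index if c in keep_any]
    return (JunctionCountMatrix(matrix.counts.loc[keep],
                                dict(matrix.library_totals)), retained)


def multigene_filter(circs: list[CircJunction], bundle: GenomeBundle
                     ) -> tuple[list[CircJunction], list[CircJunction]]:
    """Remove junctions whose start lies in an exon of one gene and whose
    end lies in an exon of a *different* gene — the signature of a linear
    splice between duplicated paralogs misread as back-splicing.  Junctions
    with no gene overlap are kept and annotated as intergenic."""
    kept, removed = [], []
    for c in circs:
        start_genes = _exon_genes_at(bundle, c.chrom, c.start)
        end_genes = _exon_genes_at(bundle, c.chrom, c.end - 1)
        host = ""
        if start_genes and end_genes:
            common = start_genes & end_genes
            if common:
                host = sorted(common)[0]
            else:
                removed.append(c)
                continue
        elif start_genes or end_genes:
            host = sorted(start_genes or end_genes)[0]
        else:
            host = "intergenic"
        kept.append(CircJunction(c.circ_id, *c.key, source=c.source,
                                 host_gene=host))
    return kept, removed


def _exon_genes_at(bundle: GenomeBundle, chrom: str, pos: int) -> set[str]:
    out = set()
    for g in bundle.genes_overlapping(chrom, pos, pos + 1):
        for s, e in g.exon_union():
            if s <= pos < e:
                out.add(g.gene_id)
                break
    return out


def write_scaffold_fasta(scaffolds: list[JunctionScaffold],
                         circs: list[CircJunction], path: str | Path) -> None:
    by_id = {c.circ_id: c for c in circs}
    with open(path, "w") as fh:
        for s in scaffolds:
            c = by_id[s.circ_id]
            fh.write(f">{s.circ_id}|{c.chrom}|{c.start}|{c.end}|{c.strand}"
                     f"|{s.offset}\n{s.sequence}\n")
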