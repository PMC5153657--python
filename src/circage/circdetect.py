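"""De novo back-splice junction discovery (split-anchor alignment).

Mates that fail linear alignment are split into two terminal anchors.  When
both anchors align uniquely to the genome with the tail anchor *upstream*
of the head anchor (out-of-order relative to the genome), the read is
extended from both anchors toward a single breakpoint flanked by canonical
splice signals: GT immediately 3' of the donor exon end and AG immediately
5' of the acceptor exon start on the plus strand, or the genomic CT..AC
equivalent on the minus strand.  Exactly one valid breakpoint must exist;
reads with two or more equally valid breakpoints are counted as ambiguous
and discarded rather than arbitrarily assigned.

Junction coordinates are 0-based half-open: ``start`` is the acceptor exon
start and ``end`` the (exclusive) donor exon end, so ``start < end`` always
holds for a back-spliced junction.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from ._align import KmerIndex, LinearClassifier
from ._seq import revcomp

log = logging.getLogger(__name__)

DEFAULT_ANCHOR = 20
DEFAULT_MAX_MM = 2
DEFAULT_MAX_SPAN = 1_000_000
DEFAULT_MIN_READS = 6

# (donor dinucleotide just after end, acceptor dinucleotide just before start)
SPLICE_SIGNALS = {"+": ("GT", "AG"), "-": ("CT", "AC")}


@dataclass(frozen=True)
class CandidateJunction:
    chrom: str
    start: int   # acceptor exon start (0-based)
    end: int     # donor exon end (exclusive)
    strand: str
    support: int = 1
    breakpoint_mismatches: int = 0
    splice_signal: str = "GTAG"


@dataclass
class DetectorStats:
    mates_in: int = 0
    too_short: int = 0
    no_unique_anchors: int = 0
    in_order: int = 0
    no_breakpoint: int = 0
    ambiguous: int = 0
    junction_reads: int = 0


def split_anchors(read: str, anchor_length: int = DEFAULT_ANCHOR
                  ) -> tuple[str, str] | None:
    """First and last ``anchor_length`` bases, or None for too-short reads."""
    if len(read) < 2 * anchor_length:
        return None
    return read[:anchor_length], read[-anchor_length:]


def linear_filter(reads, bundle, classifier: LinearClassifier | None = None,
                  max_mm: int = DEFAULT_MAX_MM):
    """Split a library's mates into linearly aligned and unaligned.

    Returns ``(unaligned, n_linear, fragment_genes)`` where ``unaligned`` is
    a list of (read_id, mate_index, sequence) for mates with no end-to-end
    genome or spliced-transcriptome alignment within the mismatch budget,
    ``n_linear`` counts linearly aligned mates, and ``fragment_genes`` maps a
    fragment name to the tuple of per-mate host-gene sets (for linear
    quantification).
    """
    if classifier is None:
        classifier = LinearClassifier(bundle, max_mm=max_mm)
    unaligned: list[tuple[str, int, str]] = []
    n_linear = 0
    fragment_genes: dict[str, list[frozenset[str] | None]] = {}
    if not reads:
        log.info("linear_filter: empty input")
    for r in reads:
        genes: list[frozenset[str] | None] = [None, None]
        for mate, seq in ((1, r.seq1), (2, r.seq2)):
            res = classifier.classify(seq)
            if res.aligned:
                n_linear += 1
                genes[mate - 1] = res.genes
            else:
                unaligned.append((r.name, mate, seq))
        fragment_genes[r.name] = genes
    return unaligned, n_linear, fragment_genes


def resolve_breakpoint(read: str, genome_index: KmerIndex,
                       anchor_length: int = DEFAULT_ANCHOR,
                       max_mm: int = DEFAULT_MAX_MM,
                       max_span: int = DEFAULT_MAX_SPAN,
                       stats: DetectorStats | None = None
                       ) -> CandidateJunction | None:
    """Try both read orientations; emit the unique out-of-order breakpoint.

    The head anchor fixes the donor-side placement, the tail anchor the
    acceptor-side placement; the breakpoint position ``b`` partitions the
    read into ``read[:b]`` (ending at donor exon end) and ``read[b:]``
    (starting at acceptor exon start).  Candidate breakpoints must have
    canonical splice signals and at most ``max_mm`` total extension
    mismatches; two or more valid candidates make the read ambiguous.
    """
    stats = stats if stats is not None else DetectorStats()
    L = len(read)
    anchors = split_anchors(read, anchor_length)
    if anchors is None:
        stats.too_short += 1
        return None
    found: list[tuple[str, int, int, str, int, str]] = []
    saw_unique_pair = False
    saw_in_order = False
    for oriented in (read, revcomp(read)):
        head, tail = oriented[:anchor_length], oriented[-anchor_length:]
        h = genome_index.unique_hit(head)
        t = genome_index.unique_hit(tail)
        if h is None or t is None:
            continue
        chrom_h, off_h = genome_index.resolve(h)
        chrom_t, off_t = genome_index.resolve(t)
        if chrom_h != chrom_t:
            continue
        saw_unique_pair = True
        if off_t >= off_h:
            saw_in_order = True
            continue
        seq = genome_index._seqs[chrom_h]
        base = off_t + anchor_length - L  # genomic start of read[b:] minus b
        # prefix mismatches of oriented[:b] against genome[off_h : off_h+b]
        head_mm = [0] * (L + 1)
        for i in range(L):
            ref_i = off_h + i
            bad = ref_i >= len(seq) or oriented[i] != seq[ref_i]
            head_mm[i + 1] = head_mm[i] + bad
        tail_mm = [0] * (L + 1)  # suffix mismatches of oriented[b:]
        for j in range(L - 1, -1, -1):
            ref_j = base + j
            bad = ref_j < 0 or oriented[j] != seq[ref_j]
            tail_mm[j] = tail_mm[j + 1] + bad
        for b in range(1, L):
            total = head_mm[b] + tail_mm[b]
            if total > max_mm:
                continue
            end = off_h + b        # donor exon end (exclusive)
            start = base + b       # acceptor exon start
            if not (0 < start < end <= len(seq)):
                continue
            if end - start > max_span:
                continue
            for strand, (donor, acceptor) in SPLICE_SIGNALS.items():
                if (seq[end:end + 2] == donor
                        and seq[start - 2:start] == acceptor):
                    found.append((chrom_h, start, end, strand, total,
                                  donor + acceptor))
    if not found:
        if not saw_unique_pair:
            stats.no_unique_anchors += 1
        elif saw_in_order:
            stats.in_order += 1
        else:
            stats.no_breakpoint += 1
        return None
    best = min(f[4] for f in found)
    top = [f for f in found if f[4] == best]
    if len(top) > 1:
        stats.ambiguous += 1
        return None
    chrom, start, end, strand, mm, signal = top[0]
    stats.junction_reads += 1
    return CandidateJunction(chrom, start, end, strand,
                             breakpoint_mismatches=mm, splice_signal=signal)


def call_junctions(unaligned_by_library: dict[str, list[tuple[str, int, str]]],
                   bundle, min_reads: int = DEFAULT_MIN_READS,
                   anchor_length: int = DEFAULT_ANCHOR,
                   max_mm: int = DEFAULT_MAX_MM,
                   max_span: int = DEFAULT_MAX_SPAN,
                   genome_index: KmerIndex | None = None,
                   stats: DetectorStats | None = None
                   ) -> list[CandidateJunction]:
    """Aggregate junction reads across libraries and filter on support.

    Support is the number of *distinct* junction reads — exact duplicates
    (same sequence, hence the same anchor placements) collapse to one.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if genome_index is None:
        genome_index = KmerIndex(bundle.sequences, anchor_length)
    stats = stats if stats is not None else DetectorStats()
    seen: dict[tuple, set] = defaultdict(set)
    meta: dict[tuple, CandidateJunction] = {}
    for lib in sorted(unaligned_by_library):
        for read_id, mate, seq in unaligned_by_library[lib]:
            stats.mates_in += 1
            cand = resolve_breakpoint(seq, genome_index, anchor_length,
                                      max_mm, max_span, stats)
            if cand is None:
                continue
            key = (cand.chrom, cand.start, cand.end, cand.strand)
            # dedup signature: placement of the read on the genome
            seen[key].add((lib, seq))
            if key not in meta:
                meta[key] = cand
    out = []
    for key in sorted(seen):
        support = len(seen[key])
        if support >= min_reads:
            c = meta[key]
            out.append(CandidateJunction(c.chrom, c.start, c.end, c.strand,
                                         support, c.breakpoint_mismatches,
                                         c.splice_signal))
    return out


def write_junction_bed(junctions: list[CandidateJunction],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, j in enumerate(junctions):
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\tdenovo{i + 1:05d}"
                     f"\t{j.support}\t{j.strand}\n")
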