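"""Seed-and-verify exact-ish read matching.

A k-mer hash index over the reference provides candidate placements; a
candidate is verified by direct end-to-end comparison with a substitution
budget.  With three disjoint seeds per read and a budget of two
substitutions, at least one seed is error-free for any read that truly
matches (pigeonhole), so candidate generation is complete.  Indels are not
modelled.
"""

from __future__ import annotations

from ._seq import mismatches, revcomp


class KmerIndex:
    """Exact k-mer index over a set of named sequences.

    Positions are stored in a single concatenated coordinate space;
    :meth:`resolve` maps a global position back to ``(name, offset)``.
    """

    def __init__(self, sequences: dict[str, str], k: int = 20):
        self.k = k
        self.names: list[str] = sorted(sequences)
        self.offsets: list[int] = []
        self._seqs = sequences
        pos = 0
        index: dict[str, int | list[int]] = {}
        self._concat_parts: list[str] = []
        for name in self.names:
            seq = sequences[name]
            self.offsets.append(pos)
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                g = pos + i
                prev = index.get(kmer)
                if prev is None:
                    index[kmer] = g
                elif isinstance(prev, int):
                    index[kmer] = [prev, g]
                else:
                    prev.append(g)
            pos += len(seq) + 1  # +1 guard so placements never span sequences
            self._concat_parts.append(seq)
        self.concat = "\x00".join(self._concat_parts)
        self.total = pos
        self.index = index

    def resolve(self, gpos: int) -> tuple[str, int]:
        lo, hi = 0, len(self.offsets) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if self.offsets[mid] <= gpos:
                lo = mid
            else:
                hi = mid - 1
        return self.names[lo], gpos - self.offsets[lo]

    def lookup(self, kmer: str) -> list[int]:
        hit = self.index.get(kmer)
        if hit is None:
            return []
        return [hit] if isinstance(hit, int) else hit

    def unique_hit(self, kmer: str) -> int | None:
        """Global position of the k-mer iff it occurs exactly once."""
        hit = self.index.get(kmer)
        return hit if isinstance(hit, int) else None

    def seed_starts(self, read_len: int) -> tuple[int, ...]:
        k = self.k
        if read_len < 3 * k:
            return tuple(sorted({0, max(0, (read_len - k) // 2), read_len - k}))
        return (0, (read_len - k) // 2, read_len - k)

    def end_to_end_hits(self, seq: str, max_mm: int = 2) -> list[tuple[int, int]]:
        """All (global_start, n_mismatches) placements of ``seq`` with
        at most ``max_mm`` substitutions, forward orientation only."""
        L = len(seq)
        concat = self.concat
        cands: set[int] = set()
        for off in self.seed_starts(L):
            for g in self.lookup(seq[off:off + self.k]):
                start = g - off
                if start >= 0 and start + L <= self.total:
                    cands.add(start)
        hits = []
        for start in cands:
            ref = concat[start:start + L]
            if len(ref) < L or "\x00" in ref:
                continue
            mm = mismatches(seq, ref, max_mm)
            if mm <= max_mm:
                hits.append((start, mm))
        return hits


class MateAlignment:
    __slots__ = ("aligned", "genes")

    def __init__(self, aligned: bool, genes: frozenset[str]):
        self.aligned = aligned
        self.genes = genes


class LinearClassifier:
    """Classifies mates as linearly aligned (genome or spliced transcriptome)
    or unaligned, and records the host gene(s) of aligned mates."""

    def __init__(self, bundle, k: int = 20, max_mm: int = 2):
        self.bundle = bundle
        self.max_mm = max_mm
        self.genome_index = KmerIndex(bundle.sequences, k)
        tx_seqs: dict[str, str] = {}
        self._tx_gene: dict[str, str] = {}
        for g in bundle.genes:
            for t in g.transcripts:
                name = t.transcript_id
                tx_seqs[name] = bundle.spliced_sequence(g, t)
                self._tx_gene[name] = g.gene_id
        self.tx_index = KmerIndex(tx_seqs, k)
        # gene spans per chromosome for genomic-hit -> gene mapping
        self._spans: dict[str, list[tuple[int, int, str]]] = {}
        for g in bundle.genes:
            s, e = g.span
            self._spans.setdefault(g.chrom, []).append((s, e, g.gene_id))
        for lst in self._spans.values():
            lst.sort()

    def _genes_at(self, chrom: str, start: int, end: int) -> set[str]:
        out = set()
        for s, e, gid in self._spans.get(chrom, []):
            if s < end and start < e:
                out.add(gid)
            if s >= end:
                break
        return out

    def classify(self, seq: str) -> MateAlignment:
        for oriented in (seq, revcomp(seq)):
            ghits = self.genome_index.end_to_end_hits(oriented, self.max_mm)
            if ghits:
                genes: set[str] = set()
                for start, _ in ghits:
                    chrom, off = self.genome_index.resolve(start)
                    genes |= self._genes_at(chrom, off, off + len(seq))
                return MateAlignment(True, frozenset(genes))
            thits = self.tx_index.end_to_end_hits(oriented, self.max_mm)
            if thits:
                genes = {
                    self._tx_gene[self.tx_index.resolve(start)[0]]
                    for start, _ in thits
                }
                return MateAlignment(True, frozenset(genes))
        return MateAlignment(False, frozenset())
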