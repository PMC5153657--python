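"""MicroRNA seed-match site scanning restricted to circRNA exons.

Canonical TargetScan-style site types against the seed (mature microRNA
bases 2-8, 5'->3'):

* 7mer-m8 — target matches the reverse complement of seed bases 2-8;
* 7mer-A1 — target matches the reverse complement of seed bases 2-7,
  followed by an A opposite microRNA position 1;
* 8mer — both: reverse complement of bases 2-8 followed by an A.

An 8mer subsumes its component 7mers (no double counting).  A site is
conserved when the aligned columns it occupies contain a valid site of the
same family (any type, unless strict typing is requested) in every other
required species of a user-supplied gapped alignment with the reference
species first.  Sites are finally restricted to annotated exons of the
circRNA locus, and the most frequent families per locus are summarised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from ._seq import revcomp
from .genome import GenomeBundle
from .junctionquant import CircJunction

log = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass(frozen=True)
class MiRNAFamily:
    name: str
    seed: str  # bases 2-8 of the mature microRNA, 5'->3', RNA alphabet

    def __post_init__(self):
        if len(self.seed) != 7:
            raise ValueError(f"{self.name}: seed must be 7 nt, got {self.seed!r}")
        if set(self.seed) - set("ACGU"):
            raise ValueError(f"{self.name}: seed must be ACGU, got {self.seed!r}")


@dataclass(frozen=True)
class SiteHit:
    circ_id: str
    family: str
    site_type: str
    position: int  # 0-based start in the scanned sequence
    length: int
    conserved: bool = False


def load_families(path: str | Path | None = None) -> list[MiRNAFamily]:
    """Family TSV (name, seed).  Without a path, the bundled representative
    list of broadly conserved mouse microRNA families is used; it is an
    editable input, not a frozen database."""
    if path is None:
        ref = resources.files("circage").joinpath("data/mir_families.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    fams = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("family"):
            continue
        name, seed = line.split("\t")[:2]
        fams.append(MiRNAFamily(name, seed.upper().replace("T", "U")))
    return fams


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _check_alphabet(seq: str) -> None:
    for i, ch in enumerate(seq.upper()):
        if ch not in "ACGTUN":
            raise ValueError(f"invalid character {ch!r} at position {i}")


def find_seed_sites(target: str, family: MiRNAFamily,
                    circ_id: str = "") -> list[SiteHit]:
    """All seed-match sites of one family in a target sequence (transcript
    orientation), with the 8mer subsumption rule applied."""
    _check_alphabet(target)
    t = _dna(target)
    m8 = _dna(revcomp(family.seed.replace("U", "T")))        # rc of bases 2-8
    m7 = _dna(revcomp(family.seed[:6].replace("U", "T")))    # rc of bases 2-7
    hits: list[SiteHit] = []
    # 8mer / 7mer-m8: scan matches of the 7-nt m8 core
    i = t.find(m8)
    while i != -1:
        if i + 7 < len(t) and t[i + 7] == "A":
            hits.append(SiteHit(circ_id, family.name, "8mer", i, 8))
        else:
            hits.append(SiteHit(circ_id, family.name, "7mer-m8", i, 7))
        i = t.find(m8, i + 1)
    # 7mer-A1: rc of bases 2-7 followed by A, not subsumed by an 8mer
    probe = m7 + "A"
    i = t.find(probe)
    while i != -1:
        is_part_of_8mer = i >= 1 and t[i - 1:i + 7] == m8 + "A"
        if not is_part_of_8mer:
            hits.append(SiteHit(circ_id, family.name, "7mer-A1", i, 7))
        i = t.find(probe, i + 1)
    hits.sort(key=lambda h: (h.position, h.site_type))
    return hits


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def _column_map(gapped: str) -> list[int]:
    """Ungapped position -> alignment column."""
    return [i for i, ch in enumerate(gapped) if ch != "-"]


def conservation_filter(hits: list[SiteHit],
                        alignment: dict[str, str],
                        reference: str,
                        required: list[str] | None = None,
                        families: dict[str, MiRNAFamily] | None = None,
                        strict_type: bool = False
                        ) -> tuple[list[SiteHit], int]:
    """Mark reference-species hits conserved when every other required
    species carries a site of the same family within the hit's aligned
    columns.  Returns (hits with conserved flags, n_unevaluable)."""
    if families is None:
        raise ValueError("families mapping (name -> MiRNAFamily) is required")
    if required is None:
        required = [s for s in alignment if s != reference]
    ref_gapped = alignment[reference]
    colmap = _column_map(ref_gapped)
    out = []
    unevaluable = 0
    for h in hits:
        if h.position + h.length > len(colmap):
            unevaluable += 1
            out.append(replace(h, conserved=False))
            continue
        cols = colmap[h.position:h.position + h.length]
        lo, hi = cols[0], cols[-1] + 1
        ok = True
        for sp in required:
            gapped = alignment.get(sp)
            if gapped is None:
                unevaluable += 1
                ok = False
                break
            window = gapped[lo:hi].replace("-", "")
            sp_hits = find_seed_sites(window, families[h.family])
            if strict_type:
                sp_hits = [s for s in sp_hits if s.site_type == h.site_type]
            if not sp_hits:
                ok = False
                break
        out.append(replace(h, conserved=ok))
    return out, unevaluable


# ---------------------------------------------------------------------------
# exon restriction and summaries
# ---------------------------------------------------------------------------

def exon_restrict(hits: list[SiteHit], circ: CircJunction,
                  bundle: GenomeBundle,
                  genomic_positions: bool = True) -> list[SiteHit]:
    """Keep only hits whose full site interval lies within an annotated exon
    of the circRNA locus (exon union of genes overlapping the circle)."""
    exons: list[tuple[int, int]] = []
    for g in bundle.genes_overlapping(circ.chrom, circ.start, circ.end):
        exons.extend(g.exon_union())
    kept = []
    for h in hits:
        s, e = h.position, h.position + h.length
        if any(es <= s and e <= ee for es, ee in exons):
            kept.append(h)
    return kept


def scan_circ_locus(circ: CircJunction, bundle: GenomeBundle,
                    families: list[MiRNAFamily]) -> list[SiteHit]:
    """Scan the genomic span of a circRNA locus in transcript orientation
    and restrict hits to annotated exons.

    Positions of returned hits are genomic (forward-strand start)."""
    chrom = bundle.sequences[circ.chrom]
    region = chrom[circ.start:circ.end]
    span = circ.end - circ.start
    hits: list[SiteHit] = []
    for fam in sorted(families, key=lambda f: f.name):
        if circ.strand == "-":
            for h in find_seed_sites(revcomp(region), fam, circ.circ_id):
                gpos = circ.start + span - (h.position + h.length)
                hits.append(replace(h, position=gpos))
        else:
            for h in find_seed_sites(region, fam, circ.circ_id):
                hits.append(replace(h, position=circ.start + h.position))
    hits = exon_restrict(hits, circ, bundle)
    hits.sort(key=lambda h: (h.position, h.family, h.site_type))
    return hits


def top_families(hits: list[SiteHit], k: int = 5,
                 conserved_only: bool = False) -> pd.DataFrame:
    """Per circRNA locus, the k families with the most sites (ties broken
    by family name ascending)."""
    rows = []
    use = [h for h in hits if h.conserved] if conserved_only else hits
    by_circ: dict[str, dict[str, int]] = {}
    for h in use:
        by_circ.setdefault(h.circ_id, {}).setdefault(h.family, 0)
        by_circ[h.circ_id][h.family] += 1
    for cid in sorted(by_circ):
        fams = sorted(by_circ[cid].items(), key=lambda kv: (-kv[1], kv[0]))
        for rank, (fam, n) in enumerate(fams[:k], start=1):
            rows.append(dict(circ_id=cid, rank=rank, family=fam, n_sites=n))
    return pd.DataFrame(rows, columns=["circ_id", "rank", "family", "n_sites"])
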