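"""Synthetic study generator with ground truth.

Emulates ribo-depleted total RNA-seq of three tissues (cortex, hippocampus,
heart) at two ages (young = 1 month, old = 22 months) in biological
triplicate, sequenced as paired-end 125 nt reads: a toy genome with
multi-exon genes and canonical splice sites, mature linear transcripts,
circular RNAs whose back-spliced junction only a small fraction of reads
crosses, per-base substitution errors, and PCR duplicates.  Every emitted
read is traceable to its fragment, and a :class:`TruthSet` records the true
circles, the junction-spanning mates, the injected duplicates and the
age effects, so downstream detection and quantification can be checked
against an exact oracle.

Only mature (spliced) linear transcripts are emitted; pre-mRNA/intronic
reads are not modelled.  Circular fragments are drawn uniformly from the
circular permutation of the mature circle sequence; fragments longer than
the circle are redrawn (no rolling-circle reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp
from .genome import GeneModel, GenomeBundle, Interval, Transcript

log = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_GROUPS = (
    ("cortex", "young"), ("cortex", "old"),
    ("hippocampus", "young"), ("hippocampus", "old"),
    ("heart", "young"), ("heart", "old"),
)


@dataclass(frozen=True)
class AgeEffect:
    """Multiplicative old/young effect applied to a subset of circRNAs in
    designated tissues (host linear abundance untouched)."""

    fraction_up: float = 0.25
    fold_up: float = 2.0
    fraction_down: float = 0.05
    fold_down: float = 1.5
    tissues: tuple[str, ...] = ("cortex", "hippocampus")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_500_000
    n_genes: int = 150
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (150, 350)
    intron_length: tuple[int, int] = (300, 1200)
    intergenic_gap: tuple[int, int] = (500, 3000)
    n_circ_genes: int = 37
    multi_circle_genes: int = 3       # how many circRNA genes carry a 2nd circle
    duplicated_gene_pairs: int = 0    # tandem near-identical gene pairs (C4a/C4b-like)
    read_length: int = 125
    fragment_length: tuple[float, float] = (300.0, 60.0)  # mean, sd (nt)
    n_fragments_per_library: int = 11_000
    n_replicates: int = 3
    groups: tuple[tuple[str, str], ...] = DEFAULT_GROUPS
    base_abundance: tuple[float, float] = (0.0, 1.0)  # log-normal mu, sigma (ln)
    # fraction of fragments drawn from circles; only ~1/4 of circular
    # fragments produce a junction-spanning mate, so the realized fraction
    # of junction reads stays below 0.1% of all reads
    circ_fraction_of_reads: float = 0.004
    age_effect: AgeEffect = field(default_factory=AgeEffect)
    duplicate_rate: float = 0.05
    error_rate: float = 0.002
    # acceptor (first circularized) exon index distribution, 1-based; exon 1
    # can never accept a back-splice (it has no upstream acceptor site), so
    # its weight is zero by default and the mode sits on exon 2
    acceptor_index_probs: tuple[float, ...] = (0.0, 0.50, 0.22, 0.16, 0.12)
    circle_exon_count_probs: tuple[float, ...] = (0.20, 0.30, 0.25, 0.15, 0.10)
    strand_specific: bool = False  # emitted pairs are unstranded-equivalent

    def validate(self) -> None:
        if self.read_length < 40:
            raise ValueError("read_length must allow two 20 nt anchors")
        if self.exon_length[0] < 1:
            raise ValueError("minimum exon length must be >= 1")
        for name in ("circ_fraction_of_reads", "duplicate_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.age_effect.fold_up < 1 or self.age_effect.fold_down < 1:
            raise ValueError("age-effect folds must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "age_effect" in raw:
            ae = raw.pop("age_effect")
            if isinstance(ae.get("tissues"), list):
                ae["tissues"] = tuple(ae["tissues"])
            raw["age_effect"] = AgeEffect(**ae)
        for key in ("exons_per_gene", "exon_length", "intron_length",
                    "intergenic_gap", "fragment_length", "base_abundance",
                    "acceptor_index_probs", "circle_exon_count_probs"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "groups" in raw:
            raw["groups"] = tuple(tuple(g) for g in raw["groups"])
        return cls(**raw)


@dataclass
class TrueCircRNA:
    circ_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[Interval, ...]   # genomic member exon intervals, ascending
    base_abundance: float = 1.0
    # (tissue, age) -> multiplier on base abundance
    multipliers: dict = field(default_factory=dict)

    def multiplier(self, tissue: str, age: str) -> float:
        return self.multipliers.get((tissue, age), 1.0)

    @property
    def span(self) -> int:
        return self.end - self.start


def library_id(tissue: str, age: str, replicate: int) -> str:
    return f"{tissue}_{age}_r{replicate}"


class TruthSet:
    """The simulator's record of what is true: circles, junction-spanning
    mates, injected duplicates, effects and per-library totals."""

    def __init__(self, circs: list[TrueCircRNA], read_length: int):
        self.circs = circs
        self.read_length = read_length
        self.libraries: list[tuple[str, str, str, int]] = []  # (lib, tissue, age, rep)
        self.totals: dict[str, int] = {}       # read pairs emitted
        self.n_fragments: dict[str, int] = {}  # sampled fragments (pre-duplication)
        self.duplicates: dict[str, list[str]] = {}
        self.junction_reads: list[dict] = []
        self.effects = pd.DataFrame(
            columns=["circ_id", "direction", "fold", "tissues"]
        )

    # -- recording -------------------------------------------------------

    def add_library(self, lib: str, tissue: str, age: str, rep: int) -> None:
        self.libraries.append((lib, tissue, age, rep))
        self.duplicates.setdefault(lib, [])

    def add_junction_read(self, lib: str, read_id: str, mate: int,
                          circ_id: str, donor_side: int, is_dup: bool) -> None:
        self.junction_reads.append(dict(
            library=lib, read_id=read_id, mate=mate, circ_id=circ_id,
            donor_side=donor_side, is_duplicate=is_dup,
        ))

    # -- oracle queries --------------------------------------------------

    def junction_read_frame(self) -> pd.DataFrame:
        cols = {"library": str, "read_id": str, "mate": int, "circ_id": str,
                "donor_side": int, "is_duplicate": bool}
        if not self.junction_reads:
            return pd.DataFrame({c: pd.Series(dtype=t) for c, t in cols.items()})
        return pd.DataFrame(self.junction_reads, columns=list(cols))

    def library_ids(self) -> list[str]:
        return [lib for lib, *_ in self.libraries]

    def true_junction_counts(self, min_overhang: int = 20,
                             include_duplicates: bool = False) -> pd.DataFrame:
        """circRNA x library counts of junction-spanning mates whose overhang
        on both sides of the junction is at least ``min_overhang``."""
        df = self.junction_read_frame()
        L = self.read_length
        if not include_duplicates:
            df = df[~df.is_duplicate]
        df = df[(df.donor_side >= min_overhang)
                & (L - df.donor_side >= min_overhang)]
        mat = (df.groupby(["circ_id", "library"]).size().unstack(fill_value=0)
               .reindex(columns=self.library_ids(), fill_value=0))
        return mat.reindex(index=[c.circ_id for c in self.circs], fill_value=0)

    def expected_scaffold_counts(self, flank: int = 100,
                                 min_overhang: int = 10) -> pd.DataFrame:
        """What a perfect scaffold quantifier reports after start-coordinate
        duplicate removal: distinct (scaffold start, strand) junction mates
        per circRNA and library.

        A mate with ``donor_side`` bases before the junction aligns end-to-end
        on the scaffold iff both sides fit within the per-circle flanks and
        clear ``min_overhang``.
        """
        L = self.read_length
        spans = {c.circ_id: c.span for c in self.circs}
        df = self.junction_read_frame()
        rows: dict[tuple[str, str], set] = {}
        for rec in df.itertuples(index=False):
            span = spans[rec.circ_id]
            fl = min(flank, span)
            b = rec.donor_side
            a = L - b
            if b < min_overhang or a < min_overhang:
                continue
            if b > fl or a > fl:
                continue  # does not fit the scaffold end-to-end
            strand = "+" if rec.mate == 1 else "-"
            rows.setdefault((rec.circ_id, rec.library), set()).add((fl - b, strand))
        mat = pd.DataFrame(0, index=[c.circ_id for c in self.circs],
                           columns=self.library_ids(), dtype=int)
        for (cid, lib), keys in rows.items():
            mat.loc[cid, lib] = len(keys)
        return mat

    # -- persistence -----------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cat = pd.DataFrame([
            dict(circ_id=c.circ_id, gene_id=c.gene_id, chrom=c.chrom,
                 start=c.start, end=c.end, strand=c.strand,
                 exons=";".join(f"{s}-{e}" for s, e in c.exons),
                 base_abundance=repr(c.base_abundance),
                 multipliers=";".join(
                     f"{t}|{a}|{m!r}" for (t, a), m in sorted(c.multipliers.items())))
            for c in self.circs
        ], columns=["circ_id", "gene_id", "chrom", "start", "end", "strand",
                    "exons", "base_abundance", "multipliers"])
        cat.to_csv(outdir / "truth_circrnas.tsv", sep="\t", index=False)
        libs = pd.DataFrame(
            [dict(library=l, tissue=t, age=a, replicate=r,
                  total_pairs=self.totals.get(l, 0),
                  n_fragments=self.n_fragments.get(l, 0))
             for l, t, a, r in self.libraries])
        libs.to_csv(outdir / "truth_libraries.tsv", sep="\t", index=False)
        self.junction_read_frame().to_csv(
            outdir / "truth_junction_reads.tsv", sep="\t", index=False)
        dups = pd.DataFrame(
            [dict(library=l, read_id=r) for l in sorted(self.duplicates)
             for r in self.duplicates[l]], columns=["library", "read_id"])
        dups.to_csv(outdir / "truth_duplicates.tsv", sep="\t", index=False)
        self.effects.to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
        counts = self.true_junction_counts(min_overhang=0, include_duplicates=False)
        counts.rename_axis("circ_id").to_csv(
            outdir / "truth_junction_counts.tsv", sep="\t")

    @classmethod
    def read(cls, outdir: str | Path, read_length: int = 125) -> "TruthSet":
        outdir = Path(outdir)
        cat = pd.read_csv(outdir / "truth_circrnas.tsv", sep="\t",
                          dtype={"exons": str, "multipliers": str})
        circs = []
        for rec in cat.itertuples(index=False):
            exons = tuple(
                tuple(map(int, part.split("-")))
                for part in str(rec.exons).split(";")) if isinstance(rec.exons, str) and rec.exons else ()
            mult = {}
            if isinstance(rec.multipliers, str) and rec.multipliers:
                for part in rec.multipliers.split(";"):
                    t, a, m = part.split("|")
                    mult[(t, a)] = float(m)
            circs.append(TrueCircRNA(
                rec.circ_id, rec.gene_id, rec.chrom, int(rec.start),
                int(rec.end), rec.strand, exons,
                float(rec.base_abundance), mult))
        truth = cls(circs, read_length)
        libs = pd.read_csv(outdir / "truth_libraries.tsv", sep="\t")
        for rec in libs.itertuples(index=False):
            truth.add_library(rec.library, rec.tissue, rec.age, int(rec.replicate))
            truth.totals[rec.library] = int(rec.total_pairs)
            truth.n_fragments[rec.library] = int(rec.n_fragments)
        jr = pd.read_csv(outdir / "truth_junction_reads.tsv", sep="\t")
        truth.junction_reads = jr.to_dict("records")
        dups = pd.read_csv(outdir / "truth_duplicates.tsv", sep="\t")
        for rec in dups.itertuples(index=False):
            truth.duplicates.setdefault(rec.library, []).append(rec.read_id)
        truth.effects = pd.read_csv(outdir / "truth_effects.tsv", sep="\t")
        return truth


def write_truth(truth: TruthSet, outdir: str | Path) -> None:
    truth.write(outdir)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _rng(config: SimulationConfig, *stream) -> np.random.Generator:
    """Named substream of the config seed, stable across runs."""
    key = [config.seed & 0x7FFFFFFF]
    for item in stream:
        if isinstance(item, str):
            key.append(abs(hash_str(item)) % (2**31))
        else:
            key.append(int(item) % (2**31))
    return np.random.default_rng(key)


def hash_str(s: str) -> int:
    # deterministic across processes (hash() is salted)
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _plant(seq: np.ndarray, pos: int, text: str) -> None:
    seq[pos:pos + len(text)] = np.frombuffer(text.encode(), dtype="S1")


def _gene_structure(rng: np.random.Generator, config: SimulationConfig
                    ) -> tuple[list[int], list[int]]:
    n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    ex = [int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
          for _ in range(n_ex)]
    iv = [int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
          for _ in range(n_ex - 1)]
    return ex, iv


def _make_gene(gene_id: str, chrom: str, strand: str, gstart: int,
               ex_lens: list[int], in_lens: list[int],
               rng: np.random.Generator) -> GeneModel:
    exons: list[Interval] = []
    pos = gstart
    for i, el in enumerate(ex_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(in_lens):
            pos += in_lens[i]
    # CDS: UTRs occupy 10-60% of the terminal exons (transcript orientation)
    tx_exons = exons if strand == "+" else exons[::-1]
    first_len = tx_exons[0][1] - tx_exons[0][0]
    last_len = tx_exons[-1][1] - tx_exons[-1][0]
    utr5 = int(rng.integers(max(1, first_len // 10), max(2, int(first_len * 0.6))))
    utr3 = int(rng.integers(max(1, last_len // 10), max(2, int(last_len * 0.6))))
    if strand == "+":
        cds = (exons[0][0] + utr5, exons[-1][1] - utr3)
    else:
        cds = (exons[0][0] + utr3, exons[-1][1] - utr5)
    tx = Transcript(f"{gene_id}.t1", tuple(exons), cds)
    return GeneModel(gene_id, chrom, strand, [tx])


def generate_genome(config: SimulationConfig) -> GenomeBundle:
    """Toy genome: non-overlapping multi-exon genes with canonical splice
    dinucleotides planted at every intron, uniform-random sequence elsewhere."""
    config.validate()
    rng = _rng(config, "genome")
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {c: _random_seq(rng, config.chrom_length) for c in chrom_names}
    genes: list[GeneModel] = []
    ci = 0
    cursor = {c: 0 for c in chrom_names}

    def place(gene_id: str, ex_lens, in_lens, strand) -> GeneModel:
        nonlocal ci
        glen = sum(ex_lens) + sum(in_lens)
        for _ in range(len(chrom_names)):
            chrom = chrom_names[ci % len(chrom_names)]
            gap = int(rng.integers(config.intergenic_gap[0],
                                   config.intergenic_gap[1] + 1))
            start = cursor[chrom] + gap
            if start + glen <= config.chrom_length:
                cursor[chrom] = start + glen
                ci += 1
                return _make_gene(gene_id, chrom, strand, start, ex_lens, in_lens, rng)
            ci += 1
        raise ValueError(
            f"chromosomes too short to place gene {gene_id} "
            f"({glen} nt needed)")

    for gi in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        ex_lens, in_lens = _gene_structure(rng, config)
        genes.append(place(f"gene{gi + 1:04d}", ex_lens, in_lens, strand))

    # tandem near-identical gene pairs (duplicated paralogs a la C4a/C4b)
    for pi in range(config.duplicated_gene_pairs):
        strand = "+" if rng.random() < 0.5 else "-"
        ex_lens, in_lens = _gene_structure(rng, config)
        ga = place(f"dup{pi + 1:02d}a", ex_lens, in_lens, strand)
        gb = place(f"dup{pi + 1:02d}b", ex_lens, in_lens, strand)
        # copy gene A's whole span onto gene B's location -> identical sequence
        sa, ea = ga.span
        sb, eb = gb.span
        seqs[gb.chrom][sb:eb] = seqs[ga.chrom][sa:ea]
        genes.extend([ga, gb])

    # plant splice dinucleotides (after any duplication copying)
    for g in genes:
        donor, acceptor = ("GT", "AG") if g.strand == "+" else ("CT", "AC")
        for t in g.transcripts:
            for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
                if g.strand == "+":
                    _plant(seqs[g.chrom], e1, "GT")
                    _plant(seqs[g.chrom], s2 - 2, "AG")
                else:
                    _plant(seqs[g.chrom], e1, "CT")
                    _plant(seqs[g.chrom], s2 - 2, "AC")

    sequences = {c: seqs[c].tobytes().decode() for c in chrom_names}
    return GenomeBundle(sequences, genes)


# ---------------------------------------------------------------------------
# circRNA assignment
# ---------------------------------------------------------------------------

def assign_circrnas(bundle: GenomeBundle, config: SimulationConfig
                    ) -> list[TrueCircRNA]:
    """Draw circles on multi-exon genes with the splice-accepting exon index
    biased toward exon 2; a configurable number of genes carry >1 circle."""
    rng = _rng(config, "circles")
    # a circle needs an acceptor site upstream of its first exon and a donor
    # site downstream of its last, so internal exons only: >= 3 exons
    eligible = [g for g in bundle.genes
                if len(g.transcripts[0].exons) >= 3
                and not g.gene_id.startswith("dup")]
    if len(eligible) < config.n_circ_genes:
        raise ValueError(
            f"requested {config.n_circ_genes} circRNA genes but only "
            f"{len(eligible)} eligible genes exist")
    idx = rng.choice(len(eligible), size=config.n_circ_genes, replace=False)
    hosts = [eligible[i] for i in sorted(idx)]
    n_multi = min(config.multi_circle_genes, len(hosts))
    circs: list[TrueCircRNA] = []
    ae = config.age_effect
    effects = []

    def draw_circle(gene: GeneModel, taken: set) -> TrueCircRNA | None:
        tx = gene.transcripts[0]
        n_ex = len(tx.exons)
        # acceptor on an internal exon (2 .. n_ex-1); donor at most n_ex-1
        ap = np.array(config.acceptor_index_probs[:n_ex - 1], dtype=float)
        ap[0] = 0.0
        if ap.sum() <= 0:
            return None
        ap /= ap.sum()
        for _ in range(30):
            a_idx = int(rng.choice(len(ap), p=ap)) + 1  # 1-based, transcript order
            max_m = n_ex - a_idx  # donor stays off the terminal exon
            mp = np.array(config.circle_exon_count_probs[:max_m], dtype=float)
            mp /= mp.sum()
            m = int(rng.choice(len(mp), p=mp)) + 1
            tx_order = tx.exons if gene.strand == "+" else tx.exons[::-1]
            members = tx_order[a_idx - 1:a_idx - 1 + m]
            members = tuple(sorted(members))
            key = (members[0][0], members[-1][1])
            if key not in taken:
                taken.add(key)
                return TrueCircRNA(
                    circ_id="", gene_id=gene.gene_id, chrom=gene.chrom,
                    start=key[0], end=key[1], strand=gene.strand,
                    exons=members)
        return None

    for gi, gene in enumerate(hosts):
        taken: set = set()
        n_here = 2 if gi < n_multi else 1
        for _ in range(n_here):
            c = draw_circle(gene, taken)
            if c is not None:
                circs.append(c)

    circs.sort(key=lambda c: (c.chrom, c.start, c.end))
    for i, c in enumerate(circs):
        c.circ_id = f"circ{i + 1:04d}"
        mu, sigma = config.base_abundance
        c.base_abundance = float(rng.lognormal(mu, sigma))

    # age effects on designated circles in designated tissues
    n = len(circs)
    n_up = int(round(ae.fraction_up * n))
    n_down = int(round(ae.fraction_down * n))
    order = rng.permutation(n)
    up_ids = [circs[i].circ_id for i in order[:n_up]]
    down_ids = [circs[i].circ_id for i in order[n_up:n_up + n_down]]
    by_id = {c.circ_id: c for c in circs}
    for cid in up_ids:
        for t in ae.tissues:
            by_id[cid].multipliers[(t, "old")] = ae.fold_up
        effects.append(dict(circ_id=cid, direction="up", fold=ae.fold_up,
                            tissues=",".join(ae.tissues)))
    for cid in down_ids:
        for t in ae.tissues:
            by_id[cid].multipliers[(t, "old")] = 1.0 / ae.fold_down
        effects.append(dict(circ_id=cid, direction="down", fold=ae.fold_down,
                            tissues=",".join(ae.tissues)))
    # stash for simulate_study to copy into the TruthSet
    assign_circrnas.last_effects = pd.DataFrame(
        effects, columns=["circ_id", "direction", "fold", "tissues"])
    return circs


def circle_sequence(bundle: GenomeBundle, circ: TrueCircRNA) -> str:
    """Mature circle sequence in transcript orientation, starting at the
    splice acceptor; the back-spliced junction sits between the last and the
    first base."""
    chrom = bundle.sequences[circ.chrom]
    seq = "".join(chrom[s:e] for s, e in circ.exons)
    return revcomp(seq) if circ.strand == "-" else seq


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

@dataclass
class FastqRead:
    name: str
    seq1: str
    seq2: str


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for p in pos:
        alt = "ACGT".replace(chars[p], "")
        chars[p] = alt[rng.integers(0, 3)]
    return "".join(chars)


def simulate_library(bundle: GenomeBundle, circs: list[TrueCircRNA],
                     truth: TruthSet, tissue: str, age: str, replicate: int,
                     config: SimulationConfig) -> list[FastqRead]:
    """Simulate one library's read pairs and record its ground truth.

    Fragments are sampled from mature linear transcripts and from the
    circular permutation of mature circle sequences, with the circular
    sampling weight scaled so that circular fragments make up
    ``circ_fraction_of_reads`` of all pairs in expectation.
    """
    if (tissue, age) not in config.groups:
        raise ValueError(f"unknown group ({tissue}, {age})")
    lib = library_id(tissue, age, replicate)
    rng = _rng(config, "library", lib)
    L = config.read_length

    # linear sources, abundance drawn per transcript from a fixed substream
    # so every library sees the same baseline
    arng = _rng(config, "abundance")
    mu, sigma = config.base_abundance
    sources: list[tuple[str, str, float]] = []  # (kind:id, seq, weight)
    for g in bundle.genes:
        for t in g.transcripts:
            ab = float(arng.lognormal(mu, sigma))
            seq = bundle.spliced_sequence(g, t)
            if len(seq) >= L:
                sources.append((f"L:{g.gene_id}", seq, ab * len(seq)))
    lin_weight = sum(w for *_, w in sources)

    circ_sources: list[tuple[str, str, float]] = []
    raw = []
    base_weight = 0.0
    for c in circs:
        seq = circle_sequence(bundle, c)
        if len(seq) < L:
            log.warning("circle %s shorter than read length; skipped", c.circ_id)
            continue
        w = c.base_abundance * c.multiplier(tissue, age) * len(seq)
        base_weight += c.base_abundance * len(seq)
        raw.append((c, seq, w))
    cf = config.circ_fraction_of_reads
    if raw and cf > 0:
        # the scale anchors the *baseline* circular fraction at cf; age
        # effects then genuinely add or remove circular read mass instead of
        # redistributing a fixed total (which would make effects
        # compositional and suppress unchanged circles)
        scale = (cf / (1.0 - cf)) * lin_weight / base_weight
        circ_sources = [(f"C:{c.circ_id}", seq, w * scale) for c, seq, w in raw]

    all_sources = sources + circ_sources
    weights = np.array([w for *_, w in all_sources])
    probs = weights / weights.sum()
    counts = rng.multinomial(config.n_fragments_per_library, probs)

    mean_fl, sd_fl = config.fragment_length
    reads: list[FastqRead] = []
    frag_idx = 0
    n_dups = 0

    for (tag, seq, _), n in zip(all_sources, counts):
        is_circ = tag.startswith("C:")
        slen = len(seq)
        doubled = seq + seq if is_circ else seq
        for _ in range(int(n)):
            # fragment length, truncated to [L, 2L+200] and the source length
            for _try in range(100):
                fl = int(round(rng.normal(mean_fl, sd_fl)))
                fl = max(L, min(fl, 2 * L + 200))
                if fl <= slen:
                    break
            else:
                fl = slen
            if is_circ:
                start = int(rng.integers(0, slen))
            else:
                start = int(rng.integers(0, slen - fl + 1))
            frag = doubled[start:start + fl]
            name = f"{lib}.f{frag_idx:06d}"
            frag_idx += 1
            s1 = frag[:L]
            s2 = revcomp(frag[-L:])
            # record junction-spanning mates before errors are applied
            if is_circ:
                cid = tag[2:]
                for mate, a0 in ((1, start), (2, start + fl - L)):
                    if a0 < slen < a0 + L:
                        truth.add_junction_read(lib, name, mate, cid,
                                                slen - a0, False)
            s1 = _apply_errors(s1, rng, config.error_rate)
            s2 = _apply_errors(s2, rng, config.error_rate)
            reads.append(FastqRead(name, s1, s2))
            if rng.random() < config.duplicate_rate:
                dname = name + ".dup"
                reads.append(FastqRead(dname, s1, s2))
                truth.duplicates[lib].append(dname)
                n_dups += 1
                if is_circ:
                    cid = tag[2:]
                    for mate, a0 in ((1, start), (2, start + fl - L)):
                        if a0 < slen < a0 + L:
                            truth.add_junction_read(lib, dname, mate, cid,
                                                    slen - a0, True)

    truth.totals[lib] = len(reads)
    truth.n_fragments[lib] = frag_idx
    return reads


def simulate_study(config: SimulationConfig, outdir: str | Path | None = None
                   ) -> tuple[GenomeBundle, list[TrueCircRNA], TruthSet,
                              dict[str, list[FastqRead]]]:
    """Generate genome, circles and all libraries of the study design.

    If ``outdir`` is given, genome FASTA, gene-model GTF, circRNA truth BED,
    paired FASTQ files and the truth TSVs are written there.
    """
    bundle = generate_genome(config)
    circs = assign_circrnas(bundle, config)
    truth = TruthSet(circs, config.read_length)
    truth.effects = assign_circrnas.last_effects
    libraries: dict[str, list[FastqRead]] = {}
    for tissue, age in config.groups:
        for rep in range(1, config.n_replicates + 1):
            lib = library_id(tissue, age, rep)
            truth.add_library(lib, tissue, age, rep)
            libraries[lib] = simulate_library(
                bundle, circs, truth, tissue, age, rep, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bundle.write_fasta(outdir / "genome.fa")
        bundle.write_gtf(outdir / "genes.gtf")
        write_circ_bed(circs, outdir / "truth_circrnas.bed")
        for lib, reads in libraries.items():
            write_fastq_pair(reads, outdir / f"{lib}_R1.fastq",
                             outdir / f"{lib}_R2.fastq")
        truth.write(outdir / "truth")
        manifest = pd.DataFrame(
            [dict(library=l, tissue=t, age=a, replicate=r,
                  fastq1=f"{l}_R1.fastq", fastq2=f"{l}_R2.fastq")
             for l, t, a, r in truth.libraries])
        manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return bundle, circs, truth, libraries


def write_circ_bed(circs: list[TrueCircRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in circs:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.circ_id}\t0\t{c.strand}\n")


def write_fastq_pair(reads: list[FastqRead], path1: str | Path,
                     path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            q = "I" * len(r.seq1)
            f1.write(f"@{r.name}/1\n{r.seq1}\n+\n{q}\n")
            q = "I" * len(r.seq2)
            f2.write(f"@{r.name}/2\n{r.seq2}\n+\n{q}\n")


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[FastqRead]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    out = []
    with open(path1) as f1, open(path2) as f2:
        for (n1, s1, _), (n2, s2, _) in zip(FastqGeneralIterator(f1),
                                            FastqGeneralIterator(f2)):
            name = n1.split("/")[0].split()[0]
            out.append(FastqRead(name, s1, s2))
    return out


# ---------------------------------------------------------------------------
# count-level simulators (for statistical calibration studies)
# ---------------------------------------------------------------------------

def simulate_count_study(n_circ: int, rng: np.random.Generator,
                         mean_count: float = 30.0, sigma_ln: float = 1.0,
                         fold: np.ndarray | float = 1.0,
                         n_young: int = 3, n_old: int = 3,
                         library_total: int = 2_000_000
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Deduplicated junction-count matrix drawn directly at the count level.

    Per-circle expected counts are log-normal around ``mean_count`` (the
    log-normal is scaled so its mean is ``mean_count``); library counts are
    Poisson; ``fold`` multiplies the old-group expectation per circle.
    Returns (counts, design, per-library totals).
    """
    base = np.exp(rng.normal(0.0, sigma_ln, size=n_circ))
    base *= mean_count / np.exp(sigma_ln ** 2 / 2)
    fold = np.broadcast_to(np.asarray(fold, dtype=float), (n_circ,))
    libs = [f"young_r{i+1}" for i in range(n_young)] + \
           [f"old_r{i+1}" for i in range(n_old)]
    lam = np.column_stack([base] * n_young + [base * fold] * n_old)
    counts = rng.poisson(lam)
    mat = pd.DataFrame(counts, columns=libs,
                       index=[f"circ{i+1:05d}" for i in range(n_circ)])
    design = pd.DataFrame(
        [dict(library=l, tissue="sim", age=("young" if l.startswith("y") else "old"),
              replicate=int(l.split("_r")[1])) for l in libs])
    totals = {l: library_total for l in libs}
    return mat, design, totals
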