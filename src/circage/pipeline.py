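"""End-to-end orchestration: detect -> annotate -> quantify -> filter ->
normalize -> differential/global/independence -> features -> microRNA sites.

`run_pipeline` works on in-memory objects and returns all tables plus a
JSON-ready summary; `run_all` is the file-based wrapper used by the CLI.
Stage outputs are cached in the results directory and a stage is skipped
when its output already exists for the same effective configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from ._align import LinearClassifier
from .circdetect import DetectorStats, call_junctions, linear_filter
from .expression import (ExpressionTable, circ_linear_independence, circ_tpm,
                         differential, gene_fpkm, global_shift, pca)
from .features import feature_table, tissue_overlap
from .genome import GenomeBundle
from .junctionquant import (CircJunction, JunctionCountMatrix,
                            align_to_scaffolds, build_scaffolds, count_junctions,
                            dedupe, expression_filter, merge_annotations,
                            multigene_filter, write_scaffold_fasta)
from .mirtargets import load_families, scan_circ_locus, top_families
from .synthdata import FastqRead, read_fastq_pair

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Every stage's thresholds, defaulting to their published values."""

    anchor_length: int = 20
    max_mismatches: int = 2
    max_span: int = 1_000_000
    min_reads: int = 6           # de novo junction support cutoff
    flank: int = 100
    score_threshold: int = -15
    min_overhang: int = 10
    min_total: int = 6           # per-tissue expression cutoff
    fc_cutoff: float = 1.5
    alpha: float = 0.05
    top_k_families: int = 5
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    annotation: list
    removed_multigene: list
    scaffolds: list
    counts: JunctionCountMatrix
    retained: dict
    circ_expr: ExpressionTable
    circ_de: dict
    linear_de: dict
    global_shift: dict
    independence: dict
    features: pd.DataFrame
    overlap: pd.DataFrame
    mir_summary: pd.DataFrame
    pca_scores: pd.DataFrame
    summary: dict


def _fragment_of(read_id: str) -> str:
    return read_id.rsplit("/", 1)[0]


def run_pipeline(bundle: GenomeBundle,
                 libraries: dict[str, list[FastqRead]],
                 design: pd.DataFrame,
                 params: PipelineParams | None = None,
                 known_circs: list[CircJunction] | None = None
                 ) -> PipelineResult:
    params = params or PipelineParams()
    lib_ids = list(design["library"])
    classifier = LinearClassifier(bundle, k=params.anchor_length,
                                  max_mm=params.max_mismatches)
    unaligned_by_lib: dict[str, list] = {}
    linear_counts: dict[str, int] = {}
    fragment_genes: dict[str, dict] = {}
    for lib in lib_ids:
        unal, n_lin, fg = linear_filter(libraries[lib], bundle, classifier)
        unaligned_by_lib[lib] = unal
        linear_counts[lib] = n_lin
        fragment_genes[lib] = fg
        log.info("library %s: %d linear mates, %d unaligned",
                 lib, n_lin, len(unal))

    det_stats = DetectorStats()
    junctions = call_junctions(unaligned_by_lib, bundle,
                               min_reads=params.min_reads,
                               anchor_length=params.anchor_length,
                               max_mm=params.max_mismatches,
                               max_span=params.max_span,
                               genome_index=classifier.genome_index
                               if classifier.genome_index.k == params.anchor_length
                               else None,
                               stats=det_stats)
    de_novo = [CircJunction(f"denovo{i + 1:05d}", j.chrom, j.start, j.end,
                            j.strand) for i, j in enumerate(junctions)]
    merged = merge_annotations(known_circs or [], de_novo)
    annotated, removed = multigene_filter(merged, bundle)
    scaffolds = build_scaffolds(annotated, bundle, params.flank)

    alignments_by_lib = {}
    for lib in lib_ids:
        mates = []
        for r in libraries[lib]:
            mates.append((f"{r.name}/1", r.seq1))
            mates.append((f"{r.name}/2", r.seq2))
        alns = align_to_scaffolds(mates, scaffolds,
                                  score_threshold=params.score_threshold,
                                  min_overhang=params.min_overhang,
                                  library=lib)
        alignments_by_lib[lib] = dedupe(alns)

    matrix = count_junctions(alignments_by_lib, scaffolds, lib_ids,
                             linear_reads=linear_counts,
                             fragment_of=_fragment_of)
    filtered, retained = expression_filter(matrix, design,
                                           min_total=params.min_total)
    expr = circ_tpm(filtered.counts, filtered.library_totals, design)
    linear_expr = gene_fpkm(fragment_genes, bundle, design)

    tissues = sorted(design["tissue"].unique())
    circ_de, linear_de, shifts, independence = {}, {}, {}, {}
    host_map = {c.circ_id: c.host_gene for c in annotated}
    for tissue in tissues:
        keep = [c for c in retained[tissue] if c in expr.values.index]
        sub = ExpressionTable(expr.values.loc[keep], design, expr.unit,
                              expr.pseudocount)
        circ_de[tissue] = differential(sub, tissue,
                                       fc_cutoff=params.fc_cutoff,
                                       alpha=params.alpha, correct="none")
        linear_de[tissue] = differential(linear_expr, tissue,
                                         fc_cutoff=params.fc_cutoff,
                                         alpha=params.alpha, correct="BH",
                                         log_transform=True)
        if keep:
            shifts[tissue] = global_shift(sub, tissue)
        independence[tissue] = circ_linear_independence(
            circ_de[tissue], linear_de[tissue], host_map,
            circ_expr=sub, linear_expr=linear_expr, tissue=tissue)

    feats = feature_table(annotated, bundle)
    overlap = tissue_overlap(retained)
    if expr.values.shape[0] >= 1 and expr.values.shape[1] >= 2:
        pca_scores = pca(expr).scores
    else:
        pca_scores = pd.DataFrame(index=expr.values.columns)
    families = load_families()
    all_hits = []
    union_retained = sorted(set().union(*[set(v) for v in retained.values()])
                            if retained else set())
    by_id = {c.circ_id: c for c in annotated}
    for cid in union_retained:
        if cid in by_id:
            all_hits.extend(scan_circ_locus(by_id[cid], bundle, families))
    mir_summary = top_families(all_hits, k=params.top_k_families)

    summary = {
        "tool": "circage",
        "version": __version__,
        "params_digest": params.digest(),
        "n_libraries": len(lib_ids),
        "n_denovo_junctions": len(junctions),
        "n_multigene_removed": len(removed),
        "n_circ_annotated": len(annotated),
        "detector": {
            "mates_in": det_stats.mates_in,
            "junction_reads": det_stats.junction_reads,
            "ambiguous": det_stats.ambiguous,
        },
        "tissues": {},
        "overlap": {row.tissues: int(row.n) for row in overlap.itertuples()},
        "n_mirna_hits": int(len(all_hits)),
    }
    for tissue in tissues:
        de = circ_de[tissue]
        entry = {
            "n_retained": len(retained[tissue]),
            "n_up": int((de["status"] == "up").sum()),
            "n_down": int((de["status"] == "down").sum()),
            "coupregulation_fraction": round(
                independence[tissue].coupregulation_fraction, 6),
        }
        if tissue in shifts:
            entry["global_shift_p"] = float(f"{shifts[tissue].p_value:.6g}")
            entry["global_shift_u"] = shifts[tissue].u_statistic
        summary["tissues"][tissue] = entry

    return PipelineResult(annotated, removed, scaffolds, filtered, retained,
                          expr, circ_de, linear_de, shifts, independence,
                          feats, overlap, mir_summary, pca_scores, summary)


# ---------------------------------------------------------------------------
# file-based wrapper
# ---------------------------------------------------------------------------

def read_known_bed(path: str | Path) -> list[CircJunction]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"known{len(out) + 1:05d}"
            strand = f[5] if len(f) > 5 else "+"
            out.append(CircJunction(name, f[0], int(f[1]), int(f[2]), strand,
                                    source="known"))
    return out


def run_all(study_dir: str | Path, results_dir: str | Path,
            params: PipelineParams | None = None,
            known_bed: str | Path | None = None,
            force: bool = False) -> dict:
    """File-based end-to-end run over a simulated (or real) study directory
    containing genome.fa, genes.gtf and a manifest.tsv of FASTQ pairs."""
    study_dir, results_dir = Path(study_dir), Path(results_dir)
    params = params or PipelineParams()
    results_dir.mkdir(parents=True, exist_ok=True)
    summary_path = results_dir / "summary.json"
    stamp = results_dir / ".stage_digest"
    if (not force and summary_path.exists() and stamp.exists()
            and stamp.read_text().strip() == params.digest()):
        log.info("results up to date; skipping (use force=True to rerun)")
        return json.loads(summary_path.read_text())

    bundle = GenomeBundle.read(study_dir / "genome.fa", study_dir / "genes.gtf")
    manifest = pd.read_csv(study_dir / "manifest.tsv", sep="\t")
    libraries = {}
    for rec in manifest.itertuples(index=False):
        libraries[rec.library] = read_fastq_pair(
            study_dir / rec.fastq1, study_dir / rec.fastq2)
    design = manifest[["library", "tissue", "age", "replicate"]].copy()
    known = read_known_bed(known_bed) if known_bed else None

    res = run_pipeline(bundle, libraries, design, params, known)

    write_outputs(res, results_dir)
    with open(results_dir / "effective_params.json", "w") as fh:
        json.dump(asdict(params), fh, indent=2, sort_keys=True)
    stamp.write_text(params.digest())
    return res.summary


def write_outputs(res: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = pd.DataFrame([dict(circ_id=c.circ_id, chrom=c.chrom, start=c.start,
                             end=c.end, strand=c.strand, source=c.source,
                             host_gene=c.host_gene) for c in res.annotation])
    ann.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    rem = pd.DataFrame([dict(circ_id=c.circ_id, chrom=c.chrom, start=c.start,
                             end=c.end, strand=c.strand, source=c.source)
                        for c in res.removed_multigene])
    rem.to_csv(outdir / "removed_multigene.tsv", sep="\t", index=False)
    write_scaffold_fasta(res.scaffolds, res.annotation,
                         outdir / "scaffolds.fa")
    scaf_meta = pd.DataFrame([dict(circ_id=s.circ_id, offset=s.offset,
                                   source=s.source,
                                   short_circle_overlap=s.short_circle_overlap,
                                   intronic_flank=s.intronic_flank)
                              for s in res.scaffolds])
    scaf_meta.to_csv(outdir / "scaffolds.tsv", sep="\t", index=False)
    ret = pd.DataFrame([dict(tissue=t, circ_id=c)
                        for t in sorted(res.retained)
                        for c in res.retained[t]])
    ret.to_csv(outdir / "retained_per_tissue.tsv", sep="\t", index=False)
    res.pca_scores.rename_axis("library").to_csv(outdir / "pca_scores.tsv",
                                                 sep="\t")
    res.counts.counts.rename_axis("circ_id").to_csv(
        outdir / "junction_counts.tsv", sep="\t")
    res.circ_expr.values.rename_axis("circ_id").to_csv(
        outdir / "circ_tpm.tsv", sep="\t")
    for tissue, de in res.circ_de.items():
        de.to_csv(outdir / f"circ_de_{tissue}.tsv", sep="\t")
    for tissue, de in res.linear_de.items():
        de.to_csv(outdir / f"linear_de_{tissue}.tsv", sep="\t")
    for tissue, rep in res.independence.items():
        rep.density_table.to_csv(outdir / f"independence_{tissue}.tsv",
                                 sep="\t", index=False)
    res.features.to_csv(outdir / "features.tsv", sep="\t", index=False)
    res.overlap.to_csv(outdir / "tissue_overlap.tsv", sep="\t", index=False)
    res.mir_summary.to_csv(outdir / "mir_top_families.tsv", sep="\t",
                           index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report(results_dir: str | Path) -> str:
    """Human-readable markdown report from a results directory."""
    results_dir = Path(results_dir)
    summary_path = results_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(
            f"no summary.json under {results_dir}; run the pipeline first")
    s = json.loads(summary_path.read_text())
    lines = [
        "# circage run report",
        f"tool: {s['tool']} {s['version']}  (params digest {s['params_digest']})",
        "",
        f"- libraries: {s['n_libraries']}",
        f"- de novo junctions: {s['n_denovo_junctions']}",
        f"- multi-gene loci removed: {s['n_multigene_removed']}",
        f"- circRNAs annotated: {s['n_circ_annotated']}",
        "",
        "| tissue | retained | up | down | global shift P | co-up fraction |",
        "|---|---|---|---|---|---|",
    ]
    for tissue in sorted(s.get("tissues", {})):
        t = s["tissues"][tissue]
        lines.append(
            f"| {tissue} | {t['n_retained']} | {t['n_up']} | {t['n_down']} | "
            f"{t.get('global_shift_p', 'NA')} | {t['coupregulation_fraction']} |")
    lines.append("")
    lines.append("Cross-tissue overlap (exclusive Venn regions):")
    for k in sorted(s.get("overlap", {})):
        lines.append(f"- {k}: {s['overlap'][k]}")
    text = "\n".join(lines) + "\n"
    (results_dir / "report.md").write_text(text)
    return text
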