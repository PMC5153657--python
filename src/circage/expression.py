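"""Normalization, differential accumulation and independence analyses.

circRNA abundance is normalized to junction reads per million library reads
(TPM); linear host genes to FPKM over the gene's exon union.  Old-versus-
young differential expression per tissue uses a two-sided t-test on the
normalized values (pooled-variance by default, Welch optional) with a
1.5-fold-change cutoff at alpha = 0.05 —
without multiple-testing correction for circRNAs and with Benjamini-
Hochberg correction for linear RNAs.  The global distribution shift between
ages is tested with a Wilcoxon rank-sum (Mann-Whitney U) test with
continuity correction, and the circular-versus-linear independence analysis
contrasts per-circle TPM fold changes with the host gene's FPKM fold
changes.  PCA operates on log10(x + 1) values, centered, via SVD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_FC_CUTOFF = 1.5
DEFAULT_ALPHA = 0.05
PSEUDOCOUNT_READS = 0.5  # fold-change pseudocount, in read units


@dataclass
class ExpressionTable:
    """Per-feature normalized abundances with the library design."""

    values: pd.DataFrame   # feature x library
    design: pd.DataFrame   # columns: library, tissue, age, replicate
    unit: str = "TPM"
    pseudocount: float = 0.0  # normalized-unit equivalent of 0.5 reads

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.design["library"])
        if missing:
            raise ValueError(f"design does not cover libraries: {missing}")

    def libraries(self, tissue: str | None = None, age: str | None = None
                  ) -> list[str]:
        d = self.design
        if tissue is not None:
            d = d[d["tissue"] == tissue]
        if age is not None:
            d = d[d["age"] == age]
        return [l for l in self.values.columns if l in set(d["library"])]


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    mean_young: float
    mean_old: float
    fold_change: float
    log2_fold_change: float
    p_value: float
    p_adjusted: float
    status: str  # up / down / unchanged
    flag: str = ""


def circ_tpm(counts: pd.DataFrame, library_totals: dict[str, int],
             design: pd.DataFrame) -> ExpressionTable:
    """TPM(i, lib) = count(i, lib) * 1e6 / N(lib), with N the per-library
    retained read count (linearly aligned + deduplicated junction reads)."""
    n = pd.Series(library_totals).reindex(counts.columns)
    if (n <= 0).any():
        bad = list(n.index[n <= 0])
        raise ValueError(f"library total N must be > 0: {bad}")
    values = counts * 1e6 / n
    eps = PSEUDOCOUNT_READS * 1e6 / float(n.mean())
    return ExpressionTable(values, design, unit="TPM", pseudocount=eps)


def gene_fpkm(fragment_genes_by_library: dict[str, dict],
              bundle, design: pd.DataFrame) -> ExpressionTable:
    """Simplified exon-union FPKM for linear host genes.

    ``fragment_genes_by_library[lib]`` maps fragment -> per-mate host-gene
    sets as produced by :func:`circage.circdetect.linear_filter`.  A
    fragment is assigned iff both mates aligned and their gene sets
    intersect in exactly one gene.  FPKM(g) = assigned fragments * 1e9 /
    (exon-union length * total assigned fragments in the library).
    """
    genes = [g for g in bundle.genes]
    lengths = pd.Series({g.gene_id: g.exon_union_length() for g in genes})
    if (lengths <= 0).any():
        raise ValueError("gene with zero exon-union length")
    libs = list(design["library"])
    counts = pd.DataFrame(0, index=lengths.index, columns=libs, dtype=float)
    totals = {}
    for lib in libs:
        n_assigned = 0
        for frag, mates in fragment_genes_by_library.get(lib, {}).items():
            g1, g2 = mates
            if g1 is None or g2 is None:
                continue
            common = (g1 & g2) if (g1 and g2) else frozenset()
            if len(common) == 1:
                counts.loc[next(iter(common)), lib] += 1
                n_assigned += 1
        totals[lib] = n_assigned
    values = counts * 1e9
    for lib in libs:
        t = max(totals[lib], 1)
        values[lib] = values[lib] / (lengths * t)
    mean_t = max(np.mean([max(t, 1) for t in totals.values()]), 1.0)
    eps = PSEUDOCOUNT_READS * 1e9 / (float(lengths.mean()) * mean_t)
    return ExpressionTable(values, design, unit="FPKM", pseudocount=eps)


def differential(expr: ExpressionTable, tissue: str,
                 fc_cutoff: float = DEFAULT_FC_CUTOFF,
                 alpha: float = DEFAULT_ALPHA,
                 correct: str = "none",
                 pseudocount: float | None = None,
                 log_transform: bool = False,
                 equal_var: bool = True) -> pd.DataFrame:
    """Old-versus-young differential expression for one tissue.

    fold_change = (mean_old + eps) / (mean_young + eps); p from a two-sided
    t-test on the normalized values (on log2(x + 1) when ``log_transform``
    is set, the linear-RNA variant); ``correct`` is "none" (circRNA
    analysis) or "BH" (linear RNA analysis).  A feature is "up" iff
    fold_change >= fc_cutoff and the (adjusted) p < alpha, "down"
    symmetrically.

    The default is the pooled-variance t-test: at triplicate scale it holds
    its nominal size, where the Welch variant (``equal_var=False``) is
    noticeably conservative.
    """
    if correct not in ("none", "BH"):
        raise ValueError("correct must be 'none' or 'BH'")
    eps = expr.pseudocount if pseudocount is None else pseudocount
    young = expr.libraries(tissue, "young")
    old = expr.libraries(tissue, "old")
    if len(young) < 2 or len(old) < 2:
        raise ValueError(f"tissue {tissue}: need >=2 replicates per age group")
    Y = expr.values[young].to_numpy(float)
    O = expr.values[old].to_numpy(float)
    my, mo = Y.mean(axis=1), O.mean(axis=1)
    fc = (mo + eps) / (my + eps)
    Yt, Ot = (np.log2(Y + 1), np.log2(O + 1)) if log_transform else (Y, O)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(Ot, Yt, axis=1, equal_var=equal_var)
    p = np.asarray(p, dtype=float)
    flags = np.full(len(p), "", dtype=object)
    degenerate = np.isnan(p)
    p[degenerate] = 1.0
    flags[degenerate] = "zero-variance"
    if correct == "BH":
        from statsmodels.stats.multitest import multipletests

        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        p_adj = p.copy()
    status = np.where((fc >= fc_cutoff) & (p_adj < alpha), "up",
                      np.where((1.0 / fc >= fc_cutoff) & (p_adj < alpha),
                               "down", "unchanged"))
    return pd.DataFrame(dict(
        feature_id=expr.values.index, mean_young=my, mean_old=mo,
        fold_change=fc, log2_fold_change=np.log2(fc), p_value=p,
        p_adjusted=p_adj, neg_log10_p=-np.log10(np.maximum(p, 1e-300)),
        status=status, flag=flags,
    )).set_index("feature_id")


# ---------------------------------------------------------------------------
# global distribution shift
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalShiftResult:
    tissue: str
    u_statistic: float
    z: float
    p_value: float
    n_old: int
    n_young: int
    method: str


def _exact_u_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumeration (ties via mid-ranks
    would need a permutation test; callers only use this for tie-free
    small samples)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    total = comb(len(pooled), n1)
    mu = n1 * len(y) / 2
    extreme = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            extreme += 1
    return u_obs, extreme / total


def global_shift(expr: ExpressionTable, tissue: str,
                 feature_ids: list[str] | None = None) -> GlobalShiftResult:
    """Mann-Whitney U comparing pooled old-library values against pooled
    young-library values for one tissue, normal approximation with
    continuity correction (exact enumeration for tie-free groups of <= 8)."""
    young = expr.libraries(tissue, "young")
    old = expr.libraries(tissue, "old")
    vals = expr.values if feature_ids is None else expr.values.loc[feature_ids]
    x = vals[old].to_numpy(float).ravel()
    y = vals[young].to_numpy(float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"tissue {tissue}: empty age group")
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    # tie-corrected variance
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sigma = np.sqrt(sigma2) if sigma2 > 0 else 0.0
    z = 0.0 if sigma == 0 else (u - mu - np.sign(u - mu) * 0.5) / sigma
    no_ties = len(tie_counts) == n
    if max(n1, n2) <= 8 and no_ties:
        u_obs, p = _exact_u_pvalue(x, y)
        method = "exact"
    else:
        p = float(2 * stats.norm.sf(abs(z))) if sigma > 0 else 1.0
        method = "normal-approx-cc"
    return GlobalShiftResult(tissue, u, float(z), float(min(p, 1.0)),
                             n1, n2, method)


# ---------------------------------------------------------------------------
# circular-vs-linear independence
# ---------------------------------------------------------------------------

@dataclass
class IndependenceReport:
    tissue: str
    n_circ_up: int
    n_circ_up_host_up: int
    n_circ_down: int
    n_circ_down_host_down: int
    n_intergenic: int
    density_table: pd.DataFrame   # circ_id, host, log2 linear FC, log2 circ FC
    ratio_tests: pd.DataFrame     # per-circle old-vs-young circ/host ratio t-test

    @property
    def coupregulation_fraction(self) -> float:
        return (self.n_circ_up_host_up / self.n_circ_up) if self.n_circ_up else 0.0


def circ_linear_independence(circ_de: pd.DataFrame, linear_de: pd.DataFrame,
                             host_map: dict[str, str],
                             circ_expr: ExpressionTable | None = None,
                             linear_expr: ExpressionTable | None = None,
                             tissue: str = "") -> IndependenceReport:
    """Contrast circRNA fold changes with their host gene's linear fold
    changes: overlap counts of concordant significance, the per-library
    circTPM/hostFPKM ratio t-test, and a density-plot table of
    (log2 linear FC, log2 circ FC) pairs.  Intergenic circles are excluded
    from the ratio and density analyses and counted separately."""
    genic = {c: g for c, g in host_map.items()
             if g and g != "intergenic" and g in linear_de.index
             and c in circ_de.index}
    n_intergenic = sum(1 for c in circ_de.index
                      if host_map.get(c, "intergenic") == "intergenic")
    rows = []
    for c, g in sorted(genic.items()):
        rows.append(dict(circ_id=c, host_gene=g,
                         log2_linear_fc=float(linear_de.loc[g, "log2_fold_change"]),
                         log2_circ_fc=float(circ_de.loc[c, "log2_fold_change"])))
    density = pd.DataFrame(rows, columns=["circ_id", "host_gene",
                                          "log2_linear_fc", "log2_circ_fc"])
    circ_up = set(circ_de.index[circ_de["status"] == "up"])
    circ_down = set(circ_de.index[circ_de["status"] == "down"])
    host_up = set(linear_de.index[linear_de["status"] == "up"])
    host_down = set(linear_de.index[linear_de["status"] == "down"])
    up_and_host_up = sum(1 for c in circ_up
                         if host_map.get(c) in host_up)
    down_and_host_down = sum(1 for c in circ_down
                             if host_map.get(c) in host_down)

    ratio_rows = []
    if circ_expr is not None and linear_expr is not None and tissue:
        young = circ_expr.libraries(tissue, "young")
        old = circ_expr.libraries(tissue, "old")
        eps = linear_expr.pseudocount or 1e-9
        for c, g in sorted(genic.items()):
            ry = (circ_expr.values.loc[c, young].to_numpy(float)
                  / (linear_expr.values.loc[g, young].to_numpy(float) + eps))
            ro = (circ_expr.values.loc[c, old].to_numpy(float)
                  / (linear_expr.values.loc[g, old].to_numpy(float) + eps))
            if np.allclose(ry.var(), 0) and np.allclose(ro.var(), 0):
                p = 1.0 if np.isclose(ry.mean(), ro.mean()) else 0.0
            else:
                p = float(stats.ttest_ind(ro, ry, equal_var=False).pvalue)
            ratio_rows.append(dict(circ_id=c, host_gene=g,
                                   mean_ratio_young=float(ry.mean()),
                                   mean_ratio_old=float(ro.mean()),
                                   p_value=p))
    ratios = pd.DataFrame(ratio_rows, columns=["circ_id", "host_gene",
                                               "mean_ratio_young",
                                               "mean_ratio_old", "p_value"])
    return IndependenceReport(tissue, len(circ_up), up_and_host_up,
                              len(circ_down), down_and_host_down,
                              n_intergenic, density, ratios)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame             # library x component
    loadings: pd.DataFrame           # feature x component
    variance_fractions: np.ndarray


def pca(expr: ExpressionTable, pseudocount: float = 1.0) -> PCAResult:
    """PCA of log10(x + pseudocount) values, features centered, no scaling;
    components via SVD of the library-by-feature matrix."""
    if expr.values.shape[1] < 2:
        raise ValueError("PCA needs >= 2 libraries")
    X = np.log10(expr.values.to_numpy(float).T + pseudocount)
    X = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    total = (s ** 2).sum()
    if total <= 0:
        k = len(s)
        scores = pd.DataFrame(np.zeros_like(u * s),
                              index=expr.values.columns,
                              columns=[f"PC{i+1}" for i in range(k)])
        loadings = pd.DataFrame(vt.T, index=expr.values.index,
                                columns=scores.columns)
        return PCAResult(scores, loadings, np.zeros(k))
    frac = s ** 2 / total
    cols = [f"PC{i+1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=expr.values.columns, columns=cols)
    loadings = pd.DataFrame(vt.T, index=expr.values.index, columns=cols)
    return PCAResult(scores, loadings, frac)
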