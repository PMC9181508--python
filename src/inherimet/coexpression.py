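"""Co-expression modules and metabolome-transcriptome integration.

Modules are built WGCNA-style on the differentially expressed gene set:
unsigned adjacency ``|r|^beta`` (beta auto-selected for approximate
scale-free topology), topological-overlap dissimilarity, average-linkage
clustering and a static tree cut; clusters below the minimum size stay
unassigned.  Each module is summarized by its eigengene (first principal
component of the standardized module submatrix, sign-oriented to follow
mean module expression), which is then correlated with traits.  Enrichment
of modules in user-supplied annotation terms is a flat hypergeometric test.
The concordance report joins per-cross inheritance calls of a gene and a
trait and regresses trait values on gene expression across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .design_io import AnnotationMap, TraitMatrix
from .expression import NormalizedExpression

logger = logging.getLogger("inherimet")

UNASSIGNED = "unassigned"


@dataclass
class ModuleSet:
    assignment: pd.Series            # gene -> module label (str)
    eigengenes: pd.DataFrame         # samples x modules, unit-norm columns
    beta: float
    var_explained: dict[str, float] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def sizes(self) -> pd.Series:
        s = self.assignment[self.assignment != UNASSIGNED].value_counts()
        return s.sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def pick_soft_power(corr_abs: np.ndarray, target_r2: float = 0.8,
                    max_beta: int = 20) -> tuple[int, float]:
    """Smallest integer beta whose connectivity distribution is scale-free.

    Fits log10 p(k) ~ log10 k over equal-width connectivity bins; returns
    (beta, R2) for the first beta reaching ``target_r2``.  Block-structured
    (modular) data often never reaches the threshold at any power; in that
    case the conventional unsigned-network default power 6 is returned.
    """
    for beta in range(1, max_beta + 1):
        a = corr_abs ** beta
        k = a.sum(axis=1) - 1.0  # drop self-adjacency
        r2 = _scale_free_r2(k)
        if r2 >= target_r2:
            return beta, r2
    default = min(6, max_beta)
    a = corr_abs ** default
    return default, _scale_free_r2(a.sum(axis=1) - 1.0)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    k = k[k > 0]
    if len(k) < n_bins:
        return -np.inf
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    centers, freqs = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            centers.append(k[sel].mean())
            freqs.append(sel.mean())
    centers, freqs = np.array(centers), np.array(freqs)
    ok = (centers > 0) & (freqs > 0)
    if ok.sum() < 3:
        return -np.inf
    r = np.corrcoef(np.log10(centers[ok]), np.log10(freqs[ok]))[0, 1]
    return float(r * r)


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Unsigned TOM: shared-neighbor similarity with unit diagonal."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (L + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def build_modules(
    ne: NormalizedExpression,
    genes: list[str] | None = None,
    beta: int | None = None,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> ModuleSet:
    """Detect co-expression modules on (a subset of) the expression matrix.

    ``cut_height`` is an absolute TOM-dissimilarity height; the default
    0.995 sits just below the no-overlap asymptote at 1, so genes sharing
    any reproducible topological overlap co-cluster and pure-noise genes
    (whose dissimilarities pile up at 1) stay singletons, to be swept into
    the unassigned pool by the size filter.  Constant genes are dropped
    with a warning.  Module labels are ``M01``, ``M02``, ... by decreasing
    size.
    """
    expr = ne.logcpm if genes is None else ne.logcpm.loc[[g for g in genes
                                                          if g in ne.logcpm.index]]
    sd = expr.std(axis=1, ddof=1)
    constant = sd[sd < 1e-10].index  # tolerance: repeated floats round to ~1e-16
    if len(constant):
        logger.warning("dropping %d constant genes before module detection",
                       len(constant))
        expr = expr.drop(index=constant)
    if expr.shape[0] < max(min_module_size, 3):
        raise ValueError("too few genes for module detection")

    corr = np.corrcoef(expr.to_numpy(float))
    corr = np.nan_to_num(corr, nan=0.0)
    corr_abs = np.abs(corr)
    if beta is None:
        beta, _ = pick_soft_power(corr_abs)
    adj = corr_abs ** beta
    tom = topological_overlap(adj)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    if cut_height is None:
        cut_height = 0.995
    flat = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    counts = pd.Series(flat).value_counts()
    keep = counts[counts >= min_module_size].index
    order = counts.loc[keep].sort_values(ascending=False).index
    label_of = {c: f"M{i + 1:02d}" for i, c in enumerate(order)}
    assignment = pd.Series(
        [label_of.get(c, UNASSIGNED) for c in flat],
        index=expr.index, name="module",
    )

    eig, varex = _eigengenes(expr, assignment)
    return ModuleSet(assignment, eig, float(beta), varex)


def _eigengenes(expr: pd.DataFrame, assignment: pd.Series
                ) -> tuple[pd.DataFrame, dict[str, float]]:
    cols, varex = {}, {}
    for mod in sorted(assignment[assignment != UNASSIGNED].unique()):
        sub = expr.loc[assignment[assignment == mod].index].to_numpy(float)
        z = (sub - sub.mean(axis=1, keepdims=True))
        s = sub.std(axis=1, ddof=1, keepdims=True)
        z = z / np.where(s == 0, 1.0, s)
        u, sv, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]                               # unit-norm sample scores
        if np.corrcoef(e, z.mean(axis=0))[0, 1] < 0:
            e = -e
        cols[mod] = e
        varex[mod] = float(sv[0] ** 2 / (sv ** 2).sum())
    eig = pd.DataFrame(cols, index=expr.columns)
    return eig, varex


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def module_trait_correlations(ms: ModuleSet, tm: TraitMatrix,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r (with two-sided p) between each eigengene and each trait."""
    shared = [s for s in ms.eigengenes.index if s in tm.values.index]
    if not shared:
        raise ValueError("eigengenes and trait matrix share no samples")
    rows = []
    for mod in ms.modules:
        e = ms.eigengenes.loc[shared, mod].to_numpy(float)
        for trait in tm.traits:
            y = tm.values.loc[shared, trait].to_numpy(float)
            ok = ~np.isnan(y)
            if ok.sum() < 4 or np.std(y[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(e[ok], y[ok])
            rows.append({"module": mod, "trait": trait, "r": r, "p": p,
                         "significant": bool(p < alpha) if p == p else False})
    return pd.DataFrame(rows)


def enrich(ms: ModuleSet, annotation: AnnotationMap,
           universe: list[str] | None = None) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of modules in annotation terms.

    The universe defaults to the clustered gene set (assigned genes plus
    the unassigned pool).  BH adjustment spans the whole module x term scan.
    """
    if universe is None:
        universe = list(ms.assignment.index)
    uni = set(universe)
    N = len(uni)
    rows = []
    for mod in ms.modules:
        mod_genes = set(ms.assignment[ms.assignment == mod].index) & uni
        for term, genes in annotation.terms.items():
            term_genes = genes & uni
            if not term_genes:
                logger.warning("term %r has no genes in the universe; skipped", term)
                continue
            k = len(mod_genes & term_genes)
            p = stats.hypergeom.sf(k - 1, N, len(term_genes), len(mod_genes))
            rows.append({"module": mod, "term": term, "overlap": k,
                         "module_size": len(mod_genes), "term_size": len(term_genes),
                         "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def gene_trait_concordance(
    gene_calls: pd.DataFrame,
    trait_calls: pd.DataFrame,
    ne: NormalizedExpression,
    tm: TraitMatrix,
    gene: str,
    trait: str,
) -> dict:
    """Mode-pair table plus trait-on-expression regression for one pair.

    Returns per-cross (gene mode, trait mode) pairs, a label summarizing
    the dominant pattern, and OLS slope / R-squared of trait values on the
    gene's normalized expression across all shared samples.
    """
    if gene not in ne.logcpm.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    if trait not in tm.values.columns:
        raise KeyError(f"trait {trait!r} absent from trait matrix")
    g = gene_calls[gene_calls["variable"] == gene].set_index("cross")["mode"]
    t = trait_calls[trait_calls["variable"] == trait].set_index("cross")["mode"]
    crosses = sorted(set(g.index) & set(t.index))
    pairs = {c: (g[c], t[c]) for c in crosses}

    shared = [s for s in ne.logcpm.columns if s in tm.values.index]
    x = ne.logcpm.loc[gene, shared].to_numpy(float)
    y = tm.values.loc[shared, trait].to_numpy(float)
    ok = ~np.isnan(y)
    res = stats.linregress(x[ok], y[ok])
    label = _pattern_label(pairs)
    return {"gene": gene, "trait": trait, "mode_pairs": pairs,
            "pattern": label, "slope": float(res.slope),
            "r2": float(res.rvalue ** 2), "p": float(res.pvalue)}


def _pattern_label(pairs: dict) -> str:
    opposing = sum(1 for gm, tmode in pairs.values()
                   if {gm, tmode} == {"OD", "OR"})
    matching = sum(1 for gm, tmode in pairs.values()
                   if gm == tmode and gm not in ("ns", "insufficient data"))
    if opposing and opposing >= matching:
        return f"opposing transgression in {opposing} crosses"
    if matching:
        return f"matching mode in {matching} crosses"
    return "no shared classified pattern"


def candidate_genes(
    ms: ModuleSet,
    ne: NormalizedExpression,
    tm: TraitMatrix,
    module_trait: pd.DataFrame,
    min_abs_r: float = 0.6,
) -> pd.DataFrame:
    """Genes strongly correlated with a trait inside a trait-linked module.

    For every significant module-trait association, every module gene whose
    |Pearson r| with that trait exceeds ``min_abs_r`` is listed as a
    candidate driver of the trait.
    """
    shared = [s for s in ne.logcpm.columns if s in tm.values.index]
    rows = []
    sig = module_trait[module_trait["significant"]]
    for _, mt in sig.iterrows():
        mod, trait = mt["module"], mt["trait"]
        y = tm.values.loc[shared, trait].to_numpy(float)
        ok = ~np.isnan(y)
        for gene in ms.assignment[ms.assignment == mod].index:
            x = ne.logcpm.loc[gene, shared].to_numpy(float)
            r, p = stats.pearsonr(x[ok], y[ok])
            if abs(r) >= min_abs_r:
                rows.append({"module": mod, "trait": trait, "gene": gene,
                             "r": float(r), "p": float(p)})
    return pd.DataFrame(rows, columns=["module", "trait", "gene", "r", "p"])
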