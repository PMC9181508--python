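"""Per-trait genetics summary statistics for a factorial design.

Three pieces, all operating on a :class:`~inherimet.design_io.TraitMatrix`:

* a two-way fixed-effects ANOVA (genotype + harvest) testing for a
  genotype effect on each trait;
* broad-sense heritability ``h2 = sG2 / (sG2 + se2)`` from the variance
  components of a mixed model with random genotype and fixed harvest,
  fitted by REML (method-of-moments fallback on non-convergence);
* trait-structure descriptors: a pairwise Spearman rank-correlation
  matrix (pairwise-complete, average ranks for ties) and an
  average-linkage hierarchical clustering of standardized trait profiles
  with ordinary bootstrap support per cluster.

Harvest is the replicate block: the three harvests of the design are the
three biological replicates, so harvest enters every model as a fixed block
factor and no genotype x harvest interaction is estimable (one observation
per cell).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .design_io import TraitMatrix


@dataclass
class HeritabilityResult:
    trait: str
    sigma_g2: float
    sigma_e2: float
    h2: float
    genotype_p: float
    method: str = "reml"  # or "moments" fallback

    def as_row(self) -> dict:
        return {"trait": self.trait, "sigma_g2": self.sigma_g2,
                "sigma_e2": self.sigma_e2, "h2": self.h2,
                "genotype_p": self.genotype_p, "method": self.method}


@dataclass
class TraitClustering:
    linkage: np.ndarray           # scipy linkage matrix over traits
    traits: list[str]
    flat_clusters: dict[str, int]
    support: dict[frozenset, float]  # bootstrap probability per internal node


# ---------------------------------------------------------------------------
# ANOVA and heritability
# ---------------------------------------------------------------------------

def _design_arrays(tm: TraitMatrix, trait: str):
    y = tm.values[trait].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    geno = tm.sample_meta["genotype"].to_numpy()[keep]
    harv = tm.sample_meta["harvest"].to_numpy()[keep]
    return y, geno, harv


def genotype_anova(tm: TraitMatrix, trait: str) -> tuple[float, float]:
    """F statistic and p-value of the genotype term in y ~ genotype + harvest."""
    y, geno, harv = _design_arrays(tm, trait)
    g_levels, g_idx = np.unique(geno, return_inverse=True)
    if len(g_levels) < 2:
        raise ValueError(f"trait {trait!r}: genotype factor has a single level")
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"y": y, "genotype": geno, "harvest": harv.astype(str)})
    fit = ols("y ~ C(genotype) + C(harvest)", data=df).fit()
    if fit.df_resid <= 0:
        raise ValueError(f"trait {trait!r}: zero residual degrees of freedom")
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(genotype)"]
    return float(row["F"]), float(row["PR(>F)"])


def heritability(tm: TraitMatrix, trait: str) -> HeritabilityResult:
    """Broad-sense heritability of one trait from REML variance components.

    Model: trait ~ harvest (fixed) with a random genotype intercept.
    The fit profiles the REML criterion over the single variance ratio
    ``lambda = sigma_g2 / sigma_e2`` (a bounded 1-D optimization, robust at
    the zero-variance boundary where general mixed-model optimizers tend to
    fail).  Negative component estimates are truncated at zero.  If the
    profiled fit still fails numerically, an EMS method-of-moments estimate
    from the two-way ANOVA is reported and flagged in ``method``.
    """
    y, geno, harv = _design_arrays(tm, trait)
    _, p = genotype_anova(tm, trait)
    method = "reml"
    try:
        sg2, se2 = _profiled_reml(y, geno, harv)
    except Exception:
        sg2, se2 = _moments_components(y, geno, harv)
        method = "moments"
    sg2, se2 = max(sg2, 0.0), max(se2, 0.0)
    h2 = sg2 / (sg2 + se2) if sg2 + se2 > 0 else 0.0
    return HeritabilityResult(trait, sg2, se2, h2, p, method)


def _profiled_reml(y, geno, harv) -> tuple[float, float]:
    """REML variance components of y = harvest + (1 | genotype) + e.

    Profiles the restricted likelihood over log lambda,
    lambda = sigma_g2 / sigma_e2, using direct Cholesky linear algebra on
    V = I + lambda Z Z' (n is small in these designs).
    """
    from scipy.linalg import cho_factor, cho_solve
    from scipy.optimize import minimize_scalar

    n = len(y)
    g_levels, g_idx = np.unique(geno, return_inverse=True)
    h_levels, h_idx = np.unique(harv, return_inverse=True)
    Z = np.zeros((n, len(g_levels)))
    Z[np.arange(n), g_idx] = 1.0
    X = np.column_stack([np.ones(n)] +
                        [(h_idx == j).astype(float) for j in range(1, len(h_levels))])
    p = X.shape[1]
    ZZt = Z @ Z.T

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        V = np.eye(n) + lam * ZZt
        c, low = cho_factor(V, lower=True)
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Vi_X = cho_solve((c, low), X)
        Vi_y = cho_solve((c, low), y)
        XtViX = X.T @ Vi_X
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        ytPy = float(r @ cho_solve((c, low), r))
        if ytPy <= 0:
            return np.inf
        return logdet_v + logdet_x + (n - p) * np.log(ytPy)

    res = minimize_scalar(neg2_reml, bounds=(-20.0, 20.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    V = np.eye(n) + lam * ZZt
    c, low = cho_factor(V, lower=True)
    Vi_X = cho_solve((c, low), X)
    Vi_y = cho_solve((c, low), y)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    r = y - X @ beta
    se2 = float(r @ cho_solve((c, low), r)) / (n - p)
    if lam < 2e-9:  # boundary: treat the genetic component as zero
        lam = 0.0
    return lam * se2, se2


def _moments_components(y, geno, harv) -> tuple[float, float]:
    """Expected-mean-squares estimate of (sigma_g2, sigma_e2) for the
    randomized-block layout; robust to mild unbalance via mean group size."""
    g_levels, g_idx = np.unique(geno, return_inverse=True)
    h_levels, h_idx = np.unique(harv, return_inverse=True)
    grand = y.mean()
    g_means = np.array([y[g_idx == i].mean() for i in range(len(g_levels))])
    h_means = np.array([y[h_idx == j].mean() for j in range(len(h_levels))])
    n = len(y)
    ss_g = sum(((g_idx == i).sum()) * (g_means[i] - grand) ** 2
               for i in range(len(g_levels)))
    ss_h = sum(((h_idx == j).sum()) * (h_means[j] - grand) ** 2
               for j in range(len(h_levels)))
    ss_tot = ((y - grand) ** 2).sum()
    ss_e = ss_tot - ss_g - ss_h
    df_g = len(g_levels) - 1
    df_e = n - len(g_levels) - len(h_levels) + 1
    ms_g = ss_g / df_g
    ms_e = ss_e / max(df_e, 1)
    r = n / len(g_levels)
    return (ms_g - ms_e) / r, ms_e


def heritability_table(tm: TraitMatrix) -> pd.DataFrame:
    return pd.DataFrame([heritability(tm, t).as_row() for t in tm.traits])


# ---------------------------------------------------------------------------
# Correlation structure
# ---------------------------------------------------------------------------

def spearman_matrix(tm: TraitMatrix, alpha: float = 0.05,
                    bh_adjust: bool = False) -> pd.DataFrame:
    """Long-format pairwise Spearman correlations between traits.

    Pairwise-complete observations, average ranks for ties, two-sided
    p-values; a constant trait yields an undefined (NaN) rho.  Requires at
    least four complete pairs per trait pair.
    """
    traits = tm.traits
    vals = tm.values.to_numpy(dtype=float)
    rows = []
    for i in range(len(traits)):
        for j in range(i + 1, len(traits)):
            x, y = vals[:, i], vals[:, j]
            keep = ~(np.isnan(x) | np.isnan(y))
            if keep.sum() < 4:
                rho, p = np.nan, np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = stats.spearmanr(x[keep], y[keep])
                if np.isnan(rho):
                    p = np.nan
            rows.append({"trait_a": traits[i], "trait_b": traits[j],
                         "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        ok = out["p"].notna()
        padj = np.full(len(out), np.nan)
        if ok.any():
            padj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["p_adj"] = padj
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def spearman_square(tm: TraitMatrix) -> pd.DataFrame:
    """Symmetric rho matrix with unit diagonal (convenience view)."""
    long = spearman_matrix(tm)
    traits = tm.traits
    m = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for _, r in long.iterrows():
        m.loc[r["trait_a"], r["trait_b"]] = r["rho"]
        m.loc[r["trait_b"], r["trait_a"]] = r["rho"]
    return m


# ---------------------------------------------------------------------------
# Trait clustering with bootstrap support
# ---------------------------------------------------------------------------

def _standardize(values: np.ndarray) -> np.ndarray:
    mu = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (values - mu) / sd
    return np.where(np.isnan(z), 0.0, z)  # missing -> column mean after scaling


def _cluster_sets(link: np.ndarray, n: int) -> list[frozenset]:
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(link):
        s = members[int(a)] | members[int(b)]
        members[n + k] = s
        out.append(s)
    return out


def cluster_traits(tm: TraitMatrix, n_boot: int = 1000, seed: int = 0,
                   n_clusters: int | None = None) -> TraitClustering:
    """Average-linkage clustering of standardized traits with bootstrap support.

    Distances are Euclidean between trait profiles across samples (traits
    scaled to zero mean / unit variance first).  Support of an internal
    node is the fraction of ``n_boot`` sample-resampled trees in which the
    node's exact trait set reappears.  Flat clusters cut the tree into
    ``n_clusters`` groups (default: square root of the trait count).
    """
    traits = tm.traits
    if len(traits) < 2:
        raise ValueError("need at least 2 traits to cluster")
    z = _standardize(tm.values.to_numpy(dtype=float))
    link = hierarchy.linkage(pdist(z.T, metric="euclidean"), method="average")

    n = len(traits)
    target_sets = _cluster_sets(link, n)
    hits = {s: 0 for s in target_sets}
    rng = np.random.default_rng(seed)
    n_samples = z.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_samples, size=n_samples)
        zb = _standardize(tm.values.to_numpy(dtype=float)[idx])
        lb = hierarchy.linkage(pdist(zb.T, metric="euclidean"), method="average")
        seen = set(_cluster_sets(lb, n))
        for s in hits:
            if s in seen:
                hits[s] += 1
    support = {s: hits[s] / n_boot for s in hits} if n_boot else {s: np.nan for s in hits}

    k = n_clusters or max(2, int(round(np.sqrt(n))))
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return TraitClustering(link, traits,
                           {t: int(c) for t, c in zip(traits, flat)}, support)


def dendrogram_newick(tc: TraitClustering) -> str:
    """Serialize the trait dendrogram as a Newick string with branch heights."""
    n = len(tc.traits)
    heights = {i: 0.0 for i in range(n)}
    labels = {i: tc.traits[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(tc.linkage):
        a, b = int(a), int(b)
        la = f"{labels[a]}:{h - heights[a]:.6g}"
        lb = f"{labels[b]}:{h - heights[b]:.6g}"
        labels[n + k] = f"({la},{lb})"
        heights[n + k] = h
    return labels[n + len(tc.linkage) - 1] + ";"
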