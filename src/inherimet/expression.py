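"""From raw counts to normalized expression and differential-expression calls.

The stage is deliberately simple and fully documented: genes are filtered
on counts-per-million, per-sample scaling factors are computed with a
trimmed-mean-of-M-values (TMM) procedure, expression is log2 CPM on
effective library sizes, and differential expression across all genotype
pairs uses a per-gene linear model on log-CPM with a moderated pooled
variance (per-gene residual variances shrunk toward the across-gene
median).  Count-level negative-binomial GLM testing is an extension point;
the normalized matrix is what feeds the inheritance classifier and the
co-expression stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .design_io import CountMatrix, DesignError, FactorialDesign

#: prior degrees of freedom for the variance moderation
MODERATION_DF = 3.0


@dataclass
class NormalizedExpression:
    """Gene x sample log2-CPM matrix plus its normalization bookkeeping."""

    logcpm: pd.DataFrame
    norm_factors: pd.Series        # TMM factors, geometric mean 1
    effective_lib: pd.Series       # library size x factor
    filter_report: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.logcpm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.logcpm.columns)


def filter_low_expression(
    cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> tuple[CountMatrix, pd.DataFrame]:
    """Keep genes with CPM >= ``min_cpm`` in >= ``min_samples`` samples."""
    counts = cm.counts
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise DesignError(f"samples with zero library size: "
                          f"{list(lib.index[lib == 0])}")
    cpm = counts / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise DesignError("low-expression filter removed every gene")
    report = pd.DataFrame({
        "gene": counts.index,
        "kept": keep.to_numpy(),
        "rule": f"CPM>={min_cpm} in >={min_samples} samples",
    })
    return CountMatrix(counts.loc[keep]), report


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, normalized to geomean 1.

    The reference is the sample whose upper quartile is closest to the mean
    upper quartile.  For each sample, M (log ratio) and A (log abundance)
    values against the reference are computed on genes expressed in both,
    doubly trimmed, and combined with inverse approximate-variance weights.
    """
    lib = counts.sum(axis=0).astype(float)
    uq = counts[counts > 0].quantile(0.75).fillna(0) / lib
    ref = (uq - uq.mean()).abs().idxmin()
    ref_p = counts[ref].to_numpy(float) / lib[ref]
    ref_n = counts[ref].to_numpy(float)

    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        obs_n = counts[s].to_numpy(float)
        obs_p = obs_n / lib[s]
        ok = (obs_n > 0) & (ref_n > 0)
        if ok.sum() < 10:
            factors[s] = 1.0
            continue
        m = np.log2(obs_p[ok] / ref_p[ok])
        a = 0.5 * np.log2(obs_p[ok] * ref_p[ok])
        # asymptotic binomial variance of M
        w = (lib[s] - obs_n[ok]) / (lib[s] * obs_n[ok]) \
            + (lib[ref] - ref_n[ok]) / (lib[ref] * ref_n[ok])
        keep = np.ones(ok.sum(), dtype=bool)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep &= (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0:
            factors[s] = 1.0
        else:
            factors[s] = float(2 ** (np.sum(m[keep] / w[keep])
                                     / np.sum(1.0 / w[keep])))
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


def normalize(cm: CountMatrix, prior_count: float = 0.5) -> NormalizedExpression:
    """log2 CPM on TMM-effective library sizes.

    The prior count is scaled per sample in proportion to library size
    (as in edgeR's log-CPM), which makes the result exactly invariant to a
    common library-size multiple.
    """
    counts = cm.counts.astype(float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise DesignError(f"samples with zero library size: "
                          f"{list(lib.index[lib == 0])}")
    f = tmm_factors(cm.counts)
    eff = lib * f
    prior = prior_count * eff / eff.mean()
    logcpm = np.log2((counts + prior).div(eff + 2 * prior, axis=1) * 1e6)
    return NormalizedExpression(logcpm, f, eff)


def deg_scan(
    ne: NormalizedExpression,
    sample_meta: pd.DataFrame,
    design: FactorialDesign,
    fdr: float = 0.05,
    contrasts: list[tuple[str, str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Differential expression across genotype contrasts with a global BH FDR.

    Default contrasts: all C(n_genotypes, 2) pairs.  Per gene, group means
    and a pooled residual variance come from the one-factor (genotype)
    linear model on log-CPM; the variance is moderated toward the
    across-gene median with ``MODERATION_DF`` prior degrees of freedom.
    Returns the long DEG table, a per-gene any-contrast summary, and the
    reciprocal-pair DEG table.
    """
    geno = sample_meta.loc[ne.samples, "genotype"]
    genotypes = design.genotypes
    known = set(genotypes)
    if contrasts is None:
        contrasts = list(combinations(genotypes, 2))
    for a, b in contrasts:
        if a not in known or b not in known:
            raise DesignError(f"contrast ({a}, {b}) references unknown genotype")

    X = ne.logcpm.to_numpy(float)
    groups = {g: np.flatnonzero((geno == g).to_numpy()) for g in genotypes}
    n_of = {g: len(idx) for g, idx in groups.items()}
    if any(n < 2 for n in n_of.values()):
        bad = [g for g, n in n_of.items() if n < 2]
        raise DesignError(f"genotypes with <2 replicates: {bad}")

    means = np.column_stack([X[:, groups[g]].mean(axis=1) for g in genotypes])
    col = {g: j for j, g in enumerate(genotypes)}
    rss = np.zeros(X.shape[0])
    for g in genotypes:
        rss += ((X[:, groups[g]] - means[:, [col[g]]]) ** 2).sum(axis=1)
    df_resid = X.shape[1] - len(genotypes)
    s2 = rss / df_resid
    s2_prior = float(np.median(s2))
    s2_mod = (MODERATION_DF * s2_prior + df_resid * s2) / (MODERATION_DF + df_resid)
    df_mod = df_resid + MODERATION_DF

    rows = []
    for a, b in contrasts:
        lfc = means[:, col[a]] - means[:, col[b]]
        se = np.sqrt(s2_mod * (1.0 / n_of[a] + 1.0 / n_of[b]))
        t = lfc / se
        p = 2.0 * stats.t.sf(np.abs(t), df_mod)
        rows.append(pd.DataFrame({"gene": ne.genes, "group_a": a, "group_b": b,
                                  "log2fc": lfc, "t": t, "p": p}))
    deg = pd.concat(rows, ignore_index=True)
    from statsmodels.stats.multitest import multipletests

    deg["p_adj"] = multipletests(deg["p"], method="fdr_bh")[1]
    deg["significant"] = deg["p_adj"] < fdr

    per_gene = (deg.groupby("gene", sort=False)["significant"].any()
                .rename("de_any").reset_index())

    recip_set = {frozenset(p) for p in design.reciprocal_pairs}
    recip = deg[[frozenset((a, b)) in recip_set
                 for a, b in zip(deg["group_a"], deg["group_b"])]].copy()
    return {"table": deg, "per_gene": per_gene, "reciprocal": recip}
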