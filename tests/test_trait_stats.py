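"""ANOVA, heritability, Spearman and clustering tests.

The heritability REML fit is cross-checked against an independent mixed
model fit in R (lme4) on a frozen fixture.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inherimet.design_io import FactorialDesign
from inherimet.synthetic_data import (TraitSimSpec, TraitSpec,
                                      default_trait_spec, simulate_traits)
from inherimet.trait_stats import (cluster_traits, dendrogram_newick,
                                   genotype_anova, heritability,
                                   spearman_matrix, spearman_square)


def _null_tm(trait_matrix_factory, n_geno=20, seed=0, n_traits=1):
    rng = np.random.default_rng(seed)
    genos = [f"g{i:02d}" for i in range(n_geno)]
    vals = {f"t{k}": 10 + rng.normal(0, 1, n_geno * 3) for k in range(n_traits)}
    return trait_matrix_factory(vals, genos)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_strong_genotype_effect_detected(trait_matrix_factory):
    rng = np.random.default_rng(1)
    y = 10 + rng.normal(0, 1, 60)
    y[:3] += 10.0  # one genotype shifted by 10 residual SDs
    tm = trait_matrix_factory({"t0": y}, [f"g{i:02d}" for i in range(20)])
    _, p = genotype_anova(tm, "t0")
    assert p < 1e-6


def test_single_genotype_level_errors(trait_matrix_factory):
    tm = trait_matrix_factory({"t": np.array([1.0, 2.0, 3.0])}, ["A"])
    with pytest.raises(ValueError, match="single level"):
        genotype_anova(tm, "t")


def test_null_anova_pvalues_approximately_uniform(trait_matrix_factory):
    """Under no genotype effect, gate p-values pass a KS uniformity test."""
    pvals = []
    tm = _null_tm(trait_matrix_factory, seed=123, n_traits=300)
    for t in tm.traits:
        pvals.append(genotype_anova(tm, t)[1])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------

def test_h2_identity_and_bounds(bundle):
    tm = bundle["traits"]
    for t in tm.traits[:5]:
        r = heritability(tm, t)
        assert 0.0 <= r.h2 <= 1.0
        assert r.sigma_g2 >= 0 and r.sigma_e2 >= 0
        assert r.h2 == pytest.approx(
            r.sigma_g2 / (r.sigma_g2 + r.sigma_e2), abs=1e-12)


def test_h2_zero_when_no_genetic_variance(design):
    spec = TraitSimSpec(traits=[TraitSpec(
        "t", {L: 10.0 for L in design.lines},
        {c.hybrid: 0.0 for c in design.crosses},
        residual_sd=1.0, harvest_sd=0.2)])
    tm, _ = simulate_traits(design, spec, seed=5)
    r = heritability(tm, "t")
    assert r.h2 < 0.15


def test_h2_invariant_under_affine_transform(bundle):
    tm = bundle["traits"]
    trait = tm.traits[0]
    base = heritability(tm, trait)
    tm2 = type(tm)(tm.values * -3.7 + 11.0, tm.sample_meta)
    moved = heritability(tm2, trait)
    assert moved.h2 == pytest.approx(base.h2, abs=1e-6)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_reml_components_match_lme4(tmp_path, trait_matrix_factory):
    """Independent oracle: variance components agree with R lme4 REML."""
    rng = np.random.default_rng(42)
    genos = [f"g{i:02d}" for i in range(20)]
    y = (10 + np.repeat(rng.normal(0, 1.2, 20), 3)
         + np.tile([0.0, 0.5, -0.3], 20) + rng.normal(0, 0.8, 60))
    tm = trait_matrix_factory({"t": y}, genos)
    r = heritability(tm, "t")
    assert r.method == "reml"
    df = pd.DataFrame({"y": y, "genotype": tm.sample_meta["genotype"].values,
                       "harvest": tm.sample_meta["harvest"].values})
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = (
        f'd<-read.csv("{csv}"); suppressMessages(library(lme4));'
        'm<-lmer(y~factor(harvest)+(1|genotype),data=d,REML=TRUE);'
        'vc<-as.data.frame(VarCorr(m));'
        'cat(sprintf("%.10f %.10f", vc$vcov[1], vc$vcov[2]))'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=120)
    sg2_r, se2_r = map(float, out.stdout.split())
    assert r.sigma_g2 == pytest.approx(sg2_r, rel=1e-4)
    assert r.sigma_e2 == pytest.approx(se2_r, rel=1e-4)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def _brute_spearman(x, y):
    """Average-rank Spearman as plain Pearson on manually computed ranks."""
    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


@pytest.mark.parametrize("x,y", [
    ([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]),
    ([1, 1, 2, 3, 3], [5, 4, 3, 2, 1]),
    ([0.3, -1.2, 5.0, 2.2, 2.2], [1.0, 1.0, 0.0, 3.0, -2.0]),
])
def test_spearman_equals_bruteforce_ranks(x, y, trait_matrix_factory):
    tm = trait_matrix_factory({"a": np.array(x, float), "b": np.array(y, float)},
                              ["g1", "g2", "g3", "g4", "g5"], n_reps=1)
    rho = spearman_matrix(tm).iloc[0]["rho"]
    assert rho == pytest.approx(_brute_spearman(x, y), abs=1e-12)


def test_spearman_monotone_invariance_and_symmetry(trait_matrix_factory):
    x = np.linspace(-2, 2, 12)
    tm = trait_matrix_factory({"x": x, "expx": np.exp(x)},
                              [f"g{i}" for i in range(4)])
    long = spearman_matrix(tm)
    assert long.iloc[0]["rho"] == pytest.approx(1.0)
    sq = spearman_square(tm)
    assert np.allclose(sq.values, sq.values.T)
    assert np.allclose(np.diag(sq.values), 1.0)


def test_spearman_constant_trait_reported_missing(trait_matrix_factory):
    tm = trait_matrix_factory({"c": np.ones(9), "v": np.arange(9.0)},
                              ["g1", "g2", "g3"])
    row = spearman_matrix(tm).iloc[0]
    assert np.isnan(row["rho"]) and not row["significant"]


def test_statistics_invariant_under_sample_permutation(bundle):
    tm = bundle["traits"]
    rng = np.random.default_rng(3)
    perm = rng.permutation(tm.samples)
    tm_p = type(tm)(tm.values.loc[perm], tm.sample_meta.loc[perm])
    a = spearman_matrix(tm).set_index(["trait_a", "trait_b"])["rho"]
    b = spearman_matrix(tm_p).set_index(["trait_a", "trait_b"])["rho"]
    pd.testing.assert_series_equal(a, b)
    ha = heritability(tm, tm.traits[0]).h2
    hb = heritability(tm_p, tm.traits[0]).h2
    assert ha == pytest.approx(hb, abs=1e-8)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_two_latent_blocks_recovered_with_high_support(trait_matrix_factory):
    rng = np.random.default_rng(7)
    n = 60
    f1, f2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
    vals = {}
    for k in range(5):
        vals[f"a{k}"] = 3 * f1 + rng.normal(0, 0.3, n)
        vals[f"b{k}"] = 3 * f2 + rng.normal(0, 0.3, n)
    tm = trait_matrix_factory(vals, [f"g{i:02d}" for i in range(20)])
    tc = cluster_traits(tm, n_boot=200, seed=1, n_clusters=2)
    groups = {}
    for t, c in tc.flat_clusters.items():
        groups.setdefault(c, set()).add(t)
    assert sorted(sorted(g) for g in groups.values()) == [
        [f"a{k}" for k in range(5)], [f"b{k}" for k in range(5)]]
    idx = {t: i for i, t in enumerate(tc.traits)}
    for side in ("a", "b"):
        node = frozenset(idx[f"{side}{k}"] for k in range(5))
        assert tc.support[node] >= 0.9


def test_duplicate_traits_merge_at_height_zero(trait_matrix_factory):
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 12)
    tm = trait_matrix_factory({"t1": x, "t2": x.copy(),
                               "t3": rng.normal(0, 1, 12)},
                              ["g1", "g2", "g3", "g4"])
    tc = cluster_traits(tm, n_boot=0, seed=0)
    first = tc.linkage[0]
    assert first[2] == pytest.approx(0.0, abs=1e-10)
    merged = {tc.traits[int(first[0])], tc.traits[int(first[1])]}
    assert merged == {"t1", "t2"}
    nwk = dendrogram_newick(tc)
    assert nwk.endswith(";") and "t3" in nwk


def test_clustering_requires_two_traits(trait_matrix_factory):
    tm = trait_matrix_factory({"t": np.arange(6.0)}, ["g1", "g2"])
    with pytest.raises(ValueError):
        cluster_traits(tm, n_boot=0, seed=0)
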