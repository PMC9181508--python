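import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inherimet.coexpression import (UNASSIGNED, build_modules, candidate_genes,
                                    enrich, gene_trait_concordance,
                                    module_trait_correlations,
                                    topological_overlap)
from inherimet.design_io import AnnotationMap
from inherimet.expression import NormalizedExpression, filter_low_expression, normalize
from inherimet.synthetic_data import CountSimSpec, simulate_counts


def _ne_from_matrix(arr, genes, samples):
    df = pd.DataFrame(arr, index=genes, columns=samples)
    ones = pd.Series(1.0, index=samples)
    return NormalizedExpression(df, ones, ones)


# ---------------------------------------------------------------------------
# TOM and eigengene oracles
# ---------------------------------------------------------------------------

def test_tom_matches_hand_computation_on_three_genes():
    """beta = 1 TOM on a 3-gene toy equals the directly summed formula."""
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, (3, 10))
    a = np.abs(np.corrcoef(x))
    np.fill_diagonal(a, 0.0)
    tom = topological_overlap(np.abs(np.corrcoef(x)))
    for i in range(3):
        for j in range(3):
            if i == j:
                assert tom[i, j] == 1.0
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(3))
            k_i, k_j = a[i].sum(), a[j].sum()
            expected = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
            assert tom[i, j] == pytest.approx(expected, abs=1e-10)
    assert np.allclose(tom, tom.T)


def test_eigengene_maximizes_explained_variance(bundle, design):
    """No other unit-norm combination explains more module variance."""
    kept, _ = filter_low_expression(bundle["counts"])
    ne = normalize(kept)
    ms = build_modules(ne, min_module_size=15)
    assert ms.modules, "expected at least one module"
    mod = ms.modules[0]
    genes = ms.assignment[ms.assignment == mod].index
    sub = ne.logcpm.loc[genes].to_numpy()
    z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, ddof=1, keepdims=True)
    e = ms.eigengenes[mod].to_numpy()
    assert np.linalg.norm(e) == pytest.approx(1.0, abs=1e-9)
    var_e = ((z @ e) ** 2).sum()
    rng = np.random.default_rng(1)
    for _ in range(50):
        v = rng.normal(0, 1, len(e))
        v /= np.linalg.norm(v)
        assert ((z @ v) ** 2).sum() <= var_e + 1e-8
    # sign orientation: positively correlated with mean module expression
    assert np.corrcoef(e, z.mean(0))[0, 1] > 0


def test_module_assignment_invariant_to_gene_order(design):
    spec = CountSimSpec(n_genes=300, module_sizes={"m1": 50, "m2": 50},
                        module_loading=1.0, n_de_genes=0)
    cm, _ = simulate_counts(design, spec, seed=7)
    ne = normalize(filter_low_expression(cm)[0])
    ms1 = build_modules(ne, min_module_size=20)
    rng = np.random.default_rng(0)
    perm = rng.permutation(ne.logcpm.index)
    ne2 = NormalizedExpression(ne.logcpm.loc[perm], ne.norm_factors,
                               ne.effective_lib)
    ms2 = build_modules(ne2, min_module_size=20)
    # same partition up to label names
    lab1 = ms1.assignment.sort_index()
    lab2 = ms2.assignment.sort_index()
    from sklearn.metrics import adjusted_rand_score
    assert adjusted_rand_score(lab1, lab2) == pytest.approx(1.0)


def test_constant_gene_dropped_with_warning(bundle, caplog):
    kept, _ = filter_low_expression(bundle["counts"])
    ne = normalize(kept)
    ne.logcpm.iloc[0] = 3.14
    with caplog.at_level("WARNING", logger="inherimet"):
        ms = build_modules(ne, min_module_size=15)
    assert ne.logcpm.index[0] not in ms.assignment.index
    assert any("constant" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# Module-trait correlation
# ---------------------------------------------------------------------------

def test_trait_equal_to_eigengene_has_r_one(bundle, design):
    kept, _ = filter_low_expression(bundle["counts"])
    ne = normalize(kept)
    ms = build_modules(ne, min_module_size=15)
    tm = bundle["traits"]
    mod = ms.modules[0]
    tm2 = type(tm)(tm.values.assign(EIG=ms.eigengenes.loc[tm.samples, mod]),
                   tm.sample_meta)
    mt = module_trait_correlations(ms, tm2)
    row = mt[(mt["module"] == mod) & (mt["trait"] == "EIG")].iloc[0]
    assert row["r"] == pytest.approx(1.0, abs=1e-9)


def test_module_trait_errors_without_shared_samples(bundle):
    kept, _ = filter_low_expression(bundle["counts"])
    ne = normalize(kept)
    ms = build_modules(ne, min_module_size=15)
    tm = bundle["traits"]
    tm_alien = type(tm)(tm.values.set_axis([f"x{i}" for i in range(60)]),
                        tm.sample_meta.set_axis([f"x{i}" for i in range(60)]))
    with pytest.raises(ValueError, match="share no samples"):
        module_trait_correlations(ms, tm_alien)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def _exhaustive_hypergeom_tail(N, K, n, k):
    """P(overlap >= k) by summing the exact combinatorial density."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)
    return total


def test_enrichment_matches_exhaustive_combinatorics():
    genes = [f"g{i}" for i in range(100)]
    assignment = pd.Series(UNASSIGNED, index=genes, dtype=object)
    assignment.iloc[:4] = "M01"
    eig = pd.DataFrame({"M01": np.zeros(5)}, index=[f"s{i}" for i in range(5)])
    from inherimet.coexpression import ModuleSet
    ms = ModuleSet(assignment, eig, beta=6)
    amap = AnnotationMap({"T1": set(genes[:3]) | set(genes[50:57]),  # overlap 3
                          "ALL": set(genes),                         # p = 1
                          "NONE": set(genes[90:])})                  # overlap 0
    out = enrich(ms, amap).set_index("term")
    assert out.loc["T1", "overlap"] == 3
    assert out.loc["T1", "p"] == pytest.approx(
        _exhaustive_hypergeom_tail(100, 10, 4, 3), abs=1e-10)
    assert out.loc["ALL", "p"] == pytest.approx(1.0, abs=1e-12)
    assert out.loc["NONE", "p"] == pytest.approx(1.0, abs=1e-12)
    assert (out["p_adj"] >= out["p"] - 1e-15).all()


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def test_concordance_regression_on_constructed_pair(bundle, design):
    kept, _ = filter_low_expression(bundle["counts"])
    ne = normalize(kept)
    tm = bundle["traits"]
    gene = ne.genes[0]
    rng = np.random.default_rng(9)
    y = -2.0 * ne.logcpm.loc[gene, tm.samples].to_numpy() \
        + rng.normal(0, 0.01, len(tm.samples))
    tm2 = type(tm)(tm.values.assign(NEG=y), tm.sample_meta)
    calls = pd.DataFrame({"cross": ["c1"], "variable": [gene], "mode": ["OD"]})
    tcalls = pd.DataFrame({"cross": ["c1"], "variable": ["NEG"], "mode": ["OR"]})
    rep = gene_trait_concordance(calls, tcalls, ne, tm2, gene, "NEG")
    assert rep["r2"] > 0.99 and rep["slope"] < 0
    assert rep["mode_pairs"]["c1"] == ("OD", "OR")
    assert "opposing" in rep["pattern"]
    with pytest.raises(KeyError):
        gene_trait_concordance(calls, tcalls, ne, tm2, "absent", "NEG")
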