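"""Per-cross mode-of-inheritance classification via the D/A (potence) ratio.

For each cross (two inbred parents P1, P2 and their F1) and each variable
(trait or normalized gene expression) the classifier

1. gates on a one-way ANOVA across the three genotypes (default alpha 0.05;
   a non-significant cross is called ``ns``),
2. orients the parents by mean so the high parent is HP, computes the
   additive component ``A = (mu_HP - mu_LP) / 2 >= 0`` and the dominance
   component ``D = mu_F1 - (mu_P1 + mu_P2) / 2``,
3. classifies the ratio D/A into five bands:

   ======================  ====
   D/A < -1.2              OR   (over-recessive: F1 below the low parent)
   -1.2 <= D/A <= -0.8     R    (recessive: F1 at the low parent)
   -0.8 <  D/A <  0.8      A    (additive: F1 near the midparent)
   0.8  <= D/A <= 1.2      D    (dominant: F1 at the high parent)
   D/A > 1.2               OD   (over-dominant: F1 above the high parent)
   ======================  ====

When the parents are indistinguishable (A below a tolerance tied to the
pooled SD) the ratio is taken as signed infinity: a transgressive F1 with
equal parents is the textbook over-dominance/over-recessiveness case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design_io import FactorialDesign, TraitMatrix

MODES = ["ns", "OR", "R", "A", "D", "OD"]

#: |D/A| band edges: +-0.8 separates additive from (over)dominant/recessive,
#: +-1.2 separates dominant/recessive from transgressive.
BAND_INNER = 0.8
BAND_OUTER = 1.2

#: A is treated as zero when below DEGENERATE_A_FACTOR x pooled SD.
DEGENERATE_A_FACTOR = 1e-8


@dataclass
class InheritanceCall:
    cross: str
    variable: str
    gate_p: float
    a_comp: float
    d_comp: float
    ratio: float
    mode: str

    def as_row(self) -> dict:
        return {"cross": self.cross, "variable": self.variable,
                "gate_p": self.gate_p, "A": self.a_comp, "D": self.d_comp,
                "ratio": self.ratio, "mode": self.mode}


def classify_ratio(ratio: float) -> str:
    """Map a D/A ratio onto the five-band mode scale (gate already passed)."""
    if ratio < -BAND_OUTER:
        return "OR"
    if ratio <= -BAND_INNER:
        return "R"
    if ratio < BAND_INNER:
        return "A"
    if ratio <= BAND_OUTER:
        return "D"
    return "OD"


def classify_cross(
    values_p1: np.ndarray,
    values_p2: np.ndarray,
    values_f1: np.ndarray,
    alpha: float = 0.05,
    cross: str = "",
    variable: str = "",
) -> InheritanceCall:
    """Classify one (cross, variable) from replicate vectors of P1, P2, F1.

    Each vector needs >= 2 non-missing replicates; otherwise the call is
    ``insufficient data`` (distinct from ``ns``, which means the gate ANOVA
    did not reach ``alpha``).
    """
    groups = [np.asarray(v, dtype=float) for v in (values_p1, values_p2, values_f1)]
    groups = [g[~np.isnan(g)] for g in groups]
    if any(len(g) < 2 for g in groups):
        return InheritanceCall(cross, variable, np.nan, np.nan, np.nan, np.nan,
                               "insufficient data")
    p1, p2, f1 = groups
    _, gate_p = stats.f_oneway(p1, p2, f1)
    if np.isnan(gate_p):  # all values identical in every group
        gate_p = 1.0

    m1, m2, mf = p1.mean(), p2.mean(), f1.mean()
    hp, lp = (m1, m2) if m1 >= m2 else (m2, m1)
    a_comp = (hp - lp) / 2.0
    d_comp = mf - (m1 + m2) / 2.0

    if gate_p >= alpha:
        return InheritanceCall(cross, variable, float(gate_p), a_comp, d_comp,
                               d_comp / a_comp if a_comp > 0 else np.nan, "ns")

    pooled_sd = np.sqrt(np.mean([g.var(ddof=1) for g in groups]))
    if a_comp < DEGENERATE_A_FACTOR * max(pooled_sd, np.finfo(float).tiny):
        ratio = np.inf if d_comp > 0 else -np.inf
    else:
        ratio = d_comp / a_comp
    return InheritanceCall(cross, variable, float(gate_p), a_comp, d_comp,
                           float(ratio), classify_ratio(ratio))


def classify_all(
    values: pd.DataFrame,
    sample_meta: pd.DataFrame,
    design: FactorialDesign,
    alpha: float = 0.05,
    bh_within_cross: bool = False,
) -> pd.DataFrame:
    """One inheritance call per (cross, variable).

    ``values`` is samples x variables (a trait matrix or a transposed
    normalized-expression matrix); reciprocal hybrids are classified
    independently against the same parent pair.  With ``bh_within_cross``
    the gate p-values are Benjamini-Hochberg adjusted across variables
    within each cross before gating.
    """
    if not design.crosses:
        raise ValueError("design declares no crosses")
    geno = sample_meta["genotype"]
    arr = values.to_numpy(dtype=float)
    col_of = {v: i for i, v in enumerate(values.columns)}
    idx_of = {g: np.flatnonzero((geno == g).to_numpy()) for g in design.genotypes}

    rows = []
    for c in design.crosses:
        calls = []
        for var in values.columns:
            j = col_of[var]
            call = classify_cross(arr[idx_of[c.female], j], arr[idx_of[c.male], j],
                                  arr[idx_of[c.hybrid], j], alpha=alpha,
                                  cross=c.hybrid, variable=var)
            calls.append(call)
        if bh_within_cross:
            _bh_regate(calls, alpha)
        rows.extend(call.as_row() for call in calls)
    return pd.DataFrame(rows)


def _bh_regate(calls: list[InheritanceCall], alpha: float) -> None:
    """Re-gate calls on BH-adjusted p within one cross (in place)."""
    from statsmodels.stats.multitest import multipletests

    ok = [c for c in calls if c.mode != "insufficient data"]
    if not ok:
        return
    rej, padj, *_ = multipletests([c.gate_p for c in ok], alpha=alpha, method="fdr_bh")
    for c, r, p in zip(ok, rej, padj):
        if not r:
            c.mode = "ns"
        elif c.mode == "ns":
            # raw gate failed but BH cannot make p smaller; never happens
            pass
        c.gate_p = float(p)


def summarize_modes(calls: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Stacked per-cross mode counts plus per-variable consistency flags.

    Returns ``per_cross`` (cross x six modes, counts and fractions in the
    stacked-barplot layout), ``overall`` (one row of counts/fractions over
    all classified calls) and ``per_variable`` with the set of modes seen
    across crosses, a transgression flag (any OD or OR) and a single-type
    flag (all transgressions of one sign).
    """
    if calls.empty:
        raise ValueError("empty call table")
    usable = calls[calls["mode"].isin(MODES)]

    per_cross = (usable.pivot_table(index="cross", columns="mode", values="variable",
                                    aggfunc="count", fill_value=0)
                 .reindex(columns=MODES, fill_value=0))
    frac = per_cross.div(per_cross.sum(axis=1), axis=0)
    per_cross = pd.concat([per_cross, frac.add_prefix("frac_")], axis=1)

    counts = usable["mode"].value_counts().reindex(MODES, fill_value=0)
    overall = pd.DataFrame([{**counts.to_dict(),
                             **{f"frac_{m}": counts[m] / counts.sum() for m in MODES}}])

    per_var = []
    for var, sub in usable.groupby("variable"):
        modes = set(sub["mode"])
        trans = {m for m in modes if m in ("OD", "OR")}
        sig = sub[sub["mode"] != "ns"]
        modal = sig["mode"].mode().iloc[0] if not sig.empty else "ns"
        per_var.append({
            "variable": var,
            "modes": ",".join(sorted(modes)),
            "transgressive": bool(trans),
            "single_type": bool(trans) and len(trans) == 1,
            "modal_mode": modal,
            "n_modal": int((sig["mode"] == modal).sum()) if not sig.empty else 0,
            "n_classified": len(sig),
        })
    return {"per_cross": per_cross, "overall": overall,
            "per_variable": pd.DataFrame(per_var)}


def mode_recovery_power(
    replicate_counts: list[int],
    effect_sizes: list[float],
    true_ratios: list[float],
    n_sim: int = 200,
    noise_sd: float = 1.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Operating characteristics of the classifier on a simulation grid.

    For each (replicate count, effect size, true d/a) cell the two parents
    sit at ``-+effect_size/2`` (so A = effect_size/2) and the F1 at
    midparent + d/a * A; ``n_sim`` draws with Gaussian noise ``noise_sd``
    give the fraction of runs recovering the true mode, with a 95% Wilson
    interval.  ``effect_size = 0`` rows measure the null ns rate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in replicate_counts:
        for eff in effect_sizes:
            for da in true_ratios:
                a = eff / 2.0
                mu = (-a, a, da * a)
                truth = "ns" if eff == 0 else classify_ratio(da)
                hits = 0
                for _ in range(n_sim):
                    g = [mu[k] + noise_sd * rng.standard_normal(n) for k in range(3)]
                    call = classify_cross(g[0], g[1], g[2], alpha=alpha)
                    hits += call.mode == truth
                lo, hi = _wilson(hits, n_sim)
                rows.append({"n_reps": n, "effect_size": eff, "true_ratio": da,
                             "true_mode": truth, "recovery": hits / n_sim,
                             "ci_low": lo, "ci_high": hi, "n_sim": n_sim})
    return pd.DataFrame(rows)


def _wilson(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)
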