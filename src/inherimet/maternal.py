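"""Cross-direction (maternal) effects between reciprocal hybrids.

A reciprocal pair is the same parental combination crossed both ways
(A female x B male vs B female x A male).  Any systematic difference in a
trait between the two hybrids must come from the cross direction —
cytoplasmic inheritance, seed-parent effects, imprinting — collectively
"maternal effects".  Detection is a per-variable two-sample t-test between
the replicate values of the two hybrids (pooled-variance Student's test by
default; Welch optional), with the direction recorded as the female parent
giving the larger mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design_io import DesignError, FactorialDesign, TraitMatrix


@dataclass
class MaternalEffectResult:
    pair: tuple[str, str]
    variable: str
    t: float
    p: float
    direction: str | None  # female parent with the larger mean, if significant
    mode_pair: tuple[str, str] | None = None

    def as_row(self) -> dict:
        return {"hybrid_1": self.pair[0], "hybrid_2": self.pair[1],
                "variable": self.variable, "t": self.t, "p": self.p,
                "direction": self.direction or "",
                "mode_1": self.mode_pair[0] if self.mode_pair else "",
                "mode_2": self.mode_pair[1] if self.mode_pair else ""}


def reciprocal_ttest(
    tm: TraitMatrix,
    design: FactorialDesign,
    pair: tuple[str, str],
    variable: str,
    alpha: float = 0.05,
    welch: bool = False,
) -> MaternalEffectResult:
    """Two-sided t-test of one variable between one reciprocal hybrid pair."""
    h1, h2 = pair
    for h in pair:
        try:
            design.cross(h)
        except KeyError:
            raise DesignError(f"reciprocal pair {pair}: hybrid {h!r} not in design")
    v1 = tm.genotype_values(h1, variable)
    v2 = tm.genotype_values(h2, variable)
    if len(v1) < 2 or len(v2) < 2:
        raise DesignError(f"pair {pair}: fewer than 2 replicates for a hybrid")
    if np.array_equal(np.sort(v1), np.sort(v2)) and np.var(np.concatenate([v1, v2])) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(v1, v2, equal_var=not welch)
        if np.isnan(t):  # identical constant groups
            t, p = 0.0, 1.0
    direction = None
    if p < alpha:
        winner = h1 if v1.mean() > v2.mean() else h2
        direction = design.cross(winner).female
    return MaternalEffectResult((h1, h2), variable, float(t), float(p), direction)


def maternal_scan(
    tm: TraitMatrix,
    design: FactorialDesign,
    alpha: float = 0.05,
    welch: bool = False,
    calls: pd.DataFrame | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """All reciprocal pairs x variables, with optional mode-change report.

    When an inheritance-call table (from ``inheritance.classify_all``) is
    supplied, each row is annotated with the modes of the two hybrids and a
    ``mode_change`` flag marking variables whose inheritance mode differs
    between the reciprocal crosses.
    """
    import logging

    if not design.reciprocal_pairs:
        logging.getLogger("inherimet").info("design has no reciprocal pairs")
        return pd.DataFrame(columns=["hybrid_1", "hybrid_2", "variable", "t", "p",
                                     "direction", "mode_1", "mode_2", "mode_change"])
    mode_of = {}
    if calls is not None:
        mode_of = {(r["cross"], r["variable"]): r["mode"] for _, r in calls.iterrows()}

    rows = []
    for pair in design.reciprocal_pairs:
        for var in tm.traits:
            res = reciprocal_ttest(tm, design, pair, var, alpha=alpha, welch=welch)
            if mode_of:
                res.mode_pair = (mode_of.get((pair[0], var), ""),
                                 mode_of.get((pair[1], var), ""))
            rows.append(res.as_row())
    out = pd.DataFrame(rows)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    out.loc[~out["significant"], "direction"] = ""
    if mode_of:
        out["mode_change"] = (out["mode_1"] != out["mode_2"])
    return out
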