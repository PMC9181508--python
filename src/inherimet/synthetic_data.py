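"""Ground-truth simulators for factorial-design trait and count data.

Every downstream stage (ANOVA/heritability, D/A classification, maternal
scan, differential expression, module detection) gets a recovery test from
these generators, because the real study data is an external download.

Trait model
-----------
For trait *t* the genotypic value of parental line *L* is a spec-declared
mean; the genotypic value of hybrid *H* = female x male is::

    midparent + (d/a) * a + maternal_shift(female)

with ``a = (mu_HP - mu_LP)/2`` the additive component and ``d/a`` the true
potence ratio declared per (cross, trait).  A replicate observation adds a
shared per-harvest block effect and Gaussian residual noise; an optional
log-normal flag exponentiates the whole value (volatile abundances are
strictly positive ratios to a reference homogenate).

Count model
-----------
Gene *g* in sample *s* is negative-binomial with mean::

    libsize_s * exp(logmu_g + loading * f_m(s) + de_g(s))

where ``f_m`` is a module-specific latent factor (a genotype-level score
plus replicate noise, so genes of one module co-vary across samples) and
``de_g`` is a per-genotype log-scale effect following a declared
inheritance mode for the spiked differentially-expressed genes.

Both simulators require an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_io import CountMatrix, FactorialDesign, TraitMatrix, study_design
from .inheritance import classify_ratio

#: representative true potence ratios for each declared mode
MODE_RATIOS = {"OR": -1.5, "R": -1.0, "A": 0.0, "D": 1.0, "OD": 1.5}


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("seed is required: simulation runs must be reproducible")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

@dataclass
class TraitSpec:
    """Simulation parameters for a single trait."""

    name: str
    line_means: dict[str, float]
    cross_ratio: dict[str, float]        # hybrid ID -> true d/a
    residual_sd: float = 0.5
    harvest_sd: float = 0.3
    maternal_shift: dict[str, float] = field(default_factory=dict)  # female -> offset
    lognormal: bool = False

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError(f"trait {self.name!r}: residual SD must be > 0")


@dataclass
class TraitSimSpec:
    traits: list[TraitSpec]
    n_harvests: int = 3


def simulate_traits(
    design: FactorialDesign, spec: TraitSimSpec, seed: int
) -> tuple[TraitMatrix, pd.DataFrame]:
    """Simulate replicate trait values and the matching ground-truth table.

    Returns the TraitMatrix (one sample per genotype per harvest) and a
    truth table with one row per (cross, trait): true additive component
    ``a``, dominance ``d``, ratio ``d/a`` and mode, plus the maternal shift
    actually applied.
    """
    rng = _require_seed(seed)
    genotypes = design.genotypes
    H = spec.n_harvests
    samples = [f"{g}_h{j + 1}" for g in genotypes for j in range(H)]
    meta = pd.DataFrame({
        "genotype": [g for g in genotypes for _ in range(H)],
        "harvest": [j + 1 for _ in genotypes for j in range(H)],
    }, index=pd.Index(samples, name="sample"))

    cross_of = {c.hybrid: c for c in design.crosses}
    data = {}
    truth_rows = []
    for ts in spec.traits:
        geno_value: dict[str, float] = dict(ts.line_means)
        for hyb, ratio in ts.cross_ratio.items():
            c = cross_of[hyb]
            m1, m2 = ts.line_means[c.female], ts.line_means[c.male]
            a = abs(m1 - m2) / 2.0
            d = ratio * a
            shift = ts.maternal_shift.get(c.female, 0.0)
            geno_value[hyb] = (m1 + m2) / 2.0 + d + shift
            truth_rows.append({
                "cross": hyb, "trait": ts.name, "a": a, "d": d,
                "ratio": ratio if a > 0 else np.nan,
                "mode": classify_ratio(ratio) if a > 0 else
                        ("OD" if d > 0 else "OR" if d < 0 else "A"),
                "maternal_shift": shift,
            })
        harvest_eff = rng.normal(0.0, ts.harvest_sd, size=H)
        col = np.empty(len(samples))
        for i, g in enumerate(genotypes):
            base = geno_value.get(g)
            if base is None:  # hybrid without a declared ratio: midparent
                c = cross_of[g]
                base = (ts.line_means[c.female] + ts.line_means[c.male]) / 2.0
            for j in range(H):
                col[i * H + j] = (base + harvest_eff[j]
                                  + rng.normal(0.0, ts.residual_sd))
        if ts.lognormal:
            col = np.exp(col)
        data[ts.name] = col

    tm = TraitMatrix(pd.DataFrame(data, index=meta.index), meta)
    return tm, pd.DataFrame(truth_rows)


def default_trait_spec(
    design: FactorialDesign,
    n_traits: int = 68,
    n_clusters: int = 8,
    seed: int = 0,
    residual_sd: float = 0.5,
    harvest_sd: float = 0.3,
    line_scale: float = 2.0,
    n_maternal_traits: int = 7,
    maternal_shift_sd_units: float = 3.0,
) -> TraitSimSpec:
    """Study-scale trait spec: clustered traits with mixed inheritance modes.

    Traits fall into ``n_clusters`` groups sharing latent per-line values
    (giving within-cluster correlation and co-clustering).  The true
    potence ratio is drawn per (cluster, parent pair) so traits of one
    cluster inherit alike within a cross, with mode probabilities
    reflecting a mixture dominated by additivity, then
    recessiveness/over-recessiveness, then (over)dominance.  Genetic
    signal is heterogeneous across traits: roughly one trait in eight
    carries essentially no genotype effect (and hence near-zero
    heritability) and a further sixth carries a weak effect, so the
    heritability distribution spans the low-to-0.99 range seen in real
    fruit-metabolite panels.  A handful of traits receive a maternal shift
    on one reciprocal cross (default 7 traits at 3 residual SDs).
    """
    rng = _require_seed(seed)
    lines = list(design.lines)
    hybrids = [c.hybrid for c in design.crosses]
    modes = np.array(["A", "R", "OR", "OD", "D"])
    probs = np.array([0.43, 0.23, 0.18, 0.11, 0.05])

    cluster_line = {c: {L: rng.normal(0.0, 1.0) for L in lines}
                    for c in range(n_clusters)}
    # One true ratio per (cluster, parent pair): reciprocal hybrids are
    # genetically identical, so they share the same genotypic value and
    # differ only by maternal shifts.  Transgressions are single-type per
    # cluster (a cluster transgresses consistently upward or downward, or
    # not at all), mirroring the consistency observed in real crosses.
    pair_of = {c.hybrid: frozenset((c.female, c.male)) for c in design.crosses}
    unique_pairs = sorted({pair_of[h] for h in hybrids}, key=sorted)
    cluster_ratio = {}
    for cl in range(n_clusters):
        trans_dir = str(rng.choice(["OR", "OD"]))
        transgressive = rng.random() < 0.65
        pair_ratio = {}
        for p in unique_pairs:
            m = str(rng.choice(modes, p=probs))
            if m in ("OR", "OD"):
                m = trans_dir if transgressive else {"OR": "R", "OD": "D"}[m]
            pair_ratio[p] = MODE_RATIOS[m]
        cluster_ratio[cl] = {h: pair_ratio[pair_of[h]] for h in hybrids}
    recip_females = sorted({design.cross(a).female for a, _ in design.reciprocal_pairs})
    maternal_idx = set(rng.choice(n_traits, size=min(n_maternal_traits, n_traits),
                                  replace=False).tolist())

    signal_mult = {"null": 0.03, "weak": 0.15, "normal": 1.0}
    traits = []
    for t in range(n_traits):
        c = t % n_clusters
        signal = str(rng.choice(["null", "weak", "normal"],
                                p=[8 / 68, 10 / 68, 50 / 68]))
        gain = rng.uniform(0.7, 1.3) * signal_mult[signal]
        means = {L: 10.0 + line_scale * gain * cluster_line[c][L] for L in lines}
        shift = {}
        if t in maternal_idx and recip_females:
            fem = recip_females[int(rng.integers(len(recip_females)))]
            shift = {fem: maternal_shift_sd_units * residual_sd
                     * (1 if rng.random() < 0.5 else -1)}
        traits.append(TraitSpec(
            name=f"T{t + 1:03d}_c{c + 1}",
            line_means=means,
            cross_ratio=dict(cluster_ratio[c]),
            residual_sd=residual_sd,
            harvest_sd=harvest_sd,
            maternal_shift=shift,
        ))
    return TraitSimSpec(traits=traits, n_harvests=3)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

@dataclass
class CountSimSpec:
    """Simulation parameters for a negative-binomial count matrix."""

    n_genes: int = 2000
    module_sizes: dict[str, int] = field(default_factory=dict)  # label -> n genes
    module_loading: float = 1.0
    base_mean: float = 100.0
    log_mean_sd: float = 1.0
    dispersion: float = 0.1
    n_de_genes: int = 0
    de_effect: float = 1.0          # SD of per-line log effects
    library_size_sd: float = 0.2    # log-normal multiplier SD
    factor_rep_sd: float = 0.3      # replicate noise on the module factor

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.library_size_sd < 0:
            raise ValueError("library-size SD must be >= 0")
        small = {m: n for m, n in self.module_sizes.items() if n < 3}
        if small:
            raise ValueError(f"modules with <3 genes are undetectable: {small}")
        if sum(self.module_sizes.values()) > self.n_genes:
            raise ValueError("module sizes exceed the gene count")


def simulate_counts(
    design: FactorialDesign,
    spec: CountSimSpec,
    seed: int,
    n_harvests: int = 3,
) -> tuple[CountMatrix, dict[str, pd.DataFrame]]:
    """Simulate counts plus ground-truth gene tables.

    Returns the CountMatrix and a dict with ``genes`` (module label, DE
    flag, true per-cross mode for DE genes as a long table ``de_modes``)
    and ``library_sizes``.
    """
    rng = _require_seed(seed)
    genotypes = design.genotypes
    H = n_harvests
    samples = [f"{g}_h{j + 1}" for g in genotypes for j in range(H)]
    geno_of = [g for g in genotypes for _ in range(H)]
    n_s = len(samples)
    G = spec.n_genes

    gene_ids = [f"G{i + 1:05d}" for i in range(G)]
    module_of = np.array(["none"] * G, dtype=object)
    pos = 0
    for label, size in spec.module_sizes.items():
        module_of[pos:pos + size] = label
        pos += size

    # module latent factors: genotype-level score + replicate noise
    factors = {}
    for label in spec.module_sizes:
        geno_score = {g: rng.normal(0.0, 1.0) for g in genotypes}
        factors[label] = np.array([geno_score[g] for g in geno_of]) \
            + rng.normal(0.0, spec.factor_rep_sd, size=n_s)

    log_mu = rng.normal(np.log(spec.base_mean), spec.log_mean_sd, size=G)
    loadings = np.zeros(G)
    for i in range(G):
        if module_of[i] != "none":
            loadings[i] = spec.module_loading * rng.uniform(0.6, 1.0)

    # spiked DE genes with declared inheritance modes
    de_idx = rng.choice(G, size=min(spec.n_de_genes, G), replace=False) \
        if spec.n_de_genes else np.array([], dtype=int)
    cross_of = {c.hybrid: c for c in design.crosses}
    modes = np.array(["A", "R", "OR", "OD", "D"])
    de_effects = np.zeros((G, len(genotypes)))
    geno_index = {g: k for k, g in enumerate(genotypes)}
    de_mode_rows = []
    pair_of = {h: frozenset((c.female, c.male)) for h, c in cross_of.items()}
    unique_pairs = sorted(set(pair_of.values()), key=sorted)
    for i in de_idx:
        line_eff = {L: rng.normal(0.0, spec.de_effect) for L in design.lines}
        # reciprocal hybrids share the true ratio (same genotype)
        pair_ratio = {p: MODE_RATIOS[rng.choice(modes)] for p in unique_pairs}
        cross_ratio = {h: pair_ratio[pair_of[h]] for h in cross_of}
        for L, e in line_eff.items():
            de_effects[i, geno_index[L]] = e
        for h, ratio in cross_ratio.items():
            c = cross_of[h]
            m1, m2 = line_eff[c.female], line_eff[c.male]
            a = abs(m1 - m2) / 2.0
            de_effects[i, geno_index[h]] = (m1 + m2) / 2.0 + ratio * a
            de_mode_rows.append({"gene": gene_ids[i], "cross": h,
                                 "ratio": ratio, "mode": classify_ratio(ratio)})

    lib = np.exp(rng.normal(0.0, spec.library_size_sd, size=n_s))
    geno_col = np.array([geno_index[g] for g in geno_of])

    log_rate = np.tile(log_mu[:, None], (1, n_s))
    for label in spec.module_sizes:
        in_mod = module_of == label
        log_rate[in_mod] += np.outer(loadings[in_mod], factors[label])
    log_rate += de_effects[:, geno_col]
    mu = np.exp(log_rate) * lib[None, :]

    size = 1.0 / spec.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=samples))

    genes = pd.DataFrame({"gene": gene_ids, "module": module_of,
                          "is_de": np.isin(np.arange(G), de_idx)})
    truth = {
        "genes": genes,
        "de_modes": pd.DataFrame(de_mode_rows,
                                 columns=["gene", "cross", "ratio", "mode"]),
        "library_sizes": pd.DataFrame({"sample": samples, "libsize": lib}),
    }
    return cm, truth


def default_count_spec(n_genes: int = 2000, n_de_genes: int = 400) -> CountSimSpec:
    """Study-shaped count spec scaled down: 12 modules, smallest 39 genes
    at the default 2000-gene size (sizes scale with ``n_genes``)."""
    sizes = [300, 250, 200, 150, 120, 100, 90, 80, 70, 60, 50, 39]
    labels = ["turquoise", "blue", "brown", "yellow", "red", "black", "pink",
              "magenta", "purple", "greenyellow", "tan", "green"]
    if n_genes < 2000:
        sizes = [max(5, round(s * n_genes / 2000)) for s in sizes]
        # keep a background pool: drop the smallest modules if they no
        # longer fit at tiny gene counts
        while sizes and sum(sizes) > 0.8 * n_genes:
            sizes.pop()
        labels = labels[:len(sizes)]
        n_de_genes = min(n_de_genes, n_genes // 5)
    return CountSimSpec(
        n_genes=n_genes,
        module_sizes=dict(zip(labels, sizes)),
        module_loading=1.0,
        n_de_genes=n_de_genes,
        de_effect=1.0,
    )


def study_bundle(seed: int, n_traits: int = 68, n_genes: int = 2000):
    """Full synthetic study-scale bundle: design, traits, counts, truths."""
    design = study_design()
    tspec = default_trait_spec(design, n_traits=n_traits, seed=seed)
    tm, trait_truth = simulate_traits(design, tspec, seed=seed + 1)
    cspec = default_count_spec(n_genes=n_genes)
    cm, count_truth = simulate_counts(design, cspec, seed=seed + 2)
    return {"design": design, "traits": tm, "trait_truth": trait_truth,
            "counts": cm, "count_truth": count_truth,
            "trait_spec": tspec, "count_spec": cspec}
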