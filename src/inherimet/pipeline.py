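"""End-to-end orchestration: one config, six stages, one manifest.

Stage order follows data dependencies: trait statistics -> inheritance
classification -> maternal scan -> differential expression (and expression
inheritance) -> co-expression modules -> gene/trait concordance.  Every
stage writes tidy TSV tables into the output directory and the manifest
records versions, seed, thresholds and per-stage row counts plus SHA-256
hashes of every output, so a re-run with the same config and seed is
verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .design_io import (FactorialDesign, TraitMatrix, read_annotation,
                        read_count_matrix, read_design, read_trait_matrix)
from .expression import deg_scan, filter_low_expression, normalize
from .inheritance import classify_all, summarize_modes
from .maternal import maternal_scan
from .trait_stats import heritability_table, spearman_matrix

logger = logging.getLogger("inherimet")

STAGES = ["traits", "inheritance", "maternal", "deg", "modules", "concordance"]


@dataclass
class RunConfig:
    design: str = ""
    trait_matrix: str = ""
    count_matrix: str = ""
    annotation: str = ""
    outdir: str = "results"
    seed: int = 0
    alpha: float = 0.05           # gate / test threshold
    fdr: float = 0.05             # global DEG threshold
    min_cpm: float = 1.0
    min_cpm_samples: int = 3
    beta: int | None = None       # soft power; None = auto
    cut_height: float | None = None
    min_module_size: int = 30
    n_boot: int = 0               # trait-cluster bootstraps (0 = skip)
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def validate(self) -> None:
        for name, lo, hi, v in [("alpha", 0, 1, self.alpha),
                                ("fdr", 0, 1, self.fdr)]:
            if not (lo < v < hi):
                raise ValueError(f"{name} must be in ({lo}, {hi}), got {v}")
        if self.min_cpm < 0 or self.min_module_size < 2:
            raise ValueError("min_cpm must be >= 0 and min_module_size >= 2")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    design: FactorialDesign | None = None,
    tm: TraitMatrix | None = None,
    cm=None,
) -> dict:
    """Run the configured stages and return {tables, manifest}.

    Inputs may be passed in memory (design / tm / cm) or read from the
    paths in the config.  A stage whose upstream dependency is toggled off
    aborts with a dependency error naming both stages.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if design is None:
        design = read_design(config.design)
    if tm is None and config.trait_matrix:
        tm = read_trait_matrix(config.trait_matrix, design)
    if cm is None and config.count_matrix:
        cm = read_count_matrix(config.count_matrix, design)

    stages = config.stages
    deps = {"maternal": "inheritance", "modules": "deg", "concordance": "modules"}
    for s in stages:
        if s in deps and deps[s] not in stages:
            raise ValueError(f"stage {s!r} requires stage {deps[s]!r}, "
                             f"which is toggled off")

    tables: dict[str, pd.DataFrame] = {}
    manifest: dict = {
        "package": "inherimet",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "thresholds": {"alpha": config.alpha, "fdr": config.fdr,
                       "min_cpm": config.min_cpm,
                       "min_module_size": config.min_module_size,
                       "cut_height": config.cut_height, "beta": config.beta},
        "stages": [],
    }

    def record(stage: str, names: list[str]) -> None:
        manifest["stages"].append(
            {"stage": stage,
             "tables": {n: int(len(tables[n])) for n in names}})

    current = None
    try:
        if "traits" in stages:
            current = "traits"
            if tm is None:
                raise ValueError("trait matrix required")
            tables["heritability"] = heritability_table(tm)
            tables["trait_correlations"] = spearman_matrix(tm, alpha=config.alpha)
            record("traits", ["heritability", "trait_correlations"])

        if "inheritance" in stages:
            current = "inheritance"
            calls = classify_all(tm.values, tm.sample_meta, design,
                                 alpha=config.alpha)
            tables["trait_calls"] = calls
            summ = summarize_modes(calls)
            tables["trait_modes_per_cross"] = summ["per_cross"].reset_index()
            tables["trait_modes_overall"] = summ["overall"]
            tables["trait_consistency"] = summ["per_variable"]
            record("inheritance", ["trait_calls", "trait_modes_per_cross",
                                   "trait_modes_overall", "trait_consistency"])

        if "maternal" in stages:
            current = "maternal"
            tables["maternal"] = maternal_scan(
                tm, design, alpha=config.alpha,
                calls=tables.get("trait_calls"))
            record("maternal", ["maternal"])

        ne = None
        if "deg" in stages:
            current = "deg"
            if cm is None:
                raise ValueError("count matrix required")
            kept, filt = filter_low_expression(cm, config.min_cpm,
                                               config.min_cpm_samples)
            ne = normalize(kept)
            ne.filter_report = filt
            deg = deg_scan(ne, tm.sample_meta, design, fdr=config.fdr)
            tables["deg"] = deg["table"]
            tables["deg_per_gene"] = deg["per_gene"]
            tables["deg_reciprocal"] = deg["reciprocal"]
            gene_calls = classify_all(ne.logcpm.T, tm.sample_meta, design,
                                      alpha=config.alpha)
            tables["gene_calls"] = gene_calls
            gsumm = summarize_modes(gene_calls)
            tables["gene_modes_overall"] = gsumm["overall"]
            tables["gene_modes_per_cross"] = gsumm["per_cross"].reset_index()
            record("deg", ["deg", "deg_per_gene", "deg_reciprocal",
                           "gene_calls", "gene_modes_overall",
                           "gene_modes_per_cross"])

        ms = None
        if "modules" in stages:
            current = "modules"
            from .coexpression import build_modules, module_trait_correlations

            de_genes = tables["deg_per_gene"]
            de_list = de_genes.loc[de_genes["de_any"], "gene"].tolist()
            ms = build_modules(ne, genes=de_list, beta=config.beta,
                               min_module_size=config.min_module_size,
                               cut_height=config.cut_height)
            tables["module_assignment"] = ms.assignment.rename("module") \
                .reset_index().rename(columns={"index": "gene"})
            tables["eigengenes"] = ms.eigengenes.reset_index() \
                .rename(columns={"index": "sample"})
            tables["module_trait"] = module_trait_correlations(
                ms, tm, alpha=config.alpha)
            if config.annotation:
                from .coexpression import enrich

                amap = read_annotation(config.annotation,
                                       universe=list(ms.assignment.index))
                tables["enrichment"] = enrich(ms, amap)
                record("modules", ["module_assignment", "eigengenes",
                                   "module_trait", "enrichment"])
            else:
                record("modules", ["module_assignment", "eigengenes",
                                   "module_trait"])

        if "concordance" in stages:
            current = "concordance"
            from .coexpression import candidate_genes, gene_trait_concordance

            cand = candidate_genes(ms, ne, tm, tables["module_trait"])
            tables["candidates"] = cand
            rows = []
            for _, r in cand.iterrows():
                rep = gene_trait_concordance(
                    tables["gene_calls"], tables["trait_calls"],
                    ne, tm, r["gene"], r["trait"])
                rows.append({"gene": rep["gene"], "trait": rep["trait"],
                             "pattern": rep["pattern"], "slope": rep["slope"],
                             "r2": rep["r2"], "p": rep["p"]})
            tables["concordance"] = pd.DataFrame(
                rows, columns=["gene", "trait", "pattern", "slope", "r2", "p"])
            record("concordance", ["candidates", "concordance"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    hashes = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        hashes[f"{name}.tsv"] = _sha256(path)
    manifest["output_hashes"] = hashes
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"tables": tables, "manifest": manifest}


# ---------------------------------------------------------------------------
# Study-style report (summary quantities over a full run)
# ---------------------------------------------------------------------------

def study_report(
    design: FactorialDesign,
    tm: TraitMatrix,
    trait_calls: pd.DataFrame,
    heritability: pd.DataFrame,
    maternal: pd.DataFrame,
    gene_calls: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Headline quantities of a factorial-design inheritance analysis.

    Computes, from already-fitted tables: the fraction of (cross, trait)
    cases per mode; counts of traits without a genotype effect and with
    h2 > 0.4; the modal-mode consistency of each trait; the number of
    variables with significant reciprocal differences; the fraction of
    transgressive traits; and (when expression calls are given) the
    mode-frequency vector of gene expression.
    """
    summ = summarize_modes(trait_calls)
    overall = summ["overall"].iloc[0]
    per_var = summ["per_variable"]

    n_no_geno = int((heritability["genotype_p"] >= alpha).sum())
    n_h2_gt_04 = int((heritability["h2"] > 0.4).sum())

    recip_sig = maternal[maternal["significant"]] if len(maternal) else maternal
    n_recip_vars = int(recip_sig["variable"].nunique()) if len(maternal) else 0

    report = {
        "n_genotypes": len(design.genotypes),
        "n_crosses": len(design.crosses),
        "n_reciprocal_pairs": len(design.reciprocal_pairs),
        "n_traits": len(tm.traits),
        "trait_mode_fractions": {m: float(overall[f"frac_{m}"])
                                 for m in ["ns", "OR", "R", "A", "D", "OD"]},
        "n_traits_no_genotype_effect": n_no_geno,
        "n_traits_h2_above_0.4": n_h2_gt_04,
        "h2_min": float(heritability["h2"].min()),
        "h2_max": float(heritability["h2"].max()),
        "n_variables_reciprocal_difference": n_recip_vars,
        "frac_traits_transgressive": float(per_var["transgressive"].mean()),
        "frac_transgressive_single_type": float(
            per_var.loc[per_var["transgressive"], "single_type"].mean())
        if per_var["transgressive"].any() else float("nan"),
    }
    if gene_calls is not None:
        gsumm = summarize_modes(gene_calls)
        g_overall = gsumm["overall"].iloc[0]
        report["gene_mode_fractions"] = {
            m: float(g_overall[f"frac_{m}"])
            for m in ["ns", "OR", "R", "A", "D", "OD"]}
    return report
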