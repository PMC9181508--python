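"""Data model and I/O for factorial cross designs and their data matrices.

A factorial design here is a set of inbred parental lines and F1 hybrids,
each hybrid recorded with its female and male parent.  Reciprocal hybrids
(same parents, swapped cross direction) are detected automatically and kept
as explicit pairs because cross-direction (maternal) effects are part of the
analysis.  Trait and count matrices are plain tab-separated files; sample
metadata (genotype, harvest/replicate) lives in the design file, never in
column-name encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("inherimet")


class DesignError(ValueError):
    """Raised when a design file or matrix violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cross:
    hybrid: str
    female: str
    male: str

    @property
    def parents(self) -> frozenset[str]:
        return frozenset((self.female, self.male))


@dataclass
class FactorialDesign:
    """Parental lines, crosses and reciprocal structure of a mating design.

    Parameters
    ----------
    lines
        Mapping of parental genotype ID to a free-text species class label
        (e.g. ``SP``, ``SLC``, ``SL``).
    crosses
        One entry per F1 hybrid, with its female and male parent.
    """

    lines: dict[str, str]
    crosses: list[Cross]
    reciprocal_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()
        if not self.reciprocal_pairs:
            self.reciprocal_pairs = self._detect_reciprocals()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        hybrids = [c.hybrid for c in self.crosses]
        if len(set(hybrids)) != len(hybrids):
            dup = sorted({h for h in hybrids if hybrids.count(h) > 1})
            raise DesignError(f"duplicate hybrid IDs: {dup}")
        clash = set(hybrids) & set(self.lines)
        if clash:
            raise DesignError(f"IDs declared both parent and hybrid: {sorted(clash)}")
        for c in self.crosses:
            for p in (c.female, c.male):
                if p not in self.lines:
                    raise DesignError(
                        f"cross {c.hybrid!r} references undeclared parent {p!r}"
                    )
        by_id = {c.hybrid: c for c in self.crosses}
        for a, b in self.reciprocal_pairs:
            if a not in by_id or b not in by_id:
                raise DesignError(f"reciprocal pair ({a}, {b}) references unknown hybrid")
            ca, cb = by_id[a], by_id[b]
            if not (ca.female == cb.male and ca.male == cb.female):
                raise DesignError(
                    f"reciprocal pair ({a}, {b}) parents are not exactly swapped"
                )

    def _detect_reciprocals(self) -> list[tuple[str, str]]:
        pairs: list[tuple[str, str]] = []
        seen: dict[tuple[str, str], str] = {}
        for c in self.crosses:
            key = (c.male, c.female)
            if key in seen:
                pairs.append((seen[key], c.hybrid))
            else:
                seen[(c.female, c.male)] = c.hybrid
        return pairs

    # -- convenience -------------------------------------------------------
    @property
    def genotypes(self) -> list[str]:
        return list(self.lines) + [c.hybrid for c in self.crosses]

    def cross(self, hybrid: str) -> Cross:
        for c in self.crosses:
            if c.hybrid == hybrid:
                return c
        raise KeyError(hybrid)


@dataclass
class TraitMatrix:
    """Replicate-level trait values plus per-sample genotype/harvest labels.

    ``values`` is samples x traits (float, NaN = missing); ``sample_meta``
    has columns ``genotype`` and ``harvest`` indexed like ``values``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.values.index]

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def genotype_values(self, genotype: str, trait: str) -> np.ndarray:
        mask = self.sample_meta["genotype"] == genotype
        v = self.values.loc[mask, trait].to_numpy(dtype=float)
        return v[~np.isnan(v)]

    def validate_against(self, design: FactorialDesign) -> None:
        known = set(design.genotypes)
        bad = set(self.sample_meta["genotype"]) - known
        if bad:
            raise DesignError(f"samples reference genotypes absent from design: {sorted(bad)}")
        counts = self.sample_meta["genotype"].value_counts()
        empty = [g for g in known if counts.get(g, 0) == 0]
        if empty:
            raise DesignError(f"genotypes with zero samples: {sorted(empty)}")


@dataclass
class CountMatrix:
    """Gene x sample matrix of raw non-negative integer read counts."""

    counts: pd.DataFrame  # genes x samples, int

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise DesignError("count matrix contains negative values")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise DesignError("count matrix contains fractional values")
            self.counts = self.counts.astype(np.int64)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class AnnotationMap:
    """Flat term -> gene-set map (a generic stand-in for GO annotation)."""

    terms: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def restrict(self, universe: Iterable[str]) -> "AnnotationMap":
        uni = set(universe)
        return AnnotationMap(
            {t: g & uni for t, g in self.terms.items() if g & uni},
            dict(self.labels),
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = ["genotype", "role", "female_parent", "male_parent", "species_class"]


def read_design(path: str | Path) -> FactorialDesign:
    """Read a factorial design from a tab-separated file.

    Expected columns: genotype, role (``parent`` | ``hybrid``),
    female_parent, male_parent, species_class.  Parent rows leave the parent
    columns empty.  Reciprocal pairs are detected from swapped parent
    columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in DESIGN_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise DesignError(f"design file missing columns: {missing}")
    if df["genotype"].duplicated().any():
        dup = df.loc[df["genotype"].duplicated(), "genotype"].tolist()
        raise DesignError(f"duplicate genotype IDs in design file: {dup}")
    lines: dict[str, str] = {}
    crosses: list[Cross] = []
    for i, row in df.iterrows():
        role = row["role"].strip().lower()
        if role == "parent":
            lines[row["genotype"]] = row.get("species_class", "")
        elif role == "hybrid":
            crosses.append(Cross(row["genotype"], row["female_parent"], row["male_parent"]))
        else:
            raise DesignError(f"row {i}: unknown role {row['role']!r}")
    try:
        return FactorialDesign(lines, crosses)
    except DesignError:
        # re-raise with the offending row located
        for i, row in df.iterrows():
            if row["role"].strip().lower() == "hybrid":
                for p in (row["female_parent"], row["male_parent"]):
                    if p not in lines:
                        raise DesignError(
                            f"row {i} (hybrid {row['genotype']!r}): "
                            f"undeclared parent {p!r}"
                        ) from None
        raise


def write_design(design: FactorialDesign, path: str | Path) -> None:
    rows = [
        {"genotype": g, "role": "parent", "female_parent": "", "male_parent": "",
         "species_class": cls}
        for g, cls in design.lines.items()
    ]
    rows += [
        {"genotype": c.hybrid, "role": "hybrid", "female_parent": c.female,
         "male_parent": c.male, "species_class": ""}
        for c in design.crosses
    ]
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_trait_matrix(
    path: str | Path,
    design: FactorialDesign,
    meta_path: str | Path | None = None,
) -> TraitMatrix:
    """Read a samples x traits TSV plus its sample-metadata sidecar.

    The sidecar (``meta_path``, default ``<path>`` with suffix
    ``.samples.tsv``) has columns sample, genotype, harvest.  Missing values
    are permitted; all-missing trait columns are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise DesignError(f"duplicated sample IDs: {dup}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            sample = df.index[bad][0]
            raise DesignError(f"non-numeric cell at sample {sample!r}, trait {col!r}")
    df = df.astype(float)
    if meta_path is None:
        meta_path = Path(path).with_suffix(".samples.tsv")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    df.index = df.index.astype(str)
    meta = meta.loc[df.index]
    all_missing = [c for c in df.columns if df[c].isna().all()]
    if all_missing:
        logger.warning("dropping all-missing trait columns: %s", all_missing)
        df = df.drop(columns=all_missing)
    tm = TraitMatrix(df, meta[["genotype", "harvest"]])
    tm.validate_against(design)
    return tm


def write_trait_matrix(tm: TraitMatrix, path: str | Path,
                       meta_path: str | Path | None = None) -> None:
    tm.values.to_csv(path, sep="\t", index_label="sample", float_format="%.10g")
    if meta_path is None:
        meta_path = Path(path).with_suffix(".samples.tsv")
    tm.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_count_matrix(path: str | Path, design: FactorialDesign,
                      trait_samples: Iterable[str] | None = None) -> CountMatrix:
    """Read a genes x samples TSV of raw counts, realigned by sample ID."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if (arr < 0).any():
        raise DesignError("negative count in count matrix")
    if not np.allclose(arr, np.round(arr)):
        raise DesignError("fractional count in count matrix")
    df = df.astype(np.int64)
    if trait_samples is not None:
        order = [s for s in trait_samples if s in df.columns]
        extra = set(df.columns) - set(order)
        if extra:
            raise DesignError(f"count samples absent from trait matrix: {sorted(extra)}")
        df = df[order]
    return CountMatrix(df)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")


def read_annotation(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationMap:
    """Read a two-column (term, gene) TSV into an AnnotationMap."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], dtype=str,
                     comment="#")
    terms: dict[str, set[str]] = {}
    for t, g in zip(df["term"], df["gene"]):
        terms.setdefault(t, set()).add(g)
    amap = AnnotationMap(terms)
    if universe is not None:
        uni = set(universe)
        stray = {g for gs in terms.values() for g in gs} - uni
        if stray:
            logger.warning("%d annotated genes outside the declared universe", len(stray))
        amap = amap.restrict(uni)
    return amap


# ---------------------------------------------------------------------------
# The study template design
# ---------------------------------------------------------------------------

def study_design() -> FactorialDesign:
    """The 6-parent / 14-hybrid factorial template used throughout.

    Two wild small-fruited lines (SP1, SP2), three cherry lines (SLC1-3) and
    one big-fruited line (SL); 14 F1s of which five pairs are reciprocal
    (SP1xSP2, SLxSP1, SLxSP2, SLxSLC2, SLxSLC3 crossed both ways).
    """
    lines = {"SP1": "SP", "SP2": "SP", "SLC1": "SLC", "SLC2": "SLC",
             "SLC3": "SLC", "SL": "SL"}
    pairs = [("SP1", "SP2"), ("SL", "SP1"), ("SL", "SP2"),
             ("SL", "SLC2"), ("SL", "SLC3")]
    crosses = []
    for f, m in pairs:
        crosses.append(Cross(f"{f}x{m}", f, m))
        crosses.append(Cross(f"{m}x{f}", m, f))
    for f, m in [("SLC1", "SLC2"), ("SLC1", "SLC3"), ("SLC3", "SP1"), ("SLC2", "SP2")]:
        crosses.append(Cross(f"{f}x{m}", f, m))
    return FactorialDesign(lines, crosses)
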