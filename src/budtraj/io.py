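"""Tabular input/output and sample-design validation.

All on-disk formats are tab-delimited UTF-8 text; lines starting with ``#``
are comments.  The sample design (cultivar, dormancy stage, replicate,
chilling-requirement group) travels with the expression matrix so every
downstream operation can group samples without re-reading metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CR_GROUPS = ("Low", "High")

#: Fixed functional-class vocabulary used for candidate plausibility gating.
FUNCTIONAL_CLASSES = (
    "TF",
    "kinase-related",
    "hormone-associated",
    "chromatin/RNA",
    "other",
)

#: Classes treated as regulatory-plausible when nominating candidates.
PLAUSIBLE_CLASSES = frozenset(FUNCTIONAL_CLASSES[:-1])

HORMONES = ("ABA", "GA3", "GA7")

DESIGN_COLUMNS = ("sample_id", "cultivar", "stage", "replicate", "cr_group")


class TableFormatError(ValueError):
    """A tabular input violates its contract (missing column, bad value...)."""


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", **kwargs)
    if df.empty:
        raise TableFormatError(f"{path}: empty table")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, header_comments: Iterable[str] = (),
              index: bool = False, float_format: str = "%.6f") -> None:
    """Write a TSV with optional ``#`` comment lines prepended."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample-design table.

    Requires columns ``sample_id, cultivar, stage, replicate, cr_group``;
    enforces unique sample ids, a single CR group per cultivar, and at least
    one replicate per (cultivar, stage) cell.  Stage becomes an ordered
    categorical whose order is the order of first appearance.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise TableFormatError(f"design missing columns: {missing}")
    design = design.loc[:, list(DESIGN_COLUMNS)].copy()
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableFormatError(f"duplicate sample id: {dup!r}")
    bad_group = set(design["cr_group"]) - set(CR_GROUPS)
    if bad_group:
        raise TableFormatError(
            f"unknown cr_group values {sorted(bad_group)}; allowed: {CR_GROUPS}")
    groups_per_cultivar = design.groupby("cultivar")["cr_group"].nunique()
    if (groups_per_cultivar > 1).any():
        offender = groups_per_cultivar[groups_per_cultivar > 1].index[0]
        raise TableFormatError(
            f"cultivar {offender!r} is mapped to more than one cr_group")
    stage_order = list(dict.fromkeys(design["stage"]))
    if len(stage_order) < 2:
        raise TableFormatError("design must contain at least 2 stages")
    design["stage"] = pd.Categorical(design["stage"], categories=stage_order,
                                     ordered=True)
    design["replicate"] = design["replicate"].astype(int)
    if (design["replicate"] < 1).any():
        raise TableFormatError("replicate indices must be positive integers")
    cells = design.groupby(["cultivar", "stage"], observed=False).size()
    empty = cells[cells == 0]
    if len(empty):
        raise TableFormatError(f"empty (cultivar, stage) cells: {list(empty.index)}")
    return design.reset_index(drop=True)


def read_sample_table(path: str | Path,
                      expected_stages: Iterable[str] | None = None) -> pd.DataFrame:
    """Read and validate the sample metadata TSV.

    Stage labels are free strings ordered by first appearance; pass
    ``expected_stages`` to additionally reject labels outside a declared
    vocabulary.
    """
    design = validate_design(_read_tsv(path, dtype={"sample_id": str,
                                                    "cultivar": str,
                                                    "stage": str,
                                                    "cr_group": str}))
    if expected_stages is not None:
        unknown = set(design["stage"].cat.categories) - set(expected_stages)
        if unknown:
            raise TableFormatError(
                f"unknown stage labels {sorted(unknown)}; "
                f"expected {sorted(expected_stages)}")
    return design


def stages_of(design: pd.DataFrame) -> list[str]:
    return list(design["stage"].cat.categories)


def cultivars_of(design: pd.DataFrame) -> list[str]:
    return list(dict.fromkeys(design["cultivar"]))


def cr_group_of_cultivar(design: pd.DataFrame) -> pd.Series:
    """Map cultivar -> CR group (validated upstream to be single-valued)."""
    return design.drop_duplicates("cultivar").set_index("cultivar")["cr_group"]


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with the sample design attached.

    ``values`` columns are ordered exactly like ``design['sample_id']``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.design = validate_design(self.design)
        if list(self.values.columns) != list(self.design["sample_id"]):
            try:
                self.values = self.values.loc[:, list(self.design["sample_id"])]
            except KeyError as exc:
                raise TableFormatError(
                    f"expression matrix is missing design samples: {exc}") from exc
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise TableFormatError(f"duplicate gene id: {dup!r}")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise TableFormatError("expression values must be numeric")
        if np.isnan(vals).any():
            gene = self.values.index[np.isnan(vals).any(axis=1)][0]
            raise TableFormatError(f"non-numeric/missing value for gene {gene!r}")
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise TableFormatError(
                f"negative TPM for gene {self.values.index[bad[0]]!r} in sample "
                f"{self.values.columns[bad[1]]!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.design)


def read_expression(path: str | Path, design: pd.DataFrame) -> ExpressionMatrix:
    """Read a gene x sample TPM TSV and attach the design.

    The first column holds gene ids; remaining columns must cover every
    design sample (extra columns are dropped); columns are reordered to the
    design order.
    """
    df = _read_tsv(path, index_col=0)
    missing = [s for s in design["sample_id"] if s not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing samples {missing}")
    df = df.loc[:, list(design["sample_id"])]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            gene = df.index[coerced.isna()][0]
            raise TableFormatError(
                f"{path}: non-numeric value for gene {gene!r}, sample {col!r}")
        df[col] = coerced.astype(float)
    return ExpressionMatrix(df, design)


def write_expression(em: ExpressionMatrix, path: str | Path,
                     header_comments: Iterable[str] = ()) -> None:
    df = em.values.copy()
    df.index.name = "gene"
    write_tsv(df, path, header_comments, index=True)


# ---------------------------------------------------------------------------
# hormones
# ---------------------------------------------------------------------------

def validate_hormones(hormones: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Validate the long-format hormone table (sample_id, hormone, value)."""
    for col in ("sample_id", "hormone", "value"):
        if col not in hormones.columns:
            raise TableFormatError(f"hormone table missing column {col!r}")
    unknown = set(hormones["sample_id"]) - set(design["sample_id"])
    if unknown:
        raise TableFormatError(f"hormone samples not in design: {sorted(unknown)[:5]}")
    bad = set(hormones["hormone"]) - set(HORMONES)
    if bad:
        raise TableFormatError(f"unknown hormones {sorted(bad)}; allowed: {HORMONES}")
    hormones = hormones.copy()
    hormones["value"] = pd.to_numeric(hormones["value"])
    if (hormones["value"] <= 0).any():
        raise TableFormatError("hormone concentrations must be positive (ng/g)")
    return hormones.reset_index(drop=True)


def read_hormones(path: str | Path, design: pd.DataFrame) -> pd.DataFrame:
    return validate_hormones(_read_tsv(path, dtype={"sample_id": str, "hormone": str}),
                             design)


def hormones_wide(hormones: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long hormone table to sample x hormone, in design order."""
    wide = hormones.pivot(index="sample_id", columns="hormone", values="value")
    return wide.loc[list(design["sample_id"])]


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Gene -> term assignments plus gene -> functional class labels.

    ``gene_terms`` is long format with columns ``gene, term, layer`` (layer
    groups terms for separate FDR control, e.g. GO vs KEGG).  Genes with no
    class row default to ``"other"``.
    """

    gene_terms: pd.DataFrame
    term_descriptions: Mapping[str, str] = field(default_factory=dict)
    classes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        for col in ("gene", "term"):
            if col not in self.gene_terms.columns:
                raise TableFormatError(f"annotation table missing column {col!r}")
        if "layer" not in self.gene_terms.columns:
            self.gene_terms = self.gene_terms.assign(layer="terms")
        if (self.gene_terms["term"].astype(str).str.len() == 0).any():
            raise TableFormatError("empty term id in annotation table")
        bad = set(self.classes.unique()) - set(FUNCTIONAL_CLASSES)
        if bad:
            raise TableFormatError(
                f"unknown functional classes {sorted(bad)}; "
                f"allowed vocabulary: {FUNCTIONAL_CLASSES}")

    @property
    def terms(self) -> pd.Index:
        return pd.Index(sorted(self.gene_terms["term"].unique()))

    def genes_for(self, term: str) -> set[str]:
        sub = self.gene_terms[self.gene_terms["term"] == term]
        return set(sub["gene"])

    def terms_for(self, gene: str) -> set[str]:
        sub = self.gene_terms[self.gene_terms["gene"] == gene]
        return set(sub["term"])

    def class_of(self, genes: Iterable[str]) -> pd.Series:
        """Functional class per gene, defaulting to ``other``."""
        genes = pd.Index(genes)
        return self.classes.reindex(genes).fillna("other")


def read_annotation_table(terms_path: str | Path,
                          classes_path: str | Path | None = None) -> AnnotationTable:
    """Read gene->term pairs (and optionally gene->class rows)."""
    terms = _read_tsv(terms_path, dtype=str)
    classes = pd.Series(dtype=object)
    if classes_path is not None:
        cls = _read_tsv(classes_path, dtype=str)
        for col in ("gene", "class"):
            if col not in cls.columns:
                raise TableFormatError(f"{classes_path}: missing column {col!r}")
        classes = cls.set_index("gene")["class"]
    return AnnotationTable(terms, classes=classes)


def write_annotation_table(ann: AnnotationTable, terms_path: str | Path,
                           classes_path: str | Path) -> None:
    write_tsv(ann.gene_terms, terms_path)
    cls = ann.classes.rename("class").rename_axis("gene").reset_index()
    write_tsv(cls, classes_path)
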