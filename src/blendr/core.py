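"""The cell-type index algorithm.

Given a normalized, log2-scale expression matrix (transcripts x samples),
each transcript row is z-scored across samples so that highly variable
transcripts cannot dominate; transcripts mapping to the same gene symbol are
averaged per sample and re-z-scored; and each publication-specific signature
set is summarized per sample as the mean z-value of its matched genes. The
resulting publication-specific indices are finally averaged within each
primary cell-type category — after discarding genes claimed by more than one
category — to give one consolidated index per category.

An index is a *relative* quantity: it says whether a sample carries more or
less expression specific to a cell type than the other samples in the same
dataset, not an absolute cell proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from blendr.celltype_db import CATEGORIES, MarkerDatabase, signature_sets_for
from blendr.errors import InputError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, rows = transcripts/probes, columns = samples.

    ``gene_symbols`` maps row ids to gene symbols (may be None before
    annotation; required for gene collapse). Row ids must be unique.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()][:5]
            raise ValidationError(f"duplicate row ids in expression matrix: {list(dupes)}")
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CellTypeIndexTable:
    """Per-sample cell-type indices (z-units, mean 0 across samples).

    ``publication`` is samples x publication-tag; ``consolidated`` is
    samples x primary-category (at most the 10 categories, in vocabulary
    order). ``coverage`` counts how many database genes each tag matched in
    the input.
    """

    publication: pd.DataFrame
    consolidated: pd.DataFrame
    coverage: dict[str, int] = field(default_factory=dict)


def _drop_nonfinite(values: pd.DataFrame, policy: str) -> pd.DataFrame:
    if policy not in ("drop", "impute"):
        raise ValueError(f"missing_policy must be 'drop' or 'impute', got {policy!r}")
    mask = ~np.isfinite(values.to_numpy(dtype=float))
    if not mask.any():
        return values
    if policy == "drop":
        keep = ~mask.any(axis=1)
        logger.info("dropping %d rows with missing values", int((~keep).sum()))
        return values.loc[keep]
    arr = values.to_numpy(dtype=float).copy()
    arr[mask] = np.nan
    row_means = np.nanmean(arr, axis=1, keepdims=True)
    arr = np.where(np.isnan(arr), row_means, arr)
    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return out.loc[np.isfinite(arr).all(axis=1)]


def zscore_rows(matrix: ExpressionMatrix, missing_policy: str = "drop") -> ExpressionMatrix:
    """Center and scale each row across samples (mean 0, sd 1, n-1 denominator).

    Zero-variance rows carry no relative information and are dropped with a
    logged count. Fewer than two samples is an error; so is losing every row.
    """
    if matrix.n_samples < 2:
        raise InputError(f"need >=2 samples to z-score, got {matrix.n_samples}")
    values = _drop_nonfinite(matrix.values.astype(float), missing_policy)
    arr = values.to_numpy()
    sd = arr.std(axis=1, ddof=1)
    # sd below float noise for the row's magnitude counts as zero variance
    tol = 1e-12 * np.maximum(1.0, np.abs(arr).max(axis=1))
    keep = sd > tol
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance rows before z-scoring", n_dropped)
    if not keep.any():
        raise InputError("every row has zero variance; nothing to z-score")
    arr = arr[keep]
    # reuse the sd the filter saw: recomputing can flip a ~1e-16 sd to 0
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[keep, None]
    out = pd.DataFrame(z, index=values.index[keep], columns=values.columns)
    genes = None if matrix.gene_symbols is None else matrix.gene_symbols.loc[out.index]
    return ExpressionMatrix(values=out, gene_symbols=genes)


def collapse_to_genes(zmatrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average transcripts of the same gene per sample, then re-z-score.

    Rows without a gene annotation are dropped (all-unannotated is an
    error). Genes whose averaged row has zero variance are dropped with a
    logged count.
    """
    if zmatrix.gene_symbols is None:
        raise InputError("collapse_to_genes requires a row -> gene_symbol annotation")
    symbols = zmatrix.gene_symbols.astype("string").str.strip().str.upper()
    annotated = symbols.notna() & (symbols != "")
    if not annotated.any():
        raise InputError("no row has a gene annotation")
    n_unannotated = int((~annotated).sum())
    if n_unannotated:
        logger.info("dropping %d rows without gene annotation", n_unannotated)
    values = zmatrix.values.loc[annotated.to_numpy()]
    by_gene = values.groupby(symbols[annotated].to_numpy()).mean()
    arr = by_gene.to_numpy()
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(arr).max(axis=1))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d genes with zero variance after averaging", n_dropped)
    if not keep.any():
        raise InputError("every gene-averaged row has zero variance")
    arr = arr[keep]
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[keep, None]
    out = pd.DataFrame(z, index=by_gene.index[keep], columns=by_gene.columns)
    return ExpressionMatrix(values=out, gene_symbols=pd.Series(out.index, index=out.index))


def publication_indices(
    genematrix: ExpressionMatrix,
    sets: Mapping[str, Iterable[str]],
    min_genes: int = 3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Average gene-level z-values over each signature set, per sample.

    Returns (samples x tag DataFrame, coverage dict tag -> matched genes).
    Tags matching fewer than ``min_genes`` genes are omitted with a warning
    (hard floor: 1 gene). Tag columns are sorted alphabetically.
    """
    if not sets:
        raise InputError("no signature sets supplied")
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    available = {str(g).upper() for g in genematrix.values.index}
    columns: dict[str, np.ndarray] = {}
    coverage: dict[str, int] = {}
    for tag in sorted(sets):
        genes = sorted({str(g).upper() for g in sets[tag]} & available)
        coverage[tag] = len(genes)
        if len(genes) < min_genes:
            logger.warning(
                "signature %s matched %d gene(s) (< min_genes=%d); omitted",
                tag,
                len(genes),
                min_genes,
            )
            continue
        columns[tag] = genematrix.values.loc[genes].to_numpy().mean(axis=0)
    if not columns:
        raise InputError("no signature set matched enough genes in the input")
    table = pd.DataFrame(columns, index=genematrix.values.columns)
    return table, coverage


def consolidate(
    genematrix: ExpressionMatrix,
    db: MarkerDatabase,
    excluded_tags: Iterable[str] = (),
    min_genes: int = 3,
    remove_cross_category: bool = True,
) -> pd.DataFrame:
    """Category-level indices: publication indices averaged within category.

    Publication indices are recomputed on signature sets with cross-category
    overlap genes removed (unless ``remove_cross_category=False``), then the
    resulting index columns are averaged within each primary category.
    Columns follow the category vocabulary order; categories with no
    surviving publication set are absent with a warning.
    """
    sets = signature_sets_for(db, excluded_tags)
    if remove_cross_category:
        overlap = db.overlap_genes
        sets = {t: frozenset(s) - overlap for t, s in sets.items()}
        sets = {t: s for t, s in sets.items() if s}
    pub, _ = publication_indices(genematrix, sets, min_genes=min_genes)
    out: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        tags = [t for t in pub.columns if db.category_of[t] == cat]
        if not tags:
            if any(db.category_of[t] == cat for t in db.signature_sets):
                logger.warning("no surviving signature set for category %s", cat)
            continue
        out[cat] = pub[tags].to_numpy().mean(axis=1)
    return pd.DataFrame(out, index=pub.index)


def compute_indices(
    matrix: ExpressionMatrix,
    db: MarkerDatabase,
    excluded_tags: Iterable[str] = (),
    min_genes: int = 3,
    missing_policy: str = "drop",
    remove_cross_category: bool = True,
) -> CellTypeIndexTable:
    """End-to-end index computation.

    z-score transcript rows -> collapse to genes -> publication indices on
    the full signature sets -> consolidated category indices with
    cross-category genes removed. Deterministic; publication columns are
    alphabetical, consolidated columns follow the category vocabulary.
    """
    z = zscore_rows(matrix, missing_policy=missing_policy)
    genes = collapse_to_genes(z)
    sets = signature_sets_for(db, excluded_tags)
    pub, coverage = publication_indices(genes, sets, min_genes=min_genes)
    cons = consolidate(
        genes,
        db,
        excluded_tags=excluded_tags,
        min_genes=min_genes,
        remove_cross_category=remove_cross_category,
    )
    return CellTypeIndexTable(publication=pub, consolidated=cons, coverage=coverage)
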