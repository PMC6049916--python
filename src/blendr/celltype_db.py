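"""Curated database of cell-type-specific marker transcripts.

The database has one row per (gene, cell-type, source-publication) claim:
the same gene may be listed by several reference publications, and a gene
claimed by two publications under *different* primary cell-type categories
is flagged as a cross-category overlap (such genes are excluded when
publication-specific indices are consolidated into category-level indices).

Ten primary cortical cell-type categories are supported: astrocytes,
endothelial cells, mural cells (pericytes/smooth muscle), microglia, mature
and immature oligodendrocytes, three neuron groupings (unsorted, interneuron,
projection), and erythrocytes (RBC, a proxy for blood content).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from blendr.errors import ConfigurationError, InputError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Closed vocabulary of primary cell-type categories, in canonical order.
CATEGORIES: tuple[str, ...] = (
    "Astrocyte",
    "Endothelial",
    "Mural",
    "Microglia",
    "Oligodendrocyte",
    "Oligodendrocyte_Immature",
    "Neuron_All",
    "Neuron_Interneuron",
    "Neuron_Projection",
    "RBC",
)

REQUIRED_COLUMNS = ("gene_symbol", "primary_category", "publication_tag")
OPTIONAL_COLUMNS = ("species", "brain_region", "platform", "citation")


@dataclass(frozen=True)
class MarkerEntry:
    """One cell-type-specificity claim: a gene, a category, a source study."""

    gene_symbol: str
    primary_category: str
    publication_tag: str
    species: str = ""
    brain_region: str = ""
    platform: str = ""
    citation: str = ""

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValidationError("gene_symbol must be non-empty")
        if not self.publication_tag:
            raise ValidationError("publication_tag must be non-empty")
        if self.primary_category not in CATEGORIES:
            raise ValidationError(
                f"unknown primary_category {self.primary_category!r}; "
                f"expected one of {CATEGORIES}"
            )


@dataclass
class MarkerDatabase:
    """All marker entries plus the derived signature sets.

    ``signature_sets`` maps each publication tag to the unique gene symbols
    it claims; ``category_of`` maps each tag to its primary category;
    ``overlap_genes`` holds genes claimed under more than one category.
    """

    entries: list[MarkerEntry]
    signature_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    category_of: dict[str, str] = field(default_factory=dict)
    overlap_genes: frozenset[str] = frozenset()

    @classmethod
    def from_entries(cls, entries: Iterable[MarkerEntry]) -> "MarkerDatabase":
        entries = list(entries)
        if not entries:
            raise InputError("marker database has no entries")
        sets: dict[str, set[str]] = {}
        category_of: dict[str, str] = {}
        gene_categories: dict[str, set[str]] = {}
        for e in entries:
            sets.setdefault(e.publication_tag, set()).add(e.gene_symbol)
            prev = category_of.setdefault(e.publication_tag, e.primary_category)
            if prev != e.primary_category:
                raise ValidationError(
                    f"publication tag {e.publication_tag!r} appears under two "
                    f"categories: {prev!r} and {e.primary_category!r}"
                )
            gene_categories.setdefault(e.gene_symbol, set()).add(e.primary_category)
        overlap = frozenset(g for g, cats in gene_categories.items() if len(cats) > 1)
        return cls(
            entries=entries,
            signature_sets={t: frozenset(s) for t, s in sets.items()},
            category_of=category_of,
            overlap_genes=overlap,
        )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(e.gene_symbol for e in self.entries)

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(sorted(self.signature_sets))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_symbol": e.gene_symbol,
                    "primary_category": e.primary_category,
                    "publication_tag": e.publication_tag,
                    "species": e.species,
                    "brain_region": e.brain_region,
                    "platform": e.platform,
                    "citation": e.citation,
                }
                for e in self.entries
            ]
        )


def _sniff_sep(path: Path, dialect: str | None) -> str:
    if dialect in ("csv", "tsv"):
        return "," if dialect == "csv" else "\t"
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def load_database(path: str | Path, dialect: str | None = None) -> MarkerDatabase:
    """Load a marker-gene table (CSV/TSV, header row) into a MarkerDatabase.

    Gene symbols are uppercased at load so matching downstream is
    case-insensitive; exact duplicate (gene, category, tag) rows are dropped
    with a logged count. Extra columns are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"marker database file not found: {path}")
    sep = _sniff_sep(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"marker database file is empty: {path}") from None
    if df.empty:
        raise InputError(f"marker database has a header but no rows: {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"marker database {path} is missing required column(s): {missing}; "
            f"found {list(df.columns)}"
        )
    df = df.fillna("")
    df["gene_symbol"] = df["gene_symbol"].str.strip().str.upper()
    df["primary_category"] = df["primary_category"].str.strip()
    df["publication_tag"] = df["publication_tag"].str.strip()

    bad = ~df["primary_category"].isin(CATEGORIES)
    if bad.any():
        row = df.index[bad][0]
        raise ValidationError(
            f"row {row} of {path}: unknown primary_category "
            f"{df.loc[row, 'primary_category']!r} (vocabulary: {CATEGORIES})"
        )

    n_before = len(df)
    df = df.drop_duplicates(subset=list(REQUIRED_COLUMNS))
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d exact duplicate rows", n_dropped)

    entries = [
        MarkerEntry(
            gene_symbol=r["gene_symbol"],
            primary_category=r["primary_category"],
            publication_tag=r["publication_tag"],
            species=r.get("species", ""),
            brain_region=r.get("brain_region", ""),
            platform=r.get("platform", ""),
            citation=r.get("citation", ""),
        )
        for r in df.to_dict("records")
    ]
    db = MarkerDatabase.from_entries(entries)
    logger.info(
        "loaded %d marker rows, %d unique genes, %d signature sets",
        len(db.entries),
        len(db.genes),
        len(db.signature_sets),
    )
    return db


def write_database(db: MarkerDatabase, path: str | Path, dialect: str | None = None) -> None:
    """Write a MarkerDatabase back to CSV/TSV (inverse of load_database)."""
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    db.to_frame().to_csv(path, sep=sep, index=False)


def signature_sets_for(
    db: MarkerDatabase, excluded_tags: Iterable[str] = ()
) -> dict[str, frozenset[str]]:
    """Return the publication signature sets minus an exclusion profile.

    ``excluded_tags`` must all be known tags. Excluding every set is a
    configuration error; removing a whole category only triggers a warning.
    """
    excluded = set(excluded_tags)
    unknown = excluded - set(db.signature_sets)
    if unknown:
        raise ValidationError(f"excluded_tags not in database: {sorted(unknown)}")
    kept = {t: s for t, s in db.signature_sets.items() if t not in excluded}
    if not kept:
        raise ConfigurationError("exclusion profile removes every signature set")
    kept_categories = {db.category_of[t] for t in kept}
    lost = {db.category_of[t] for t in excluded} - kept_categories
    for cat in sorted(lost):
        logger.warning("exclusion removed every signature set for category %s", cat)
    return kept


def cross_category_genes(db: MarkerDatabase) -> frozenset[str]:
    """Genes claimed as cell-type specific under >= 2 distinct categories.

    A gene listed under the same category by two publications is a
    replication, not an overlap, and is not returned.
    """
    return db.overlap_genes


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    descriptions: Mapping[str, str] | None = None,
    path: str | Path = "sets.gmt",
) -> None:
    """Write gene sets in the GSEA .gmt dialect.

    One tab-separated line per set: name, description, then the genes.
    Empty sets are malformed .gmt and raise.
    """
    descriptions = descriptions or {}
    path = Path(path)
    with path.open("w", newline="") as fh:
        for name in sets:
            genes = sorted(set(sets[name]))
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty; .gmt forbids empty sets")
            if any("\t" in g or "\n" in g for g in genes):
                raise ValidationError(f"gene set {name!r} contains tab/newline in a symbol")
            fh.write("\t".join([name, descriptions.get(name, name), *genes]) + "\n")


def read_gmt(path: str | Path) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Read a .gmt file back into (sets, descriptions)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"malformed .gmt line (needs >=3 fields): {line!r}")
            name, desc, *genes = fields
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    return sets, descriptions
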