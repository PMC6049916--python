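"""Synthetic stand-in for the curated cell-type marker reference table.

The published curated database of cortical cell-type-specific transcripts
is a spreadsheet with one row per (gene, cell type, source publication)
claim: 3383 rows covering 2499 unique gene symbols, organized into 38
publication-specific signature sets over the 10 primary categories, with an
erythrocyte (RBC) set of exactly 17 hemoglobin/erythrocyte genes. That
spreadsheet is distributed separately from the article text, so this module
builds a *synthetic* table with the same structure — identical row, gene,
set, and category counts, the same schema, and a realistic amount of
within-category replication and cross-category overlap — using synthetic
gene symbols. It is a structural stand-in for tests and examples, not the
curated gene content.

The construction is fully deterministic (no RNG): marker symbols are
category-prefixed serial numbers, base rows enumerate each gene once under
one publication tag of its home category, and a fixed number of extra rows
re-list genes under a second tag (same category: replication) or a second
category (cross-category overlap).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from blendr.celltype_db import MarkerDatabase, MarkerEntry

#: Publication tags per category (38 total), patterned on the mix of
#: single-cell and purified-cell reference studies behind each category.
TAGS_PER_CATEGORY: dict[str, int] = {
    "Astrocyte": 6,
    "Endothelial": 4,
    "Mural": 2,
    "Microglia": 5,
    "Oligodendrocyte": 6,
    "Oligodendrocyte_Immature": 3,
    "Neuron_All": 4,
    "Neuron_Interneuron": 4,
    "Neuron_Projection": 3,
    "RBC": 1,
}

#: Unique genes per category (2499 total, 17 of them RBC).
GENES_PER_CATEGORY: dict[str, int] = {
    "Astrocyte": 450,
    "Endothelial": 300,
    "Mural": 120,
    "Microglia": 350,
    "Oligodendrocyte": 400,
    "Oligodendrocyte_Immature": 150,
    "Neuron_All": 300,
    "Neuron_Interneuron": 212,
    "Neuron_Projection": 200,
    "RBC": 17,
}

#: Extra same-category rows (a second publication replicating the claim).
REPLICATED_PER_CATEGORY: dict[str, int] = {
    "Astrocyte": 150,
    "Endothelial": 80,
    "Mural": 30,
    "Microglia": 120,
    "Oligodendrocyte": 150,
    "Oligodendrocyte_Immature": 40,
    "Neuron_All": 100,
    "Neuron_Interneuron": 74,
    "Neuron_Projection": 80,
    "RBC": 0,
}

#: Cross-category overlap rows: (home category, second category, count).
CROSS_CATEGORY_OVERLAPS: tuple[tuple[str, str, int], ...] = (
    ("Astrocyte", "Endothelial", 12),
    ("Oligodendrocyte", "Oligodendrocyte_Immature", 15),
    ("Neuron_Interneuron", "Neuron_All", 12),
    ("Neuron_Projection", "Neuron_All", 11),
    ("Microglia", "Endothelial", 10),
)

_PREFIX: dict[str, str] = {
    "Astrocyte": "ASTS",
    "Endothelial": "ENDS",
    "Mural": "MURS",
    "Microglia": "MICS",
    "Oligodendrocyte": "OLGS",
    "Oligodendrocyte_Immature": "OPCS",
    "Neuron_All": "NEUS",
    "Neuron_Interneuron": "INTS",
    "Neuron_Projection": "PRJS",
    "RBC": "RBCS",
}

_SPECIES_CYCLE = ("mouse", "human", "rat")
_PLATFORM_CYCLE = ("RNA-Seq", "microarray")


def build_reference_marker_table() -> pd.DataFrame:
    """Return the synthetic reference table as a DataFrame (3383 rows)."""
    rows: list[dict[str, str]] = []
    genes: dict[str, list[str]] = {}
    for cat, n in GENES_PER_CATEGORY.items():
        genes[cat] = [f"{_PREFIX[cat]}{i:04d}" for i in range(1, n + 1)]

    def add(gene: str, cat: str, tag_i: int, note: str) -> None:
        rows.append(
            {
                "gene_symbol": gene,
                "primary_category": cat,
                "publication_tag": f"{cat}_SynthRef{tag_i}",
                "species": _SPECIES_CYCLE[len(rows) % 3],
                "brain_region": "cortex",
                "platform": _PLATFORM_CYCLE[tag_i % 2],
                "citation": f"synthetic reference ({note})",
            }
        )

    for cat, pool in genes.items():
        k = TAGS_PER_CATEGORY[cat]
        for i, g in enumerate(pool):  # base row: each gene once, round-robin tag
            add(g, cat, i % k + 1, "base")
        n_rep = REPLICATED_PER_CATEGORY[cat]
        for i, g in enumerate(pool[:n_rep]):  # replication: same gene, next tag
            add(g, cat, (i + 1) % k + 1, "replication")
    for home, other, count in CROSS_CATEGORY_OVERLAPS:
        for g in genes[home][-count:]:  # overlap: same gene, second category
            add(g, other, 1, "cross-category")
    return pd.DataFrame(rows)


def reference_database() -> MarkerDatabase:
    """The synthetic reference table as a loaded MarkerDatabase."""
    df = build_reference_marker_table()
    entries = [MarkerEntry(**{k: str(v) for k, v in r.items()}) for r in df.to_dict("records")]
    return MarkerDatabase.from_entries(entries)


def write_reference_table(path: str | Path) -> None:
    """Write the synthetic reference table to CSV/TSV by extension."""
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    build_reference_marker_table().to_csv(path, sep=sep, index=False)
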