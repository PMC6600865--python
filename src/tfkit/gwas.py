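"""Joining TF catalogs and TF-target sets against GWAS-catalog records.

Two genetic-epidemiology questions are answered by simple tabulations (no
enrichment statistics — counts only):

* *Which TFs are themselves GWAS hits for a trait?*  — intersect the trait's
  mapped genes with a catalog's HGNC universe (:func:`direct_hits`).
* *Which traits are associated with the targets of a TF?* — resolve the TF's
  target set from a gene-set collection, then count the GWAS records whose
  mapped genes touch it (:func:`top_traits_of_targets`).

The catalog's ``MAPPED_GENE`` field may list several symbols with varying
delimiters; :func:`split_mapped_genes` normalizes it.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .catalog import HGNC_COLUMN, TFCatalog, hgnc_universe
from .errors import SchemaError
from .genesets import GeneSetCollection, remap_identifiers, targets_of

REQUIRED_COLUMNS = ("DISEASE_TRAIT", "MAPPED_GENE", "SNPS", "CHR_ID", "CHR_POS")

#: header spellings seen in EBI exports, normalized on load
_COLUMN_ALIASES = {"DISEASE.TRAIT": "DISEASE_TRAIT", "DISEASE/TRAIT": "DISEASE_TRAIT"}

#: multi-gene delimiters observed in EBI GWAS catalog exports
DEFAULT_DELIMITERS = ("; ", ", ", " - ")


@dataclass
class GwasCatalog:
    """GWAS-catalog records: trait, mapped gene(s), SNP id, chrom, position."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = self.records.rename(columns=_COLUMN_ALIASES)
        for col in REQUIRED_COLUMNS:
            if col not in self.records.columns:
                raise SchemaError(f"GWAS table lacks column {col!r}")
        pos = self.records["CHR_POS"]
        nonmissing = pos[pos.notna() & (pos.astype(str).str.strip() != "")]
        bad = nonmissing[~nonmissing.astype(str).str.fullmatch(r"\d+")]
        if len(bad):
            raise SchemaError(f"non-integer CHR_POS values, e.g. {bad.iloc[0]!r}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_tsv(cls, path) -> "GwasCatalog":
        return cls(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def split_mapped_genes(
    field: str, delimiters: tuple[str, ...] = DEFAULT_DELIMITERS
) -> list[str]:
    """Split a MAPPED_GENE field into individual symbols, order-preserving.

    >>> split_mapped_genes("A - B; C")
    ['A', 'B', 'C']
    """
    if field is None or (isinstance(field, float) and field != field):
        return []
    pattern = "|".join(re.escape(d) for d in delimiters)
    parts = re.split(pattern, str(field))
    return [p.strip() for p in parts if p.strip()]


def filter_by_chrom(gwas: GwasCatalog, chrom: str) -> GwasCatalog:
    """Records on one chromosome (exact CHR_ID match)."""
    sub = gwas.records[gwas.records["CHR_ID"].astype(str) == str(chrom)]
    return GwasCatalog(sub.reset_index(drop=True))


def direct_hits(
    trait: str,
    gwas: GwasCatalog,
    catalog: TFCatalog,
    family_column: str = "Family_Name",
    case_insensitive: bool = False,
) -> pd.DataFrame:
    """TFs appearing as mapped genes of a trait, with their family labels.

    Trait matching is exact, case-sensitive string equality by default.
    Result rows are unique on HGNC, ordered by first appearance in the
    catalog, each carrying the family value of the symbol's first catalog
    occurrence.
    """
    if not trait:
        raise ValueError("trait must be non-empty")
    if family_column not in catalog.hgnc_map.columns:
        raise SchemaError(
            f"catalog {catalog.name!r} lacks family column {family_column!r}"
        )
    traits = gwas.records["DISEASE_TRAIT"].astype(str)
    if case_insensitive:
        mask = traits.str.lower() == trait.lower()
    else:
        mask = traits == trait
    mapped: set[str] = set()
    for field in gwas.records.loc[mask, "MAPPED_GENE"]:
        mapped.update(split_mapped_genes(field))
    universe = hgnc_universe(catalog)
    hits = mapped & universe
    first = catalog.hgnc_map.drop_duplicates(subset=HGNC_COLUMN, keep="first")
    first = first[first[HGNC_COLUMN].isin(hits)]
    out = first[[HGNC_COLUMN, family_column]].reset_index(drop=True)
    return out


def top_traits_of_targets(
    tf: str,
    collection: GeneSetCollection,
    gwas: GwasCatalog,
    id_map: Mapping[str, str] | None = None,
    hgnc_universe: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Traits reported for GWAS hits in the targets of one TF.

    Pipeline: remap the collection to symbols if an ``id_map`` is given,
    take the union of targets over sets naming the TF, keep GWAS records
    with at least one mapped gene in that target set, and tabulate records
    per trait (each record counts once even if several of its mapped genes
    are targets).  Returns ``(hit_table, trait_counts)``; the hit table
    retains the five GWAS columns, and trait counts are sorted by trait name
    for determinism.
    """
    if not tf:
        raise ValueError("tf must be non-empty")
    if id_map is not None:
        collection = remap_identifiers(collection, id_map)
    elif collection.id_type != "symbol":
        raise SchemaError(
            f"collection id_type is {collection.id_type!r}; an id_map to "
            "symbols is required"
        )
    target_set = set(targets_of(collection, tf, hgnc_universe))
    cols = list(REQUIRED_COLUMNS)
    if not target_set:
        warnings.warn(f"TF {tf!r} matches no set in collection {collection.name!r}")
        empty = pd.DataFrame(columns=cols)
        return empty, pd.DataFrame(columns=["DISEASE_TRAIT", "n_records"])
    mask = gwas.records["MAPPED_GENE"].map(
        lambda f: bool(set(split_mapped_genes(f)) & target_set)
    )
    hit_table = gwas.records.loc[mask, cols].reset_index(drop=True)
    counts = (
        hit_table.groupby("DISEASE_TRAIT").size().reset_index(name="n_records")
    )
    counts = counts.sort_values("DISEASE_TRAIT", kind="mergesort").reset_index(drop=True)
    return hit_table, counts
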