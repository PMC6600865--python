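"""Transcription-factor catalogs under a common HGNC-keyed contract.

Reference catalogs of human TFs (CISBP, HOCOMOCO, direct GO annotation) use
incompatible native identifiers: CISBP keys motif models with IDs like
``T004843_1.02``, HOCOMOCO uses model names like ``AHR_HUMAN.H11MO.0.B``, and
GO annotates plain gene symbols.  The :class:`TFCatalog` container keeps the
native IDs alongside a metadata table whose obligatory ``HGNC`` column carries
the official gene symbol, so catalogs from any source can be compared on a
shared nomenclature.

Comparison of HGNC symbols here is case-sensitive after stripping surrounding
whitespace; alias expansion is deliberately out of scope (the heuristic
matcher for gene-set names lives in :mod:`tfkit.genesets`).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyInputError, SchemaError

HGNC_COLUMN = "HGNC"

#: GO molecular-function term "DNA binding transcription factor activity"
GO_TF_ACTIVITY = "GO:0003700"


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and value != value)


def _clean_symbol(value) -> str | None:
    """Strip surrounding whitespace; map blank/NA to None."""
    if _is_missing(value):
        return None
    s = str(value).strip()
    return s or None


@dataclass
class TFCatalog:
    """A named catalog of TFs with native identifiers and HGNC metadata.

    Parameters
    ----------
    name:
        Short label for the catalog (non-empty).
    native_ids:
        One catalog-native identifier per record; duplicates permitted
        (CISBP maps several motif models to one gene).
    hgnc_map:
        Metadata table, one row per native id, with an obligatory column
        named ``HGNC``.  Source-specific columns (``Family_Name``, class
        strings, ...) are carried through opaquely.
    """

    name: str
    native_ids: list[str]
    hgnc_map: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("catalog name must be non-empty")
        self.native_ids = [str(x) for x in self.native_ids]
        if len(self.native_ids) != len(self.hgnc_map):
            raise ValueError(
                f"native_ids ({len(self.native_ids)}) and hgnc_map "
                f"({len(self.hgnc_map)}) must have the same length"
            )
        if HGNC_COLUMN not in self.hgnc_map.columns:
            raise SchemaError(
                f"catalog {self.name!r}: hgnc_map lacks obligatory column "
                f"{HGNC_COLUMN!r}"
            )

    def __len__(self) -> int:
        return len(self.native_ids)

    def __repr__(self) -> str:
        uni = self.hgnc_universe()
        head = ", ".join(self.native_ids[:2])
        return (
            f"TFCatalog {self.name!r}: {len(self)} native ids"
            f" ({head}{', ...' if len(self) > 2 else ''}),"
            f" {len(uni)} unique HGNC symbols"
        )

    def hgnc_universe(self) -> set[str]:
        """Deduplicated set of non-missing HGNC symbols (see module docs)."""
        return hgnc_universe(self)


@dataclass
class TFClassLabel:
    """A parsed TF class string, e.g. ``"HOX-related factors{3.1.1}"``.

    HOCOMOCO class annotations append the dotted TFClass subfamily ID in
    braces; ``subfamily_id`` is None when no suffix is present.  ``malformed``
    flags brace content that did not parse as a dotted numeric ID (the whole
    string is then kept as the label).
    """

    raw: str
    label: str
    subfamily_id: str | None = None
    malformed: bool = False


_SUBFAMILY_RE = re.compile(r"^(.*)\{(\d+(?:\.\d+){0,2})\}$", re.DOTALL)


def parse_tfclass_label(raw: str) -> TFClassLabel:
    """Split a class string into human-readable label and TFClass subfamily.

    >>> parse_tfclass_label("More than 3 adjacent zinc finger factors{2.3.3}")
    TFClassLabel(raw='More than 3 adjacent zinc finger factors{2.3.3}', \
label='More than 3 adjacent zinc finger factors', subfamily_id='2.3.3', \
malformed=False)
    """
    if not raw:
        raise ValueError("class label must be non-empty")
    m = _SUBFAMILY_RE.match(raw)
    if m:
        return TFClassLabel(raw=raw, label=m.group(1).rstrip(), subfamily_id=m.group(2))
    # brace-like but not a dotted numeric id -> plain label, flagged
    malformed = bool(re.search(r"\{.*\}$", raw))
    if malformed:
        warnings.warn(f"malformed TFClass suffix in {raw!r}; kept as plain label")
    return TFClassLabel(raw=raw, label=raw, subfamily_id=None, malformed=malformed)


# ---------------------------------------------------------------------------
# loaders


def _read_tsv(path, rename: Mapping[str, str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if rename:
        df = df.rename(columns=dict(rename))
    return df


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def load_cisbp_catalog(
    path,
    name: str = "CISBP",
    rename: Mapping[str, str] | None = None,
) -> TFCatalog:
    """Load a CISBP-schema snapshot (wide TSV, one row per motif model).

    The first column supplies native ids; the ``HGNC`` column is populated
    from ``TF_Name``.  ``rename`` maps snapshot header spellings onto the
    canonical ``TF_Name`` / ``Family_Name`` names when they differ.
    """
    df = _read_tsv(path, rename)
    _require_columns(df, ["TF_Name", "Family_Name"], path)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    df = df.copy()
    df[HGNC_COLUMN] = df["TF_Name"]
    return TFCatalog(name=name, native_ids=df.iloc[:, 0].tolist(), hgnc_map=df)


def load_hocomoco_catalog(
    path,
    name: str = "HOCOMOCO",
    model_column: str = "Model",
    tf_column: str = "Transcription factor",
    rename: Mapping[str, str] | None = None,
) -> TFCatalog:
    """Load a HOCOMOCO-schema snapshot (9-column TSV of binding models).

    Native ids are model names; HGNC symbols come from the
    ``Transcription factor`` column.  Class strings (with their TFClass
    ``{x.y.z}`` suffixes) are retained verbatim in the metadata table.
    """
    df = _read_tsv(path, rename)
    _require_columns(df, [model_column, tf_column], path)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    df = df.copy()
    df[HGNC_COLUMN] = df[tf_column]
    return TFCatalog(name=name, native_ids=df[model_column].tolist(), hgnc_map=df)


def load_go_catalog(
    annotation_table,
    go_id: str = GO_TF_ACTIVITY,
    name: str = "GO",
    symbol_column: str | None = None,
    go_column: str | None = None,
) -> TFCatalog:
    """Build a catalog from direct GO annotations of gene symbols.

    ``annotation_table`` is a two-column table (path to TSV, or DataFrame)
    mapping gene symbols to GO ids.  Only *direct* annotations to ``go_id``
    are used — no propagation through ontology ancestors, which is why the
    default term GO:0003700 yields a smaller set than ontology browsers that
    fold in broader receptor activities.
    """
    if isinstance(annotation_table, pd.DataFrame):
        df = annotation_table
    else:
        df = _read_tsv(annotation_table)
    if symbol_column is None:
        symbol_column = df.columns[0]
    if go_column is None:
        go_column = df.columns[1]
    _require_columns(df, [symbol_column, go_column], "annotation table")
    hits = df[df[go_column] == go_id]
    if hits.empty:
        warnings.warn(f"GO id {go_id!r} has no direct annotations; empty catalog")
    symbols = [s for s in (_clean_symbol(v) for v in hits[symbol_column]) if s]
    hgnc_map = pd.DataFrame({HGNC_COLUMN: symbols})
    return TFCatalog(name=name, native_ids=list(symbols), hgnc_map=hgnc_map)


# ---------------------------------------------------------------------------
# universes, overlaps, class frequencies


def hgnc_universe(catalog: TFCatalog, with_report: bool = False):
    """Deduplicated set of non-missing HGNC symbols in a catalog.

    Blank or NA entries are excluded; with ``with_report=True`` the number of
    excluded entries is returned alongside the set.
    """
    n_blank = 0
    out: set[str] = set()
    for value in catalog.hgnc_map[HGNC_COLUMN]:
        sym = _clean_symbol(value)
        if sym is None:
            n_blank += 1
        else:
            out.add(sym)
    if with_report:
        return out, n_blank
    return out


def overlap_counts(catalogs: Sequence[TFCatalog]) -> pd.DataFrame:
    """Membership-signature counts over the catalogs' HGNC universes.

    Each unique symbol in the union belongs to exactly one signature (the
    subset of catalogs containing it).  The result has one boolean column per
    catalog name plus a ``count`` column, one row per *possible* signature
    (so planted zeros are visible), with the all-catalogs intersection and
    single-catalog-exclusive regions included.  Counts sum to the size of the
    union of the universes.
    """
    if len(catalogs) < 2:
        raise ValueError("overlap_counts requires at least two catalogs")
    names = [c.name for c in catalogs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate catalog names: {names}")
    universes = {c.name: hgnc_universe(c) for c in catalogs}
    union = set().union(*universes.values())
    sig_counts: dict[tuple[bool, ...], int] = {}
    for sym in union:
        sig = tuple(sym in universes[n] for n in names)
        sig_counts[sig] = sig_counts.get(sig, 0) + 1
    rows = []
    for sig in product([True, False], repeat=len(names)):
        if not any(sig):
            continue
        rows.append(dict(zip(names, sig)) | {"count": sig_counts.get(sig, 0)})
    return pd.DataFrame(rows)


def overlap_region_count(table: pd.DataFrame, **membership: bool) -> int:
    """Count for one signature row, e.g. ``overlap_region_count(t, A=True, B=False)``."""
    mask = pd.Series(True, index=table.index)
    for name, value in membership.items():
        mask &= table[name] == value
    sub = table[mask]
    if len(sub) != 1:
        raise KeyError(f"signature {membership} selects {len(sub)} rows")
    return int(sub["count"].iloc[0])


def class_frequency(
    catalog: TFCatalog, class_column: str, tf_column: str = HGNC_COLUMN
) -> pd.DataFrame:
    """Number of distinct TFs per class, ranked by frequency.

    Each TF counts at most once per class regardless of how many catalog rows
    (motif models) it appears in.  Sorted descending by count; ties broken by
    class string ascending.
    """
    _require_columns(catalog.hgnc_map, [class_column, tf_column], f"catalog {catalog.name!r}")
    df = catalog.hgnc_map[[class_column, tf_column]].drop_duplicates()
    counts = (
        df.groupby(class_column, sort=False)[tf_column]
        .nunique()
        .reset_index(name="n_distinct_tfs")
    )
    counts = counts.sort_values(
        ["n_distinct_tfs", class_column], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return counts


def table_to_json(table: pd.DataFrame) -> str:
    """Serialize a report table (overlap or class-frequency) as JSON records."""
    return json.dumps(table.to_dict(orient="records"), indent=2)
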