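"""GMT gene-set collections and the TF-target set-name grammar.

MSigDb's c3/TFT collection names its sets with underscore-delimited tokens
describing a binding motif, a gene, and version qualifiers, e.g.
``GGGNNTTTCC_NFKB_Q6_01``.  The nomenclature predates stable gene symbols, so
associating a set with an HGNC symbol is heuristic: this module's
:func:`parse_tft_name` classifies the tokens and matches the gene token
against a supplied symbol universe (exact case-insensitive, then a
trailing-digit-stripping retry).  Vintage names that resolve to nothing
(``NFKAPPAB``, the literal ``UNKNOWN``) are reported as unmatched rather than
guessed at.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError

IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")

#: minimum length for a token to be read as a motif rather than a gene name;
#: short symbols like MYC or E2F1 must never be absorbed as motifs
MOTIF_MIN_LEN = 6

_QUALIFIER_RE = re.compile(r"^(Q\d+|\d+|[A-Za-z])$")


@dataclass
class GeneSet:
    """One gene set: name, free-text description, ordered unique members."""

    name: str
    description: str
    members: list[str]
    id_type: str = "symbol"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        seen: dict[str, None] = {}
        for m in self.members:
            m = str(m).strip()
            if m:
                seen.setdefault(m, None)
        self.members = list(seen)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets sharing one identifier type."""

    name: str
    sets: list[GeneSet]
    id_type: str = "symbol"
    #: per-set counts of duplicate members dropped on read / unmapped members
    #: dropped on remap; informational only
    report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate set names in collection: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def unique_members(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out.update(s.members)
        return out


def read_gmt(path, id_type: str = "symbol", name: str | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, member ids...).

    Duplicate members within a line are dropped, with per-set counts recorded
    in the collection's ``report``.  Lines with fewer than three fields are a
    format error citing the line number.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    report: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            raw_members = [m for m in fields[2:] if m.strip()]
            gs = GeneSet(
                name=fields[0], description=fields[1], members=raw_members, id_type=id_type
            )
            n_dupes = len(raw_members) - len(gs.members)
            if n_dupes:
                report[gs.name] = n_dupes
            sets.append(gs)
    return GeneSetCollection(
        name=name or path.stem, sets=sets, id_type=id_type, report=report
    )


def write_gmt(collection: GeneSetCollection, path) -> Path:
    """Write a collection as GMT (UTF-8, LF line endings); round-trip safe."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")
    return path


@dataclass
class TFTNameParse:
    """Token classification of one c3/TFT set name.

    ``match_kind`` is ``exact`` (case-insensitive symbol hit), ``close``
    (hit after stripping trailing digits from the gene token) or ``unknown``.
    Joining ``motif_token``, ``gene_token`` and ``qualifier_tokens`` with
    underscores in their original order reproduces ``raw``.
    """

    raw: str
    motif_token: str | None
    gene_token: str | None
    matched_hgnc: str | None
    match_kind: str
    qualifier_tokens: list[str]


def _is_motif_token(token: str) -> bool:
    return len(token) >= MOTIF_MIN_LEN and set(token) <= IUPAC_CODES


def parse_tft_name(raw: str, hgnc_universe: Iterable[str] = ()) -> TFTNameParse:
    """Parse an underscore-delimited TF-target set name.

    Tokens are classified in order: the first token of length >= 6 drawn
    wholly from IUPAC nucleotide codes is the motif; tokens shaped like
    ``Q6``, ``01`` or a single letter are version qualifiers; the leftmost
    remaining token is the gene candidate, matched against
    ``hgnc_universe``.

    >>> p = parse_tft_name("GGGNNTTTCC_NFKB_Q6_01")
    >>> p.motif_token, p.gene_token, p.qualifier_tokens
    ('GGGNNTTTCC', 'NFKB', ['Q6', '01'])
    """
    if not raw:
        raise ValueError("set name must be non-empty")
    lookup = {s.upper(): s for s in hgnc_universe}
    tokens = raw.split("_")
    motif_token: str | None = None
    gene_token: str | None = None
    qualifiers: list[str] = []
    for tok in tokens:
        if motif_token is None and _is_motif_token(tok):
            motif_token = tok
        elif _QUALIFIER_RE.match(tok):
            qualifiers.append(tok)
        elif gene_token is None:
            gene_token = tok
        else:
            qualifiers.append(tok)

    matched: str | None = None
    kind = "unknown"
    if gene_token is not None and gene_token != "UNKNOWN":
        if gene_token.upper() in lookup:
            matched, kind = lookup[gene_token.upper()], "exact"
        else:
            stripped = gene_token.rstrip("0123456789")
            if stripped and stripped != gene_token and stripped.upper() in lookup:
                matched, kind = lookup[stripped.upper()], "close"
    return TFTNameParse(
        raw=raw,
        motif_token=motif_token,
        gene_token=gene_token,
        matched_hgnc=matched,
        match_kind=kind,
        qualifier_tokens=qualifiers,
    )


def grep_sets(collection: GeneSetCollection, pattern: str) -> list[str]:
    """Set names matching a regex/substring pattern, in collection order."""
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid pattern {pattern!r}: {exc}") from exc
    return [n for n in collection.names() if rx.search(n)]


def remap_identifiers(
    collection: GeneSetCollection,
    id_map: Mapping[str, str],
    new_id_type: str = "symbol",
) -> GeneSetCollection:
    """Translate member identifiers through a map (e.g. Entrez -> symbol).

    Unmapped members are dropped; per-set drop counts land in the returned
    collection's ``report``.  Translated members are deduplicated, so the
    total member count never increases.
    """
    if not id_map:
        raise ValueError("id_map is empty")
    new_sets: list[GeneSet] = []
    report: dict[str, int] = {}
    for s in collection.sets:
        translated = [id_map[m] for m in s.members if m in id_map]
        dropped = len(s.members) - len(translated)
        if dropped:
            report[s.name] = dropped
        new_sets.append(
            GeneSet(name=s.name, description=s.description, members=translated,
                    id_type=new_id_type)
        )
    return GeneSetCollection(
        name=collection.name, sets=new_sets, id_type=new_id_type, report=report
    )


def targets_of(
    collection: GeneSetCollection,
    tf_symbol: str,
    hgnc_universe: Iterable[str] | None = None,
) -> list[str]:
    """Merged target list of a TF: union over sets whose name matches it.

    A set contributes when :func:`parse_tft_name` resolves its gene token to
    ``tf_symbol``.  Order of first appearance is preserved; empty when no set
    name matches.
    """
    if not tf_symbol:
        raise ValueError("tf_symbol must be non-empty")
    universe = set(hgnc_universe) if hgnc_universe is not None else {tf_symbol}
    universe.add(tf_symbol)
    merged: dict[str, None] = {}
    for s in collection.sets:
        parse = parse_tft_name(s.name, universe)
        if parse.matched_hgnc == tf_symbol:
            for m in s.members:
                merged.setdefault(m, None)
    return list(merged)
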