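"""Report collections, surface-term normalization and category mapping.

A report collection is a table with one row per medical report and one
column per attribute.  Structured collections carry canonical category codes
(values of the attribute schema); narrative collections carry raw surface
terms as physicians typed them — with dropped diacritics, inconsistent case,
merged spaces, digit-for-letter typos and Roman numerals.  An empty cell is a
missing observation.

Narrative terms are folded onto canonical categories in two deterministic
steps: a lexical normalization pipeline (each step independently toggleable)
followed by a dictionary lookup in a curated term mapping.  Terms the
dictionary does not know are surfaced as *unmapped*, never guessed: the
original category assignment in the source study was manual, and silent fuzzy
matching would fabricate semantics.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .estimation import CategoryCounts

__all__ = [
    "NormalizationConfig",
    "AttributeSchema",
    "TermMapping",
    "ReportCollection",
    "normalize_term",
    "map_to_category",
    "count_raw_terms",
    "tabulate",
    "read_collection_csv",
    "read_mapping_csv",
    "write_mapping_csv",
    "read_schema",
]


@dataclass(frozen=True)
class NormalizationConfig:
    """Toggles for the lexical normalization pipeline (all on by default)."""

    strip_diacritics: bool = True
    casefold: bool = True
    collapse_whitespace: bool = True
    repair_digit_zero: bool = True
    roman_to_arabic: bool = True


_ROMAN_RE = re.compile(r"^[ivxlcdm]+$")
_ROMAN_VALUES = {"i": 1, "v": 5, "x": 10, "l": 50, "c": 100, "d": 500, "m": 1000}


def _roman_to_int(token: str) -> int | None:
    total, prev = 0, 0
    for ch in reversed(token):
        v = _ROMAN_VALUES[ch]
        total = total - v if v < prev else total + v
        prev = max(prev, v)
    # reject malformed sequences ("iiii", "vx") by round-tripping
    return total if _int_to_roman(total) == token else None


def _int_to_roman(n: int) -> str:
    if not 0 < n < 4000:
        return ""
    pairs = [(1000, "m"), (900, "cm"), (500, "d"), (400, "cd"), (100, "c"),
             (90, "xc"), (50, "l"), (40, "xl"), (10, "x"), (9, "ix"),
             (5, "v"), (4, "iv"), (1, "i")]
    out = []
    for v, s in pairs:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


def _strip_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def _repair_digit_zero(token: str) -> str:
    # "0" typed for the letter O inside an otherwise alphabetic token
    if "0" in token and any(ch.isalpha() for ch in token) \
            and not any(ch.isdigit() and ch != "0" for ch in token):
        return token.replace("0", "o")
    return token


def normalize_term(raw: str, config: NormalizationConfig | None = None) -> str:
    """Deterministic, idempotent lexical normalization of a surface term.

    Pipeline (each step toggleable): strip diacritics via Unicode
    decomposition; casefold; collapse runs of whitespace; repair the digit 0
    typed for the letter O inside alphabetic tokens; rewrite standalone
    Roman-numeral tokens as Arabic numerals ("heart sounds II" ->
    "heart sounds 2").  Unrecognized content passes through unchanged.
    """
    if config is None:
        config = NormalizationConfig()
    text = str(raw)
    if config.strip_diacritics:
        text = _strip_diacritics(text)
    if config.casefold:
        text = text.casefold()
    if config.collapse_whitespace:
        text = " ".join(text.split())
    else:
        text = text.strip()
    tokens = text.split(" ")
    out = []
    for tok in tokens:
        if config.repair_digit_zero:
            tok = _repair_digit_zero(tok)
        # single letters (Czech "i" = and, "v" = in) are left alone
        if config.roman_to_arabic and len(tok) >= 2 \
                and _ROMAN_RE.match(tok.lower()):
            value = _roman_to_int(tok.lower())
            if value is not None:
                tok = str(value)
        out.append(tok)
    return " ".join(out)


@dataclass(frozen=True)
class AttributeSchema:
    """Canonical category list of one attribute (e.g. the MDMC smoking
    categories smoker / occasional smoker / ex-smoker / nonsmoker)."""

    attribute_name: str
    canonical_categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.canonical_categories) < 1:
            raise ValueError("schema needs at least one category")
        if len(set(self.canonical_categories)) != len(self.canonical_categories):
            raise ValueError("schema categories must be unique")

    @property
    def k(self) -> int:
        return len(self.canonical_categories)


@dataclass
class TermMapping:
    """Many-to-one mapping of normalized surface terms to canonical categories."""

    attribute_name: str
    entries: dict[str, str] = field(default_factory=dict)
    config: NormalizationConfig = field(default_factory=NormalizationConfig)

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        for term, cat in self.entries.items():
            key = normalize_term(term, self.config)
            if key in normalized and normalized[key] != cat:
                raise ValueError(
                    f"attribute {self.attribute_name!r}: surface term {term!r} "
                    f"maps ambiguously after normalization")
            normalized[key] = cat
        self.entries = normalized

    def validate_against(self, schema: AttributeSchema) -> None:
        bad = sorted(set(self.entries.values()) - set(schema.canonical_categories))
        if bad:
            raise ValueError(
                f"attribute {self.attribute_name!r}: mapping targets "
                f"{bad} not in schema")


def map_to_category(raw: str, mapping: TermMapping,
                    config: NormalizationConfig | None = None) -> str | None:
    """Look up the normalized surface term; ``None`` marks an unmapped term."""
    key = normalize_term(raw, config if config is not None else mapping.config)
    return mapping.entries.get(key)


@dataclass
class ReportCollection:
    """A set of report records over an attribute schema.

    ``data`` has one row per report (index = record id, unique) and one
    column per attribute; ``None``/NaN marks a missing observation.  In
    ``structured`` mode values must be canonical schema categories; in
    ``narrative`` mode they are raw surface terms.
    """

    data: pd.DataFrame
    mode: str  # "narrative" | "structured"

    def __post_init__(self) -> None:
        if self.mode not in ("narrative", "structured"):
            raise ValueError("mode must be 'narrative' or 'structured'")
        if self.data.index.has_duplicates:
            raise ValueError("record ids must be unique")

    @property
    def n_reports(self) -> int:
        return len(self.data)

    @property
    def attributes(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, attribute: str) -> pd.Series:
        if attribute not in self.data.columns:
            raise KeyError(f"attribute {attribute!r} not in collection")
        return self.data[attribute]

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=True, index_label="record_id",
                         encoding="utf-8", lineterminator="\n")


def count_raw_terms(coll: ReportCollection, attribute: str,
                    config: NormalizationConfig | None = None) -> int:
    """Number of distinct normalized surface terms among recorded values.

    This is the narrative analogue of the number of categories: the
    number-of-categories diversity of a narrative attribute is this count
    minus one.
    """
    values = coll.values_for(attribute).dropna()
    return len({normalize_term(v, config) for v in values})


def tabulate(coll: ReportCollection, schema: AttributeSchema,
             mapping: TermMapping | None = None,
             config: NormalizationConfig | None = None) -> CategoryCounts:
    """Count reports per canonical category for one attribute.

    Structured collections are counted directly (a value outside the schema
    is an error naming the record).  Narrative collections are first folded
    through the term mapping; unmapped terms are counted into ``n_missing``
    and additionally reported via ``n_unmapped``.  Zero-count categories are
    retained, so every report is accounted for:
    ``sum(counts) + n_missing == n_reports``.
    """
    values = coll.values_for(schema.attribute_name)
    recorded = values.dropna()
    n_missing_blank = len(values) - len(recorded)
    tally = {cat: 0 for cat in schema.canonical_categories}
    n_unmapped = 0
    if coll.mode == "structured":
        for record_id, v in recorded.items():
            v = str(v)
            if v not in tally:
                raise ValueError(
                    f"record {record_id!r}: structured value {v!r} is not a "
                    f"canonical category of {schema.attribute_name!r}")
            tally[v] += 1
    else:
        if mapping is None:
            raise ValueError("narrative collections require a term mapping")
        mapping.validate_against(schema)
        for v in recorded:
            cat = map_to_category(str(v), mapping, config)
            if cat is None:
                n_unmapped += 1
            else:
                tally[cat] += 1
    return CategoryCounts(
        attribute_name=schema.attribute_name,
        labels=schema.canonical_categories,
        counts=tuple(tally[cat] for cat in schema.canonical_categories),
        n_missing=n_missing_blank + n_unmapped,
        n_unmapped=n_unmapped,
    )


# ---------------------------------------------------------------------------
# File round-trips (UTF-8 CSV, comma separator, header row required)


def read_collection_csv(path, mode: str) -> ReportCollection:
    """Read a report collection: one row per report, one column per attribute,
    empty cell = missing, first column ``record_id``."""
    df = pd.read_csv(path, encoding="utf-8", dtype=str)
    if "record_id" in df.columns:
        df = df.set_index("record_id")
    else:
        df.index = df.index.astype(str)
    return ReportCollection(df, mode)


def read_mapping_csv(path) -> dict[str, TermMapping]:
    """Read term mappings (columns: attribute, surface_term, canonical_category)."""
    df = pd.read_csv(path, encoding="utf-8", dtype=str)
    required = {"attribute", "surface_term", "canonical_category"}
    if not required.issubset(df.columns):
        raise ValueError(f"mapping CSV {path} lacks columns {sorted(required - set(df.columns))}")
    out: dict[str, TermMapping] = {}
    for attr, sub in df.groupby("attribute", sort=False):
        out[str(attr)] = TermMapping(
            str(attr), dict(zip(sub["surface_term"], sub["canonical_category"])))
    return out


def write_mapping_csv(mappings: Mapping[str, TermMapping] | Iterable[TermMapping],
                      path) -> None:
    if isinstance(mappings, Mapping):
        mappings = mappings.values()
    rows = [(m.attribute_name, term, cat)
            for m in mappings for term, cat in sorted(m.entries.items())]
    pd.DataFrame(rows, columns=["attribute", "surface_term", "canonical_category"]
                 ).to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_schema(path) -> dict[str, AttributeSchema]:
    """Read attribute schemas from CSV (columns: attribute, category, in order)
    or YAML (mapping of attribute -> category list)."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return {name: AttributeSchema(name, tuple(cats))
                for name, cats in raw.items()}
    df = pd.read_csv(path, encoding="utf-8", dtype=str)
    if not {"attribute", "category"}.issubset(df.columns):
        raise ValueError(f"schema CSV {path} needs columns attribute, category")
    return {str(attr): AttributeSchema(str(attr), tuple(sub["category"]))
            for attr, sub in df.groupby("attribute", sort=False)}
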