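"""Packaged reference dataset: the MDMC cardiology report study counts.

The package ships the per-attribute category counts of a study comparing 110
Czech narrative medical reports with 1119 structured reports from two
preventive-cardiology outpatient departments, for eight attributes selected
from the Minimal Data Model for Cardiology (MDMC).  Narrative counts are the
published tallies *after* manual folding of surface terms onto the closest
MDMC category; the surface terms themselves were never published, so
term-level behavior is exercised on synthetic collections instead
(:mod:`fdiversity.synthetic`).

Attribute-level metadata carries the published number of distinct narrative
surface terms per attribute and the structured number-of-categories
diversities as printed in the study's summary table.  Note that the printed
structured values (3,2,2,2,2,1,1,1) disagree with ``k - 1`` of the category
sets the study itself uses everywhere else (3,2,2,1,1,1,1,1): for Dyspnoea
and Chest pain the summary prints 2 although both attributes are dichotomies
in every per-category table.  Both versions are exposed; computations in this
package always derive ``k`` from the category set.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .estimation import MISSING_ROW_LABEL, CategoryCounts

__all__ = ["FixtureTable", "load_fixture", "FixtureIntegrityError"]

_CHECKSUMS = {
    "mdmc_counts.csv":
        "b7b3ffde68705a72383a67f6c088158e5f88b24c394c421cfb3bcefc1d8b02d7",
    "mdmc_attributes.csv":
        "6d4dadf885adeeb82044987789929717e7de999dcd5a2075fbf1b4c00e5e362c",
}


class FixtureIntegrityError(RuntimeError):
    """Packaged reference data failed its checksum."""


@dataclass(frozen=True)
class FixtureTable:
    """The eight MDMC attributes with narrative and structured counts."""

    narrative: dict[str, CategoryCounts]
    structured: dict[str, CategoryCounts]
    #: published count of distinct narrative surface terms per attribute
    narrative_distinct_terms: dict[str, int]
    #: structured number-of-categories diversities as printed in the study
    structured_noc_printed: dict[str, int]

    @property
    def attributes(self) -> list[str]:
        return list(self.narrative)

    def pairs(self) -> list[tuple[CategoryCounts, CategoryCounts]]:
        """(narrative, structured) count pairs in table order."""
        return [(self.narrative[a], self.structured[a]) for a in self.attributes]

    @property
    def n_narrative_reports(self) -> int:
        return next(iter(self.narrative.values())).n_total_reports

    @property
    def n_structured_reports(self) -> int:
        return next(iter(self.structured.values())).n_total_reports


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("fdiversity.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"packaged data {name} is corrupted (sha256 {digest})")
    from io import BytesIO
    return pd.read_csv(BytesIO(raw), encoding="utf-8")


def load_fixture() -> FixtureTable:
    """Load the packaged study counts, verifying their checksums."""
    counts = _read_packaged("mdmc_counts.csv")
    meta = _read_packaged("mdmc_attributes.csv")
    narrative: dict[str, CategoryCounts] = {}
    structured: dict[str, CategoryCounts] = {}
    for attr in counts["attribute"].drop_duplicates():
        sub = counts[counts["attribute"] == attr]
        body = sub[sub["category"] != MISSING_ROW_LABEL]
        miss = sub[sub["category"] == MISSING_ROW_LABEL]
        labels = tuple(body["category"])
        narrative[attr] = CategoryCounts(
            attr, labels, tuple(int(x) for x in body["count_collection_a"]),
            n_missing=int(miss["count_collection_a"].sum()))
        structured[attr] = CategoryCounts(
            attr, labels, tuple(int(x) for x in body["count_collection_b"]),
            n_missing=int(miss["count_collection_b"].sum()))
    meta = meta.set_index("attribute")
    return FixtureTable(
        narrative=narrative,
        structured=structured,
        narrative_distinct_terms=meta["narrative_distinct_terms"].astype(int).to_dict(),
        structured_noc_printed=meta["structured_noc_diversity_printed"].astype(int).to_dict(),
    )
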