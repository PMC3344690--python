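"""Synthetic paired narrative/structured report collections with known truth.

The study data this package ships (:mod:`fdiversity.fixture`) is count-level
only — the raw reports and their surface terms were never published.  This
module generates what the count tables cannot give: full report collections
with a known ground truth, so the term-normalization, mapping and tabulation
stages are testable end to end.

The generator emulates the study design: two collections share the same true
category distribution per attribute, but the structured collection records
canonical category codes while the narrative one records surface terms
perturbed by the lexical phenomena of free-text Czech reports — dropped
diacritics, ad-hoc abbreviation, typing errors, inconsistent case, synonym
choice.  Missingness is drawn independently per attribute per report; an
optional informative mode skews missingness toward the most frequent
category, emulating negative findings physicians leave unrecorded.

The default synonym dictionaries are small illustrative Czech-flavored sets
invented for this package (synthetic — they are not the study's terms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .reports import ReportCollection, TermMapping, _strip_diacritics

__all__ = [
    "CategoryVariantModel",
    "AttributeConfig",
    "GeneratorConfig",
    "TruthRecord",
    "generate_pair",
    "study_like_config",
    "config_from_yaml",
    "config_to_yaml",
]


def _check_prob(x: float, what: str) -> float:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{what} must be in [0, 1], got {x!r}")
    return float(x)


@dataclass(frozen=True)
class CategoryVariantModel:
    """Surface-term model for one category of one attribute.

    ``synonyms`` are the base surface forms a physician might write; each
    probability governs one independent perturbation applied to the drawn
    synonym (in order: diacritic dropping, abbreviation truncation, typo
    injection, case change).  Typos are the one perturbation the curated
    mapping does not cover, so they surface as unmapped terms downstream.
    """

    synonyms: tuple[str, ...]
    p_strip_diacritics: float = 0.0
    p_abbreviate: float = 0.0
    p_typo: float = 0.0
    p_case_change: float = 0.0

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise ValueError("need at least one synonym per category")
        for name in ("p_strip_diacritics", "p_abbreviate", "p_typo",
                     "p_case_change"):
            _check_prob(getattr(self, name), name)


@dataclass(frozen=True)
class AttributeConfig:
    """One attribute: categories, true distribution, missingness, variants."""

    name: str
    categories: tuple[str, ...]
    probs: tuple[float, ...]
    missing_rate_narrative: float = 0.0
    missing_rate_structured: float = 0.0
    variants: dict[str, CategoryVariantModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.probs):
            raise ValueError(f"attribute {self.name!r}: categories/probs mismatch")
        if any(p < 0 for p in self.probs) or abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"attribute {self.name!r}: probs must be a distribution")
        _check_prob(self.missing_rate_narrative, "missing_rate_narrative")
        _check_prob(self.missing_rate_structured, "missing_rate_structured")
        unknown = set(self.variants) - set(self.categories)
        if unknown:
            raise ValueError(f"attribute {self.name!r}: variant models for "
                             f"unknown categories {sorted(unknown)}")

    def variant_for(self, category: str) -> CategoryVariantModel:
        # default: the canonical label itself, unperturbed
        return self.variants.get(category, CategoryVariantModel((category,)))


@dataclass(frozen=True)
class GeneratorConfig:
    """Full generator configuration.  ``seed`` is mandatory: every run is
    reproducible, and identical seed + config give byte-identical output."""

    attributes: tuple[AttributeConfig, ...]
    n_narrative: int = 110
    n_structured: int = 1119
    seed: int = 0
    informative_missingness: bool = False
    #: share the underlying category draws between the two collections
    #: (they remain two samples of different sizes from the same truth)
    share_draws: bool = True

    def __post_init__(self) -> None:
        if not self.attributes:
            raise ValueError("config needs at least one attribute")
        if self.n_narrative < 1 or self.n_structured < 1:
            raise ValueError("sample sizes must be >= 1")


@dataclass
class TruthRecord:
    """Every draw the generator made, for oracle checks downstream."""

    seed: int
    true_probs: dict[str, dict[str, float]]
    #: true category of every report, before missingness was applied
    narrative_categories: dict[str, list[str]]
    structured_categories: dict[str, list[str]]
    narrative_missing: dict[str, list[bool]]
    structured_missing: dict[str, list[bool]]
    narrative_surface: dict[str, list[str | None]]  # None = missing
    mappings: dict[str, dict[str, str]]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, ensure_ascii=False, indent=1)


def _abbreviate(term: str) -> str:
    """Deterministic ad-hoc abbreviation: first word cut to 4 letters + '.'."""
    head = term.split(" ")[0]
    if len(head) <= 4:
        return head + "."
    return head[:4] + "."


def _inject_typo(term: str, rng: np.random.Generator) -> str:
    """Swap one adjacent character pair at a random position."""
    if len(term) < 2:
        return term + term
    i = int(rng.integers(0, len(term) - 1))
    return term[:i] + term[i + 1] + term[i] + term[i + 2:]


def _surface_form(term: str, vm: CategoryVariantModel,
                  rng: np.random.Generator) -> str:
    if rng.random() < vm.p_strip_diacritics:
        term = _strip_diacritics(term)
    if rng.random() < vm.p_abbreviate:
        term = _abbreviate(term)
    if rng.random() < vm.p_typo:
        term = _inject_typo(term, rng)
    if rng.random() < vm.p_case_change:
        term = term.upper() if rng.random() < 0.5 else term.capitalize()
    return term


def build_mapping(attr: AttributeConfig) -> TermMapping:
    """Curated mapping covering every synonym and its abbreviation.

    Typo-injected forms are deliberately absent: they are the 'unknown term'
    case the pipeline must surface as unmapped.
    """
    entries: dict[str, str] = {}
    for cat in attr.categories:
        vm = attr.variant_for(cat)
        entries[cat] = cat
        for syn in vm.synonyms:
            entries[syn] = cat
            entries[_abbreviate(syn)] = cat
    return TermMapping(attr.name, entries)


def _missing_mask(true_cats: np.ndarray, rate: float, modal: str,
                  informative: bool, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(len(true_cats))
    if not informative:
        return u < rate
    # skew missingness toward the modal (most frequent) category: its reports
    # are twice as likely to go unrecorded, overall rate roughly preserved
    w = np.where(true_cats == modal, 2.0, 1.0)
    p = rate * w / float(w.mean())
    return u < np.minimum(p, 1.0)


def generate_pair(config: GeneratorConfig
                  ) -> tuple[ReportCollection, ReportCollection, TruthRecord]:
    """Generate one paired (narrative, structured) collection set.

    Both collections are drawn from the same true category distributions;
    with ``share_draws`` (default) they read a common category stream, so a
    degenerate config (no perturbation, no missingness, equal sizes) yields
    identical collections.  The truth record keeps every draw and the exact
    term mapping needed to fold the narrative collection back onto canonical
    categories.
    """
    rng = np.random.default_rng(config.seed)
    nn, ns = config.n_narrative, config.n_structured
    narr_cols: dict[str, list] = {}
    struct_cols: dict[str, list] = {}
    truth = TruthRecord(config.seed, {}, {}, {}, {}, {}, {}, {})
    for attr in config.attributes:
        cats = np.array(attr.categories, dtype=object)
        probs = np.array(attr.probs, dtype=float)
        modal = attr.categories[int(np.argmax(probs))]
        if config.share_draws:
            common = rng.choice(cats, size=max(nn, ns), p=probs)
            narr_true, struct_true = common[:nn], common[:ns]
        else:
            narr_true = rng.choice(cats, size=nn, p=probs)
            struct_true = rng.choice(cats, size=ns, p=probs)
        narr_missing = _missing_mask(narr_true, attr.missing_rate_narrative,
                                     modal, config.informative_missingness, rng)
        struct_missing = _missing_mask(struct_true, attr.missing_rate_structured,
                                       modal, config.informative_missingness, rng)
        narr_vals: list[str | None] = []
        narr_surface: list[str | None] = []
        for cat, miss in zip(narr_true, narr_missing):
            if miss:
                narr_vals.append(None)
                narr_surface.append(None)
                continue
            vm = attr.variant_for(cat)
            syn = vm.synonyms[int(rng.integers(0, len(vm.synonyms)))]
            form = _surface_form(syn, vm, rng)
            narr_vals.append(form)
            narr_surface.append(form)
        struct_vals = [None if miss else cat
                       for cat, miss in zip(struct_true, struct_missing)]
        narr_cols[attr.name] = narr_vals
        struct_cols[attr.name] = struct_vals
        truth.true_probs[attr.name] = dict(zip(attr.categories,
                                               (float(p) for p in probs)))
        truth.narrative_categories[attr.name] = [str(c) for c in narr_true]
        truth.structured_categories[attr.name] = [str(c) for c in struct_true]
        truth.narrative_missing[attr.name] = [bool(m) for m in narr_missing]
        truth.structured_missing[attr.name] = [bool(m) for m in struct_missing]
        truth.narrative_surface[attr.name] = narr_surface
        truth.mappings[attr.name] = dict(build_mapping(attr).entries)
    narr_df = pd.DataFrame(narr_cols, index=[f"N{i:05d}" for i in range(nn)])
    struct_df = pd.DataFrame(struct_cols, index=[f"S{i:05d}" for i in range(ns)])
    return (ReportCollection(narr_df, "narrative"),
            ReportCollection(struct_df, "structured"),
            truth)


# ---------------------------------------------------------------------------
# Default study-like configuration

# Synthetic Czech-flavored synonym sets (invented for this package; the study
# never published its surface terms).
_SYNTHETIC_SYNONYMS: dict[str, dict[str, tuple[str, ...]]] = {
    "Smoking": {
        "smoker": ("kuřák", "kouří", "silný kuřák"),
        "occasional smoker": ("příležitostný kuřák", "občas kouří"),
        "ex-smoker": ("exkuřák", "bývalý kuřák", "přestal kouřit"),
        "nonsmoker": ("nekuřák", "nekouří", "nikdy nekouřil"),
    },
    "Dyspnoea": {
        "yes": ("dušnost", "zadýchává se", "dušnost II", "námahová dušnost"),
        "no": ("bez dušnosti", "dýchání volné", "neguje dušnost"),
    },
}


def _default_variant(synonyms: tuple[str, ...]) -> CategoryVariantModel:
    # perturbation rates chosen as plausible free-text noise levels: diacritics
    # are dropped often (fast typing), abbreviation and case drift are common,
    # outright typos are rarer
    return CategoryVariantModel(synonyms, p_strip_diacritics=0.5,
                                p_abbreviate=0.2, p_typo=0.05,
                                p_case_change=0.25)


def study_like_config(seed: int = 0,
                      informative_missingness: bool = False) -> GeneratorConfig:
    """A configuration shaped like the MDMC study.

    Sample sizes 110 (narrative) and 1119 (structured); true category
    distributions and per-attribute missingness rates taken from the packaged
    structured counts; synthetic synonym dictionaries where provided, the
    canonical label elsewhere.
    """
    from .fixture import load_fixture
    fx = load_fixture()
    attrs = []
    for name in fx.attributes:
        sc = fx.structured[name]
        nc = fx.narrative[name]
        total = sc.n_recorded
        probs = tuple(c / total for c in sc.counts)
        syns = _SYNTHETIC_SYNONYMS.get(name, {})
        variants = {cat: _default_variant(syns[cat]) if cat in syns
                    else _default_variant((cat,))
                    for cat in sc.labels}
        attrs.append(AttributeConfig(
            name=name, categories=sc.labels, probs=probs,
            missing_rate_narrative=nc.n_missing / nc.n_total_reports,
            missing_rate_structured=sc.n_missing / sc.n_total_reports,
            variants=variants))
    return GeneratorConfig(tuple(attrs), n_narrative=110, n_structured=1119,
                           seed=seed,
                           informative_missingness=informative_missingness)


# ---------------------------------------------------------------------------
# YAML round-trip


def config_to_yaml(config: GeneratorConfig, path) -> None:
    import yaml
    doc = {
        "seed": config.seed,
        "n_narrative": config.n_narrative,
        "n_structured": config.n_structured,
        "informative_missingness": config.informative_missingness,
        "share_draws": config.share_draws,
        "attributes": [
            {
                "name": a.name,
                "categories": list(a.categories),
                "probs": [float(p) for p in a.probs],
                "missing_rate_narrative": a.missing_rate_narrative,
                "missing_rate_structured": a.missing_rate_structured,
                "variants": {
                    cat: {
                        "synonyms": list(vm.synonyms),
                        "p_strip_diacritics": vm.p_strip_diacritics,
                        "p_abbreviate": vm.p_abbreviate,
                        "p_typo": vm.p_typo,
                        "p_case_change": vm.p_case_change,
                    }
                    for cat, vm in a.variants.items()
                },
            }
            for a in config.attributes
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, allow_unicode=True, sort_keys=False)


def config_from_yaml(path) -> GeneratorConfig:
    import yaml
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    attrs = []
    for a in doc["attributes"]:
        variants = {
            cat: CategoryVariantModel(
                tuple(vm["synonyms"]),
                p_strip_diacritics=vm.get("p_strip_diacritics", 0.0),
                p_abbreviate=vm.get("p_abbreviate", 0.0),
                p_typo=vm.get("p_typo", 0.0),
                p_case_change=vm.get("p_case_change", 0.0),
            )
            for cat, vm in a.get("variants", {}).items()
        }
        attrs.append(AttributeConfig(
            name=a["name"], categories=tuple(a["categories"]),
            probs=tuple(a["probs"]),
            missing_rate_narrative=a.get("missing_rate_narrative", 0.0),
            missing_rate_structured=a.get("missing_rate_structured", 0.0),
            variants=variants))
    return GeneratorConfig(
        tuple(attrs),
        n_narrative=int(doc.get("n_narrative", 110)),
        n_structured=int(doc.get("n_structured", 1119)),
        seed=int(doc["seed"]),
        informative_missingness=bool(doc.get("informative_missingness", False)),
        share_draws=bool(doc.get("share_draws", True)),
    )
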