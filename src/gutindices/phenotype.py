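"""Phenotype binning from self-reported gut conditions.

Subjects fall into exactly one of three bins. Healthy subjects report
no health or gut issues; mild covers bloating, constipation, gassiness,
and IBS; diseased covers celiac disease, Crohn's disease,
gastroesophageal reflux disease, inflammatory bowel disease, and
ulcerative colitis. Mixed reports bin by severity (any diseased term
dominates any mild term). A non-empty report containing only
unrecognized terms is "unknown" — kept distinct rather than forced into
mild so unparseable survey text cannot contaminate the healthy/mild
contrast; downstream comparisons exclude it.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

from .exceptions import ValidationError
from .profile_io import CohortTable

logger = logging.getLogger(__name__)


class Phenotype(str, Enum):
    HEALTHY = "healthy"
    MILD = "mild"
    DISEASED = "diseased"
    UNKNOWN = "unknown"


#: Severity ordering used by the dominance rule; unknown is
#: incomparable and never produced by adding recognized terms.
SEVERITY = {Phenotype.HEALTHY: 0, Phenotype.MILD: 1, Phenotype.DISEASED: 2}

DEFAULT_MILD_TERMS = frozenset({"bloating", "constipation", "gassiness", "ibs"})
DEFAULT_DISEASED_TERMS = frozenset(
    {
        "celiac disease",
        "crohn's disease",
        "gastroesophageal reflux disease",
        "inflammatory bowel disease",
        "ulcerative colitis",
    }
)
#: Survey free text is messy; common aliases map onto canonical terms.
DEFAULT_SYNONYMS = {
    "irritable bowel syndrome": "ibs",
    "gerd": "gastroesophageal reflux disease",
    "acid reflux": "gastroesophageal reflux disease",
    "ibd": "inflammatory bowel disease",
    "celiac": "celiac disease",
    "coeliac disease": "celiac disease",
    "crohns disease": "crohn's disease",
    "crohn disease": "crohn's disease",
    "crohn's": "crohn's disease",
    "uc": "ulcerative colitis",
    "bloated": "bloating",
    "constipated": "constipation",
    "gassy": "gassiness",
    "gas": "gassiness",
}


def normalize_condition(text: str) -> str:
    return " ".join(text.replace("’", "'").casefold().split()).strip(" .;,")


@dataclass
class ConditionLexicon:
    mild_terms: frozenset[str] = DEFAULT_MILD_TERMS
    diseased_terms: frozenset[str] = DEFAULT_DISEASED_TERMS
    synonyms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SYNONYMS))

    def __post_init__(self) -> None:
        self.mild_terms = frozenset(normalize_condition(t) for t in self.mild_terms)
        self.diseased_terms = frozenset(
            normalize_condition(t) for t in self.diseased_terms
        )
        self.synonyms = {
            normalize_condition(k): normalize_condition(v)
            for k, v in self.synonyms.items()
        }
        overlap = self.mild_terms & self.diseased_terms
        if overlap:
            raise ValidationError(
                f"mild and diseased term sets must be disjoint; overlap: {sorted(overlap)}"
            )

    def canonical(self, condition: str) -> str:
        term = normalize_condition(condition)
        return self.synonyms.get(term, term)


def default_lexicon() -> ConditionLexicon:
    return ConditionLexicon()


def load_lexicon(path: str | Path) -> ConditionLexicon:
    """Load a lexicon from YAML with keys ``mild``, ``diseased``, ``synonyms``."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    unknown = set(raw) - {"mild", "diseased", "synonyms"}
    if unknown:
        raise ValidationError(f"{path}: unknown lexicon keys {sorted(unknown)}")
    return ConditionLexicon(
        mild_terms=frozenset(raw.get("mild", DEFAULT_MILD_TERMS)),
        diseased_terms=frozenset(raw.get("diseased", DEFAULT_DISEASED_TERMS)),
        synonyms=dict(raw.get("synonyms", DEFAULT_SYNONYMS)),
    )


def assign_phenotype(
    conditions: list[str], lexicon: ConditionLexicon | None = None
) -> Phenotype:
    """Bin one subject's condition list.

    Any diseased term -> diseased; else any mild term -> mild; else an
    empty list -> healthy; a non-empty list of only unrecognized terms
    -> unknown.
    """
    lexicon = lexicon or default_lexicon()
    terms = [lexicon.canonical(c) for c in conditions if normalize_condition(c)]
    if any(t in lexicon.diseased_terms for t in terms):
        return Phenotype.DISEASED
    if any(t in lexicon.mild_terms for t in terms):
        return Phenotype.MILD
    if not terms:
        return Phenotype.HEALTHY
    return Phenotype.UNKNOWN


def annotate_cohort(
    cohort: CohortTable, lexicon: ConditionLexicon | None = None
) -> CohortTable:
    """Set the phenotype field for every sample with metadata (in place).

    Samples without a metadata entry are left unset and counted;
    re-annotation is idempotent (the phenotype is recomputed from the
    condition list each time).
    """
    lexicon = lexicon or default_lexicon()
    counts: Counter[str] = Counter()
    missing = 0
    for sample_id in cohort.sample_ids:
        meta = cohort.metadata.get(sample_id)
        if meta is None:
            missing += 1
            continue
        meta.phenotype = assign_phenotype(meta.conditions, lexicon).value
        counts[meta.phenotype] += 1
    logger.info(
        "phenotype counts: %s%s",
        dict(counts),
        f" ({missing} samples without metadata left unset)" if missing else "",
    )
    return cohort
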