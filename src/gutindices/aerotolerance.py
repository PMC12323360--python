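"""Taxon -> aerotolerance-category table behind the MAPI numerator/denominator.

The index contrasts taxa that tolerate oxygen (aerobes plus facultative
anaerobes, here "aerotolerant") against obligate ("strict") anaerobes.
Classification is at genus level, with species-level overrides consulted
first — the mechanism that lets *Bifidobacterium* be classified per
species while every other genus usually carries one genus-wide label.

The curated list the scores were designed around is an external input;
this package bundles a starter table covering common gut genera and
treats the table as fully swappable, so scores stay reproducible against
any curated list without code changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

from ._names import normalize_taxon_name
from .exceptions import ConflictError, ValidationError
from .profile_io import TaxonLineage

logger = logging.getLogger(__name__)


class AeroClass(str, Enum):
    AEROTOLERANT = "aerotolerant"
    STRICT_ANAEROBE = "strict_anaerobe"
    UNCLASSIFIED = "unclassified"


_CATEGORIES = {AeroClass.AEROTOLERANT.value, AeroClass.STRICT_ANAEROBE.value}
_LEVELS = {"genus", "species"}


@dataclass
class AerotoleranceTable:
    """Genus-level categories plus species-level overrides.

    Keys are normalized (case-folded, underscores unified to spaces);
    matching is exact after normalization, with no synonym resolution.
    """

    genus_map: dict[str, AeroClass] = field(default_factory=dict)
    species_overrides: dict[str, AeroClass] = field(default_factory=dict)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.genus_map) + len(self.species_overrides)


def load_classification(path: str | Path) -> AerotoleranceTable:
    """Load a classification TSV.

    Expected columns: ``taxon``, ``level`` (``genus``/``species``),
    ``category`` (``aerotolerant``/``strict_anaerobe``), and an optional
    free-text ``citation``. A header line is recognized and skipped.
    Identical duplicate rows are tolerated; conflicting duplicates are
    rejected.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    table = AerotoleranceTable(provenance=str(path))
    n_rows = 0
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = [c.strip() for c in line.split("\t")]
        if i == 1 and cells[0].casefold() == "taxon":
            continue
        if len(cells) < 3:
            raise ValidationError(
                f"{path}: line {i}: expected taxon, level, category"
            )
        taxon, level, category = cells[0], cells[1].casefold(), cells[2].casefold()
        if level not in _LEVELS:
            raise ValidationError(f"{path}: line {i}: unknown level {cells[1]!r}")
        if category not in _CATEGORIES:
            raise ValidationError(f"{path}: line {i}: unknown category {cells[2]!r}")
        key = normalize_taxon_name(taxon)
        target = table.genus_map if level == "genus" else table.species_overrides
        value = AeroClass(category)
        if key in target and target[key] is not value:
            raise ConflictError(
                f"{path}: line {i}: conflicting duplicate for {taxon!r} "
                f"({target[key].value} vs {category})"
            )
        target[key] = value
        n_rows += 1
    if n_rows == 0:
        logger.warning("%s: empty aerotolerance classification table", path)
    return table


def load_default_classification() -> AerotoleranceTable:
    """Load the starter table bundled with the package."""
    ref = resources.files("gutindices.data") / "aerotolerance.tsv"
    with resources.as_file(ref) as path:
        table = load_classification(path)
    table.provenance = "bundled starter table (gutindices.data/aerotolerance.tsv)"
    return table


def classify(lineage: TaxonLineage, table: AerotoleranceTable) -> AeroClass:
    """Classify a lineage, species overrides first, then the genus map.

    A pure function of its arguments; taxa matching neither map are
    ``UNCLASSIFIED`` (a value, not an error), so for any profile the
    aerotolerant, strict-anaerobe, and unclassified masses partition the
    total exactly.
    """
    if lineage.species is not None:
        override = table.species_overrides.get(normalize_taxon_name(lineage.species))
        if override is not None:
            return override
    if lineage.genus is not None:
        category = table.genus_map.get(normalize_taxon_name(lineage.genus))
        if category is not None:
            return category
    return AeroClass.UNCLASSIFIED
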