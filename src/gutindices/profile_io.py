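"""Parsing, harmonization, and I/O for taxonomic abundance tables.

Three TSV dialects are supported and funnel into one in-memory cohort
representation:

``microbiomehd``
    100% OTU tables with greengenes-style rank-prefixed lineages joined
    by ``|`` (e.g. ``k__Bacteria|g__Faecalibacterium|s__prausnitzii``).
``mgnify``
    Taxonomy-summary exports. Four documented fixes are applied before
    parsing (see :func:`apply_mgnify_fixes`).
``plain``
    A generic ``taxon<TAB>sample...`` table; the first column holds a
    lineage string, remaining columns one sample each.

Both ``;`` and ``|`` are accepted as lineage separators in every dialect:
the upstream pipelines convert between the two, so hard-failing on the
"wrong" separator would only punish files caught mid-conversion.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .exceptions import (
    DegenerateSampleError,
    FormatError,
    MalformedLineageError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Rank codes from highest to lowest assigned rank. "sk" (superkingdom)
#: is folded into "k" on parse.
RANK_ORDER = "kpcofgs"

DIALECTS = ("mgnify", "microbiomehd", "plain")

_RANK_TOKEN = re.compile(r"^(sk|[kpcofgs])__(.*)$")
_SEPARATORS = re.compile(r"[;|]")

#: Default pattern for the taxon-identifier artifact stripped by the
#: first of the four harmonization edits: a stray "s" prepended to the
#: "k__" kingdom prefix (i.e. a superkingdom "sk__" spelled where a
#: kingdom is expected). Exposed as a parameter because exports vary.
DEFAULT_OTU_PREFIX_PATTERN = r"^s(?=k__)"


def _clean_name(name: str) -> str:
    return " ".join(name.replace("_", " ").split())


@dataclass(frozen=True)
class TaxonLineage:
    """A parsed taxonomic rank ladder.

    ``ranks`` holds ``(rank_code, name)`` pairs from highest to lowest
    assigned rank, with codes drawn from ``kpcofgs`` in strictly
    descending order. ``species``, when present, is the full binomial
    ("Genus epithet"); ``genus`` is its first token.
    """

    ranks: tuple[tuple[str, str], ...]
    genus: str | None = None
    species: str | None = None

    def spelled(self, sep: str = ";", prefixed: bool = True) -> str:
        """Render the lineage back into a separator-joined string."""
        if prefixed:
            return sep.join(f"{code}__{name}" for code, name in self.ranks)
        return sep.join(name for _, name in self.ranks)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.spelled()


@dataclass
class AbundanceProfile:
    """Per-sample abundances (counts or proportions) over lineages."""

    sample_id: str
    abundances: dict[TaxonLineage, float] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(self.abundances.values()))

    def validate(self) -> None:
        for lineage, value in self.abundances.items():
            if value < 0 or not math.isfinite(value):
                raise ValidationError(
                    f"sample {self.sample_id!r}: abundance {value!r} for "
                    f"{lineage.spelled()} is not a finite non-negative number"
                )
        if self.total() <= 0:
            raise DegenerateSampleError(
                f"sample {self.sample_id!r} has zero total abundance"
            )


@dataclass
class SampleMetadata:
    """Survey covariates attached to one sample."""

    age: float | None = None
    gender: str = "unknown"
    conditions: list[str] = field(default_factory=list)
    phenotype: str | None = None


@dataclass
class CohortTable:
    """A set of abundance profiles plus per-sample survey metadata."""

    profiles: list[AbundanceProfile] = field(default_factory=list)
    metadata: dict[str, SampleMetadata] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def profile(self, sample_id: str) -> AbundanceProfile:
        for p in self.profiles:
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)

    def validate(self) -> tuple[list[str], list[str]]:
        """Check id uniqueness and profile/metadata agreement.

        Unmatched entries are reported (returned and logged), never
        silently dropped. Returns ``(profiles_without_metadata,
        metadata_without_profile)``.
        """
        ids = self.sample_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        known = set(ids)
        missing_meta = [i for i in ids if i not in self.metadata]
        orphan_meta = [k for k in self.metadata if k not in known]
        if missing_meta:
            logger.warning(
                "%d profile(s) without metadata: %s",
                len(missing_meta), missing_meta[:10],
            )
        if orphan_meta:
            logger.warning(
                "%d metadata row(s) without a profile: %s",
                len(orphan_meta), orphan_meta[:10],
            )
        return missing_meta, orphan_meta

    def to_frame(self):
        """Taxa x samples abundance matrix as a pandas DataFrame."""
        import pandas as pd

        taxa: dict[TaxonLineage, None] = {}
        for p in self.profiles:
            for lineage in p.abundances:
                taxa.setdefault(lineage)
        index = list(taxa)
        data = {
            p.sample_id: [p.abundances.get(t, 0.0) for t in index]
            for p in self.profiles
        }
        return pd.DataFrame(data, index=index)


def parse_lineage(lineage_string: str, dialect: str = "plain") -> TaxonLineage:
    """Parse one lineage string into a :class:`TaxonLineage`.

    Rank prefixes (``k__`` ... ``s__``, plus ``sk__`` folded into ``k``)
    are stripped into ``(rank, name)`` pairs; ``;`` and ``|`` are both
    accepted as separators; a leading ``Root`` element is discarded.
    When the species field holds a bare epithet it is joined with the
    genus into a binomial. Unprefixed strings are accepted only as a
    bare genus ("Prevotella") or binomial ("Prevotella copri").

    Raises
    ------
    MalformedLineageError
        For an empty string, a string with no parseable rank, or a rank
        ladder that does not strictly descend.
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    s = lineage_string.strip()
    if not s:
        raise MalformedLineageError("empty lineage string")
    tokens = [t.strip() for t in _SEPARATORS.split(s)]
    tokens = [t for t in tokens if t]
    if tokens and tokens[0].casefold() == "root":
        tokens = tokens[1:]
    if not tokens:
        raise MalformedLineageError(f"no taxon after 'Root' in {lineage_string!r}")

    prefixed = [bool(_RANK_TOKEN.match(t)) for t in tokens]
    ranks: list[tuple[str, str]] = []
    if any(prefixed):
        if not all(prefixed):
            bad = tokens[prefixed.index(False)]
            raise MalformedLineageError(
                f"mixed prefixed and bare elements in {lineage_string!r} "
                f"(offending element {bad!r})"
            )
        for token in tokens:
            m = _RANK_TOKEN.match(token)
            assert m is not None
            code = "k" if m.group(1) == "sk" else m.group(1)
            name = _clean_name(m.group(2))
            if not name:  # unassigned rank, e.g. bare "g__"
                continue
            ranks.append((code, name))
    else:
        if any("__" in t for t in tokens):
            raise MalformedLineageError(
                f"unrecognized rank prefix in {lineage_string!r}"
            )
        words = _clean_name(tokens[0]).split()
        if len(tokens) == 1 and len(words) == 1:
            ranks = [("g", words[0])]
        elif len(tokens) == 1 and len(words) == 2:
            ranks = [("g", words[0]), ("s", " ".join(words))]
        else:
            raise MalformedLineageError(
                f"no parseable rank in {lineage_string!r}"
            )

    if not ranks:
        raise MalformedLineageError(
            f"no assigned rank in {lineage_string!r} (all fields empty)"
        )
    positions = [RANK_ORDER.index(code) for code, _ in ranks]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise MalformedLineageError(
            f"rank order does not strictly descend in {lineage_string!r}"
        )

    by_code = dict(ranks)
    genus = by_code.get("g")
    species_name = by_code.get("s")
    species: str | None = None
    if species_name is not None:
        words = species_name.split()
        if len(words) >= 2:
            species = species_name
        elif genus is not None:
            species = f"{genus} {species_name}"
        # a bare epithet with no genus cannot form a binomial; the rank
        # entry is kept but `species` stays unset
    if genus is None and species is not None:
        genus = species.split()[0]
    if species is not None:
        # canonicalize the species rank entry to the full binomial so a
        # write/parse round trip is the identity
        ranks = [
            (code, species if code == "s" else name) for code, name in ranks
        ]
    return TaxonLineage(ranks=tuple(ranks), genus=genus, species=species)


def apply_mgnify_fixes(
    raw_table: Iterable[str],
    otu_prefix_pattern: str = DEFAULT_OTU_PREFIX_PATTERN,
) -> list[str]:
    """Apply the four harmonization edits to a taxonomy-summary table.

    In order: (i) strip the taxon-identifier prefix artifact matched by
    ``otu_prefix_pattern`` from the first field of each data line,
    (ii) remove every ``"Root;"`` occurrence, (iii) rename header cells
    equal to ``"SampleID"`` to ``"OTU ID"``, and (iv) replace every
    ``";"`` with ``"|"``. No other characters are altered. The composite
    is idempotent on typical exports (where a taxon identifier starts
    with either the prefix artifact or ``"Root;"``, not both nested).
    """
    lines = list(raw_table)
    if not lines or not lines[0].strip():
        raise FormatError("taxonomy-summary table is missing its header line")
    pattern = re.compile(otu_prefix_pattern)

    header, data = lines[0], lines[1:]
    # (i) taxon-id prefix artifact, first column of data lines only
    fixed = []
    for line in data:
        parts = line.split("\t")
        parts[0] = pattern.sub("", parts[0], count=1)
        fixed.append("\t".join(parts))
    # (ii) Root; occurrences, everywhere
    header = header.replace("Root;", "")
    fixed = [line.replace("Root;", "") for line in fixed]
    # (iii) header rename
    header = "\t".join(
        "OTU ID" if cell.strip() == "SampleID" else cell
        for cell in header.split("\t")
    )
    # (iv) separator conversion, everywhere
    return [line.replace(";", "|") for line in [header, *fixed]]


def _detect_orientation(rows: Sequence[Sequence[str]]) -> str:
    """Heuristic used only for ``orientation="auto"``.

    If the header cells beyond the first look like lineage strings
    (rank prefixes or multi-element ladders), samples must be on rows;
    otherwise the majority-numeric axis decides, defaulting to
    taxa-on-rows for square ambiguity.
    """
    header = rows[0][1:]
    if any("__" in cell or "|" in cell or ";" in cell for cell in header):
        return "samples_rows"

    def numeric_fraction(cells: Iterable[str]) -> float:
        cells = list(cells)
        ok = 0
        for c in cells:
            try:
                float(c)
                ok += 1
            except ValueError:
                pass
        return ok / max(len(cells), 1)

    first_col = [r[0] for r in rows[1:]]
    # lineage labels in column 0 are non-numeric; sample ids may be numeric
    if numeric_fraction(first_col) > 0.5:
        return "samples_rows"
    return "taxa_rows"


def read_abundance_table(
    path: str | Path,
    dialect: str = "plain",
    orientation: str = "taxa_rows",
) -> CohortTable:
    """Read a TSV abundance table into a :class:`CohortTable`.

    One :class:`AbundanceProfile` is created per sample column (or row,
    with ``orientation="samples_rows"``). Duplicate lineage rows —
    legitimate in 100% OTU tables, where many OTUs share an assignment —
    are summed. Metadata is left unset. Zero cells are dropped from the
    sparse per-sample maps.
    """
    if orientation not in ("taxa_rows", "samples_rows", "auto"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: empty table")
    if dialect == "mgnify":
        lines = apply_mgnify_fixes(lines)
    elif dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")

    rows = [line.split("\t") for line in lines]
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row {i + 1} has {len(row)} fields, expected {width}"
            )
    if width < 2 or len(rows) < 2:
        raise FormatError(f"{path}: need at least one taxon and one sample")

    if orientation == "auto":
        orientation = _detect_orientation(rows)
        logger.info("auto-detected orientation %s for %s", orientation, path)
    if orientation == "samples_rows":
        rows = [list(r) for r in zip(*rows)]

    sample_ids = [c.strip() for c in rows[0][1:]]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample columns")

    sums: dict[TaxonLineage, list[float]] = {}
    for i, row in enumerate(rows[1:], start=2):
        lineage = parse_lineage(row[0], dialect)
        values = []
        for j, cell in enumerate(row[1:], start=2):
            try:
                v = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric cell at row {i}, column {j}: {cell!r}"
                ) from exc
            if v < 0 or not math.isfinite(v):
                raise ValidationError(
                    f"{path}: negative or non-finite abundance {cell!r} "
                    f"at row {i}, column {j}"
                )
            values.append(v)
        acc = sums.setdefault(lineage, [0.0] * len(sample_ids))
        for k, v in enumerate(values):
            acc[k] += v

    profiles = []
    for k, sid in enumerate(sample_ids):
        abund = {t: vec[k] for t, vec in sums.items() if vec[k] != 0.0}
        if not abund:
            logger.warning("%s: sample %r has zero total abundance", path, sid)
        profiles.append(AbundanceProfile(sample_id=sid, abundances=abund))
    return CohortTable(profiles=profiles)


def to_relative(profile: AbundanceProfile) -> AbundanceProfile:
    """Convert a profile to relative abundances summing to 1."""
    total = profile.total()
    if total <= 0:
        raise DegenerateSampleError(
            f"sample {profile.sample_id!r} has zero total abundance"
        )
    return AbundanceProfile(
        sample_id=profile.sample_id,
        abundances={t: v / total for t, v in profile.abundances.items()},
    )


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    """Write the plain-dialect TSV (taxon column + one column per sample).

    Cell values are written with ``repr`` so that a write/read round
    trip reproduces each float exactly.
    """
    taxa: dict[TaxonLineage, None] = {}
    for p in cohort.profiles:
        for lineage in p.abundances:
            taxa.setdefault(lineage)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon\t" + "\t".join(cohort.sample_ids) + "\n")
        for lineage in taxa:
            cells = [repr(float(p.abundances.get(lineage, 0.0))) for p in cohort.profiles]
            fh.write(lineage.spelled(";") + "\t" + "\t".join(cells) + "\n")


_METADATA_COLUMNS = ("sample_id", "age", "gender", "conditions", "phenotype")


def write_metadata_table(
    metadata: Mapping[str, SampleMetadata], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_METADATA_COLUMNS) + "\n")
        for sid, meta in metadata.items():
            age = "" if meta.age is None else repr(float(meta.age))
            fh.write(
                "\t".join(
                    [
                        sid,
                        age,
                        meta.gender,
                        ";".join(meta.conditions),
                        meta.phenotype or "",
                    ]
                )
                + "\n"
            )


def read_metadata_table(path: str | Path) -> dict[str, SampleMetadata]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: empty metadata table")
    header = [c.strip() for c in lines[0].split("\t")]
    if header[0] != "sample_id":
        raise FormatError(f"{path}: metadata header must start with 'sample_id'")
    idx = {name: header.index(name) for name in header}
    out: dict[str, SampleMetadata] = {}
    for i, line in enumerate(lines[1:], start=2):
        row = line.split("\t")
        if len(row) != len(header):
            raise FormatError(f"{path}: ragged metadata row {i}")
        sid = row[idx["sample_id"]].strip()
        if sid in out:
            raise ValidationError(f"{path}: duplicate sample id {sid!r} at row {i}")
        age_cell = row[idx["age"]].strip() if "age" in idx else ""
        conditions_cell = row[idx["conditions"]] if "conditions" in idx else ""
        out[sid] = SampleMetadata(
            age=float(age_cell) if age_cell else None,
            gender=(row[idx["gender"]].strip() or "unknown") if "gender" in idx else "unknown",
            conditions=[c.strip() for c in conditions_cell.split(";") if c.strip()],
            phenotype=(row[idx["phenotype"]].strip() or None) if "phenotype" in idx else None,
        )
    return out
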