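"""Keystone score: summed cohort Z-scores of six keystone species.

Keystone species are strictly anaerobic gut commensals posited to carry
functions essential to microbiome balance ("ecosystem engineers"). For
each panel species the per-sample relative proportion p is transformed
as L = log10(p + pseudocount), Z-scored against the whole analyzed
cohort (sample SD, n-1 denominator), and the per-sample keystone score
is the sum of the six Z-scores. By construction each Z column has mean
0 and SD 1 (or is identically 0 when a species shows no variation), so
the keystone scores of a cohort always sum to 0: the score ranks
samples within a cohort rather than carrying absolute meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._names import normalize_taxon_name
from .exceptions import (
    AmbiguityError,
    InsufficientCohortError,
    ValidationError,
)
from .profile_io import CohortTable, to_relative

#: The six-species panel used throughout: strict anaerobes (and one
#: methanogenic archaeon) recurrently depleted under gut dysbiosis.
DEFAULT_KEYSTONE_SPECIES = (
    "Akkermansia muciniphila",
    "Bifidobacterium longum",
    "Christensenella minuta",
    "Faecalibacterium prausnitzii",
    "Methanobrevibacter smithii",
    "Ruminococcus bromii",
)

#: Default pseudocount on the relative-abundance scale for log10 of
#: absent species; a fixed floor keeps Z-scores comparable across
#: cohorts profiled at different depths.
DEFAULT_KEYSTONE_PSEUDOCOUNT = 1e-6


@dataclass(frozen=True)
class KeystonePanel:
    """An ordered list of unique species binomials."""

    species: tuple[str, ...] = field(default=DEFAULT_KEYSTONE_SPECIES)

    def __post_init__(self) -> None:
        if not self.species:
            raise ValidationError("keystone panel must be non-empty")
        normalized = [normalize_taxon_name(s) for s in self.species]
        if len(set(normalized)) != len(normalized):
            raise ValidationError("keystone panel binomials must be unique")

    @classmethod
    def from_file(cls, path) -> "KeystonePanel":
        """One binomial per line; blank lines and '#' comments ignored."""
        from pathlib import Path

        names = [
            line.strip()
            for line in Path(path).read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        ]
        return cls(species=tuple(names))


def extract_keystone_matrix(
    cohort: CohortTable, panel: KeystonePanel | None = None
) -> pd.DataFrame:
    """Samples x species matrix of panel relative proportions.

    Matching is on the parsed binomial after case/space normalization;
    a species absent from a sample yields 0. A panel binomial matching
    more than one distinct lineage in a sample is an error (the caller
    must harmonize the table first).
    """
    panel = panel or KeystonePanel()
    lookup = {normalize_taxon_name(s): s for s in panel.species}
    rows = []
    for profile in cohort.profiles:
        rel = to_relative(profile)
        hits: dict[str, list] = {s: [] for s in panel.species}
        for lineage, value in rel.abundances.items():
            if lineage.species is None:
                continue
            name = lookup.get(normalize_taxon_name(lineage.species))
            if name is not None:
                hits[name].append((lineage, value))
        for name, matched in hits.items():
            if len(matched) > 1:
                spelled = [lin.spelled() for lin, _ in matched]
                raise AmbiguityError(
                    f"sample {profile.sample_id!r}: panel species {name!r} "
                    f"matches multiple lineages: {spelled}"
                )
        rows.append([hits[s][0][1] if hits[s] else 0.0 for s in panel.species])
    return pd.DataFrame(
        rows,
        index=pd.Index([p.sample_id for p in cohort.profiles], name="sample_id"),
        columns=list(panel.species),
        dtype=float,
    )


def keystone_zscores(
    matrix: pd.DataFrame, pseudocount: float = DEFAULT_KEYSTONE_PSEUDOCOUNT
) -> pd.DataFrame:
    """Column-wise Z-scores of log10(p + pseudocount).

    A species constant across the cohort (SD 0) gets an all-zero
    column rather than a division by zero.
    """
    if pseudocount <= 0:
        raise ValidationError("keystone pseudocount must be positive")
    if matrix.shape[0] < 2:
        raise InsufficientCohortError(
            "keystone Z-scores need at least 2 samples (sample SD undefined)"
        )
    if (matrix.to_numpy() < 0).any():
        raise ValidationError("negative relative proportion in keystone matrix")
    log_abund = np.log10(matrix + pseudocount)
    mean = log_abund.mean(axis=0)
    sd = log_abund.std(axis=0, ddof=1)
    z = (log_abund - mean).div(sd.where(sd > 0, np.inf), axis=1)
    return z


def keystone_score(zmatrix: pd.DataFrame) -> pd.Series:
    """Per-sample keystone score: row sum of the Z-matrix."""
    values = zmatrix.to_numpy()
    if not np.isfinite(values).all():
        raise ValidationError("keystone Z-matrix contains non-finite values")
    return zmatrix.sum(axis=1).rename("keystone")
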