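"""Metagenomic aerotolerant predominance index (MAPI).

For one sample the score is the natural logarithm of the ratio of the
summed abundance of aerotolerant taxa (A) to the summed abundance of
strict anaerobic taxa (S):

    MAPI = ln(A / S)

A score above 0 indicates predominance of aerotolerant organisms; a
negative score a higher relative abundance of anaerobes. Because the
ratio is of sums within one sample, the score is identical on counts
and on proportions (scale invariant), and taxa classified as neither
category have no influence.

When exactly one of the two sums is zero the ratio is undefined; a
symmetric pseudocount added to *both* sums keeps such edge samples
finite without moving the A = S balance point, and its use is flagged
per sample for auditability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .aerotolerance import AeroClass, AerotoleranceTable, classify
from .exceptions import (
    ComputationError,
    EmptyInputError,
    NoClassifiedMassError,
    UndefinedScoreError,
    ValidationError,
)
from .profile_io import AbundanceProfile, CohortTable

logger = logging.getLogger(__name__)

#: Default symmetric pseudocount, on the relative-abundance scale,
#: applied only when one category sum is zero.
DEFAULT_PSEUDOCOUNT = 1e-6


@dataclass
class MapiResult:
    """Per-sample MAPI with its component masses."""

    sample_id: str
    aero_mass: float
    anaero_mass: float
    unclassified_mass: float
    mapi: float
    pseudocount_used: bool = False


def compute_mapi(
    profile: AbundanceProfile,
    table: AerotoleranceTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> MapiResult:
    """Compute the MAPI score for one profile.

    Raises
    ------
    NoClassifiedMassError
        If neither category receives any mass.
    UndefinedScoreError
        If one category sum is zero and ``pseudocount`` is 0.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    aero = anaero = unclassified = 0.0
    for lineage, value in profile.abundances.items():
        if value < 0:
            raise ValidationError(
                f"sample {profile.sample_id!r}: negative abundance for "
                f"{lineage.spelled()}"
            )
        category = classify(lineage, table)
        if category is AeroClass.AEROTOLERANT:
            aero += value
        elif category is AeroClass.STRICT_ANAEROBE:
            anaero += value
        else:
            unclassified += value

    if aero == 0.0 and anaero == 0.0:
        raise NoClassifiedMassError(
            f"sample {profile.sample_id!r}: no aerotolerant or strict-anaerobe "
            "mass; MAPI is undefined"
        )
    a, s = aero, anaero
    used = False
    if a == 0.0 or s == 0.0:
        if pseudocount == 0.0:
            raise UndefinedScoreError(
                f"sample {profile.sample_id!r}: zero "
                f"{'aerotolerant' if a == 0.0 else 'strict-anaerobe'} mass "
                "with pseudocount 0"
            )
        a += pseudocount
        s += pseudocount
        used = True
    return MapiResult(
        sample_id=profile.sample_id,
        aero_mass=aero,
        anaero_mass=anaero,
        unclassified_mass=unclassified,
        mapi=math.log(a / s),
        pseudocount_used=used,
    )


def mapi_batch(
    cohort: CohortTable,
    table: AerotoleranceTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[list[MapiResult], dict[str, str]]:
    """Score every profile in a cohort, isolating per-sample failures.

    Returns the order-preserving list of successful results and a map
    of sample id -> failure message for degenerate profiles; a bad
    sample never aborts the batch.
    """
    if not cohort.profiles:
        raise EmptyInputError("cannot score an empty cohort")
    results: list[MapiResult] = []
    failures: dict[str, str] = {}
    for profile in cohort.profiles:
        try:
            results.append(compute_mapi(profile, table, pseudocount))
        except ComputationError as exc:
            failures[profile.sample_id] = str(exc)
    if failures:
        logger.warning(
            "MAPI undefined for %d of %d samples", len(failures), len(cohort.profiles)
        )
    return results, failures
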