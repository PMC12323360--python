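"""Synthetic gut-microbiome cohorts with controllable index structure.

The generator emulates the statistical structure the two indices assume
rather than sequencing reality: each sample gets a target MAPI drawn
from a phenotype- and age-dependent normal distribution, an abundance
profile constructed to hit that target exactly, log-normal keystone
species abundances with graded phenotype shifts, and survey metadata
(age, gender, condition lists) consistent with its phenotype bin.

Construction inverts the MAPI definition: for a target score m the
aerotolerant share of classified mass is the logistic 1/(1 + e^-m),
masses within each category are split by a symmetric Dirichlet, and the
six keystone species (all strict anaerobes) receive their log-normal
draws out of the strict-anaerobe budget, with the remaining anaerobe
genera scaled to fill it. The recomputed MAPI of a generated profile
therefore equals its target to floating-point precision.

Default calibration: the healthy phenotype reproduces the published
healthy distribution (mean -5.2, SD 1.8 natural-log units); the mild
and diseased means sit +0.5 and +1.0 above it — invented effect sizes
chosen so group tests at realistic n separate while the distributions
overlap heavily. Age effects are mean-zero contrasts within each
phenotype (+0.5 for the 61+ bins against the rest), so the phenotype
marginal mean stays at its calibrated value while scores still increase
with age. Keystone log10 means sit in plausible gut ranges; disease
depresses them by 0.5 log10 units (mild: half), except for
Methanobrevibacter smithii whose anomalous direction is preserved by a
zero shift multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.special import expit

from .demographics import AGE_BINS, commercial_age_counts, commercial_gender_counts
from .exceptions import ConfigError
from .keystone import DEFAULT_KEYSTONE_SPECIES
from .phenotype import DEFAULT_DISEASED_TERMS, DEFAULT_MILD_TERMS
from .profile_io import AbundanceProfile, CohortTable, SampleMetadata, TaxonLineage

PHENOTYPES = ("healthy", "mild", "diseased")

#: Genus panels nested inside the bundled aerotolerance starter table,
#: so generated cohorts score without extra configuration. Keystone
#: species live among the strict anaerobes; Bifidobacterium enters only
#: through B. longum because its classification is species-level.
DEFAULT_AERO_GENERA = (
    "Escherichia",
    "Klebsiella",
    "Enterococcus",
    "Streptococcus",
    "Lactobacillus",
)
DEFAULT_ANAERO_GENERA = (
    "Bacteroides",
    "Prevotella",
    "Alistipes",
    "Blautia",
    "Roseburia",
    "Coprococcus",
    "Faecalibacterium",
    "Ruminococcus",
    "Akkermansia",
    "Christensenella",
    "Methanobrevibacter",
)

DEFAULT_KEYSTONE_LOG10_MEAN = {
    "Akkermansia muciniphila": -2.0,
    "Bifidobacterium longum": -2.0,
    "Christensenella minuta": -3.0,
    "Faecalibacterium prausnitzii": -1.5,
    "Methanobrevibacter smithii": -3.0,
    "Ruminococcus bromii": -2.0,
}

_ARCHAEAL_GENERA = {"Methanobrevibacter"}


def _age_bin_frequencies() -> dict[str, float]:
    counts = commercial_age_counts()
    total = sum(counts.values())
    return {label: count / total for label, count in counts.items()}


def _gender_frequencies() -> dict[str, float]:
    counts = commercial_gender_counts()
    total = sum(counts.values())
    return {label: count / total for label, count in counts.items()}


@dataclass
class SimConfig:
    """Cohort generator parameters; defaults are the study conditions."""

    n: dict[str, int] = field(
        default_factory=lambda: {"healthy": 200, "mild": 200, "diseased": 200}
    )
    mapi_mean: dict[str, float] = field(
        default_factory=lambda: {"healthy": -5.2, "mild": -4.7, "diseased": -4.2}
    )
    mapi_sd: float = 1.8
    age_bin_freqs: dict[str, float] = field(default_factory=_age_bin_frequencies)
    #: Added mean shift per age bin (natural-log units), applied as a
    #: mean-zero contrast when ``center_age_effect`` is set.
    age_effect: dict[str, float] = field(
        default_factory=lambda: {"61-70": 0.5, "71-80": 0.5, "81+": 0.5}
    )
    center_age_effect: bool = True
    gender_freqs: dict[str, float] = field(default_factory=_gender_frequencies)
    keystone_log10_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KEYSTONE_LOG10_MEAN)
    )
    keystone_log10_sd: float = 0.5
    #: log10 units subtracted from keystone means in the diseased bin
    #: (mild gets ``mild_fraction`` of it), scaled per species by
    #: ``keystone_shift_multiplier`` (default 1; M. smithii 0).
    keystone_disease_shift: float = 0.5
    keystone_mild_fraction: float = 0.5
    keystone_shift_multiplier: dict[str, float] = field(
        default_factory=lambda: {"Methanobrevibacter smithii": 0.0}
    )
    aero_genera: tuple[str, ...] = DEFAULT_AERO_GENERA
    anaero_genera: tuple[str, ...] = DEFAULT_ANAERO_GENERA
    dirichlet_concentration: float = 1.0
    #: Mass routed to taxa outside both categories (0 disables).
    unclassified_fraction: float = 0.0
    unclassified_genera: tuple[str, ...] = ("UnassignedA", "UnassignedB")
    seed: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in self.n.values()):
            raise ConfigError("sample sizes must be non-negative")
        if set(self.n) - set(PHENOTYPES):
            raise ConfigError(f"unknown phenotypes in n: {sorted(set(self.n) - set(PHENOTYPES))}")
        if self.mapi_sd < 0:
            raise ConfigError("mapi_sd must be non-negative")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be positive")
        if not self.aero_genera or not self.anaero_genera:
            raise ConfigError("both taxon panel categories must be non-empty")
        if not 0 <= self.unclassified_fraction < 1:
            raise ConfigError("unclassified_fraction must lie in [0, 1)")
        if self.keystone_log10_sd < 0:
            raise ConfigError("keystone_log10_sd must be non-negative")
        for name, freqs in (("age_bin_freqs", self.age_bin_freqs),
                            ("gender_freqs", self.gender_freqs)):
            if not freqs or any(v < 0 for v in freqs.values()) or sum(freqs.values()) <= 0:
                raise ConfigError(f"{name} must be non-negative with positive total")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown SimConfig keys {sorted(unknown)}")
        for key in ("aero_genera", "anaero_genera", "unclassified_genera"):
            if key in raw:
                raw[key] = tuple(raw[key])
        config = cls(**raw)
        config.validate()
        return config


def _genus_lineage(genus: str) -> TaxonLineage:
    kingdom = "Archaea" if genus in _ARCHAEAL_GENERA else "Bacteria"
    return TaxonLineage(ranks=(("k", kingdom), ("g", genus)), genus=genus)


def _species_lineage(binomial: str) -> TaxonLineage:
    genus = binomial.split()[0]
    kingdom = "Archaea" if genus in _ARCHAEAL_GENERA else "Bacteria"
    return TaxonLineage(
        ranks=(("k", kingdom), ("g", genus), ("s", binomial)),
        genus=genus,
        species=binomial,
    )


def profile_from_target_mapi(
    m: float,
    aero_genera: Sequence[str] = DEFAULT_AERO_GENERA,
    anaero_genera: Sequence[str] = DEFAULT_ANAERO_GENERA,
    concentration: float = 1.0,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
) -> AbundanceProfile:
    """Build a relative-abundance profile whose MAPI equals ``m``.

    The aerotolerant fraction of (unit) classified mass is the logistic
    1/(1 + e^-m); within-category masses follow a symmetric Dirichlet.
    """
    if not aero_genera or not anaero_genera:
        raise ConfigError("both taxon panel categories must be non-empty")
    if concentration <= 0:
        raise ConfigError("dirichlet concentration must be positive")
    rng = rng or np.random.default_rng()
    f = float(expit(m))
    aero_w = rng.dirichlet([concentration] * len(aero_genera))
    anaero_w = rng.dirichlet([concentration] * len(anaero_genera))
    abundances = {
        _genus_lineage(g): f * w for g, w in zip(aero_genera, aero_w)
    }
    abundances.update(
        {_genus_lineage(g): (1.0 - f) * w for g, w in zip(anaero_genera, anaero_w)}
    )
    return AbundanceProfile(sample_id=sample_id, abundances=abundances)


def _phenotype_conditions(phenotype: str, rng: np.random.Generator) -> list[str]:
    mild = sorted(DEFAULT_MILD_TERMS)
    diseased = sorted(DEFAULT_DISEASED_TERMS)
    if phenotype == "healthy":
        return []
    if phenotype == "mild":
        k = int(rng.integers(1, 3))
        return [str(c) for c in rng.choice(mild, size=k, replace=False)]
    conditions = [str(rng.choice(diseased))]
    if rng.random() < 0.5:
        conditions.append(str(rng.choice(mild)))
    return conditions


def _draw_age(bin_label: str, rng: np.random.Generator) -> int:
    for label, low, high in AGE_BINS:
        if label == bin_label:
            return int(rng.integers(low, (high if high is not None else low + 9) + 1))
    raise ConfigError(f"unknown age bin {bin_label!r}")


def generate_cohort(config: SimConfig | None = None) -> CohortTable:
    """Generate a cohort, fully reproducible from ``config.seed``.

    A single RNG stream is consumed in a fixed order — phenotypes in
    (healthy, mild, diseased) order, and per sample: age bin, age,
    gender, MAPI noise, keystone log-normal draws, aerotolerant
    Dirichlet, anaerobe Dirichlet, (unclassified Dirichlet when
    enabled), then condition terms — so identical configs yield
    identical cohorts.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    age_labels = list(config.age_bin_freqs)
    age_p = np.asarray([config.age_bin_freqs[b] for b in age_labels], dtype=float)
    age_p = age_p / age_p.sum()
    gender_labels = list(config.gender_freqs)
    gender_p = np.asarray([config.gender_freqs[g] for g in gender_labels], dtype=float)
    gender_p = gender_p / gender_p.sum()

    effect = np.asarray([config.age_effect.get(b, 0.0) for b in age_labels])
    if config.center_age_effect:
        effect = effect - float(effect @ age_p)
    effect_by_bin = dict(zip(age_labels, effect))

    species = list(DEFAULT_KEYSTONE_SPECIES)
    keystone_mu = np.asarray(
        [config.keystone_log10_mean[s] for s in species], dtype=float
    )
    multiplier = np.asarray(
        [config.keystone_shift_multiplier.get(s, 1.0) for s in species], dtype=float
    )
    shift_scale = {"healthy": 0.0, "mild": config.keystone_mild_fraction, "diseased": 1.0}

    classified = 1.0 - config.unclassified_fraction
    profiles: list[AbundanceProfile] = []
    metadata: dict[str, SampleMetadata] = {}
    aero_lineages = [_genus_lineage(g) for g in config.aero_genera]
    anaero_lineages = [_genus_lineage(g) for g in config.anaero_genera]
    keystone_lineages = [_species_lineage(s) for s in species]
    unclass_lineages = [_genus_lineage(g) for g in config.unclassified_genera]

    for phenotype in PHENOTYPES:
        mu = keystone_mu - config.keystone_disease_shift * shift_scale[phenotype] * multiplier
        for i in range(config.n.get(phenotype, 0)):
            bin_label = age_labels[rng.choice(len(age_labels), p=age_p)]
            age = _draw_age(bin_label, rng)
            gender = gender_labels[rng.choice(len(gender_labels), p=gender_p)]
            m = config.mapi_mean[phenotype] + effect_by_bin[bin_label]
            if config.mapi_sd > 0:
                m += rng.normal(0.0, config.mapi_sd)

            f = float(expit(m))
            aero_mass = f * classified
            anaero_mass = (1.0 - f) * classified
            keystone_abund = 10.0 ** rng.normal(mu, config.keystone_log10_sd)
            cap = 0.9 * anaero_mass
            total_keystone = float(keystone_abund.sum())
            if total_keystone > cap:
                keystone_abund *= cap / total_keystone
                total_keystone = cap
            aero_w = rng.dirichlet([config.dirichlet_concentration] * len(aero_lineages))
            anaero_w = rng.dirichlet(
                [config.dirichlet_concentration] * len(anaero_lineages)
            )

            abundances: dict[TaxonLineage, float] = {}
            for lineage, w in zip(aero_lineages, aero_w):
                abundances[lineage] = float(aero_mass * w)
            remainder = anaero_mass - total_keystone
            for lineage, w in zip(anaero_lineages, anaero_w):
                abundances[lineage] = float(remainder * w)
            for lineage, value in zip(keystone_lineages, keystone_abund):
                abundances[lineage] = float(value)
            if config.unclassified_fraction > 0:
                unclass_w = rng.dirichlet(
                    [config.dirichlet_concentration] * len(unclass_lineages)
                )
                for lineage, w in zip(unclass_lineages, unclass_w):
                    abundances[lineage] = float(config.unclassified_fraction * w)

            sample_id = f"{phenotype}_{i:05d}"
            profiles.append(AbundanceProfile(sample_id=sample_id, abundances=abundances))
            metadata[sample_id] = SampleMetadata(
                age=float(age),
                gender=gender,
                conditions=_phenotype_conditions(phenotype, rng),
                phenotype=phenotype,
            )
    return CohortTable(profiles=profiles, metadata=metadata)
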