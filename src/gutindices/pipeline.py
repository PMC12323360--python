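"""End-to-end orchestration: read -> harmonize -> classify -> score ->
bin -> compare -> report.

Outputs are pure functions of inputs plus configuration: no wall-clock
timestamps or locale-dependent formatting appear in any written value,
and files are written atomically (temp file + rename) with partial
outputs removed on failure. The run log records the package version, a
configuration hash, and every exclusion (unknown phenotypes, samples
whose score is undefined, bins dropped for size) so censoring is
visible rather than silent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aerotolerance import AerotoleranceTable, load_classification, load_default_classification
from .cohort_stats import TestResult, compare_by_bins, group_summary
from .demographics import age_to_bin
from .exceptions import ConfigError, InsufficientCohortError
from .keystone import (
    DEFAULT_KEYSTONE_PSEUDOCOUNT,
    KeystonePanel,
    extract_keystone_matrix,
    keystone_score,
    keystone_zscores,
)
from .mapi import DEFAULT_PSEUDOCOUNT, mapi_batch
from .phenotype import ConditionLexicon, annotate_cohort, default_lexicon, load_lexicon
from .profile_io import CohortTable, read_abundance_table, read_metadata_table

logger = logging.getLogger(__name__)

SCORE_COLUMNS = (
    "sample_id",
    "mapi",
    "aero_mass",
    "anaero_mass",
    "unclassified_mass",
    "pseudocount_used",
    "keystone",
    "phenotype",
    "age",
    "age_bin",
    "gender",
    "error",
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    table: str
    dialect: str = "plain"
    orientation: str = "taxa_rows"
    metadata: str | None = None
    aerotolerance_table: str | None = None  # None -> bundled starter table
    keystone_panel: str | None = None  # None -> default six species
    lexicon: str | None = None  # None -> bundled condition lexicon
    mapi_pseudocount: float = DEFAULT_PSEUDOCOUNT
    keystone_pseudocount: float = DEFAULT_KEYSTONE_PSEUDOCOUNT
    compare_by: str = "phenotype"
    scheme: str = "omnibus"
    value_field: str = "mapi"
    out_dir: str = "results"

    def validate_paths(self) -> None:
        """Fail fast: every referenced input must exist before any compute."""
        for name in ("table", "metadata", "aerotolerance_table", "keystone_panel", "lexicon"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown RunConfig keys {sorted(unknown)}")
        if "table" not in raw:
            raise ConfigError(f"{path}: 'table' is required")
        config = cls(**raw)
        config.validate_paths()
        return config

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_score_table(
    cohort: CohortTable,
    aero_table: AerotoleranceTable,
    panel: KeystonePanel | None = None,
    mapi_pseudocount: float = DEFAULT_PSEUDOCOUNT,
    keystone_pseudocount: float = DEFAULT_KEYSTONE_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-sample score table combining MAPI, keystone, and metadata.

    Samples whose MAPI is undefined keep their row with a NaN score and
    the failure message in the ``error`` column. Keystone scores are
    referenced to the whole scored cohort; with fewer than 2 samples
    they are left missing.
    """
    results, failures = mapi_batch(cohort, aero_table, mapi_pseudocount)
    by_id = {r.sample_id: r for r in results}

    keystone: pd.Series | None = None
    try:
        matrix = extract_keystone_matrix(cohort, panel)
        keystone = keystone_score(keystone_zscores(matrix, keystone_pseudocount))
    except InsufficientCohortError:
        logger.warning("fewer than 2 samples; keystone scores left unset")

    rows = []
    for profile in cohort.profiles:
        sid = profile.sample_id
        meta = cohort.metadata.get(sid)
        result = by_id.get(sid)
        rows.append(
            {
                "sample_id": sid,
                "mapi": result.mapi if result else math.nan,
                "aero_mass": result.aero_mass if result else math.nan,
                "anaero_mass": result.anaero_mass if result else math.nan,
                "unclassified_mass": result.unclassified_mass if result else math.nan,
                "pseudocount_used": bool(result.pseudocount_used) if result else False,
                "keystone": float(keystone[sid]) if keystone is not None else math.nan,
                "phenotype": meta.phenotype if meta else None,
                "age": meta.age if meta else None,
                "age_bin": age_to_bin(meta.age) if meta else None,
                "gender": meta.gender if meta else None,
                "error": failures.get(sid),
            }
        )
    return pd.DataFrame(rows, columns=list(SCORE_COLUMNS))


def test_results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "method": r.method,
                "groups": "|".join(r.groups),
                "n_per_group": "|".join(str(n) for n in r.n_per_group),
                "statistic": r.statistic,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted if r.p_adjusted is not None else np.nan,
                "mode": r.details.get("mode", ""),
                "df": r.details.get("df", ""),
            }
        )
    return pd.DataFrame(rows)


def _write_atomic(frame_or_text, path: Path, is_frame: bool = True) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    try:
        if is_frame:
            frame_or_text.to_csv(tmp, sep="\t", index=False, float_format="%.6f")
        else:
            tmp.write_text(frame_or_text, encoding="utf-8")
        os.replace(tmp, path)
    except BaseException:
        tmp.unlink(missing_ok=True)
        raise


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline; returns the paths of the four outputs.

    Identical config + inputs produce byte-identical outputs. On any
    stage failure the partially written files from this run are removed
    and the error propagates.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "scores": out_dir / "scores.tsv",
        "comparisons": out_dir / "comparisons.tsv",
        "group_summary": out_dir / "group_summary.tsv",
        "run_log": out_dir / "run_log.json",
    }
    written: list[Path] = []
    try:
        aero = (
            load_classification(config.aerotolerance_table)
            if config.aerotolerance_table
            else load_default_classification()
        )
        panel = (
            KeystonePanel.from_file(config.keystone_panel)
            if config.keystone_panel
            else KeystonePanel()
        )
        lexicon: ConditionLexicon = (
            load_lexicon(config.lexicon) if config.lexicon else default_lexicon()
        )
        cohort = read_abundance_table(config.table, config.dialect, config.orientation)
        if config.metadata:
            cohort.metadata = read_metadata_table(config.metadata)
        missing_meta, orphan_meta = cohort.validate()
        annotate_cohort(cohort, lexicon)

        scores = build_score_table(
            cohort, aero, panel, config.mapi_pseudocount, config.keystone_pseudocount
        )
        comparisons = compare_by_bins(
            scores, config.compare_by, config.scheme, config.value_field
        )
        summaries = group_summary(scores, config.compare_by, config.value_field)

        _write_atomic(scores, outputs["scores"])
        written.append(outputs["scores"])
        _write_atomic(test_results_to_frame(comparisons), outputs["comparisons"])
        written.append(outputs["comparisons"])
        summary_frame = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
        _write_atomic(summary_frame, outputs["group_summary"])
        written.append(outputs["group_summary"])

        phenotype_counts = scores["phenotype"].value_counts(dropna=False)
        log = {
            "package": "gutindices",
            "version": __version__,
            "config_hash": config.hash(),
            "config": dataclasses.asdict(config),
            "n_samples": int(len(scores)),
            "n_score_failures": int(scores["error"].notna().sum()),
            "n_profiles_without_metadata": len(missing_meta),
            "n_metadata_without_profile": len(orphan_meta),
            "phenotype_counts": {str(k): int(v) for k, v in phenotype_counts.items()},
            "n_unknown_phenotype_excluded": int((scores["phenotype"] == "unknown").sum()),
        }
        _write_atomic(json.dumps(log, indent=2, sort_keys=True) + "\n",
                      outputs["run_log"], is_frame=False)
        written.append(outputs["run_log"])
    except BaseException:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return outputs
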