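"""Cohort CSV I/O, model persistence and the end-to-end pipeline.

The single cohort format is a flat CSV with the 13 canonical scale columns,
the four demographic columns and a binary ``diagnosis`` column.  Classifier
models persist as versioned JSON; the pipeline runs match -> learn(x2) ->
evaluate -> compare-correlations -> what-if and writes a manifest recording
the configuration, seed and library versions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (ClassifierModel, baseline_scale278, evaluate_rsscv,
                         fit_classifier)
from .cohort import Cohort
from .correlations import permutation_equality_test
from .errors import MmpiBnError, ModelFormatError
from .gbn import (arc_strength, dag_to_graphml, network_from_json,
                  network_to_json, save_network)
from .matching import match_study
from .scales import CANONICAL_SCALES, DEMOGRAPHIC_COLUMNS, LABEL_COLUMN
from .simulate import StudyConfig, make_two_group_study, mmpi2_preset
from .whatif import whatif_difference_table, whatif_tables_to_frame

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "save_model",
    "load_model",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("mmpibn")

MODEL_FORMAT = "mmpibn-classifier"
MODEL_VERSION = 1

_REQUIRED = (*CANONICAL_SCALES, *DEMOGRAPHIC_COLUMNS, LABEL_COLUMN)


def read_cohort_csv(path, mapping: dict[str, str] | None = None) -> Cohort:
    """Read a cohort CSV, mapping columns to canonical order.

    ``mapping`` translates canonical names to the file's column names.
    Missing columns, missing values and non-numeric cells are rejected with
    the offending location.
    """
    raw = pd.read_csv(path)
    mapping = mapping or {}
    frame = pd.DataFrame(index=raw.index)
    for canonical in _REQUIRED:
        source = mapping.get(canonical, canonical)
        if source not in raw.columns:
            raise MmpiBnError(f"missing column {source!r} in {path}")
        col = pd.to_numeric(raw[source], errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            raise MmpiBnError(
                f"non-numeric or missing value at row {int(bad[0])}, "
                f"column {source!r} in {path}")
        frame[canonical] = col.astype(float)
    return Cohort(frame[list(CANONICAL_SCALES)],
                  frame[list(DEMOGRAPHIC_COLUMNS)],
                  frame[LABEL_COLUMN].to_numpy(dtype=int))


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def save_model(model: ClassifierModel, path) -> None:
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "log_prior_odds": model.log_prior_odds,
        "net_healthy": network_to_json(model.net_healthy),
        "net_schiz": network_to_json(model.net_schiz),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> ClassifierModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    if doc.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"not a {MODEL_FORMAT} file: {path}")
    if doc.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"unsupported model version {doc.get('version')!r} "
            f"(expected {MODEL_VERSION})")
    known = {"format", "version", "log_prior_odds", "net_healthy", "net_schiz"}
    extra = set(doc) - known
    if extra:
        logger.warning("ignoring unknown model fields: %s", sorted(extra))
    return ClassifierModel(network_from_json(doc["net_healthy"]),
                           network_from_json(doc["net_schiz"]),
                           float(doc["log_prior_odds"]))


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the end-to-end run (all randomness flows from seed)."""

    out_dir: str = "results"
    input_csv: str | None = None  # None: simulate the two-group study
    n_per_group: int = 714
    age_shift: float = 0.0
    alpha: float = 0.05
    iterations: int = 100
    train_frac: float = 0.8
    n_perm: int = 10000
    whatif_n: int = 1000
    caliper: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.train_frac < 1):
            raise ValueError("alpha and train_frac must be in (0, 1)")
        if min(self.iterations, self.n_perm, self.whatif_n) < 1:
            raise ValueError("iterations, n_perm and whatif_n must be >= 1")
        if self.caliper < 0:
            raise ValueError("caliper must be >= 0")


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute match -> learn(x2) -> evaluate -> correlations -> what-if.

    Returns a name -> path map of every artifact written.  Idempotent for a
    fixed configuration and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    _stage("cohort")
    if config.input_csv is None:
        cohort = make_two_group_study(StudyConfig(
            n_per_group=config.n_per_group, seed=config.seed,
            age_shift=config.age_shift))
        path = out / "cohort.csv"
        write_cohort_csv(cohort, path)
        artifacts["cohort"] = str(path)
    else:
        cohort = read_cohort_csv(config.input_csv)

    _stage("match")
    try:
        matched, _, balance = match_study(cohort, caliper=config.caliper)
    except MmpiBnError as exc:
        raise MmpiBnError(f"stage 'match' failed: {exc}") from exc
    path = out / "matched_cohort.csv"
    write_cohort_csv(matched, path)
    artifacts["matched_cohort"] = str(path)
    path = out / "balance.json"
    path.write_text(json.dumps(balance, indent=1))
    artifacts["balance"] = str(path)

    _stage("learn")
    try:
        model = fit_classifier(matched, alpha=config.alpha)
    except MmpiBnError as exc:
        raise MmpiBnError(f"stage 'learn' failed: {exc}") from exc
    for name, net, stratum_label in (("net_healthy", model.net_healthy, 0),
                                     ("net_schiz", model.net_schiz, 1)):
        jpath = out / f"{name}.json"
        save_network(net, jpath)
        artifacts[name] = str(jpath)
        gpath = out / f"{name}.graphml"
        strengths = arc_strength(net.dag, matched.stratum(stratum_label).profiles)
        dag_to_graphml(net.dag, gpath, strengths)
        artifacts[f"{name}_graphml"] = str(gpath)
    path = out / "model.json"
    save_model(model, path)
    artifacts["model"] = str(path)

    _stage("evaluate")
    report = evaluate_rsscv(matched, iterations=config.iterations,
                            train_frac=config.train_frac, alpha=config.alpha,
                            seed=config.seed)
    baseline = baseline_scale278(matched, iterations=config.iterations,
                                 train_frac=config.train_frac, seed=config.seed)
    path = out / "eval_report.json"
    path.write_text(json.dumps({"dual_network": report.as_dict(),
                                "scale278_logistic": baseline.as_dict()},
                               indent=1))
    artifacts["eval_report"] = str(path)

    _stage("compare-correlations")
    comparison = permutation_equality_test(
        matched.stratum(0).profiles, matched.stratum(1).profiles,
        n_perm=config.n_perm, seed=config.seed)
    path = out / "correlation_comparison.json"
    path.write_text(json.dumps({
        "statistic": comparison.statistic,
        "statistic_name": comparison.statistic_name,
        "p_value": comparison.p_value,
        "n_perm": comparison.n_perm,
        "nodes": list(CANONICAL_SCALES),
        "corr_healthy": comparison.corr_a.tolist(),
        "corr_schizophrenia": comparison.corr_b.tolist(),
        "difference": comparison.difference.tolist(),
    }, indent=1))
    artifacts["correlation_comparison"] = str(path)

    _stage("whatif")
    tables = whatif_difference_table(model.net_healthy, model.net_schiz,
                                     n=config.whatif_n, seed=config.seed)
    path = out / "whatif.csv"
    whatif_tables_to_frame(tables).to_csv(path, index=False)
    artifacts["whatif"] = str(path)

    _stage("manifest")
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "mmpibn": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": artifacts,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = str(path)
    return artifacts


def preset_networks_json() -> dict:
    """Truth networks of the synthetic study, for the simulate command."""
    net_h, net_s = mmpi2_preset()
    return {"healthy": network_to_json(net_h),
            "schizophrenia": network_to_json(net_s)}
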