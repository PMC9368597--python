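"""End-to-end pipeline orchestration and stratified severity-share summaries.

The pipeline chains the stages — synthetic corpus (or user corpus) ->
extraction -> severity scoring -> feature assembly -> worker-level split ->
model bench -> Shapley attributions -> stratified severity shares — writing
every artifact plus a manifest (seed, row counts, content hashes) so a run
is reproducible and auditable. Severity shares answer the reporting
question "within a stratum (gender, seniority band, production area), which
body parts carry what percentage of the total predicted severity?".
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bench import default_registry, evaluate_models, results_to_frame
from .bodyparts import PART_NAMES
from .extraction import Lexicon, build_profile, profiles_to_frame
from .features import FEATURE_COLUMNS, FeatureTable, assemble_features, split_by_worker
from .gbdt import GBDTParams, fit_gbdt
from .scoring import ScoringConfig, score_profile, scores_to_frame
from .shapley import explain_records, summary_data
from .synthetic import GeneratorConfig, corpus_to_jsonl, generate_cohort

__all__ = ["StratumShare", "severity_shares", "seniority_bin", "stratified_shares", "run_pipeline"]

SENIORITY_BINS = ("1-10", "10-20", ">20")


def seniority_bin(years: float) -> str:
    """Fixed reporting bands; the boundaries 10 and 20 go to the upper bin."""
    if years < 10:
        return "1-10"
    if years < 20:
        return "10-20"
    return ">20"


@dataclass
class StratumShare:
    dimension: str  # gender | seniority | area
    level: str
    shares: dict  # body part -> percentage of summed predicted severity
    n_records: int

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if self.shares and abs(total - 100.0) > 0.01:
            raise ValueError(f"shares for {self.dimension}={self.level} sum to {total}, not 100")


def severity_shares(predictions: pd.DataFrame, dimension: str, level: str) -> StratumShare:
    """Body-part percentages of the summed predicted severity in one stratum.

    ``predictions`` holds one row per record with non-negative per-part
    predicted severities in the 14 part columns. share_p = 100 * sum_records
    pred_p / sum_records sum_q pred_q.
    """
    if len(predictions) == 0:
        raise ValueError(f"empty stratum {dimension}={level}")
    vals = predictions[list(PART_NAMES)].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("predicted severities must be non-negative")
    total = vals.sum()
    if total == 0:
        shares = {p: 0.0 for p in PART_NAMES}
    else:
        shares = {p: float(100.0 * vals[:, i].sum() / total) for i, p in enumerate(PART_NAMES)}
    return StratumShare(dimension, level, shares, len(predictions))


def stratified_shares(predictions: pd.DataFrame) -> pd.DataFrame:
    """Severity shares for every gender, seniority band and area stratum."""
    frame = predictions.copy()
    frame["seniority_band"] = frame["seniority_years"].map(seniority_bin)
    rows = []
    for dim, col in (("gender", "gender"), ("seniority", "seniority_band"), ("area", "area")):
        for level, grp in frame.groupby(col, sort=True):
            share = severity_shares(grp, dim, str(level))
            row = {"dimension": dim, "level": level, "n_records": share.n_records}
            row.update(share.shares)
            rows.append(row)
    return pd.DataFrame(rows, columns=["dimension", "level", "n_records", *PART_NAMES])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: GeneratorConfig | None = None,
    out_dir: str | Path = "ohpp_run",
    *,
    scoring: ScoringConfig | None = None,
    test_fraction: float = 0.2,
    k_folds: int = 10,
    n_explain: int = 25,
    use_observed_shares: bool = False,
    registry: dict | None = None,
) -> dict:
    """Run the four-phase pipeline end to end; returns the manifest.

    Stages: simulate, extract, score, features (+split), train, explain,
    report. Every stage writes its artifact under ``out_dir``; a failure
    halts with the stage name while earlier artifacts remain on disk. The
    manifest is deterministic per seed (no timestamps).

    Severity shares are computed from the per-part severities *predicted*
    by the built-in model for each record's next appointment;
    ``use_observed_shares`` switches to the observed next scores for
    diagnostics.
    """
    config = config or GeneratorConfig()
    scoring = scoring or ScoringConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    stage = "simulate"
    try:
        corpus = generate_cohort(config)
        corpus_path = out / "corpus.jsonl"
        corpus_to_jsonl(corpus, corpus_path)
        manifest["stages"][stage] = {"rows": len(corpus), "sha256": _sha256(corpus_path)}

        stage = "extract"
        lexicon = Lexicon.default()
        profiles = [
            build_profile(a.sentences, lexicon, metadata=a.__dict__) for a in corpus
        ]
        prof_frame = profiles_to_frame(profiles)
        prof_path = out / "profiles.csv"
        prof_frame.to_csv(prof_path, index=False)
        manifest["stages"][stage] = {"rows": len(prof_frame), "sha256": _sha256(prof_path)}

        stage = "score"
        scored = [score_profile(p, scoring) for p in profiles]
        score_frame = scores_to_frame(scored)
        score_path = out / "scores.csv"
        score_frame.to_csv(score_path, index=False)
        manifest["stages"][stage] = {"rows": len(score_frame), "sha256": _sha256(score_path)}

        stage = "features"
        table = assemble_features(score_frame)
        feat_path = out / "features.csv"
        table.frame.to_csv(feat_path, index=False)
        table.vocabulary.save(out / "vocabulary.json")
        plan = split_by_worker(table, test_fraction, config.seed, k_folds=k_folds)
        plan.save(out / "split.json")
        manifest["stages"][stage] = {
            "rows": len(table.frame),
            "train": len(plan.train_index),
            "test": len(plan.test_index),
            "sha256": _sha256(feat_path),
        }

        stage = "train"
        registry = registry or default_registry(seed=config.seed, include_optional=False)
        results = evaluate_models(registry, table, plan, scenario="interval")
        eval_frame = results_to_frame(results)
        eval_path = out / "eval_interval.csv"
        eval_frame.to_csv(eval_path, index=False)
        manifest["stages"][stage] = {"rows": len(eval_frame), "sha256": _sha256(eval_path)}

        stage = "explain"
        X = table.X
        tr = np.asarray(plan.train_index, dtype=int)
        ens = fit_gbdt(X[tr], table.y_interval()[tr], GBDTParams(seed=config.seed))
        rng = np.random.default_rng(config.seed)
        bg = X[tr][rng.choice(len(tr), size=min(50, len(tr)), replace=False)]
        te = np.asarray(plan.test_index, dtype=int)
        explain_idx = te[: min(n_explain, len(te))]
        att = explain_records(
            ens.predict, bg, X[explain_idx], feature_names=list(FEATURE_COLUMNS),
            mode="sampled", n_permutations=100, seed=config.seed,
        )
        att_path = out / "attributions.csv"
        att.to_frame().to_csv(att_path, index=False)
        ranking, _ = summary_data(att)
        ranking.to_csv(out / "attribution_ranking.csv", index=False)
        manifest["stages"][stage] = {"rows": len(att.attributions), "sha256": _sha256(att_path)}

        stage = "report"
        if use_observed_shares:
            preds = table.frame[[f"next_{p}" for p in PART_NAMES]].to_numpy(dtype=float)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                preds = _predict_next_severities(table, plan, seed=config.seed)
        pred_frame = table.frame[["worker_id", "gender", "area", "seniority_years"]].copy()
        for i, p in enumerate(PART_NAMES):
            pred_frame[p] = np.clip(preds[:, i], 0.0, None)
        shares = stratified_shares(pred_frame)
        shares_path = out / "severity_shares.csv"
        shares.to_csv(shares_path, index=False)
        manifest["stages"][stage] = {"rows": len(shares), "sha256": _sha256(shares_path)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
        raise RuntimeError(f"pipeline halted at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest


def _predict_next_severities(table: FeatureTable, plan, seed: int = 0) -> np.ndarray:
    """Per-record next-severity predictions from one built-in model per part,
    fitted on the training side."""
    X = table.X
    tr = np.asarray(plan.train_index, dtype=int)
    out = np.zeros((len(X), len(PART_NAMES)))
    params = GBDTParams(n_trees=100, seed=seed)
    for i, part in enumerate(PART_NAMES):
        y = table.y_next_score(part)
        if np.ptp(y[tr]) == 0:
            out[:, i] = y[tr].mean()
            continue
        ens = fit_gbdt(X[tr], y[tr], params)
        out[:, i] = ens.predict(X)
    return out
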