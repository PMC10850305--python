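"""End-to-end orchestration: preprocess -> features -> matching ->
inference -> LOOCV classification -> univariate cutoffs, with exclusion
bookkeeping at every stage."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .classify import compute_cv_metrics, loocv_classify, univariate_cut_table
from .config import PipelineConfig
from .features import extract_feature_table
from .inference import run_inference
from .io import read_metadata, read_recording, write_feature_table
from .matching import (balance_table, compute_match_weights, fit_propensity,
                       ipw_weights, optimal_full_match)
from .preprocess import preprocess_recording
from .types import EpochSet, Exclusion

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, input_dir, out_dir,
                 manual_exclusions: list[str] | None = None) -> int:
    """Run all stages on a directory of recordings plus metadata.csv.

    Writes features.csv, inference.csv, cv_predictions.csv, metrics.json,
    univariate.csv, match.csv, balance.csv and exclusions.json under
    ``out_dir``. Identical config and inputs give identical outputs.
    Returns 0 on success; stage failures raise :class:`PipelineError`.
    """
    cfg.validate()
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manual = set(manual_exclusions or [])

    meta = read_metadata(input_dir / "metadata.csv")
    files = {p.stem: p for ext in ("*.csv", "*.edf") for p in input_dir.glob(ext)
             if p.name != "metadata.csv"}

    exclusions: dict[str, str] = {}
    epoch_sets: list[EpochSet] = []
    provenance: dict[str, dict] = {}
    for pid in meta.index:
        if pid in manual:
            exclusions[pid] = "manual (visual inspection)"
            continue
        if pid not in files:
            exclusions[pid] = "recording missing"
            continue
        try:
            rec = read_recording(files[pid], participant_id=pid)
        except Exception as exc:
            raise PipelineError("read", f"{pid}: {exc}") from exc
        result = preprocess_recording(rec, cfg)
        if isinstance(result, Exclusion):
            exclusions[pid] = result.reason
            continue
        provenance[pid] = {
            "removed_channels": result.removed_channels,
            "rejected_epochs": {str(k): v for k, v in result.rejected_epochs.items()},
            "n_epochs_retained": result.n_epochs,
        }
        epoch_sets.append(result)

    analyzed = [es.participant_id for es in epoch_sets]
    accounting = {
        "n_input": int(len(meta)),
        "n_analyzed": len(analyzed),
        "n_excluded": len(exclusions),
        "reasons": _reason_counts(exclusions),
    }
    with open(out_dir / "exclusions.json", "w") as fh:
        json.dump({"exclusions": exclusions, "accounting": accounting,
                   "preprocess": provenance}, fh, indent=2)

    meta_used = meta.loc[analyzed]
    if (meta_used["group"] == 0).sum() == 0:
        raise PipelineError("preprocess", "no controls remain after exclusions")
    if (meta_used["group"] == 1).sum() == 0:
        raise PipelineError("preprocess", "no cases remain after exclusions")

    features = extract_feature_table(epoch_sets, cfg)
    write_feature_table(features, out_dir / "features.csv")

    try:
        pm = fit_propensity(meta_used, cfg.covariates)
        groups = meta_used.loc[pm.scores.index, "group"]
        if cfg.matching_method == "ipw":
            weights = ipw_weights(pm.scores, groups)
            match_df = pd.DataFrame({"participant_id": weights.index,
                                     "matched_set_id": -1,
                                     "weight": weights.to_numpy()})
        else:
            mr = optimal_full_match(pm.scores, groups)
            weights = compute_match_weights(mr, groups)
            match_df = pd.DataFrame({"participant_id": weights.index,
                                     "matched_set_id": mr.set_id.loc[weights.index].to_numpy(),
                                     "weight": weights.to_numpy()})
        match_df.to_csv(out_dir / "match.csv", index=False)
        balance_table(meta_used.loc[weights.index], weights, cfg.covariates) \
            .to_csv(out_dir / "balance.csv", index=False)
    except ValueError as exc:
        raise PipelineError("matching", str(exc)) from exc

    inference = run_inference(features, meta_used, weights, cfg)
    inference.to_csv(out_dir / "inference.csv", index=False)

    try:
        cv = loocv_classify(features, meta_used, cfg)
    except ValueError as exc:
        raise PipelineError("classify", str(exc)) from exc
    cv.predictions.to_csv(out_dir / "cv_predictions.csv", index=False)
    metrics = compute_cv_metrics(cv.predictions, cfg)
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)

    sig = inference.loc[inference["significant"], "feature"].tolist()
    univariate_cut_table(features, meta_used, sig) \
        .to_csv(out_dir / "univariate.csv", index=False)
    return 0


def _reason_counts(exclusions: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for reason in exclusions.values():
        counts[reason] = counts.get(reason, 0) + 1
    return counts
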