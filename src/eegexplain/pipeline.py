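"""End-to-end orchestration: simulate -> decode -> attribute -> score -> report.

The report bundle mirrors the structure of a decoding/interpretability
study: per-fold test accuracies per decoder, per-(network, method, layer)
interpretability summaries (group mean of per-participant maximum scores
and latencies, significant-sample counts), pairwise method/layer contrasts,
and ground-truth-recovery metrics that only a simulation can provide.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import attribution as attr
from . import decoding as dec
from . import interpretability as interp
from .simulate import EpochsSet, SimConfig, ground_truth_mask, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class FoldResult:
    fold_id: int
    trained: dec.TrainedDecoder
    test_accuracy: float
    evaluation_all: dec.EvaluationResult  # over the full dataset, for attribution


def run_protocol(epochs: EpochsSet, plan: dec.SplitPlan, family: str = "eegnet_style",
                 arch: dec.ArchitectureSpec | None = None,
                 train_config: dec.TrainConfig | None = None,
                 seed: int = 0, attribution_scope: str = "all") -> list[FoldResult]:
    """Train and evaluate one decoder family across all folds of a split plan.

    ``attribution_scope`` controls which trials are later eligible for
    feature extraction: "all" evaluates the fold decoder on every
    participant's trials (the default), "test" restricts to the fold's
    held-out participants.
    """
    arch = arch or dec.ArchitectureSpec(family=family)
    cfg = train_config or dec.default_train_config(arch.family)
    results = []
    for fold_id, (train_p, val_p, test_p) in enumerate(plan.folds):
        tr = dec.subset_by_participants(epochs, train_p)
        va = dec.subset_by_participants(epochs, val_p)
        te = dec.subset_by_participants(epochs, test_p)
        est = dec.build_decoder(arch, epochs.n_channels, epochs.n_samples,
                                len(np.unique(epochs.labels)),
                                seed=int(np.random.default_rng([seed, fold_id]).integers(2**31)),
                                train_config=cfg)
        trained = dec.train_decoder(est, tr, va, fold_id=fold_id, spec=arch)
        test_eval = dec.evaluate_decoder(trained, te)
        scope = epochs if attribution_scope == "all" else te
        eval_all = dec.evaluate_decoder(trained, scope)
        logger.info("fold %d (%s): test accuracy %.3f (best epoch %d)", fold_id,
                    arch.family, test_eval.accuracy, trained.estimator.best_epoch_)
        results.append(FoldResult(fold_id, trained, test_eval.accuracy, eval_all))
    return results


def _method_layer_grid(methods, layers, trained_example, probe):
    """Expand (method, layer-preset) into concrete (method, layer) pairs."""
    out = []
    for m in methods:
        if m == "saliency":
            out.append(("saliency", "input"))
        else:
            for preset in layers:
                out.append(("gradcam",
                            attr.resolve_layer_preset(trained_example, preset, probe)))
    return out


def score_network(fold_results: list[FoldResult], epochs: EpochsSet, methods, layers,
                  alpha: float, conditions=None) -> dict:
    """Attribution + interpretability scoring for one trained family.

    Per (method, layer): per-condition maps are computed, correlation time
    courses are averaged across conditions per participant, and group
    statistics are run on the averaged time courses.
    """
    trained_folds = [f.trained for f in fold_results]
    evaluations = [f.evaluation_all for f in fold_results]
    conditions = list(conditions or np.unique(epochs.labels))
    probe = epochs.data[0]
    grid = _method_layer_grid(methods, layers, trained_folds[0], probe)
    out = {}
    for method, layer in grid:
        cond_maps = {}
        for cond in conditions:
            try:
                cond_maps[cond] = attr.attribute_condition(
                    trained_folds, epochs, evaluations, cond, method, layer)
            except ValueError as e:
                logger.warning("%s/%s condition %r skipped: %s", method, layer, cond, e)
        if not cond_maps:
            continue
        participants = sorted(set().union(
            *[set(cm.per_participant) for cm in cond_maps.values()]))
        tc = np.full((len(participants), epochs.n_samples), np.nan)
        for i, p in enumerate(participants):
            per_cond = []
            for cm in cond_maps.values():
                if p in cm.per_participant:
                    per_cond.append(interp.interpretability_timecourse(
                        cm.per_participant_eeg[p], cm.per_participant[p]))
            if per_cond:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    tc[i] = np.nanmean(per_cond, axis=0)
        mask, p_raw, p_adj = interp.group_significance(tc, alpha=alpha)
        defined = [i for i in range(len(participants)) if not np.all(np.isnan(tc[i]))]
        if len(defined) < len(participants):
            logger.warning("%s/%s: %d participant(s) had an all-undefined "
                           "correlation time course (flat feature map) and are "
                           "excluded from max-score statistics", method, layer,
                           len(participants) - len(defined))
        maxima = [interp.max_score_and_latency(tc[i], epochs.times) for i in defined]
        participants = [participants[i] for i in defined]
        result = interp.InterpretabilityResult(
            r_timecourses=tc, times=epochs.times, group_mask=mask, p_values=p_raw,
            p_adjusted=p_adj, max_scores=np.array([m[0] for m in maxima]),
            max_latencies=np.array([m[1] for m in maxima]), method=method, layer=layer)
        out[(method, layer)] = {"result": result, "condition_maps": cond_maps,
                                "participants": participants}
    return out


def recovery_metrics(cond_maps: attr.ConditionMaps, config: SimConfig,
                     top_k: int = 5) -> dict:
    """How well an aggregate map recovers the planted component.

    Reports the latency of the map's time-marginal argmax, its offset from
    the planted peak, and the overlap between the map's top-``top_k``
    channels and the planted channel set.
    """
    mask = ground_truth_mask(config, cond_maps.condition)
    agg = cond_maps.aggregate
    t_marginal = agg.sum(axis=0)
    t_hat = float(cond_maps.times[int(np.argmax(t_marginal))])
    planted_t = cond_maps.times[mask.any(axis=0)]
    planted_channels = set(np.flatnonzero(mask.any(axis=1)).tolist())
    ch_marginal = agg.sum(axis=1)
    top = set(np.argsort(ch_marginal)[::-1][:top_k].tolist())
    peak_center = float(planted_t.mean()) if planted_t.size else np.nan
    return {
        "argmax_latency_s": t_hat,
        "latency_offset_s": abs(t_hat - peak_center) if planted_t.size else np.nan,
        "top_channel_overlap": len(top & planted_channels),
        "n_planted_channels": len(planted_channels),
    }


def shuffled_feature_control(scored: dict, epochs: EpochsSet, seed: int) -> dict:
    """Permutation control: re-score against time-shuffled feature maps.

    Shuffling the time axis of each participant's feature map destroys the
    temporal alignment with the EEG while preserving its value distribution;
    real features should beat this control.
    """
    rng = np.random.default_rng([seed, 987])
    out = {}
    for (method, layer), bundle in scored.items():
        real = float(np.mean(bundle["result"].max_scores))
        shuf_scores = []
        for p in bundle["participants"]:
            per_cond = []
            for cm in bundle["condition_maps"].values():
                if p not in cm.per_participant:
                    continue
                feat = cm.per_participant[p][:, rng.permutation(epochs.n_samples)]
                per_cond.append(interp.interpretability_timecourse(
                    cm.per_participant_eeg[p], feat))
            if per_cond:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    tc = np.nanmean(per_cond, axis=0)
                if not np.all(np.isnan(tc)):
                    shuf_scores.append(interp.max_score_and_latency(tc, epochs.times)[0])
        out[f"{method}/{layer}"] = {
            "mean_max_score": real,
            "shuffled_mean_max_score": float(np.mean(shuf_scores)) if shuf_scores
            else float("nan")}
    return out


def run_pipeline(sim_config: SimConfig, families=("eegnet_style",),
                 methods=("saliency", "gradcam"),
                 layers=("early", "intermediate", "late"), alpha: float = 0.05,
                 seed: int = 0, n_folds: int = 5,
                 train_configs: dict | None = None, out_dir=None) -> dict:
    """Full study: simulate, decode under participant-wise CV, attribute,
    score interpretability, run group and pairwise statistics, and report.

    Returns the report dictionary; when ``out_dir`` is given, writes
    ``results.json`` plus CSV tables there.
    """
    epochs = simulate_dataset(sim_config)
    plan = dec.make_participant_splits(np.unique(epochs.participants),
                                       n_folds=n_folds, seed=seed)
    report: dict = {"seed": seed, "n_folds": n_folds,
                    "classes": sorted(np.unique(epochs.labels).tolist()),
                    "n_trials": int(epochs.n_trials),
                    "accuracy": {}, "interpretability": {}, "comparisons": [],
                    "recovery": {}, "shuffle_control": {}}
    signal_classes = sorted({c for comp in sim_config.components
                             for c in comp.class_selector})
    per_family_scored = {}
    for family in families:
        cfg = (train_configs or {}).get(family)
        folds = run_protocol(epochs, plan, family=family, train_config=cfg, seed=seed)
        report["accuracy"][family] = {
            "per_fold": [f.test_accuracy for f in folds],
            "mean": float(np.mean([f.test_accuracy for f in folds])),
        }
        scored = score_network(folds, epochs, methods, layers, alpha,
                               conditions=signal_classes or None)
        per_family_scored[family] = scored
        fam_rows = {}
        for (method, layer), bundle in scored.items():
            r = bundle["result"]
            has_scores = r.max_scores.size > 0
            fam_rows[f"{method}/{layer}"] = {
                "mean_max_score": float(np.mean(r.max_scores)) if has_scores else None,
                "mean_max_latency_s": (float(np.mean(r.max_latencies))
                                       if has_scores else None),
                "n_significant_samples": int(r.group_mask.sum()),
                "n_participants": len(bundle["participants"]),
            }
        report["interpretability"][family] = fam_rows
        # pairwise method/layer contrasts within the family
        keys = list(scored)
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b = scored[keys[i]]["result"], scored[keys[j]]["result"]
                if len(a.max_scores) != len(b.max_scores) or len(a.max_scores) < 5:
                    continue
                cmp_s = interp.compare_paired(a.max_scores, b.max_scores,
                                              label="max_score")
                cmp_l = interp.compare_paired(a.max_latencies, b.max_latencies,
                                              label="max_latency")
                report["comparisons"].append({
                    "network": family,
                    "a": f"{keys[i][0]}/{keys[i][1]}", "b": f"{keys[j][0]}/{keys[j][1]}",
                    "score_z": cmp_s.z_statistic, "score_p": cmp_s.p_value,
                    "latency_z": cmp_l.z_statistic, "latency_p": cmp_l.p_value,
                    "n_pairs": cmp_s.n_pairs})
        rec = {}
        for (method, layer), bundle in scored.items():
            for cond, cm in bundle["condition_maps"].items():
                if cond in signal_classes:
                    rec[f"{method}/{layer}/{cond}"] = recovery_metrics(cm, sim_config)
        report["recovery"][family] = rec
        report["shuffle_control"][family] = shuffled_feature_control(scored, epochs, seed)
    # across-family contrasts on matched (method, layer presets)
    fams = list(per_family_scored)
    for i in range(len(fams)):
        for j in range(i + 1, len(fams)):
            sa, sb = per_family_scored[fams[i]], per_family_scored[fams[j]]
            for key in sa:
                if key[0] != "saliency":
                    continue  # concrete gradcam layer names differ across families
                if key in sb:
                    a, b = sa[key]["result"], sb[key]["result"]
                    if len(a.max_scores) == len(b.max_scores) >= 5:
                        c = interp.compare_paired(a.max_scores, b.max_scores)
                        report["comparisons"].append({
                            "network": f"{fams[i]} vs {fams[j]}",
                            "a": f"{key[0]}/{key[1]}", "b": f"{key[0]}/{key[1]}",
                            "score_z": c.z_statistic, "score_p": c.p_value,
                            "n_pairs": c.n_pairs})
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: dict, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    acc_rows = [{"network": fam, "fold": i, "test_accuracy": a}
                for fam, d in report["accuracy"].items()
                for i, a in enumerate(d["per_fold"])]
    if acc_rows:
        pd.DataFrame(acc_rows).to_csv(out / "accuracy.csv", index=False)
    interp_rows = [{"network": fam, "feature": key, **vals}
                   for fam, d in report["interpretability"].items()
                   for key, vals in d.items()]
    if interp_rows:
        pd.DataFrame(interp_rows).to_csv(out / "interpretability.csv", index=False)
    if report["comparisons"]:
        pd.DataFrame(report["comparisons"]).to_csv(out / "comparisons.csv", index=False)
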