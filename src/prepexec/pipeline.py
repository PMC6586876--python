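"""End-to-end per-session orchestration.

Runs preprocess -> behavior -> trigger -> subspace -> jump-distance on one
session with a single serializable configuration, recording every
exclusion (units, trials, conditions) with a machine-readable reason
code.  Sessions with fewer than 10 simultaneously recorded units are an
exclusion *outcome*, not an error, mirroring the dataset inclusion rule
of the analysis this package implements.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import behavior as bh
from . import jump_distance as jd
from . import preprocess as pp
from . import subspace as sb
from . import trigger as tg
from .errors import PrepexecError
from .session import Session


@dataclass
class PipelineConfig:
    """Every tunable of the full analysis; defaults follow the per-module
    documentation."""

    kernel_sd: float = 0.030
    step: float = 0.010
    svm_seed: int = 0
    svm_C: float = 1e-3
    heldout_fraction: float = 0.1
    svm_window: tuple = (-0.45, 0.35)      # move_onset aligned
    go_window: tuple = (0.0, 0.75)         # go_cue aligned, crossing search
    target_window: tuple = (-0.10, 0.45)   # target_on aligned
    delay_epoch: tuple = (0.0, 0.3)
    move_epoch: tuple = (0.0, 0.3)
    min_delay: float = 0.3                 # delay needed for the delay epoch
    dim_threshold: float = 0.70
    d_prep: int | None = None              # None -> variance rule
    d_move: int | None = None
    subspace_seed: int = 0
    subspace_starts: int = 10
    min_units: int = 10
    fit_sigmoids: bool = True
    n_bootstrap_ci: int = 1000
    behavior_seed: int = 0
    max_ci_ms: float = 50.0
    min_jump_trials: int = 8
    kurtosis_n_random: int = 10000
    kurtosis_seed: int = 0
    distance_window: tuple = (0.0, 0.2)
    distance_alignments: tuple = ("target_on", "go_cue", "move_onset")
    distance_seed: int = 0
    compute_trigger_events: bool = True

    def config_hash(self) -> str:
        d = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(d.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    outcome: str                       # "complete" or "excluded"
    n_units: int
    n_trials: int
    exclusions: list = field(default_factory=list)  # (stage, code, detail)
    summary: dict = field(default_factory=dict)
    # heavyweight stage outputs, for downstream use
    artifacts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """Numbers-only view (stable across runs for determinism audits)."""
        return {"config_hash": self.config_hash, "outcome": self.outcome,
                "n_units": self.n_units, "n_trials": self.n_trials,
                "exclusions": [list(e) for e in self.exclusions],
                "summary": self.summary}


def _jump_condition_refs(session: Session) -> dict:
    """Map jump condition id -> (non-jump first cond id, final cond id)."""
    target_to_cond = {}
    for t in session.trials:
        if not t.is_jump:
            target_to_cond.setdefault(tuple(np.round(t.final_target_xy, 6)),
                                      t.condition_id)
    refs = {}
    for cid, jc in session.jump_conditions().items():
        first = target_to_cond.get(tuple(np.round(jc.first_target_xy, 6)))
        final = target_to_cond.get(tuple(np.round(jc.final_target_xy, 6)))
        if first is not None and final is not None:
            refs[cid] = (first, final)
    return refs


def run_pipeline(session: Session, config: PipelineConfig | None = None
                 ) -> RunReport:
    if config is None:
        config = PipelineConfig()
    report = RunReport(config_hash=config.config_hash(), outcome="complete",
                       n_units=session.n_units, n_trials=session.n_trials)
    if session.n_units < config.min_units:
        report.outcome = "excluded"
        report.exclusions.append(
            ("session", "min_units",
             f"{session.n_units} < {config.min_units}"))
        return report
    flagged = session.validate()
    for tid in flagged:
        report.exclusions.append(("validate", "jump_after_onset", tid))

    # ---------------------------------------------------------- preprocess
    for trial in session.trials:
        if trial.move_onset_time is None:
            try:
                trial.move_onset_time = pp.detect_movement_onset(trial)
            except PrepexecError as e:
                trial.valid = False
                report.exclusions.append(
                    ("preprocess", "onset_detection", str(e)))
    for tid in session.validate():
        report.exclusions.append(("validate", "jump_after_onset", tid))
    divisors = pp.unit_normalization(session, config.kernel_sd, config.step)

    def tensor(alignment, window):
        rt = pp.smooth_rates(session, alignment, window,
                             config.kernel_sd, config.step)
        rt = pp.normalize_rates(rt, divisors)
        for tid in rt.excluded_trials:
            report.exclusions.append((f"rates_{alignment}", "window", tid))
        return rt

    rt_move = tensor("move_onset", config.svm_window)
    need_go = config.compute_trigger_events or \
        "go_cue" in config.distance_alignments
    rt_go = tensor("go_cue", config.go_window) if need_go else None
    rt_target = tensor("target_on", config.target_window)
    valid_ids = {t.trial_id for t in session.trials if t.valid}

    # ------------------------------------------------------------ behavior
    by_trial = {t.trial_id: t for t in session.trials}
    jump_conds = session.jump_conditions()
    angles, labels, latencies = {}, {}, {}
    for t in session.trials:
        if not (t.is_jump and t.valid and t.move_onset_time is not None):
            continue
        try:
            a = bh.initial_reach_angle(t)
        except PrepexecError as e:
            report.exclusions.append(("behavior", "no_radius_crossing", str(e)))
            continue
        na = bh.normalize_angle(a, jump_conds[t.condition_id])
        angles[t.trial_id] = na
        labels[t.trial_id] = "first" if na < 0 else "final"
        latencies[t.trial_id] = (t.move_onset_time - t.jump_time) * 1000.0
    report.summary["n_jump_trials_labeled"] = len(labels)

    fits = retained = None
    if config.fit_sigmoids and labels:
        fits = {}
        for cid in jump_conds:
            tids = [i for i in labels if by_trial[i].condition_id == cid]
            if len(tids) < config.min_jump_trials:
                report.exclusions.append(
                    ("behavior", "few_trials", f"{cid}: {len(tids)}"))
                continue
            try:
                fits[cid] = bh.fit_behavior_sigmoid(
                    np.array([latencies[i] for i in tids]),
                    np.array([angles[i] for i in tids]),
                    n_bootstrap=config.n_bootstrap_ci,
                    seed=config.behavior_seed)
            except PrepexecError as e:
                report.exclusions.append(("behavior", "fit_failed",
                                          f"{cid}: {e}"))
        retained, excluded_fits = bh.filter_fits_by_ci(fits, config.max_ci_ms)
        for cid in excluded_fits:
            report.exclusions.append(("behavior", "wide_ci", cid))
        report.summary["behavior_t50_ms"] = {
            c: f.t50 for c, f in retained.items()}
        report.summary["behavior_crossings_ms"] = {
            c: f.crossings for c, f in retained.items()}

    # ------------------------------------------------------------- trigger
    model = tg.train_trigger_svm(
        rt_move.subset([i for i in rt_move.trial_ids if i in valid_ids]),
        session, seed=config.svm_seed, C=config.svm_C,
        heldout_fraction=config.heldout_fraction)
    report.summary["svm_heldout_accuracy"] = model.heldout_accuracy
    events = tg.trigger_events(model, rt_go, session) \
        if config.compute_trigger_events else []
    offsets = {e.trial_id: e.offset_vs_jump * 1000.0
               for e in events if e.offset_vs_jump is not None}
    cond_offsets, cond_angles = {}, {}
    for tid, off in offsets.items():
        if tid not in angles:
            continue
        cid = by_trial[tid].condition_id
        cond_offsets.setdefault(cid, []).append(off)
        cond_angles.setdefault(cid, []).append(angles[tid])
    predictions, skipped = tg.predict_jump_behavior(
        cond_offsets, cond_angles, min_trials=config.min_jump_trials)
    for cond, why in skipped:
        report.exclusions.append(("trigger", "prediction_skipped",
                                  f"{cond}: {why}"))
    if predictions:
        report.summary["loo_r2_median"] = float(
            np.median([p.r2 for p in predictions.values()]))
        report.summary["classification_accuracy_median"] = float(
            np.median([p.accuracy for p in predictions.values()]))
    ktest = tg.kurtosis_projection_test(
        model.w, n_random=config.kurtosis_n_random, seed=config.kurtosis_seed)
    report.summary["kurtosis"] = ktest.kurtosis
    report.summary["kurtosis_p"] = ktest.p_value

    # ------------------------------------------------------------ subspace
    def delay_ok(trial):
        if trial.is_jump or not trial.valid:
            return None
        if trial.go_cue_time - trial.target_on_time < config.min_delay:
            return None
        return trial.condition_id

    avg_delay = pp.align_and_average(rt_target, session, delay_ok)
    avg_move = pp.align_and_average(
        rt_move, session,
        lambda t: None if (t.is_jump or not t.valid) else t.condition_id)
    epochs = sb.build_epoch_data(avg_delay, avg_move, model.w,
                                 config.delay_epoch, config.move_epoch)
    d_prep = config.d_prep or sb.choose_dims(epochs.X_prep,
                                             config.dim_threshold)
    d_move = config.d_move or sb.choose_dims(epochs.X_move,
                                             config.dim_threshold)
    pair = sb.optimize_subspaces(epochs, d_prep, d_move,
                                 seed=config.subspace_seed,
                                 n_starts=config.subspace_starts)
    report.summary["d_prep"] = d_prep
    report.summary["d_move"] = d_move
    report.summary["subspace_objective"] = pair.objective

    K = epochs.null_basis
    var_delay = sb.cross_condition_variance(
        sb.project_average(avg_delay, K), pair)
    var_move = sb.cross_condition_variance(
        sb.project_average(avg_move, K), pair)

    def _epoch_share(trace, window):
        m = (trace.time >= window[0] - 1e-9) & (trace.time <= window[1] + 1e-9)
        return (float(trace.share_prep[m].mean()),
                float(trace.share_move[m].mean()))

    sp_d, sm_d = _epoch_share(var_delay, config.delay_epoch)
    sp_m, sm_m = _epoch_share(var_move, config.move_epoch)
    report.summary["prep_share_delay"] = sp_d
    report.summary["move_share_delay"] = sm_d
    report.summary["prep_share_move"] = sp_m
    report.summary["move_share_move"] = sm_m

    # ------------------------------------------------------- jump distance
    def dist_group(trial):
        if not trial.valid:
            return None
        if trial.is_jump:
            lab = labels.get(trial.trial_id)
            return None if lab is None else (trial.condition_id, lab)
        return trial.condition_id

    refs = _jump_condition_refs(session)
    # trial-count-matched non-jump baselines: subsample the non-jump
    # first-target trials down to each jump-first group's size so the two
    # distance estimates carry the same few-trial noise bias
    n_first = {}
    for t in session.trials:
        if t.is_jump and labels.get(t.trial_id) == "first":
            n_first[t.condition_id] = n_first.get(t.condition_id, 0) + 1
    dist_rng = np.random.default_rng(config.distance_seed)
    matched_ids = {}
    for jc, (first_id, _) in sorted(refs.items()):
        pool = [t.trial_id for t in session.trials
                if not t.is_jump and t.valid and t.condition_id == first_id]
        n = n_first.get(jc, 0)
        if 0 < n < len(pool):
            pick = dist_rng.choice(len(pool), size=n, replace=False)
            matched_ids[jc] = [pool[i] for i in np.sort(pick)]
        elif n > 0:
            matched_ids[jc] = pool

    avg_by_alignment = {}
    for alignment in config.distance_alignments:
        rt = {"target_on": rt_target, "go_cue": rt_go,
              "move_onset": rt_move}[alignment]
        avg = pp.align_and_average(rt, session, dist_group)
        for jc, ids in matched_ids.items():
            idx = [rt.trial_ids.index(i) for i in ids if i in rt.trial_ids]
            if idx:
                avg.groups[(jc, "baseline_matched")] = \
                    rt.values[:, :, idx].mean(axis=2)
                avg.counts[(jc, "baseline_matched")] = len(idx)
        avg_by_alignment[alignment] = sb.project_average(avg, K)
    traces, skipped = jd.jump_distance_panel(avg_by_alignment, pair, refs)
    for s in skipped:
        report.exclusions.append(("distance", "skipped_group", str(s)))
    try:
        stat, pval, jump_means, base_means = jd.movement_epoch_distance_test(
            traces, window=config.distance_window)
        report.summary["distance_ranksum_p"] = pval
        report.summary["distance_ranksum_stat"] = stat
        report.summary["distance_jump_mean"] = float(
            np.mean(list(jump_means.values())))
        report.summary["distance_nonjump_mean"] = float(
            np.mean(list(base_means.values())))
    except PrepexecError as e:
        report.exclusions.append(("distance", "test_skipped", str(e)))

    report.artifacts = {
        "divisors": divisors, "trigger_model": model, "trigger_events": events,
        "behavior_fits": retained if retained is not None else fits,
        "predictions": predictions, "kurtosis_test": ktest,
        "epochs": epochs, "subspaces": pair,
        "variance_delay": var_delay, "variance_move": var_move,
        "distance_traces": traces, "angles": angles, "labels": labels,
    }
    return report
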