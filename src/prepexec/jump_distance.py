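"""Subspace distances between jump and non-jump neural trajectories.

For each jump condition the three informative pairings are compared, in
both the preparatory and movement subspaces and per alignment event:

* jump trials initiated toward the first target vs the non-jump
  trajectory to the final target (the corrected reaches);
* jump trials initiated toward the final target vs the same non-jump
  trajectory (the early-jump reaches);
* the two non-jump trajectories (first vs final target) — the scale bar.

The headline statistic is the average preparatory-space distance over
0-200 ms after movement onset: corrected jump reaches against the
non-jump baseline, compared across conditions with a two-sided Wilcoxon
rank-sum test.  A significant elevation is the signature of preparatory
re-engagement during movement; its absence is what a direct-response
population would produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AlignmentError, DimensionError, StatisticsError
from .subspace import SubspacePair

PAIR_LABELS = ("jump_first_vs_nonjump_final",
               "jump_final_vs_nonjump_final",
               "nonjump_first_vs_nonjump_final")


@dataclass
class DistanceTrace:
    time: np.ndarray
    alignment: str
    d_prep: np.ndarray
    d_move: np.ndarray
    pair_label: str
    condition: str


def neural_distance(traj_a: np.ndarray, traj_b: np.ndarray,
                    Q: np.ndarray) -> np.ndarray:
    """Per-timepoint Euclidean distance ||Q' (a(t) - b(t))|| in a subspace."""
    a = np.asarray(traj_a, float)
    b = np.asarray(traj_b, float)
    if a.shape != b.shape:
        raise AlignmentError("trajectories must share a time grid")
    if a.shape[0] != Q.shape[0]:
        raise DimensionError("trajectory and basis dimensions differ")
    return np.linalg.norm(Q.T @ (a - b), axis=0)


def jump_distance_panel(avg_by_alignment: dict, pair: SubspacePair,
                        jump_conditions: dict):
    """All pairwise traces per jump condition and alignment.

    ``avg_by_alignment`` maps alignment -> null-space
    :class:`ConditionAverage` whose groups contain non-jump condition ids
    (``T*``) and jump groups keyed ``(condition_id, label)``.
    ``jump_conditions`` maps jump condition id -> (first_cond_id,
    final_cond_id) naming the matching non-jump conditions.  Jump groups
    missing a label are skipped and reported.
    """
    traces, skipped = [], []
    for alignment, avg in avg_by_alignment.items():
        for jc, (first_id, final_id) in jump_conditions.items():
            if first_id not in avg.groups or final_id not in avg.groups:
                skipped.append((alignment, jc, "missing non-jump reference"))
                continue
            ref_final = avg.groups[final_id]
            # the baseline uses a trial-count-matched non-jump average when
            # one is provided, so that jump and non-jump distance estimates
            # carry the same few-trial noise bias
            baseline = avg.groups.get((jc, "baseline_matched"),
                                      avg.groups[first_id])
            sources = {
                "jump_first_vs_nonjump_final": avg.groups.get((jc, "first")),
                "jump_final_vs_nonjump_final": avg.groups.get((jc, "final")),
                "nonjump_first_vs_nonjump_final": baseline,
            }
            for label, src in sources.items():
                if src is None:
                    skipped.append((alignment, jc, f"no trials for {label}"))
                    continue
                traces.append(DistanceTrace(
                    time=avg.time, alignment=alignment,
                    d_prep=neural_distance(src, ref_final, pair.Q_prep),
                    d_move=neural_distance(src, ref_final, pair.Q_move),
                    pair_label=label, condition=jc))
    return traces, skipped


def mean_sem_across_conditions(traces, alignment: str, pair_label: str,
                               which: str = "d_prep"):
    """Across-condition mean +/- s.e.m. of one trace family."""
    sel = [getattr(t, which) for t in traces
           if t.alignment == alignment and t.pair_label == pair_label]
    if not sel:
        raise StatisticsError(
            f"no traces for {pair_label!r} aligned to {alignment!r}")
    M = np.vstack(sel)
    sem = M.std(axis=0, ddof=1) / np.sqrt(M.shape[0]) if M.shape[0] > 1 \
        else np.zeros(M.shape[1])
    return M.mean(axis=0), sem, M.shape[0]


def movement_epoch_distance_test(traces, window: tuple = (0.0, 0.2),
                                 exact_max_n: int = 25):
    """Rank-sum test: corrected-jump vs non-jump preparatory distance.

    Per jump condition, the preparatory-space distance is averaged over
    ``window`` after movement onset for (i) jump trials initiated toward
    the first target vs the non-jump final trajectory and (ii) the two
    non-jump trajectories.  Returns (statistic, p, jump_means,
    nonjump_means) from a two-sided Mann-Whitney/Wilcoxon rank-sum across
    conditions (exact when both groups are small and untied).
    """
    move_traces = [t for t in traces if t.alignment == "move_onset"]

    def _means(pair_label):
        vals = {}
        for t in move_traces:
            if t.pair_label != pair_label:
                continue
            mask = (t.time >= window[0] - 1e-9) & (t.time <= window[1] + 1e-9)
            if not mask.any():
                raise AlignmentError("trace does not cover the test window")
            vals[t.condition] = float(t.d_prep[mask].mean())
        return vals

    jump = _means("jump_first_vs_nonjump_final")
    base = _means("nonjump_first_vs_nonjump_final")
    conds = sorted(set(jump) & set(base))
    if len(conds) < 3:
        raise StatisticsError(
            f"rank-sum test needs >= 3 jump conditions, got {len(conds)}")
    x = np.array([jump[c] for c in conds])
    y = np.array([base[c] for c in conds])
    if np.ptp(np.concatenate([x, y])) == 0:
        return 0.0, 1.0, jump, base   # identical distributions
    method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n
                         and np.unique(np.concatenate([x, y])).size
                         == len(x) + len(y)) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), jump, base
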