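"""Event-level scoring, workload reduction, threshold sweeps, group statistics.

Consecutive flagged 60-s intervals merge into one detected event.  A
detected event overlapping at least one expert-marked seizure is a true
positive event; multiple detected events on one seizure still count that
seizure once, so TP + FN always equals the number of marked seizures.
Sensitivity is TPR = TP/(TP+FN) x 100%, precision PPV = TP/(TP+FP) x 100%.
The workload reduction P_reduc = 100 (t_base - t_TP - t_FP) / t_base is
the share of the recording an expert no longer needs to review when only
flagged episodes are checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import Segmentation
from .recording import Marking


@dataclass(frozen=True)
class Event:
    start_s: float
    end_s: float

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, iv) -> bool:
        return self.start_s < iv.end_s and iv.start_s < self.end_s


@dataclass
class EventSet:
    """Disjoint, sorted detected events, each a union of whole intervals."""

    events: tuple[Event, ...] = ()

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


@dataclass
class EvalReport:
    TP: int
    FP: int
    FN: int
    TPR: float | None        # percent; None when no true events exist
    PPV: float | None        # percent; None when there are no detections
    t_TP: float              # minutes of true-positive detected events
    t_FP: float              # minutes of false-positive detected events
    t_base: float            # minutes reviewed without the detector
    P_reduc: float
    extras: dict = field(default_factory=dict)


def merge_events(flags: np.ndarray, seg: Segmentation) -> EventSet:
    """Maximal runs of consecutive flagged intervals become single events."""
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != seg.M:
        raise ValueError(f"flags length {len(flags)} != M {seg.M}")
    events = []
    bounds = seg.interval_bounds
    m = 0
    while m < seg.M:
        if flags[m]:
            start = bounds[m][0]
            while m + 1 < seg.M and flags[m + 1]:
                m += 1
            events.append(Event(start, bounds[m][1]))
        m += 1
    return EventSet(tuple(events))


def match_events(
    detected: EventSet, truth: Marking, min_overlap_fraction: float = 0.0
) -> tuple[int, int, int]:
    """Match detected events to expert-marked seizures.

    Returns event counts (TP, FP, FN).  TP counts *seizures* that at least
    one detected event overlaps; FP counts detected events overlapping no
    seizure; FN counts seizures no event overlaps.  With a nonzero
    ``min_overlap_fraction`` an overlap only counts when it covers at
    least that fraction of the seizure's duration.
    """
    seizures = truth.seizures
    detected_seizure = np.zeros(len(seizures), dtype=bool)
    fp = 0
    for ev in detected:
        hit = False
        for k, sz in enumerate(seizures):
            ov = min(ev.end_s, sz.end_s) - max(ev.start_s, sz.start_s)
            if ov > 0 and ov >= min_overlap_fraction * sz.duration:
                detected_seizure[k] = True
                hit = True
        if not hit:
            fp += 1
    tp = int(detected_seizure.sum())
    fn = len(seizures) - tp
    return tp, fp, fn


def tpr(TP: int, FN: int) -> float | None:
    """True positive rate, percent; None (missing) when no true events."""
    if TP + FN == 0:
        return None
    return 100.0 * TP / (TP + FN)


def ppv(TP: int, FP: int) -> float | None:
    """Positive predictive value, percent; None when there are no detections."""
    if TP + FP == 0:
        return None
    return 100.0 * TP / (TP + FP)


def workload_reduction(t_TP: float, t_FP: float, t_base: float) -> float:
    """P_reduc = 100 (t_base - t_TP - t_FP) / t_base, percent, 2 decimals.

    Rounded half-up, matching how review-time tables are conventionally
    printed (93.125 -> 93.13).
    """
    if t_base <= 0:
        raise ValueError("t_base must be positive")
    if t_TP + t_FP > t_base + 1e-9:
        raise ValueError("reviewed time exceeds total recording time")
    p = 100.0 * (t_base - t_TP - t_FP) / t_base
    return float(Decimal(repr(p)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def evaluate_subject(
    flags: np.ndarray, seg: Segmentation, truth: Marking, min_overlap_fraction: float = 0.0
) -> EvalReport:
    """Full event-level report for one subject."""
    detected = merge_events(flags, seg)
    TP, FP, FN = match_events(detected, truth, min_overlap_fraction)
    # attribute flagged minutes to TP/FP via the same matching rule
    seizures = truth.seizures
    t_tp = t_fp = 0.0
    for ev in detected:
        is_tp = any(
            min(ev.end_s, sz.end_s) - max(ev.start_s, sz.start_s) > 0
            and (min(ev.end_s, sz.end_s) - max(ev.start_s, sz.start_s))
            >= min_overlap_fraction * sz.duration
            for sz in seizures
        )
        if is_tp:
            t_tp += ev.duration / 60.0
        else:
            t_fp += ev.duration / 60.0
    t_base = seg.M * seg.interval_s / 60.0
    return EvalReport(
        TP=TP, FP=FP, FN=FN,
        TPR=tpr(TP, FN), PPV=ppv(TP, FP),
        t_TP=t_tp, t_FP=t_fp, t_base=t_base,
        P_reduc=workload_reduction(t_tp, t_fp, t_base),
    )


def threshold_sweep(
    subjects: list,
    thresholds=None,
    schemes: tuple[str, ...] = ("cv", "loo"),
    k_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean TPR/PPV over subjects for each (threshold, scheme) cell.

    ``subjects`` is a list of :class:`~eegevt.detector.Subject`.  Undefined
    per-subject TPR/PPV values (zero denominators) are excluded from the
    means rather than coerced to zero.  Fold permutations are held fixed
    across the threshold sweep (same seed).
    """
    from .detector import THRESHOLD_GRID, DetectorConfig, run_scheme

    thresholds = THRESHOLD_GRID if thresholds is None else thresholds
    rows = []
    for scheme in schemes:
        for thr in thresholds:
            cfg = DetectorConfig(threshold=thr, scheme=scheme, k_folds=k_folds, seed=seed)
            results = run_scheme(subjects, cfg)
            tprs, ppvs = [], []
            for subj, res in zip(subjects, results):
                rep = evaluate_subject(res.flags, subj.features.segmentation, subj.marking)
                if rep.TPR is not None:
                    tprs.append(rep.TPR)
                if rep.PPV is not None:
                    ppvs.append(rep.PPV)
            rows.append(
                dict(threshold=thr, scheme=scheme,
                     TPR_mean=float(np.mean(tprs)) if tprs else float("nan"),
                     PPV_mean=float(np.mean(ppvs)) if ppvs else float("nan"),
                     n_subjects=len(subjects))
            )
    return pd.DataFrame(rows)


@dataclass
class SchemeComparison:
    wilcoxon: dict
    holm_adjusted: dict
    ks_normality: dict
    degenerate: dict


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(pvals, method="holm")[1]


def compare_schemes(
    tpr_cv, tpr_loo, ppv_cv, ppv_loo
) -> SchemeComparison:
    """Paired comparison of CV vs LOO on per-subject TPR and PPV.

    Kolmogorov-Smirnov normality per sample, Wilcoxon signed-rank on the
    paired differences, Holm correction over the two-test family.
    All-zero difference vectors make Wilcoxon degenerate; those are
    reported as p = 1 and flagged.
    """
    samples = dict(tpr_cv=np.asarray(tpr_cv, float), tpr_loo=np.asarray(tpr_loo, float),
                   ppv_cv=np.asarray(ppv_cv, float), ppv_loo=np.asarray(ppv_loo, float))
    ks = {}
    for name, x in samples.items():
        sd = x.std(ddof=1)
        if sd == 0:
            ks[name] = dict(stat=float("nan"), p=float("nan"), degenerate=True)
        else:
            stat, p = stats.kstest((x - x.mean()) / sd, "norm")
            ks[name] = dict(stat=float(stat), p=float(p), degenerate=False)
    wil, degenerate = {}, {}
    raw_p = []
    for metric, (a, b) in dict(TPR=(samples["tpr_cv"], samples["tpr_loo"]),
                               PPV=(samples["ppv_cv"], samples["ppv_loo"])).items():
        diff = a - b
        if np.all(diff == 0):
            wil[metric] = dict(stat=float("nan"), p=1.0)
            degenerate[metric] = True
            raw_p.append(1.0)
        else:
            stat, p = stats.wilcoxon(a, b)
            wil[metric] = dict(stat=float(stat), p=float(p))
            degenerate[metric] = False
            raw_p.append(float(p))
    adj = holm_adjust(raw_p)
    holm = {metric: float(adj[i]) for i, metric in enumerate(("TPR", "PPV"))}
    return SchemeComparison(wilcoxon=wil, holm_adjusted=holm, ks_normality=ks,
                            degenerate=degenerate)
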