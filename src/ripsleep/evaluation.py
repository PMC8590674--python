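"""Clinical-agreement evaluation battery.

Everything needed to compare algorithmic sleep staging against manual
reference scoring the way validation studies in sleep medicine report it:

* epoch-by-epoch agreement — pooled 3x3 confusion matrix, Cohen's kappa,
  one-vs-rest sensitivity/specificity per stage;
* summary sleep metrics — total sleep time (TST), sleep efficiency (SE),
  apnea-hypopnea index (AHI) — with Pearson correlation and Bland-Altman
  bias / limits of agreement between methods;
* AHI severity grouping (<5, 5-15, 15-30, >=30 events/h) and per-group
  classification accuracy;
* sleep-onset agreement: a four-fields (2x2) sleep/wake analysis over the
  +/-10 epochs surrounding the reference's first sleep epoch;
* rank-based group comparisons (Mann-Whitney U, Kruskal-Wallis).

Statistics that are undefined for an input (AHI at TST = 0, Pearson r with
fewer than 3 pairs or zero variance) are reported as explicit ``None`` /
NaN markers, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .types import (
    EPOCH_SECONDS,
    SLEEP_STAGES,
    STAGES,
    RespiratoryEventList,
    as_hypnogram,
    is_sleep,
)

__all__ = [
    "ConfusionMatrix3",
    "SleepMetrics",
    "AgreementReport",
    "confusion_matrix",
    "cohens_kappa",
    "stage_sensitivity_specificity",
    "sleep_metrics",
    "severity_group",
    "group_accuracy",
    "agreement_stats",
    "sleep_onset_agreement",
    "rank_test_two_groups",
    "rank_test_k_groups",
    "evaluate_cohort",
]


@dataclass
class ConfusionMatrix3:
    """3x3 stage confusion matrix, rows = reference, cols = predicted,
    both in (WAKE, REM, NREM) order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(self.counts < 0) or not np.issubdtype(
            self.counts.dtype, np.integer
        ):
            raise ValueError("confusion matrix entries must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix3") -> "ConfusionMatrix3":
        return ConfusionMatrix3(self.counts + other.counts)


def confusion_matrix(reference, predicted) -> ConfusionMatrix3:
    """Tally reference-vs-predicted stage counts for paired hypnograms."""
    ref = as_hypnogram(reference)
    pred = as_hypnogram(predicted)
    if len(ref) != len(pred):
        raise ValueError(
            f"hypnogram length mismatch: reference has {len(ref)} epochs, "
            f"prediction has {len(pred)}"
        )
    counts = np.zeros((3, 3), dtype=np.int64)
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    for r, p in zip(ref, pred):
        counts[stage_idx[r], stage_idx[p]] += 1
    return ConfusionMatrix3(counts)


def cohens_kappa(cm: ConfusionMatrix3) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    ``p_o`` is the observed agreement (trace / total) and ``p_e`` the
    agreement expected from the marginals.  When both raters are constant
    and identical (p_e = p_o = 1) the agreement is perfect and 1.0 is
    returned.
    """
    n = cm.total
    if n == 0:
        raise ValueError("cannot compute kappa on an empty confusion matrix")
    c = cm.counts.astype(float)
    p_o = np.trace(c) / n
    p_e = float(np.sum(c.sum(axis=1) * c.sum(axis=0)) / n**2)
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def stage_sensitivity_specificity(
    cm: ConfusionMatrix3, stage: str
) -> tuple[float, float]:
    """One-vs-rest sensitivity and specificity for one stage.

    Sensitivity = TP / (TP + FN) over the stage's reference row;
    specificity = TN / (TN + FP) over all non-stage reference epochs.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    i = STAGES.index(stage)
    c = cm.counts.astype(float)
    row = c[i].sum()
    if row == 0:
        raise ValueError(
            f"sensitivity undefined: no reference epochs for stage {stage}"
        )
    tp = c[i, i]
    rest = np.delete(np.arange(3), i)
    fp = c[rest, i].sum()
    tn = c[np.ix_(rest, rest)].sum()
    if fp + tn == 0:
        raise ValueError(
            f"specificity undefined: no reference epochs outside stage {stage}"
        )
    return float(tp / row), float(tn / (tn + fp))


@dataclass
class SleepMetrics:
    """Summary sleep metrics for one night.

    ``ahi`` is ``None`` (undefined, not zero) when TST = 0.
    """

    tst: float  # minutes
    se: float  # percent of analysis duration
    ahi: float | None  # events per hour of sleep
    analysis_duration: float  # minutes

    def __post_init__(self) -> None:
        if not 0 <= self.tst <= self.analysis_duration + 1e-9:
            raise ValueError("TST must lie within [0, analysis_duration]")
        if not 0 <= self.se <= 100 + 1e-9:
            raise ValueError("SE must lie in [0, 100]")
        if self.ahi is not None and self.ahi < 0:
            raise ValueError("AHI must be non-negative")


def sleep_metrics(
    hypnogram,
    events: RespiratoryEventList | int,
    analysis_duration: float,
) -> SleepMetrics:
    """Compute TST, SE and AHI from a hypnogram and scored events.

    Parameters
    ----------
    hypnogram : sequence of stage labels
    events : RespiratoryEventList or int
        Scored respiratory events (or just their count).
    analysis_duration : float
        Analysis window (time in bed) in **minutes**; must cover the
        hypnogram span.

    TST = 0.5 min per sleep epoch; SE = 100 * TST / analysis_duration;
    AHI = events per hour of sleep, ``None`` when TST = 0.
    """
    hyp = as_hypnogram(hypnogram)
    span_min = len(hyp) * EPOCH_SECONDS / 60.0
    if analysis_duration + 1e-9 < span_min:
        raise ValueError(
            f"analysis_duration ({analysis_duration} min) is shorter than "
            f"the hypnogram span ({span_min} min)"
        )
    n_events = len(events) if not isinstance(events, int) else events
    tst = float(is_sleep(hyp).sum()) * EPOCH_SECONDS / 60.0
    se = 100.0 * tst / analysis_duration if analysis_duration > 0 else 0.0
    ahi = None if tst == 0 else n_events / (tst / 60.0)
    return SleepMetrics(tst=tst, se=se, ahi=ahi,
                        analysis_duration=analysis_duration)


def severity_group(ahi: float) -> int:
    """Map an AHI to its SDB severity group.

    [0, 5) -> 1 (none), [5, 15) -> 2 (mild), [15, 30) -> 3 (moderate),
    [30, inf) -> 4 (severe).
    """
    if ahi < 0 or not np.isfinite(ahi):
        raise ValueError(f"AHI must be a finite non-negative number, got {ahi}")
    if ahi < 5:
        return 1
    if ahi < 15:
        return 2
    if ahi < 30:
        return 3
    return 4


def group_accuracy(
    reference_ahis: Sequence[float], estimated_ahis: Sequence[float]
) -> dict[int, dict[str, float | int | None]]:
    """One-vs-rest severity-group classification accuracy.

    For each group g: sensitivity = P(estimated group = g | reference
    group = g), specificity = P(estimated group != g | reference group
    != g), n = number of reference members.  Undefined entries (empty
    group) are ``None``.
    """
    ref = np.asarray(reference_ahis, dtype=float)
    est = np.asarray(estimated_ahis, dtype=float)
    if ref.size == 0:
        raise ValueError("empty input")
    if ref.shape != est.shape:
        raise ValueError("reference and estimated AHI vectors differ in length")
    ref_g = np.array([severity_group(a) for a in ref])
    est_g = np.array([severity_group(a) for a in est])
    out: dict[int, dict] = {}
    for g in (1, 2, 3, 4):
        in_g = ref_g == g
        n = int(in_g.sum())
        sens = float(np.mean(est_g[in_g] == g)) if n else None
        spec = float(np.mean(est_g[~in_g] != g)) if (~in_g).any() else None
        out[g] = {"sensitivity": sens, "specificity": spec, "n": n}
    return out


def agreement_stats(
    reference_values: Sequence[float], estimated_values: Sequence[float]
) -> dict[str, float | tuple[float, float] | None]:
    """Pearson correlation and Bland-Altman agreement between two methods.

    bias = mean(estimated - reference), so a positive bias is an
    overestimation by the algorithm.  Limits of agreement are
    bias +/- 1.96 * SD(differences).  ``r`` is ``None`` when undefined
    (n < 3 or zero variance in either vector).
    """
    ref = np.asarray(reference_values, dtype=float)
    est = np.asarray(estimated_values, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("paired vectors differ in length")
    if ref.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(est))):
        raise ValueError("inputs must be finite")
    diff = est - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    if ref.std() == 0 or est.std() == 0:
        r = None
    else:
        r = float(stats.pearsonr(ref, est).statistic)
    return {"pearson_r": r, "bias": bias, "loa": loa}


def sleep_onset_agreement(
    reference_hyp, predicted_hyp, half_width: int = 10
) -> dict:
    """Four-fields sleep/wake agreement around the reference sleep onset.

    The comparison window spans ``half_width`` epochs before and after the
    first reference sleep epoch (inclusive; truncated at record
    boundaries).  Both hypnograms are binarized to sleep/wake within the
    window; sleep is the positive class.

    Returns a dict with the 2x2 table (tp, fp, fn, tn), sensitivity,
    specificity and F1 = 2TP / (2TP + FP + FN).  Entries undefined for the
    window (e.g. specificity with no reference wake epochs) are ``None``.
    """
    ref = as_hypnogram(reference_hyp)
    pred = as_hypnogram(predicted_hyp)
    if len(ref) != len(pred):
        raise ValueError("hypnogram length mismatch")
    ref_sleep = is_sleep(ref)
    if not ref_sleep.any():
        raise ValueError("reference contains no sleep; onset undefined")
    onset = int(np.argmax(ref_sleep))
    lo = max(0, onset - half_width)
    hi = min(len(ref), onset + half_width + 1)
    r = ref_sleep[lo:hi]
    p = is_sleep(pred)[lo:hi]
    tp = int(np.sum(r & p))
    fp = int(np.sum(~r & p))
    fn = int(np.sum(r & ~p))
    tn = int(np.sum(~r & ~p))
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    return {
        "window": (lo, hi),
        "n_compared": hi - lo,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": sens, "specificity": spec, "f1": f1,
    }


def rank_test_two_groups(a: Sequence[float], b: Sequence[float]):
    """Two-sided Mann-Whitney U test for a distributional shift.

    Uses exact enumeration for small samples (both n <= 8, no ties) and
    the continuity-corrected normal approximation with midrank tie
    handling otherwise.  Returns ``(U_of_a, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def rank_test_k_groups(groups: Sequence[Sequence[float]]):
    """Kruskal-Wallis H test (tie-corrected, chi-square reference).

    Returns ``(H, p)``; identical values across all groups give H = 0 and
    p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # scipy raises when all values are tied
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AgreementReport:
    """Full cohort-level agreement summary (see :func:`evaluate_cohort`)."""

    confusion: ConfusionMatrix3
    kappa: float
    per_stage: dict[str, dict[str, float]]
    subjects: list[dict]
    metric_agreement: dict[str, dict]
    group_accuracy: dict[int, dict]
    onset: dict
    group_tests: dict[str, dict]

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion.counts.tolist(),
            "stages": list(STAGES),
            "kappa": self.kappa,
            "per_stage": self.per_stage,
            "subjects": self.subjects,
            "metric_agreement": self.metric_agreement,
            "group_accuracy": {str(k): v for k, v in self.group_accuracy.items()},
            "sleep_onset": self.onset,
            "group_tests": self.group_tests,
        }


def _mean_or_none(values: list[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def evaluate_cohort(
    cohort: list[tuple[np.ndarray, np.ndarray, RespiratoryEventList, float]],
) -> AgreementReport:
    """Run the full validation battery on a cohort.

    Parameters
    ----------
    cohort : list of (reference_hyp, predicted_hyp, events, analysis_duration)
        One entry per subject; ``analysis_duration`` in minutes.  The same
        scored event list feeds both AHI variants — only the sleep-time
        denominator differs between the reference (manual TST) and the
        estimate (algorithm TST).

    The report pools epochs across subjects for the confusion matrix and
    kappa; per-subject TST/SE/AHI pairs feed Pearson/Bland-Altman
    agreement, severity-group accuracy, averaged sleep-onset analysis, and
    Kruskal-Wallis tests of the TST/SE estimation error across severity
    groups.
    """
    if not cohort:
        raise ValueError("cohort is empty")

    pooled = ConfusionMatrix3(np.zeros((3, 3), dtype=np.int64))
    subjects = []
    onset_rows = []
    for i, (ref, pred, events, dur) in enumerate(cohort):
        sid = f"subject {i}"
        try:
            pooled = pooled + confusion_matrix(ref, pred)
            m_ref = sleep_metrics(ref, events, dur)
            m_est = sleep_metrics(pred, events, dur)
            onset = (
                sleep_onset_agreement(ref, pred)
                if is_sleep(ref).any()
                else None
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{sid}: {exc}") from exc
        if onset is not None:
            onset_rows.append(onset)
        subjects.append({
            "subject": i,
            "reference": {"tst": m_ref.tst, "se": m_ref.se, "ahi": m_ref.ahi},
            "estimated": {"tst": m_est.tst, "se": m_est.se, "ahi": m_est.ahi},
            "analysis_duration": dur,
        })

    kappa = cohens_kappa(pooled)
    per_stage = {}
    for s in STAGES:
        try:
            sens, spec = stage_sensitivity_specificity(pooled, s)
            per_stage[s] = {"sensitivity": sens, "specificity": spec}
        except ValueError:
            per_stage[s] = {"sensitivity": None, "specificity": None}

    metric_agreement: dict[str, dict] = {}
    defined = [
        s for s in subjects
        if s["reference"]["ahi"] is not None and s["estimated"]["ahi"] is not None
    ]
    for key in ("tst", "se", "ahi"):
        rows = defined if key == "ahi" else subjects
        ref_v = [s["reference"][key] for s in rows]
        est_v = [s["estimated"][key] for s in rows]
        if len(ref_v) >= 3:
            metric_agreement[key] = agreement_stats(ref_v, est_v)
        else:
            metric_agreement[key] = {"pearson_r": None, "bias": None,
                                     "loa": None, "note": "n < 3"}

    if defined:
        ga = group_accuracy(
            [s["reference"]["ahi"] for s in defined],
            [s["estimated"]["ahi"] for s in defined],
        )
    else:
        ga = {g: {"sensitivity": None, "specificity": None, "n": 0}
              for g in (1, 2, 3, 4)}

    onset_summary = {
        "n_subjects": len(onset_rows),
        "sensitivity": _mean_or_none([o["sensitivity"] for o in onset_rows]),
        "specificity": _mean_or_none([o["specificity"] for o in onset_rows]),
        "f1": _mean_or_none([o["f1"] for o in onset_rows]),
    }

    # estimation-error spread across severity groups (reference grouping)
    group_tests: dict[str, dict] = {}
    for key in ("tst", "se"):
        by_group: dict[int, list[float]] = {}
        for s in defined:
            g = severity_group(s["reference"]["ahi"])
            by_group.setdefault(g, []).append(
                s["estimated"][key] - s["reference"][key]
            )
        nonempty = [v for v in by_group.values() if v]
        if len(nonempty) >= 2:
            h, p = rank_test_k_groups(nonempty)
            group_tests[key] = {"H": h, "p": p,
                                "groups": sorted(g for g, v in by_group.items() if v)}
        else:
            group_tests[key] = {"H": None, "p": None,
                                "note": "fewer than 2 non-empty severity groups"}

    return AgreementReport(
        confusion=pooled,
        kappa=kappa,
        per_stage=per_stage,
        subjects=subjects,
        metric_agreement=metric_agreement,
        group_accuracy=ga,
        onset=onset_summary,
        group_tests=group_tests,
    )
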