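"""Statistics for the two-arm rater trial.

Covers the design and analysis machinery of a randomized rater study:
stratified 1:1 allocation (permuted blocks within profession x experience
strata), answer-key scoring of rater responses into per-participant
sensitivity and specificity, a normality-gated two-group comparison
(Shapiro-Wilk, then Welch t or Mann-Whitney), the two-sample t-test power /
sample-size computation via the noncentral t distribution, and a seeded
rater-response simulator so the whole pipeline is testable without human
data.

Sensitivity is the probability of correctly identifying an asynchrony
(scored per scenario against the key's primary label), specificity the
probability of correctly identifying its absence (synchronous scenarios
called synchronous). Per-type sensitivity requires the exact type match; the
looser "any asynchrony" sensitivity is reported alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .battery import AnswerKey
from .labeler import ASYNCHRONY_LABELS, LABELS, SYNCHRONOUS

__all__ = [
    "Participant",
    "RaterResponse",
    "RaterPerformance",
    "GroupComparison",
    "allocate_stratified",
    "score_responses",
    "compare_groups",
    "power_at",
    "required_sample_size",
    "monte_carlo_power",
    "simulate_rater_responses",
]

PROFESSIONS = ("physician", "respiratory_therapist")
EXPERIENCE_STRATA = ("<=5y", ">5y")
GROUPS = ("control", "pmus")


@dataclass
class Participant:
    id: str
    profession: str
    experience_stratum: str
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.profession not in PROFESSIONS:
            raise ValueError(f"unknown profession {self.profession!r}")
        if self.experience_stratum not in EXPERIENCE_STRATA:
            raise ValueError(f"unknown experience stratum {self.experience_stratum!r}")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class RaterResponse:
    participant_id: str
    scenario_id: int
    answered_label: str

    def __post_init__(self) -> None:
        if self.answered_label not in LABELS:
            raise ValueError(f"unknown label {self.answered_label!r}")


@dataclass
class RaterPerformance:
    participant_id: str
    sensitivity: float  # exact-type match over asynchronous scenarios
    sensitivity_any: float  # any-asynchrony detection over asynchronous scenarios
    specificity: float
    per_type_sensitivity: dict[str, float] = field(default_factory=dict)
    complete: bool = True


@dataclass
class GroupComparison:
    test_used: str  # student_t | mann_whitney
    p_value: float
    group_summaries: dict[str, dict[str, float]]
    significant: bool


def allocate_stratified(
    participants: Sequence[Participant], seed: int = 0, block_size: int = 2
) -> list[Participant]:
    """1:1 permuted-block randomization within (profession x experience)
    strata; per-stratum group sizes differ by at most one."""
    rng = np.random.default_rng(seed)
    out: list[Participant] = []
    strata: dict[tuple[str, str], list[Participant]] = {}
    for p in participants:
        strata.setdefault((p.profession, p.experience_stratum), []).append(p)
    for key in sorted(strata):
        members = strata[key]
        order = rng.permutation(len(members))
        for b_start in range(0, len(members), block_size):
            block_idx = order[b_start : b_start + block_size]
            labels = ["control", "pmus"] * (block_size // 2 + 1)
            labels = labels[: len(block_idx)]
            labels = [labels[i] for i in rng.permutation(len(labels))]
            for i, g in zip(block_idx, labels):
                p = members[i]
                out.append(Participant(p.id, p.profession, p.experience_stratum, g))
    return out


def score_responses(
    responses: Sequence[RaterResponse] | pd.DataFrame, key: AnswerKey
) -> list[RaterPerformance]:
    """Score each participant's responses against the answer key.

    A response is correct on an asynchronous scenario when it matches the
    key's primary label exactly; a synchronous scenario is correct when called
    synchronous. Participants with missing responses are flagged
    (``complete=False``) and should be excluded from group means; a warning is
    emitted.
    """
    if isinstance(responses, pd.DataFrame):
        responses = [
            RaterResponse(str(r.participant_id), int(r.scenario_id), str(r.answered_label))
            for r in responses.itertuples()
        ]
    scenario_ids = set(key.entries)
    by_participant: dict[str, dict[int, str]] = {}
    for r in responses:
        if r.scenario_id not in scenario_ids:
            raise ValueError(f"response for unknown scenario {r.scenario_id}")
        d = by_participant.setdefault(r.participant_id, {})
        if r.scenario_id in d:
            raise ValueError(
                f"duplicate response (participant {r.participant_id}, "
                f"scenario {r.scenario_id})"
            )
        d[r.scenario_id] = r.answered_label

    out = []
    for pid in sorted(by_participant):
        answers = by_participant[pid]
        complete = set(answers) == scenario_ids
        if not complete:
            warnings.warn(
                f"participant {pid} missing {len(scenario_ids) - len(answers)} "
                "responses; flagged and excluded from means",
                stacklevel=2,
            )
        n_asynch = n_correct = n_any = n_syn = n_syn_correct = 0
        per_type_n: dict[str, int] = {t: 0 for t in ASYNCHRONY_LABELS}
        per_type_c: dict[str, int] = {t: 0 for t in ASYNCHRONY_LABELS}
        for sid, truth_all in key.entries.items():
            if sid not in answers:
                continue
            truth = truth_all[0]
            ans = answers[sid]
            if truth == SYNCHRONOUS:
                n_syn += 1
                n_syn_correct += ans == SYNCHRONOUS
            else:
                n_asynch += 1
                n_correct += ans == truth
                n_any += ans != SYNCHRONOUS
                per_type_n[truth] += 1
                per_type_c[truth] += ans == truth
        out.append(
            RaterPerformance(
                participant_id=pid,
                sensitivity=n_correct / n_asynch if n_asynch else math.nan,
                sensitivity_any=n_any / n_asynch if n_asynch else math.nan,
                specificity=n_syn_correct / n_syn if n_syn else math.nan,
                per_type_sensitivity={
                    t: (per_type_c[t] / per_type_n[t]) if per_type_n[t] else math.nan
                    for t in ASYNCHRONY_LABELS
                },
                complete=complete,
            )
        )
    return out


def _normalish(x: np.ndarray, alpha: float = 0.05) -> bool:
    if np.ptp(x) == 0:  # constant sample: Shapiro-Wilk undefined
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return stats.shapiro(x).pvalue > alpha
        except ValueError:
            return False


def compare_groups(
    perf_control: Sequence[float],
    perf_pmus: Sequence[float],
    alpha: float = 0.05,
    pooled_t: bool = False,
) -> GroupComparison:
    """Normality-gated two-group comparison.

    Shapiro-Wilk on each group at alpha = 0.05: both normal -> two-sample t
    (Welch by default; ``pooled_t=True`` selects the pooled-variance classic
    variant) reported as mean +/- sd; otherwise Mann-Whitney reported as
    median (IQR). Two identical constant groups compare with p = 1.
    """
    a = np.asarray(perf_control, dtype=float)
    b = np.asarray(perf_pmus, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")

    def summary(x: np.ndarray) -> dict[str, float]:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {
            "n": int(x.size),
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)),
            "median": float(med),
            "iqr_low": float(q1),
            "iqr_high": float(q3),
        }

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
        test = "mann_whitney"
    elif _normalish(a) and _normalish(b):
        test = "student_t"
        p = float(stats.ttest_ind(a, b, equal_var=pooled_t).pvalue)
    else:
        test = "mann_whitney"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return GroupComparison(
        test_used=test,
        p_value=p,
        group_summaries={"control": summary(a), "pmus": summary(b)},
        significant=p < alpha,
    )


def power_at(n_per_group: int, delta: float, sd: float, alpha: float = 0.05) -> float:
    """Two-sample two-sided t-test power at n per group via the noncentral t.

    ``delta`` and ``sd`` share units (e.g. percentage points).
    """
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    ncp = delta / (sd * math.sqrt(2.0 / n_per_group))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def required_sample_size(
    delta_pp: float, sd_pp: float, power: float = 0.9, alpha_two_sided: float = 0.05
) -> tuple[int, int]:
    """Smallest n per group with two-sample t-test power >= target.

    Returns (n per group, total). Iterates the noncentral-t power upward from
    a normal-approximation starting point.
    """
    if not (0 < power < 1 and 0 < alpha_two_sided < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    if delta_pp <= 0 or sd_pp <= 0:
        raise ValueError("delta and sd must be positive")
    za = stats.norm.ppf(1 - alpha_two_sided / 2)
    zb = stats.norm.ppf(power)
    n0 = max(2, int(math.floor(2.0 * ((za + zb) * sd_pp / delta_pp) ** 2)) - 2)
    n = n0
    while power_at(n, delta_pp, sd_pp, alpha_two_sided) < power:
        n += 1
        if n > 10_000_000:
            raise ValueError("unattainable sample-size inputs")
    return n, 2 * n


def monte_carlo_power(
    n_per_group: int,
    delta: float,
    sd: float,
    alpha: float = 0.05,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> float:
    """Simulated rejection proportion of the Welch t-test for two normal
    groups differing by ``delta`` (vectorized over replicates)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, (n_replicates, n_per_group))
    b = rng.normal(delta, sd, (n_replicates, n_per_group))
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return float(np.mean(res.pvalue < alpha))


def simulate_rater_responses(
    key: AnswerKey,
    sensitivity: float | dict[str, float],
    specificity: float,
    seed: int = 0,
    participant_id: str = "r0",
    confusion: Optional[dict[str, float]] = None,
) -> list[RaterResponse]:
    """Generate one rater's seeded responses to every scenario of the key.

    On each asynchronous scenario the rater answers the true type with its
    (per-type or scalar) sensitivity; otherwise an incorrect label is drawn
    from ``confusion`` (default: uniform over the remaining labels, including
    synchronous). Synchronous scenarios are answered correctly with
    probability ``specificity``, otherwise a uniform asynchrony label.
    """
    rng = np.random.default_rng(seed)
    if isinstance(sensitivity, dict):
        sens = {t: float(sensitivity.get(t, 0.0)) for t in ASYNCHRONY_LABELS}
    else:
        sens = {t: float(sensitivity) for t in ASYNCHRONY_LABELS}
    for v in list(sens.values()) + [specificity]:
        if not (0.0 <= v <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")

    responses = []
    for sid in sorted(key.entries):
        truth = key.entries[sid][0]
        if truth == SYNCHRONOUS:
            if rng.random() < specificity:
                ans = SYNCHRONOUS
            else:
                ans = str(rng.choice(ASYNCHRONY_LABELS))
        else:
            if rng.random() < sens[truth]:
                ans = truth
            else:
                if confusion:
                    cand = [l for l in confusion if l != truth]
                    w = np.array([confusion[l] for l in cand], dtype=float)
                    ans = str(rng.choice(cand, p=w / w.sum()))
                else:
                    cand = [l for l in LABELS if l != truth]
                    ans = str(rng.choice(cand))
        responses.append(RaterResponse(participant_id, sid, ans))
    return responses
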