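"""Noninvasive Pmus estimation from airway pressure, flow, and volume.

The transparent route inverts the single-compartment equation of motion: with
mechanics estimates (R-hat, C-hat, P0-hat),

    Pmus_hat(t) = R_hat * V'(t) + V(t) * E_hat + P0_hat - Paw(t),

re-zeroed per breath on the expiratory-baseline median, floored at zero
(muscle pressure is displayed nonnegative) and lightly smoothed. Mechanics are
identified by least squares on passive breaths, or — when no breath is known
passive — by an iteratively reweighted fit that down-weights effort-suspect
samples (effort makes the airway pressure fall *below* the passive model, so
only negative residuals are down-weighted).

The robust full-record fit exploits the structure of assisted breaths, where
no sample is guaranteed effort-free and a plain regression would absorb the
effort into the mechanics:

- P0 is the median airway pressure over expiration (the circuit holds PEEP);
- the expiratory time constant tau = R*C comes from the passive expiratory
  manifold flow = -V/tau, with effort-suspect samples masked iteratively
  (effort makes flow + V/tau strictly positive);
- R comes from the expiratory-switch jump: at cycle-off the ventilator drops
  the airway pressure sharply while volume and muscle pressure are continuous,
  so R = dPaw/dFlow across the transition (the flow-interruption principle);
  the per-breath ratios are pooled by median;
- E = R/tau closes the triplet.

An optional recurrent-network estimator trained on simulator output lives in
:mod:`pvsim.rnn`; this module's :func:`evaluate_estimator` scores either
method against the gold channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .waveform import (
    PHASE_EXP,
    PHASE_INSP,
    BreathSignals,
    EffortEpisode,
    detect_effort_episodes,
)

__all__ = [
    "MechanicsEstimate",
    "PmusEstimate",
    "UnidentifiableError",
    "fit_mechanics",
    "estimate_pmus_model_based",
    "evaluate_estimator",
]

#: Minimum effort-episode duration (s) used when detecting efforts on an
#: *estimated* Pmus channel: longer than the gold-channel default so brief
#: inversion blips from circuit artifacts are not mistaken for efforts.
ESTIMATE_MIN_EFFORT_DURATION_S = 0.25


class UnidentifiableError(RuntimeError):
    """Raised when the regression design cannot identify the mechanics."""


@dataclass
class MechanicsEstimate:
    """Respiratory mechanics identified from a record.

    resistance_hat cmH2O.s/L, compliance_hat mL/cmH2O, peep_hat cmH2O
    (the fitted baseline pressure P0), fit_residual_rms cmH2O.
    """

    resistance_hat: float
    compliance_hat: float
    peep_hat: float
    fit_residual_rms: float
    method: str = "passive_ls"

    def __post_init__(self) -> None:
        if self.resistance_hat <= 0 or self.compliance_hat <= 0:
            raise ValueError("fitted resistance and compliance must be positive")

    @property
    def elastance_hat(self) -> float:
        return 1000.0 / self.compliance_hat


@dataclass
class PmusEstimate:
    series: np.ndarray
    method: str  # model_based | recurrent
    rms_error_vs_gold: Optional[float] = None


def _design(signals: BreathSignals, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # The equation of motion is pointwise linear, so smoothing response and
    # regressors with the same kernel preserves it exactly while averaging
    # down measurement noise (avoids errors-in-variables attenuation of R).
    n_win = max(1, int(round(0.05 * signals.fs)))
    flow_s = _smooth(signals.flow, n_win)
    vol_s = _smooth(signals.volume, n_win)
    paw_s = _smooth(signals.paw, n_win)
    X = np.column_stack([flow_s[mask], vol_s[mask], np.ones(int(mask.sum()))])
    return X, paw_s[mask]


def _solve(X: np.ndarray, y: np.ndarray, w: Optional[np.ndarray] = None) -> np.ndarray:
    if w is not None:
        sw = np.sqrt(w)
        X = X * sw[:, None]
        y = y * sw
    beta, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3 or sv[0] / max(sv[-1], 1e-300) > 1e8:
        raise UnidentifiableError(
            "mechanics not identifiable from this record (rank-deficient design: "
            "insufficient flow/volume excitation)"
        )
    return beta


def _robust_full_record_fit(signals: BreathSignals) -> tuple[float, float, float, float]:
    """Structure-exploiting mechanics identification on effortful records.

    Returns (R, E, P0, residual_rms). Requires the phase channel (expiratory
    segments and cycle-off transitions are the information source).
    """
    if signals.phase is None:
        raise ValueError(
            "robust full-record fit needs the ventilator phase channel "
            "(expiratory segments and cycle-off transitions)"
        )
    ph = signals.phase
    f, V, y = signals.flow, signals.volume, signals.paw
    exp = ph == PHASE_EXP
    if not np.any(exp):
        raise UnidentifiableError("record contains no expiratory samples")
    P0 = float(np.median(y[exp]))

    # expiratory time constant from the passive manifold flow = -V/tau;
    # effort makes (flow + V/tau) strictly positive -> iterative masking
    m = exp & (np.abs(V) > 0.02)
    if int(m.sum()) < 10:
        raise UnidentifiableError("insufficient expiratory excursion for tau")
    inv_tau = -float(np.sum(f[m] * V[m]) / np.sum(V[m] ** 2))
    for _ in range(6):
        if inv_tau <= 0:
            raise UnidentifiableError("nonphysical expiratory time constant")
        z = f + V * inv_tau
        m = exp & (np.abs(V) > 0.02) & (z < 0.05)
        if int(m.sum()) < 10:
            break
        inv_tau = -float(np.sum(f[m] * V[m]) / np.sum(V[m] ** 2))
    if inv_tau <= 0:
        raise UnidentifiableError("nonphysical expiratory time constant")
    tau = 1.0 / inv_tau

    # R from the cycle-off jump (flow-interruption principle): Paw and flow
    # jump together at the expiratory switch while V and Pmus are continuous.
    offs = np.flatnonzero((ph[1:] == PHASE_EXP) & (ph[:-1] == PHASE_INSP)) + 1
    ratios = []
    for k1 in offs:
        k0 = k1 - 1
        df = f[k1] - f[k0]
        dp = y[k1] - y[k0]
        if abs(df) > 0.3 and dp < -1.0:
            ratios.append(dp / df)
    if not ratios:
        raise UnidentifiableError(
            "no usable cycle-off transitions for resistance identification"
        )
    R = float(np.median(ratios))
    E = R / tau
    if R <= 0 or E <= 0:
        raise UnidentifiableError("nonphysical robust fit")
    resid = y - (R * f + E * V + P0)
    resid_rms = float(np.sqrt(np.mean(resid[resid >= -0.5] ** 2)))
    return R, E, P0, resid_rms


def fit_mechanics(
    signals: BreathSignals,
    passive_breath_ids: Optional[Sequence[int]] = None,
    robust: bool = False,
) -> MechanicsEstimate:
    """Identify R, C, and the baseline pressure P0 from a record.

    With ``passive_breath_ids``, a plain least-squares fit of
    Paw = R*flow + V*E + P0 over the samples of those (effort-free) ventilator
    cycles. Without them, pass ``robust=True`` to run the structured
    full-record fit (module docstring); otherwise the call fails with an
    explicit instruction (an unflagged record generally contains efforts that
    would bias the plain fit).
    """
    if passive_breath_ids is not None and len(passive_breath_ids) > 0:
        if signals.breath_id is None:
            raise ValueError("record carries no breath_id channel")
        mask = np.isin(signals.breath_id, np.asarray(passive_breath_ids))
        if not np.any(mask):
            raise ValueError("passive_breath_ids select no samples")
        X, y = _design(signals, mask)
        beta = _solve(X, y)
        method = "passive_ls"
        resid = y - X @ beta
        R_hat, E_hat, P0_hat = float(beta[0]), float(beta[1]), float(beta[2])
        resid_rms = float(np.sqrt(np.mean(resid**2)))
    elif robust:
        R_hat, E_hat, P0_hat, resid_rms = _robust_full_record_fit(signals)
        method = "robust_structured"
    else:
        raise ValueError(
            "no passive breaths flagged: pass passive_breath_ids, or set "
            "robust=True to use the robust full-record fit"
        )
    if R_hat <= 0 or E_hat <= 0:
        raise UnidentifiableError(
            f"nonphysical fit (R={R_hat:.3g}, E={E_hat:.3g}); record lacks "
            "passive excitation"
        )
    return MechanicsEstimate(
        resistance_hat=R_hat,
        compliance_hat=1000.0 / E_hat,
        peep_hat=P0_hat,
        fit_residual_rms=resid_rms,
        method=method,
    )


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    pad = n // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad : pad + x.size]
    return out


def estimate_pmus_model_based(
    signals: BreathSignals,
    mech: MechanicsEstimate,
    smooth_window_s: float = 0.05,
) -> PmusEstimate:
    """Invert the equation of motion for the Pmus waveform.

    The raw inversion is smoothed with a centered moving average
    (``smooth_window_s``), re-zeroed per breath on the median of its
    expiratory samples (mechanics misfit shows up as a baseline offset, not as
    effort), and floored at zero.
    """
    raw = (
        mech.resistance_hat * signals.flow
        + mech.elastance_hat * signals.volume
        + mech.peep_hat
        - signals.paw
    )
    n_win = max(1, int(round(smooth_window_s * signals.fs)))
    est = _smooth(raw, n_win)

    if signals.breath_id is not None and signals.phase is not None:
        # Re-zero on the expiratory baseline. Per-breath medians track slow
        # drift, but a breath whose expiration is short or filled by a
        # continuing effort (stacked cycles) has no reliable baseline of its
        # own -> fall back to the record-wide expiratory median.
        all_exp = signals.phase == PHASE_EXP
        global_base = float(np.median(est[all_exp])) if np.any(all_exp) else float(np.median(est))
        min_baseline_samples = int(round(0.8 * signals.fs))
        for bid in np.unique(signals.breath_id):
            in_breath = signals.breath_id == bid
            expir = in_breath & all_exp
            if int(expir.sum()) >= min_baseline_samples:
                base = float(np.median(est[expir]))
            else:
                base = global_base
            est[in_breath] = est[in_breath] - base
    else:
        est = est - np.median(est)
    est = np.maximum(est, 0.0)

    rms = None
    if signals.pmus_true is not None:
        rms = float(np.sqrt(np.mean((est - signals.pmus_true) ** 2)))
    return PmusEstimate(series=est, method="model_based", rms_error_vs_gold=rms)


def evaluate_estimator(
    estimate: np.ndarray,
    gold: np.ndarray,
    time: np.ndarray,
    scenario_id: Optional[int] = None,
    method: str = "model_based",
    onset_threshold: float = 0.5,
) -> dict:
    """Per-record error metrics of an estimated Pmus series vs gold.

    Returns rms error, peak-amplitude error (max estimate - max gold), and
    mean onset-time error over effort episodes matched by nearest onset
    (positive = estimate detects the onset late). Series must be aligned.
    """
    estimate = np.asarray(estimate, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if estimate.shape != gold.shape:
        raise ValueError(
            f"length mismatch: estimate {estimate.shape} vs gold {gold.shape}"
        )
    rms = float(np.sqrt(np.mean((estimate - gold) ** 2)))
    peak_err = float(np.max(estimate) - np.max(gold)) if gold.size else np.nan

    eps_gold = detect_effort_episodes(gold, time, threshold=onset_threshold)
    eps_est = detect_effort_episodes(
        estimate, time, threshold=onset_threshold,
        min_duration_s=ESTIMATE_MIN_EFFORT_DURATION_S,
    )
    onset_errs = []
    for g in eps_gold:
        if not eps_est:
            break
        cand = min(eps_est, key=lambda e: abs(e.onset_time - g.onset_time))
        if abs(cand.onset_time - g.onset_time) <= 0.5:
            onset_errs.append(cand.onset_time - g.onset_time)
    onset_err = float(np.mean(onset_errs)) if onset_errs else np.nan
    return {
        "scenario_id": scenario_id,
        "method": method,
        "rms_error_cmh2o": rms,
        "peak_amplitude_error_cmh2o": peak_err,
        "onset_time_error_s": onset_err,
        "n_gold_efforts": len(eps_gold),
        "n_detected_efforts": len(eps_est),
    }


def evaluation_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Pool per-record metric dicts into a tidy table with a pooled row per
    method."""
    df = pd.DataFrame(rows)
    pooled = (
        df.groupby("method", as_index=False)
        .agg(
            rms_error_cmh2o=("rms_error_cmh2o", lambda s: float(np.sqrt(np.mean(s**2)))),
            peak_amplitude_error_cmh2o=("peak_amplitude_error_cmh2o", "mean"),
            onset_time_error_s=("onset_time_error_s", "mean"),
        )
        .assign(scenario_id="pooled")
    )
    return pd.concat([df, pooled], ignore_index=True)
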