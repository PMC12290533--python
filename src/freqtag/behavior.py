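"""Behavioral scoring: oddball d-prime, selective-attention accuracy,
and logistic cue-weight estimation.

The detection task is scored with the loglinear d' correction (0.5
added to hit and false-alarm counts, 1 to their denominators), which
keeps d' finite at perfect or empty cells.  Cue weights are the
coefficients of a per-participant logistic regression of binary
category responses on pitch and duration level, each predictor centered
and divided by two standard deviations so a coefficient reads as the
change in log odds per SD of that cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stimgen import EventList

__all__ = [
    "ResponseLog",
    "CueWeightFit",
    "score_oddball",
    "dprime_loglinear",
    "score_attention",
    "rescale_2sd",
    "fit_cue_weights",
    "flag_invalid_categorizer",
]

HIT_WINDOW_S = 1.25


@dataclass
class ResponseLog:
    """Key-press times within one session."""

    times: np.ndarray  # s, sorted
    session_duration: float

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))
        if len(self.times) and (self.times[0] < 0 or self.times[-1] > self.session_duration):
            raise ValueError("response times must lie within the session")


def score_oddball(log: ResponseLog, events: EventList, window: float = HIT_WINDOW_S) -> dict:
    """Credit responses to oddballs within the hit window.

    A response within ``window`` seconds after an oddball onset is a hit
    for that (nearest preceding) oddball; each oddball can be hit once
    and every other response is a false alarm.  The false-alarm
    denominator is the non-oddball stimulus count.
    """
    odd = events.onset[events.is_oddball]
    if len(odd) > 1 and np.min(np.diff(odd)) < window:
        raise ValueError("oddball hit windows overlap")
    hit_taken = np.zeros(len(odd), dtype=bool)
    hits = fas = 0
    for t in log.times:
        j = np.searchsorted(odd, t, side="right") - 1
        if j >= 0 and t - odd[j] <= window and not hit_taken[j]:
            hit_taken[j] = True
            hits += 1
        else:
            fas += 1
    return {
        "hits": hits,
        "n_oddballs": int(len(odd)),
        "false_alarms": fas,
        "n_nonoddballs": int(len(events) - len(odd)),
    }


def dprime_loglinear(hits: int, n_oddballs: int, false_alarms: int, n_nonoddballs: int) -> float:
    """Loglinear d': Phi^-1((h+0.5)/(n+1)) - Phi^-1((fa+0.5)/(m+1))."""
    h = (hits + 0.5) / (n_oddballs + 1.0)
    f = (false_alarms + 0.5) / (n_nonoddballs + 1.0)
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def score_attention(trials: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per (domain, attended dimension).

    A response is correct when it matches the presence of a repetition
    in the *attended* dimension; the unattended dimension never affects
    correctness.  Rates of change are collapsed.

    ``trials`` needs columns: domain, attended ("pitch"/"duration"),
    has_pitch_rep, has_dur_rep, response (1 = "yes").
    """
    t = trials.copy()
    attended_rep = np.where(
        t["attended"].to_numpy() == "pitch",
        t["has_pitch_rep"].to_numpy(bool),
        t["has_dur_rep"].to_numpy(bool),
    )
    t["correct"] = t["response"].astype(bool).to_numpy() == attended_rep
    out = (
        t.groupby(["domain", "attended"], as_index=False)["correct"]
        .mean()
        .rename(columns={"correct": "prop_correct"})
    )
    return out


def rescale_2sd(x) -> np.ndarray:
    """Center and divide by two sample standard deviations.

    The rescaled vector has mean 0 and SD 0.5, so a logistic
    coefficient on it is the log-odds change per one SD of the raw
    predictor.
    """
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("cannot rescale a constant predictor")
    return (x - x.mean()) / (2.0 * sd)


@dataclass
class CueWeightFit:
    b0: float
    b_pitch: float
    b_dur: float
    se_b0: float
    se_b_pitch: float
    se_b_dur: float
    converged: bool
    separation: bool
    n_trials: int
    log_likelihood: float

    def ci(self, name: str, level: float = 0.95):
        """Wald confidence interval for a coefficient."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        b = getattr(self, name)
        se = getattr(self, f"se_{name}")
        return (b - z * se, b + z * se)


def fit_cue_weights(trials: pd.DataFrame, max_iter: int = 100, tol: float = 1e-8) -> CueWeightFit:
    """Maximum-likelihood logistic fit of response on the 2-SD-rescaled
    pitch and duration levels, by iteratively reweighted least squares.

    Convergence: absolute log-likelihood change below ``tol``.  Complete
    or quasi-complete separation is detected (fitted probabilities
    saturating at the observed classes) and flagged as non-converged.
    """
    y = trials["response"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("responses are all identical; no fit possible")
    for col in ("pitch_level", "duration_level"):
        if trials[col].nunique() < 2:
            raise ValueError(f"{col} needs at least 2 distinct levels")
    X = np.column_stack(
        [
            np.ones(len(y)),
            rescale_2sd(trials["pitch_level"].to_numpy(float)),
            rescale_2sd(trials["duration_level"].to_numpy(float)),
        ]
    )
    beta = np.zeros(3)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        eps = 1e-12
        ll = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    # separation: every fitted probability saturates at its observed class
    saturated = np.all(np.where(y == 1, mu > 1 - 1e-6, mu < 1e-6))
    diverged = np.max(np.abs(beta)) > 30
    separation = bool(saturated or diverged)
    if separation:
        converged = False
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    return CueWeightFit(
        b0=float(beta[0]),
        b_pitch=float(beta[1]),
        b_dur=float(beta[2]),
        se_b0=float(se[0]),
        se_b_pitch=float(se[1]),
        se_b_dur=float(se[2]),
        converged=converged,
        separation=separation,
        n_trials=int(len(y)),
        log_likelihood=ll,
    )


def flag_invalid_categorizer(trials: pd.DataFrame, alpha: float = 0.05) -> str:
    """Participant-exclusion decision from response-vs-level correlations.

    Point-biserial correlation (Pearson r of the binary response with
    each level column), two-sided test at ``alpha``:

    * any significant negative correlation -> ``"negative"``
    * neither dimension significant -> ``"none-significant"``
    * otherwise -> ``"keep"``
    """
    y = trials["response"].to_numpy(float)
    results = []
    for col in ("pitch_level", "duration_level"):
        x = trials[col].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            results.append((0.0, 1.0))
            continue
        r, p = stats.pearsonr(y, x)
        results.append((r, p))
    if any(r < 0 and p < alpha for r, p in results):
        return "negative"
    if not any(p < alpha for r, p in results):
        return "none-significant"
    return "keep"
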