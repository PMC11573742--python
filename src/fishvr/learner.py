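"""Learner-session classification.

A shocked-group session counts as a "learner session" when it beats the
day's reference control session (the control session with the highest
success rate that day) in all three of:

1. an exact one-sided binomial test of the whole-session success count
   against the reference session's success rate,
2. a one-sided two-sample Kolmogorov-Smirnov test that the session's
   moving success-rate values (mean of the last ten trials, so values
   0, 0.1, ..., 1) are stochastically higher than the reference's, and
3. a one-sided two-sample Student t test (pooled variance; success rates
   are approximately normal in this task) on the same moving success-rate
   series,

each at alpha = 1e-4 (a conservative Bonferroni-style threshold for the
hundreds of session tests such an experiment accrues).  A fish is a
"learner fish" when its chronologically last session is a learner session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .metrics import moving_success_rate


def binomial_higher(successes: int, n_trials: int, p0: float) -> float:
    """Exact upper-tail binomial p-value P[X >= successes | n, p0]."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if not 0 <= successes <= n_trials:
        raise ValueError("successes must be in [0, n_trials]")
    return float(stats.binom.sf(successes - 1, n_trials, p0))


def ks_statistic_higher(sample_high, sample_ref) -> float:
    """One-sided two-sample KS statistic: sup over pooled points of
    (CDF_ref - CDF_high), positive when sample_high tends larger."""
    a = np.sort(np.asarray(sample_high, float))
    b = np.sort(np.asarray(sample_ref, float))
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(cdf_b - cdf_a))


def ks_higher(sample_shocked, sample_ref, method: str = "auto") -> float:
    """One-sided two-sample KS p-value for the shocked sample's CDF lying
    below the reference's (i.e. stochastically higher values)."""
    a = np.asarray(sample_shocked, float)
    b = np.asarray(sample_ref, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b, alternative="less", method=method).pvalue)


def t_higher(sample_shocked, sample_ref, equal_var: bool = True) -> float:
    """One-sided two-sample t p-value for a higher shocked mean (pooled
    variance by default; set equal_var=False for Welch)."""
    a = np.asarray(sample_shocked, float)
    b = np.asarray(sample_ref, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in both samples")
    with warnings.catch_warnings():
        # near-constant success series (e.g. a ceiling performer) trip scipy's
        # precision-loss warning; the limiting p-value is still well-defined
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=equal_var, alternative="greater").pvalue)


@dataclass
class LearnerDecision:
    """The three p-values and the conjunction decision at the alpha threshold."""

    p_binomial: float
    p_ks: float
    p_ttest: float
    alpha: float
    is_learner_session: bool

    def to_dict(self) -> dict:
        return {
            "p_binomial": self.p_binomial,
            "p_ks": self.p_ks,
            "p_ttest": self.p_ttest,
            "alpha": self.alpha,
            "is_learner_session": self.is_learner_session,
        }


def _successes_of(session) -> np.ndarray:
    """Accept a SessionRecord or a plain success-boolean sequence."""
    if hasattr(session, "successes"):
        return np.asarray(session.successes, dtype=bool)
    return np.asarray(session, dtype=bool)


def classify_learner_session(
    shocked_session,
    reference_session,
    alpha: float = 1e-4,
    window: int = 10,
) -> LearnerDecision:
    """Run the three-test procedure on a shocked session against a
    reference control session (both given as SessionRecords or success
    vectors).

    The binomial test uses the whole-session success count against the
    reference session's success rate; the KS and t tests use the
    full-window moving success-rate series (trials >= window) of both
    sessions.  Sessions shorter than the window cannot be classified.
    """
    s = _successes_of(shocked_session)
    r = _successes_of(reference_session)
    if s.size < window or r.size < window:
        raise ValueError(f"sessions must have at least {window} trials")
    p0 = float(r.mean())
    p_binom = binomial_higher(int(s.sum()), s.size, p0)
    ms = moving_success_rate(s, window)[window - 1 :]
    mr = moving_success_rate(r, window)[window - 1 :]
    p_ks = ks_higher(ms, mr)
    p_t = t_higher(ms, mr)
    decision = (p_binom < alpha) and (p_ks < alpha) and (p_t < alpha)
    return LearnerDecision(p_binom, p_ks, p_t, alpha, decision)


def select_reference_sessions(control_sessions: Sequence) -> dict[int, object]:
    """Per day, the control session with the highest success rate (ties ->
    lowest agent id); raises when a day has no control session."""
    by_day: dict[int, list] = {}
    for sess in control_sessions:
        by_day.setdefault(sess.day, []).append(sess)
    if not by_day:
        raise ValueError("no control sessions")
    out = {}
    for day, sessions in by_day.items():
        out[day] = max(sessions, key=lambda s: (s.success_rate, _neg_id(s.agent_id)))
    return out


def _neg_id(agent_id) -> tuple:
    # max() with reversed id ordering implements "ties -> lowest id"
    s = str(agent_id)
    return tuple(-ord(c) for c in s)


def classify_learner_fish(
    sessions: Sequence,
    references: dict[int, object],
    alpha: float = 1e-4,
    window: int = 10,
) -> bool:
    """A fish is a learner iff its chronologically last session is a
    learner session (judged against that day's reference)."""
    if not sessions:
        raise ValueError("no sessions for this fish")
    last = max(sessions, key=lambda s: s.day)
    if last.day not in references:
        raise ValueError(f"no reference session for day {last.day}")
    return classify_learner_session(last, references[last.day], alpha, window).is_learner_session
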