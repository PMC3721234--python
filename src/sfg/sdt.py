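"""Signal-detection analysis of figure-detection response tables.

Sensitivity is quantified as d' = z(hit rate) - z(false-alarm rate) for the
yes/no figure-detection task, and via the differencing-model two-alternative
approximation d' = sqrt(2) * z(proportion correct) for the AXB odd-one-out
task.  Ceiling-level performance (hit rates above 90% are typical for
salient figures) would produce infinite z-scores, so the log-linear
correction — add 0.5 to every response cell before computing rates — is
applied throughout; it leaves large-sample values essentially untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SensitivityResult",
    "d_prime_yesno",
    "d_prime_axb",
    "summarize_conditions",
]


@dataclass(frozen=True)
class SensitivityResult:
    hits: float
    misses: float
    false_alarms: float
    correct_rejections: float
    hit_rate: float
    fa_rate: float
    d_prime: float


def d_prime_yesno(
    hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> SensitivityResult:
    """Yes/no sensitivity with the log-linear (+0.5 per cell) correction.

    Rates are computed after adding 0.5 to every cell, which keeps them
    strictly inside (0, 1) and d' finite even at perfect performance.
    """
    counts = (hits, misses, false_alarms, correct_rejections)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if hits + misses == 0:
        raise ValueError("no signal trials")
    if false_alarms + correct_rejections == 0:
        raise ValueError("no noise trials")
    hit_rate = (hits + 0.5) / (hits + misses + 1.0)
    fa_rate = (false_alarms + 0.5) / (false_alarms + correct_rejections + 1.0)
    d = float(norm.ppf(hit_rate) - norm.ppf(fa_rate))
    return SensitivityResult(
        hits=hits,
        misses=misses,
        false_alarms=false_alarms,
        correct_rejections=correct_rejections,
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        d_prime=d,
    )


def d_prime_axb(proportion_correct: float, n_trials: int) -> SensitivityResult:
    """AXB sensitivity via the 2AFC differencing approximation.

    d' = sqrt(2) * z(pc), with pc log-linear corrected using the trial count:
    pc' = (pc * n + 0.5) / (n + 1).  The exact mapping from AXB responses to
    d' depends on the listener's decision rule; the differencing model is a
    standard, clearly-stated choice.
    """
    if not (0.0 <= proportion_correct <= 1.0):
        raise ValueError("proportion correct must lie in [0, 1]")
    if n_trials < 1:
        raise ValueError("need at least one trial")
    pc = (proportion_correct * n_trials + 0.5) / (n_trials + 1.0)
    d = float(np.sqrt(2.0) * norm.ppf(pc))
    n_correct = proportion_correct * n_trials
    return SensitivityResult(
        hits=n_correct,
        misses=n_trials - n_correct,
        false_alarms=np.nan,
        correct_rejections=np.nan,
        hit_rate=pc,
        fa_rate=np.nan,
        d_prime=d,
    )


def summarize_conditions(
    trials: pd.DataFrame, paradigm: str = "yesno"
) -> pd.DataFrame:
    """Group mean d' and between-subject SEM per (coherence, duration) cell.

    ``trials`` columns: ``subject``, ``coherence``, ``duration``, plus for
    the yes/no paradigm ``figure_present`` and ``response`` (both 0/1), or
    for AXB ``correct`` (0/1).  Cells missing for a subject are simply
    absent from that subject's summary (never imputed).  With a single
    subject the SEM is reported as NaN (not applicable).
    """
    required = {"subject", "coherence", "duration"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial table needs columns {sorted(required)}")

    def subject_dprime(df: pd.DataFrame) -> float:
        if paradigm == "yesno":
            sig = df[df["figure_present"] == 1]
            noi = df[df["figure_present"] == 0]
            res = d_prime_yesno(
                int(sig["response"].sum()),
                int((1 - sig["response"]).sum()),
                int(noi["response"].sum()),
                int((1 - noi["response"]).sum()),
            )
        elif paradigm == "axb":
            res = d_prime_axb(df["correct"].mean(), len(df))
        else:
            raise ValueError(f"unknown paradigm {paradigm!r}")
        return res.d_prime

    per_subject = (
        trials.groupby(["coherence", "duration", "subject"])
        .apply(subject_dprime, include_groups=False)
        .rename("d_prime")
        .reset_index()
    )
    grouped = per_subject.groupby(["coherence", "duration"])["d_prime"]
    out = grouped.agg(
        mean_d_prime="mean",
        sem_d_prime=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
        n_subjects="count",
    ).reset_index()
    return out
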