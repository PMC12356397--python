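"""Signal-detection metrics for the category-folded letter task.

The 6AFC letter task is analysed as a 2AFC category task: a response is
scored by its letter category (consonant vs vowel).  With unequal base
rates, the *rare* category plays the role of the signal:

* hit   — rare shown, rare responded
* miss  — rare shown, frequent responded
* false alarm — frequent shown, rare responded
* correct rejection — frequent shown, frequent responded

accuracy = (H+CR)/(H+M+FA+CR), HR = H/(H+M), FAR = FA/(FA+CR),
d' = z(HR) - z(FAR), c = -(z(HR)+z(FAR))/2, with z the standard-normal
quantile.  A positive criterion c means the observer under-reports the rare
category, i.e. is biased toward the frequent one.

Rates of exactly 0 or 1 are replaced by 1/(2N) and 1-1/(2N) (N the trial
count behind that rate), the usual log-linear-free correction for extreme
proportions in small cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .stimuli import LETTERS, LETTER_CATEGORY

__all__ = ["TrialRecord", "SDTCounts", "SDTSummary", "classify_responses",
           "accuracy", "rates", "dprime", "criterion", "summarize",
           "SUMMARY_COLUMNS"]


@dataclass(frozen=True)
class TrialRecord:
    """One letter presentation and its response."""

    participant_id: str
    block: str
    trial_index: int
    sigma: float
    letter_shown: str
    response_letter: str
    increment: float
    category_shown: str = field(default="", compare=True)
    response_category: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        for letter in (self.letter_shown, self.response_letter):
            if letter not in LETTERS:
                raise ValueError(f"letter {letter!r} outside the stimulus set")
        shown = LETTER_CATEGORY[self.letter_shown]
        resp = LETTER_CATEGORY[self.response_letter]
        if self.category_shown and self.category_shown != shown:
            raise ValueError("category_shown inconsistent with letter_shown")
        if self.response_category and self.response_category != resp:
            raise ValueError("response_category inconsistent with response_letter")
        object.__setattr__(self, "category_shown", shown)
        object.__setattr__(self, "response_category", resp)

    @property
    def correct_category(self) -> bool:
        return self.category_shown == self.response_category

    @property
    def correct_letter(self) -> bool:
        return self.letter_shown == self.response_letter


@dataclass(frozen=True)
class SDTCounts:
    H: int
    M: int
    FA: int
    CR: int

    def __post_init__(self) -> None:
        if min(self.H, self.M, self.FA, self.CR) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_rare(self) -> int:
        return self.H + self.M

    @property
    def n_frequent(self) -> int:
        return self.FA + self.CR


@dataclass(frozen=True)
class SDTSummary:
    participant_id: str
    sigma: float
    counts: SDTCounts
    accuracy: float
    HR: float
    FAR: float
    dprime: float
    criterion: float
    correction_applied: bool


def classify_responses(trials, rare_category: str) -> SDTCounts:
    """Tally hits, misses, false alarms and correct rejections."""
    if rare_category not in ("consonant", "vowel"):
        raise ValueError("rare_category must be consonant or vowel")
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to classify")
    h = m = fa = cr = 0
    for t in trials:
        rare_shown = t.category_shown == rare_category
        rare_resp = t.response_category == rare_category
        if rare_shown:
            h += rare_resp
            m += not rare_resp
        else:
            fa += rare_resp
            cr += not rare_resp
    return SDTCounts(H=h, M=m, FA=fa, CR=cr)


def accuracy(counts: SDTCounts) -> float:
    total = counts.H + counts.M + counts.FA + counts.CR
    if total == 0:
        raise ValueError("no trials")
    return (counts.H + counts.CR) / total


def rates(counts: SDTCounts) -> tuple[float, float, bool]:
    """(HR, FAR, correction_applied) with the 1/(2N) extreme-rate remedy."""
    if counts.n_rare == 0 or counts.n_frequent == 0:
        raise ValueError("need at least one rare and one frequent trial")
    hr = counts.H / counts.n_rare
    far = counts.FA / counts.n_frequent
    corrected = False
    if hr == 0.0:
        hr, corrected = 1.0 / (2 * counts.n_rare), True
    elif hr == 1.0:
        hr, corrected = 1.0 - 1.0 / (2 * counts.n_rare), True
    if far == 0.0:
        far, corrected = 1.0 / (2 * counts.n_frequent), True
    elif far == 1.0:
        far, corrected = 1.0 - 1.0 / (2 * counts.n_frequent), True
    return hr, far, corrected


def _z(p: float) -> float:
    if not (0.0 < p < 1.0):
        raise ValueError("rates must lie strictly in (0, 1); apply the "
                         "extreme-rate correction first")
    return float(norm.ppf(p))


def dprime(HR: float, FAR: float) -> float:
    """Sensitivity d' = z(HR) - z(FAR)."""
    return _z(HR) - _z(FAR)


def criterion(HR: float, FAR: float) -> float:
    """Response criterion c = -(z(HR) + z(FAR)) / 2.

    Positive when the observer under-responds the rare category.
    """
    return -0.5 * (_z(HR) + _z(FAR))


def summarize(trials, rare_category: str,
              blocks=("block4", "block5")) -> pd.DataFrame:
    """Per participant x noise level SDT summary over the test blocks.

    Blocks 4 and 5 are pooled before tallying, so the zero-noise rows from
    both blocks form a single baseline per participant.
    """
    trials = [t for t in trials if t.block in blocks]
    if not trials:
        raise ValueError(f"no trials in blocks {blocks}")
    rows = []
    key = lambda t: (t.participant_id, t.sigma)
    frame = pd.DataFrame({"pid": [t.participant_id for t in trials],
                          "sigma": [t.sigma for t in trials],
                          "idx": range(len(trials))})
    for (pid, sigma), grp in frame.groupby(["pid", "sigma"], sort=True):
        cell = [trials[i] for i in grp["idx"]]
        counts = classify_responses(cell, rare_category)
        if counts.n_rare == 0 or counts.n_frequent == 0:
            import warnings
            warnings.warn(f"participant {pid} sigma {sigma}: one-sided cell, "
                          "row omitted")
            continue
        hr, far, corr = rates(counts)
        rows.append({
            "participant_id": pid, "sigma": sigma,
            "n_rare": counts.n_rare, "n_frequent": counts.n_frequent,
            "H": counts.H, "M": counts.M, "FA": counts.FA, "CR": counts.CR,
            "accuracy": accuracy(counts), "HR": hr, "FAR": far,
            "dprime": dprime(hr, far), "criterion": criterion(hr, far),
            "correction_applied": corr,
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


SUMMARY_COLUMNS = ["participant_id", "sigma", "n_rare", "n_frequent",
                   "H", "M", "FA", "CR", "accuracy", "HR", "FAR",
                   "dprime", "criterion", "correction_applied"]
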