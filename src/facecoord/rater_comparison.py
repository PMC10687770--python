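"""Human-rater panel vs classifier comparison statistics.

Covers group-level rater accuracy (all / expert / non-expert), per-participant
human accuracy, extraction of "hard cases" (participants most raters got
wrong), and the correlation between per-participant human and classifier
accuracy, with an optional exclusion of participants that nearly all raters
classified correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RaterPanel",
    "ComparisonReport",
    "group_accuracy",
    "participant_human_accuracy",
    "hard_cases",
    "human_ai_agreement",
    "compare_panel",
]

EXPERTISE_LEVELS = ("expert", "non_expert")


@dataclass(frozen=True)
class RaterPanel:
    """Binary predictions of a rater panel over a participant cohort.

    ``predictions`` is (n_raters, n_participants) of label strings;
    ``expertise`` tags each rater ``expert`` or ``non_expert``; ``truth``
    holds the participants' true labels.
    """

    predictions: np.ndarray
    expertise: tuple[str, ...]
    truth: tuple[str, ...]
    participant_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        preds = np.asarray(self.predictions)
        object.__setattr__(self, "predictions", preds)
        object.__setattr__(self, "expertise", tuple(self.expertise))
        object.__setattr__(self, "truth", tuple(self.truth))
        if preds.ndim != 2 or preds.shape[0] < 1:
            raise ValueError("predictions must be (raters, participants), >= 1 rater")
        if preds.shape[0] != len(self.expertise):
            raise ValueError("one expertise tag per rater required")
        if preds.shape[1] != len(self.truth):
            raise ValueError("one truth label per participant required")
        bad = set(self.expertise) - set(EXPERTISE_LEVELS)
        if bad:
            raise ValueError(f"unknown expertise levels: {sorted(bad)}")
        ids = self.participant_ids or tuple(
            f"p{i:03d}" for i in range(preds.shape[1])
        )
        object.__setattr__(self, "participant_ids", tuple(ids))

    @property
    def n_raters(self) -> int:
        return self.predictions.shape[0]

    @property
    def n_participants(self) -> int:
        return self.predictions.shape[1]

    def correct(self) -> np.ndarray:
        """Boolean (raters, participants) correctness indicator."""
        return self.predictions == np.asarray(self.truth)[None, :]

    def to_file(self, path) -> None:
        df = pd.DataFrame(self.predictions, columns=list(self.participant_ids))
        df.insert(0, "expertise", list(self.expertise))
        df.to_csv(path, index=False)

    @classmethod
    def from_file(cls, path, truth) -> "RaterPanel":
        df = pd.read_csv(path)
        expertise = tuple(df.pop("expertise"))
        return cls(df.to_numpy(), expertise, tuple(truth), tuple(df.columns))


@dataclass(frozen=True)
class ComparisonReport:
    """All human-vs-classifier comparison outputs for one cohort."""

    group_accuracies: dict[str, float]
    participant_human_accuracy: np.ndarray
    participant_ai_accuracy: np.ndarray
    hard_case_table: pd.DataFrame
    agreement_full: float
    agreement_filtered: float

    def to_json_dict(self) -> dict:
        return {
            "group_accuracies": self.group_accuracies,
            "participant_human_accuracy": self.participant_human_accuracy.tolist(),
            "participant_ai_accuracy": self.participant_ai_accuracy.tolist(),
            "hard_cases": self.hard_case_table.to_dict(orient="records"),
            "agreement_full": self.agreement_full,
            "agreement_filtered": self.agreement_filtered,
        }


def group_accuracy(panel: RaterPanel) -> dict[str, float]:
    """Mean per-rater accuracy for all raters and each expertise stratum.

    Each rater's accuracy is their fraction of correct calls; strata means
    weight raters equally, so the all-rater value is the rater-count-weighted
    mean of the two strata.
    """
    per_rater = panel.correct().mean(axis=1)
    expertise = np.asarray(panel.expertise)
    out = {"all": float(per_rater.mean())}
    for level in EXPERTISE_LEVELS:
        mask = expertise == level
        out[level] = float(per_rater[mask].mean()) if mask.any() else float("nan")
    return out


def participant_human_accuracy(panel: RaterPanel) -> np.ndarray:
    """Per-participant fraction of raters whose call was correct."""
    return panel.correct().mean(axis=0)


def hard_cases(
    panel: RaterPanel,
    ai_participant_acc: np.ndarray,
    ai_loocv: np.ndarray,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Participants misclassified by most raters, hardest first.

    Keeps participants with human accuracy strictly below ``threshold``
    (ties at the threshold are excluded), sorted ascending by human
    accuracy, joined with the classifier's repeated-CV accuracy and its
    leave-one-out prediction.
    """
    human_acc = participant_human_accuracy(panel)
    ai_acc = np.asarray(ai_participant_acc, dtype=float)
    ai_pred = np.asarray(ai_loocv)
    if ai_acc.shape[0] != panel.n_participants or ai_pred.shape[0] != panel.n_participants:
        raise ValueError("AI vectors must have one entry per participant")
    keep = np.flatnonzero(human_acc < threshold)
    keep = keep[np.argsort(human_acc[keep], kind="stable")]
    return pd.DataFrame(
        {
            "participant": [panel.participant_ids[i] for i in keep],
            "dx": [panel.truth[i] for i in keep],
            "human_accuracy": human_acc[keep],
            "ai_accuracy": ai_acc[keep],
            "ai_loocv_prediction": ai_pred[keep],
        }
    )


def human_ai_agreement(
    human_acc: np.ndarray,
    ai_acc: np.ndarray,
    exclude_above: float | None = None,
) -> float:
    """Pearson correlation of per-participant human and classifier accuracy.

    With ``exclude_above=q``, participants correctly classified by at least
    a fraction ``q`` of the raters (human accuracy >= q) are removed before
    correlating.

    Raises
    ------
    ValueError
        If fewer than 3 participants remain, or a retained vector is
        constant (the correlation is undefined, not zero).
    """
    human_acc = np.asarray(human_acc, dtype=float)
    ai_acc = np.asarray(ai_acc, dtype=float)
    if human_acc.shape != ai_acc.shape:
        raise ValueError("accuracy vectors must have equal length")
    if exclude_above is not None:
        keep = human_acc < exclude_above
        human_acc, ai_acc = human_acc[keep], ai_acc[keep]
    if human_acc.shape[0] < 3:
        raise ValueError("fewer than 3 participants after exclusion")
    if np.ptp(human_acc) == 0 or np.ptp(ai_acc) == 0:
        raise ValueError("correlation undefined for a constant accuracy vector")
    return float(stats.pearsonr(human_acc, ai_acc).statistic)


def compare_panel(
    panel: RaterPanel,
    ai_participant_acc: np.ndarray,
    ai_loocv: np.ndarray,
    ai_overall_accuracy: float,
    hard_threshold: float = 0.5,
    exclusion: float = 0.95,
) -> ComparisonReport:
    """Assemble the full comparison report for one cohort."""
    groups = group_accuracy(panel)
    groups["ai"] = float(ai_overall_accuracy)
    human_acc = participant_human_accuracy(panel)
    try:
        full = human_ai_agreement(human_acc, ai_participant_acc)
    except ValueError:
        full = float("nan")
    try:
        filtered = human_ai_agreement(human_acc, ai_participant_acc, exclusion)
    except ValueError:
        filtered = float("nan")
    return ComparisonReport(
        group_accuracies=groups,
        participant_human_accuracy=human_acc,
        participant_ai_accuracy=np.asarray(ai_participant_acc, dtype=float),
        hard_case_table=hard_cases(panel, ai_participant_acc, ai_loocv, hard_threshold),
        agreement_full=full,
        agreement_filtered=filtered,
    )
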