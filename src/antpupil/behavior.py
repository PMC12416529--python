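"""ANT behavioral scoring: reaction-time summaries and network effects.

The Attention Network Test indexes three networks through RT contrasts
computed from correct trials only:

* alerting  = RT(no-cue) - RT(center-cue)
* orienting = RT(center-cue) - RT(spatial-cue)
* executive = RT(incongruent) - RT(congruent)

Trials with a missing response count as incorrect for accuracy and are
excluded from every RT mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_eyelink import CUE_TYPES, TARGET_TYPES, TrialRecord, trials_to_frame


@dataclass
class RTSummary:
    cue_means: dict[str, float]        # mean RT (ms) per cue type, correct trials
    target_means: dict[str, float]     # mean RT (ms) per target type
    overall_mean: float                # ms; trial-weighted over correct trials
    accuracy: float                    # correct / total
    n_trials: int
    n_correct: int
    flagged: bool = False              # some condition had no correct trials


@dataclass
class NetworkEffects:
    alerting: float
    orienting: float
    executive: float
    cue_means: dict[str, float] = field(default_factory=dict)
    target_means: dict[str, float] = field(default_factory=dict)
    accuracy: float = np.nan


def summarize_rt(
    trials: list[TrialRecord] | pd.DataFrame, condition_weighted: bool = False
) -> RTSummary:
    """Per-condition mean RTs over correct trials, plus accuracy.

    ``condition_weighted=True`` averages the six cell means equally for the
    overall RT instead of pooling trials.
    """
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    n_total = len(df)
    correct = df[(df["correct"] == True) & df["rt"].notna()]  # noqa: E712
    flagged = False

    cue_means: dict[str, float] = {}
    for cue in CUE_TYPES:
        sub = correct[correct["cue_type"] == cue]
        cue_means[cue] = float(sub["rt"].mean()) if len(sub) else np.nan
    target_means: dict[str, float] = {}
    for tgt in TARGET_TYPES:
        sub = correct[correct["target_type"] == tgt]
        target_means[tgt] = float(sub["rt"].mean()) if len(sub) else np.nan

    if any(np.isnan(v) for v in {**cue_means, **target_means}.values()):
        flagged = True
        warnings.warn("empty RT condition: subject flagged for exclusion")

    if condition_weighted:
        cells = [
            correct[(correct["cue_type"] == c) & (correct["target_type"] == t)]["rt"].mean()
            for c in CUE_TYPES
            for t in TARGET_TYPES
        ]
        overall = float(np.mean(cells))
    else:
        overall = float(correct["rt"].mean()) if len(correct) else np.nan

    return RTSummary(
        cue_means=cue_means,
        target_means=target_means,
        overall_mean=overall,
        accuracy=(len(correct) / n_total) if n_total else np.nan,
        n_trials=n_total,
        n_correct=len(correct),
        flagged=flagged,
    )


def network_effects(summary: RTSummary) -> NetworkEffects:
    """The three attention-network RT contrasts, in ms.

    A missing condition mean propagates to a missing (NaN) effect.
    """
    cm, tm = summary.cue_means, summary.target_means
    return NetworkEffects(
        alerting=cm["none"] - cm["center"],
        orienting=cm["center"] - cm["spatial"],
        executive=tm["incongruent"] - tm["congruent"],
        cue_means=dict(cm),
        target_means=dict(tm),
        accuracy=summary.accuracy,
    )
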