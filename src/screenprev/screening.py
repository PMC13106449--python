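"""Screening-score classification and two-phase flow bookkeeping.

The screening instrument is a 39-item binary questionnaire whose total score
ranges 0–39.  A child is screening-positive when the total meets the cutoff
(default 11; the clinically common cutoff 15 is available through
:class:`ScreenConfig`).  :func:`summarize_flow` tabulates the two-phase flow
— screened → screen-positive → participated → diagnosed positive — per
stratum and overall, with the diagnostic-phase response rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_ITEMS = 39


@dataclass(frozen=True)
class ScreenConfig:
    cutoff: int = 11
    max_score: int = N_ITEMS

    def __post_init__(self) -> None:
        if not (0 <= self.cutoff <= self.max_score):
            raise ValueError(f"cutoff must lie in [0, {self.max_score}]")


def score_scq(item_responses) -> int:
    """Total score of a 39-item binary response vector."""
    arr = np.asarray(item_responses)
    if arr.shape != (N_ITEMS,):
        raise ValueError(f"expected {N_ITEMS} item responses, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("item responses must be binary (0/1)")
    return int(arr.sum())


def classify_screen(score: int, config: ScreenConfig = ScreenConfig()) -> bool:
    """True iff ``score >= config.cutoff``."""
    if not (0 <= score <= config.max_score):
        raise ValueError(f"score {score} outside [0, {config.max_score}]")
    return score >= config.cutoff


@dataclass(frozen=True)
class PhaseSummary:
    """Two-phase flow counts per stratum plus the overall row.

    ``table`` columns: invited, screened, screen_positive, eligible,
    participated, diagnosed_positive, response_rate (participated /
    screen-positive).  Counts are non-increasing along the flow.
    """

    table: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {str(k): {c: (None if pd.isna(v) else (float(v) if c == "response_rate" else int(v)))
                      for c, v in row.items()}
             for k, row in self.table.to_dict(orient="index").items()},
            indent=2,
        )

    def to_text(self) -> str:
        return self.table.to_string(float_format=lambda x: f"{x:.3f}")


def summarize_flow(records: pd.DataFrame, invited: dict[str, int] | None = None) -> PhaseSummary:
    """Tabulate the case-identification flow from a cohort frame.

    ``invited`` optionally supplies per-stratum invitation counts (families
    approached during the screening phase); when absent the screened count is
    used, i.e. screening-phase non-response is not represented.
    """
    rows = {}
    for stratum, grp in records.groupby("stratum", sort=True):
        n_inv = invited.get(str(stratum), len(grp)) if invited else len(grp)
        n_screened = len(grp)
        n_pos = int(grp["screen_positive"].sum())
        part = grp.loc[grp["screen_positive"], "participated"].fillna(False)
        n_part = int(part.sum())
        n_diag = int((grp["diagnosis"] == "positive").sum())
        if n_inv < n_screened:
            raise ValueError(f"stratum {stratum!r}: invited < screened")
        rows[str(stratum)] = dict(
            invited=n_inv, screened=n_screened, screen_positive=n_pos,
            eligible=n_pos, participated=n_part, diagnosed_positive=n_diag,
            response_rate=(n_part / n_pos) if n_pos else np.nan,
        )
    total = {k: sum(r[k] for r in rows.values())
             for k in ("invited", "screened", "screen_positive", "eligible",
                       "participated", "diagnosed_positive")}
    total["response_rate"] = (
        total["participated"] / total["screen_positive"] if total["screen_positive"] else np.nan
    )
    rows["overall"] = total
    table = pd.DataFrame.from_dict(rows, orient="index")
    return PhaseSummary(table=table)
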