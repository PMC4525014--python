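"""Behavioral trial categorization and the two-level exclusion procedure.

Hits and errors are not split at a fixed distance: within each performer the
trials are sorted by their minimal ball-target distance, and up to 50 trials
from the lower end with distance below 5 cm become the *hit* category while
up to 50 trials from the upper end with distance above 12 cm become the
*error* category.  The marginal 5-12 cm band is never categorized.
Performers with fewer than 20 artifact-free trials in either category are
excluded, and performers whose hit percentage or release-angle dispersion
deviates by at least 2 cohort standard deviations are screened out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CategoryAssignment",
    "categorize",
    "apply_trial_count_rule",
    "screen_cohort",
]


@dataclass
class CategoryAssignment:
    """Per-performer hit/error trial ids with the inclusion decision."""

    participant: str
    hit_ids: list[int]
    error_ids: list[int]
    included: bool | None = None
    reason: str = ""

    @property
    def n_hits(self) -> int:
        return len(self.hit_ids)

    @property
    def n_errors(self) -> int:
        return len(self.error_ids)


def categorize(trials: pd.DataFrame, hit_max: float = 0.05,
               err_min: float = 0.12, cap: int = 50,
               errors_from: str = "largest") -> CategoryAssignment:
    """Distance-sorted categorization of one performer's trials.

    Hits: up to ``cap`` trials with the smallest distances, all below
    ``hit_max``.  Errors: up to ``cap`` trials with distance above
    ``err_min`` — taken from the largest distances down by default
    (``errors_from='largest'``), or from the smallest distances above the
    threshold up (``errors_from='smallest_above'``).  Post-hit trials enter
    via their truncated-trajectory distance.  Ties break on trial index.
    """
    d = trials["min_distance"].to_numpy(float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    idx = trials["trial"].to_numpy(int)
    order = np.lexsort((idx, d))  # ascending distance, then trial id
    hit_ids = [int(idx[k]) for k in order if d[k] < hit_max][:cap]
    above = [k for k in order if d[k] > err_min]
    if errors_from == "largest":
        # top of the distance vector; tie-break still to the lower trial id
        err_order = np.lexsort((idx[above], -d[above]))
        error_ids = [int(idx[above[k]]) for k in err_order][:cap]
    elif errors_from == "smallest_above":
        error_ids = [int(idx[k]) for k in above][:cap]
    else:
        raise ValueError(f"unknown errors_from mode {errors_from!r}")
    participant = str(trials["participant"].iloc[0]) if len(trials) else ""
    return CategoryAssignment(participant, hit_ids, error_ids)


def apply_trial_count_rule(assignments: list[CategoryAssignment],
                           post_rejection_counts: dict[str, tuple[int, int]],
                           min_n: int = 20) -> list[CategoryAssignment]:
    """Exclude performers without ``min_n`` surviving trials per category.

    ``post_rejection_counts`` maps participant id to the (hits, errors)
    counts remaining after artifact rejection.
    """
    for a in assignments:
        n_hit, n_err = post_rejection_counts.get(a.participant,
                                                 (a.n_hits, a.n_errors))
        if n_hit < min_n or n_err < min_n:
            a.included = False
            a.reason = "insufficient_trials"
        else:
            a.included = True
            a.reason = ""
    return assignments


def screen_cohort(stats: pd.DataFrame, k: float = 2.0) -> pd.DataFrame:
    """Single-pass +/- k SD outlier screen on performance and dispersion.

    ``stats`` must hold one row per currently included performer with columns
    ``participant``, ``hit_percentage`` (percent of target hits over all
    session trials) and ``angle_sd`` (release-angle standard deviation, deg).
    A performer is excluded when either z-score magnitude reaches ``k``;
    exclusions do not trigger re-computation of the cohort moments.
    """
    if len(stats) < 3:
        raise ValueError("need at least 3 participants to screen")
    out = stats.copy()
    for col, zcol in (("hit_percentage", "z_hit"), ("angle_sd", "z_angle")):
        x = out[col].to_numpy(float)
        sd = x.std(ddof=1)
        if sd == 0:
            import warnings
            warnings.warn(f"zero cohort variance in {col}; screening skipped")
            out[zcol] = 0.0
        else:
            out[zcol] = (x - x.mean()) / sd
    out["included"] = (np.abs(out["z_hit"]) < k) & (np.abs(out["z_angle"]) < k)
    out["reason"] = np.where(out["included"], "",
                             np.where(np.abs(out["z_hit"]) >= k,
                                      "performance_outlier",
                                      "dispersion_outlier"))
    return out
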