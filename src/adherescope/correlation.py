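"""Lagged correlation between daily sleep metrics and next-day dose-taking.

For each subject, the predictor is either total hours of rest on day ``d``
or the number of nocturnal disturbances in the 22:00-08:00 night ending on
the morning of day ``d+1``; the response is the number of doses taken on
day ``d+1`` (0-2 under a twice-daily regimen, or a binary any-dose
indicator).  Days without full patch function are excluded: a pair is kept
only when both of its days pass QC.  Per-subject Pearson r and two-sided
p-values are reported uncorrected, mirroring per-subject exploratory
analysis; a Holm-adjusted column is appended as a clearly labelled
extension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adherence import daily_taken_counts
from .stats import CorrelationResult, holm_adjust, pearson

METRICS = ("rest_hours", "disturbances")


def build_lagged_pairs(
    profiles: pd.DataFrame,
    slots: pd.DataFrame,
    excluded_days: set[tuple[str, int]] | set[int] | None = None,
    metric: str = "rest_hours",
    binary_response: bool = False,
) -> pd.DataFrame:
    """One row per eligible (day d, day d+1) pair for one subject.

    ``excluded_days`` may contain plain study-day integers or
    ``(subject_id, study_day)`` tuples (the cohort-level QC mask).
    Pairs touching an excluded or underivable day are dropped.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    subject = profiles["subject_id"].iloc[0] if len(profiles) else ""
    excluded: set[int] = set()
    for item in excluded_days or ():
        if isinstance(item, tuple):
            if item[0] == subject:
                excluded.add(int(item[1]))
        else:
            excluded.add(int(item))

    taken = daily_taken_counts(slots)
    prof = profiles.set_index("study_day")
    rows = []
    for d in prof.index[:-1]:
        nxt = d + 1
        if nxt not in prof.index:
            continue
        if d in excluded or nxt in excluded:
            continue
        if not (prof.loc[d, "derivable"] and prof.loc[nxt, "derivable"]):
            continue
        if metric == "rest_hours":
            predictor = prof.loc[d, "rest_hours"]
        else:
            # disturbances of the night d -> d+1 are attributed to day d+1
            predictor = prof.loc[nxt, "disturbances"]
        if pd.isna(predictor):
            continue
        response = int(taken.get(nxt, 0))
        rows.append(
            {
                "subject_id": subject,
                "study_day": int(d),
                "predictor": float(predictor),
                "response": int(response > 0) if binary_response else response,
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "study_day", "predictor", "response"])


def lagged_correlation(pairs: pd.DataFrame) -> CorrelationResult:
    """Pearson r between the lagged predictor and next-day dose count."""
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 eligible pairs, got {len(pairs)}")
    return pearson(pairs["predictor"], pairs["response"])


def cohort_correlation_report(
    per_subject: dict[str, dict[str, pd.DataFrame]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subject correlation table for both sleep metrics.

    ``per_subject`` maps subject_id -> {metric -> pairs DataFrame}.
    Output columns: subject_id, metric, r, p, n_pairs, significant
    (uncorrected, at ``alpha``), p_holm, significant_holm (extension).
    """
    rows = []
    for subject, metrics in per_subject.items():
        for metric, pairs in metrics.items():
            try:
                res = lagged_correlation(pairs)
                rows.append(
                    {
                        "subject_id": subject,
                        "metric": metric,
                        "r": res.r,
                        "p": res.p,
                        "n_pairs": res.n,
                        "reason": "",
                    }
                )
            except ValueError as err:
                rows.append(
                    {
                        "subject_id": subject,
                        "metric": metric,
                        "r": np.nan,
                        "p": np.nan,
                        "n_pairs": len(pairs),
                        "reason": str(err),
                    }
                )
    table = pd.DataFrame(rows)
    table["significant"] = table["p"] < alpha
    # Holm adjustment within each metric family (extension, clearly labelled)
    table["p_holm"] = np.nan
    for metric in table["metric"].unique():
        sel = table["metric"].eq(metric) & table["p"].notna()
        if sel.any():
            table.loc[sel, "p_holm"] = holm_adjust(table.loc[sel, "p"].to_numpy())
    table["significant_holm"] = table["p_holm"] < alpha
    return table
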