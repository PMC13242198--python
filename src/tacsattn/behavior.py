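"""Reaction-time cleaning, trial categorization, and subject-level summaries.

RT inference downstream is subject-as-unit: every statistical routine
receives exactly one value per subject x session x trial type, so the
summaries here aggregate trials to subject means before anything else is
computed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError
from .taskgen import TRIAL_TYPES, trial_type_label


def filter_rts(table: pd.DataFrame, lo: float = 0.1, hi: float = 1.0
               ) -> tuple[pd.DataFrame, pd.Series]:
    """Remove anticipatory (<lo), overly slow (>hi) and missing responses.

    The retention interval is closed: responses at exactly ``lo`` or ``hi``
    seconds are kept. Returns the retained rows and the per-subject
    rejected fraction (NaN-free; an empty input yields an empty fraction
    series).
    """
    if lo >= hi:
        raise DataError(f"lo ({lo}) must be smaller than hi ({hi})")
    if table.empty:
        return table.copy(), pd.Series(dtype=float, name="rejected_fraction")
    keep = table["rt_s"].notna() & (table["rt_s"] >= lo) & (table["rt_s"] <= hi)
    rejected = (~keep).groupby(table["subject"]).mean()
    rejected.name = "rejected_fraction"
    return table.loc[keep].copy(), rejected


def categorize_trials(table: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Attach the four-way trial-type label (cue type x validity).

    Returns the labeled table and the per-label trial counts.
    """
    bad_cue = set(table["cue_type"]) - {"endogenous", "exogenous"}
    bad_val = set(table["validity"]) - {"valid", "invalid"}
    if bad_cue or bad_val:
        raise DataError(f"unknown cue_type/validity values: "
                        f"{sorted(bad_cue | bad_val)}")
    out = table.copy()
    out["trial_type"] = [trial_type_label(c, v) for c, v in
                         zip(out["cue_type"], out["validity"])]
    counts = out["trial_type"].value_counts().reindex(TRIAL_TYPES,
                                                      fill_value=0)
    counts.name = "n_trials"
    return out, counts


def subject_condition_means(table: pd.DataFrame,
                            by: Sequence[str] = ("group", "session",
                                                 "trial_type")
                            ) -> pd.DataFrame:
    """One mean RT (ms) per subject x condition cell — the inference unit."""
    cols = ["subject", *by]
    agg = (table.groupby(cols, observed=True)["rt_s"].mean() * 1000.0)
    return agg.rename("mean_rt_ms").reset_index()


def summarize_rt(table: pd.DataFrame,
                 by: Sequence[str] = ("group", "session", "trial_type")
                 ) -> pd.DataFrame:
    """Condition summaries with 95% t-based CIs on subject-level means.

    ``n`` counts subjects, and mean/SD describe the distribution of subject
    mean RTs (ms) — matching subject-as-unit inference, not trial-level
    pooling. Cells with fewer than two subjects get NaN CIs and are flagged
    in ``ci_defined``.
    """
    per_subject = subject_condition_means(table, by)
    rows = []
    for key, grp in per_subject.groupby(list(by), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp["mean_rt_ms"].to_numpy()
        n = len(vals)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        if n > 1 and sd > 0:
            half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            ci_lo, ci_hi, defined = mean - half, mean + half, True
        elif n > 1:
            ci_lo, ci_hi, defined = mean, mean, True
        else:
            ci_lo, ci_hi, defined = np.nan, np.nan, False
        rows.append((*key, n, mean, sd, ci_lo, ci_hi, defined))
    return pd.DataFrame(rows, columns=[*by, "n", "mean_ms", "sd_ms",
                                       "ci_lo", "ci_hi", "ci_defined"])
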