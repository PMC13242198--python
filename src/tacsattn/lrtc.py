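"""Detrended fluctuation analysis for long-range temporal correlations.

The series is mean-subtracted and cumulatively summed; for each window size
n the profile is split into floor(N/n) contiguous non-overlapping segments
taken from the start, a least-squares line is removed per segment, and the
root-mean-square residual over the covered samples gives F(n). The scaling
exponent alpha is the ordinary least-squares slope of log F(n) against
log n over the window grid (default: ~15 log-spaced sizes in [25, 200]).

alpha = 0.5 indicates an uncorrelated signal, alpha > 0.5 persistent
long-range temporal correlations, and alpha = 1.5 Brownian motion
(cumulative white noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .taskgen import EEGEpochs

DEFAULT_FIT_RANGE = (25, 200)


def default_n_grid(n_lo: int = 25, n_hi: int = 200,
                   n_points: int = 15) -> np.ndarray:
    """Log-spaced unique integer window sizes within [n_lo, n_hi]."""
    grid = np.unique(np.round(np.geomspace(n_lo, n_hi, n_points)).astype(int))
    return grid[(grid >= n_lo) & (grid <= n_hi)]


@dataclass
class DFAResult:
    window_sizes: np.ndarray
    fluctuations: np.ndarray
    alpha: float
    fit_r2: float


def dfa(series: np.ndarray, n_grid: np.ndarray | None = None) -> DFAResult:
    """Detrended fluctuation analysis of a 1-D series.

    Requires N >= 2 * max(n_grid) and non-zero variance. The trailing
    remainder of length N mod n is excluded from F(n), whose normalization
    runs over the covered samples.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise DataError("series must be 1-D")
    n_grid = np.sort(np.asarray(n_grid if n_grid is not None
                                else default_n_grid(), dtype=int))
    if n_grid[0] < 4:
        raise DataError("window sizes below 4 samples are not meaningful "
                        "for linear detrending")
    N = x.size
    if N < 2 * n_grid[-1]:
        raise DataError(f"series length {N} is insufficient for max window "
                        f"{n_grid[-1]} (need >= {2 * n_grid[-1]})")
    if np.var(x) == 0.0:
        raise DataError("series has zero variance; fluctuations undefined")
    y = np.cumsum(x - x.mean())
    fluct = np.empty(n_grid.size)
    for i, n in enumerate(n_grid):
        m = N // n
        seg = y[:m * n].reshape(m, n)
        t = np.arange(n, dtype=float)
        t = t - t.mean()
        denom = (t ** 2).sum()
        slope = seg @ t / denom
        intercept = seg.mean(axis=1)
        resid = seg - intercept[:, None] - slope[:, None] * t[None, :]
        fluct[i] = np.sqrt((resid ** 2).sum() / (m * n))
    logn, logf = np.log(n_grid), np.log(fluct)
    slope, intercept = np.polyfit(logn, logf, 1)
    pred = slope * logn + intercept
    ss_res = float(((logf - pred) ** 2).sum())
    ss_tot = float(((logf - logf.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DFAResult(window_sizes=n_grid, fluctuations=fluct,
                     alpha=float(slope), fit_r2=r2)


def dfa_epochs(cti_epochs: dict, mode: str = "concatenate",
               n_grid: np.ndarray | None = None,
               channel_names=None) -> pd.DataFrame:
    """Scaling exponents per subject x session x cue_type x channel.

    ``cti_epochs`` maps CTI length -> cue-aligned EEGEpochs. In
    ``concatenate`` mode (default) all same-condition CTI segments of a
    subject-session are mean-subtracted and concatenated before a single
    DFA, which guarantees enough samples for the full window range at any
    sampling rate; ``per_epoch`` computes a DFA per trial (requiring
    individually long-enough epochs) and averages the exponents.
    """
    if mode not in ("concatenate", "per_epoch"):
        raise DataError(f"unknown DFA combination mode {mode!r}")
    segments: dict[tuple, list] = {}
    meta_any: dict[tuple, tuple] = {}
    for _cti, ep in sorted(cti_epochs.items()):
        chans = channel_names or ep.channel_names
        idx = [ep.channel_names.index(c) for c in chans]
        for i in range(ep.n_trials):
            meta = ep.trials.iloc[i]
            for c, ci in zip(chans, idx):
                key = (meta["subject"], meta["session"], meta["cue_type"], c)
                meta_any[key] = (meta["subject"], meta["group"],
                                 meta["session"], meta["cue_type"], c)
                segments.setdefault(key, []).append(ep.data[i, ci])
    rows = []
    for key, segs in segments.items():
        subject, group, session, cue_type, channel = meta_any[key]
        if mode == "concatenate":
            series = np.concatenate([s - s.mean() for s in segs])
            res = dfa(series, n_grid)
            rows.append((subject, group, session, cue_type, channel,
                         res.alpha, res.fit_r2))
        else:
            alphas, r2s = [], []
            for s in segs:
                res = dfa(s, n_grid)
                alphas.append(res.alpha)
                r2s.append(res.fit_r2)
            rows.append((subject, group, session, cue_type, channel,
                         float(np.mean(alphas)), float(np.mean(r2s))))
    return pd.DataFrame(rows, columns=["subject", "group", "session",
                                       "cue_type", "channel", "alpha",
                                       "fit_r2"])
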