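"""Inferential machinery for the pre/post stimulation design.

* classical univariate mixed repeated-measures ANOVA (one between-subject
  factor, one or two within-subject factors) with partial eta squared and
  no sphericity correction,
* paired/independent t-tests with Cohen's d,
* Bonferroni / Holm / Benjamini-Hochberg p-value adjustment,
* cluster-based permutation tests on electrode graphs (sign-flip
  relabeling for paired contrasts, group-label shuffles for independent),
* continuity-corrected McNemar test for the blinding survey,
* design sensitivity analysis (minimum detectable Cohen's d from the
  two-sample noncentral-t power equation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DataError, InferenceError
from .taskgen import ContingencyTable2x2

# --------------------------------------------------------------------------
# Mixed repeated-measures ANOVA
# --------------------------------------------------------------------------

def _f_row(ss_eff, df_eff, ss_err, df_err):
    ms_eff = ss_eff / df_eff if df_eff > 0 else 0.0
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    if ms_err == 0.0:
        f = 0.0 if ms_eff == 0.0 else np.inf
    else:
        f = ms_eff / ms_err
    p = float(sps.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return f, p, eta


def mixed_anova(data: pd.DataFrame, dv: str, subject: str, between: str,
                within: Sequence[str]) -> pd.DataFrame:
    """Classical mixed-design ANOVA on a balanced complete table.

    ``data`` holds exactly one observation per subject x within-cell;
    subjects are nested in the levels of ``between``. Each within-subject
    effect and its interaction with the group factor is tested against the
    corresponding factor x subject-within-group error term; the between
    factor is tested against subjects-within-groups. Returns one row per
    effect with F, integer dfs, p, partial eta squared, and the SS terms.
    """
    within = list(within)
    if len(within) not in (1, 2):
        raise ConfigurationError("mixed_anova supports 1 or 2 within factors")
    cols = [subject, between, *within, dv]
    df = data[cols].copy()
    if df[dv].isna().any():
        raise DataError("missing responses in the ANOVA table")
    glv = sorted(df[between].unique())
    subj_group = df.groupby(subject, observed=True)[between].nunique()
    if (subj_group > 1).any():
        raise DataError("a subject appears in more than one group")
    levels = [sorted(df[w].unique()) for w in within]
    cell_sizes = df.groupby([subject, *within], observed=True).size()
    if (cell_sizes != 1).any() or len(cell_sizes) != \
            df[subject].nunique() * int(np.prod([len(l) for l in levels])):
        raise DataError("design must be complete with one observation per "
                        "subject per within-cell")
    group_of = df.drop_duplicates(subject).set_index(subject)[between]
    n_per_group = group_of.value_counts()
    if (n_per_group < 2).any():
        raise InferenceError("need at least 2 subjects per group")
    if n_per_group.nunique() != 1:
        raise DataError("groups must be of equal size")
    n = int(n_per_group.iloc[0])
    g = len(glv)
    subjects = sorted(df[subject].unique())

    # data tensor Y[subject, level_1 (, level_2)]
    wide = df.set_index([subject, *within])[dv]
    shape = (len(subjects), *(len(l) for l in levels))
    Y = np.empty(shape)
    for si, s in enumerate(subjects):
        for idx in np.ndindex(*shape[1:]):
            key = (s, *(levels[k][idx[k]] for k in range(len(levels))))
            Y[(si, *idx)] = wide.loc[key]
    gi = np.array([glv.index(group_of.loc[s]) for s in subjects])

    if len(within) == 1:
        Y = Y[:, :, None]  # dummy second factor with one level
        levels = levels + [["_"]]
    a, b = len(levels[0]), len(levels[1])
    N = len(subjects)

    m = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_g = np.array([m_s[gi == k].mean() for k in range(g)])
    m_i = Y.mean(axis=(0, 2))
    m_j = Y.mean(axis=(0, 1))
    m_gi = np.array([Y[gi == k].mean(axis=(0, 2)) for k in range(g)])
    m_gj = np.array([Y[gi == k].mean(axis=(0, 1)) for k in range(g)])
    m_ij = Y.mean(axis=0)
    m_gij = np.array([Y[gi == k].mean(axis=0) for k in range(g)])
    m_si = Y.mean(axis=2)
    m_sj = Y.mean(axis=1)

    ss_total = float(((Y - m) ** 2).sum())
    ss_G = n * a * b * float(((m_g - m) ** 2).sum())
    ss_SG = a * b * float(((m_s - m_g[gi]) ** 2).sum())
    ss_A = N * b * float(((m_i - m) ** 2).sum())
    ss_AG = n * b * float(((m_gi - m_g[:, None] - m_i[None, :] + m) ** 2).sum())
    ss_ASG = b * float(((m_si - m_s[:, None] - m_gi[gi]
                         + m_g[gi][:, None]) ** 2).sum())
    ss_B = N * a * float(((m_j - m) ** 2).sum())
    ss_BG = n * a * float(((m_gj - m_g[:, None] - m_j[None, :] + m) ** 2).sum())
    ss_BSG = a * float(((m_sj - m_s[:, None] - m_gj[gi]
                         + m_g[gi][:, None]) ** 2).sum())
    ss_AB = N * float(((m_ij - m_i[:, None] - m_j[None, :] + m) ** 2).sum())
    ss_ABG = n * float(((m_gij - m_gi[:, :, None] - m_gj[:, None, :]
                         - m_ij[None] + m_g[:, None, None]
                         + m_i[None, :, None] + m_j[None, None, :]
                         - m) ** 2).sum())
    ss_ABSG = ss_total - (ss_G + ss_SG + ss_A + ss_AG + ss_ASG + ss_B
                          + ss_BG + ss_BSG + ss_AB + ss_ABG)
    ss_ABSG = max(ss_ABSG, 0.0)

    w1 = within[0]
    rows = []

    def add(effect, ss_eff, df_eff, ss_err, df_err):
        f, p, eta = _f_row(ss_eff, df_eff, ss_err, df_err)
        rows.append((effect, f, int(df_eff), int(df_err), p, eta,
                     ss_eff, ss_err))

    add(between, ss_G, g - 1, ss_SG, N - g)
    if len(within) == 1 or b == 1:
        err = ss_ASG + ss_ABSG  # dummy factor contributes nothing
        df_err = (a - 1) * (N - g)
        add(w1, ss_A, a - 1, err, df_err)
        add(f"{between}:{w1}", ss_AG, (a - 1) * (g - 1), err, df_err)
    else:
        w2 = within[1]
        add(w1, ss_A, a - 1, ss_ASG, (a - 1) * (N - g))
        add(f"{between}:{w1}", ss_AG, (a - 1) * (g - 1), ss_ASG,
            (a - 1) * (N - g))
        add(w2, ss_B, b - 1, ss_BSG, (b - 1) * (N - g))
        add(f"{between}:{w2}", ss_BG, (b - 1) * (g - 1), ss_BSG,
            (b - 1) * (N - g))
        add(f"{w1}:{w2}", ss_AB, (a - 1) * (b - 1), ss_ABSG,
            (a - 1) * (b - 1) * (N - g))
        add(f"{between}:{w1}:{w2}", ss_ABG, (a - 1) * (b - 1) * (g - 1),
            ss_ABSG, (a - 1) * (b - 1) * (N - g))

    out = pd.DataFrame(rows, columns=["effect", "F", "df_num", "df_den",
                                      "p", "partial_eta_sq", "ss",
                                      "ss_error"])
    out.attrs["ss_total"] = ss_total
    out.attrs["ss_subjects_within_groups"] = ss_SG
    out.attrs["ss_residuals"] = (ss_ASG, ss_BSG, ss_ABSG)
    return out


# --------------------------------------------------------------------------
# t-tests and p-value adjustment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    cohen_d: float


def ttest(a: np.ndarray, b: np.ndarray, mode: str = "independent"
          ) -> TTestResult:
    """Two-sided t-test with Cohen's d (pooled for independent samples,
    difference-SD standardization for paired)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "paired":
        if a.size != b.size:
            raise DataError("paired samples must have equal length")
        if a.size < 2:
            raise InferenceError("need n >= 2")
        diff = a - b
        n = diff.size
        sd = diff.std(ddof=1)
        df = n - 1
        if sd == 0.0:
            if diff.mean() == 0.0:
                return TTestResult(0.0, df, 1.0, 0.0)
            return TTestResult(np.inf * np.sign(diff.mean()), df, 0.0,
                               np.inf * np.sign(diff.mean()))
        t = diff.mean() / (sd / np.sqrt(n))
        d = diff.mean() / sd
    elif mode == "independent":
        if a.size < 2 or b.size < 2:
            raise InferenceError("need n >= 2 per sample")
        n1, n2 = a.size, b.size
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
        delta = a.mean() - b.mean()
        if sp2 == 0.0:
            if delta == 0.0:
                return TTestResult(0.0, df, 1.0, 0.0)
            return TTestResult(np.inf * np.sign(delta), df, 0.0,
                               np.inf * np.sign(delta))
        t = delta / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        d = delta / np.sqrt(sp2)
    else:
        raise ConfigurationError(f"unknown t-test mode {mode!r}")
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), min(p, 1.0), float(d))


def adjust_pvalues(p: Sequence[float], method: str = "holm",
                   m: int | None = None) -> np.ndarray:
    """Multiplicity-adjusted p-values, clipped at 1 with monotonicity.

    ``m`` is the family size; it may exceed ``len(p)`` when some family
    members are not observed (their adjustment then assumes they are
    larger than every observed p-value).
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise DataError("p-values must lie in [0, 1]")
    k = p.size
    m = k if m is None else int(m)
    if m < k:
        raise ConfigurationError("family size m cannot be below len(p)")
    if k == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(k)
    if method == "bonferroni":
        adj = np.minimum(p * m, 1.0)
        return adj
    if method == "holm":
        mult = m - np.arange(k)
        stepped = np.maximum.accumulate(np.minimum(ranked * mult, 1.0))
        out = np.empty(k)
        out[order] = np.minimum(stepped, 1.0)
        return out
    if method == "bh_fdr":
        mult = m / (np.arange(k) + 1.0)
        stepped = np.minimum.accumulate((ranked * mult)[::-1])[::-1]
        out = np.empty(k)
        out[order] = np.minimum(stepped, 1.0)
        return out
    raise ConfigurationError(f"unknown adjustment method {method!r}")


# --------------------------------------------------------------------------
# Cluster-based permutation test
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    electrodes: tuple[str, ...]
    sign: int
    mass: float  # sum of member t-values
    p_perm: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: dict[str, float]
    n_permutations: int
    threshold_p: float

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_perm < 0.05]


def _paired_t_matrix(diff: np.ndarray, signs: np.ndarray) -> np.ndarray:
    n = diff.shape[0]
    mu = signs @ diff / n
    ssq = (diff ** 2).sum(axis=0)
    var = (ssq[None, :] - n * mu ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, mu / np.sqrt(var / n), 0.0)
    return t


def _independent_t_matrix(x: np.ndarray, assign: np.ndarray, n1: int
                          ) -> np.ndarray:
    n = x.shape[0]
    n2 = n - n1
    s_tot = x.sum(axis=0)
    ssq_tot = (x ** 2).sum(axis=0)
    s1 = assign @ x
    q1 = assign @ (x ** 2)
    m1 = s1 / n1
    m2 = (s_tot[None, :] - s1) / n2
    ss1 = q1 - n1 * m1 ** 2
    ss2 = (ssq_tot[None, :] - q1) - n2 * m2 ** 2
    sp2 = np.maximum(ss1 + ss2, 0.0) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sp2 > 0,
                     (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2)), 0.0)
    return t


def _clusters_from_t(t: np.ndarray, tcrit: float,
                     neighbors: list[np.ndarray]) -> list[tuple[int, float,
                                                                list[int]]]:
    """Same-sign connected components of supra-threshold electrodes (>= 2)."""
    out = []
    for sign in (1, -1):
        supra = (sign * t) > tcrit
        seen = np.zeros(t.size, dtype=bool)
        for start in np.flatnonzero(supra):
            if seen[start]:
                continue
            stack = [start]
            seen[start] = True
            comp = []
            while stack:
                node = stack.pop()
                comp.append(node)
                for nb in neighbors[node]:
                    if supra[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            if len(comp) >= 2:
                out.append((sign, float(t[comp].sum()), sorted(comp)))
    return out


def cluster_permutation(values_a: np.ndarray, values_b: np.ndarray,
                        adjacency: nx.Graph, labels: Sequence[str],
                        design: str = "paired", threshold_p: float = 0.05,
                        n_perm: int = 2000, seed: int = 0) -> ClusterResult:
    """Cluster-based permutation test over an electrode graph.

    ``values_a``/``values_b`` are subjects x electrodes matrices: the two
    conditions of matched subjects (paired) or the two groups
    (independent). Clusters are connected sets of >= 2 adjacent electrodes
    whose t-values exceed the two-sided critical value at ``threshold_p``
    with identical signs; cluster mass is the summed t. The two-tailed
    Monte Carlo p-value references the null distribution of the maximum
    absolute cluster mass over ``n_perm`` random relabelings (sign-flips
    within subject for paired contrasts, group-label shuffles for
    independent), with the +1 convention so p is never exactly zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    labels = list(labels)
    missing = [l for l in labels if l not in adjacency.nodes]
    if missing:
        raise DataError(f"adjacency graph is missing electrodes: {missing}")
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != len(labels) \
            or b.shape[1] != len(labels):
        raise DataError("value matrices must be subjects x electrodes")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation null",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    index = {l: i for i, l in enumerate(labels)}
    neighbors = [np.array(sorted(index[nb] for nb in adjacency.neighbors(l)
                                 if nb in index), dtype=int)
                 for l in labels]

    if design == "paired":
        if a.shape != b.shape:
            raise DataError("paired design requires matched subjects")
        if a.shape[0] < 2:
            raise InferenceError("need >= 2 subjects")
        diff = a - b
        n = diff.shape[0]
        df = n - 1
        t_obs = _paired_t_matrix(diff, np.ones((1, n)))[0]
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        t_null = _paired_t_matrix(diff, signs)
    elif design == "independent":
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise InferenceError("need >= 2 subjects per group")
        x = np.vstack([a, b])
        n1, n_tot = a.shape[0], a.shape[0] + b.shape[0]
        df = n_tot - 2
        obs_assign = np.zeros((1, n_tot))
        obs_assign[0, :n1] = 1.0
        t_obs = _independent_t_matrix(x, obs_assign, n1)[0]
        assign = np.zeros((n_perm, n_tot))
        for r in range(n_perm):
            assign[r, rng.permutation(n_tot)[:n1]] = 1.0
        t_null = _independent_t_matrix(x, assign, n1)
    else:
        raise ConfigurationError(f"unknown design {design!r}")

    tcrit = float(sps.t.ppf(1.0 - threshold_p / 2.0, df))
    obs_clusters = _clusters_from_t(t_obs, tcrit, neighbors)
    null_max = np.zeros(n_perm)
    for r in range(n_perm):
        cl = _clusters_from_t(t_null[r], tcrit, neighbors)
        if cl:
            null_max[r] = max(abs(mass) for _s, mass, _c in cl)
    clusters = []
    for sign, mass, comp in sorted(obs_clusters,
                                   key=lambda c: -abs(c[1])):
        p = (1.0 + float((null_max >= abs(mass)).sum())) / (n_perm + 1.0)
        clusters.append(Cluster(electrodes=tuple(labels[i] for i in comp),
                                sign=sign, mass=mass, p_perm=p))
    return ClusterResult(clusters=clusters,
                         t_values=dict(zip(labels, t_obs.tolist())),
                         n_permutations=n_perm, threshold_p=threshold_p)


# --------------------------------------------------------------------------
# McNemar blinding test
# --------------------------------------------------------------------------

def mcnemar_cc(table: ContingencyTable2x2 | tuple[int, int]
               ) -> tuple[float, float]:
    """Continuity-corrected McNemar test on the discordant cells.

    chi^2 = (max(|b - c| - 1, 0))^2 / (b + c), referred to a chi-square
    distribution with 1 df; symmetric in (b, c) and floored at zero when
    |b - c| <= 1.
    """
    if isinstance(table, ContingencyTable2x2):
        b, c = table.b, table.c
    else:
        b, c = table
    if b < 0 or c < 0:
        raise DataError("discordant counts must be >= 0")
    if b + c == 0:
        raise InferenceError("no discordant pairs; McNemar test undefined")
    chi_sq = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    return float(chi_sq), float(sps.chi2.sf(chi_sq, 1))


# --------------------------------------------------------------------------
# Sensitivity analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivitySolution:
    n_per_group: int
    alpha: float
    power: float
    sides: int
    d_min: float


def two_sample_power(d: float, n_per_group: int, alpha: float = 0.05,
                     sides: int = 2) -> float:
    """Power of the two-sample t-test at standardized difference ``d``."""
    df = 2 * n_per_group - 2
    tcrit = sps.t.ppf(1.0 - alpha / sides, df)
    nc = d * np.sqrt(n_per_group / 2.0)
    power = float(sps.nct.sf(tcrit, df, nc))
    if sides == 2:
        power += float(sps.nct.cdf(-tcrit, df, nc))
    return power


def min_detectable_d(n_per_group: int, alpha: float = 0.05,
                     power: float = 0.80, sides: int = 2
                     ) -> SensitivitySolution:
    """Minimum detectable Cohen's d of a two-sample comparison.

    Solves the noncentral-t power equation by bisection to 1e-6. Applied to
    the primary offline contrast this is a between-group comparison of
    pre-post change scores.
    """
    if n_per_group < 2:
        raise InferenceError("need n >= 2 per group")
    if not 0 < alpha < 1 or not 0 < power < 1 or power <= alpha:
        raise ConfigurationError("require 0 < alpha < power < 1")
    lo, hi = 0.0, 1.0
    while two_sample_power(hi, n_per_group, alpha, sides) < power:
        hi *= 2.0
        if hi > 1e3:
            raise InferenceError("requested power unreachable")
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if two_sample_power(mid, n_per_group, alpha, sides) < power:
            lo = mid
        else:
            hi = mid
    return SensitivitySolution(n_per_group=n_per_group, alpha=alpha,
                               power=power, sides=sides,
                               d_min=0.5 * (lo + hi))
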