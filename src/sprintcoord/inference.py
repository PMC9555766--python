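"""Discrete-kinematics extraction and the inferential layer.

One-way repeated-measures ANOVA with Mauchly sphericity check and
Greenhouse-Geisser correction, Friedman tests on bin frequencies, Wilcoxon
signed-rank pairwise tests and Bonferroni adjustment.  The ANOVA, Mauchly
test and Friedman statistic are implemented directly (and cross-checked
against pingouin/scipy in the test suite); Wilcoxon p-values come from
scipy with an exact null for small samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert

from .errors import ParameterError, SpanError, ValidationError
from .io import AnalysisConfig, Trial, segment_id
from .preprocessing import StepWindow
from .coordstats import bin_frequencies  # noqa: F401  (re-export convenience)
from .vector_coding import N_BINS

log = logging.getLogger(__name__)

#: joint angles derived from segment angles; dorsiflexion decreases the
#: ankle (shank minus foot) angle.
JOINT_DEFINITIONS = {
    "hip": ("trunk", "thigh"),
    "knee": ("thigh", "shank"),
    "ankle": ("shank", "foot"),
}

DISCRETE_VARIABLES = ("trunk", "thigh", "shank", "foot", "hip", "knee", "ankle")


def _interp_at(trial: Trial, seg: str, time: float) -> float:
    s = trial.series[seg]
    if not (s.start_time <= time <= s.end_time):
        raise SpanError(f"event time {time:g}s outside span of segment {seg}")
    return float(np.interp(time, s.times, s.values))


def extract_event_angles(
    trial: Trial, windows: list[StepWindow]
) -> pd.DataFrame:
    """Touchdown and closing toe-off angles per step (stance-limb variables).

    Sided variables (thigh, shank, foot and the derived joints) are taken
    from the limb in stance during the step, i.e. the leading limb.
    Returns a tidy frame: participant, step, event, variable, angle_deg.
    """
    rows = []
    for w in windows:
        side = w.leading_side
        for event, t in (("touchdown", w.t_td), ("toe_off", w.t_end)):
            seg_angles = {
                "trunk": _interp_at(trial, "trunk", t),
                "thigh": _interp_at(trial, segment_id("thigh", side), t),
                "shank": _interp_at(trial, segment_id("shank", side), t),
                "foot": _interp_at(trial, segment_id("foot", side), t),
            }
            for joint, (prox, dist) in JOINT_DEFINITIONS.items():
                seg_angles[joint] = seg_angles[prox] - seg_angles[dist]
            for var in DISCRETE_VARIABLES:
                rows.append(
                    {
                        "participant": trial.participant_id,
                        "step": w.step_index,
                        "event": event,
                        "variable": var,
                        "angle_deg": seg_angles[var],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df_num: float
    df_den: float
    p: float
    eta_sq: float  # partial eta squared
    gg_applied: bool
    epsilon: float
    mauchly_w: float
    mauchly_p: float


def _check_matrix(values: np.ndarray, min_rows: int, min_cols: int) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValidationError("values must be a participant x condition matrix")
    n, k = x.shape
    if n < min_rows or k < min_cols:
        raise ValidationError(f"need at least {min_rows} rows and {min_cols} columns")
    if not np.all(np.isfinite(x)):
        raise ValidationError("matrix contains missing values; complete cases required")
    return x


def mauchly(values: np.ndarray) -> tuple[float, float, float, float]:
    """Mauchly's sphericity test: (W, chi2, df, p).

    Uses orthonormal (Helmert) contrasts of the condition covariance matrix
    and the standard chi-square approximation.
    """
    x = _check_matrix(values, 3, 3)
    n, k = x.shape
    c = helmert(k, full=False)
    t = c @ np.cov(x, rowvar=False, ddof=1) @ c.T
    eig = np.linalg.eigvalsh(t)
    eig = np.clip(eig, 1e-300, None)
    w = float(np.exp(np.sum(np.log(eig)) - (k - 1) * np.log(eig.mean())))
    w = max(w, np.finfo(float).tiny)
    df = k * (k - 1) / 2 - 1
    d = 1 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6 * (k - 1) * (n - 1))
    chi2 = -(n - 1) * d * np.log(w)
    p = float(stats.chi2.sf(chi2, df))
    return w, float(chi2), float(df), p


def gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon, lower-bounded at 1/(k-1)."""
    x = _check_matrix(values, 2, 2)
    k = x.shape[1]
    c = helmert(k, full=False)
    t = c @ np.cov(x, rowvar=False, ddof=1) @ c.T
    eps = np.trace(t) ** 2 / ((k - 1) * np.trace(t @ t))
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def rm_anova(values: np.ndarray, alpha_sphericity: float = 0.05) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a participant x condition matrix.

    Greenhouse-Geisser correction is applied to the degrees of freedom and
    p-value only when Mauchly's test rejects sphericity (p < 0.05, and only
    for k > 2 where sphericity is testable).  Effect size is partial eta
    squared, SS_effect / (SS_effect + SS_error).
    """
    x = _check_matrix(values, 3, 2)
    n, k = x.shape
    grand = x.mean()
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    ss_cond = n * np.sum((col_means - grand) ** 2)
    ss_subj = k * np.sum((row_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df1 = float(k - 1)
    df2 = float((n - 1) * (k - 1))
    if ss_err == 0.0:
        f = 0.0 if ss_cond == 0.0 else float("inf")
    else:
        f = (ss_cond / df1) / (ss_err / df2)
    eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    gg_applied = False
    eps = 1.0
    w_stat, p_mauchly = float("nan"), float("nan")
    if k > 2:
        w_stat, _, _, p_mauchly = mauchly(x)
        eps = gg_epsilon(x)
        if p_mauchly < alpha_sphericity:
            gg_applied = True
            df1 *= eps
            df2 *= eps
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return RMAnovaResult(
        F=float(f),
        df_num=df1,
        df_den=df2,
        p=p,
        eta_sq=float(eta),
        gg_applied=gg_applied,
        epsilon=eps if gg_applied else (eps if k > 2 else 1.0),
        mauchly_w=w_stat,
        mauchly_p=p_mauchly,
    )


# ---------------------------------------------------------------------------
# rank-based tests
# ---------------------------------------------------------------------------

def friedman_statistic(values: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square with mid-rank tie correction; returns (chi2, df)."""
    x = _check_matrix(values, 2, 2)
    n, k = x.shape
    ranks = stats.rankdata(x, axis=1)
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    den = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    if den == 0.0:  # all rows fully tied
        return 0.0, float(k - 1)
    return float(num / den), float(k - 1)


def friedman(values: np.ndarray, exact: bool = False) -> tuple[float, float, float]:
    """Friedman test across conditions: (chi2, df, p).

    ``exact=True`` enumerates within-row permutations of the observed values
    (feasible for small samples, e.g. <= 8 rows with 3 conditions) and
    returns the permutation p-value; otherwise the chi-square approximation
    is used.
    """
    x = _check_matrix(values, 2, 2)
    n, k = x.shape
    chi2, df = friedman_statistic(x)
    if not exact:
        p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
        return chi2, df, p
    perms = list(itertools.permutations(range(k)))
    total = len(perms) ** n
    if total > 2_000_000:
        raise ParameterError(
            f"exact Friedman infeasible: {total} permutations; use exact=False"
        )
    count = 0
    tol = 1e-9
    for combo in itertools.product(perms, repeat=n):
        xp = np.vstack([x[i, list(combo[i])] for i in range(n)])
        stat, _ = friedman_statistic(xp)
        if stat >= chi2 - tol:
            count += 1
    return chi2, df, count / total


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples: (W+, p).

    Zero differences are dropped; the p-value is exact for n <= 25 non-zero
    pairs and a normal approximation with continuity correction otherwise.
    The statistic reported is the sum of ranks of positive differences.
    If every difference is zero the test is degenerate and (0, 1) returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        log.warning("all paired differences are zero; Wilcoxon test degenerate")
        return 0.0, 1.0
    method = "exact" if d.size <= 25 else "approx"
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return w_plus, float(res.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p <- min(1, p * m); m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _pivot(df: pd.DataFrame, value_col: str) -> np.ndarray:
    wide = df.pivot(index="participant", columns="step", values=value_col)
    if wide.isna().any().any():
        raise ValidationError("incomplete participant x step matrix")
    return wide.to_numpy()


def discrete_kinematics_report(discrete: pd.DataFrame) -> pd.DataFrame:
    """RM-ANOVA per variable x event over steps, plus Bonferroni pairwise t-tests."""
    rows = []
    for (event, var), sub in discrete.groupby(["event", "variable"]):
        x = _pivot(sub, "angle_deg")
        n, k = x.shape
        res = rm_anova(x)
        pair_ps = []
        pairs = list(itertools.combinations(range(k), 2))
        for i, j in pairs:
            t = stats.ttest_rel(x[:, i], x[:, j])
            pair_ps.append(t.pvalue)
        adj = bonferroni(pair_ps)
        rows.append(
            {
                "event": event,
                "variable": var,
                "F": res.F,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "p": res.p,
                "eta_sq": res.eta_sq,
                "gg_applied": res.gg_applied,
                "epsilon": res.epsilon,
                "significant_pairs": ";".join(
                    f"S{i + 1}-S{j + 1}" for (i, j), pa in zip(pairs, adj) if pa < 0.05
                ),
                **{f"mean_step{j + 1}": x[:, j].mean() for j in range(k)},
                **{f"sd_step{j + 1}": x[:, j].std(ddof=1) for j in range(k)},
            }
        )
    return pd.DataFrame(rows)


def bin_frequency_report(bin_table: pd.DataFrame) -> pd.DataFrame:
    """Friedman test across steps per coupling x bin, plus Wilcoxon pairwise.

    Bins with zero frequency for every participant in every step are skipped
    (the test is undefined there) and logged.
    """
    rows = []
    for (coupling, b), sub in bin_table.groupby(["coupling", "bin_index"]):
        x = _pivot(sub, "freq_pct")
        if np.all(x == 0.0):
            log.info("skipping bin %s of %s: zero frequency everywhere", b, coupling)
            continue
        chi2, df, p = friedman(x)
        n, k = x.shape
        pairs = list(itertools.combinations(range(k), 2))
        raw = []
        stats_w = []
        for i, j in pairs:
            w, pr = wilcoxon_signed_rank(x[:, i], x[:, j])
            raw.append(pr)
            stats_w.append(w)
        adj = bonferroni(raw)
        for (i, j), w, pr, pa in zip(pairs, stats_w, raw, adj):
            rows.append(
                {
                    "coupling": coupling,
                    "bin_index": b,
                    "bin_label": sub["bin_label"].iloc[0],
                    "friedman_chi2": chi2,
                    "friedman_df": df,
                    "friedman_p": p,
                    "pair": f"S{i + 1}-S{j + 1}",
                    "wilcoxon_w": w,
                    "p_raw": pr,
                    "p_adjusted": pa,
                }
            )
    return pd.DataFrame(rows)
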