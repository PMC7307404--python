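"""Serial-reaction-time statistics for MILO sessions.

The analysis chain mirrors standard practice for sequential-search data:
per-trial SRT series, per-participant median SRT curves (the median is the
point estimate because trial-level latencies are right-skewed), a balanced
mixed ANOVA (one between-subject factor, up to two repeated-measures
factors) with Greenhouse-Geisser sphericity correction, orthogonal
polynomial trend contrasts, BIC-approximated Bayes factors with equal-prior
posterior probabilities, and per-participant variability summaries.

Latencies are converted from milliseconds to seconds before sums of squares
are formed, so mean-square errors come out on the conventional seconds^2
scale; reported latencies stay in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import TrialResult

__all__ = [
    "SRTSeries",
    "BayesResult",
    "compute_srt",
    "median_curves",
    "mixed_anova",
    "gg_epsilon",
    "polynomial_trends",
    "bic_bayes_factor",
    "posterior_prob",
    "classify_evidence",
    "variability_summary",
]


@dataclass(frozen=True)
class SRTSeries:
    """Ordered serial reaction times T1..TN (ms) of one trial."""

    participant: str
    trial: int
    condition: str
    srt: tuple[float, ...]


@dataclass(frozen=True)
class BayesResult:
    """BIC-approximated Bayes factor for one ANOVA effect."""

    delta_bic: float
    bf10: float
    bf01: float
    posterior_h1: float
    posterior_h0: float
    n_used: int


# ---------------------------------------------------------------------------
# SRT derivation and curves
# ---------------------------------------------------------------------------


def compute_srt(result: TrialResult, participant: str = "") -> SRTSeries:
    """Derive the SRT series of a trial: T1 from response onset, later
    targets from the previous selection."""
    if not result.selections:
        raise ValueError("trial has no selections")
    times = [t for _s, t, _x, _y in result.selections]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("selection times must be strictly increasing")
    prev = result.spec.preview_ms
    srts: list[float] = []
    for t in times:
        srts.append(float(t - prev))
        prev = t
    return SRTSeries(
        participant=participant,
        trial=result.spec.trial_id,
        condition=result.spec.condition,
        srt=tuple(srts),
    )


def median_curves(
    table: pd.DataFrame,
    group_by: tuple[str, ...] = ("participant", "condition", "target_index"),
    value: str = "srt_ms",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-wise median SRTs plus a between-participant curve summary.

    Returns ``(medians, summary)``: the first has one row per group cell
    with the median of ``value`` (even cell counts average the two central
    order statistics, the usual median rule); the second collapses the
    participant level into mean +/- SEM per remaining cell for plotting.
    """
    if table.empty:
        raise ValueError("no observations to summarise")
    med = (
        table.groupby(list(group_by), observed=True)[value]
        .median()
        .reset_index()
        .rename(columns={value: "median_" + value})
    )
    rest = [g for g in group_by if g != "participant"]
    if rest:
        grp = med.groupby(rest, observed=True)["median_" + value]
        summary = grp.agg(mean="mean", sem="sem", n="count").reset_index()
    else:
        summary = pd.DataFrame(
            {
                "mean": [med["median_" + value].mean()],
                "sem": [med["median_" + value].sem()],
                "n": [len(med)],
            }
        )
    return med, summary


# ---------------------------------------------------------------------------
# Greenhouse-Geisser epsilon
# ---------------------------------------------------------------------------


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal (Helmert) contrasts, all orthogonal to the unit
    vector."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -float(j)
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def _epsilon_from_cov(cov: np.ndarray, contrasts: np.ndarray) -> float:
    m = contrasts.T @ cov @ contrasts
    d = m.shape[0]
    tr = float(np.trace(m))
    tr2 = float(np.trace(m @ m))
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (d * tr2)
    return float(min(1.0, max(1.0 / d, eps)))


def gg_epsilon(cov: np.ndarray) -> float:
    """Box/Greenhouse-Geisser epsilon of a k x k within-effect covariance.

    Equals 1 under compound symmetry and is clipped to the analytic range
    ``[1/(k-1), 1]``.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    k = cov.shape[0]
    if k < 2:
        raise ValueError("need at least two levels")
    return _epsilon_from_cov(cov, _orthonormal_contrasts(k))


def _pooled_within_cov(x: np.ndarray) -> np.ndarray | None:
    """Pooled within-group covariance of subject profiles, x: (g, n, k)."""
    g, n, k = x.shape
    dof = g * (n - 1)
    if dof < 1:
        return None
    s = np.zeros((k, k))
    for grp in range(g):
        d = x[grp] - x[grp].mean(axis=0)
        s += d.T @ d
    return s / dof


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

_ANOVA_COLS = [
    "effect",
    "F",
    "df_num",
    "df_den",
    "df_num_unadj",
    "df_den_unadj",
    "MSE",
    "p",
    "partial_eta_sq",
    "gg_epsilon",
]


def _pivot_balanced(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: tuple[str, ...],
    between: str | None,
) -> tuple[np.ndarray, dict]:
    """Reshape tidy data to y[group, subject, A, B]; reject unbalanced input."""
    cols = [subject, *within] + ([between] if between else [])
    for c in cols + [dv]:
        if c not in data.columns:
            raise ValueError(f"column {c!r} missing from data")
    counts = data.groupby([subject, *within], observed=True)[dv].size()
    if (counts != 1).any():
        raise ValueError("unbalanced data: need exactly one value per subject x cell")
    levels = {w: sorted(data[w].unique()) for w in within}
    subjects = sorted(data[subject].unique())
    full = len(subjects) * int(np.prod([len(levels[w]) for w in within]))
    if len(data) != full:
        raise ValueError("unbalanced data: missing cells")
    if between:
        grp_of = data.groupby(subject, observed=True)[between].agg(
            lambda v: v.iloc[0] if v.nunique() == 1 else None
        )
        if grp_of.isna().any():
            raise ValueError("a subject appears in more than one between-group")
        groups = sorted(grp_of.unique())
        per = [sum(grp_of[s] == g for s in subjects) for g in groups]
        if len(set(per)) != 1:
            raise ValueError("unbalanced data: unequal group sizes")
    else:
        grp_of = pd.Series({s: "_all" for s in subjects})
        groups = ["_all"]
    wide = data.set_index([subject, *within])[dv].sort_index()
    a = len(levels[within[0]])
    b = len(levels[within[1]]) if len(within) > 1 else 1
    n = len(subjects) // len(groups)
    y = np.empty((len(groups), n, a, b))
    for gi, g in enumerate(groups):
        subs = [s for s in subjects if grp_of[s] == g]
        for si, s in enumerate(subs):
            for ai, la in enumerate(levels[within[0]]):
                if len(within) > 1:
                    for bi, lb in enumerate(levels[within[1]]):
                        y[gi, si, ai, bi] = wide.loc[(s, la, lb)]
                else:
                    y[gi, si, ai, 0] = wide.loc[(s, la)]
    meta = {"groups": groups, "levels": levels, "subjects": subjects}
    return y, meta


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "srt_ms",
    subject: str = "participant",
    within: tuple[str, ...] = ("condition", "target_index"),
    between: str | None = "sequence_type",
    to_seconds: bool | None = None,
) -> pd.DataFrame:
    """Balanced mixed ANOVA with Greenhouse-Geisser correction.

    Supports one between-subject factor (optional) crossed with one or two
    repeated-measures factors — the full design used for median SRT curves
    (e.g. 2 Condition x 2 Sequence x 8 Target) as well as the follow-up
    splits (T1-only 2x2; T2-T8 2x2x7).  Unbalanced input is rejected, never
    imputed.  Returns a table with one row per effect: F, GG-adjusted
    degrees of freedom and p, the error-term mean square, partial eta
    squared and the epsilon applied.
    """
    within = tuple(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("within must name one or two factors")
    if between is not None and between in data.columns and data[between].nunique() < 2:
        between = None  # single-level between factor degenerates to none
    data = data.copy()
    if to_seconds is None:
        to_seconds = dv.endswith("_ms")
    if to_seconds:
        data[dv] = data[dv] / 1000.0
    y, meta = _pivot_balanced(data, dv, subject, within, between)
    g, n, a, b = y.shape
    grand = y.mean()

    def ss(mean_arr: np.ndarray, mult: float) -> float:
        return float(mult * ((mean_arr - grand) ** 2).sum())

    m_s = y.mean(axis=(2, 3))
    m_g = y.mean(axis=(1, 2, 3))
    ss_bs = ss(m_s, a * b)
    ss_G = ss(m_g, n * a * b)
    ss_S = ss_bs - ss_G
    m_a = y.mean(axis=(0, 1, 3))
    ss_A = ss(m_a, g * n * b)
    m_ga = y.mean(axis=(1, 3))
    ss_GA = ss(m_ga, n * b) - ss_G - ss_A
    m_sa = y.mean(axis=3)
    ss_AS = ss(m_sa, b) - ss_bs - ss_A - ss_GA
    m_b = y.mean(axis=(0, 1, 2))
    ss_B = ss(m_b, g * n * a)
    m_gb = y.mean(axis=(1, 2))
    ss_GB = ss(m_gb, n * a) - ss_G - ss_B
    m_sb = y.mean(axis=2)
    ss_BS = ss(m_sb, a) - ss_bs - ss_B - ss_GB
    m_ab = y.mean(axis=(0, 1))
    ss_AB = ss(m_ab, g * n) - ss_A - ss_B
    m_gab = y.mean(axis=1)
    ss_GAB = ss(m_gab, n) - ss_G - ss_A - ss_B - ss_GA - ss_GB - ss_AB
    ss_tot = float(((y - grand) ** 2).sum())
    ss_ABS = ss_tot - (
        ss_G + ss_S + ss_A + ss_GA + ss_AS + ss_B + ss_GB + ss_BS + ss_AB + ss_GAB
    )

    df_S = g * (n - 1)
    eps_A = eps_B = eps_AB = 1.0
    if a > 2:
        cov = _pooled_within_cov(m_sa.reshape(g, n, a))
        eps_A = gg_epsilon(cov) if cov is not None else 1.0
    if b > 2:
        cov = _pooled_within_cov(m_sb.reshape(g, n, b))
        eps_B = gg_epsilon(cov) if cov is not None else 1.0
    if a > 1 and b > 1 and (a - 1) * (b - 1) > 1:
        cov = _pooled_within_cov(y.reshape(g, n, a * b))
        if cov is not None:
            K = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
            eps_AB = _epsilon_from_cov(cov, K)

    name_A = within[0]
    name_B = within[1] if len(within) > 1 else None
    name_G = between

    rows: list[dict] = []

    def add(effect, ss_eff, df_eff, ss_err, df_err, eps=None):
        if df_eff <= 0 or df_err <= 0:
            return
        mse = ss_err / df_err
        F = (ss_eff / df_eff) / mse if mse > 0 else np.inf
        e = 1.0 if eps is None else eps
        p = float(stats.f.sf(F, df_eff * e, df_err * e))
        rows.append(
            {
                "effect": effect,
                "F": F,
                "df_num": df_eff * e,
                "df_den": df_err * e,
                "df_num_unadj": df_eff,
                "df_den_unadj": df_err,
                "MSE": mse,
                "p": p,
                "partial_eta_sq": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
                "gg_epsilon": eps,
            }
        )

    if name_G:
        add(name_G, ss_G, g - 1, ss_S, df_S)
    add(name_A, ss_A, a - 1, ss_AS, (a - 1) * df_S, eps_A if a > 2 else None)
    if name_G:
        add(f"{name_G} * {name_A}", ss_GA, (g - 1) * (a - 1), ss_AS, (a - 1) * df_S,
            eps_A if a > 2 else None)
    if name_B:
        add(name_B, ss_B, b - 1, ss_BS, (b - 1) * df_S, eps_B if b > 2 else None)
        if name_G:
            add(f"{name_G} * {name_B}", ss_GB, (g - 1) * (b - 1), ss_BS,
                (b - 1) * df_S, eps_B if b > 2 else None)
        add(f"{name_A} * {name_B}", ss_AB, (a - 1) * (b - 1), ss_ABS,
            (a - 1) * (b - 1) * df_S, eps_AB if (a - 1) * (b - 1) > 1 else None)
        if name_G:
            add(f"{name_G} * {name_A} * {name_B}", ss_GAB,
                (g - 1) * (a - 1) * (b - 1), ss_ABS, (a - 1) * (b - 1) * df_S,
                eps_AB if (a - 1) * (b - 1) > 1 else None)
    return pd.DataFrame(rows, columns=_ANOVA_COLS)


# ---------------------------------------------------------------------------
# polynomial trends
# ---------------------------------------------------------------------------


def _poly_contrasts(k: int, max_order: int) -> np.ndarray:
    """Orthonormal polynomial contrasts (columns: linear, quadratic, ...)."""
    x = np.arange(k, dtype=float)
    v = np.column_stack([x**p for p in range(max_order + 1)])
    q, _ = np.linalg.qr(v)
    return q[:, 1:]


_TREND_NAMES = ["linear", "quadratic", "cubic", "quartic", "quintic"]


def polynomial_trends(means: np.ndarray | pd.DataFrame, max_order: int = 3) -> pd.DataFrame:
    """Orthogonal polynomial trend tests over ordered within-subject levels.

    ``means`` is (participants x levels); each contrast is tested as a
    one-sample F (t^2) on the per-participant contrast scores.
    """
    m = np.asarray(means, dtype=float)
    if m.ndim != 2:
        raise ValueError("means must be participants x levels")
    n, k = m.shape
    if k < max_order + 1:
        raise ValueError(f"need at least {max_order + 1} levels for order {max_order}")
    if n < 2:
        raise ValueError("need at least two participants")
    C = _poly_contrasts(k, max_order)
    rows = []
    # scale-aware zero threshold: contrast scores of constant-profile input
    # carry O(ulp) noise that must not masquerade as variance
    tol = 1e-12 * max(1.0, float(np.abs(m).max())) ** 2
    for j in range(max_order):
        scores = m @ C[:, j]
        mean, var = scores.mean(), scores.var(ddof=1)
        if var < tol:
            F = 0.0 if mean**2 < tol else np.inf
        else:
            F = n * mean**2 / var
        rows.append(
            {
                "trend": _TREND_NAMES[j],
                "F": F,
                "df_num": 1,
                "df_den": n - 1,
                "p": float(stats.f.sf(F, 1, n - 1)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------


def bic_bayes_factor(F: float, df_effect: int, df_error: int, n: int) -> BayesResult:
    """BIC-approximated Bayes factor for an ANOVA effect.

    Uses the unit-information approximation: the restricted/full error
    ratio is recovered from the printed F, the BIC difference is
    ``n * ln(SSE1/SSE0) + df_effect * ln(n)``, and ``BF01 = exp(dBIC/2)``.
    ``n`` is the number of independent observations — by this package's
    convention the number of participants.
    """
    if F < 0:
        raise ValueError("F must be non-negative")
    if df_effect <= 0 or df_error <= 0 or n <= 1:
        raise ValueError("degrees of freedom must be positive and n > 1")
    sse_ratio = df_error / (df_error + F * df_effect)
    delta_bic = n * np.log(sse_ratio) + df_effect * np.log(n)
    bf01 = float(np.exp(delta_bic / 2.0))
    bf10 = 1.0 / bf01
    p1 = posterior_prob(bf10)
    return BayesResult(
        delta_bic=float(delta_bic),
        bf10=bf10,
        bf01=bf01,
        posterior_h1=p1,
        posterior_h0=1.0 - p1,
        n_used=n,
    )


def posterior_prob(bf: float) -> float:
    """Posterior probability of the favoured hypothesis under equal priors."""
    if bf <= 0:
        raise ValueError("Bayes factor must be positive")
    return bf / (1.0 + bf)


def classify_evidence(bf: float, posterior: float | None = None) -> str:
    """Label evidence ``weak`` iff BF < 3.0 and posterior < .75 (strict)."""
    if posterior is None:
        posterior = posterior_prob(bf)
    return "weak" if (bf < 3.0 and posterior < 0.75) else "substantial"


# ---------------------------------------------------------------------------
# variability
# ---------------------------------------------------------------------------


def variability_summary(table: pd.DataFrame, value: str = "srt_ms") -> pd.DataFrame:
    """Per participant x condition dispersion of T1 and of T2-TN SRTs.

    Initial-response variability is a sensitive individual-differences
    marker, so SD and IQR are reported separately for the first response
    and for the rest of the sequence.  Cells with fewer than two trials
    yield NaN rather than a misleading zero.
    """

    def iqr(v):
        return float(np.subtract(*np.percentile(v, [75, 25]))) if len(v) >= 2 else np.nan

    def sd(v):
        return float(np.std(v, ddof=1)) if len(v) >= 2 else np.nan

    rows = []
    for (pid, cond), grp in table.groupby(["participant", "condition"], observed=True):
        t1 = grp.loc[grp["target_index"] == 1, value].to_numpy()
        later = grp.loc[grp["target_index"] >= 2, value].to_numpy()
        rows.append(
            {
                "participant": pid,
                "condition": cond,
                "t1_sd": sd(t1),
                "t1_iqr": iqr(t1),
                "later_sd": sd(later),
                "later_iqr": iqr(later),
                "n_trials": int((grp["target_index"] == 1).sum()),
            }
        )
    return pd.DataFrame(rows)
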