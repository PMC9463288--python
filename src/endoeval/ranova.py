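"""Repeated-measures ANOVA over attempt-triplet sessions, Huynh-Feldt corrected.

For every feature and every session (attempts 1-3, 4-6, 7-9) a split-plot
model is fitted: the attempt index within the session is the within-subject
factor (k = 3 levels), the participant is the random factor and the
endoscope mode (2D vs 3D) is the sole between-subject factor. The F-tests of
the time effect and the time x endoscope interaction are corrected for
sphericity violation by multiplying both numerator and denominator degrees
of freedom with the Huynh-Feldt epsilon.

Epsilon follows the standard two-step construction: the Greenhouse-Geisser
estimate from the pooled within-group covariance of the k repeated measures,

    eps_GG = tr(M)^2 / ((k-1) tr(M^2)),   M = C S C',

with C an orthonormal contrast matrix, then the Huynh-Feldt adjustment for a
design with g groups and N subjects,

    eps_HF = (N (k-1) eps_GG - 2) / ((k-1) (N - g - (k-1) eps_GG)),

clipped to at most 1. Sums of squares use the classical split-plot
decomposition (Type III via effect coding, exact for balanced groups and
well-defined for the mildly unbalanced 7-vs-8 split).

p-value distributions across the feature set are summarised as -log10
boxplots with significance ticks at p = 0.05, 0.01 and 0.001
(-log10 = 1.3010, 2 and 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .table import ANNOTATION_COLS

__all__ = [
    "SessionModel",
    "RanovaResult",
    "SIGNIFICANCE_TICKS",
    "hf_epsilon",
    "gg_epsilon",
    "ranova_session",
    "ranova_table",
    "neglog10_summary",
    "sessions_of",
]

#: -log10 of the significance thresholds 0.05, 0.01, 0.001.
SIGNIFICANCE_TICKS = (1.3010, 2.0, 3.0)

#: session label -> attempt indices
SESSIONS = {1: (1, 2, 3), 2: (4, 5, 6), 3: (7, 8, 9)}


@dataclass(frozen=True)
class SessionModel:
    """One feature's N x k response matrix for one session, with group labels."""

    Y: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        g = np.asarray(self.group)
        if Y.ndim != 2 or Y.shape[0] != g.size:
            raise ValueError("Y must be N x k with one group label per row")
        if np.unique(g).size < 2:
            raise ValueError("both endoscope groups must be represented")
        counts = pd.Series(g).value_counts()
        if counts.min() < 2:
            raise ValueError("every group needs at least 2 subjects")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "group", g)


@dataclass(frozen=True)
class RanovaResult:
    p_time: float
    p_time_endo: float
    eps_hf: float
    F_time: float
    F_int: float
    df_time: tuple[float, float]
    df_int: tuple[float, float]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to the mean)."""
    h = np.eye(k) - np.full((k, k), 1.0 / k)
    # orthonormal basis of the contrast space via QR of the centring matrix
    q, _ = np.linalg.qr(h.T)
    return q[:, : k - 1].T


def _pooled_within_cov(Y: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Pooled within-group covariance of the k repeated measures (divisor N - g)."""
    n, _ = Y.shape
    groups = np.unique(group)
    s = np.zeros((Y.shape[1], Y.shape[1]))
    for gval in groups:
        sub = Y[group == gval]
        d = sub - sub.mean(axis=0)
        s += d.T @ d
    return s / (n - groups.size)


def gg_epsilon(Y: np.ndarray, group: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    Y = np.asarray(Y, dtype=float)
    k = Y.shape[1]
    C = _orthonormal_contrasts(k)
    M = C @ _pooled_within_cov(Y, np.asarray(group)) @ C.T
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0  # degenerate (constant) data: sphericity trivially holds
    return float(tr**2 / ((k - 1) * tr2))


def hf_epsilon(Y: np.ndarray, group: np.ndarray) -> float:
    """Huynh-Feldt epsilon for a split-plot design, clipped to (1/(k-1), 1]."""
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    g = np.unique(np.asarray(group)).size
    e_gg = gg_epsilon(Y, group)
    denom = (k - 1) * (n - g - (k - 1) * e_gg)
    if denom <= 0:
        return 1.0
    e_hf = (n * (k - 1) * e_gg - 2.0) / denom
    return float(min(e_hf, 1.0))


def _split_plot_ss(Y: np.ndarray, group: np.ndarray) -> tuple[float, float, float, tuple]:
    """Within-subject sums of squares: (SS_time, SS_interaction, SS_error, dfs)."""
    n, k = Y.shape
    groups = np.unique(group)
    g = groups.size
    # centre within subject: removes subject (and between-group) effects
    r = (Y - Y.mean(axis=1, keepdims=True)).ravel()
    # effect-coded design for time and time x group on the long layout
    time_idx = np.tile(np.arange(k), n)
    grp_idx = np.repeat(np.searchsorted(groups, group), k)
    t_eff = np.zeros((n * k, k - 1))
    for j in range(k - 1):
        t_eff[:, j] = (time_idx == j).astype(float) - (time_idx == k - 1)
    g_eff = np.zeros((n * k, g - 1))
    for j in range(g - 1):
        g_eff[:, j] = (grp_idx == j).astype(float) - (grp_idx == g - 1)
    inter = np.einsum("ij,il->ijl", t_eff, g_eff).reshape(n * k, (k - 1) * (g - 1))

    def rss(X: np.ndarray) -> float:
        if X.size == 0:
            return float(r @ r)
        beta, *_ = np.linalg.lstsq(X, r, rcond=None)
        resid = r - X @ beta
        return float(resid @ resid)

    full = np.hstack([t_eff, inter])
    ss_err = rss(full)
    ss_time = rss(inter) - ss_err
    ss_int = rss(t_eff) - ss_err
    dfs = (k - 1, (g - 1) * (k - 1), (n - g) * (k - 1))
    return max(ss_time, 0.0), max(ss_int, 0.0), ss_err, dfs


def ranova_session(model: SessionModel) -> RanovaResult:
    """Huynh-Feldt-corrected split-plot ANOVA of one session model."""
    Y, group = model.Y, model.group
    n, k = Y.shape
    ss_time, ss_int, ss_err, (df_t, df_i, df_e) = _split_plot_ss(Y, group)
    eps = hf_epsilon(Y, group)
    ms_err = ss_err / df_e if df_e > 0 else np.nan
    if ms_err > 0:
        f_time = (ss_time / df_t) / ms_err
        f_int = (ss_int / df_i) / ms_err
        p_time = float(stats.f.sf(f_time, df_t * eps, df_e * eps))
        p_int = float(stats.f.sf(f_int, df_i * eps, df_e * eps))
    else:
        # no within-subject error variance: degenerate, report non-significance
        f_time = f_int = 0.0
        p_time = p_int = 1.0
    return RanovaResult(
        p_time=p_time,
        p_time_endo=p_int,
        eps_hf=eps,
        F_time=float(f_time),
        F_int=float(f_int),
        df_time=(df_t * eps, df_e * eps),
        df_int=(df_i * eps, df_e * eps),
    )


def sessions_of(tbl: pd.DataFrame, feature: str) -> dict[int, SessionModel]:
    """Build the three per-session N x 3 models of one feature from a table."""
    wide = tbl.pivot_table(
        index=["participant", "endoscope"], columns="attempt", values=feature
    )
    out = {}
    for ses, attempts in SESSIONS.items():
        cols = [a for a in attempts if a in wide.columns]
        sub = wide[cols].dropna()
        out[ses] = SessionModel(
            Y=sub.to_numpy(), group=sub.index.get_level_values("endoscope").to_numpy()
        )
    return out


def ranova_table(tbl: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """RANOVA of every feature x session of one exercise table.

    Returns a tidy frame with columns feature, session, p_time, p_time_endo,
    eps_hf, F_time, F_int.
    """
    if features is None:
        features = [c for c in tbl.columns if c not in ANNOTATION_COLS]
    rows = []
    for feat in features:
        for ses, model in sessions_of(tbl, feat).items():
            res = ranova_session(model)
            rows.append(
                {
                    "feature": feat,
                    "session": ses,
                    "p_time": res.p_time,
                    "p_time_endo": res.p_time_endo,
                    "eps_hf": res.eps_hf,
                    "F_time": res.F_time,
                    "F_int": res.F_int,
                }
            )
    return pd.DataFrame(rows)


def neglog10_summary(
    results: pd.DataFrame, ticks: tuple[float, ...] = SIGNIFICANCE_TICKS
) -> dict:
    """Boxplot statistics of -log10 p per session and effect, with outliers.

    Whiskers follow the 1.5 IQR convention (most extreme point inside the
    fence); outliers beyond the upper fence are listed by feature name.
    """
    if results.empty:
        raise ValueError("empty RANOVA results")
    summary: dict = {"ticks": list(ticks), "sessions": {}}
    for ses, sub in results.groupby("session"):
        entry = {}
        for effect, col in (("time", "p_time"), ("time_endo", "p_time_endo")):
            v = -np.log10(sub[col].clip(lower=1e-300).to_numpy())
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = v[(v >= lo_fence) & (v <= hi_fence)]
            out_mask = v > hi_fence
            entry[effect] = {
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "whisker_low": float(inside.min()) if inside.size else float(q1),
                "whisker_high": float(inside.max()) if inside.size else float(q3),
                "outliers": sorted(sub["feature"].to_numpy()[out_mask].tolist()),
            }
        summary["sessions"][int(ses)] = entry
    return summary
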