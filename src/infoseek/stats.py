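"""Within-subject statistics: repeated-measures ANOVA with the
Greenhouse-Geisser correction and partial eta squared, paired t-tests
with Bonferroni correction, one-sample t-tests, and the group-level
preference-on-cost analysis.

The rm-ANOVA supports one or two within-subject factors on a complete,
balanced participant x condition table.  The Greenhouse-Geisser epsilon
for each effect is the standard sample estimator
``tr(V)^2 / (df * tr(V V))`` where ``V = C' S C`` for the effect's
orthonormal contrast matrix ``C`` and the sample covariance ``S`` of the
condition columns; corrected p-values use F with both degrees of freedom
multiplied by epsilon.  By default the correction is applied only when
epsilon is below 1 (i.e. when sphericity is violated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

_TINY_P = np.finfo(float).tiny


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    epsilon: float
    df_num_corr: float
    df_den_corr: float
    p_uncorrected: float
    p: float
    partial_eta_sq: float
    sphericity_corrected: bool

    def report(self) -> str:
        """Human-readable line in conventional reporting style."""
        d1, d2 = (
            (self.df_num_corr, self.df_den_corr)
            if self.sphericity_corrected
            else (self.df_num, self.df_den)
        )
        return (
            f"{self.effect}: F({d1:.2f}, {d2:.2f}) = {self.F:.2f}, "
            f"p = {self.p:.4g}, eta_p^2 = {self.partial_eta_sq:.2f}"
            + (f" (GG epsilon = {self.epsilon:.3f})" if self.sphericity_corrected else "")
        )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal matrix orthogonal to the unit vector."""
    # QR of the centring projector spans the contrast space
    basis = np.eye(k) - np.full((k, k), 1.0 / k)
    q, _ = np.linalg.qr(basis)
    return q[:, : k - 1]


def _gg_epsilon(cov: np.ndarray, contrasts: np.ndarray) -> float:
    v = contrasts.T @ cov @ contrasts
    df = contrasts.shape[1]
    denom = df * float(np.sum(v * v.T))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(v)) ** 2 / denom
    return float(np.clip(eps, 1.0 / df, 1.0))


def _pivot(
    data: pd.DataFrame, dv: str, within: Sequence[str], subject: str
) -> tuple[np.ndarray, list[tuple], list[str]]:
    wide = data.pivot_table(
        index=subject, columns=list(within), values=dv, aggfunc="mean",
        dropna=False,
    )
    wide = wide.sort_index(axis=1)
    if wide.isna().any().any():
        raise ValueError(
            "incomplete within-subject table: every participant needs every cell"
        )
    cols = list(wide.columns)
    return wide.to_numpy(float), cols, list(wide.index)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str] | str,
    subject: str = "participant",
    correction: str = "auto",
) -> list[AnovaResult]:
    """Repeated-measures ANOVA for one or two within-subject factors.

    Parameters
    ----------
    data
        Long-format table with one row per subject x cell (replicates are
        cell-averaged).
    correction
        ``"auto"`` (GG applied when epsilon < 1), ``"always"`` or
        ``"never"``.
    """
    if correction not in ("auto", "always", "never"):
        raise ValueError("correction must be 'auto', 'always' or 'never'")
    within = [within] if isinstance(within, str) else list(within)
    if len(within) not in (1, 2):
        raise ValueError("rm_anova supports 1 or 2 within-subject factors")
    y, cols, subjects = _pivot(data, dv, within, subject)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    cov = np.cov(y, rowvar=False)
    grand = y.mean()

    if len(within) == 1:
        a = y.shape[1]
        m_a = y.mean(axis=0)
        m_s = y.mean(axis=1)
        ss_a = n * np.sum((m_a - grand) ** 2)
        resid = y - m_a[None, :] - m_s[:, None] + grand
        ss_err = np.sum(resid**2)
        qa = _orthonormal_contrasts(a)
        effects = [
            (within[0], ss_a, a - 1, ss_err, (a - 1) * (n - 1), qa)
        ]
    else:
        la = sorted({c[0] for c in cols})
        lb = sorted({c[1] for c in cols})
        a, b = len(la), len(lb)
        cube = y.reshape(n, a, b)  # columns sorted lexicographically
        m_s = cube.mean(axis=(1, 2))
        m_a = cube.mean(axis=(0, 2))
        m_b = cube.mean(axis=(0, 1))
        m_ab = cube.mean(axis=0)
        m_sa = cube.mean(axis=2)
        m_sb = cube.mean(axis=1)
        ss_a = n * b * np.sum((m_a - grand) ** 2)
        ss_b = n * a * np.sum((m_b - grand) ** 2)
        ss_ab = n * np.sum(
            (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
        )
        ss_sa = b * np.sum(
            (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2
        )
        ss_sb = a * np.sum(
            (m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2
        )
        fitted = (
            m_sa[:, :, None] + m_sb[:, None, :] + m_ab[None, :, :]
            - m_s[:, None, None] - m_a[None, :, None] - m_b[None, None, :]
            + grand
        )
        ss_sab = np.sum((cube - fitted) ** 2)
        qa = _orthonormal_contrasts(a)
        qb = _orthonormal_contrasts(b)
        ones_a = np.full((a, 1), 1.0 / np.sqrt(a))
        ones_b = np.full((b, 1), 1.0 / np.sqrt(b))
        effects = [
            (within[0], ss_a, a - 1, ss_sa, (a - 1) * (n - 1), np.kron(qa, ones_b)),
            (within[1], ss_b, b - 1, ss_sb, (b - 1) * (n - 1), np.kron(ones_a, qb)),
            (
                f"{within[0]}:{within[1]}",
                ss_ab, (a - 1) * (b - 1),
                ss_sab, (a - 1) * (b - 1) * (n - 1),
                np.kron(qa, qb),
            ),
        ]

    results = []
    for name, ss_e, df1, ss_err, df2, contrasts in effects:
        ms_e = ss_e / df1
        ms_err = ss_err / df2 if df2 > 0 else np.nan
        f_val = float(ms_e / ms_err) if ms_err > 0 else 0.0
        eps = _gg_epsilon(cov, contrasts)
        p_unc = float(sps.f.sf(f_val, df1, df2))
        apply_gg = correction == "always" or (
            correction == "auto" and eps < 1.0 - 1e-12
        )
        p_corr = float(sps.f.sf(f_val, eps * df1, eps * df2)) if apply_gg else p_unc
        pes = float(ss_e / (ss_e + ss_err)) if (ss_e + ss_err) > 0 else 0.0
        results.append(
            AnovaResult(
                effect=name,
                F=f_val,
                df_num=float(df1),
                df_den=float(df2),
                epsilon=eps,
                df_num_corr=float(eps * df1),
                df_den_corr=float(eps * df2),
                p_uncorrected=p_unc,
                p=p_corr,
                partial_eta_sq=pes,
                sphericity_corrected=apply_gg,
            )
        )
    return results


def anova_to_frame(results: Sequence[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def paired_tests_bonferroni(
    data: pd.DataFrame,
    comparisons: Sequence[tuple[str, str]],
    dv: str = "mean_amplitude",
    condition: str = "condition",
    subject: str = "participant",
) -> pd.DataFrame:
    """Paired t-tests with Bonferroni-corrected p = min(1, m * p_raw)."""
    wide = data.pivot_table(index=subject, columns=condition, values=dv)
    if len(wide) < 2:
        raise ValueError("need at least 2 participants for paired tests")
    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        pair = wide[[a, b]].dropna()
        diff = (pair[a] - pair[b]).to_numpy(float)
        if np.ptp(diff) == 0.0:
            t, p = (
                (0.0, 1.0)
                if diff[0] == 0.0
                else (float(np.sign(diff[0]) * np.inf), _TINY_P)
            )
        else:
            t, p = sps.ttest_rel(pair[a], pair[b])
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "t": float(t),
                "df": len(pair) - 1,
                "p_raw": float(p),
                "p_bonferroni": min(1.0, m * float(p)),
            }
        )
    return pd.DataFrame(rows)


def one_sample_t(values, null_value: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t-test against ``null_value``.

    A zero-variance sample yields t = 0, p = 1 when the mean equals the
    null, and a signed infinite t with an underflow-safe p otherwise.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0.0:
        if x[0] == null_value:
            return 0.0, 1.0
        return float(np.sign(x[0] - null_value) * np.inf), _TINY_P
    t, p = sps.ttest_1samp(x, null_value)
    return float(t), float(p)


def preference_cost_analysis(summary: dict, correction: str = "auto") -> dict:
    """Group tests on the behavioural summary.

    Runs (a) a repeated-measures ANOVA of preference over cost levels,
    (b) a one-sample t-test of zero-cost preference against 0.5, (c) a
    one-sample t-test of preference at positive costs against 0, and (d)
    a one-sample t-test of per-participant cost slopes against 0.
    """
    pref = summary["preference"]
    if pref["cost"].nunique() < 2:
        raise ValueError("need at least 2 cost levels")
    anova = rm_anova(
        pref, dv="pr_informative", within="cost", subject="participant",
        correction=correction,
    )
    zero_cost = pref.loc[
        pref["cost"] == pref["cost"].min(), "pr_informative"
    ]
    t_free, p_free = one_sample_t(zero_cost, 0.5)
    costly = (
        pref[pref["cost"] > pref["cost"].min()]
        .groupby("participant")["pr_informative"]
        .mean()
    )
    t_cost, p_cost = one_sample_t(costly, 0.0)
    t_slope, p_slope = one_sample_t(summary["slopes"]["slope"], 0.0)
    return {
        "anova_cost": anova[0],
        "zero_cost_vs_half": {"t": t_free, "p": p_free},
        "costly_pref_vs_zero": {"t": t_cost, "p": p_cost},
        "slope_vs_zero": {"t": t_slope, "p": p_slope},
    }


def write_results_tsv(results: Sequence[AnovaResult], path) -> None:
    anova_to_frame(results).to_csv(path, sep="\t", index=False)


def format_report(results: Sequence[AnovaResult]) -> str:
    return "\n".join(r.report() for r in results)
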