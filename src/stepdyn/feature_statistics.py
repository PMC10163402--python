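"""Group-level statistics on the extracted response features.

Descriptives by message x day type, two-way repeated-measures ANOVA
(within-person factors: message type, day type) with a Mauchly gate,
Greenhouse-Geisser correction and generalized eta squared, Friedman tests
with Kendall W for non-normal features split by day type, and
Bonferroni-corrected pairwise post hocs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .arx import CHANNELS
from .response_analysis import FEATURE_NAMES

DAY_TYPES = ("weekday", "weekend")

TABLE_COLUMNS = ("participant", "message_type", "day_type", "feature", "value")


class StatisticsError(ValueError):
    pass


@dataclass
class AnovaEffect:
    F: float
    df1: float
    df2: float
    p: float
    eta2: float
    ss: float
    ss_error: float
    sphericity_corrected: bool = False


@dataclass
class AnovaResult:
    message: AnovaEffect
    day: AnovaEffect
    interaction: AnovaEffect
    n_subjects: int


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    kendall_w: float
    n_blocks: int


@dataclass
class PairwiseResult:
    level_a: str
    level_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    test: str  # "paired_t" | "wilcoxon" | "undefined"


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def complete_cases(table: pd.DataFrame, feature: str) -> np.ndarray:
    """Participants x message x day value cube, listwise-complete.

    Returns an array of shape ``(n, 3, 2)`` in :data:`CHANNELS` x
    :data:`DAY_TYPES` order; participants missing any of the 6 cells (or
    with a non-finite value) are dropped.
    """
    sub = table.loc[table["feature"] == feature]
    wide = sub.pivot_table(
        index="participant",
        columns=["message_type", "day_type"],
        values="value",
        aggfunc="mean",
    )
    cols = pd.MultiIndex.from_product([CHANNELS, DAY_TYPES])
    wide = wide.reindex(columns=cols)
    wide = wide.dropna()
    return wide.to_numpy().reshape(len(wide), len(CHANNELS), len(DAY_TYPES))


def describe_features(table: pd.DataFrame) -> pd.DataFrame:
    """Mean / SD / range per feature x message type x day type."""
    rows = []
    for (feature, msg, day), grp in table.groupby(
        ["feature", "message_type", "day_type"], sort=False
    ):
        vals = grp["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "feature": feature,
                "message_type": msg,
                "day_type": day,
                "n": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else math.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan,
                "min": float(np.min(vals)) if len(vals) else math.nan,
                "max": float(np.max(vals)) if len(vals) else math.nan,
            }
        )
    return pd.DataFrame(rows)


def check_normality(table: pd.DataFrame, feature: str, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk in each of the 6 cells; False if any cell fails.

    Constant (zero-variance) cells count as non-normal.
    """
    cube = complete_cases(table, feature)
    if cube.shape[0] < 3:
        raise StatisticsError("need >= 3 complete participants")
    for i in range(cube.shape[1]):
        for j in range(cube.shape[2]):
            vals = cube[:, i, j]
            if np.ptp(vals) == 0:
                return False
            if scipy.stats.shapiro(vals).pvalue < alpha:
                return False
    return True


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (Helmert, normalized)."""
    C = np.zeros((k, k - 1))
    for j in range(k - 1):
        C[: j + 1, j] = 1.0
        C[j + 1, j] = -(j + 1)
        C[:, j] /= np.linalg.norm(C[:, j])
    return C


def _gg_epsilon(D: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from transformed scores (n x q)."""
    S = np.cov(D, rowvar=False)
    S = np.atleast_2d(S)
    q = S.shape[0]
    tr = np.trace(S)
    denom = q * np.trace(S @ S)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(tr**2 / denom, 1.0 / q)))


def _mauchly_p(D: np.ndarray) -> float:
    """Mauchly's sphericity test on transformed scores (n x q)."""
    n, q = D.shape
    if q < 2:
        return 1.0
    S = np.cov(D, rowvar=False)
    eigvals = np.linalg.eigvalsh(S)
    if np.any(eigvals <= 0):
        return 0.0  # singular covariance: sphericity untestable, treat as violated
    W = np.prod(eigvals) / (np.mean(eigvals) ** q)
    dof = q * (q + 1) // 2 - 1
    f = 1.0 - (2 * q**2 + q + 2) / (6.0 * q * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    return float(scipy.stats.chi2.sf(chi2, dof))


def rm_anova_2way(
    table: pd.DataFrame,
    feature: str,
    correction: str = "auto",
    alpha_sphericity: float = 0.05,
) -> AnovaResult:
    """Two-way within-subject ANOVA (message x day) on one feature.

    Sums of squares come from the balanced cell-mean decomposition with a
    separate subject-by-effect error stratum per effect.  When Mauchly's
    test rejects (``correction="auto"``) — or always, with
    ``correction="always"`` — Greenhouse-Geisser-scaled (fractional)
    degrees of freedom are used for the message and interaction effects.
    Effect sizes are generalized eta squared.
    """
    if correction not in ("auto", "always", "never"):
        raise ValueError("correction must be auto|always|never")
    Y = complete_cases(table, feature)
    n, a, b = Y.shape
    if n < 2:
        raise StatisticsError("need >= 2 complete participants")

    gm = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)

    ss_subj = a * b * np.sum((m_s - gm) ** 2)
    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_err_a = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_err_b = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
    ss_total = np.sum((Y - gm) ** 2)
    ss_err_ab = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_err_a + ss_err_b)
    ss_err_ab = max(ss_err_ab, 0.0)

    ss_err_all = ss_err_a + ss_err_b + ss_err_ab

    def effect(ss_eff, ss_err, df1, df2, D_for_eps) -> AnovaEffect:
        if ss_err <= 0:
            raise StatisticsError("zero error variance: F undefined")
        F = (ss_eff / df1) / (ss_err / df2)
        corrected = False
        eps = 1.0
        if D_for_eps is not None and correction != "never":
            if correction == "always" or _mauchly_p(D_for_eps) < alpha_sphericity:
                eps = _gg_epsilon(D_for_eps)
                corrected = eps < 1.0
        p = float(scipy.stats.f.sf(F, df1 * eps, df2 * eps))
        eta2 = float(ss_eff / (ss_eff + ss_subj + ss_err_all))
        return AnovaEffect(
            F=float(F),
            df1=float(df1 * eps),
            df2=float(df2 * eps),
            p=p,
            eta2=eta2,
            ss=float(ss_eff),
            ss_error=float(ss_err),
            sphericity_corrected=corrected,
        )

    C_a = _orthonormal_contrasts(a)
    C_b = _orthonormal_contrasts(b)
    D_a = m_sa @ C_a
    D_ab = Y.reshape(n, a * b) @ np.kron(C_a, C_b)

    res_a = effect(ss_a, ss_err_a, a - 1, (a - 1) * (n - 1), D_a)
    res_b = effect(ss_b, ss_err_b, b - 1, (b - 1) * (n - 1), None)
    res_ab = effect(ss_ab, ss_err_ab, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), D_ab)
    return AnovaResult(message=res_a, day=res_b, interaction=res_ab, n_subjects=n)


# ---------------------------------------------------------------------------
# nonparametric route
# ---------------------------------------------------------------------------


def friedman_by_daytype(
    table: pd.DataFrame, feature: str, day_type: str
) -> FriedmanResult:
    """Friedman test over message types within one day type, plus Kendall W."""
    if day_type not in DAY_TYPES:
        raise ValueError(f"unknown day_type {day_type!r}")
    cube = complete_cases(table, feature)
    j = DAY_TYPES.index(day_type)
    blocks = cube[:, :, j]  # n x 3
    n, k = blocks.shape
    if n < 2:
        raise StatisticsError("need >= 2 participants for the Friedman test")
    if np.allclose(blocks, blocks[:, :1]):
        chi2, p = 0.0, 1.0  # identical treatments: midranks, no effect
    else:
        chi2, p = scipy.stats.friedmanchisquare(*(blocks[:, i] for i in range(k)))
    w = float(chi2) / (n * (k - 1))
    return FriedmanResult(chi2=float(chi2), df=k - 1, p=float(p), kendall_w=w, n_blocks=n)


# ---------------------------------------------------------------------------
# post hocs
# ---------------------------------------------------------------------------


def _paired_samples(
    table: pd.DataFrame, feature: str, effect: str, day_type: str | None
) -> tuple[list[str], np.ndarray]:
    cube = complete_cases(table, feature)
    if effect == "message":
        if day_type is None:
            data = cube.mean(axis=2)  # average over day types
        else:
            data = cube[:, :, DAY_TYPES.index(day_type)]
        return list(CHANNELS), data
    if effect == "day":
        return list(DAY_TYPES), cube.mean(axis=1)
    raise ValueError("effect must be 'message' or 'day'")


def pairwise_posthoc(
    table: pd.DataFrame,
    feature: str,
    effect: str,
    parametric: bool = True,
    day_type: str | None = None,
) -> list[PairwiseResult]:
    """Bonferroni-corrected paired tests for each level pair of ``effect``.

    Paired t tests, or Wilcoxon signed-rank when ``parametric=False``.
    Raw p values are multiplied by the number of comparisons (capped at 1).
    Zero-variance difference vectors are reported as undefined.
    """
    levels, data = _paired_samples(table, feature, effect, day_type)
    pairs = [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]
    m = len(pairs)
    results = []
    for i, j in pairs:
        diff = data[:, i] - data[:, j]
        if np.ptp(diff) == 0 and diff[0] == 0:
            results.append(
                PairwiseResult(levels[i], levels[j], math.nan, math.nan, math.nan, "undefined")
            )
            continue
        if parametric:
            stat, p = scipy.stats.ttest_rel(data[:, i], data[:, j])
            test = "paired_t"
        else:
            stat, p = scipy.stats.wilcoxon(data[:, i], data[:, j])
            test = "wilcoxon"
        results.append(
            PairwiseResult(
                levels[i], levels[j], float(stat), float(p), min(1.0, float(p) * m), test
            )
        )
    return results


# ---------------------------------------------------------------------------
# heterogeneity summary and orchestration
# ---------------------------------------------------------------------------


def heterogeneity_summary(
    table: pd.DataFrame, reference_difference: float = 250.0
) -> dict:
    """Per-participant best message type by steady state, per day type.

    Partitions participants exhaustively (argmax over the three types) and
    reports the fraction whose max-minus-min mean steady state exceeds the
    reference difference.
    """
    summary: dict = {}
    sub = table.loc[table["feature"] == "steady_state"]
    for day in DAY_TYPES:
        wide = sub.loc[sub["day_type"] == day].pivot_table(
            index="participant", columns="message_type", values="value", aggfunc="mean"
        )
        wide = wide.reindex(columns=CHANNELS).dropna()
        if wide.empty:
            continue
        best = wide.idxmax(axis=1)
        spread = wide.max(axis=1) - wide.min(axis=1)
        summary[day] = {
            "n": int(len(wide)),
            "best_fraction": {ch: float((best == ch).mean()) for ch in CHANNELS},
            "fraction_spread_over_reference": float(
                (spread > reference_difference).mean()
            ),
            "reference_difference": reference_difference,
        }
    return summary


def run_feature_statistics(
    table: pd.DataFrame,
    out_dir: Path | str | None = None,
    alpha: float = 0.05,
    correction: str = "auto",
) -> dict:
    """Full statistical analysis of a long-format feature table.

    Normality-gated routing: features passing Shapiro-Wilk in every cell go
    to the two-way RM-ANOVA; the rest to Friedman tests per day type.
    Significant main effects get Bonferroni pairwise post hocs.
    """
    descriptives = describe_features(table)
    results: dict = {"descriptives": descriptives, "anova": {}, "friedman": {}, "posthoc": {}}
    features = [f for f in FEATURE_NAMES if f in set(table["feature"])]
    for feature in features:
        try:
            normal = check_normality(table, feature, alpha=alpha)
        except StatisticsError:
            continue
        if normal:
            try:
                res = rm_anova_2way(table, feature, correction=correction)
            except StatisticsError:
                continue
            results["anova"][feature] = res
            posthocs = []
            if res.message.p < alpha:
                posthocs += pairwise_posthoc(table, feature, "message")
            if res.day.p < alpha:
                posthocs += pairwise_posthoc(table, feature, "day")
            if posthocs:
                results["posthoc"][feature] = posthocs
        else:
            for day in DAY_TYPES:
                try:
                    res = friedman_by_daytype(table, feature, day)
                except StatisticsError:
                    continue
                results["friedman"][(feature, day)] = res
                if res.p < alpha:
                    results["posthoc"][(feature, day)] = pairwise_posthoc(
                        table, feature, "message", parametric=False, day_type=day
                    )
    results["heterogeneity"] = heterogeneity_summary(table)
    if out_dir is not None:
        _write_outputs(results, Path(out_dir))
    return results


def _write_outputs(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    results["descriptives"].to_csv(out_dir / "table1.csv", index=False)

    rows = []
    for feature, res in results["anova"].items():
        for name, eff in (
            ("message", res.message),
            ("day", res.day),
            ("interaction", res.interaction),
        ):
            rows.append(
                {
                    "feature": feature,
                    "effect": name,
                    "test": "rm_anova",
                    "statistic": eff.F,
                    "df1": eff.df1,
                    "df2": eff.df2,
                    "p": eff.p,
                    "effect_size": eff.eta2,
                    "sphericity_corrected": eff.sphericity_corrected,
                }
            )
    for (feature, day), res in results["friedman"].items():
        rows.append(
            {
                "feature": feature,
                "effect": f"message_on_{day}",
                "test": "friedman",
                "statistic": res.chi2,
                "df1": res.df,
                "df2": math.nan,
                "p": res.p,
                "effect_size": res.kendall_w,
                "sphericity_corrected": False,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "table2.csv", index=False)

    ph_rows = []
    for key, items in results["posthoc"].items():
        label = key if isinstance(key, str) else f"{key[0]}:{key[1]}"
        for r in items:
            ph_rows.append(
                {
                    "feature": label,
                    "level_a": r.level_a,
                    "level_b": r.level_b,
                    "test": r.test,
                    "statistic": r.statistic,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                }
            )
    pd.DataFrame(ph_rows).to_csv(out_dir / "posthoc.csv", index=False)

    (out_dir / "heterogeneity.json").write_text(
        json.dumps(results["heterogeneity"], indent=2)
    )
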