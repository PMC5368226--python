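"""Analysis battery for rejection-rate data.

Mirrors the analyses usually run on yes/no grammaticality judgments from a
2 (order, between) x 2 (violation mode, between) x 4 (item type, within)
design: one-sample t tests of per-participant rejection rates against
chance (50%), paired contrasts between item types, a 2x2 mixed ANOVA
(within regularity x between order), and a trial-level logistic regression
on the feature-additive design of :mod:`aglearn.behavior`. Because the
original trial-level responses were never deposited, these procedures are
validated by parameter recovery on simulated data rather than against the
published tables.

Standard fits are delegated: scipy.stats for t tests, pingouin for the
mixed ANOVA, statsmodels for the logistic regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps

from aglearn.behavior import PREDICTORS, design_row


class DegenerateVarianceError(ValueError):
    """Raised when a test statistic is undefined because variance is zero."""


def _is_degenerate(x: np.ndarray) -> bool:
    """Numerically-zero spread (exactly constant up to float cancellation)."""
    sd = x.std(ddof=1)
    return sd <= 1e-10 * max(1.0, float(np.abs(x).max(initial=0.0)))


class SeparationError(RuntimeError):
    """Raised when a logistic fit is non-identified by perfect separation."""


@dataclass(frozen=True)
class SignificanceConfig:
    alpha: float = 0.05
    bonferroni_family: int = 4  # the four item types tested per condition
    chance_level: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.bonferroni_family < 1:
            raise ValueError("bonferroni_family must be >= 1")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_uncorrected: float
    p_adjusted: float
    effect_size: float
    effect_size_name: str
    direction: str  # above | below | none


@dataclass(frozen=True)
class CoefficientEstimate:
    name: str
    estimate: float
    se: float
    z: float
    p: float


def bonferroni_adjust(p_values, family_size: int):
    """min(1, p * family_size), elementwise."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    out = np.minimum(1.0, p * family_size)
    return float(out) if out.ndim == 0 else out


def one_sample_t_vs_chance(
    participant_rates, config: SignificanceConfig | None = None
) -> TestResult:
    """Classical one-sample t of per-participant rates against chance.

    Cohen's d = (mean - chance) / sd. Bonferroni uses the configured family.
    """
    config = config or SignificanceConfig()
    x = np.asarray(participant_rates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 participants")
    if _is_degenerate(x):
        raise DegenerateVarianceError("participant rates have zero variance")
    sd = x.std(ddof=1)
    res = sps.ttest_1samp(x, config.chance_level)
    diff = x.mean() - config.chance_level
    d = diff / sd
    direction = "above" if diff > 0 else ("below" if diff < 0 else "none")
    return TestResult(
        statistic=float(res.statistic),
        df=float(x.size - 1),
        p_uncorrected=float(res.pvalue),
        p_adjusted=float(bonferroni_adjust(res.pvalue, config.bonferroni_family)),
        effect_size=float(d),
        effect_size_name="cohen_d",
        direction=direction,
    )


def paired_contrast(
    rates_a, rates_b, config: SignificanceConfig | None = None
) -> TestResult:
    """Paired t test between two within-participant rate vectors.

    Effect size is Cohen's d corrected for the dependence between means:
    d_rm = (mean difference / sd of differences) * sqrt(2 (1 - r)), with r
    the A-B correlation across participants.
    """
    config = config or SignificanceConfig()
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 participants")
    diff = a - b
    if _is_degenerate(diff):
        raise DegenerateVarianceError("paired differences have zero variance")
    sd_diff = diff.std(ddof=1)
    res = sps.ttest_rel(a, b)
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    d = diff.mean() / sd_diff * math.sqrt(2.0 * (1.0 - r))
    direction = "above" if diff.mean() > 0 else ("below" if diff.mean() < 0 else "none")
    return TestResult(
        statistic=float(res.statistic),
        df=float(a.size - 1),
        p_uncorrected=float(res.pvalue),
        p_adjusted=float(bonferroni_adjust(res.pvalue, config.bonferroni_family)),
        effect_size=float(d),
        effect_size_name="cohen_d_rm",
        direction=direction,
    )


def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str = "rate",
    within: str = "regularity",
    between: str = "order",
    subject: str = "participant_id",
) -> dict[str, TestResult]:
    """2x2 mixed ANOVA (one within, one between factor), partial eta squared.

    Expects a long table with one row per participant x within-level and a
    balanced design. Returns TestResults keyed 'between', 'within',
    'interaction'.
    """
    for col in (dv, within, between, subject):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    counts = data.groupby([between, within], observed=True)[subject].nunique()
    if counts.nunique() != 1:
        raise ValueError("design must be balanced")
    if data.groupby(between, observed=True)[subject].nunique().min() < 2:
        raise ValueError("need at least 2 participants per between-level")

    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject
    )
    aov = aov.set_index("Source")
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    keymap = {"between": between, "within": within, "interaction": "Interaction"}
    out: dict[str, TestResult] = {}
    for key, source in keymap.items():
        row = aov.loc[source]
        f = float(row["F"])
        p = float(row[p_col])
        out[key] = TestResult(
            statistic=f,
            df=(float(row["DF1"]), float(row["DF2"])),
            p_uncorrected=p,
            p_adjusted=p,
            effect_size=float(row["np2"]),
            effect_size_name="partial_eta_sq",
            direction="none",
        )
    return out


def _separating_column(X: pd.DataFrame, y: np.ndarray) -> str | None:
    """Heuristically name a covariate producing (quasi-)separation."""
    if len(np.unique(y)) < 2:
        return "response"
    for col in X.columns:
        if col == "intercept":
            continue
        v = X[col].to_numpy()
        for level in np.unique(v):
            mask = v == level
            if mask.any() and (~mask).any() and len(np.unique(y[mask])) == 1:
                return col
    return None


def fit_rejection_logistic(
    trials: pd.DataFrame, predictors: tuple[str, ...] = PREDICTORS
) -> list[CoefficientEstimate]:
    """Maximum-likelihood logistic regression of trial-level rejections.

    Uses the treatment-coded feature-additive design (order, violation mode,
    the two violation indicators and their interactions) and Wald z tests.
    Raises :class:`SeparationError` naming the offending covariate when the
    likelihood is unbounded.
    """
    needed = {"order", "violation_mode", "item_class", "rejected"}
    missing = needed - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns {sorted(missing)}")

    X_full = np.vstack(
        [
            design_row(o, m, c)
            for o, m, c in zip(
                trials["order"], trials["violation_mode"], trials["item_class"]
            )
        ]
    )
    X = pd.DataFrame(X_full, columns=PREDICTORS)[list(predictors)]
    y = trials["rejected"].to_numpy(dtype=float)

    culprit = _separating_column(X, y)
    if culprit is not None:
        raise SeparationError(
            f"perfect separation: outcome is constant within a level of {culprit!r}"
        )
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed to identify: {exc}") from exc
    return [
        CoefficientEstimate(
            name=name,
            estimate=float(fit.params.iloc[i]),
            se=float(fit.bse.iloc[i]),
            z=float(fit.tvalues.iloc[i]),
            p=float(fit.pvalues.iloc[i]),
        )
        for i, name in enumerate(predictors)
    ]


def rates_vs_chance_table(
    per_participant: pd.DataFrame,
    config: SignificanceConfig | None = None,
) -> pd.DataFrame:
    """One-sample tests vs chance for every design cell, as a tidy table."""
    config = config or SignificanceConfig()
    rows = []
    for (order, mode, cls), grp in per_participant.groupby(
        ["order", "violation_mode", "item_class"], observed=True
    ):
        try:
            res = one_sample_t_vs_chance(grp["rejected"].to_numpy(), config)
        except DegenerateVarianceError:
            continue
        rows.append(
            {
                "order": order,
                "violation_mode": mode,
                "item_class": cls,
                "t": res.statistic,
                "df": res.df,
                "p_uncorrected": res.p_uncorrected,
                "p_bonferroni": res.p_adjusted,
                "cohen_d": res.effect_size,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(rows)
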