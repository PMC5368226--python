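"""Feature-additive logistic simulator of yes/no rejection responses.

The generative model treats the two regularities as independent features of
a string: the log-odds of rejecting a test item is a linear combination of
indicators for the grammar order (repetition-di vs di-repetition), the
violation mode (position vs presence), whether the repetition regularity is
violated, whether the /di/ regularity is violated, and four interactions
(order x each violation, mode x /di/ violation, and the two violations with
each other). The default coefficients are the published trial-level
estimates from the combined analysis of both experiments, so the simulator
reproduces the headline graded pattern: double violations are rejected more
than single violations, which are rejected more than grammatical items, in
every cell. An optional Normal participant random intercept adds
between-subject variability (default sd 0).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.special import expit

ORDERS = ("di_repetition", "repetition_di")      # reference level first
VIOLATION_MODES = ("presence", "position")       # reference level first
ITEM_CLASSES = ("grammatical", "rep_violation", "di_violation", "double_violation")

#: design-matrix column names, in model order (intercept first)
PREDICTORS = (
    "intercept",
    "order_repetition_di",
    "violation_type_position",
    "violation_of_repetition",
    "violation_of_di",
    "order_x_violation_of_repetition",
    "order_x_violation_of_di",
    "violation_type_x_violation_of_di",
    "violation_of_repetition_x_violation_of_di",
)


@dataclass(frozen=True)
class ResponseModelSpec:
    """Fixed-effect coefficients on the log-odds-of-rejection scale.

    Defaults are the published combined-analysis estimates; set
    ``participant_intercept_sd`` > 0 to add participant heterogeneity.
    """

    intercept: float = -1.67
    order_repetition_di: float = -0.54
    violation_type_position: float = -0.11
    violation_of_repetition: float = 2.03
    violation_of_di: float = 2.19
    order_x_violation_of_repetition: float = -0.62
    order_x_violation_of_di: float = 0.96
    violation_type_x_violation_of_di: float = 0.55
    violation_of_repetition_x_violation_of_di: float = -0.90
    participant_intercept_sd: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"coefficient {f.name} must be finite")
        if self.participant_intercept_sd < 0:
            raise ValueError("participant_intercept_sd must be >= 0")

    def coefficients(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PREDICTORS])


def null_spec(participant_intercept_sd: float = 0.0) -> ResponseModelSpec:
    """All fixed effects zero (rejection probability 0.5 everywhere)."""
    return ResponseModelSpec(
        **{name: 0.0 for name in PREDICTORS},
        participant_intercept_sd=participant_intercept_sd,
    )


@dataclass(frozen=True)
class ExperimentDesign:
    """Balanced 2 (order) x 2 (violation mode) between-subject design.

    Each participant contributes ``trials_per_class`` trials for each of the
    four item classes (9 x 4 = 36 by default, matching the test phase).
    """

    participants_per_cell: int = 20
    trials_per_class: int = 9
    orders: tuple[str, ...] = ORDERS
    violation_modes: tuple[str, ...] = VIOLATION_MODES

    def __post_init__(self) -> None:
        if self.participants_per_cell < 1 or self.trials_per_class < 1:
            raise ValueError("design counts must be >= 1")
        for o in self.orders:
            if o not in ORDERS:
                raise ValueError(f"unknown order {o!r}")
        for m in self.violation_modes:
            if m not in VIOLATION_MODES:
                raise ValueError(f"unknown violation mode {m!r}")


def design_row(order: str, violation_mode: str, item_class: str) -> np.ndarray:
    """Treatment-coded predictor vector (intercept included).

    Reference levels: order = di_repetition, violation mode = presence, no
    violations; so the reference cell is a grammatical item heard after
    /di/-initial familiarization in the presence-violation experiment.
    """
    if order not in ORDERS:
        raise ValueError(f"unknown order {order!r}")
    if violation_mode not in VIOLATION_MODES:
        raise ValueError(f"unknown violation mode {violation_mode!r}")
    if item_class not in ITEM_CLASSES:
        raise ValueError(f"unknown item class {item_class!r}")
    o = 1.0 if order == "repetition_di" else 0.0
    m = 1.0 if violation_mode == "position" else 0.0
    vr = 1.0 if item_class in ("rep_violation", "double_violation") else 0.0
    vd = 1.0 if item_class in ("di_violation", "double_violation") else 0.0
    return np.array([1.0, o, m, vr, vd, o * vr, o * vd, m * vd, vr * vd])


def cell_probability(
    spec: ResponseModelSpec, order: str, violation_mode: str, item_class: str
) -> float:
    """Closed-form rejection probability of a design cell (sd ignored)."""
    return float(expit(design_row(order, violation_mode, item_class) @ spec.coefficients()))


def simulate_trials(
    spec: ResponseModelSpec | None = None,
    design: ExperimentDesign | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the full trial table.

    Per participant a random intercept ~ Normal(0, sd) is drawn, then each
    trial's rejection ~ Bernoulli(logistic(linear predictor + intercept)).
    Returns a tidy DataFrame with columns participant_id, order,
    violation_mode, item_class, rejected. Deterministic given ``seed``.
    """
    spec = spec or ResponseModelSpec()
    design = design or ExperimentDesign()
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    pid = 0
    for order in design.orders:
        for mode in design.violation_modes:
            for _ in range(design.participants_per_cell):
                b = rng.normal(0.0, spec.participant_intercept_sd) \
                    if spec.participant_intercept_sd > 0 else 0.0
                for item_class in ITEM_CLASSES:
                    eta = design_row(order, mode, item_class) @ spec.coefficients() + b
                    p = expit(eta)
                    rejected = rng.random(design.trials_per_class) < p
                    for r in rejected:
                        rows.append(
                            {
                                "participant_id": f"p{pid:04d}",
                                "order": order,
                                "violation_mode": mode,
                                "item_class": item_class,
                                "rejected": int(r),
                            }
                        )
                pid += 1
    return pd.DataFrame(rows)


def participant_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean rejection rate per design cell (long format)."""
    if trials.empty:
        raise ValueError("no trials to aggregate")
    return (
        trials.groupby(
            ["order", "violation_mode", "item_class", "participant_id"],
            observed=True,
        )["rejected"]
        .mean()
        .reset_index()
    )


def summarize_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean rejection rate with between-subject standard error.

    Aggregates to participant-level means first; SE is the standard
    deviation of participant means divided by sqrt(n participants), reported
    as NaN when a cell has a single participant.
    """
    per_participant = participant_means(trials)

    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    out = (
        per_participant.groupby(["order", "violation_mode", "item_class"], observed=True)["rejected"]
        .agg(mean_rejection="mean", se_between=_se, n_participants="count")
        .reset_index()
    )
    return out
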