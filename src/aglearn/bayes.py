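"""Size-principle Bayesian rule learning over edge regularities.

The learner entertains four rules about six-syllable strings built from an
inventory of ``S`` syllables:

- ``default``: true of every string (extension size S^6);
- ``repetition_edge``: an immediate syllable repetition at the grammatical
  edge pair (S^5 strings);
- ``affix_edge``: the constant affix syllable /di/ at the opposite edge
  (S^5 strings);
- ``conjunction``: both regularities at once (S^4 strings).

Under strong sampling the likelihood of a consistent example is 1/|h| (the
size principle), so after |T| training items the posterior weight of rule h
is prior(h) * |h|^-|T|, normalized. The posterior predictive of a test item
sums w(h)/|h| over the rules consistent with it. With S = 97 and |T| = 36
the conjunction rule takes essentially all the mass, and the predictive for
grammatical items exceeds that for single-violation items by a factor of
S^37, about 3e73 — hence Luce choice picks the grammatical item with
probability 1. Dropping the conjunction rule leaves the two single rules
with weight ~1/2 each, giving the graded 2/(2+N) choice pattern.

All probability arithmetic is done in natural-log space: the linear-scale
predictives underflow doubles (S^-216 at the default configuration).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

HYPOTHESES = ("default", "repetition_edge", "affix_edge", "conjunction")

#: extension size of each rule is S ** exponent
EXTENSION_EXPONENT = {
    "default": 6,
    "repetition_edge": 5,
    "affix_edge": 5,
    "conjunction": 4,
}

ITEM_CLASSES = (
    "grammatical",
    "single_violation_rep",
    "single_violation_di",
    "double_violation",
)

#: which rules each test-item class satisfies. A class violating the
#: repetition regularity still satisfies the affix rule and vice versa; the
#: conjunction holds only for fully grammatical items; the default always.
CONSISTENCY: dict[str, frozenset[str]] = {
    "grammatical": frozenset(HYPOTHESES),
    "single_violation_rep": frozenset({"default", "affix_edge"}),
    "single_violation_di": frozenset({"default", "repetition_edge"}),
    "double_violation": frozenset({"default"}),
}


@dataclass(frozen=True)
class BayesConfig:
    """Model configuration.

    S: syllable inventory size (97 = four disjoint 24-syllable category
    pools plus /di/). T_size: number of familiarization items |T| (all of
    which are consistent with every rule by design). The prior is uniform
    over the included hypotheses unless given explicitly.
    """

    S: int = 97
    T_size: int = 36
    include_conjunction: bool = True
    prior: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("S must be >= 2")
        if self.T_size < 0:
            raise ValueError("T_size must be >= 0")
        if self.prior is not None:
            if len(self.prior) != len(self.hypotheses):
                raise ValueError("prior length must match the hypothesis set")
            if any(p < 0 for p in self.prior) or not math.isclose(
                sum(self.prior), 1.0, rel_tol=0, abs_tol=1e-12
            ):
                raise ValueError("prior must be a probability vector")

    @property
    def hypotheses(self) -> tuple[str, ...]:
        if self.include_conjunction:
            return HYPOTHESES
        return tuple(h for h in HYPOTHESES if h != "conjunction")

    def log_prior(self) -> dict[str, float]:
        hyps = self.hypotheses
        if self.prior is None:
            return {h: -math.log(len(hyps)) for h in hyps}
        return {h: (math.log(p) if p > 0 else -math.inf)
                for h, p in zip(hyps, self.prior)}


def log_extension_size(hypothesis: str, S: int) -> float:
    """Natural log of the rule's extension size, exponent * ln S."""
    if S < 2:
        raise ValueError("S must be >= 2")
    if hypothesis not in EXTENSION_EXPONENT:
        raise KeyError(f"unknown hypothesis {hypothesis!r}")
    return EXTENSION_EXPONENT[hypothesis] * math.log(S)


@dataclass(frozen=True)
class PosteriorState:
    """Normalized log posterior weights over the hypothesis set."""

    log_weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.log_weights:
            raise ValueError("empty hypothesis set")

    def weight(self, hypothesis: str) -> float:
        return math.exp(self.log_weights[hypothesis])


def posterior_over_hypotheses(config: BayesConfig) -> PosteriorState:
    """Posterior after |T| consistent training items.

    log w(h) = log prior(h) - |T| * log|h|, normalized by log-sum-exp.
    """
    log_prior = config.log_prior()
    raw = {
        h: lp - config.T_size * log_extension_size(h, config.S)
        for h, lp in log_prior.items()
    }
    norm = logsumexp(list(raw.values()))
    return PosteriorState(log_weights={h: v - norm for h, v in raw.items()})


def predictive_log_prob(
    item_class: str, state: PosteriorState, config: BayesConfig
) -> float:
    """Log posterior predictive of one test item of the given class.

    log p(t|T) = logsumexp over rules consistent with t of
    (log w(h) - log|h|).
    """
    if item_class not in CONSISTENCY:
        raise KeyError(f"unknown item class {item_class!r}")
    terms = [
        state.log_weights[h] - log_extension_size(h, config.S)
        for h in state.log_weights
        if h in CONSISTENCY[item_class]
    ]
    return float(logsumexp(terms))


def surprisal(item_class: str, state: PosteriorState, config: BayesConfig) -> float:
    """Surprisal in nats: negative log posterior predictive."""
    return -predictive_log_prob(item_class, state, config)


@dataclass(frozen=True)
class PredictiveResult:
    """Per-class log predictives and surprisals for one model variant."""

    config: BayesConfig
    log_predictive: dict[str, float]

    @property
    def surprisal(self) -> dict[str, float]:
        return {c: -lp for c, lp in self.log_predictive.items()}


def predict_all(config: BayesConfig) -> PredictiveResult:
    state = posterior_over_hypotheses(config)
    return PredictiveResult(
        config=config,
        log_predictive={
            c: predictive_log_prob(c, state, config) for c in ITEM_CLASSES
        },
    )


def luce_choice(
    choice_set: tuple[str, ...] | list[str], predictive: PredictiveResult
) -> np.ndarray:
    """Luce-choice probabilities over the alternatives' predictives.

    Softmax of the log predictives: p_i = exp(logp_i - logsumexp(logp)).
    """
    if len(choice_set) == 0:
        raise ValueError("choice set must be non-empty")
    logp = np.array([predictive.log_predictive[c] for c in choice_set])
    return np.exp(logp - logsumexp(logp))


def posterior_ratio_log10(
    class_a: str, class_b: str, config: BayesConfig
) -> float:
    """log10 of predictive(class_a) / predictive(class_b).

    Reported in log10 because the linear-scale ratio overflows for the
    default configuration (S^37 ~ 3e73 between grammatical and
    single-violation items).
    """
    pred = predict_all(config)
    return (pred.log_predictive[class_a] - pred.log_predictive[class_b]) / math.log(10)


# --------------------------------------------------------------------------
# Exhaustive enumeration oracle
# --------------------------------------------------------------------------

# representative test string per item class for a small inventory, with the
# affix symbol 0 at slot 1 and the repetition pair at slots 5-6 (di_first
# geometry; the model is symmetric in the two orders). Symbols: 0 = /di/;
# the strings below only use {0, 1} so they exist for every S >= 2.
_REPRESENTATIVES = {
    "grammatical": (0, 1, 1, 1, 1, 1),
    "single_violation_rep": (0, 1, 1, 1, 0, 1),
    "single_violation_di": (1, 0, 1, 1, 0, 0),
    "double_violation": (1, 0, 1, 1, 0, 1),
}


def _holds(hypothesis: str, string: tuple[int, ...]) -> bool:
    if hypothesis == "default":
        return True
    if hypothesis == "repetition_edge":
        return string[4] == string[5]
    if hypothesis == "affix_edge":
        return string[0] == 0
    if hypothesis == "conjunction":
        return string[4] == string[5] and string[0] == 0
    raise KeyError(hypothesis)


def enumerate_oracle(S_small: int, config: BayesConfig | None = None) -> PredictiveResult:
    """Brute-force predictive by materializing all S^6 strings.

    Extension sizes are counted by scanning strings, posterior weights and
    predictives are computed by explicit summation, and a representative
    concrete string of each item class is evaluated by membership tests.
    Exists purely to validate the closed-form path; capped at S <= 5.
    """
    if S_small < 2 or S_small > 5:
        raise ValueError("enumeration oracle requires 2 <= S <= 5")
    if config is None:
        config = BayesConfig(S=S_small)
    if config.S != S_small:
        raise ValueError("config.S must equal S_small")

    strings = list(itertools.product(range(S_small), repeat=6))
    sizes = {
        h: sum(1 for s in strings if _holds(h, s)) for h in config.hypotheses
    }
    log_prior = config.log_prior()
    raw = {h: log_prior[h] - config.T_size * math.log(sizes[h]) for h in sizes}
    norm = logsumexp(list(raw.values()))
    log_w = {h: v - norm for h, v in raw.items()}

    log_predictive = {}
    for item_class in ITEM_CLASSES:
        t = _REPRESENTATIVES[item_class]
        terms = [log_w[h] - math.log(sizes[h]) for h in sizes if _holds(h, t)]
        log_predictive[item_class] = float(logsumexp(terms))
    return PredictiveResult(config=config, log_predictive=log_predictive)


def predictions_as_dict(pred: PredictiveResult, choice_sets: dict[str, list[str]] | None = None) -> dict:
    """JSON-serializable summary of a model variant's predictions."""
    if choice_sets is None:
        choice_sets = {
            "three_way": ["grammatical", "single_violation_rep", "double_violation"],
            "four_way": list(ITEM_CLASSES),
        }
    out = {
        "config": {
            "S": pred.config.S,
            "T_size": pred.config.T_size,
            "include_conjunction": pred.config.include_conjunction,
        },
        "log_predictive": pred.log_predictive,
        "surprisal": pred.surprisal,
        "choice_probabilities": {
            name: dict(zip(cs, luce_choice(cs, pred).tolist()))
            for name, cs in choice_sets.items()
        },
    }
    return out
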