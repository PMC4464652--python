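"""Verbalization experiments.

Each condition prescribes, per test item, which verbal-layer units receive an
external input of 1.0 (soft-clamped) for 10 cycles before the retinotopic
input arrives, and whether that input is maintained or removed during the
10-cycle recognition phase that follows:

* control — no verbalization; a plain recognition trial,
* similar distractors — the item's own (consistent) labels, maintained:
  descriptions plausible for targets and distractors alike,
* dissimilar distractors — old items get consistent labels, new items the
  within-pair-opposite (inconsistent) labels, maintained,
* irrelevant face — inconsistent labels for every item, removed at
  retinotopic onset (the describer knows they are unrelated to the probe),
* graded description accuracy — exactly k of the 3 features receive their
  correct label (the rest flipped within their pair), k in {0..3}, with the
  identity of the correct features drawn per item from a logged seed.

Old/new accuracy in every condition is judged with the decision criterion
frozen on the control condition of the same model instance, and conditions
are compared to control with a paired t-test across model instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import (
    DecisionCriterion,
    PolarityDistribution,
    judge_old_new,
    measure_item_polarity,
    select_criterion,
)
from .network import ClampSpec, NetworkParams, Phase, TrialSpec, WeightSet
from .stimuli import StimulusSet

__all__ = [
    "ConditionSpec",
    "ConditionResult",
    "LineupResult",
    "CONDITIONS",
    "selected_verbal_units",
    "validate_selection",
    "condition_trial",
    "measure_condition",
    "run_condition",
    "run_graded_distributions",
    "accuracy_from_distributions",
    "paired_t_vs_control",
    "one_sample_t_vs_chance",
    "single_trial_lineup",
    "run_experiment_suite",
    "SuiteConfig",
    "SuiteResult",
]

logger = logging.getLogger(__name__)

VERBAL_RULES = ("none", "consistent", "inconsistent", 0, 1, 2, 3)


@dataclass(frozen=True)
class ConditionSpec:
    """A verbalization condition.

    ``old_rule``/``new_rule`` select the externally activated verbal units
    for trained and untrained probes ("none", "consistent", "inconsistent",
    or an integer k = number of correctly described features);
    ``maintain`` keeps the external verbal input on during recognition.
    """

    name: str
    old_rule: object = "none"
    new_rule: object = "none"
    maintain: bool = True

    def __post_init__(self):
        for rule in (self.old_rule, self.new_rule):
            if rule not in VERBAL_RULES:
                raise ValueError(f"unknown verbal selection rule {rule!r}")


#: the named conditions of the main simulations
CONDITIONS = {
    "control": ConditionSpec("control", "none", "none", maintain=False),
    "similar": ConditionSpec("similar", "consistent", "consistent", maintain=True),
    "dissimilar": ConditionSpec("dissimilar", "consistent", "inconsistent", maintain=True),
    "irrelevant": ConditionSpec("irrelevant", "inconsistent", "inconsistent", maintain=False),
}


def validate_selection(units: np.ndarray) -> np.ndarray:
    """Check a verbal unit selection: exactly one unit per feature pair."""
    units = np.asarray(units, dtype=int)
    for f in range(3):
        n_in_pair = np.isin(units, [2 * f, 2 * f + 1]).sum()
        if n_in_pair != 1:
            raise ValueError(
                f"selection {units.tolist()} has {n_in_pair} units in feature pair {f}; expected 1"
            )
    return units


def selected_verbal_units(verbal: np.ndarray, rule, rng: np.random.Generator | None = None):
    """Externally activated verbal units for one item under a selection rule.

    Returns an index array of 3 units (one per feature pair), or None when
    the rule is "none".  For integer k, which k features are described
    correctly is sampled from ``rng``.
    """
    own = np.flatnonzero(np.asarray(verbal) > 0)
    if rule == "none":
        return None
    if rule == "consistent":
        return validate_selection(own)
    if rule == "inconsistent":
        return validate_selection(np.array([u + 1 if u % 2 == 0 else u - 1 for u in own]))
    k = int(rule)
    if rng is None:
        raise ValueError("graded selection requires a random generator")
    correct_features = rng.choice(3, size=k, replace=False)
    units = []
    for f, u in enumerate(own):
        if f in correct_features:
            units.append(u)
        else:
            units.append(u + 1 if u % 2 == 0 else u - 1)
    return validate_selection(np.array(units))


def condition_trial(
    item_index: int,
    units: np.ndarray | None,
    maintain: bool,
    stimuli: StimulusSet,
    params: NetworkParams,
) -> TrialSpec:
    """Recognition trial, optionally preceded by a verbalization phase.

    With ``units`` set, the selected verbal units are soft-clamped to 1.0
    for one full phase (no retinotopic input), then the retinotopic input is
    hard-clamped for a second phase with the verbal input maintained or
    removed.  Early stopping is disabled: polarity is read on the 10th cycle
    after retinotopic onset.
    """
    cycles = params.cycles_per_phase
    retino_clamp = ClampSpec("retinotopic", "hard", stimuli.retinotopic[item_index])
    if units is None:
        phases = [Phase(cycles, clamps=[retino_clamp], early_stop=False)]
        return TrialSpec("visual_recognition", phases, item_index=item_index)
    ext = np.zeros(params.n_verbal)
    mask = np.zeros(params.n_verbal, dtype=bool)
    ext[units] = 1.0
    mask[units] = True
    verbal_clamp = ClampSpec("verbal", "soft", ext, unit_mask=mask)
    recog_clamps = [retino_clamp] + ([verbal_clamp] if maintain else [])
    phases = [
        Phase(cycles, clamps=[verbal_clamp], early_stop=False),
        Phase(cycles, clamps=recog_clamps, early_stop=False),
    ]
    return TrialSpec("recognition_after_verbalization", phases, item_index=item_index)


def measure_condition(
    weights: WeightSet,
    stimuli: StimulusSet,
    spec: ConditionSpec,
    model_id: int,
    params: NetworkParams | None = None,
    seed: int = 0,
) -> PolarityDistribution:
    """Polarity of every item of the set under one condition, one model."""
    if params is None:
        params = weights.params
    rng = np.random.default_rng(np.random.SeedSequence([seed, model_id]))
    samples = []
    for i in range(stimuli.n_items):
        old = bool(stimuli.trained_mask[i])
        rule = spec.old_rule if old else spec.new_rule
        units = selected_verbal_units(stimuli.verbal[i], rule, rng)
        trial = condition_trial(i, units, spec.maintain, stimuli, params)
        samples.append(
            measure_item_polarity(weights, trial, stimuli.specs[i].item_id, old, params)
        )
    return PolarityDistribution(condition=spec.name, model_id=model_id, samples=samples)


@dataclass
class ConditionResult:
    """Per-model and aggregate old/new performance in one condition."""

    name: str
    hit_rates: np.ndarray
    cr_rates: np.ndarray
    accuracies: np.ndarray
    distributions: list[PolarityDistribution]
    t_vs_control: float | None = None
    df: int | None = None
    p_vs_control: float | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def se_accuracy(self) -> float:
        n = self.accuracies.size
        return float(np.std(self.accuracies, ddof=1) / np.sqrt(n)) if n > 1 else 0.0


def run_condition(
    spec: ConditionSpec,
    models: list[WeightSet],
    stimuli: StimulusSet,
    criteria: list[DecisionCriterion],
    params: NetworkParams | None = None,
    seed: int = 0,
) -> ConditionResult:
    """Measure one condition on every model and judge with frozen criteria."""
    hits, crs, accs, dists = [], [], [], []
    for m, (weights, criterion) in enumerate(zip(models, criteria)):
        dist = measure_condition(weights, stimuli, spec, m, params, seed=seed)
        res = judge_old_new(dist, criterion)
        hits.append(res.hit_rate)
        crs.append(res.correct_rejection_rate)
        accs.append(res.accuracy)
        dists.append(dist)
    return ConditionResult(
        name=spec.name,
        hit_rates=np.array(hits),
        cr_rates=np.array(crs),
        accuracies=np.array(accs),
        distributions=dists,
    )


def run_graded_distributions(
    models: list[WeightSet],
    stimuli: StimulusSet,
    params: NetworkParams | None = None,
    seed: int = 0,
) -> dict[int, list[PolarityDistribution]]:
    """Polarity distributions for every description-accuracy level k in 0..3.

    Each level applies the k-correct selection (maintained during
    recognition) to all 64 items of every model; the distributions shift
    leftward (lower polarity) as k decreases.
    """
    out: dict[int, list[PolarityDistribution]] = {}
    for k in range(4):
        spec = ConditionSpec(f"graded_k{k}", k, k, maintain=True)
        out[k] = [
            measure_condition(w, stimuli, spec, m, params, seed=seed + 101 * k)
            for m, w in enumerate(models)
        ]
    return out


def accuracy_from_distributions(
    old_dists: list[PolarityDistribution],
    new_dists: list[PolarityDistribution],
    criteria: list[DecisionCriterion],
    name: str,
) -> ConditionResult:
    """Old/new accuracy pairing old-item and new-item distributions.

    Used for the graded conditions, where the target and the distractors may
    be described with different accuracy (e.g. old items at k=2 against new
    items at k=1).
    """
    hits, crs, accs = [], [], []
    for od, nd, crit in zip(old_dists, new_dists, criteria):
        hit = float(np.mean(od.old_values > crit.threshold))
        cr = float(np.mean(nd.new_values <= crit.threshold))
        hits.append(hit)
        crs.append(cr)
        accs.append(0.5 * (hit + cr))
    return ConditionResult(
        name=name,
        hit_rates=np.array(hits),
        cr_rates=np.array(crs),
        accuracies=np.array(accs),
        distributions=list(old_dists) + list(new_dists),
    )


def paired_t_vs_control(condition: ConditionResult, control: ConditionResult):
    """Two-sided paired t on per-model accuracies (control minus condition).

    Positive t means the condition reduced accuracy.  With zero variance of
    the differences, t is reported as signed infinity (p -> 0) or 0 (p = 1)
    and the degenerate path is logged.  Returns ``(t, df, p)``.
    """
    a = np.asarray(control.accuracies, dtype=np.float64)
    b = np.asarray(condition.accuracies, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t requires matched per-model accuracies, n >= 2")
    diff = a - b
    df = diff.size - 1
    if np.std(diff, ddof=1) == 0:
        logger.info("zero-variance differences in paired t for %s", condition.name)
        if diff.mean() == 0:
            return 0.0, df, 1.0
        return float(np.sign(diff.mean()) * np.inf), df, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p)


def one_sample_t_vs_chance(condition: ConditionResult, chance: float = 0.5):
    """Two-sided one-sample t of per-model accuracies against chance.

    Alternative reading of the cross-model statistics (the paired contrast
    against control is the primary one).  Returns ``(t, df, p)``.
    """
    a = np.asarray(condition.accuracies, dtype=np.float64)
    if a.size < 2:
        raise ValueError("one-sample t requires at least 2 model instances")
    t, p = stats.ttest_1samp(a, chance)
    return float(t), a.size - 1, float(p)


@dataclass
class LineupResult:
    """Single-trial N+1-alternative lineup outcome."""

    n_distractors: int
    repetitions: int
    proportion_correct: float
    mc_se: float
    n_ties: int
    outcomes: np.ndarray


def single_trial_lineup(
    old_values: np.ndarray,
    new_values: np.ndarray,
    n_distractors: int,
    repetitions: int,
    seed: int,
) -> LineupResult:
    """Monte-Carlo single-trial lineup from per-item polarity samples.

    Each repetition draws one old item and ``n_distractors`` new items
    (without replacement) and succeeds iff the old item's polarity is
    strictly maximal; ties count as failures and are tallied.
    """
    old_values = np.asarray(old_values, dtype=np.float64)
    new_values = np.asarray(new_values, dtype=np.float64)
    if n_distractors > new_values.size:
        raise ValueError(
            f"n_distractors={n_distractors} exceeds the {new_values.size} available new items"
        )
    rng = np.random.default_rng(seed)
    outcomes = np.zeros(repetitions, dtype=bool)
    n_ties = 0
    for r in range(repetitions):
        target = old_values[rng.integers(old_values.size)]
        foils = new_values[rng.choice(new_values.size, size=n_distractors, replace=False)]
        top = foils.max() if n_distractors else -np.inf
        if target > top:
            outcomes[r] = True
        elif target == top:
            n_ties += 1
    p = float(outcomes.mean())
    if n_ties:
        logger.info("%d tie(s) in %d lineup repetitions (scored as failures)", n_ties, repetitions)
    return LineupResult(
        n_distractors=n_distractors,
        repetitions=repetitions,
        proportion_correct=p,
        mc_se=float(np.sqrt(p * (1 - p) / repetitions)),
        n_ties=n_ties,
        outcomes=outcomes,
    )


# ---------------------------------------------------------------------------
# full suite
# ---------------------------------------------------------------------------

@dataclass
class SuiteConfig:
    """Everything needed to reproduce a full experiment run."""

    stimulus_seed: int = 1
    n_models: int = 5
    profile: str = "reduced"
    smoothing_sd: float = 0.2
    condition_seed: int = 7
    lineup_distractors: int = 7
    lineup_repetitions: int = 2000


@dataclass
class SuiteResult:
    config: SuiteConfig
    summary: pd.DataFrame
    conditions: dict
    graded: dict
    criteria: list
    training_metrics: pd.DataFrame
    lineups: dict
    models: list
    stimuli: StimulusSet


def run_experiment_suite(config: SuiteConfig, models=None, stimuli=None, params=None) -> SuiteResult:
    """Train (or reuse) the model instances and run all six simulations.

    Returns per-condition accuracies, the graded polarity distributions, the
    frozen per-model criteria, training-performance metrics, and lineup
    outcomes, plus a printable summary table.
    """
    from .evaluation import imagery_accuracy, verbal_accuracy, visual_accuracy
    from .stimuli import build_stimulus_set
    from .training import PROFILES, train_model

    if params is None:
        params = NetworkParams()
    if stimuli is None:
        stimuli = build_stimulus_set(config.stimulus_seed, sd=config.smoothing_sd)
    if models is None:
        tc = PROFILES[config.profile]
        models = []
        for m in range(config.n_models):
            w, _ = train_model(stimuli, params, tc, seed=config.stimulus_seed * 1000 + m)
            models.append(w)

    # training performance
    tm_rows = []
    for m, w in enumerate(models):
        tm_rows.append(
            {
                "model": m,
                "visual_trained": visual_accuracy(w, stimuli, stimuli.trained_indices, params),
                "visual_untrained": visual_accuracy(w, stimuli, stimuli.untrained_indices, params),
                "verbal_all": verbal_accuracy(w, stimuli, range(stimuli.n_items), params),
                "imagery_trained": imagery_accuracy(w, stimuli, stimuli.trained_indices, params),
            }
        )
    training_metrics = pd.DataFrame(tm_rows)

    # control condition fixes the per-model criteria
    conditions: dict[str, ConditionResult] = {}
    control_dists = [
        measure_condition(w, stimuli, CONDITIONS["control"], m, params)
        for m, w in enumerate(models)
    ]
    criteria = [select_criterion(d) for d in control_dists]
    judged = [judge_old_new(d, c) for d, c in zip(control_dists, criteria)]
    control = ConditionResult(
        name="control",
        hit_rates=np.array([j.hit_rate for j in judged]),
        cr_rates=np.array([j.correct_rejection_rate for j in judged]),
        accuracies=np.array([j.accuracy for j in judged]),
        distributions=control_dists,
    )
    conditions["control"] = control

    for name in ("similar", "dissimilar", "irrelevant"):
        res = run_condition(
            CONDITIONS[name], models, stimuli, criteria, params, seed=config.condition_seed
        )
        res.t_vs_control, res.df, res.p_vs_control = paired_t_vs_control(res, control)
        conditions[name] = res

    graded = run_graded_distributions(models, stimuli, params, seed=config.condition_seed)
    for old_k, new_k in ((2, 1), (1, 0)):
        res = accuracy_from_distributions(
            graded[old_k], graded[new_k], criteria, name=f"graded_old{old_k}_new{new_k}"
        )
        res.t_vs_control, res.df, res.p_vs_control = paired_t_vs_control(res, control)
        conditions[res.name] = res

    lineups = {}
    for name in ("control", "similar"):
        per_model = []
        for d in conditions[name].distributions[: len(models)]:
            per_model.append(
                single_trial_lineup(
                    d.old_values,
                    d.new_values,
                    config.lineup_distractors,
                    config.lineup_repetitions,
                    seed=config.condition_seed + d.model_id,
                )
            )
        lineups[name] = per_model

    rows = []
    for name, res in conditions.items():
        rows.append(
            {
                "condition": name,
                "accuracy": res.mean_accuracy,
                "se": res.se_accuracy,
                "hit_rate": float(np.mean(res.hit_rates)),
                "cr_rate": float(np.mean(res.cr_rates)),
                "t_vs_control": res.t_vs_control,
                "df": res.df,
                "p_vs_control": res.p_vs_control,
            }
        )
    summary = pd.DataFrame(rows)
    return SuiteResult(
        config=config,
        summary=summary,
        conditions=conditions,
        graded=graded,
        criteria=criteria,
        training_metrics=training_metrics,
        lineups=lineups,
        models=models,
        stimuli=stimuli,
    )
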