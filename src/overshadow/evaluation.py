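"""Scoring of network outputs.

Four measurements are provided:

* nearest-neighbour item classification of the visual image layer output
  (smallest Euclidean distance to the item targets, connected units only),
* per-unit *polarity*, one minus the binary entropy of an activation:

      polarity(a) = a log2 a + (1 - a) log2(1 - a) + 1

  which is 0 at a = 0.5 and 1 at the sigmoid asymptotes — the familiarity
  axis for the old/new recognition judgment,
* a criterion-based old/new decision: an item is judged "old" iff its mean
  visual-image polarity exceeds a threshold fitted once on the control
  condition (just below the minimum trained-item polarity, so hits are 100%
  by construction and the correct-rejection rate is emergent),
* classical metric MDS of hidden-layer settling trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import NetworkParams, Phase, TrialSpec, WeightSet, run_trial
from .stimuli import StimulusSet

__all__ = [
    "PolaritySample",
    "PolarityDistribution",
    "DecisionCriterion",
    "nearest_neighbor_classify",
    "polarity",
    "measure_item_polarity",
    "select_criterion",
    "judge_old_new",
    "project_mds",
    "visual_accuracy",
    "verbal_accuracy",
    "imagery_accuracy",
]

logger = logging.getLogger(__name__)

CRITERION_MARGIN = 1e-9


# ---------------------------------------------------------------------------
# nearest-neighbour classification
# ---------------------------------------------------------------------------

def nearest_neighbor_classify(
    output: np.ndarray, stimuli: StimulusSet, weights: WeightSet
) -> int:
    """Item id of the target closest (Euclidean) to a visual-layer output.

    ``output`` is in full visual-layer coordinates; the comparison is
    restricted to connected units.  Ties break toward the lowest item id and
    are logged.
    """
    mask = weights.mask.visual
    targets = stimuli.images[:, mask].astype(np.float64)
    d2 = np.sum((targets - np.asarray(output, dtype=np.float64)[mask]) ** 2, axis=1)
    best = np.flatnonzero(d2 == d2.min())
    if best.size > 1:
        logger.info("nearest-neighbour tie among items %s; taking lowest id", stimuli.item_ids[best])
    return int(stimuli.item_ids[best[0]])


# ---------------------------------------------------------------------------
# polarity (familiarity)
# ---------------------------------------------------------------------------

def polarity(a) -> np.ndarray | float:
    """One minus binary entropy of an activation, with 0 log 0 = 0.

    Vectorized; values must lie in [0, 1] and the result does too.
    Symmetric: polarity(a) = polarity(1 - a).
    """
    arr = np.asarray(a, dtype=np.float64)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("activations must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(arr > 0, arr * np.log2(np.where(arr > 0, arr, 1.0)), 0.0)
        comp = 1.0 - arr
        term = term + np.where(comp > 0, comp * np.log2(np.where(comp > 0, comp, 1.0)), 0.0)
    out = np.clip(term + 1.0, 0.0, 1.0)
    return float(out) if np.isscalar(a) or np.ndim(a) == 0 else out


@dataclass
class PolaritySample:
    """Mean visual-image-layer polarity of one item in one condition."""

    item_id: int
    old: bool
    mean_polarity: float


@dataclass
class PolarityDistribution:
    """Per-item polarity samples of one model instance in one condition."""

    condition: str
    model_id: int
    samples: list[PolaritySample]

    @property
    def old_values(self) -> np.ndarray:
        return np.array([s.mean_polarity for s in self.samples if s.old])

    @property
    def new_values(self) -> np.ndarray:
        return np.array([s.mean_polarity for s in self.samples if not s.old])


def measure_item_polarity(
    weights: WeightSet,
    trial: TrialSpec,
    item_id: int,
    old: bool,
    params: NetworkParams | None = None,
    connected_only: bool = True,
) -> PolaritySample:
    """Run an evaluation trial and average unit polarity at its final cycle.

    The trial (possibly two-phase: verbalization then recognition) is run
    with noise disabled and no early stopping, so the measurement falls on
    the 10th cycle after retinotopic onset.  By default the average covers
    connected visual-image units only; disconnected units receive no hidden
    input and would only add a constant dilution term.
    """
    if params is None:
        params = weights.params
    traj = run_trial(trial, weights, params, rng=None)
    sl = weights.slices["visual"]
    acts = traj.a_p[-1][sl]
    if not connected_only:
        n_total = params.n_visual
        # disconnected units sit at sigmoid(0) = 0.5, i.e. polarity 0
        mean = float(np.sum(polarity(acts)) / n_total) if n_total else 0.0
        return PolaritySample(item_id=item_id, old=old, mean_polarity=mean)
    return PolaritySample(item_id=item_id, old=old, mean_polarity=float(np.mean(polarity(acts))))


# ---------------------------------------------------------------------------
# old/new decision
# ---------------------------------------------------------------------------

@dataclass
class DecisionCriterion:
    """Polarity threshold for the old/new judgment, frozen after fitting."""

    threshold: float
    provenance: str


def select_criterion(control: PolarityDistribution) -> DecisionCriterion:
    """Place the threshold infinitesimally below the minimum old-item polarity.

    The resulting hit rate on the control condition is 100% by construction;
    the correct-rejection rate is whatever the new-item distribution yields.
    """
    old = control.old_values
    new = control.new_values
    if old.size == 0:
        raise ValueError("control distribution has no old-item samples")
    if old.size and new.size and np.ptp(np.concatenate([old, new])) == 0:
        logger.warning("degenerate polarity distribution (all values equal)")
        return DecisionCriterion(threshold=float(old.min()), provenance=control.condition)
    return DecisionCriterion(threshold=float(old.min()) - CRITERION_MARGIN, provenance=control.condition)


@dataclass
class JudgmentResult:
    hit_rate: float
    correct_rejection_rate: float

    @property
    def accuracy(self) -> float:
        """Unweighted mean of hit and correct-rejection rates."""
        return 0.5 * (self.hit_rate + self.correct_rejection_rate)


def judge_old_new(samples: PolarityDistribution, criterion: DecisionCriterion) -> JudgmentResult:
    """Judge each item "old" iff mean polarity exceeds the frozen threshold."""
    old = samples.old_values
    new = samples.new_values
    hit = float(np.mean(old > criterion.threshold)) if old.size else 0.0
    cr = float(np.mean(new <= criterion.threshold)) if new.size else 0.0
    return JudgmentResult(hit_rate=hit, correct_rejection_rate=cr)


# ---------------------------------------------------------------------------
# task accuracies
# ---------------------------------------------------------------------------

def _recognition_trial(weights, stimuli, idx, params, task="visual_recognition"):
    from .training import make_trial  # local import to avoid a cycle

    return make_trial(task, idx, stimuli, weights, train=False)


def visual_accuracy(
    weights: WeightSet,
    stimuli: StimulusSet,
    indices,
    params: NetworkParams | None = None,
) -> float:
    """Nearest-neighbour visual recognition accuracy over the given items."""
    if params is None:
        params = weights.params
    correct = 0
    for i in indices:
        trial = _recognition_trial(weights, stimuli, int(i), params)
        trial = TrialSpec(trial.task, [Phase(p.cycles, p.clamps, early_stop=False) for p in trial.phases])
        traj = run_trial(trial, weights, params, rng=None)
        out = weights.unpack("visual", traj.a_p[-1][weights.slices["visual"]])
        if nearest_neighbor_classify(out, stimuli, weights) == stimuli.specs[int(i)].item_id:
            correct += 1
    return correct / len(list(indices))


def verbal_accuracy(weights, stimuli, indices, params=None) -> float:
    """Fraction of items whose verbal output picks the correct label per pair."""
    if params is None:
        params = weights.params
    correct = 0
    idx_list = list(indices)
    for i in idx_list:
        trial = _recognition_trial(weights, stimuli, int(i), params, task="verbalization")
        trial = TrialSpec(trial.task, [Phase(p.cycles, p.clamps, early_stop=False) for p in trial.phases])
        traj = run_trial(trial, weights, params, rng=None)
        out = weights.unpack("verbal", traj.a_p[-1][weights.slices["verbal"]])
        pred = np.zeros(6, dtype=np.uint8)
        for f in range(3):
            pred[2 * f + int(np.argmax(out[2 * f : 2 * f + 2]))] = 1
        if np.array_equal(pred, stimuli.verbal[int(i)]):
            correct += 1
    return correct / len(idx_list)


def imagery_accuracy(weights, stimuli, indices, params=None) -> float:
    """Item-exact accuracy of imagining a face from its verbal labels.

    Bounded below 100% whenever several items share a verbal triple (the
    one-to-many mapping): identical inputs cannot yield different outputs.
    """
    if params is None:
        params = weights.params
    correct = 0
    idx_list = list(indices)
    for i in idx_list:
        trial = _recognition_trial(weights, stimuli, int(i), params, task="imagery")
        trial = TrialSpec(trial.task, [Phase(p.cycles, p.clamps, early_stop=False) for p in trial.phases])
        traj = run_trial(trial, weights, params, rng=None)
        out = weights.unpack("visual", traj.a_p[-1][weights.slices["visual"]])
        if nearest_neighbor_classify(out, stimuli, weights) == stimuli.specs[int(i)].item_id:
            correct += 1
    return correct / len(idx_list)


# ---------------------------------------------------------------------------
# MDS of hidden trajectories
# ---------------------------------------------------------------------------

def project_mds(hidden_states: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Classical (Torgerson) metric MDS of hidden-layer snapshots.

    ``hidden_states`` is (n_points, n_hidden); returns (n_points, k)
    coordinates from the eigendecomposition of the double-centered squared
    Euclidean distance matrix.  If fewer than ``n_components`` eigenvalues
    are positive the embedding is truncated with a warning.  Eigenvectors are
    sign-fixed (largest-magnitude coordinate positive) for determinism.
    """
    X = np.asarray(hidden_states, dtype=np.float64)
    n = X.shape[0]
    sq = np.sum(X**2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.clip(D2, 0.0, None, out=D2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-10, 1e-12 * max(vals.max(), 1.0))
    k = min(n_components, int(pos.sum()))
    if k < n_components:
        logger.warning("only %d positive eigenvalues; returning %d MDS dimensions", int(pos.sum()), k)
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for j in range(k):
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] *= -1.0
    return coords
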