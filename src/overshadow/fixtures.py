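"""Deterministic micro-instances for desk-scale testing.

Three kinds are available, each regenerated bit-identically from
``(kind, seed)``:

* ``gradient_check`` — a 2-5-unit network plus a short training trial,
  small enough for central finite-difference gradient verification,
* ``four_item_stimuli`` — a 4-face subset (two verbal-triple pairs) that a
  reduced training run drives to 100% visual and verbal accuracy while the
  one-to-many verbal-to-image mapping caps imagery accuracy below 100%,
* ``overlap_distributions`` — synthetic old/new polarity samples with a
  controllable degree of overlap, for the decision and lineup statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    ClampSpec,
    ConnectivityMask,
    NetworkParams,
    Phase,
    TrialSpec,
    WeightSet,
    init_network,
)
from .stimuli import StimulusSet, build_stimulus_set, subset_stimulus_set

__all__ = ["MicroNetwork", "CannedDistribution", "make_micro_instance", "FOUR_ITEM_TYPES"]

KINDS = ("gradient_check", "four_item_stimuli", "overlap_distributions")

#: (eye, nose, lip) subordinate types of the 4-item subset; items 1 & 2 share
#: one verbal triple, items 3 & 4 the other
FOUR_ITEM_TYPES = ((0, 0, 0), (1, 1, 1), (2, 2, 2), (3, 3, 3))


@dataclass
class MicroNetwork:
    """A hand-checkable network instance with an example training trial."""

    params: NetworkParams
    weights: WeightSet
    trial: TrialSpec


@dataclass
class CannedDistribution:
    """Synthetic per-item polarity samples for old and new items."""

    old: np.ndarray
    new: np.ndarray
    overlap: float


def _gradient_check_fixture(seed: int) -> MicroNetwork:
    params = NetworkParams(
        n_retinotopic=3,
        n_visual=3,
        n_verbal=2,
        n_hidden=3,
        cycles_per_phase=4,
        hidden_input_noise_sd=0.0,  # noise off: finite differences need determinism
        zero_error_radius=0.0,  # radius off: the mask is not differentiable
        early_stop_threshold=0.0,  # fixed trial length
        init_weight_range=0.5,
    )
    mask = ConnectivityMask(
        retinotopic=np.ones(3, dtype=bool),
        visual=np.ones(3, dtype=bool),
        verbal=np.ones(2, dtype=bool),
    )
    weights = init_network(params, mask, seed)
    rng = np.random.default_rng(seed + 1)
    retino = rng.uniform(0.1, 0.9, size=3)
    target = rng.integers(0, 2, size=3).astype(float)
    ext = np.array([1.0, 0.0])
    trial = TrialSpec(
        task="visual_recognition",
        phases=[
            Phase(
                params.cycles_per_phase,
                clamps=[
                    ClampSpec("retinotopic", "hard", retino),
                    ClampSpec("verbal", "soft", ext, unit_mask=np.array([True, False])),
                ],
                target_layer="visual",
                target=target,
                early_stop=False,
            )
        ],
        train=True,
    )
    return MicroNetwork(params=params, weights=weights, trial=trial)


def _four_item_fixture(seed: int) -> StimulusSet:
    full = build_stimulus_set(seed)
    by_types = {(s.eye_type, s.nose_type, s.lip_type): i for i, s in enumerate(full.specs)}
    idx = [by_types[t] for t in FOUR_ITEM_TYPES]
    return subset_stimulus_set(full, idx)


def _overlap_fixture(seed: int, overlap: float) -> CannedDistribution:
    """Old ~ N(mu_old, 0.05), new ~ N(mu_old - shift, 0.05), clipped to [0, 1].

    ``overlap`` = 0 gives disjoint supports; ``overlap`` = 1 gives identical
    distributions.
    """
    rng = np.random.default_rng(seed)
    sd = 0.02
    shift = (1.0 - overlap) * 0.5
    old = np.clip(rng.normal(0.75, sd, size=32), 0.0, 1.0)
    new = np.clip(rng.normal(0.75 - shift, sd, size=32), 0.0, 1.0)
    if overlap <= 0:
        # force disjoint supports
        new = np.minimum(new, old.min() - 1e-6)
    return CannedDistribution(old=old, new=new, overlap=overlap)


def make_micro_instance(kind: str, seed: int, **kwargs):
    """Deterministic fixture factory; unknown kinds are rejected."""
    if kind == "gradient_check":
        return _gradient_check_fixture(seed)
    if kind == "four_item_stimuli":
        return _four_item_fixture(seed)
    if kind == "overlap_distributions":
        return _overlap_fixture(seed, overlap=float(kwargs.get("overlap", 0.0)))
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {KINDS}")
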