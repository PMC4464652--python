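import numpy as np
import pytest

import overshadow as ov


@pytest.fixture(scope="session")
def stimulus_set():
    """The canonical 64-face bank (seed 1)."""
    return ov.build_stimulus_set(1)


@pytest.fixture(scope="session")
def four_item_set():
    return ov.make_micro_instance("four_item_stimuli", 1)


@pytest.fixture(scope="session")
def trained_four_item(four_item_set):
    """A 4-item model trained with the smoke profile (seconds, not minutes)."""
    params = ov.NetworkParams()
    weights, log = ov.train_model(four_item_set, params, ov.PROFILES["smoke"], seed=0)
    return weights, log


@pytest.fixture(scope="session")
def micro_gradient():
    return ov.make_micro_instance("gradient_check", 3)


@pytest.fixture(scope="session")
def paper_scale_suite():
    """The full 5-instance experiment run at the reduced training profile.

    Expensive (most of the suite's runtime); shared by every test that needs
    trained full-scale models.
    """
    cfg = ov.SuiteConfig(stimulus_seed=1, n_models=5, profile="reduced")
    return ov.run_experiment_suite(cfg)


def make_micro_weights(n_r=2, n_v=2, n_l=2, n_h=1, **param_overrides):
    """An all-connected micro WeightSet with zero weights for hand-built cases."""
    defaults = dict(
        n_retinotopic=n_r,
        n_visual=n_v,
        n_verbal=n_l,
        n_hidden=n_h,
        hidden_input_noise_sd=0.0,
    )
    defaults.update(param_overrides)
    params = ov.NetworkParams(**defaults)
    mask = ov.ConnectivityMask(
        retinotopic=np.ones(n_r, dtype=bool),
        visual=np.ones(n_v, dtype=bool),
        verbal=np.ones(n_l, dtype=bool),
    )
    return ov.WeightSet(params, mask)
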