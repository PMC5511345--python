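import warnings

import numpy as np
import pytest

from sheathchase import (BleachChaseModel, CellGeometry, CellShape,
                         FluorophorePool, Mechanism, OpticsConfig,
                         SeededSheath, SimulationConfig, render_stack,
                         simulate)
from sheathchase.kymograph import background_stats, extract_kymogram
from sheathchase.presets import chase_experiment, speed_experiment

warnings.filterwarnings("ignore", message="sheath still growing")


@pytest.fixture(scope="session")
def spheroplast5():
    return CellGeometry(CellShape.SPHEROPLAST, 5.0)


@pytest.fixture(scope="session")
def single_sheath_sim(spheroplast5):
    """One distal sheath growing across a 5-um spheroplast, no bleach."""
    cfg = SimulationConfig(
        geometry=spheroplast5, seed=7, nucleation_rate_per_min=0.0,
        extended_dwell_s=None, duration_s=80.0,
        seeded_sheaths=[SeededSheath(4.0, (-2.5, 0.0), (1.0, 0.0), 55.0)],
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def noiseless_optics():
    return OpticsConfig(shot_noise=False, read_noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_stack(single_sheath_sim, noiseless_optics):
    return render_stack(single_sheath_sim, noiseless_optics)


@pytest.fixture(scope="session")
def distal_event_clean():
    """A noiseless compliant photobleach-chase event (distal mechanism)."""
    return chase_experiment("distal", seed=11, noise=False)


@pytest.fixture(scope="session")
def distal_event_clean_fit(distal_event_clean):
    exp = distal_event_clean
    model = BleachChaseModel.from_stack(exp.stack, exp.line)
    return model, model.fit()


def fit_chase(mechanism, seed, noise=True):
    exp = chase_experiment(mechanism, seed=seed, noise=noise)
    return BleachChaseModel.from_stack(exp.stack, exp.line).fit()


@pytest.fixture(scope="session")
def clean_speed_run():
    """Noiseless growth experiment with its kymogram and background."""
    exp = speed_experiment(55.0, seed=2, noise=False)
    kym = extract_kymogram(exp.stack, exp.line)
    bg = background_stats(exp.stack)
    return exp, kym, bg
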