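import numpy as np
import pytest

from wmosc.core import TrialEpochs, make_metadata, standard_montage
from wmosc.simulate import EffectConfig, make_task_schedule, simulate_subject


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def schedule():
    return make_task_schedule(seed=11)


@pytest.fixture(scope="session")
def hc_subject(schedule, montage):
    """One healthy-control-like subject with all default effects injected.

    Reduced sampling rate (250 Hz) keeps the module tests fast; the epoch
    window and trial structure are the full session.
    """
    epochs, baseline, truth = simulate_subject(
        schedule, EffectConfig(), group="HC", seed=21, sfreq=250.0,
        montage=montage, return_truth=True)
    return epochs, baseline, truth


@pytest.fixture(scope="session")
def ms_subject(schedule, montage):
    epochs, baseline, truth = simulate_subject(
        schedule, EffectConfig(), group="MS", seed=22, sfreq=250.0,
        montage=montage, return_truth=True)
    return epochs, baseline, truth


def sine_epochs(montage, freq=6.0, amp=1.0, sfreq=250.0, n_trials=3,
                phase=0.0):
    """Epochs whose every channel carries one pure sinusoid."""
    n_lo = int(round(0.5 * sfreq))
    n = n_lo + int(round(3.8 * sfreq))
    times = (np.arange(n) - n_lo) / sfreq
    sig = amp * np.cos(2 * np.pi * freq * times + phase)
    data = np.tile(sig, (n_trials, len(montage), 1))
    meta = make_metadata(ml=[2, 4, 6] * (n_trials // 3 + 1))[:n_trials]
    return TrialEpochs(data, sfreq, times, montage, meta)


@pytest.fixture(scope="session")
def pure_sine(montage):
    return sine_epochs(montage)
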