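import numpy as np
import pytest

from seegflow import core_io, dtf, synthetic


def make_recording(signal, fs=500.0, soz=None, positions=None, labels=None):
    """Build a Recording around a raw (channels x samples) array."""
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n = signal.shape[0]
    soz = soz if soz is not None else [False] * n
    labels = labels or [f"C{i:02d}" for i in range(n)]
    positions = positions if positions is not None else [(0.0, 0.0, 0.0)] * n
    channels = [
        core_io.ChannelInfo(label=labels[i], position=tuple(positions[i]), soz=bool(soz[i]))
        for i in range(n)
    ]
    return core_io.Recording(channels=channels, signal=signal, fs=fs)


@pytest.fixture(scope="session")
def bivariate_system():
    """The printed bivariate MVAR: A_1 = [[0.5, 0], [0.4, 0.5]] (flow 1 -> 2)."""
    return np.array([[[0.5, 0.0], [0.4, 0.5]]])


@pytest.fixture(scope="session")
def fitted_patient():
    """One synthetic patient with a fitted DTF tensor, shared across tests."""
    rec, truth = synthetic.simulate_patient(12, delta=0.25, duration=90.0, seed=42)
    ep = core_io.epoch(rec)
    model = dtf.fit_mvar(ep, 6)
    tensor = dtf.dtf(model, labels=rec.labels)
    return rec, truth, tensor
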