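import numpy as np
import pandas as pd
import pytest

from ieegdyn import sigproc, synthgen


def make_epochs(data, fs=512.0, t0="hll", t_cue_rel=-2.0, times=None, rois=None,
                context=None, rt=None):
    """Wrap a trials x channels x samples array into an Epochs container."""
    data = np.asarray(data, float)
    n_tr, n_ch, n_s = data.shape
    if times is None:
        times = np.arange(n_s) / fs - n_s / (2 * fs)
    meta = pd.DataFrame(
        {
            "trial_id": np.arange(n_tr),
            "context": 0.0 if context is None else context,
            "is_stop": False,
            "t_cue": t_cue_rel,
            "t_press": -0.57,
            "t_hll": 0.0,
            "t_upper": 0.18,
            "t_release": 0.05,
            "correct": True,
            "rt": 0.05 if rt is None else rt,
        }
    )
    return sigproc.Epochs(
        data=data,
        fs=fs,
        t0_event=t0,
        times=np.asarray(times, float),
        trial_meta=meta,
        roi_labels=list(rois) if rois is not None else ["pfc"] * n_ch,
        ch_names=[f"CH{i}" for i in range(n_ch)],
    )


@pytest.fixture(scope="session")
def small_session():
    """One modest synthetic session shared across tests (seeded)."""
    cfg = synthgen.SimConfig(
        n_trials_per_context=15, n_channels={"pfc": 2, "motor": 2}, pac_depth=1.0, seed=5
    )
    raw, truth = synthgen.simulate_session(cfg)
    return cfg, raw, truth


@pytest.fixture(scope="session")
def small_hfa(small_session):
    cfg, raw, truth = small_session
    ep = sigproc.epoch(sigproc.preprocess(raw), "hll", (-3.0, 1.0))
    hfa = sigproc.extract_hfa(ep, seed=1)
    return ep, hfa
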