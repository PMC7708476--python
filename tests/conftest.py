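"""Shared fixtures: small synthetic sessions with known ground truth."""

import numpy as np
import pytest

from lerens import LERParams, SessionConfig, sample_ler, render_session
from lerens.session import Session


@pytest.fixture(scope="session")
def small_planted():
    """A small session with 100 planted IEDs (K=3, N=20)."""
    params = LERParams(K=3, N=20, M=100)
    gt = sample_ler(params, seed=1)
    session = render_session(gt, SessionConfig(seed=2))
    return gt, session


@pytest.fixture(scope="session")
def seed_labels_factory():
    """Build (frames, labels) seed annotations from ground truth."""

    def make(gt, session, n_pos=15, n_neg=15, seed=3):
        rng = np.random.default_rng(seed)
        pos = rng.choice(gt.event_frames, n_pos, replace=False)
        non = np.setdiff1d(np.arange(session.n_frames), gt.event_frames)
        neg = rng.choice(non, n_neg, replace=False)
        idx = np.concatenate([pos, neg])
        y = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
        order = np.argsort(idx)
        return idx[order], y[order]

    return make


def make_noise_session(n_cells=20, n_frames=3000, frame_rate=10.0,
                       samples_per_frame=10, seed=0, dff=None):
    """Session with iid Gaussian traces and silent LFP (exchangeable null)."""
    rng = np.random.default_rng(seed)
    if dff is None:
        dff = rng.standard_normal((n_cells, n_frames))
    n_cells, n_frames = dff.shape
    return Session(
        dff=dff,
        lfp=np.zeros(n_frames * samples_per_frame),
        frame_bounds=np.arange(n_frames + 1, dtype=np.int64) * samples_per_frame,
        labels=np.asarray(["mGC"] * n_cells, dtype=object),
        speed=np.zeros(n_frames),
        frame_rate=frame_rate,
        lfp_rate=frame_rate * samples_per_frame,
    )
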