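"""Shared fixtures: tiny phantom cohorts and hand-constructed networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import brainpad as bp
from brainpad._nn import BrainAgeCNN
from brainpad.model import _CategoryEncoder
from brainpad.phantom import subject_render_seed
from brainpad.preprocess import AgeScaler, VolumePreprocessor


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small in-memory phantom configuration (16-voxel grid)."""
    return bp.PhantomConfig(group_sizes={"HC": 24, "BD": 4, "SZ": 4},
                            grid_size=16, seed=7, noise_sd=0.0)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    cohort = bp.generate_cohort(tiny_cfg, write_volumes=False)
    prep = VolumePreprocessor(target_edge=16)
    X = np.stack([
        prep.transform(bp.render_phantom(
            r, tiny_cfg, subject_render_seed(tiny_cfg, r.id))[None])[0]
        for r in cohort.records])
    return cohort.to_frame(), X


def make_passthrough_net(grid: int = 16, channels=(2, 4), head_units: int = 8):
    """A hand-wired network whose output is the sum of the input over the
    whole field of view, carried on channel 0 through every block.

    Convolutions are center-tap identities on channel 0 and zero elsewhere;
    batch norm and FiLM are left at identity statistics/affines; the dense
    head sums channel-0 features with unit weights. Useful as a controlled
    saliency oracle: the output gradient w.r.t. any block's channel-0
    activation is a positive constant.
    """
    net = BrainAgeCNN(grid=grid, channels=channels, head_units=head_units,
                      head_dropout=0.0, n_sexes=1, n_scanners=1, film=True,
                      sex_batchnorm=True, rng=np.random.default_rng(0))
    for b in net.blocks:
        b["conv"].W.value[...] = 0.0
        b["conv"].W.value[0, 0, 1, 1, 1] = 1.0  # identity tap on channel 0
        b["conv"].b.value[...] = 0.0
        b["bn"].seen[:] = True  # identity running stats (mean 0, var 1)
    net.fc1.W.value[...] = 0.0
    final_edge = grid // (2 ** len(channels))
    n_per_channel = final_edge ** 3
    net.fc1.W.value[:n_per_channel, 0] = 1.0  # sum channel-0 features
    net.fc1.b.value[...] = 0.0
    net.fc2.W.value[...] = 0.0
    net.fc2.W.value[0, 0] = 1.0
    net.fc2.b.value[...] = 0.0
    return net


def make_manual_estimator(net, scaler_mean: float = 30.0,
                          scaler_sd: float = 10.0) -> bp.BrainAgeRegressor:
    """Wrap a hand-wired network as a fitted BrainAgeRegressor."""
    est = bp.BrainAgeRegressor(channels=net.channels, head_dropout=0.0)
    est._sex_enc_ = _CategoryEncoder([0])
    est._scanner_enc_ = _CategoryEncoder([0])
    est.scaler_ = AgeScaler(mean=scaler_mean, sd=scaler_sd)
    est.n_features_in_ = net.grid ** 3
    est.model_ = net
    est.history_ = pd.DataFrame()
    est.best_epoch_ = 0
    return est
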