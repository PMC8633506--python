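import numpy as np
import pytest

from mdvae import features as F
from mdvae import models as Mo
from mdvae import synthetic_data as S


@pytest.fixture(scope="session")
def toy_config():
    """Small two-state system for fast module tests."""
    return S.ToyEnsembleConfig(
        n_atoms=20, n_frames=400, noise_sigma=0.3, switch_prob=0.1, seed=11
    )


@pytest.fixture(scope="session")
def toy_trajectory(toy_config):
    traj, labels = S.generate_two_state_trajectory(toy_config)
    return traj, labels


@pytest.fixture(scope="session")
def small_trained_vae(toy_config, toy_trajectory):
    """A quickly trained VAE on the small toy system."""
    traj, labels = toy_trajectory
    fm = F.fit_transform(F.align_to_first_frame(traj))
    split = F.stride_split(fm.n_frames, 4)
    spec = Mo.ModelSpec(
        model_kind="vae",
        input_dim=fm.n_features,
        encoder_layer_sizes=Mo.scaled_architecture(fm.n_features),
        epochs=120,
        kl_anneal_epochs=60,
        seed=3,
    )
    model = Mo.train(Mo.build_model(spec), fm, split)
    return {"model": model, "features": fm, "split": split, "labels": labels}


@pytest.fixture(scope="session")
def two_state_pipeline():
    """Full-size synthetic pipeline: 50 atoms, 2000 frames, 4-layer VAE
    trained 200 epochs.  Shared by the end-to-end checks."""
    cfg = S.ToyEnsembleConfig(
        n_atoms=50, n_frames=2000, noise_sigma=0.5, switch_prob=0.05, seed=1
    )
    traj, labels = S.generate_two_state_trajectory(cfg)
    aligned = F.align_to_first_frame(traj)
    fm = F.fit_transform(aligned)
    split = F.stride_split(fm.n_frames, 4)
    spec = Mo.ModelSpec(
        model_kind="vae",
        input_dim=fm.n_features,
        encoder_layer_sizes=Mo.scaled_architecture(fm.n_features, 4),
        epochs=200,
        seed=2,
    )
    model = Mo.train(Mo.build_model(spec), fm, split)
    emb = Mo.encode(model, fm)
    return {
        "config": cfg,
        "trajectory": aligned,
        "labels": labels,
        "features": fm,
        "split": split,
        "model": model,
        "embedding": emb,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
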