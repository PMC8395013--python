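"""Shared fixtures: tiny phantom datasets and (expensive) toy training runs.

The toy corruption model — gain 1.1, offset 40 HU, cupping 60 HU, Gaussian
noise 10 HU — is fixed across the suite so that supervised and unsupervised
recovery are exercised on the same conditions; the unsupervised variant adds
gas-cavity mismatch to probe anatomy preservation.
"""

from __future__ import annotations

import numpy as np
import pytest

from synthct.evaluation import compute_mae_hu
from synthct.nn import DiscriminatorConfig, GeneratorConfig
from synthct.phantom import (ArtifactModel, PhantomSpec, apply_cbct_artifacts,
                             body_mask_of, generate_phantom)
from synthct.preprocess import body_mask
from synthct.training import TrainConfig, train_cyclegan, train_supervised, _split
from synthct.types import PairedSlice

TOY_MODEL = ArtifactModel(gain=1.1, offset=40.0, cupping_amplitude=60.0,
                          noise_sigma=10.0)
TOY_MODEL_MISMATCH = ArtifactModel(gain=1.1, offset=40.0, cupping_amplitude=60.0,
                                   noise_sigma=10.0, cavity_mismatch=True)

TOY_GEN = GeneratorConfig(channels=(16, 16, 32, 32, 32), residual=True)
TOY_GEN_SMALL = GeneratorConfig(channels=(8, 8, 16, 16, 16), residual=True)
TOY_DISC = DiscriminatorConfig(channels=(8, 16, 32, 32))


def toy_spec(rng: np.random.Generator) -> PhantomSpec:
    return PhantomSpec(image_size=64,
                       body_axes=(rng.uniform(22, 28), rng.uniform(17, 23)),
                       n_bone_structures=int(rng.integers(2, 5)),
                       gas_cavity_probability=0.3, texture_sigma_hu=15.0)


def make_toy_dataset(seed: int = 0, n_subjects: int = 20,
                     slices_per_subject: int = 10,
                     model: ArtifactModel = TOY_MODEL) -> list[PairedSlice]:
    """200 paired 64x64 slices, 20 subjects, fixed toy corruption."""
    pairs = []
    for si in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, si)))
        spec = toy_spec(rng)
        for zi in range(slices_per_subject):
            s = int(np.random.SeedSequence(
                entropy=(seed, si, zi)).generate_state(1)[0] % 2 ** 31)
            ct = generate_phantom(spec, s)
            cbct = apply_cbct_artifacts(ct, body_mask_of(spec), model, s + 1)
            pairs.append(PairedSlice(ct=ct, cbct=cbct,
                                     subject_id=f"subj{si:03d}", seed=s))
    return pairs


def masked_mae(pairs) -> float:
    return float(np.mean([compute_mae_hu(p.ct, p.cbct,
                                         region=body_mask(p.ct).pixels)
                          for p in pairs]))


@pytest.fixture(scope="session")
def toy_pairs():
    return make_toy_dataset(seed=1)


@pytest.fixture(scope="session")
def supervised_run(toy_pairs):
    """One seeded 5-epoch supervised toy run, shared across tests."""
    config = TrainConfig(epochs=5, batch_size=10, learning_rate=2e-4,
                         beta1=0.5, beta2=0.999, seed=1)
    train_pairs, val_pairs = _split(toy_pairs, config.val_fraction, config.seed)
    gen, history = train_supervised(toy_pairs, config,
                                    generator_config=TOY_GEN)
    return {"generator": gen, "history": history, "config": config,
            "train_pairs": train_pairs, "val_pairs": val_pairs}


@pytest.fixture(scope="session")
def cyclegan_run():
    """One seeded 5-epoch unsupervised toy run on mismatch-bearing data."""
    pairs = make_toy_dataset(seed=1, model=TOY_MODEL_MISMATCH)
    config = TrainConfig(epochs=5, batch_size=10, learning_rate=5e-4,
                         d_learning_rate=2e-3, d_steps=15,
                         beta1=0.5, beta2=0.999, seed=1)
    train_pairs, val_pairs = _split(pairs, config.val_fraction, config.seed)
    models, history = train_cyclegan(pairs, config,
                                     generator_config=TOY_GEN_SMALL,
                                     discriminator_config=TOY_DISC)
    return {"models": models, "history": history, "config": config,
            "pairs": pairs, "train_pairs": train_pairs, "val_pairs": val_pairs}
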