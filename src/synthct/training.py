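"""Supervised (pixel-wise MAE) and unsupervised (cycle-consistent
adversarial) training routines, plus slice/volume inference.

Both routines follow the same optimization protocol: ADAM (learning rate
2e-4, beta1 0.5, beta2 0.999), batch size 10, coherent 90-degree-rotation /
horizontal-flip augmentation re-sampled each epoch, and best-weights
checkpointing on maximal validation SSIM.  The unsupervised routine consumes
the CT and CBCT pools independently (pairing is never used for training),
while its checkpoint rule evaluates the CT-direction generator on a paired
validation split.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .evaluation import compute_mae_hu, compute_ssim
from .losses import LossReport, LossWeights, bce_patch_loss, l1_loss, lsgan_patch_loss
from .nn import Adam, Discriminator, DiscriminatorConfig, Generator, GeneratorConfig
from .preprocess import body_mask, denormalize, normalize
from .types import HUImage, PairedSlice

__all__ = ["TrainConfig", "train_supervised", "train_cyclegan",
           "translate_slice", "translate_volume"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 25
    batch_size: int = 10
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    val_fraction: float = 0.2
    augment: bool = True
    #: Discriminator updates per generator update (adversarial training only).
    d_steps: int = 1
    #: Discriminator learning rate; None means same as the generator's.
    d_learning_rate: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


def _rng(*entropy) -> np.random.Generator:
    ints = tuple(zlib.crc32(e.encode()) if isinstance(e, str) else int(e)
                 for e in entropy)
    return np.random.default_rng(np.random.SeedSequence(entropy=ints))


def _norm_stack(pairs: list[PairedSlice]):
    ct = np.stack([normalize(p.ct).pixels for p in pairs])[:, None]
    cbct = np.stack([normalize(p.cbct).pixels for p in pairs])[:, None]
    return ct.astype(np.float32), cbct.astype(np.float32)


def _augment_batch(ct: np.ndarray, cbct: np.ndarray, rng: np.random.Generator):
    """Coherent per-image rotation by multiples of 90 deg + horizontal flip."""
    ct = ct.copy()
    cbct = cbct.copy()
    for i in range(ct.shape[0]):
        k = int(rng.integers(4))
        flip = bool(rng.integers(2))
        a = np.rot90(ct[i, 0], k)
        b = np.rot90(cbct[i, 0], k)
        if flip:
            a, b = np.fliplr(a), np.fliplr(b)
        ct[i, 0] = a
        cbct[i, 0] = b
    return ct, cbct


def _split(dataset: list[PairedSlice], val_fraction: float, seed: int):
    if not dataset:
        raise ValueError("empty dataset")
    idx = _rng(seed, "split").permutation(len(dataset))
    n_val = max(1, int(round(val_fraction * len(dataset))))
    val = [dataset[i] for i in idx[:n_val]]
    train = [dataset[i] for i in idx[n_val:]]
    if not train:
        raise ValueError("dataset too small for the requested validation split")
    return train, val


def _validate(generator: Generator, val_pairs: list[PairedSlice]):
    """Mean validation SSIM (body mask) and MAE in HU of G(CBCT) vs CT."""
    ssims, maes = [], []
    for p in val_pairs:
        sct = translate_slice(generator, p.cbct)
        mask = body_mask(p.ct).pixels
        a = normalize(p.ct).pixels
        b = normalize(sct).pixels
        ssims.append(compute_ssim(a, b, region=mask))
        maes.append(compute_mae_hu(p.ct, sct, region=mask))
    return float(np.mean(ssims)), float(np.mean(maes))


def train_supervised(dataset: list[PairedSlice], config: TrainConfig | None = None,
                     generator_config: GeneratorConfig | None = None,
                     val_pairs: list[PairedSlice] | None = None):
    """Minimize mean absolute error between G(CBCT) and the paired CT.

    Returns the generator restored to its best-validation-SSIM checkpoint and
    a per-epoch loss history.
    """
    config = config or TrainConfig()
    if val_pairs is None:
        train_pairs, val_pairs = _split(dataset, config.val_fraction, config.seed)
    else:
        train_pairs = list(dataset)
    if not train_pairs:
        raise ValueError("empty training set")

    gen = Generator(generator_config, seed=config.seed)
    opt = Adam(gen.parameters(), lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2)
    ct_all, cbct_all = _norm_stack(train_pairs)
    n = len(train_pairs)

    history: list[LossReport] = []
    best_ssim, best_state = -np.inf, None
    for epoch in range(config.epochs):
        rng = _rng(config.seed, "epoch", epoch)
        ct_e, cbct_e = (_augment_batch(ct_all, cbct_all, rng)
                        if config.augment else (ct_all, cbct_all))
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            x, y = cbct_e[sel], ct_e[sel]
            gen.zero_grad()
            pred, ctx = gen.forward(x)
            value, grad = l1_loss(pred, y)
            gen.backward(grad, ctx)
            opt.step()
            losses.append(value)
        val_ssim, val_mae = _validate(gen, val_pairs)
        history.append(LossReport(epoch=epoch, terms={
            "supervised_mae": float(np.mean(losses)),
            "val_ssim": val_ssim, "val_mae_hu": val_mae}))
        history[-1].validate()
        if val_ssim > best_ssim:
            best_ssim, best_state = val_ssim, gen.state()
    if best_state is not None:
        gen.load_state(best_state)
    gen.trained = True
    return gen, history


def _adv_loss(kind: str):
    return bce_patch_loss if kind == "bce" else lsgan_patch_loss


def train_cyclegan(dataset: list[PairedSlice], config: TrainConfig | None = None,
                   weights: LossWeights | None = None,
                   generator_config: GeneratorConfig | None = None,
                   discriminator_config: DiscriminatorConfig | None = None,
                   val_pairs: list[PairedSlice] | None = None):
    """Cycle-consistent adversarial training on unpaired CT / CBCT pools.

    Returns ``(g_ct, g_cbct, d_ct, d_cbct)`` (generators restored to the best
    validation-SSIM checkpoint of the CT-direction generator) and the
    per-epoch loss history.
    """
    config = config or TrainConfig()
    weights = weights or LossWeights()
    if val_pairs is None:
        train_pairs, val_pairs = _split(dataset, config.val_fraction, config.seed)
    else:
        train_pairs = list(dataset)
    if not train_pairs:
        raise ValueError("empty training pool")

    g_ct = Generator(generator_config, seed=config.seed)
    g_cbct = Generator(generator_config, seed=config.seed + 1)
    d_ct = Discriminator(discriminator_config, seed=config.seed + 2)
    d_cbct = Discriminator(discriminator_config, seed=config.seed + 3)
    opt_g = Adam(g_ct.parameters() + g_cbct.parameters(),
                 lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2)
    d_lr = (config.d_learning_rate if config.d_learning_rate is not None
            else config.learning_rate)
    opt_d_ct = Adam(d_ct.parameters(), lr=d_lr,
                    beta1=config.beta1, beta2=config.beta2)
    opt_d_cbct = Adam(d_cbct.parameters(), lr=d_lr,
                      beta1=config.beta1, beta2=config.beta2)

    ct_all, cbct_all = _norm_stack(train_pairs)
    n = len(train_pairs)
    adv = _adv_loss(weights.adversarial)
    lam_c, lam_i = weights.lambda_cycle, weights.lambda_identity

    history: list[LossReport] = []
    best_ssim, best_states = -np.inf, None
    for epoch in range(config.epochs):
        rng = _rng(config.seed, "cgan-epoch", epoch)
        ct_e, cbct_e = (_augment_batch(ct_all, cbct_all, rng)
                        if config.augment else (ct_all, cbct_all))
        # the two pools are shuffled independently: pairing is never used
        order_ct = rng.permutation(n)
        order_cbct = rng.permutation(n)
        epoch_terms: dict[str, list[float]] = {}
        for start in range(0, n, config.batch_size):
            xct = ct_e[order_ct[start:start + config.batch_size]]
            xcb = cbct_e[order_cbct[start:start + config.batch_size]]
            m = min(len(xct), len(xcb))
            xct, xcb = xct[:m], xcb[:m]

            # ---- generator update -------------------------------------
            for mdl in (g_ct, g_cbct, d_ct, d_cbct):
                mdl.zero_grad()
            sct, c_sct = g_ct.forward(xcb)
            scb, c_scb = g_cbct.forward(xct)
            cyc_cb, c_cyccb = g_cbct.forward(sct)
            cyc_ct, c_cycct = g_ct.forward(scb)
            id_ct_img, c_idct = g_ct.forward(xct)
            id_cb_img, c_idcb = g_cbct.forward(xcb)
            p_fake_ct, c_dct = d_ct.forward(sct)
            p_fake_cb, c_dcb = d_cbct.forward(scb)

            v_adv_ct, g_adv = adv(p_fake_ct, 1.0)
            d_sct = d_ct.backward(g_adv, c_dct)
            v_adv_cb, g_adv = adv(p_fake_cb, 1.0)
            d_scb = d_cbct.backward(g_adv, c_dcb)

            v_cyc1, g_cyc = l1_loss(cyc_cb, xcb)
            d_sct = d_sct + g_cbct.backward(lam_c * g_cyc, c_cyccb)
            v_cyc2, g_cyc = l1_loss(cyc_ct, xct)
            d_scb = d_scb + g_ct.backward(lam_c * g_cyc, c_cycct)

            v_id1, g_id = l1_loss(id_ct_img, xct)
            g_ct.backward(lam_i * g_id, c_idct)
            v_id2, g_id = l1_loss(id_cb_img, xcb)
            g_cbct.backward(lam_i * g_id, c_idcb)

            g_ct.backward(d_sct, c_sct)
            g_cbct.backward(d_scb, c_scb)
            opt_g.step()  # only generator parameters are stepped

            # ---- discriminator updates --------------------------------
            for mdl in (g_ct, g_cbct, d_ct, d_cbct):
                mdl.zero_grad()
            d_terms = {}
            for name, disc, opt_d, pool, fake in (
                    ("d_ct", d_ct, opt_d_ct, ct_e, sct),
                    ("d_cbct", d_cbct, opt_d_cbct, cbct_e, scb)):
                vals = []
                for _ in range(max(1, config.d_steps)):
                    real = pool[rng.integers(0, n, size=len(fake))]
                    p_real, c_r = disc.forward(real)
                    v_r, g_r = adv(p_real, 1.0)
                    disc.backward(g_r, c_r)
                    p_fake, c_f = disc.forward(fake)  # fake arrays are detached
                    v_f, g_f = adv(p_fake, 0.0)
                    disc.backward(g_f, c_f)
                    opt_d.step()
                    disc.zero_grad()
                    vals.append(v_r + v_f)
                d_terms[name] = float(np.mean(vals))

            step_terms = {
                "g_adv_ct": v_adv_ct, "g_adv_cbct": v_adv_cb,
                "cycle": v_cyc1 + v_cyc2, "identity": v_id1 + v_id2,
                "g_total": (v_adv_ct + v_adv_cb + lam_c * (v_cyc1 + v_cyc2)
                            + lam_i * (v_id1 + v_id2)),
                **d_terms,
            }
            for k, v in step_terms.items():
                epoch_terms.setdefault(k, []).append(v)

        val_ssim, val_mae = _validate(g_ct, val_pairs)
        terms = {k: float(np.mean(v)) for k, v in epoch_terms.items()}
        terms.update({"val_ssim": val_ssim, "val_mae_hu": val_mae})
        history.append(LossReport(epoch=epoch, terms=terms))
        history[-1].validate()
        if val_ssim > best_ssim:
            best_ssim = val_ssim
            best_states = [m.state() for m in (g_ct, g_cbct, d_ct, d_cbct)]
    if best_states is not None:
        for mdl, st in zip((g_ct, g_cbct, d_ct, d_cbct), best_states):
            mdl.load_state(st)
    for mdl in (g_ct, g_cbct):
        mdl.trained = True
    return (g_ct, g_cbct, d_ct, d_cbct), history


def translate_slice(generator: Generator, image: HUImage) -> HUImage:
    """normalize -> generate -> denormalize for a single slice."""
    x = normalize(image).pixels[None, None]
    y = generator(x)[0, 0]
    out = denormalize(y)
    return HUImage(out.pixels, image.pixel_spacing, image.slice_thickness)


def translate_volume(generator: Generator, volume: list[HUImage]) -> list[HUImage]:
    """Slice-wise translation of a CBCT volume into synthetic CT (HU)."""
    if not getattr(generator, "trained", False):
        raise ValueError("generator has not been trained "
                         "(set generator.trained = True to override)")
    return [translate_slice(generator, sl) for sl in volume]
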