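"""Training objectives: pixel-wise MAE for the supervised route and the
adversarial / cycle-consistency / identity terms of the unsupervised route.

The adversarial criterion is binary cross-entropy on the discriminator's
sigmoid patch map, averaged over patches, with real labelled 1 and synthetic
labelled 0.  A least-squares variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LossWeights", "TranslationBundle", "LossReport",
           "supervised_loss", "l1_loss", "bce_patch_loss", "lsgan_patch_loss",
           "cyclegan_losses"]

_EPS = 1e-7  # clamp for BCE away from {0,1}


@dataclass(frozen=True)
class LossWeights:
    """Relative weights of the generator loss terms (adversarial fixed at 1)."""

    lambda_cycle: float = 10.0
    lambda_identity: float = 5.0
    adversarial: str = "bce"  # "bce" | "lsgan"

    def __post_init__(self):
        if self.lambda_cycle < 0 or self.lambda_identity < 0:
            raise ValueError("loss weights must be non-negative")
        if self.adversarial not in ("bce", "lsgan"):
            raise ValueError("adversarial must be 'bce' or 'lsgan'")


@dataclass
class TranslationBundle:
    """All images produced from one (CT, CBCT) batch during a cycle step."""

    ct: np.ndarray
    cbct: np.ndarray
    sct: np.ndarray        # G_CT(CBCT)
    scbct: np.ndarray      # G_CBCT(CT)
    cycle_cbct: np.ndarray  # G_CBCT(sCT)
    cycle_ct: np.ndarray    # G_CT(sCBCT)
    id_ct: np.ndarray       # G_CT(CT)
    id_cbct: np.ndarray     # G_CBCT(CBCT)

    def __post_init__(self):
        members = [self.ct, self.cbct, self.sct, self.scbct, self.cycle_cbct,
                   self.cycle_ct, self.id_ct, self.id_cbct]
        shape = members[0].shape
        for m in members:
            if m is None:
                raise ValueError("incomplete translation bundle")
            if m.shape != shape:
                raise ValueError("bundle members must share one shape")


@dataclass
class LossReport:
    """Per-term scalar losses for one step or one epoch."""

    epoch: int = 0
    terms: dict = field(default_factory=dict)

    def __getitem__(self, k):
        return self.terms[k]

    def validate(self) -> None:
        for k, v in self.terms.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite loss term {k}: {v}")


def supervised_loss(ct: np.ndarray, sct: np.ndarray) -> float:
    """Mean absolute pixel difference (the supervised objective)."""
    ct = np.asarray(ct, dtype=np.float64)
    sct = np.asarray(sct, dtype=np.float64)
    if ct.shape != sct.shape:
        raise ValueError("shape mismatch")
    return float(np.abs(ct - sct).mean())


def l1_loss(pred: np.ndarray, target: np.ndarray):
    """L1 loss and its gradient with respect to ``pred``."""
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    diff = pred - target
    grad = np.sign(diff).astype(np.float32) / diff.size
    return float(np.abs(diff).mean()), grad


def bce_patch_loss(pred: np.ndarray, label: float):
    """Binary cross-entropy of a sigmoid patch map against a constant label,
    averaged over patches; returns (value, gradient wrt pred)."""
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    n = p.size
    value = float(-(label * np.log(p) + (1.0 - label) * np.log1p(-p)).mean())
    grad = ((p - label) / (p * (1.0 - p))).astype(np.float32) / n
    return value, grad


def lsgan_patch_loss(pred: np.ndarray, label: float):
    """Least-squares adversarial criterion (config alternative to BCE)."""
    diff = pred - label
    return float((diff ** 2).mean()), (2.0 * diff / diff.size).astype(np.float32)


def _adv(pred: np.ndarray, label: float, kind: str):
    return bce_patch_loss(pred, label) if kind == "bce" \
        else lsgan_patch_loss(pred, label)


def cyclegan_losses(bundle: TranslationBundle, d_outputs: dict,
                    weights: LossWeights | None = None) -> LossReport:
    """Scalar loss terms of one cycle-consistent adversarial step.

    ``d_outputs`` must contain patch maps 'd_ct_fake', 'd_cbct_fake' (for the
    generator's adversarial terms) and optionally 'd_ct_real', 'd_cbct_real'
    (for the discriminator terms).
    """
    w = weights or LossWeights()
    kind = w.adversarial
    terms: dict[str, float] = {}
    terms["g_adv_ct"] = _adv(d_outputs["d_ct_fake"], 1.0, kind)[0]
    terms["g_adv_cbct"] = _adv(d_outputs["d_cbct_fake"], 1.0, kind)[0]
    terms["cycle"] = supervised_loss(bundle.cycle_cbct, bundle.cbct) \
        + supervised_loss(bundle.cycle_ct, bundle.ct)
    terms["identity"] = supervised_loss(bundle.id_ct, bundle.ct) \
        + supervised_loss(bundle.id_cbct, bundle.cbct)
    terms["g_total"] = (terms["g_adv_ct"] + terms["g_adv_cbct"]
                        + w.lambda_cycle * terms["cycle"]
                        + w.lambda_identity * terms["identity"])
    for name, real_key, fake_key in (("d_ct", "d_ct_real", "d_ct_fake"),
                                     ("d_cbct", "d_cbct_real", "d_cbct_fake")):
        if real_key in d_outputs:
            terms[name] = (_adv(d_outputs[real_key], 1.0, kind)[0]
                           + _adv(d_outputs[fake_key], 0.0, kind)[0])
    report = LossReport(terms=terms)
    report.validate()
    return report
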