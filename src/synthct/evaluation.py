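"""Image-quality metrics (SSIM / PSNR / MAE), patient-wise cross-validation,
and nonparametric model comparison.

MAE is reported in HU over the body mask after rescaling from the normalized
range; SSIM and PSNR are computed on [0,1] images with data range 1.0.  SSIM
uses an 11x11 Gaussian window (sigma 1.5) with K1=0.01, K2=0.03.  Model
comparison uses the Kruskal-Wallis test with tie correction followed, when
significant, by Tukey-Kramer-type pairwise comparisons on rank sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from .types import HU_RANGE, BodyMask, HUImage

__all__ = [
    "MetricsRecord",
    "FoldSplit",
    "StatsReport",
    "compute_mae_hu",
    "compute_psnr",
    "compute_ssim",
    "kruskal_wallis",
    "make_folds",
    "cross_validate",
    "compare_models",
    "aggregate_records",
    "PSNR_CAP_DB",
]

#: Reported PSNR when the two images are identical (MSE = 0).
PSNR_CAP_DB = 100.0

METRICS = ("ssim", "psnr", "mae")


@dataclass
class MetricsRecord:
    ssim: float
    psnr: float
    mae: float
    image_id: str = ""
    model_label: str = ""
    fold: int = -1

    def __post_init__(self):
        if not -0.05 <= self.ssim <= 1.0 + 1e-9:
            raise ValueError(f"ssim out of range: {self.ssim}")
        if self.mae < 0:
            raise ValueError("mae must be >= 0")


@dataclass
class FoldSplit:
    k: int
    assignment: dict  # subject_id -> fold index

    def subjects_in(self, fold: int) -> list:
        return [s for s, f in self.assignment.items() if f == fold]


@dataclass
class StatsReport:
    """Kruskal-Wallis p-values, post-hoc decisions, and median (IQR) per
    metric and model group."""

    alpha: float = 0.01
    kruskal_p: dict = field(default_factory=dict)       # metric -> p
    kruskal_h: dict = field(default_factory=dict)       # metric -> H
    posthoc: dict = field(default_factory=dict)         # metric -> {(a,b): bool}
    medians: dict = field(default_factory=dict)         # metric -> {group: median}
    iqrs: dict = field(default_factory=dict)            # metric -> {group: IQR}


def _pixels(a) -> np.ndarray:
    return a.pixels if isinstance(a, HUImage) else np.asarray(a, dtype=np.float64)


def _region(region, shape) -> np.ndarray:
    if region is None:
        return np.ones(shape, dtype=bool)
    m = region.pixels if isinstance(region, BodyMask) else np.asarray(region, bool)
    if m.shape != shape:
        raise ValueError("region shape mismatch")
    return m


def compute_mae_hu(a, b, region=None) -> float:
    """Mean absolute error in HU over the region."""
    pa, pb = _pixels(a), _pixels(b)
    if pa.shape != pb.shape:
        raise ValueError("shape mismatch")
    m = _region(region, pa.shape)
    if not m.any():
        raise ValueError("empty region")
    return float(np.abs(pa - pb)[m].mean())


def compute_psnr(a, b, data_range: float = 1.0) -> float:
    """10*log10(range^2 / MSE) in dB, capped at ``PSNR_CAP_DB`` for MSE=0."""
    pa, pb = np.asarray(a, np.float64), np.asarray(b, np.float64)
    if pa.shape != pb.shape:
        raise ValueError("shape mismatch")
    mse = float(((pa - pb) ** 2).mean())
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(float(10.0 * np.log10(data_range ** 2 / mse)), PSNR_CAP_DB)


def compute_ssim(a, b, region=None, data_range: float = 1.0) -> float:
    """Mean local SSIM (Gaussian window 11x11, sigma 1.5), optionally averaged
    over a region mask only."""
    pa, pb = np.asarray(a, np.float64), np.asarray(b, np.float64)
    if pa.shape != pb.shape:
        raise ValueError("shape mismatch")
    if min(pa.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    mean_ssim, smap = structural_similarity(
        pa, pb, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03,
        data_range=data_range, full=True)
    if region is None:
        # standard convention: average over full-window (interior) positions
        return float(mean_ssim)
    m = _region(region, pa.shape)
    if not m.any():
        raise ValueError("empty region")
    return float(smap[m].mean())


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H statistic and p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def make_folds(subject_ids, k: int, seed: int = 0) -> FoldSplit:
    """Seeded subject-level partition into k near-equal folds."""
    ids = list(dict.fromkeys(subject_ids))  # stable unique
    if k < 1 or k > len(ids):
        raise ValueError(f"k={k} incompatible with {len(ids)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: int(i % k) for i, j in enumerate(order)}
    return FoldSplit(k=k, assignment=assignment)


def _evaluate_pairs(pairs, translate, model_label, fold):
    """Metrics of translated CBCT (or raw CBCT) against ground-truth CT."""
    from .preprocess import body_mask, normalize

    records = []
    for i, pair in enumerate(pairs):
        sct = translate(pair.cbct)
        mask = body_mask(pair.ct).pixels
        a = normalize(pair.ct).pixels
        b = normalize(sct).pixels
        records.append(MetricsRecord(
            ssim=compute_ssim(a, b, region=mask),
            psnr=compute_psnr(a, b),
            mae=compute_mae_hu(pair.ct, sct, region=mask),
            image_id=f"{pair.subject_id}/{i}",
            model_label=model_label,
            fold=fold))
    return records


def cross_validate(dataset, train_config=None, mode: str = "identity",
                   k: int = 4, seed: int = 0, loss_weights=None,
                   generator_config=None, discriminator_config=None):
    """Patient-wise k-fold cross-validation.

    For each fold, a model is trained on the other folds and evaluated on the
    held-out subjects; baseline CBCT metrics are recorded alongside.  ``mode``
    selects supervised, unsupervised, or an identity plug-in (no training;
    sCT = CBCT), the latter serving as a self-check oracle.
    """
    from . import training  # local import to avoid a cycle

    subjects = [p.subject_id for p in dataset]
    folds = make_folds(subjects, k, seed=seed)
    records: list[MetricsRecord] = []
    for fold in range(k):
        test_subjects = set(folds.subjects_in(fold))
        train_pairs = [p for p in dataset if p.subject_id not in test_subjects]
        test_pairs = [p for p in dataset if p.subject_id in test_subjects]
        if not test_pairs:
            raise ValueError(f"fold {fold} holds no images")
        assert not ({p.subject_id for p in train_pairs} & test_subjects)

        if mode == "identity":
            translate = lambda img: img.clipped()  # noqa: E731
            label = "identity sCT"
        elif mode == "supervised":
            gen, _ = training.train_supervised(
                train_pairs, train_config, generator_config=generator_config)
            translate = lambda img, g=gen: training.translate_slice(g, img)  # noqa: E731
            label = "supervised sCT"
        elif mode == "unsupervised":
            models, _ = training.train_cyclegan(
                train_pairs, train_config, weights=loss_weights,
                generator_config=generator_config,
                discriminator_config=discriminator_config)
            g_ct = models[0]
            translate = lambda img, g=g_ct: training.translate_slice(g, img)  # noqa: E731
            label = "unsupervised sCT"
        else:
            raise ValueError(f"unknown mode {mode!r}")

        records += _evaluate_pairs(test_pairs, lambda im: im.clipped(),
                                   "CBCT", fold)
        records += _evaluate_pairs(test_pairs, translate, label, fold)
    return records


def aggregate_records(records) -> pd.DataFrame:
    """Median (IQR) per model label and metric."""
    df = pd.DataFrame([{"model": r.model_label, "fold": r.fold,
                        "ssim": r.ssim, "psnr": r.psnr, "mae": r.mae}
                       for r in records])
    med = df.groupby("model")[list(METRICS)].median()
    iqr = df.groupby("model")[list(METRICS)].quantile(0.75) \
        - df.groupby("model")[list(METRICS)].quantile(0.25)
    out = med.join(iqr, lsuffix="_median", rsuffix="_iqr")
    return out


def compare_models(records_by_model: dict, alpha: float = 0.01) -> StatsReport:
    """Kruskal-Wallis across model groups per metric; when p < alpha, pairwise
    Tukey-Kramer-type decisions on mean ranks using the studentized range.

    ``records_by_model`` maps a model label to its list of MetricsRecord.
    """
    labels = list(records_by_model)
    if len(labels) < 2:
        raise ValueError("need at least two model groups")
    for lab in labels:
        if len(records_by_model[lab]) < 5:
            raise ValueError(f"group {lab!r} has fewer than 5 records")
    report = StatsReport(alpha=alpha)
    kgroups = len(labels)
    for metric in METRICS:
        groups = {lab: np.array([getattr(r, metric)
                                 for r in records_by_model[lab]], dtype=np.float64)
                  for lab in labels}
        h, p = kruskal_wallis(*groups.values())
        report.kruskal_h[metric] = h
        report.kruskal_p[metric] = p
        report.medians[metric] = {lab: float(np.median(g))
                                  for lab, g in groups.items()}
        report.iqrs[metric] = {
            lab: float(np.percentile(g, 75) - np.percentile(g, 25))
            for lab, g in groups.items()}
        decisions: dict = {}
        if p < alpha:
            pooled = np.concatenate([groups[lab] for lab in labels])
            ranks = stats.rankdata(pooled)
            n_total = len(pooled)
            mean_ranks, sizes, start = {}, {}, 0
            for lab in labels:
                n = len(groups[lab])
                mean_ranks[lab] = ranks[start:start + n].mean()
                sizes[lab] = n
                start += n
            qcrit = stats.studentized_range.ppf(1 - alpha, kgroups, np.inf)
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    se = np.sqrt(n_total * (n_total + 1) / 12.0
                                 * (1.0 / sizes[a] + 1.0 / sizes[b]))
                    diff = abs(mean_ranks[a] - mean_ranks[b])
                    decisions[(a, b)] = bool(diff > qcrit / np.sqrt(2) * se)
        else:
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    decisions[(a, b)] = False
        report.posthoc[metric] = decisions
    return report
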