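"""Synthetic slide simulator: feature stores, point patterns, labels, continua.

The generators reproduce the statistical structure the learner and the
phenotype metrics assume, at desk scale and with no downloads:

* a rare positive class — default prevalence 2%, inside the 0.02–5.6%
  band observed for vascular endothelial nuclei on real slides;
* spatial clustering of positives (microvascular hyperplasia), via a
  Neyman–Scott process: Poisson parents with Gaussian-dispersed offspring,
  against a homogeneous Poisson background of negatives;
* class-conditional Gaussian features over F=48 dimensions with a
  controllable Mahalanobis separation between class means — the learner's
  behavior depends on separability, which this parameterizes directly
  rather than mimicking real histomic marginals;
* a 1-D latent morphologic continuum in (area, eccentricity, perimeter)
  space for hypertrophy testing: f_i = g(lambda_i) + noise along a known
  quadratic curve, with a Gamma(4)-distributed latent whose closed-form
  skewness (2/sqrt(4) = 1) pins down the expected hypertrophy index.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .data_model import (
    NEGATIVE,
    POSITIVE,
    DataValidationError,
    FeatureStore,
    LabelSet,
    SlideMeta,
)

__all__ = [
    "SimConfig",
    "HypertrophyPopulation",
    "simulate_slide",
    "simulate_benchmark",
    "simulate_hypertrophy_population",
    "make_seed_labels",
    "truth_oracle",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: 5 slides x 10,000 objects (the last slide held out for
    validation), positive prevalence 2%, 48 features with class separation
    3.0 (Mahalanobis), positives clustered with ~20 offspring per parent at
    a 10 µm spread, 10 x 10 mm slides at 0.5 µm/px.
    """

    seed: int = 0
    n_slides: int = 5
    n_objects: int = 10_000  # per slide
    positive_prevalence: float = 0.02
    feature_dim: int = 48
    class_separation: float = 3.0  # Mahalanobis distance between class means
    n_informative: int = 8  # features carrying the class-mean difference
    offspring_mean: float = 20.0  # mean positives per cluster parent
    offspring_sigma_microns: float = 10.0  # cluster spread
    parent_intensity_per_mm2: float | None = None  # overrides offspring_mean when set
    slide_width_microns: float = 10_000.0
    slide_height_microns: float = 10_000.0
    mpp: float = 0.5
    validation_slides: int = 1  # trailing slides held out
    validation_per_class: int = 100
    # hypertrophy continuum
    n_hypertrophy: int = 2_000
    hypertrophy_noise_sigma: float = 0.05
    latent_shape: float = 4.0  # Gamma shape; skewness 2/sqrt(shape)

    def __post_init__(self) -> None:
        if not (0 < self.positive_prevalence < 1):
            raise DataValidationError("positive_prevalence must lie in (0, 1)")
        for name in (
            "n_slides", "n_objects", "feature_dim", "offspring_mean",
            "offspring_sigma_microns", "slide_width_microns",
            "slide_height_microns", "mpp", "n_hypertrophy", "latent_shape",
        ):
            if getattr(self, name) <= 0:
                raise DataValidationError(f"{name} must be positive")
        if self.validation_slides >= self.n_slides:
            raise DataValidationError("need at least one training slide")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _class_means(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Class means separated by the configured Mahalanobis distance.

    The mean difference is carried by the first ``n_informative`` features
    (the rest are pure noise), mirroring real histomic panels where a
    subset of shape/intensity features separates the positive class while
    most texture features carry little class signal.
    """
    f = config.feature_dim
    m = min(config.n_informative, f)
    delta = np.zeros(f)
    delta[:m] = config.class_separation / np.sqrt(m)
    return np.zeros(f), delta  # identity covariance -> Mahalanobis = separation


def simulate_slide(
    config: SimConfig, slide_index: int
) -> tuple[SlideMeta, FeatureStore, LabelSet]:
    """Simulate one slide: metadata, per-object features/centroids, truth labels.

    Negative-class centroids follow a homogeneous Poisson process
    (conditioned on the count); positives follow a Neyman–Scott cluster
    process — uniform Poisson parents, Gaussian offspring with spread
    ``offspring_sigma_microns`` — emulating microvascular clustering.
    Deterministic given (config.seed, slide_index).
    """
    rng = np.random.default_rng([config.seed, slide_index])
    w_um, h_um = config.slide_width_microns, config.slide_height_microns
    meta = SlideMeta(
        slide_id=f"slide_{slide_index:03d}",
        width_px=int(np.ceil(w_um / config.mpp)),
        height_px=int(np.ceil(h_um / config.mpp)),
        mpp=config.mpp,
        patient_id=f"patient_{slide_index:03d}",
    )
    n = config.n_objects
    if n * config.positive_prevalence < 1:
        import warnings

        warnings.warn("expected positive count < 1; slide may contain none", stacklevel=2)
    n_pos = int(rng.binomial(n, config.positive_prevalence))
    n_neg = n - n_pos

    neg_um = rng.uniform([0, 0], [w_um, h_um], size=(n_neg, 2))

    if config.parent_intensity_per_mm2 is not None:
        area_mm2 = (w_um / 1000.0) * (h_um / 1000.0)
        n_parents = max(1, int(rng.poisson(config.parent_intensity_per_mm2 * area_mm2)))
    else:
        n_parents = max(1, int(rng.poisson(max(n_pos, 1) / config.offspring_mean)))
    parents = rng.uniform([0, 0], [w_um, h_um], size=(n_parents, 2))
    assign = rng.integers(0, n_parents, size=n_pos)
    pos_um = parents[assign] + rng.normal(0, config.offspring_sigma_microns, size=(n_pos, 2))
    pos_um[:, 0] = np.clip(pos_um[:, 0], 0, np.nextafter(w_um, 0))
    pos_um[:, 1] = np.clip(pos_um[:, 1], 0, np.nextafter(h_um, 0))

    mean_neg, mean_pos = _class_means(config)
    feats = np.empty((n, config.feature_dim))
    feats[:n_neg] = rng.normal(size=(n_neg, config.feature_dim)) + mean_neg
    feats[n_neg:] = rng.normal(size=(n_pos, config.feature_dim)) + mean_pos
    centroids_um = np.vstack([neg_um, pos_um])
    y = np.concatenate([np.full(n_neg, NEGATIVE), np.full(n_pos, POSITIVE)])

    perm = rng.permutation(n)
    feats, centroids_um, y = feats[perm], centroids_um[perm], y[perm]

    object_ids = slide_index * config.n_objects + np.arange(n, dtype=np.int64)
    centroids_px = np.minimum(
        centroids_um / config.mpp,
        np.array([meta.width_px, meta.height_px]) - 1e-6,
    )
    store = FeatureStore(
        features=feats,
        object_ids=object_ids,
        slide_ids=np.full(n, meta.slide_id, dtype=object),
        centroids=centroids_px,
        feature_names=[f"f{i:02d}" for i in range(config.feature_dim)],
    )
    truth = LabelSet(role="training")
    for oid, label in zip(object_ids, y):
        truth.add(int(oid), int(label), source="truth", iteration=0)
    return meta, store, truth


def _concat_stores(stores: Sequence[FeatureStore]) -> FeatureStore:
    return FeatureStore(
        features=np.vstack([s.features for s in stores]),
        object_ids=np.concatenate([s.object_ids for s in stores]),
        slide_ids=np.concatenate([s.slide_ids for s in stores]),
        centroids=np.vstack([s.centroids for s in stores]),
        feature_names=stores[0].feature_names,
    )


def simulate_benchmark(
    config: SimConfig | None = None,
) -> tuple[list[SlideMeta], FeatureStore, LabelSet, LabelSet]:
    """Multi-slide benchmark with a held-out validation label set.

    Returns (slides, store, truth, validation). The trailing
    ``validation_slides`` slides are never used for training: ``truth``
    covers training slides only (it drives the labeling oracle), while
    ``validation`` is a class-balanced sample from the held-out slides.
    """
    config = config or SimConfig()
    metas, stores, truths = [], [], []
    for i in range(config.n_slides):
        meta, store, truth = simulate_slide(config, i)
        metas.append(meta)
        stores.append(store)
        truths.append(truth)
    store = _concat_stores(stores)
    n_train_slides = config.n_slides - config.validation_slides

    truth = LabelSet(role="training")
    for t in truths[:n_train_slides]:
        for oid, label in t.entries.items():
            truth.add(oid, label, source="truth", iteration=0)

    rng = np.random.default_rng([config.seed, 10_000 + config.n_slides])
    val_entries: dict[int, int] = {}
    for t in truths[n_train_slides:]:
        val_entries.update(t.entries)
    val_ids = np.array(sorted(val_entries))
    val_y = np.array([val_entries[o] for o in val_ids])
    validation = LabelSet(role="validation")
    for cls in (POSITIVE, NEGATIVE):
        pool = val_ids[val_y == cls]
        take = min(config.validation_per_class, len(pool))
        for oid in rng.choice(pool, size=take, replace=False):
            validation.add(int(oid), cls, source="truth", iteration=0)
    return metas, store, truth, validation


def truth_oracle(truth: LabelSet):
    """Labeling oracle backed by simulation ground truth."""

    def oracle(object_id: int) -> int:
        return truth.entries[int(object_id)]

    return oracle


def make_seed_labels(
    truth: LabelSet, per_class: int = 4, seed: int = 0
) -> LabelSet:
    """Class-balanced seed labels drawn from the truth (default 8 nuclei)."""
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(truth.entries))
    y = np.array([truth.entries[o] for o in ids])
    out = LabelSet(role="training")
    for cls in (POSITIVE, NEGATIVE):
        pool = ids[y == cls]
        if len(pool) < per_class:
            raise DataValidationError(f"not enough class {cls} objects to seed")
        for oid in rng.choice(pool, size=per_class, replace=False):
            out.add(int(oid), cls, source="seed", iteration=0)
    return out


# ---------------------------------------------------------------------------
# Hypertrophy continuum
# ---------------------------------------------------------------------------


def _continuum_curve(lam: np.ndarray) -> np.ndarray:
    """Known quadratic morphologic continuum g(lambda) in 3-space."""
    lam = np.asarray(lam, dtype=float)
    return np.column_stack([lam, 0.8 * lam**2, 0.5 * lam - 0.3 * lam**2])


@dataclass
class HypertrophyPopulation:
    """Synthetic (area, eccentricity, perimeter)-like cloud with known latent."""

    features: np.ndarray  # (n, 3)
    latent: np.ndarray  # (n,) true lambda_i, Gamma-distributed
    anchors: tuple[int, int]  # (min-latent, max-latent) row indices
    latent_shape: float
    latent_scale: float
    noise_sigma: float


def simulate_hypertrophy_population(
    config: SimConfig | None = None,
) -> HypertrophyPopulation:
    """Draw nuclei from the generative continuum model f_i = g(lambda_i) + e_i.

    The latent lambda_i ~ Gamma(shape, scale) with scale chosen so the bulk
    of the population spans the unit-parameter stretch of the curve; noise is
    isotropic Gaussian with sigma = ``hypertrophy_noise_sigma``. Anchors are
    the rows with minimal (normal-appearing) and maximal (hypertrophic)
    latent. The Gamma latent has closed-form skewness 2/sqrt(shape), so the
    expected hypertrophy index of the true latent is -2/sqrt(shape).
    """
    config = config or SimConfig()
    rng = np.random.default_rng([config.seed, 777])
    n = config.n_hypertrophy
    # scale so the latent has unit mean: the continuum then spans a few
    # units of curve parameter and the default noise (0.05) is small
    # relative to the curve's extent
    latent_scale = 1.0 / config.latent_shape
    lam = rng.gamma(config.latent_shape, latent_scale, size=n)
    feats = _continuum_curve(lam) + rng.normal(
        0, config.hypertrophy_noise_sigma, size=(n, 3)
    )
    anchors = (int(np.argmin(lam)), int(np.argmax(lam)))
    return HypertrophyPopulation(
        features=feats,
        latent=lam,
        anchors=anchors,
        latent_shape=config.latent_shape,
        latent_scale=latent_scale,
        noise_sigma=config.hypertrophy_noise_sigma,
    )
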