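"""Machine-learning acceptance threshold for localizations.

Rather than a hand-picked intensity cutoff, localizations are classified
as true or false positives by a regularized logistic regression trained on
labeled simulations at the user's own optical configuration.  Features are
quantities the deconvolution and fit already produce (fitted photons, fit
residual, blob mass and extent, sub-grid offset, crowding, local
background).  The decision threshold is chosen on a held-out third of the
labeled data to maximize recall subject to a bounded false-positive rate:
a lower recall costs measuring time, but false positives distort the
recovered structure, so the operating point favors purity.

Models are configuration-specific: the feature provenance hash refuses
application across incompatible pipelines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .admm import ADMMParams
from .bench import (
    DEFAULT_AXIAL_RADIUS_NM,
    DEFAULT_LATERAL_RADIUS_NM,
    localize_frame,
    match_localizations,
    subtract_background,
)
from .forward import NoiseModel, simulate_frame
from .optics import PSFStack
from .refine import Localization

FEATURE_NAMES = (
    "photons",
    "residual_norm",
    "blob_mass",
    "blob_voxels",
    "offset_frac",
    "nn_dist_nm",
    "local_bg",
)


class FeatureMismatchError(ValueError):
    """A model was applied to a pipeline it was not trained for."""


def stack_fingerprint(stack: PSFStack) -> str:
    """Hash of the discrete PSF a model was trained against; threshold
    models are optics-specific and refuse to transfer across stacks."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(stack.values, dtype=np.float32).tobytes())
    h.update(np.ascontiguousarray(stack.z_planes_nm).tobytes())
    return h.hexdigest()[:16]


_LOG_FEATURES = {"photons", "blob_mass"}


def feature_matrix(locs: list[Localization]) -> np.ndarray:
    """Stack localization features in the documented fixed order.

    Photon and blob-mass features enter on a log1p scale (clipped at 0):
    both span orders of magnitude, and a pathological fit can return a
    wildly inflated intensity that would otherwise dominate a linear
    classifier.
    """
    out = np.array(
        [[l.features[name] for name in FEATURE_NAMES] for l in locs], dtype=float
    ).reshape(len(locs), len(FEATURE_NAMES))
    for col, name in enumerate(FEATURE_NAMES):
        if name in _LOG_FEATURES:
            out[:, col] = np.log1p(np.clip(out[:, col], 0.0, None))
    if len(out) and not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature values")
    return out


def label_candidates(
    locs: list[Localization],
    truth,
    lateral_radius_nm: float = DEFAULT_LATERAL_RADIUS_NM,
    axial_radius_nm: float = DEFAULT_AXIAL_RADIUS_NM,
) -> np.ndarray:
    """True/false-positive labels by greedy 3D matching against the ground
    truth (one truth claims at most one localization)."""
    match = match_localizations(locs, truth, lateral_radius_nm, axial_radius_nm)
    labels = np.zeros(len(locs), dtype=bool)
    for i, _, _ in match.pairs:
        labels[i] = True
    return labels


@dataclass
class ThresholdModel:
    """Serializable trained classifier + operating threshold."""

    feature_names: tuple
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coef: np.ndarray
    intercept: float
    threshold: float
    provenance: dict = field(default_factory=dict)

    @property
    def provenance_hash(self) -> str:
        payload = json.dumps(
            {"features": list(self.feature_names), **self.provenance},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def logits(self, features: np.ndarray) -> np.ndarray:
        """Classifier decision function (threshold lives on this scale —
        probabilities saturate for well-separated classes)."""
        z = (features - self.scaler_mean) / self.scaler_scale
        return z @ self.coef + self.intercept

    def scores(self, features: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits(features)))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "feature_names": list(self.feature_names),
                    "scaler_mean": self.scaler_mean.tolist(),
                    "scaler_scale": self.scaler_scale.tolist(),
                    "coef": self.coef.tolist(),
                    "intercept": self.intercept,
                    "threshold": self.threshold,
                    "provenance": self.provenance,
                    "provenance_hash": self.provenance_hash,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=tuple(d["feature_names"]),
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_scale=np.asarray(d["scaler_scale"]),
            coef=np.asarray(d["coef"]),
            intercept=float(d["intercept"]),
            threshold=float(d["threshold"]),
            provenance=d.get("provenance", {}),
        )


def train_threshold(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    max_fp_rate: float = 0.05,
    provenance: dict | None = None,
) -> ThresholdModel:
    """Fit the classifier and choose the operating threshold.

    A deterministic seeded shuffle splits the labeled set 2:1; the logistic
    regression (L2, lbfgs) is fit on the first part and the threshold is
    the score cut maximizing held-out recall subject to a held-out
    false-positive rate (FP among accepted) of at most ``max_fp_rate``.
    Falls back to the most FP-pure cut when no threshold meets the bound.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(features) < 200:
        raise ValueError(f"need >= 200 labeled localizations, got {len(features)}")
    if labels.all() or not labels.any():
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    n_train = (2 * len(labels)) // 3
    tr, ho = order[:n_train], order[n_train:]
    if labels[tr].all() or not labels[tr].any() or labels[ho].all() or not labels[ho].any():
        # stratify manually if the shuffle unbalanced a split
        pos, neg = np.flatnonzero(labels), np.flatnonzero(~labels)
        rng = np.random.default_rng(seed)
        pos, neg = rng.permutation(pos), rng.permutation(neg)
        tr = np.concatenate([pos[: (2 * len(pos)) // 3], neg[: (2 * len(neg)) // 3]])
        ho = np.concatenate([pos[(2 * len(pos)) // 3 :], neg[(2 * len(neg)) // 3 :]])

    scaler = StandardScaler().fit(features[tr])
    clf = LogisticRegression(C=1.0, max_iter=2000, solver="lbfgs")
    clf.fit(scaler.transform(features[tr]), labels[tr])

    model = ThresholdModel(
        feature_names=FEATURE_NAMES,
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        threshold=0.0,
        provenance=provenance or {},
    )
    logits = model.logits(features[ho])
    y = labels[ho]
    uniq = np.unique(logits)
    # candidate cuts: midpoints between neighboring held-out scores, plus
    # one below and one above the observed range
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best_thr, best_recall = None, -1.0
    fallback = (np.inf, cuts[-1])
    for thr in cuts:
        acc = logits >= thr
        if not acc.any():
            continue
        fp_rate = np.sum(acc & ~y) / np.sum(acc)
        recall = np.sum(acc & y) / max(np.sum(y), 1)
        fallback = min(fallback, (fp_rate, float(thr)))
        if fp_rate <= max_fp_rate and recall > best_recall:
            best_recall, best_thr = recall, float(thr)
    if best_thr is None:
        # no cut is pure enough; take the one with the lowest FP rate
        best_thr = fallback[1]
    model.threshold = best_thr
    model.provenance = {
        **model.provenance,
        "n_labeled": int(len(labels)),
        "n_positive": int(labels.sum()),
        "seed": int(seed),
        "max_fp_rate": max_fp_rate,
    }
    return model


def apply_threshold(
    locs: list[Localization], model: ThresholdModel
) -> list[Localization]:
    """Set ``accepted`` on each localization (rejected ones are retained).

    Raises :class:`FeatureMismatchError` when the model's feature
    definition does not match the pipeline's.
    """
    if tuple(model.feature_names) != FEATURE_NAMES:
        raise FeatureMismatchError(
            "model feature definition does not match this pipeline"
        )
    if not locs:
        return locs
    logits = model.logits(feature_matrix(locs))
    for loc, s in zip(locs, logits):
        loc.accepted = bool(s >= model.threshold)
        loc.features["ml_score"] = float(s)
    return locs


def train_from_simulation(
    stack: PSFStack,
    seed: int,
    densities: tuple[float, ...] = (0.2, 0.4, 0.7, 1.0),
    frames_per_density: int = 3,
    field_px: int = 64,
    noise: NoiseModel | None = None,
    params: ADMMParams | None = None,
    photon_median: float = 3000.0,
    max_fp_rate: float = 0.05,
) -> ThresholdModel:
    """Self-train a threshold model at the user's optical configuration.

    Simulates labeled frames spanning the working density range, runs the
    deconvolve/refine pipeline, labels against ground truth and calls
    :func:`train_threshold`.  Fully deterministic for a fixed seed.
    """
    noise = noise or NoiseModel()
    params = params or ADMMParams(log_every=0)
    feats, labels = [], []
    for di, density in enumerate(densities):
        for f in range(frames_per_density):
            fseed = seed + 7919 * (di + 1) + f
            frame, truth = simulate_frame(
                density,
                stack,
                field_px=field_px,
                noise=NoiseModel(
                    noise.background, noise.read_noise_sd, noise.gain, seed=fseed + 500
                ),
                photon_median=photon_median,
                seed=fseed,
            )
            locs = localize_frame(subtract_background(frame), stack, params)
            if not locs:
                continue
            feats.append(feature_matrix(locs))
            labels.append(label_candidates(locs, truth))
    features = np.concatenate(feats) if feats else np.zeros((0, len(FEATURE_NAMES)))
    labels = np.concatenate(labels) if labels else np.zeros(0, dtype=bool)
    return train_threshold(
        features,
        labels,
        seed=seed,
        max_fp_rate=max_fp_rate,
        provenance={
            "stack_fingerprint": stack_fingerprint(stack),
            "densities": list(densities),
            "frames_per_density": frames_per_density,
            "field_px": field_px,
            "photon_median": photon_median,
            "noise_background": noise.background,
            "train_seed": seed,
        },
    )
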