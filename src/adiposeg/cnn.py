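"""CNN-based segmentation: the :class:`UNetSegmenter` estimator, cohort
splitting, and volume-level inference.

``UNetSegmenter`` follows the scikit-learn estimator protocol — seeded
``fit(X, y)`` on stacks of grayscale slices with 3-class masks,
``predict``/``predict_proba``, ``get_params``/``set_params`` — so it
composes with sklearn model selection.  Training minimises categorical
cross-entropy with the adaptive-moment (Adam) optimizer, by default for
15 epochs at batch size 16.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from skimage.transform import resize

from .core import CohortManifest, LabelMap, VolumeImage
from .nn.unet import UNet

__all__ = ["UNetSegmenter", "build_model", "split_dataset",
           "normalize_volume", "volume_to_slices", "predict_volume"]


def build_model(input_size=(384, 384), encoder_channels=(16, 32, 64),
                bottleneck_channels=128, n_classes=3, dropout_rate=0.5,
                convs_per_block=2, seed=0) -> UNet:
    """Construct the untrained encoder–decoder network (paper-scale defaults)."""
    return UNet(input_size=input_size, encoder_channels=encoder_channels,
                bottleneck_channels=bottleneck_channels, n_classes=n_classes,
                dropout_rate=dropout_rate, convs_per_block=convs_per_block,
                seed=seed)


class UNetSegmenter(BaseEstimator):
    """3-class (background/SAT/VAT) slice segmenter.

    Parameters mirror the architecture and training protocol: three
    down-sampling steps with ``encoder_channels`` feature widths, batch
    size 16, categorical cross-entropy, Adam.  ``fit`` expects
    ``X`` of shape (n_slices, H, W) with intensities in [0, 1] and ``y``
    of the same spatial shape with classes in {0, 1, 2}.

    Attributes
    ----------
    net_ : UNet
        The fitted network.
    history_ : dict
        Per-epoch ``loss`` and (if validation data given) ``val_loss``.
    """

    def __init__(self, input_size=(384, 384), encoder_channels=(16, 32, 64),
                 bottleneck_channels=128, dropout_rate=0.5, convs_per_block=2,
                 epochs=15, batch_size=16, learning_rate=1e-3,
                 class_weights=None, random_state=0):
        self.input_size = input_size
        self.encoder_channels = encoder_channels
        self.bottleneck_channels = bottleneck_channels
        self.dropout_rate = dropout_rate
        self.convs_per_block = convs_per_block
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.class_weights = class_weights
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_slices, H, W), got shape {X.shape}")
        if y.shape != X.shape:
            raise ValueError(
                f"image/mask size mismatch: X {X.shape} vs y {y.shape}")
        if tuple(X.shape[1:]) != tuple(self.input_size):
            raise ValueError(
                f"slices are {X.shape[1:]}, model input is {self.input_size}")
        if not np.isin(np.unique(y), [0, 1, 2]).all():
            raise ValueError("mask values must be in {0, 1, 2}")
        return X, y.astype(np.int64)

    def fit(self, X, y, validation_data=None):
        """Seeded training; records per-epoch train (and val) loss."""
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        X, y = self._validate_xy(X, y)
        if validation_data is not None:
            Xv, yv = self._validate_xy(*validation_data)
        net = build_model(input_size=self.input_size,
                          encoder_channels=self.encoder_channels,
                          bottleneck_channels=self.bottleneck_channels,
                          dropout_rate=self.dropout_rate,
                          convs_per_block=self.convs_per_block,
                          seed=self.random_state)
        opt = net.make_optimizer(self.learning_rate)
        rng = np.random.default_rng(self.random_state)
        cw = (None if self.class_weights is None
              else np.asarray(self.class_weights, dtype=np.float64))
        history = {"loss": [], "val_loss": []}
        n = len(X)
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, counts = [], []
            for i in range(0, n, self.batch_size):
                idx = order[i:i + self.batch_size]
                loss = net.train_step(opt, X[idx][:, None], y[idx],
                                      class_weights=cw)
                losses.append(loss)
                counts.append(len(idx))
            history["loss"].append(float(np.average(losses, weights=counts)))
            if validation_data is not None:
                history["val_loss"].append(
                    net.evaluate_loss(Xv[:, None], yv,
                                      batch_size=self.batch_size,
                                      class_weights=cw))
        if validation_data is None:
            del history["val_loss"]
        self.net_ = net
        self.history_ = history
        self.n_features_in_ = int(np.prod(self.input_size))
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(n_slices, H, W) → per-pixel class probabilities (n, 3, H, W)."""
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or tuple(X.shape[1:]) != tuple(self.input_size):
            raise ValueError(f"X must be (n, {self.input_size[0]}, "
                             f"{self.input_size[1]}), got {X.shape}")
        out = []
        for i in range(0, len(X), self.batch_size):
            out.append(self.net_.predict_proba(X[i:i + self.batch_size][:, None]))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """Argmax class maps; ties break toward the lower class index."""
        return np.argmax(self.predict_proba(X), axis=1).astype(np.uint8)

    # ------------------------------------------------------------------

    def save(self, path) -> None:
        """Persist weights plus a JSON snapshot of the configuration."""
        check_is_fitted(self, "net_")
        import json
        from pathlib import Path
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        weights = self.net_.get_weights()
        np.savez(path / "weights.npz",
                 **{f"w{i}": w for i, w in enumerate(weights)})
        snapshot = {"params": self.get_params(), "history": self.history_}
        (path / "config.json").write_text(json.dumps(snapshot, indent=2))

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        import json
        from pathlib import Path
        path = Path(path)
        snapshot = json.loads((path / "config.json").read_text())
        params = snapshot["params"]
        for key in ("input_size", "encoder_channels"):
            params[key] = tuple(params[key])
        if params.get("class_weights") is not None:
            params["class_weights"] = tuple(params["class_weights"])
        est = cls(**params)
        with np.load(path / "weights.npz") as z:
            weights = [z[f"w{i}"] for i in range(len(z.files))]
        est.net_ = build_model(input_size=est.input_size,
                               encoder_channels=est.encoder_channels,
                               bottleneck_channels=est.bottleneck_channels,
                               dropout_rate=est.dropout_rate,
                               convs_per_block=est.convs_per_block,
                               seed=est.random_state)
        est.net_.set_weights(weights)
        est.history_ = snapshot["history"]
        est.n_features_in_ = int(np.prod(est.input_size))
        return est


# ---------------------------------------------------------------- cohort

def _tertile_bins(values: np.ndarray) -> np.ndarray:
    qs = np.quantile(values, [1 / 3, 2 / 3])
    return np.digitize(values, qs)


def split_dataset(m: CohortManifest, fractions=(0.50, 0.06, 0.44),
                  strata=("age", "bmi"), seed: int = 0) -> CohortManifest:
    """Subject-level train/val/test assignment, stratified on age and BMI
    tertiles (within group) so the splits stay demographically balanced.

    Whole subjects — never individual slices — are assigned, to prevent
    information leakage between splits.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    subjects = list(m.subjects)
    n = len(subjects)
    rng = np.random.default_rng(seed)

    keys = []
    age = np.array([s.age for s in subjects])
    bmi = np.array([s.bmi for s in subjects])
    aget, bmit = _tertile_bins(age), _tertile_bins(bmi)
    for i, s in enumerate(subjects):
        key = [s.group]
        if "age" in strata:
            key.append(int(aget[i]))
        if "bmi" in strata:
            key.append(int(bmit[i]))
        keys.append(tuple(key))

    strata_map: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        strata_map.setdefault(k, []).append(i)
    if any(len(v) < 3 for v in strata_map.values()):
        warnings.warn("a stratum has fewer than 3 subjects; "
                      "falling back to group-only stratification")
        strata_map = {}
        for i, s in enumerate(subjects):
            strata_map.setdefault((s.group,), []).append(i)

    def largest_remainder(total, fracs):
        ideal = np.array(fracs) * total
        base = np.floor(ideal).astype(int)
        rem = total - base.sum()
        order = np.argsort(-(ideal - base))
        for j in order[:rem]:
            base[j] += 1
        return base

    global_counts = largest_remainder(n, fractions)
    remaining = global_counts.copy()
    names = ("train", "val", "test")
    assignment = [None] * n
    # large strata first so the global quota constrains only the tail
    for key in sorted(strata_map, key=lambda k: -len(strata_map[k])):
        idxs = np.array(strata_map[key])
        rng.shuffle(idxs)
        counts = largest_remainder(len(idxs), fractions)
        counts = np.minimum(counts, remaining)
        while counts.sum() < len(idxs):  # give the slack to the largest split
            counts[int(np.argmax(remaining - counts))] += 1
        pos = 0
        for which, c in enumerate(counts):
            for i in idxs[pos:pos + c]:
                assignment[i] = names[which]
            pos += c
        remaining = remaining - counts

    out = []
    for s, a in zip(subjects, assignment):
        rec = type(s)(**{**s.__dict__, "split": a})
        out.append(rec)
    return CohortManifest(subjects=out)


# --------------------------------------------------------------- volumes

def normalize_volume(v: VolumeImage) -> np.ndarray:
    """Per-volume min–max normalization to [0, 1]."""
    data = np.asarray(v.data, dtype=np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def volume_to_slices(v: VolumeImage, gt: LabelMap | None = None):
    """Normalized axial slice stack (z-major), optionally with mask slices."""
    norm = normalize_volume(v)
    X = np.moveaxis(norm, 2, 0)
    if gt is None:
        return X
    if gt.shape != v.shape:
        raise ValueError("image/mask size mismatch")
    y = np.moveaxis(gt.classes, 2, 0)
    return X, y


def predict_volume(model: UNetSegmenter, v: VolumeImage) -> LabelMap:
    """Slicewise inference on a whole volume.

    Slices are min–max normalized per volume and resampled to the model's
    input size if needed; the predicted class grid is mapped back to the
    volume's grid with nearest-neighbour interpolation.
    """
    if v.spacing is None or any(s <= 0 for s in v.spacing):
        raise ValueError("volume spacing metadata is required for prediction")
    X = volume_to_slices(v)
    in_shape = X.shape[1:]
    target = tuple(model.input_size)
    if in_shape != target:
        X = np.stack([resize(sl, target, order=1, preserve_range=True,
                             anti_aliasing=False) for sl in X]).astype(np.float32)
    labels = model.predict(X)
    if in_shape != target:
        labels = np.stack([resize(sl, in_shape, order=0, preserve_range=True,
                                  anti_aliasing=False).astype(np.uint8)
                           for sl in labels])
    return LabelMap(classes=np.moveaxis(labels, 0, 2), spacing=v.spacing,
                    subject_id=v.subject_id)
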