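"""The multi-channel 2D U-Net segmenter and its training loop.

The model consumes ``[H, W, 4]`` slices (water, fat, fat-fraction, R2*
channels in canonical order, at their original signal intensities — no
normalisation, no cropping) and emits a per-pixel vertebra probability map.
Training minimises the soft-Jaccard distance with Adam (learning rate 1e-4,
batch size 4 by default), holds out whole subjects for validation, and early
stopping restores the best-validation-loss weights.

The public surface follows scikit-learn conventions
(:class:`VertebraSegmenter` with ``fit`` / ``predict_proba`` / ``predict``);
the module-level functions are thin wrappers operating on
:class:`~spinefat.io_dixon.DixonSeries` / :class:`~spinefat.io_dixon.MaskVolume`
pairs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from .errors import SpinefatError, ValidationError
from .io_dixon import DixonSeries, MaskVolume, check_same_geometry


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    ``validation_fraction_subjects`` is the fraction of subjects held out for
    validation (default 7/31); ``model_scale`` multiplies the base filter
    count of 64 so reduced models can be trained on a desktop CPU.
    """

    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 100
    early_stopping_patience: int = 10
    validation_fraction_subjects: float = 7 / 31
    threshold: float = 0.5
    seed: int = 0
    model_scale: float = 1.0
    depth: int = 4
    smooth: float = 100.0
    bce_weight: float = 0.1

    def validate(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValidationError("threshold must lie strictly in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValidationError("batch_size and max_epochs must be >= 1")
        if not (0.0 < self.validation_fraction_subjects < 1.0):
            raise ValidationError("validation_fraction_subjects must lie in (0, 1)")


def jaccard_distance_loss(
    y_true: np.ndarray, y_pred: np.ndarray, smooth: float = 100.0
) -> float:
    """Soft-Jaccard distance ``1 - (|I| + s) / (|U| + s)`` over pixels.

    ``I = sum(y_true * y_pred)`` and ``U = sum(y_true) + sum(y_pred) - I``.
    ``y_true`` must be binary, ``y_pred`` a probability map of the same
    shape.  Zero exactly when ``y_pred == y_true`` on binary inputs; for
    binary predictions and ``smooth -> 0`` it equals ``1 - IoU``.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"shape mismatch: y_true {y_true.shape} vs y_pred {y_pred.shape}"
        )
    inter = float((y_true * y_pred).sum())
    union = float(y_true.sum() + y_pred.sum() - inter)
    return 1.0 - (inter + smooth) / (union + smooth)


class VertebraSegmenter(BaseEstimator):
    """2D multi-channel U-Net vertebra segmenter (scikit-learn style).

    Parameters mirror :class:`TrainConfig`; ``base_filters`` is the top-level
    filter count at ``model_scale=1.0``.

    Fitted attributes
    -----------------
    ``model_`` : the underlying network, ``history_`` : per-epoch train and
    validation losses, ``best_epoch_`` : epoch whose weights were restored,
    ``input_shape_`` : accepted ``(H, W, C)``.
    """

    def __init__(
        self,
        learning_rate: float = 1e-4,
        batch_size: int = 4,
        max_epochs: int = 100,
        early_stopping_patience: int = 10,
        validation_fraction_subjects: float = 7 / 31,
        threshold: float = 0.5,
        seed: int = 0,
        model_scale: float = 1.0,
        depth: int = 4,
        smooth: float = 100.0,
        bce_weight: float = 0.1,
        base_filters: int = 64,
    ):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stopping_patience = early_stopping_patience
        self.validation_fraction_subjects = validation_fraction_subjects
        self.threshold = threshold
        self.seed = seed
        self.model_scale = model_scale
        self.depth = depth
        self.smooth = smooth
        self.bce_weight = bce_weight
        self.base_filters = base_filters

    # -- construction -------------------------------------------------------

    def _scaled_base(self) -> int:
        return max(1, int(round(self.base_filters * self.model_scale)))

    def init_model(self, input_size: tuple[int, int], n_channels: int = 4) -> "VertebraSegmenter":
        """Build the (untrained) network for a given slice geometry."""
        h, w = input_size
        div = 2**self.depth
        if h % div or w % div:
            raise ValidationError(
                f"input size {input_size} not divisible by 2^{self.depth}; "
                f"pad slices to a multiple of {div}"
            )
        self.model_ = _nn.UNet(
            in_channels=n_channels, base=self._scaled_base(), depth=self.depth, seed=self.seed
        )
        self.input_shape_ = (h, w, n_channels)
        self.history_ = {"train_loss": [], "val_loss": []}
        return self

    # -- training ------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, groups: Sequence | None = None):
        """Train on slices ``X [n, H, W, C]`` against binary masks ``y [n, H, W]``.

        ``groups`` gives the subject of each slice; the validation split is
        by whole subjects (never slices), matching how clinical hold-outs are
        defined.  Every slice enters training, including vertebra-free ones.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 4 or y.ndim != 3 or X.shape[:3] != y.shape:
            raise ValidationError(f"incompatible shapes X {X.shape}, y {y.shape}")
        if X.shape[0] == 0:
            raise ValidationError("empty training cohort")
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            early_stopping_patience=self.early_stopping_patience,
            validation_fraction_subjects=self.validation_fraction_subjects,
            threshold=self.threshold,
            seed=self.seed,
            model_scale=self.model_scale,
            depth=self.depth,
            smooth=self.smooth,
            bce_weight=self.bce_weight,
        )
        cfg.validate()
        if groups is None:
            groups = np.arange(X.shape[0])
        groups = np.asarray(groups)

        rng = np.random.default_rng(self.seed)
        uniq = np.unique(groups)
        if len(uniq) < 2:
            raise ValidationError("need >= 2 subjects (>= 1 train, >= 1 validation)")
        n_val = max(1, int(round(len(uniq) * self.validation_fraction_subjects)))
        n_val = min(n_val, len(uniq) - 1)
        perm = rng.permutation(uniq)
        val_subjects = set(perm[:n_val].tolist())
        val_idx = np.flatnonzero([g in val_subjects for g in groups])
        train_idx = np.flatnonzero([g not in val_subjects for g in groups])

        if not hasattr(self, "model_") or self.input_shape_ != X.shape[1:]:
            self.init_model(X.shape[1:3], X.shape[3])
            # scale-aware initialisation: channel magnitudes differ by orders
            # of magnitude and the inputs themselves are never normalised
            Xtr = X[train_idx]
            self.model_.fold_input_scaling(
                Xtr.mean(axis=(0, 1, 2)), Xtr.std(axis=(0, 1, 2))
            )
        model = self.model_
        opt = _nn.Adam(model.parameters(), lr=self.learning_rate)

        best_val = np.inf
        best_weights = model.get_weights()
        best_epoch = 0
        patience_left = self.early_stopping_patience
        self.history_ = {"train_loss": [], "val_loss": []}
        self.train_subjects_ = sorted(set(uniq.tolist()) - val_subjects)
        self.val_subjects_ = sorted(val_subjects)

        for epoch in range(self.max_epochs):
            order = rng.permutation(train_idx)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(order), self.batch_size):
                bidx = order[start : start + self.batch_size]
                z = model.forward(X[bidx], train=True)
                loss, dz = _nn.soft_jaccard_loss_and_grad(
                    y[bidx], z, self.smooth, self.bce_weight
                )
                if not np.isfinite(loss):
                    raise SpinefatError(
                        f"NaN/inf loss at epoch {epoch}, batch {n_batches}; "
                        "check input scaling or lower the learning rate"
                    )
                model.backward(dz)
                opt.step(model.gradients())
                epoch_loss += loss
                n_batches += 1
            val_loss = self._eval_loss(X[val_idx], y[val_idx])
            self.history_["train_loss"].append(epoch_loss / max(n_batches, 1))
            self.history_["val_loss"].append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_weights = model.get_weights()
                best_epoch = epoch
                patience_left = self.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        model.set_weights(best_weights)
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = best_val
        return self

    def _eval_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        if X.shape[0] == 0:
            return np.nan
        total = 0.0
        n = 0
        for start in range(0, X.shape[0], self.batch_size):
            z = self.model_.forward(X[start : start + self.batch_size], train=False)
            loss, _ = _nn.soft_jaccard_loss_and_grad(
                y[start : start + self.batch_size], z, self.smooth, self.bce_weight
            )
            total += loss * z.shape[0]
            n += z.shape[0]
        return total / n

    # -- inference -----------------------------------------------------------

    def predict_proba(self, X: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Per-pixel vertebra probabilities for slices ``X [n, H, W, C]``."""
        if not hasattr(self, "model_"):
            raise SpinefatError("model is not fitted/initialised")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1:] != self.input_shape_:
            raise ValidationError(
                f"input shape {X.shape[1:]} does not match model contract {self.input_shape_}"
            )
        out = np.empty(X.shape[:3], dtype=np.float64)
        for start in range(0, X.shape[0], batch_size):
            z = self.model_.forward(X[start : start + batch_size], train=False)
            out[start : start + batch_size] = _nn.sigmoid(z.astype(np.float64))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary masks at the configured threshold (strict ``>``)."""
        return (self.predict_proba(X) > self.threshold).astype(np.uint8)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean per-volume Dice coefficient of ``predict(X)`` against ``y``."""
        pred = self.predict(X).astype(bool)
        truth = np.asarray(y).astype(bool)
        tp = np.logical_and(pred, truth).sum()
        denom = pred.sum() + truth.sum()
        return 1.0 if denom == 0 else 2.0 * tp / denom

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Single-file checkpoint: weights + config snapshot + history."""
        if not hasattr(self, "model_"):
            raise SpinefatError("nothing to save: model is not initialised")
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "params": self.get_params(),
            "input_shape": list(self.input_shape_),
            "history": getattr(self, "history_", {}),
            "best_epoch": getattr(self, "best_epoch_", None),
        }
        weights = {f"w{i}": w for i, w in enumerate(self.model_.get_weights())}
        np.savez_compressed(path, meta=json.dumps(meta), **weights)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "VertebraSegmenter":
        with np.load(str(path), allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            weights = [archive[f"w{i}"] for i in range(len(archive.files) - 1)]
        est = cls(**meta["params"])
        h, w, c = meta["input_shape"]
        est.init_model((h, w), c)
        est.model_.set_weights(weights)
        est.history_ = meta.get("history", {})
        if meta.get("best_epoch") is not None:
            est.best_epoch_ = meta["best_epoch"]
        return est


# ---------------------------------------------------------------------------
# thin wrappers over the estimator, operating on the domain types
# ---------------------------------------------------------------------------

def build_unet(
    input_size: tuple[int, int],
    n_channels: int = 4,
    model_scale: float = 1.0,
    depth: int = 4,
    seed: int = 0,
) -> VertebraSegmenter:
    """Construct an untrained U-Net for ``input_size`` slices."""
    est = VertebraSegmenter(model_scale=model_scale, depth=depth, seed=seed)
    return est.init_model(input_size, n_channels)


def cohort_to_arrays(
    cohort: Sequence[tuple[DixonSeries, MaskVolume]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a (series, mask) cohort into ``(X, y, groups)`` slice arrays."""
    if not cohort:
        raise ValidationError("empty cohort")
    xs, ys, gs = [], [], []
    for series, mask in cohort:
        check_same_geometry(mask, series)
        xs.append(series.channel_stack())
        ys.append(mask.data.astype(np.float32))
        gs.extend([series.subject_id] * series.n_slices)
    return np.concatenate(xs), np.concatenate(ys), np.asarray(gs)


def train_model(
    model: VertebraSegmenter,
    cohort: Sequence[tuple[DixonSeries, MaskVolume]],
    config: TrainConfig | None = None,
) -> VertebraSegmenter:
    """Train ``model`` on a cohort of (series, ground-truth mask) pairs."""
    if config is not None:
        config.validate()
        model.set_params(**asdict(config))
    X, y, groups = cohort_to_arrays(cohort)
    return model.fit(X, y, groups=groups)


def predict_proba(model: VertebraSegmenter, series: DixonSeries) -> MaskVolume:
    """Slice-wise inference over a whole series -> probability mask."""
    probs = model.predict_proba(series.channel_stack())
    return MaskVolume(np.clip(probs, 0.0, 1.0), kind="probability")


def binarize(prob: MaskVolume, threshold: float = 0.5) -> MaskVolume:
    """Threshold a probability mask: pixel -> 1 iff p > threshold."""
    if prob.kind != "probability":
        raise ValidationError("binarize expects a probability mask")
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must lie strictly in (0, 1)")
    return MaskVolume((prob.data > threshold).astype(np.uint8), kind="binary")
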