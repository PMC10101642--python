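"""Risk classifiers over profile images.

:class:`TGanDClassifier` trains the AC-WGAN-GP on the training images and
then uses the *frozen* critic's auxiliary softmax head as a standalone
low/high-risk classifier (transfer learning: no further updates happen at
prediction time).  :class:`BenchmarkCNN` is the reference discriminative
model: the same convolutional trunk shape trained directly with
cross-entropy, batch normalisation and ReLU, for a fixed number of epochs.

Both follow the scikit-learn estimator contract (``fit`` /
``predict_proba`` / ``predict``, ``get_params``/``set_params``) and can be
cloned by sklearn model-selection utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _autodiff as ad
from ._autodiff import Tensor
from . import nn
from .acwgan import GanConfig, TrainedGan, train_gan, generate_synthetic


@dataclass
class Prediction:
    patient_id: str
    predicted: int  # 0 = LOW, 1 = HIGH
    score: float    # P(HIGH)
    fold: int = -1


def _check_images(X):
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError("X must be (n, side, side) profile images")
    return X


def tgand_predict(gan: TrainedGan, images, patient_ids=None,
                  threshold: float = 0.5, fold: int = -1) -> list[Prediction]:
    """Classify images with the frozen critic's auxiliary head.

    The softmax of the class logits gives P(HIGH); a score at or above the
    threshold predicts HIGH (ties go to the alert class).  The critic's
    parameters are bit-identical before and after.
    """
    X = _check_images(images)
    if X.shape[1] != gan.side:
        raise ValueError(f"image side {X.shape[1]} does not match gan side {gan.side}")
    if patient_ids is None:
        patient_ids = [str(i) for i in range(len(X))]
    before = nn.params_digest(gan.critic.params())
    with ad.no_grad():
        logits = gan.critic.logits(Tensor(X[:, None]))
        probs = ad.softmax(logits, axis=1).data
    after = nn.params_digest(gan.critic.params())
    assert before == after, "critic parameters changed during prediction"
    out = []
    for pid, p in zip(patient_ids, probs):
        score = float(p[1])
        out.append(Prediction(pid, int(score >= threshold), score, fold))
    return out


def predictions_to_frame(preds: list[Prediction], true_labels=None) -> pd.DataFrame:
    df = pd.DataFrame([{"patient_id": p.patient_id, "fold": p.fold,
                        "score": p.score, "predicted": p.predicted} for p in preds])
    if true_labels is not None:
        df["true_label"] = [true_labels[p.patient_id] for p in preds]
    return df


class TGanDClassifier(ClassifierMixin, BaseEstimator):
    """Trained-GAN-discriminator risk classifier.

    ``fit`` trains the full AC-WGAN-GP on the training images; the critic is
    then frozen and its auxiliary head does the classifying.  Parameters
    mirror :class:`~tgand.acwgan.GanConfig`.
    """

    def __init__(self, z_dim=250, epochs=1000, batch_size=32, lr=5e-5,
                 gp_lambda=10.0, leaky_slope=0.2, warmup_runs=3,
                 gen_filters=(128, 64), critic_filters=(64, 128),
                 label_embed_dim=50, aux_on_fake=True, critic_steps_per_gen=1,
                 decision_threshold=0.5, random_state=0):
        self.z_dim = z_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.gp_lambda = gp_lambda
        self.leaky_slope = leaky_slope
        self.warmup_runs = warmup_runs
        self.gen_filters = gen_filters
        self.critic_filters = critic_filters
        self.label_embed_dim = label_embed_dim
        self.aux_on_fake = aux_on_fake
        self.critic_steps_per_gen = critic_steps_per_gen
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    def _config(self) -> GanConfig:
        return GanConfig(
            z_dim=self.z_dim, epochs=self.epochs, batch_size=self.batch_size,
            lr=self.lr, gp_lambda=self.gp_lambda, leaky_slope=self.leaky_slope,
            warmup_runs=self.warmup_runs, gen_filters=tuple(self.gen_filters),
            critic_filters=tuple(self.critic_filters),
            label_embed_dim=self.label_embed_dim, aux_on_fake=self.aux_on_fake,
            critic_steps_per_gen=self.critic_steps_per_gen,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = _check_images(X)
        y = np.asarray(y, dtype=np.int64)
        self.classes_ = np.unique(y)
        self.gan_ = train_gan(X, y, self._config())
        self.side_ = self.gan_.side
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "gan_")
        preds = tgand_predict(self.gan_, X, threshold=self.decision_threshold)
        p_high = np.array([p.score for p in preds])
        return np.column_stack([1.0 - p_high, p_high])

    def predict(self, X):
        scores = self.predict_proba(X)[:, 1]
        return (scores >= self.decision_threshold).astype(np.int64)


class _CnnNet(nn.Module):
    """Conv trunk mirroring the critic's shape + batch norm + ReLU head."""

    def __init__(self, side, filters, n_classes, rng):
        c0, c1 = filters
        self.conv1 = nn.Conv2d(1, c0, rng)
        self.bn1 = nn.BatchNorm2d(c0)
        self.conv2 = nn.Conv2d(c0, c1, rng)
        self.bn2 = nn.BatchNorm2d(c1)
        self.flat_dim = (side // 4) ** 2 * c1
        self.head = nn.Dense(self.flat_dim, n_classes, rng)
        self.training = True

    def _children(self):
        return (self.conv1, self.bn1, self.conv2, self.bn2, self.head)

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.relu(self.bn1(self.conv1(x)))
        h = ad.relu(self.bn2(self.conv2(h)))
        return self.head(ad.reshape(h, (h.shape[0], self.flat_dim)))


class BenchmarkCNN(ClassifierMixin, BaseEstimator):
    """Plain CNN baseline trained with cross-entropy for a fixed epoch count."""

    def __init__(self, epochs=1250, batch_size=32, lr=5e-5,
                 filters=(64, 128), random_state=0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.filters = filters
        self.random_state = random_state

    def fit(self, X, y):
        X = _check_images(X)
        y = np.asarray(y, dtype=np.int64)
        counts = np.bincount(y, minlength=2)
        if (counts == 0).any():
            raise ValueError("single-class data")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.classes_ = np.unique(y)
        ss = np.random.SeedSequence(self.random_state)
        s_init, s_order = ss.spawn(2)
        net = _CnnNet(X.shape[1], tuple(self.filters), 2,
                      np.random.default_rng(s_init))
        opt = nn.RMSprop(net.params(), lr=self.lr)
        rng_order = np.random.default_rng(s_order)
        n = len(X)
        log = []
        for epoch in range(self.epochs):
            order = rng_order.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = net(Tensor(X[idx][:, None]))
                loss = ad.softmax_cross_entropy(logits, y[idx])
                if not np.isfinite(loss.item()):
                    raise RuntimeError(f"non-finite CNN loss at epoch {epoch}")
                grads = ad.grad(loss, net.params())
                opt.step(grads)
                losses.append(loss.item())
            log.append({"epoch": epoch, "loss": float(np.mean(losses))})
        self.net_ = net
        self.side_ = X.shape[1]
        self.log_ = pd.DataFrame(log)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        X = _check_images(X)
        self.net_.set_training(False)
        try:
            with ad.no_grad():
                probs = ad.softmax(self.net_(Tensor(X[:, None])), axis=1).data
        finally:
            self.net_.set_training(True)
        return probs.astype(np.float64)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)


def train_cnn(images, labels, epochs=1250, seed=0, **kwargs) -> BenchmarkCNN:
    """Convenience wrapper fitting a :class:`BenchmarkCNN`."""
    return BenchmarkCNN(epochs=epochs, random_state=seed, **kwargs).fit(images, labels)


def augment_with_synthetic(train_images, train_labels, gan: TrainedGan,
                           multiplier: int = 2, seed: int = 0):
    """Extend a training set with ``multiplier × n`` generator samples.

    Synthetic class counts follow the real training set's class
    proportions; synthetic samples carry their conditioning class as label.
    Returns (X, y, is_synthetic).
    """
    X = _check_images(train_images)
    y = np.asarray(train_labels, dtype=np.int64)
    n = len(X)
    if multiplier == 0:
        return X, y, np.zeros(n, dtype=bool)
    if X.shape[1] != gan.side:
        raise ValueError("training images do not match the gan's layout side")
    counts = np.bincount(y, minlength=gan.config.n_classes)
    want = np.round(counts / counts.sum() * n * multiplier).astype(int)
    # rounding drift goes to the largest class so the total is exact
    drift = n * multiplier - want.sum()
    want[np.argmax(counts)] += drift
    n_max = int(want.max())
    Xs_all, ys_all = generate_synthetic(gan, n_max, seed)
    parts_X, parts_y = [X], [y]
    for cls, k in enumerate(want):
        sel = np.flatnonzero(ys_all == cls)[:k]
        parts_X.append(Xs_all[sel])
        parts_y.append(np.full(k, cls, dtype=np.int64))
    Xa = np.concatenate(parts_X)
    ya = np.concatenate(parts_y)
    is_syn = np.concatenate([np.zeros(n, dtype=bool), np.ones(n * multiplier, dtype=bool)])
    return Xa, ya, is_syn
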