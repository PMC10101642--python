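"""Auxiliary-classifier Wasserstein GAN with gradient penalty (AC-WGAN-GP).

The generator maps a latent vector z (default size 250) concatenated with a
learned class embedding through a dense seed projection and three stride-2
transposed-convolution stages (batch-normalised, LeakyReLU) to a square
image ×8 the seed side, finished by a single-filter stride-1 smoothing
convolution and tanh.  The critic is a batch-norm-free stride-2
convolutional trunk (LeakyReLU) with two heads sharing it: a linear
Wasserstein score and two-class logits.  Training uses RMSprop for both
networks, the Gulrajani-style gradient penalty on real/fake interpolates,
and an auxiliary cross-entropy on real (and, by default, conditioned fake)
samples.  Before the adversarial epochs, a configurable number of
critic-only warm-up epochs run with the generator frozen at its
initialisation.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Tensor
from . import nn


@dataclass
class GanConfig:
    z_dim: int = 250
    epochs: int = 1000
    batch_size: int = 32
    lr: float = 5e-5
    gp_lambda: float = 10.0
    leaky_slope: float = 0.2
    warmup_runs: int = 3
    n_classes: int = 2
    gen_filters: tuple[int, int] = (128, 64)
    critic_filters: tuple[int, int] = (64, 128)
    label_embed_dim: int = 50
    aux_on_fake: bool = True
    critic_steps_per_gen: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.z_dim < 1 or self.epochs < 1:
            raise ValueError("z_dim and epochs must be >= 1")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be >= 0")
        if not (0.0 < self.leaky_slope < 1.0):
            raise ValueError("leaky_slope must be in (0, 1)")


def scaled_config(**overrides) -> GanConfig:
    """Desk-scale configuration for small synthetic images (e.g. side 24).

    Narrower networks and a smaller latent space so a full 5-fold ×
    multi-seed experiment runs on one CPU in minutes; three critic steps
    per generator step (the classic WGAN-GP regime, which at short
    training lengths keeps the critic near-optimal and stops the
    adversarial term from eroding the shared trunk); auxiliary
    cross-entropy on real samples only (fakes early in a short run carry
    no class signal and only inject label noise).
    """
    defaults = dict(epochs=150, gen_filters=(8, 4), critic_filters=(8, 16),
                    label_embed_dim=16, z_dim=64, batch_size=32,
                    critic_steps_per_gen=3, aux_on_fake=False)
    defaults.update(overrides)
    return GanConfig(**defaults)


class Generator(nn.Module):
    def __init__(self, side: int, config: GanConfig, rng: np.random.Generator):
        if side % 8 != 0:
            raise ValueError("image side must be a multiple of 8")
        self.side = side
        self.start_side = side // 8
        self.slope = config.leaky_slope
        f0, f1 = config.gen_filters
        self.embed = nn.Embedding(config.n_classes, config.label_embed_dim, rng)
        self.dense = nn.Dense(config.z_dim + config.label_embed_dim,
                              self.start_side**2 * f0, rng)
        self.bn0 = nn.BatchNorm2d(f0)
        self.up1 = nn.ConvTranspose2d(f0, f0, rng)
        self.bn1 = nn.BatchNorm2d(f0)
        self.up2 = nn.ConvTranspose2d(f0, f1, rng)
        self.bn2 = nn.BatchNorm2d(f1)
        self.up3 = nn.ConvTranspose2d(f1, f1, rng)
        self.bn3 = nn.BatchNorm2d(f1)
        self.smooth = nn.Conv2d(f1, 1, rng, kernel=3, stride=1, padding=1)
        self.training = True

    def _param_names(self):
        return ()

    def _children(self):
        return (self.embed, self.dense, self.bn0, self.up1, self.bn1,
                self.up2, self.bn2, self.up3, self.bn3, self.smooth)

    def __call__(self, z: Tensor, labels: np.ndarray) -> Tensor:
        h = ad.concat([z, self.embed(labels)], axis=1)
        h = self.dense(h)
        n = h.shape[0]
        f0 = self.bn0.gamma.shape[0]
        h = ad.reshape(h, (n, f0, self.start_side, self.start_side))
        h = ad.leaky_relu(self.bn0(h), self.slope)
        h = ad.leaky_relu(self.bn1(self.up1(h)), self.slope)
        h = ad.leaky_relu(self.bn2(self.up2(h)), self.slope)
        h = ad.leaky_relu(self.bn3(self.up3(h)), self.slope)
        return ad.tanh(self.smooth(h))


class Critic(nn.Module):
    """Two-headed critic; deliberately contains no normalisation layers."""

    def __init__(self, side: int, config: GanConfig, rng: np.random.Generator):
        self.side = side
        self.slope = config.leaky_slope
        c0, c1 = config.critic_filters
        self.conv1 = nn.Conv2d(1, c0, rng)
        self.conv2 = nn.Conv2d(c0, c1, rng)
        self.flat_dim = (side // 4) ** 2 * c1
        self.head_score = nn.Dense(self.flat_dim, 1, rng)
        self.head_class = nn.Dense(self.flat_dim, config.n_classes, rng)
        self.training = True

    def _param_names(self):
        return ()

    def _children(self):
        return (self.conv1, self.conv2, self.head_score, self.head_class)

    def trunk(self, x: Tensor) -> Tensor:
        h = ad.leaky_relu(self.conv1(x), self.slope)
        h = ad.leaky_relu(self.conv2(h), self.slope)
        return ad.reshape(h, (h.shape[0], self.flat_dim))

    def forward(self, x: Tensor):
        h = self.trunk(x)
        return self.head_score(h), self.head_class(h)

    def score(self, x: Tensor) -> Tensor:
        return self.head_score(self.trunk(x))

    def logits(self, x: Tensor) -> Tensor:
        return self.head_class(self.trunk(x))


@dataclass
class TrainedGan:
    generator: Generator
    critic: Critic
    config: GanConfig
    log: pd.DataFrame
    layout_ref: str = ""
    side: int = 0


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _as_image_tensor(batch, requires_grad=False) -> Tensor:
    x = np.asarray(batch, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    return Tensor(x, requires_grad=requires_grad)


def gradient_penalty(critic, real_batch, fake_batch, gp_lambda: float = 10.0,
                     rng: np.random.Generator | None = None) -> Tensor:
    """λ · mean over interpolates x̂ of (‖∇_x̂ score(x̂)‖₂ − 1)².

    ``critic`` is either a callable score function on image tensors or an
    object with a ``.score`` method.  Each interpolate uses its own
    ε ~ Uniform(0, 1): x̂ = ε·real + (1−ε)·fake.  Returns a scalar graph
    tensor (use ``.item()`` for the value).
    """
    score_fn = critic.score if hasattr(critic, "score") else critic
    real = np.asarray(real_batch, dtype=np.float32)
    fake = np.asarray(fake_batch, dtype=np.float32)
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must have the same shape")
    if real.ndim == 3:
        real, fake = real[:, None], fake[:, None]
    if gp_lambda < 0:
        raise ValueError("gp_lambda must be >= 0")
    rng = rng or np.random.default_rng(0)
    eps = rng.uniform(0.0, 1.0, size=(real.shape[0],) + (1,) * (real.ndim - 1)).astype(np.float32)
    x_hat = Tensor(eps * real + (1.0 - eps) * fake, requires_grad=True)
    s = score_fn(x_hat)
    g, = ad.grad(ad.tsum(s), [x_hat], create_graph=True)
    if not np.all(np.isfinite(g.data)):
        raise FloatingPointError("non-finite critic input gradient")
    sq = ad.tsum(ad.mul(g, g), axis=tuple(range(1, real.ndim)))
    norm = ad.sqrt(ad.add(sq, Tensor(np.float32(1e-12))))
    pen = ad.tmean(ad.power(ad.sub(norm, Tensor(np.float32(1.0))), 2.0))
    return ad.mul(pen, Tensor(np.float32(gp_lambda)))


def critic_loss(critic: Critic, real_batch, real_labels, fake_batch, fake_labels,
                config: GanConfig, rng: np.random.Generator | None = None,
                include_gp: bool = True, include_class: bool = True):
    """Critic objective and its logged components.

    total = mean score(fake) − mean score(real) + gradient penalty
            + auxiliary cross-entropy on real samples (and on fake samples
            with their conditioning labels when ``config.aux_on_fake``).
    """
    real_labels = np.asarray(real_labels)
    fake_labels = np.asarray(fake_labels)
    if len(real_labels) == 0 or len(fake_labels) == 0:
        raise ValueError("empty batch")
    real_t = _as_image_tensor(real_batch)
    fake_t = _as_image_tensor(fake_batch)
    s_real, logits_real = critic.forward(real_t)
    s_fake, logits_fake = critic.forward(fake_t)
    w_real = ad.tmean(s_real)
    w_fake = ad.tmean(s_fake)
    total = ad.sub(w_fake, w_real)
    components = {"critic_real": float(w_real.item()),
                  "critic_fake": float(w_fake.item()),
                  "wasserstein": float(total.item())}
    if include_gp and config.gp_lambda > 0:
        gp = gradient_penalty(critic, real_batch, fake_batch, config.gp_lambda, rng)
        total = ad.add(total, gp)
        components["gradient_penalty"] = float(gp.item())
    else:
        components["gradient_penalty"] = 0.0
    if include_class:
        cls = ad.softmax_cross_entropy(logits_real, real_labels)
        if config.aux_on_fake:
            cls = ad.add(cls, ad.softmax_cross_entropy(logits_fake, fake_labels))
        total = ad.add(total, cls)
        components["critic_class"] = float(cls.item())
    else:
        components["critic_class"] = 0.0
    components["total"] = float(total.item())
    return total, components


def generator_loss(critic: Critic, fake_batch, cond_labels):
    """Generator objective: −mean score(fake) + auxiliary CE on fakes."""
    cond_labels = np.asarray(cond_labels)
    if len(cond_labels) == 0:
        raise ValueError("empty batch")
    fake_t = fake_batch if isinstance(fake_batch, Tensor) else _as_image_tensor(fake_batch)
    s_fake, logits_fake = critic.forward(fake_t)
    adv = ad.neg(ad.tmean(s_fake))
    cls = ad.softmax_cross_entropy(logits_fake, cond_labels)
    total = ad.add(adv, cls)
    components = {"generator_adv": float(adv.item()),
                  "generator_class": float(cls.item()),
                  "total": float(total.item())}
    return total, components


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _set_requires(params, flag: bool):
    for p in params:
        p.requires_grad = flag


def _check_finite(value: float, epoch: int, step: int, what: str):
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite {what} at epoch {epoch}, step {step}")


def train_gan(images, labels, config: GanConfig, layout_ref: str = "") -> TrainedGan:
    """Train the AC-WGAN-GP on labelled profile images.

    ``images``: (n, side, side) array in [−1, 1]; ``labels``: 0/1 per image.
    Runs ``config.warmup_runs`` critic-only epochs (generator frozen at its
    initialisation), then ``config.epochs`` adversarial epochs; RMSprop for
    both networks; all randomness derives from ``config.seed``.
    """
    X = np.asarray(images, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError("images must be (n, side, side)")
    counts = np.bincount(y, minlength=config.n_classes)
    if (counts == 0).any():
        raise ValueError("single-class data: need samples from every class")
    if (counts < 2).any():
        raise ValueError("need at least 2 samples per class")
    side = X.shape[1]
    n = X.shape[0]

    ss = np.random.SeedSequence(config.seed)
    s_ginit, s_cinit, s_order, s_z, s_eps, s_lab = ss.spawn(6)
    gen = Generator(side, config, np.random.default_rng(s_ginit))
    critic = Critic(side, config, np.random.default_rng(s_cinit))
    rng_order = np.random.default_rng(s_order)
    rng_z = np.random.default_rng(s_z)
    rng_eps = np.random.default_rng(s_eps)
    rng_lab = np.random.default_rng(s_lab)

    opt_c = nn.RMSprop(critic.params(), lr=config.lr)
    opt_g = nn.RMSprop(gen.params(), lr=config.lr)
    class_freq = counts / counts.sum()

    def draw_fakes(batch_labels, train_gen: bool):
        z = Tensor(rng_z.standard_normal((len(batch_labels), config.z_dim)).astype(np.float32))
        if train_gen:
            return gen(z, batch_labels)
        with ad.no_grad():
            return gen(z, batch_labels).detach()

    log_rows = []
    step_counter = 0
    for epoch in range(-config.warmup_runs, config.epochs):
        warmup = epoch < 0
        order = rng_order.permutation(n)
        sums: dict[str, float] = {}
        n_batches = 0
        gen_rows = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = X[idx], y[idx]
            # --- critic step (generator frozen; fakes are constants) ----
            fake = draw_fakes(yb, train_gen=False)
            total, comp = critic_loss(critic, xb, yb, fake.data[:, 0], yb,
                                      config, rng_eps)
            _check_finite(comp["total"], epoch, step_counter, "critic loss")
            grads = ad.grad(total, critic.params())
            opt_c.step(grads)
            for k, v in comp.items():
                sums[k] = sums.get(k, 0.0) + v
            n_batches += 1
            step_counter += 1
            # --- generator step ----------------------------------------
            if not warmup and step_counter % config.critic_steps_per_gen == 0:
                cond = rng_lab.choice(config.n_classes, size=len(idx), p=class_freq)
                fake = draw_fakes(cond, train_gen=True)
                _set_requires(critic.params(), False)
                try:
                    g_total, g_comp = generator_loss(critic, fake, cond)
                finally:
                    _set_requires(critic.params(), True)
                _check_finite(g_comp["total"], epoch, step_counter, "generator loss")
                g_grads = ad.grad(g_total, gen.params())
                opt_g.step(g_grads)
                gen_rows.append(g_comp)
        if not warmup:
            row = {k: v / n_batches for k, v in sums.items() if k != "total"}
            row["epoch"] = epoch
            if gen_rows:
                row["generator_adv"] = float(np.mean([r["generator_adv"] for r in gen_rows]))
                row["generator_class"] = float(np.mean([r["generator_class"] for r in gen_rows]))
            log_rows.append(row)

    log = pd.DataFrame(log_rows)
    return TrainedGan(gen, critic, config, log, layout_ref, side)


def generate_synthetic(gan: TrainedGan, n_per_class: int, seed: int):
    """Sample ``n_per_class`` conditioned images per class from the generator.

    Returns (X, y) with X in [−1, 1], shape (n_classes*n_per_class, side,
    side).  Uses the generator's running batch-norm statistics (eval mode).
    """
    if n_per_class == 0:
        side = gan.side
        return np.empty((0, side, side), dtype=np.float32), np.empty(0, dtype=np.int64)
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(gan.config.n_classes), n_per_class)
    z = Tensor(rng.standard_normal((len(labels), gan.config.z_dim)).astype(np.float32))
    gan.generator.set_training(False)
    try:
        with ad.no_grad():
            out = gan.generator(z, labels)
    finally:
        gan.generator.set_training(True)
    return out.data[:, 0].copy(), labels


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(gan: TrainedGan, path):
    arrays = {}
    for prefix, net in (("g", gan.generator), ("c", gan.critic)):
        for i, arr in enumerate(net.state_arrays()):
            arrays[f"{prefix}{i}"] = arr
    cfg = asdict(gan.config)
    cfg["gen_filters"] = list(cfg["gen_filters"])
    cfg["critic_filters"] = list(cfg["critic_filters"])
    meta = json.dumps({"config": cfg, "side": gan.side, "layout_ref": gan.layout_ref})
    log_csv = gan.log.to_csv(index=False)
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             __log__=np.frombuffer(log_csv.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> TrainedGan:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        log = pd.read_csv(io.StringIO(bytes(data["__log__"]).decode()))
        cfg = meta["config"]
        cfg["gen_filters"] = tuple(cfg["gen_filters"])
        cfg["critic_filters"] = tuple(cfg["critic_filters"])
        config = GanConfig(**cfg)
        rng = np.random.default_rng(0)
        gen = Generator(meta["side"], config, rng)
        critic = Critic(meta["side"], config, rng)
        for prefix, net in (("g", gen), ("c", critic)):
            arrays = net.state_arrays()
            for i, arr in enumerate(arrays):
                arr[...] = data[f"{prefix}{i}"]
    return TrainedGan(gen, critic, config, log, meta["layout_ref"], meta["side"])
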