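import numpy as np
import pytest

from tgand import acwgan, imaging, synthdata


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, strongly separable synthetic cohort (side-8 images)."""
    cfg = synthdata.SynthConfig(n=80, m=60, n_informative=20, delta=3.0,
                                sigma=1.0, seed=42)
    return synthdata.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_images(tiny_cohort):
    labeled = synthdata.to_risk_labeled(tiny_cohort)
    layout = imaging.plan_layout(labeled.expression.gene_ids)
    X, y, pats = imaging.cohort_to_images(labeled, layout, run_seed=7)
    return X, y, pats, layout, labeled


@pytest.fixture(scope="session")
def tiny_gan(tiny_images):
    """A GAN trained to competence on the tiny cohort, shared across tests.

    Side-8 images train in seconds, so the adversarial run is long enough
    for both the auxiliary head and the conditional generator to converge.
    """
    X, y, _, layout, _ = tiny_images
    config = acwgan.GanConfig(epochs=600, batch_size=16, seed=3, lr=2e-4,
                              gen_filters=(16, 8), critic_filters=(8, 16),
                              z_dim=32, label_embed_dim=8, aux_on_fake=False)
    return acwgan.train_gan(X, y, config, layout_ref=layout.layout_id)


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
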