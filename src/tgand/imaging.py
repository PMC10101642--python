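"""Deterministic embedding of transcriptome profiles into square images.

A profile of m genes is written row-major into the smallest square grid
whose side is a multiple of 8 (the generator upsamples its seed grid by
×8 through three stride-2 stages) and whose area holds all genes:
m = 18543 → 144×144 from an 18×18 seed, m = 14042 → 120×120 from 15×15.
Surplus cells are filled with values drawn once per patient from
Uniform(−1, 1), seeded so runs are reproducible; gene cells carry the
rescaled expression clipped to [−1, 1].
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import h5py
import numpy as np

from .cohorts import RiskLabeledCohort

UPSAMPLE_FACTOR = 8


@dataclass
class EmbeddingLayout:
    """Gene → pixel assignment for one gene universe."""

    gene_order: list[str]
    side: int
    start_side: int
    pad_indices: np.ndarray  # flat grid positions without a gene
    upsample_factor: int = UPSAMPLE_FACTOR

    @property
    def m(self) -> int:
        return len(self.gene_order)

    @property
    def layout_id(self) -> str:
        return f"{zlib.crc32('|'.join(self.gene_order).encode()):08x}-{self.side}"


@dataclass
class ProfileImage:
    patient_id: str
    label: int | None  # 0 = LOW, 1 = HIGH, None = unknown
    pixels: np.ndarray
    layout_ref: str
    pad_seed: int


def plan_layout(gene_ids, order: str = "lex") -> EmbeddingLayout:
    """Plan the square grid for a gene universe.

    side is the smallest positive multiple of 8 with side² ≥ m; the seed
    grid is side/8.  Genes fill the grid row-major — lexicographically by
    symbol by default (``order="given"`` keeps the input order) — and the
    trailing cells are padding.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("empty gene list")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids")
    if order == "lex":
        gene_ids = sorted(gene_ids)
    elif order != "given":
        raise ValueError("order must be 'lex' or 'given'")
    m = len(gene_ids)
    side = UPSAMPLE_FACTOR
    while side * side < m:
        side += UPSAMPLE_FACTOR
    pad = np.arange(m, side * side, dtype=np.int64)
    return EmbeddingLayout(gene_ids, side, side // UPSAMPLE_FACTOR, pad)


def patient_pad_seed(run_seed: int, patient_id: str) -> int:
    """Stable per-patient seed (< 2^31): run seed XOR a patient-id CRC."""
    return (int(run_seed) ^ zlib.crc32(str(patient_id).encode())) & 0x7FFFFFFF


def profile_to_image(profile, layout: EmbeddingLayout, pad_seed: int,
                     patient_id: str = "", label: int | None = None) -> ProfileImage:
    """Convert one per-gene profile (mapping or aligned array) to an image.

    Gene cells are the expression values clipped to [−1, 1]; pad cells are
    Uniform(−1, 1) draws from a generator seeded with ``pad_seed`` —
    bit-identical for a fixed seed.
    """
    if isinstance(profile, dict):
        missing = [g for g in layout.gene_order if g not in profile]
        extra = [g for g in profile if g not in set(layout.gene_order)]
        if missing or extra:
            raise ValueError(
                f"profile/gene-order mismatch; missing={missing[:5]} extra={extra[:5]}"
            )
        vec = np.array([profile[g] for g in layout.gene_order], dtype=np.float32)
    else:
        vec = np.asarray(profile, dtype=np.float32)
        if vec.shape != (layout.m,):
            raise ValueError(
                f"profile length {vec.shape} does not match layout m={layout.m}"
            )
    if np.isnan(vec).any():
        raise ValueError("profile contains missing values")
    flat = np.empty(layout.side * layout.side, dtype=np.float32)
    flat[: layout.m] = np.clip(vec, -1.0, 1.0)
    rng = np.random.default_rng(pad_seed)
    flat[layout.pad_indices] = rng.uniform(-1.0, 1.0, size=layout.pad_indices.size)
    return ProfileImage(patient_id, label, flat.reshape(layout.side, layout.side),
                        layout.layout_id, pad_seed)


def image_to_profile(image: ProfileImage, layout: EmbeddingLayout) -> np.ndarray:
    """Recover the gene-ordered values; pad cells are discarded."""
    if image.layout_ref != layout.layout_id:
        raise ValueError("image was built with a different layout")
    return image.pixels.reshape(-1)[: layout.m].copy()


def cohort_to_images(cohort: RiskLabeledCohort, layout: EmbeddingLayout,
                     run_seed: int = 0):
    """Stack a cohort into (X, y, patient_ids) with per-patient pad seeds.

    X has shape (n, side, side); y is 0/1 (LOW/HIGH) ordered like X.
    """
    gene_index = {g: i for i, g in enumerate(cohort.expression.gene_ids)}
    missing = [g for g in layout.gene_order if g not in gene_index]
    if missing:
        raise ValueError(f"cohort lacks layout genes: {missing[:5]}")
    rows = np.array([gene_index[g] for g in layout.gene_order])
    values = cohort.expression.values[rows]  # (m, n) in layout order
    y = cohort.label_array()
    pats = cohort.expression.patient_ids
    X = np.empty((len(pats), layout.side, layout.side), dtype=np.float32)
    for j, pid in enumerate(pats):
        img = profile_to_image(values[:, j], layout,
                               patient_pad_seed(run_seed, pid), pid, int(y[j]))
        X[j] = img.pixels
    return X, y, list(pats)


def save_images_h5(path, X, y, patient_ids, layout: EmbeddingLayout, run_seed: int):
    with h5py.File(path, "w") as f:
        f.create_dataset("pixels", data=np.asarray(X, dtype=np.float32))
        f.create_dataset("labels", data=np.asarray(y, dtype=np.int64))
        f.create_dataset("patient_ids", data=np.array(patient_ids, dtype="S"))
        f.create_dataset("gene_order", data=np.array(layout.gene_order, dtype="S"))
        f.create_dataset("pad_indices", data=layout.pad_indices)
        f.attrs["side"] = layout.side
        f.attrs["start_side"] = layout.start_side
        f.attrs["run_seed"] = int(run_seed)


def load_images_h5(path):
    with h5py.File(path, "r") as f:
        X = f["pixels"][()]
        y = f["labels"][()]
        pats = [p.decode() for p in f["patient_ids"][()]]
        layout = EmbeddingLayout(
            [g.decode() for g in f["gene_order"][()]],
            int(f.attrs["side"]), int(f.attrs["start_side"]),
            f["pad_indices"][()],
        )
        run_seed = int(f.attrs["run_seed"])
    return X, y, pats, layout, run_seed
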