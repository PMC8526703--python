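"""Painting per-sample expression onto the grid embedding as network images.

Each occupied grid cell receives the arithmetic mean of log2(x+1)-transformed
expression over the genes embedded there; unoccupied cells stay exactly zero.
By default images are max-normalized to [0, 1] so CNN inputs share one scale
regardless of a sample's sequencing depth; raw (log-scale, unnormalized)
images are available via a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from netimg.embedding import GridEmbedding

logger = logging.getLogger(__name__)

__all__ = ["NetworkImage", "render_image", "render_cohort", "write_images", "read_images"]


@dataclass
class NetworkImage:
    """A single sample's G x G expression image with its class label."""

    sample_id: str
    pixels: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2D matrix")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels must be finite")
        if (self.pixels < 0).any():
            raise ValueError("pixels must be non-negative")


def render_image(
    embedding: GridEmbedding,
    profile: Mapping[str, float] | pd.Series,
    normalize: bool = True,
    log_transform: bool = True,
    sample_id: str = "",
    label: str = "",
) -> NetworkImage:
    """Paint one expression profile onto the embedding grid.

    Parameters
    ----------
    embedding
        Shared grid embedding of the DEG subnetwork.
    profile
        gene -> non-negative expression value. Genes absent from the
        embedding are ignored (counted in a log line); embedded genes absent
        from the profile contribute nothing to their cell's mean.
    normalize
        Linearly rescale so the brightest occupied cell equals 1
        (an all-zero image stays all-zero).
    log_transform
        Apply log2(x+1) before averaging (default). Disable for already-log
        or synthetic unit-scale inputs.
    """
    if isinstance(profile, pd.Series):
        profile = profile.to_dict()
    g = embedding.grid_size
    total = np.zeros((g, g), dtype=float)
    count = np.zeros((g, g), dtype=int)
    n_unembedded = 0
    n_used = 0
    for gene, value in profile.items():
        cell = embedding.cells.get(gene)
        if cell is None:
            n_unembedded += 1
            continue
        if value < 0:
            raise ValueError(f"negative expression for gene {gene!r}")
        v = np.log2(value + 1.0) if log_transform else float(value)
        total[cell] += v
        count[cell] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("profile shares no genes with the embedding")
    if n_unembedded:
        logger.debug("%d profile genes not in embedding (ignored)", n_unembedded)
    pixels = np.divide(total, count, out=np.zeros_like(total), where=count > 0)
    if normalize:
        peak = pixels.max()
        if peak > 0:
            pixels = pixels / peak
    return NetworkImage(sample_id=sample_id, pixels=pixels, label=label)


def render_cohort(
    embedding: GridEmbedding,
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    normalize: bool = True,
    log_transform: bool = True,
) -> list[NetworkImage]:
    """One image per metadata sample, in metadata order.

    Tumor samples are labeled with their cancer type, normals ``normal``.
    ``expression`` is genes x samples with sample ids as columns.
    """
    ids = metadata["sample_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = metadata["sample_id"][metadata["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id in metadata: {dupes!r}")
    missing = [s for s in ids if s not in expression.columns]
    if missing:
        raise ValueError(f"sample missing from expression matrix: {missing[0]!r}")
    images = []
    for _, row in metadata.iterrows():
        label = "normal" if row["status"] == "normal" else str(row["cancer"])
        images.append(
            render_image(
                embedding,
                expression[row["sample_id"]],
                normalize=normalize,
                log_transform=log_transform,
                sample_id=str(row["sample_id"]),
                label=label,
            )
        )
    return images


def write_images(images: list[NetworkImage], outdir: str | Path) -> Path:
    """Store each image as a plain-text matrix plus a manifest TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    with manifest.open("w") as mh:
        mh.write("sample_id\tlabel\tpath\n")
        for img in images:
            fname = f"{img.sample_id}.tsv"
            np.savetxt(outdir / fname, img.pixels, delimiter="\t", fmt="%.10g")
            mh.write(f"{img.sample_id}\t{img.label}\t{fname}\n")
    return manifest


def read_images(manifest: str | Path) -> list[NetworkImage]:
    manifest = Path(manifest)
    base = manifest.parent
    images = []
    table = pd.read_csv(manifest, sep="\t", dtype=str)
    for _, row in table.iterrows():
        pixels = np.loadtxt(base / row["path"], delimiter="\t", ndmin=2)
        images.append(NetworkImage(row["sample_id"], pixels, row["label"]))
    return images
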