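"""Dataset indexing, train/val/test partitioning, and synthetic OCT B-scans.

The split rule reproduces the published partition arithmetic for a
70/15/15 split: the training size is the floor of ``0.70 * n``, the test size
is ``0.15 * n`` rounded half-up, and validation takes the remainder (2316
images -> 1621/348/347; 4326 -> a 649-image test set).  The split is
image-level and unstratified.

The synthetic generator emulates grayscale OCT B-scans for three diagnostic
classes.  Every image shares a per-index "anatomy" (smooth, gently curved
horizontal retinal bands over a dark background) so that switching off the
class-specific pathology parameters makes the classes pixel-identical:

* normal — the bands alone;
* dry AMD — bright, bumpy drusen deposits deforming the brightest (RPE) band;
* wet AMD — a dark sub-RPE fluid pocket that locally elevates the bands.

All images are corrupted by multiplicative log-normal speckle, rendered 8-bit
grayscale and replicated to three channels.  Generation is a pure function of
the spec (bit-identical across reruns).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "DatasetIndex",
    "SplitSpec",
    "SyntheticSpec",
    "split_sizes",
    "split",
    "load_dataset",
    "generate_synthetic",
    "write_split_manifest",
    "CLASS_NAMES",
]

CLASS_NAMES = ["dry_amd", "normal", "wet_amd"]
IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


class Entry(NamedTuple):
    path: str
    class_index: int
    class_name: str


@dataclass
class DatasetIndex:
    entries: list[Entry]
    class_names: list[str]

    def __post_init__(self) -> None:
        paths = [e.path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("dataset entries contain duplicate paths")
        for e in self.entries:
            if self.class_names[e.class_index] != e.class_name:
                raise ValueError(f"entry {e.path} inconsistent with class_names")

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> np.ndarray:
        return np.array([e.class_index for e in self.entries], dtype=np.int64)

    def subset(self, indices) -> "DatasetIndex":
        return DatasetIndex([self.entries[i] for i in indices], list(self.class_names))


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    val_fraction: float = 0.15
    test_fraction: float = 0.15
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.val_fraction, self.test_fraction)
        if not all(0 < f < 1 for f in fracs):
            raise ValueError("split fractions must lie in (0, 1)")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_sizes(n_total: int, spec: SplitSpec | None = None) -> tuple[int, int, int]:
    """(n_train, n_val, n_test) under floor-train / half-up-test rounding."""
    spec = spec or SplitSpec()
    if n_total < 3:
        raise ValueError("need at least 3 samples to form three partitions")
    # tiny epsilon guards against 0.70*n landing just below an integer
    n_train = math.floor(spec.train_fraction * n_total + 1e-9)
    n_test = math.floor(spec.test_fraction * n_total + 0.5 + 1e-9)
    n_val = n_total - n_train - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split of {n_total} leaves an empty partition: "
            f"({n_train}, {n_val}, {n_test})"
        )
    return n_train, n_val, n_test


def split(
    index: DatasetIndex, spec: SplitSpec | None = None
) -> tuple[DatasetIndex, DatasetIndex, DatasetIndex]:
    """Seeded disjoint train/val/test partition covering the index."""
    spec = spec or SplitSpec()
    if len(index) == 0:
        raise ValueError("cannot split an empty dataset index")
    n_train, n_val, n_test = split_sizes(len(index), spec)
    perm = np.random.default_rng(spec.shuffle_seed).permutation(len(index))
    return (
        index.subset(perm[:n_train]),
        index.subset(perm[n_train : n_train + n_val]),
        index.subset(perm[n_train + n_val :]),
    )


def write_split_manifest(partitions, path) -> None:
    """CSV manifest (path, class_name, partition) for a train/val/test triple."""
    rows = []
    for name, part in zip(("train", "val", "test"), partitions):
        rows.extend((e.path, e.class_name, name) for e in part.entries)
    pd.DataFrame(rows, columns=["path", "class_name", "partition"]).to_csv(path, index=False)


def load_dataset(root) -> DatasetIndex:
    """Index ``root/<class_name>/*.{png,jpg,...}``; classes are sorted subdirs."""
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories found under {root}")
    class_names = [p.name for p in class_dirs]
    entries: list[Entry] = []
    for ci, cdir in enumerate(class_dirs):
        files = sorted(
            p for p in cdir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
        )
        kept = 0
        for f in files:
            try:
                with Image.open(f) as im:
                    im.verify()
            except Exception:
                warnings.warn(f"skipping unreadable image {f}", stacklevel=2)
                continue
            entries.append(Entry(str(f), ci, class_names[ci]))
            kept += 1
        if kept == 0:
            raise ValueError(f"class subdirectory {class_names[ci]!r} contains no readable images")
    return DatasetIndex(entries, class_names)


# ---------------------------------------------------------------------------
# synthetic B-scan generator


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic B-scan generator.

    ``drusen_amplitude`` and ``fluid_radius`` are in pixels; setting either to
    zero removes that class's pathology signal entirely, and setting
    ``speckle_sigma`` to zero disables the noise, leaving the three classes
    pixel-identical.
    """

    n_per_class: int = 32
    seed: int = 0
    image_size: tuple[int, int] = (224, 224)
    band_count: int = 6
    drusen_count: int = 5
    drusen_amplitude: int = 12
    fluid_radius: int = 28
    speckle_sigma: float = 0.15

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.band_count < 1 or self.band_count * 6 > h:
            raise ValueError("band_count does not fit the image height")
        if self.drusen_amplitude < 0 or self.fluid_radius < 0 or self.speckle_sigma < 0:
            raise ValueError("pathology and noise scales must be nonnegative")
        if self.drusen_amplitude > h // 4 or self.fluid_radius > h // 4:
            raise ValueError("pathology scales must fit inside the image")


def _render_anatomy(spec: SyntheticSpec, rng: np.random.Generator):
    """Shared per-index anatomy: band centers/widths/amplitudes and curvature."""
    h, w = spec.image_size
    x = np.arange(w, dtype=np.float64)
    top, bottom = 0.32 * h, 0.72 * h
    base = np.linspace(top, bottom, spec.band_count)
    base += rng.uniform(-2.0, 2.0, size=spec.band_count)
    tilt = rng.uniform(-0.08, 0.08)
    bow = rng.uniform(0.0, 8.0)
    curve = tilt * (x - w / 2) + bow * ((x - w / 2) / (w / 2)) ** 2
    widths = rng.uniform(1.8, 4.0, size=spec.band_count)
    amps = rng.uniform(70.0, 110.0, size=spec.band_count)
    amps[0] = rng.uniform(140.0, 170.0)  # inner limiting membrane
    amps[-1] = rng.uniform(170.0, 200.0)  # RPE complex: brightest band
    background = rng.uniform(12.0, 22.0)
    return base, curve, widths, amps, background


def _render_image(spec: SyntheticSpec, class_name: str, anat, class_rng) -> np.ndarray:
    h, w = spec.image_size
    base, curve, widths, amps, background = anat
    x = np.arange(w, dtype=np.float64)[None, :]
    y = np.arange(h, dtype=np.float64)[:, None]
    centers = base[:, None] + curve[None, :]  # (band, w)
    centers = centers.copy()
    extra = np.zeros((h, w))

    if class_name == "dry_amd" and spec.drusen_amplitude > 0 and spec.drusen_count > 0:
        # bright bumpy deposits deforming the RPE band upward
        xs = class_rng.uniform(0.1 * w, 0.9 * w, size=spec.drusen_count)
        heights = spec.drusen_amplitude * class_rng.uniform(0.5, 1.0, spec.drusen_count)
        sigmas = class_rng.uniform(4.0, 9.0, size=spec.drusen_count)
        for xj, hj, sj in zip(xs, heights, sigmas):
            bump = hj * np.exp(-((x[0] - xj) ** 2) / (2 * sj**2))
            centers[-1] -= bump
            # amorphous hyper-reflective material under the deformed band
            blob_y = base[-1] + curve - bump / 2
            extra += (
                0.9
                * amps[-1]
                * (hj / max(spec.drusen_amplitude, 1))
                * np.exp(
                    -((x - xj) ** 2) / (2 * (1.2 * sj) ** 2)
                    - ((y - blob_y[None, :]) ** 2) / (2 * (0.6 * hj + 1.5) ** 2)
                )
            )

    dark = np.ones((h, w))
    if class_name == "wet_amd" and spec.fluid_radius > 0:
        # sub-RPE fluid pocket: dome-shaped band elevation + dark cavity
        r = float(spec.fluid_radius)
        cx = class_rng.uniform(0.25 * w, 0.75 * w)
        dome = 0.8 * r * np.exp(-((x[0] - cx) ** 2) / (2 * (1.6 * r) ** 2))
        centers -= dome[None, :]
        cy = base[-1] - 0.2 * r
        ell = ((x - cx) ** 2) / (1.6 * r) ** 2 + ((y - cy) ** 2) / (0.8 * r) ** 2
        dark -= 0.85 * np.exp(-(ell**2))

    img = np.full((h, w), background)
    for c, wd, a in zip(centers, widths, amps):
        img += a * np.exp(-((y - c[None, :]) ** 2) / (2 * wd**2))
    img += extra
    img *= dark

    if spec.speckle_sigma > 0:
        img *= np.exp(
            spec.speckle_sigma * class_rng.standard_normal((h, w))
            - spec.speckle_sigma**2 / 2
        )
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_synthetic(spec: SyntheticSpec | None = None, out=None) -> DatasetIndex:
    """Write ``n_per_class`` PNGs per class under ``out`` and return the index."""
    spec = spec or SyntheticSpec()
    if out is None:
        raise ValueError("an output directory is required")
    out = Path(out)
    entries: list[Entry] = []
    for ci, cname in enumerate(CLASS_NAMES):
        cdir = out / cname
        cdir.mkdir(parents=True, exist_ok=True)
        for i in range(spec.n_per_class):
            anat_rng = np.random.default_rng([spec.seed, i])
            class_rng = np.random.default_rng([spec.seed, ci, i])
            anat = _render_anatomy(spec, anat_rng)
            gray = _render_image(spec, cname, anat, class_rng)
            rgb = np.repeat(gray[:, :, None], 3, axis=2)
            path = cdir / f"bscan_{i:04d}.png"
            Image.fromarray(rgb, mode="RGB").save(path)
            entries.append(Entry(str(path), ci, cname))
    return DatasetIndex(entries, list(CLASS_NAMES))
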