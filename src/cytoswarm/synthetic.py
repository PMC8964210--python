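"""Synthetic single-cell Pap-smear image generator.

Real Pap-smear single-cell datasets ship an RGB crop per cell together with
expert-validated nucleus and cytoplasm masks and one of seven morphology
labels.  This module emulates that unit of data so that every downstream
stage (feature extraction, clustering, feature selection, evaluation) is
testable without any download.

The seven classes follow the standard dysplasia progression: through the
precancerous grades the nucleus grows and darkens, the cytoplasm shrinks,
and chromatin texture becomes coarser; carcinoma in situ has the largest,
darkest nucleus.  Geometry is modelled as two nested rasterized ellipses
(cytoplasm and nucleus), intensity as a class mean plus per-pixel Gaussian
noise plus a band-limited sinusoidal texture.  This is deliberately the
simplest model that exposes the size/darkness/texture contrasts the classes
differ by; it makes no claim to staining realism (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CLASS_NAMES",
    "NORMAL_CLASSES",
    "CANCEROUS_CLASSES",
    "DATASET_PRESETS",
    "ClassProfile",
    "GeneratorConfig",
    "CellImage",
    "GenerationError",
    "default_profiles",
    "generate_cell",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
    "planted_feature_groups",
]

#: Canonical class order (normal classes first, then the four dysplasia grades
#: ordered mild -> carcinoma in situ as listed in the source data's catalogue).
CLASS_NAMES = (
    "preliminary_squamous",
    "moderate_squamous",
    "columnar",
    "in_situ",
    "preliminary_dysplastic",
    "intermediate_dysplastic",
    "last_stage_dysplastic",
)

NORMAL_CLASSES = ("preliminary_squamous", "moderate_squamous", "columnar")
CANCEROUS_CLASSES = (
    "in_situ",
    "preliminary_dysplastic",
    "intermediate_dysplastic",
    "last_stage_dysplastic",
)

#: Per-class image counts of the two public single-cell collections the
#: package emulates (1614 and 1500 images respectively).
DATASET_PRESETS = {
    "table1_dataset24": (174, 170, 190, 258, 280, 248, 294),
    "table1_dataset25": (190, 250, 280, 240, 290, 100, 150),
}

#: Microscope sampling of the emulated datasets; carried as metadata only.
PIXEL_SIZE_UM = 0.197


class GenerationError(RuntimeError):
    """Raised when a sampled nucleus cannot be placed inside its cytoplasm."""


@dataclass(frozen=True)
class ClassProfile:
    """Morphology parameters for one of the seven cell classes.

    Radii are in pixels (semi-major axis of the rasterized ellipse),
    intensities are gray levels in [0, 255], ``texture_amplitude`` is the
    peak amplitude of the sinusoidal chromatin texture in gray levels and
    ``eccentricity_range`` bounds the sampled ellipse eccentricity.
    """

    class_name: str
    nucleus_radius_mean: float
    nucleus_radius_sd: float
    nucleus_intensity_mean: float
    nucleus_intensity_sd: float
    cytoplasm_radius_mean: float
    cytoplasm_radius_sd: float
    cytoplasm_intensity_mean: float
    cytoplasm_intensity_sd: float
    texture_amplitude: float
    eccentricity_range: tuple[float, float] = (0.0, 0.4)

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class name: {self.class_name!r}")
        if not self.nucleus_radius_mean < self.cytoplasm_radius_mean:
            raise ValueError("nucleus radius mean must be below cytoplasm radius mean")
        for sd in (
            self.nucleus_radius_sd,
            self.nucleus_intensity_sd,
            self.cytoplasm_radius_sd,
            self.cytoplasm_intensity_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for val in (self.nucleus_intensity_mean, self.cytoplasm_intensity_mean):
            if not 0 <= val <= 255:
                raise ValueError("intensity means must lie in [0, 255]")
        lo, hi = self.eccentricity_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("eccentricity range must satisfy 0 <= lo <= hi < 1")


def default_profiles() -> list[ClassProfile]:
    """Default profiles for the seven classes, in canonical order.

    The quantitative values are free parameters of the generator (the classes
    are only defined qualitatively); they encode the dysplasia progression:
    nucleus radius strictly increases and nucleus intensity strictly
    decreases from mild dysplasia to carcinoma in situ, while the cytoplasm
    shrinks for the severe grades.
    """
    return [
        ClassProfile("preliminary_squamous", 7, 1.0, 120, 8, 45, 4.0, 190, 8, 6, (0.0, 0.3)),
        ClassProfile("moderate_squamous", 8, 1.0, 115, 8, 42, 4.0, 185, 8, 6, (0.0, 0.3)),
        ClassProfile("columnar", 10, 1.2, 100, 8, 24, 2.5, 170, 8, 8, (0.2, 0.5)),
        ClassProfile("in_situ", 24, 2.0, 55, 8, 34, 2.5, 150, 10, 14, (0.1, 0.4)),
        ClassProfile("preliminary_dysplastic", 13, 1.5, 95, 8, 40, 4.0, 170, 8, 10, (0.1, 0.4)),
        ClassProfile("intermediate_dysplastic", 17, 1.8, 82, 8, 36, 3.0, 165, 10, 12, (0.1, 0.4)),
        ClassProfile("last_stage_dysplastic", 21, 2.0, 70, 8, 30, 2.5, 160, 10, 14, (0.1, 0.4)),
    ]


@dataclass
class GeneratorConfig:
    """Configuration for :func:`generate_dataset`.

    ``counts_per_class`` follows the canonical :data:`CLASS_NAMES` order.
    """

    counts_per_class: tuple[int, ...]
    image_size: int = 128
    seed: int = 0
    background_intensity: int = 235

    def __post_init__(self) -> None:
        self.counts_per_class = tuple(int(c) for c in self.counts_per_class)
        if len(self.counts_per_class) != len(CLASS_NAMES):
            raise ValueError(f"counts_per_class must have {len(CLASS_NAMES)} entries")
        if any(c < 0 for c in self.counts_per_class):
            raise ValueError("counts must be >= 0")
        if not 0 <= self.background_intensity <= 255:
            raise ValueError("background_intensity must lie in [0, 255]")

    @classmethod
    def from_preset(cls, name: str, **kwargs) -> "GeneratorConfig":
        if name not in DATASET_PRESETS:
            raise KeyError(f"unknown preset {name!r}; choose from {sorted(DATASET_PRESETS)}")
        return cls(counts_per_class=DATASET_PRESETS[name], **kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        payload = json.loads(Path(path).read_text())
        if "preset" in payload:
            preset = payload.pop("preset")
            payload.pop("counts_per_class", None)
            return cls.from_preset(preset, **payload)
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclass
class CellImage:
    """A single segmented cell: RGB pixels, the two masks, and its label.

    ``nucleus_mask`` and ``cytoplasm_mask`` are disjoint boolean arrays whose
    union is the cell region (background already excluded, as in the
    expert-segmented source data).
    """

    pixels: np.ndarray
    nucleus_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    label: str
    image_id: str
    pixel_size_um: float = PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        self.cytoplasm_mask = np.asarray(self.cytoplasm_mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.nucleus_mask.shape != self.pixels.shape[:2]:
            raise ValueError("nucleus_mask shape must match pixels")
        if self.cytoplasm_mask.shape != self.pixels.shape[:2]:
            raise ValueError("cytoplasm_mask shape must match pixels")
        if not self.nucleus_mask.any():
            raise ValueError("nucleus_mask is empty")
        if not self.cytoplasm_mask.any():
            raise ValueError("cytoplasm_mask is empty")
        if (self.nucleus_mask & self.cytoplasm_mask).any():
            raise ValueError("nucleus and cytoplasm masks must be disjoint")

    @property
    def cell_mask(self) -> np.ndarray:
        return self.nucleus_mask | self.cytoplasm_mask


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float, theta: float) -> np.ndarray:
    """Boolean interior of a rotated ellipse with semi-axes a >= b."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


_MAX_PLACEMENT_ATTEMPTS = 100


def generate_cell(
    profile: ClassProfile,
    rng: np.random.Generator,
    *,
    image_size: int = 128,
    background_intensity: int = 235,
    image_id: str = "cell",
) -> CellImage:
    """Draw one synthetic cell from a class profile.

    The cytoplasm is a rasterized ellipse with random orientation and an
    eccentricity drawn from the profile's range; the nucleus is a smaller
    ellipse placed fully inside it (re-sampled up to 100 times, then
    :class:`GenerationError`).  Pixel gray values are the class intensity
    mean plus N(0, sd) noise plus a sinusoidal texture of random wavelength
    and orientation scaled by ``texture_amplitude``, clipped to [0, 255] and
    replicated to the three RGB channels.
    """
    center = (image_size - 1) / 2.0

    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        a_c = max(3.0, rng.normal(profile.cytoplasm_radius_mean, profile.cytoplasm_radius_sd))
        e_c = rng.uniform(*profile.eccentricity_range)
        b_c = a_c * np.sqrt(1.0 - e_c**2)
        th_c = rng.uniform(0.0, np.pi)
        cy = center + rng.normal(0.0, 1.0)
        cx = center + rng.normal(0.0, 1.0)
        cyt_interior = _ellipse_mask(image_size, cy, cx, a_c, b_c, th_c)

        a_n = max(2.0, rng.normal(profile.nucleus_radius_mean, profile.nucleus_radius_sd))
        e_n = rng.uniform(*profile.eccentricity_range)
        b_n = a_n * np.sqrt(1.0 - e_n**2)
        th_n = rng.uniform(0.0, np.pi)
        # jitter the nucleus centre within the slack left by the two radii
        slack = max(0.0, b_c - a_n - 1.0)
        ny = cy + rng.normal(0.0, 0.3 * slack + 1e-9)
        nx = cx + rng.normal(0.0, 0.3 * slack + 1e-9)
        nuc = _ellipse_mask(image_size, ny, nx, a_n, b_n, th_n)

        if nuc.any() and (nuc & ~cyt_interior).sum() == 0 and (cyt_interior & ~nuc).any():
            break
    else:
        raise GenerationError(
            f"could not place a {profile.class_name} nucleus inside its cytoplasm "
            f"after {_MAX_PLACEMENT_ATTEMPTS} attempts"
        )

    cyt_mask = cyt_interior & ~nuc
    cell = cyt_interior  # nucleus ∪ cytoplasm

    gray = np.full((image_size, image_size), float(background_intensity))
    wavelength = rng.uniform(4.0, 12.0)
    phi = rng.uniform(0.0, np.pi)
    phase = rng.uniform(0.0, 2 * np.pi)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    texture = np.sin(2 * np.pi * (np.cos(phi) * xx + np.sin(phi) * yy) / wavelength + phase)

    noise = rng.normal(0.0, 1.0, size=gray.shape)
    gray[cyt_mask] = (
        profile.cytoplasm_intensity_mean
        + profile.cytoplasm_intensity_sd * noise[cyt_mask]
        + profile.texture_amplitude * texture[cyt_mask]
    )
    gray[nuc] = (
        profile.nucleus_intensity_mean
        + profile.nucleus_intensity_sd * noise[nuc]
        + profile.texture_amplitude * texture[nuc]
    )
    gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    pixels = np.repeat(gray[:, :, None], 3, axis=2)

    return CellImage(pixels, nuc, cyt_mask, profile.class_name, image_id)


def _cell_rng(seed: int, class_index: int, index: int) -> np.random.Generator:
    # stable per-image substream: generation order cannot change outputs
    return np.random.default_rng([int(seed), int(class_index), int(index)])


def generate_dataset(
    config: GeneratorConfig,
    profiles: list[ClassProfile] | None = None,
) -> tuple[list[CellImage], pd.DataFrame]:
    """Generate a labelled dataset and its manifest.

    Returns the list of cells plus a manifest with one row per image
    (``image_id, label, image_path, nucleus_mask_path, cytoplasm_mask_path``);
    the paths are the relative locations :func:`write_dataset` uses.
    """
    if profiles is None:
        profiles = default_profiles()
    by_name = {p.class_name: p for p in profiles}

    max_radius = max(
        p.cytoplasm_radius_mean + 3 * p.cytoplasm_radius_sd for p in profiles
    )
    if config.image_size < 2 * max_radius + 4:
        raise ValueError(
            f"image_size {config.image_size} too small for the largest cytoplasm "
            f"(needs >= {int(np.ceil(2 * max_radius + 4))})"
        )

    cells: list[CellImage] = []
    rows = []
    for ci, name in enumerate(CLASS_NAMES):
        profile = by_name[name]
        for i in range(config.counts_per_class[ci]):
            image_id = f"{name}_{i:04d}"
            cell = generate_cell(
                profile,
                _cell_rng(config.seed, ci, i),
                image_size=config.image_size,
                background_intensity=config.background_intensity,
                image_id=image_id,
            )
            cells.append(cell)
            rows.append(
                {
                    "image_id": image_id,
                    "label": name,
                    "image_path": f"images/{image_id}.png",
                    "nucleus_mask_path": f"masks/{image_id}_nucleus.png",
                    "cytoplasm_mask_path": f"masks/{image_id}_cytoplasm.png",
                }
            )
    manifest = pd.DataFrame(
        rows,
        columns=["image_id", "label", "image_path", "nucleus_mask_path", "cytoplasm_mask_path"],
    )
    return cells, manifest


def write_dataset(cells: list[CellImage], manifest: pd.DataFrame, outdir: str | Path) -> Path:
    """Write images/masks as PNG and the manifest as CSV under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    by_id = {c.image_id: c for c in cells}
    for row in manifest.itertuples(index=False):
        cell = by_id[row.image_id]
        Image.fromarray(cell.pixels, mode="RGB").save(outdir / row.image_path)
        Image.fromarray(cell.nucleus_mask.astype(np.uint8) * 255, mode="L").save(
            outdir / row.nucleus_mask_path
        )
        Image.fromarray(cell.cytoplasm_mask.astype(np.uint8) * 255, mode="L").save(
            outdir / row.cytoplasm_mask_path
        )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return outdir / "manifest.csv"


def load_dataset(indir: str | Path) -> tuple[list[CellImage], pd.DataFrame]:
    """Load a dataset previously written by :func:`write_dataset`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    cells = []
    for row in manifest.itertuples(index=False):
        for col in ("image_path", "nucleus_mask_path", "cytoplasm_mask_path"):
            if not (indir / getattr(row, col)).exists():
                raise FileNotFoundError(
                    f"image_id {row.image_id}: missing file {getattr(row, col)}"
                )
        pixels = np.asarray(Image.open(indir / row.image_path).convert("RGB"))
        nuc = np.asarray(Image.open(indir / row.nucleus_mask_path).convert("L")) > 127
        cyt = np.asarray(Image.open(indir / row.cytoplasm_mask_path).convert("L")) > 127
        cells.append(CellImage(pixels, nuc, cyt, row.label, row.image_id))
    return cells, manifest


def planted_feature_groups(
    n_per_class: int = 24,
    n_classes: int = 7,
    n_groups: int = 14,
    n_informative: int = 7,
    class_separation: float = 3.0,
    seed: int = 0,
):
    """Feature matrix with a planted informative/noise group structure.

    Informative group ``j`` has mean ``class_separation`` for class
    ``j mod n_classes`` and 0 otherwise (unit-variance Gaussian noise
    everywhere), so the classes form well-separated blobs in the informative
    subspace while the remaining groups are pure noise.  Used to benchmark
    whether wrapper selection recovers the informative set.

    Returns ``(features, labels, informative_mask)`` where ``features`` is a
    :class:`cytoswarm.features.GroupedFeatures` with one column per group.
    """
    from .features import GroupedFeatures

    if not 0 < n_informative <= n_groups:
        raise ValueError("need 0 < n_informative <= n_groups")
    rng = np.random.default_rng([int(seed), 1414])
    n = n_per_class * n_classes
    labels = np.repeat(np.arange(n_classes), n_per_class)
    X = rng.normal(size=(n, n_groups))
    for j in range(n_informative):
        X[labels == (j % n_classes), j] += class_separation
    perm = rng.permutation(n)
    X, labels = X[perm], labels[perm]
    informative = np.zeros(n_groups, dtype=bool)
    informative[:n_informative] = True
    names = [f"informative_{j}" if informative[j] else f"noise_{j}" for j in range(n_groups)]
    gf = GroupedFeatures(X=X, group_names=names, group_slices=[slice(j, j + 1) for j in range(n_groups)])
    return gf, np.array([f"class_{c}" for c in labels]), informative
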