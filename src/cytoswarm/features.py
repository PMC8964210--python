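"""Morphometric and texture features for segmented single-cell images.

Thirteen scalar morphometrics (eight nucleus, three cytoplasm, two
whole-cell) plus a binary-histogram-Fourier (BHF) texture block:

* nucleus: area A_n, bounding-box length L_n and width W_n, aspect ratio
  AR = W_n/L_n, perimeter P_n (boundary-pixel count), roundness
  4*pi*A_n/P_n^2, histogram homogeneity (energy of the 256-bin gray
  histogram), brightness B_n (mean gray);
* cytoplasm: Max_c, Min_c, brightness B_c;
* cell: area (|nucleus| + |cytoplasm|) and the nucleus-to-cell area ratio,
  the classical N/C ratio.

The BHF block is a rotation-invariant texture descriptor in the
LBP-histogram-Fourier family: P-bit binary codes (neighbor >= center) are
histogrammed over rotation classes of uniform patterns, each ones-count row
of that histogram is Fourier-transformed along the rotation index, and the
DFT magnitudes (rotation-invariant by construction) are concatenated with
the all-zeros, all-ones and non-uniform bins.

For subset selection the vector is treated as 14 groups: the 13 scalars
individually plus the BHF block as one selectable unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MORPHO_NAMES",
    "GROUP_NAMES",
    "SUBSET_PRESETS",
    "Morphometrics",
    "BHFVector",
    "FeatureVector",
    "GroupedFeatures",
    "to_gray",
    "extract_morphometrics",
    "compute_bhf",
    "extract_features",
    "reduce_features",
    "subset_mask",
    "feature_table",
    "grouped_from_table",
    "write_feature_table",
    "read_feature_table",
]

MORPHO_NAMES = (
    "nucleus_area",
    "nucleus_length",
    "nucleus_width",
    "aspect_ratio",
    "nucleus_perimeter",
    "nucleus_roundness",
    "nucleus_homogeneity",
    "nucleus_brightness",
    "cytoplasm_max",
    "cytoplasm_min",
    "cytoplasm_brightness",
    "cell_area",
    "nucleus_cell_ratio",
)

#: Selectable feature groups: the 13 scalars plus the BHF block as one unit.
GROUP_NAMES = MORPHO_NAMES + ("bhf",)

#: The pruned seven-feature set: three nucleus features (area, roundness,
#: brightness), cytoplasm brightness, whole-cell area, the N/C ratio, and the
#: BHF texture block counted as the seventh group.
SUBSET_PRESETS = {
    "paper7": (
        "nucleus_area",
        "nucleus_roundness",
        "nucleus_brightness",
        "cytoplasm_brightness",
        "cell_area",
        "nucleus_cell_ratio",
        "bhf",
    ),
    "all": GROUP_NAMES,
}

_LUMA = np.array([0.299, 0.587, 0.114])


def to_gray(pixels: np.ndarray) -> np.ndarray:
    """Luma conversion 0.299 R + 0.587 G + 0.114 B, rounded half-up."""
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim == 2:
        g = arr
    else:
        g = arr @ _LUMA
    return np.clip(np.floor(g + 0.5), 0, 255).astype(np.int64)


@dataclass(frozen=True)
class Morphometrics:
    nucleus_area: float
    nucleus_length: float
    nucleus_width: float
    aspect_ratio: float
    nucleus_perimeter: float
    nucleus_roundness: float
    nucleus_homogeneity: float
    nucleus_brightness: float
    cytoplasm_max: float
    cytoplasm_min: float
    cytoplasm_brightness: float
    cell_area: float
    nucleus_cell_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MORPHO_NAMES], dtype=float)


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def extract_morphometrics(
    gray: np.ndarray, nucleus_mask: np.ndarray, cytoplasm_mask: np.ndarray
) -> Morphometrics:
    """Compute the 13 scalar morphometrics from a gray image and two masks.

    Conventions: L_n/W_n are the larger/smaller side of the axis-aligned
    bounding box of the nucleus; the perimeter counts nucleus pixels with at
    least one 4-neighbor outside the mask (image border counts as outside);
    homogeneity is the energy sum(p_i^2) of the normalized 256-bin gray
    histogram of nucleus pixels.
    """
    gray = np.asarray(gray)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cytoplasm_mask = np.asarray(cytoplasm_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("nucleus_mask is empty")
    if not cytoplasm_mask.any():
        raise ValueError("cytoplasm_mask is empty")
    if (nucleus_mask & cytoplasm_mask).any():
        raise ValueError("nucleus and cytoplasm masks must be disjoint")

    area = int(nucleus_mask.sum())
    ys, xs = np.nonzero(nucleus_mask)
    h = int(ys.max() - ys.min() + 1)
    w = int(xs.max() - xs.min() + 1)
    length, width = max(h, w), min(h, w)
    aspect = width / length

    interior = ndimage.binary_erosion(nucleus_mask, structure=_CROSS, border_value=0)
    perimeter = int(area - interior.sum())
    roundness = 4.0 * np.pi * area / perimeter**2

    nuc_vals = gray[nucleus_mask].astype(np.int64)
    hist = np.bincount(nuc_vals, minlength=256)
    p = hist / area
    homogeneity = float((p**2).sum())

    cyt_vals = gray[cytoplasm_mask]
    cell_area = area + int(cytoplasm_mask.sum())

    return Morphometrics(
        nucleus_area=float(area),
        nucleus_length=float(length),
        nucleus_width=float(width),
        aspect_ratio=float(aspect),
        nucleus_perimeter=float(perimeter),
        nucleus_roundness=float(roundness),
        nucleus_homogeneity=homogeneity,
        nucleus_brightness=float(nuc_vals.mean()),
        cytoplasm_max=float(cyt_vals.max()),
        cytoplasm_min=float(cyt_vals.min()),
        cytoplasm_brightness=float(cyt_vals.mean()),
        cell_area=float(cell_area),
        nucleus_cell_ratio=float(area / cell_area),
    )


@dataclass(frozen=True)
class BHFVector:
    """Binary-histogram-Fourier texture block.

    ``magnitudes[n-1, f]`` is |DFT| at frequency ``f`` of the rotation-class
    histogram row for uniform patterns with ``n`` ones (1 <= n <= P-1,
    0 <= f <= P//2).  ``rotation_histogram`` keeps the pre-DFT rows so the
    normalization invariant (rows + the three special bins sum to 1) and the
    rotation behaviour stay inspectable.
    """

    magnitudes: np.ndarray
    bin_all_zeros: float
    bin_all_ones: float
    bin_nonuniform: float
    rotation_histogram: np.ndarray
    n_neighbors: int = 8
    radius: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.concatenate(
            [
                self.magnitudes.ravel(),
                [self.bin_all_zeros, self.bin_all_ones, self.bin_nonuniform],
            ]
        )

    def names(self) -> list[str]:
        P = self.n_neighbors
        out = [f"bhf_n{n}_f{f}" for n in range(1, P) for f in range(P // 2 + 1)]
        out += ["bhf_zeros", "bhf_ones", "bhf_nonuniform"]
        return out

    @property
    def histogram_total(self) -> float:
        """Total pre-DFT histogram mass (should be 1)."""
        return float(
            self.rotation_histogram.sum()
            + self.bin_all_zeros
            + self.bin_all_ones
            + self.bin_nonuniform
        )


def bhf_length(n_neighbors: int = 8) -> int:
    return (n_neighbors - 1) * (n_neighbors // 2 + 1) + 3


def _neighbor_values(gray: np.ndarray, P: int, R: float) -> np.ndarray:
    """Bilinearly interpolated circular-neighbor values, shape (P, H, W)."""
    pad = int(np.ceil(R)) + 1
    g = np.pad(gray.astype(float), pad, mode="edge")
    H, W = gray.shape
    out = np.empty((P, H, W))
    for p in range(P):
        angle = 2.0 * np.pi * p / P
        dx = R * np.cos(angle)
        dy = -R * np.sin(angle)  # rows grow downwards
        fy, fx = int(np.floor(dy)), int(np.floor(dx))
        ty, tx = dy - fy, dx - fx

        def block(oy: int, ox: int) -> np.ndarray:
            return g[pad + oy : pad + oy + H, pad + ox : pad + ox + W]

        out[p] = (
            (1 - ty) * (1 - tx) * block(fy, fx)
            + (1 - ty) * tx * block(fy, fx + 1)
            + ty * (1 - tx) * block(fy + 1, fx)
            + ty * tx * block(fy + 1, fx + 1)
        )
    return out


def compute_bhf(
    gray: np.ndarray,
    mask: np.ndarray,
    n_neighbors: int = 8,
    radius: float = 1.0,
) -> BHFVector:
    """Binary-histogram-Fourier descriptor over the masked region.

    Codes are computed only at pixels whose full sampling neighborhood lies
    inside the mask (square erosion by ceil(radius)); ties neighbor == center
    count as 1, with a 1e-6 interpolation tolerance so constant regions give
    all-ones codes exactly.
    """
    gray = np.asarray(gray)
    mask = np.asarray(mask, dtype=bool)
    P = int(n_neighbors)
    pad = int(np.ceil(radius))
    valid = ndimage.binary_erosion(
        mask, structure=np.ones((2 * pad + 1, 2 * pad + 1), dtype=bool), border_value=0
    )
    if not valid.any():
        raise ValueError("mask too small: no pixel has its full neighborhood inside the mask")

    neigh = _neighbor_values(gray, P, radius)  # (P, H, W)
    center = gray.astype(float)[valid]
    bits = neigh[:, valid] >= center[None, :] - 1e-6  # (P, n_valid)

    n_ones = bits.sum(axis=0)
    transitions = (bits != np.roll(bits, -1, axis=0)).sum(axis=0)
    uniform = transitions <= 2
    n_valid = bits.shape[1]

    all_zeros = n_ones == 0
    all_ones = n_ones == P
    nonuniform = ~uniform
    mid = uniform & ~all_zeros & ~all_ones  # uniform with 1..P-1 ones

    hist = np.zeros((P - 1, P))
    if mid.any():
        prev = np.roll(bits, 1, axis=0)
        start = bits & ~prev  # one True per uniform mid column
        r = start[:, mid].argmax(axis=0)
        n = n_ones[mid]
        np.add.at(hist, (n - 1, r), 1.0)
    hist /= n_valid

    spectra = np.fft.fft(hist, axis=1)
    magnitudes = np.abs(spectra[:, : P // 2 + 1])

    return BHFVector(
        magnitudes=magnitudes,
        bin_all_zeros=float(all_zeros.sum() / n_valid),
        bin_all_ones=float(all_ones.sum() / n_valid),
        bin_nonuniform=float(nonuniform.sum() / n_valid),
        rotation_histogram=hist,
        n_neighbors=P,
        radius=float(radius),
    )


@dataclass
class FeatureVector:
    """The full per-cell feature vector: 13 morphometrics + BHF block."""

    morpho: Morphometrics
    bhf: BHFVector
    label: str | None = None
    image_id: str | None = None

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.morpho.as_array(), self.bhf.as_array()])

    @property
    def names(self) -> list[str]:
        return list(MORPHO_NAMES) + self.bhf.names()


def extract_features(cell, n_neighbors: int = 8, radius: float = 1.0) -> FeatureVector:
    """Extract the full feature vector from a cell (pixels + two masks).

    BHF is computed over the whole cell region (nucleus plus cytoplasm).
    """
    gray = to_gray(cell.pixels)
    morpho = extract_morphometrics(gray, cell.nucleus_mask, cell.cytoplasm_mask)
    bhf = compute_bhf(
        gray, cell.nucleus_mask | cell.cytoplasm_mask, n_neighbors=n_neighbors, radius=radius
    )
    return FeatureVector(
        morpho=morpho,
        bhf=bhf,
        label=getattr(cell, "label", None),
        image_id=getattr(cell, "image_id", None),
    )


def subset_mask(subset) -> np.ndarray:
    """Normalize a preset name or boolean sequence to a length-14 group mask."""
    if isinstance(subset, str):
        if subset not in SUBSET_PRESETS:
            raise KeyError(f"unknown subset preset {subset!r}")
        keep = SUBSET_PRESETS[subset]
        mask = np.array([name in keep for name in GROUP_NAMES])
    else:
        mask = np.asarray(subset, dtype=bool)
        if mask.shape != (len(GROUP_NAMES),):
            raise ValueError(f"subset mask must have length {len(GROUP_NAMES)}")
    if not mask.any():
        raise ValueError("subset must keep at least one feature group")
    return mask


def reduce_features(fv: FeatureVector, subset) -> tuple[np.ndarray, list[str]]:
    """Keep the flagged feature groups, concatenated in canonical order."""
    mask = subset_mask(subset)
    values: list[np.ndarray] = []
    names: list[str] = []
    morpho = fv.morpho.as_array()
    for i, name in enumerate(MORPHO_NAMES):
        if mask[i]:
            values.append(morpho[i : i + 1])
            names.append(name)
    if mask[-1]:
        values.append(fv.bhf.as_array())
        names.extend(fv.bhf.names())
    return np.concatenate(values), names


@dataclass
class GroupedFeatures:
    """A feature matrix with named column groups for subset selection."""

    X: np.ndarray
    group_names: list[str]
    group_slices: list[slice]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if len(self.group_names) != len(self.group_slices):
            raise ValueError("group_names and group_slices must have the same length")

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def select(self, mask) -> np.ndarray:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_groups,):
            raise ValueError(f"mask must have length {self.n_groups}")
        if not mask.any():
            raise ValueError("mask must keep at least one group")
        cols = np.concatenate(
            [np.arange(s.start, s.stop) for s, m in zip(self.group_slices, mask) if m]
        )
        return self.X[:, cols]

    def rows(self, idx) -> "GroupedFeatures":
        return GroupedFeatures(self.X[idx], list(self.group_names), list(self.group_slices))


def feature_table(cells, n_neighbors: int = 8, radius: float = 1.0) -> pd.DataFrame:
    """Feature table with one row per cell: image_id, label, then columns."""
    rows = []
    columns = None
    for cell in cells:
        fv = extract_features(cell, n_neighbors=n_neighbors, radius=radius)
        if columns is None:
            columns = fv.names
        rows.append([fv.image_id, fv.label, *fv.values])
    if columns is None:
        columns = list(MORPHO_NAMES) + [
            f"bhf_{i}" for i in range(bhf_length(n_neighbors))
        ]
        return pd.DataFrame(columns=["image_id", "label", *columns])
    return pd.DataFrame(rows, columns=["image_id", "label", *columns])


def grouped_from_table(df: pd.DataFrame) -> tuple[GroupedFeatures, np.ndarray]:
    """Split a feature table into a GroupedFeatures matrix and its labels.

    The 13 morphometrics are single-column groups; every ``bhf_*`` column
    belongs to the one BHF group.
    """
    feature_cols = [c for c in df.columns if c not in ("image_id", "label")]
    for name in MORPHO_NAMES:
        if name not in feature_cols:
            raise ValueError(f"feature table is missing column {name!r}")
    bhf_cols = [c for c in feature_cols if c.startswith("bhf_")]
    ordered = list(MORPHO_NAMES) + bhf_cols
    X = df[ordered].to_numpy(dtype=float)
    slices = [slice(i, i + 1) for i in range(len(MORPHO_NAMES))]
    slices.append(slice(len(MORPHO_NAMES), len(ordered)))
    gf = GroupedFeatures(X=X, group_names=list(GROUP_NAMES), group_slices=slices)
    labels = df["label"].to_numpy()
    return gf, labels


_SCHEMA_COMMENT = "# cytoswarm feature table v1: image_id,label,13 morphometrics,bhf block"


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_SCHEMA_COMMENT + "\n")
        df.to_csv(fh, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
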