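"""Core domain containers for MSI pipelines.

An MSI acquisition is a 2-D raster of pixels (typically 100 µm pitch), each
carrying one mass spectrum per ionization mode.  After preprocessing the
dataset collapses to a :class:`PeakMatrix` — pixels × aligned m/z features —
which is the common currency of segmentation, classification, marker
statistics and grading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

POSITIVE = "positive"
NEGATIVE = "negative"
MODES = (POSITIVE, NEGATIVE)

#: m/z window acquired in both ionization modes (daltons).
DEFAULT_MASS_RANGE = (460.0, 1200.0)

#: Pixel pitch of the acquisition raster in micrometres.
DEFAULT_SPACING_UM = 100.0


class HistologyLabel(str, Enum):
    """Histopathological compartments of a treated liver metastasis.

    ``MUCIN_MATRIX`` pools loose mucin with off-tissue MALDI matrix noise,
    which share a low-lipid spectral appearance.  ``NECROSIS_UNSPECIFIED``
    is for annotations that do not subtype necrosis into usual necrosis
    (UN, tumor-progression necrosis) versus infarct-like necrosis (ILN,
    treatment-response necrosis).
    """

    ADJACENT_LIVER = "adjacent_liver"
    TUMOR = "tumor"
    USUAL_NECROSIS = "usual_necrosis"
    INFARCT_LIKE_NECROSIS = "infarct_like_necrosis"
    NECROSIS_UNSPECIFIED = "necrosis_unspecified"
    FIBROSIS = "fibrosis"
    INFLAMMATION = "inflammation"
    MUCIN_MATRIX = "mucin_matrix"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Display palette: liver blue, tumor red, necrosis purple (ILN a lighter
#: shade so the subtypes remain distinguishable), fibrosis grey,
#: inflammation green, mucin/matrix white.
LABEL_COLORS: dict[HistologyLabel, str] = {
    HistologyLabel.ADJACENT_LIVER: "#1f4fd8",
    HistologyLabel.TUMOR: "#d81f1f",
    HistologyLabel.USUAL_NECROSIS: "#6a1fd8",
    HistologyLabel.INFARCT_LIKE_NECROSIS: "#a877e8",
    HistologyLabel.NECROSIS_UNSPECIFIED: "#80d",
    HistologyLabel.FIBROSIS: "#9c9c9c",
    HistologyLabel.INFLAMMATION: "#1fa83c",
    HistologyLabel.MUCIN_MATRIX: "#ffffff",
}


def _check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return mode


@dataclass
class Spectrum:
    """A single mass spectrum: an m/z axis with non-negative intensities."""

    mz: np.ndarray
    intensities: np.ndarray
    mode: str = POSITIVE

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        _check_mode(self.mode)
        if self.mz.shape != self.intensities.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensities must be equal-length 1-D arrays")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all intensities."""
        return float(self.intensities.sum())

    def crop(self, mass_range: tuple[float, float]) -> "Spectrum":
        """Restrict to ``lo <= m/z <= hi`` without reordering."""
        lo, hi = mass_range
        keep = (self.mz >= lo) & (self.mz <= hi)
        return Spectrum(self.mz[keep], self.intensities[keep], self.mode)


@dataclass
class PixelGrid:
    """Integer (x, y) positions of acquired pixels on a regular raster."""

    coords: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("pixel coordinates must be unique")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def positions_um(self) -> np.ndarray:
        """Physical pixel positions in micrometres."""
        return self.coords * self.spacing_um

    def index_map(self) -> dict[tuple[int, int], int]:
        return {(int(x), int(y)): i for i, (x, y) in enumerate(self.coords)}

    @classmethod
    def full_raster(cls, width: int, height: int,
                    spacing_um: float = DEFAULT_SPACING_UM) -> "PixelGrid":
        """Dense raster in row-major (y, x) order."""
        ys, xs = np.mgrid[0:height, 0:width]
        return cls(np.column_stack([xs.ravel(), ys.ravel()]), spacing_um)


@dataclass
class MSIDataset:
    """One ionization mode's spectra over a pixel grid."""

    grid: PixelGrid
    spectra: list[Spectrum]
    mode: str = POSITIVE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_mode(self.mode)
        if len(self.spectra) != len(self.grid):
            raise ValueError("one spectrum required per grid pixel")
        for s in self.spectra:
            if s.mode != self.mode:
                raise ValueError("all spectra must share the dataset polarity")

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass(frozen=True)
class FeatureDescriptor:
    """A mode-tagged centroid m/z feature, e.g. ``POS_703.57``."""

    mode: str
    mz: float

    def __post_init__(self) -> None:
        _check_mode(self.mode)

    @property
    def name(self) -> str:
        prefix = "POS" if self.mode == POSITIVE else "NEG"
        return f"{prefix}_{self.mz:.2f}"

    @classmethod
    def from_name(cls, name: str) -> "FeatureDescriptor":
        try:
            prefix, mz = name.split("_", 1)
            mode = {"POS": POSITIVE, "NEG": NEGATIVE}[prefix]
            return cls(mode, float(mz))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"not a feature name: {name!r}") from exc

    def sort_key(self) -> tuple[int, float]:
        # positive mode sorts first so joint matrices read POS_ then NEG_
        return (0 if self.mode == POSITIVE else 1, self.mz)


@dataclass
class PeakMatrix:
    """Pixels × aligned features; non-negative intensities.

    Features are kept sorted by (mode, m/z) with positive mode first, and
    names must be unique — two features of the same mode may not collide at
    two-decimal precision.
    """

    grid: PixelGrid
    features: list[FeatureDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid), len(self.features)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.grid)} pixels x {len(self.features)} features")
        if np.any(self.values < 0):
            raise ValueError("peak intensities must be non-negative")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        keys = [f.sort_key() for f in self.features]
        if keys != sorted(keys):
            idx = sorted(range(len(keys)), key=lambda i: keys[i])
            self.features = [self.features[i] for i in idx]
            self.values = self.values[:, idx]

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def n_features(self) -> int:
        return len(self.features)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError as exc:
            raise KeyError(f"no feature named {name!r}") from exc
        return self.values[:, j]

    def select_features(self, names: list[str]) -> "PeakMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return PeakMatrix(self.grid, [self.features[i] for i in idx],
                          self.values[:, idx])

    def tic_scaled(self, target: float | None = None) -> "PeakMatrix":
        """Per-pixel TIC scaling of the matrix rows.

        Every row is scaled so its sum equals ``target`` (default: the
        median raw row TIC, keeping intensities in a familiar range).
        All-zero rows are left untouched.
        """
        sums = self.values.sum(axis=1)
        if target is None:
            pos = sums[sums > 0]
            target = float(np.median(pos)) if pos.size else 1.0
        scale = np.ones_like(sums)
        nz = sums > 0
        scale[nz] = target / sums[nz]
        return PeakMatrix(self.grid, list(self.features),
                          self.values * scale[:, None])
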