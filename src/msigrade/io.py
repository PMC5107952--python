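"""Reading and writing MSI data, peak matrices and label maps.

imzML (continuous or processed dialect) is the interchange format for
spectra; peak matrices and label maps travel as ``x,y,...`` CSV/TSV tables.
imzML stores 1-based pixel coordinates — they are converted to the package's
0-based convention on read and restored on write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (DEFAULT_MASS_RANGE, DEFAULT_SPACING_UM, NEGATIVE, POSITIVE,
                   FeatureDescriptor, HistologyLabel, MSIDataset, PeakMatrix,
                   PixelGrid, Spectrum)


def read_imzml(path: str, mass_range: tuple[float, float] = DEFAULT_MASS_RANGE,
               mode: str | None = None,
               spacing_um: float = DEFAULT_SPACING_UM) -> MSIDataset:
    """Load an imzML file into an :class:`MSIDataset`.

    Parameters
    ----------
    path : str
        Path to the ``.imzML`` XML file (the paired ``.ibd`` must sit
        beside it).
    mass_range : (lo, hi)
        m/z values outside this closed window are dropped.
    mode : str, optional
        Override the polarity; by default taken from the file metadata and
        falling back to positive.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    parser = ImzMLParser(path)
    if not parser.coordinates:
        raise ValueError(f"{path}: imzML file contains no pixels")
    if mode is None:
        polarity = getattr(parser, "polarity", "") or ""
        mode = NEGATIVE if "negative" in str(polarity).lower() else POSITIVE
    coords = []
    spectra = []
    for i, (x, y, *_z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        s = Spectrum(np.asarray(mz), np.maximum(np.asarray(inten), 0.0), mode)
        spectra.append(s.crop(mass_range))
        coords.append((x - 1, y - 1))  # imzML is 1-based
    grid = PixelGrid(np.array(coords), spacing_um)
    return MSIDataset(grid, spectra, mode, metadata={"source": path})


def write_imzml(dataset: MSIDataset, path: str) -> None:
    """Write a dataset as processed-dialect imzML (per-pixel m/z axes)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    polarity = "positive" if dataset.mode == POSITIVE else "negative"
    with ImzMLWriter(path, polarity=polarity, mode="processed") as writer:
        for (x, y), s in zip(dataset.grid.coords, dataset.spectra):
            writer.addSpectrum(s.mz, s.intensities, (int(x) + 1, int(y) + 1))


def _delimiter(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def save_peak_matrix(pm: PeakMatrix, path: str) -> None:
    """Write a peak matrix as a delimited table ``x,y,<feature names>``.

    The round trip through :func:`load_peak_matrix` is lossless to full
    float precision.
    """
    df = pd.DataFrame(pm.values, columns=pm.feature_names)
    df.insert(0, "y", pm.grid.coords[:, 1])
    df.insert(0, "x", pm.grid.coords[:, 0])
    # default float formatting is the shortest exact repr, so the
    # round trip through the reader is lossless
    df.to_csv(path, sep=_delimiter(path), index=False)


def load_peak_matrix(path: str,
                     spacing_um: float = DEFAULT_SPACING_UM) -> PeakMatrix:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_delimiter(path), float_precision="round_trip")
    if list(df.columns[:2]) != ["x", "y"]:
        raise ValueError(f"{path}: expected leading 'x,y' columns")
    features = [FeatureDescriptor.from_name(c) for c in df.columns[2:]]
    grid = PixelGrid(df[["x", "y"]].to_numpy(), spacing_um)
    return PeakMatrix(grid, features, df.iloc[:, 2:].to_numpy(dtype=float))


def save_label_map(labels: list[HistologyLabel | None], grid: PixelGrid,
                   path: str) -> None:
    """Write per-pixel histology labels as ``x,y,label`` CSV."""
    df = pd.DataFrame({
        "x": grid.coords[:, 0],
        "y": grid.coords[:, 1],
        "label": ["" if l is None else HistologyLabel(l).value for l in labels],
    })
    df.to_csv(path, sep=_delimiter(path), index=False)


def load_label_map(path: str, spacing_um: float = DEFAULT_SPACING_UM
                   ) -> tuple[list[HistologyLabel | None], PixelGrid]:
    df = pd.read_csv(path, sep=_delimiter(path), keep_default_na=False)
    if list(df.columns) != ["x", "y", "label"]:
        raise ValueError(f"{path}: expected 'x,y,label' columns")
    labels = [HistologyLabel(v) if v else None for v in df["label"]]
    return labels, PixelGrid(df[["x", "y"]].to_numpy(), spacing_um)


def save_label_image(labels: list[HistologyLabel | None], grid: PixelGrid,
                     path: str) -> None:
    """Render a label map as a color-coded PNG/TIFF image.

    Colors follow the package palette (liver blue, tumor red, necrosis
    purple shades, fibrosis grey, inflammation green, mucin/matrix white);
    unlabelled pixels are black.
    """
    from PIL import Image

    from .core import LABEL_COLORS

    w = int(grid.coords[:, 0].max()) + 1
    h = int(grid.coords[:, 1].max()) + 1
    img = np.zeros((h, w, 3), dtype=np.uint8)
    for (x, y), lab in zip(grid.coords, labels):
        if lab is None:
            continue
        hexcol = LABEL_COLORS[HistologyLabel(lab)].lstrip("#")
        if len(hexcol) == 3:
            hexcol = "".join(2 * c for c in hexcol)
        img[int(y), int(x)] = [int(hexcol[i:i + 2], 16) for i in (0, 2, 4)]
    Image.fromarray(img).save(path)


@dataclass
class CoregistrationResult:
    """Outcome of pairing two polarity grids into a joint matrix."""

    matrix: PeakMatrix
    pairs: np.ndarray          # (n_paired, 2): positive index, negative index
    dropped_positive: np.ndarray
    dropped_negative: np.ndarray


def coregister_modes(pos: PeakMatrix, neg: PeakMatrix,
                     offset_um: tuple[float, float] = (50.0, 50.0)
                     ) -> CoregistrationResult:
    """Pair positive- and negative-mode pixels into one joint matrix.

    The negative raster is acquired at a fixed (dx, dy) micrometre offset
    from the positive raster (50 µm in both axes for an interleaved dual
    acquisition on a 100 µm grid).  Each positive pixel is paired with its
    nearest offset-corrected negative pixel within one pixel pitch;
    Euclidean ties are broken by the lowest (y, x) negative coordinate.
    Each mode is TIC-scaled independently before concatenation because
    ionization efficiencies differ between polarities.

    Returns the joint matrix on the paired positive pixels with ``POS_``
    features followed by ``NEG_`` features.
    """
    if pos.grid.spacing_um != neg.grid.spacing_um:
        raise ValueError("grids must share pixel spacing")
    spacing = pos.grid.spacing_um
    dx, dy = offset_um
    if np.hypot(dx, dy) >= spacing:
        raise ValueError("offset magnitude must be below the pixel pitch")

    pos_um = pos.grid.positions_um
    neg_um = neg.grid.positions_um + np.array([dx, dy])
    tree = cKDTree(neg_um)
    k = min(4, len(neg.grid))
    dist, idx = tree.query(pos_um, k=k)
    dist = np.atleast_2d(dist.reshape(len(pos_um), -1))
    idx = np.atleast_2d(idx.reshape(len(pos_um), -1))

    pairs = []
    dropped_pos = []
    used = {}
    for i in range(len(pos_um)):
        best = dist[i, 0]
        if not np.isfinite(best) or best > spacing:
            dropped_pos.append(i)
            continue
        # tie-break among equidistant candidates by lowest (y, x)
        tied = [int(idx[i, j]) for j in range(dist.shape[1])
                if np.isclose(dist[i, j], best, rtol=0, atol=1e-9)]
        j = min(tied, key=lambda t: (neg.grid.coords[t, 1],
                                     neg.grid.coords[t, 0]))
        pairs.append((i, j))
        used[j] = True
    if not pairs:
        raise ValueError("disjoint grids: no pixel pair within one pitch")
    pairs = np.array(pairs, dtype=int)
    dropped_neg = np.array(sorted(set(range(len(neg.grid))) - set(used)),
                           dtype=int)

    pos_scaled = pos.tic_scaled()
    neg_scaled = neg.tic_scaled()
    joint_grid = PixelGrid(pos.grid.coords[pairs[:, 0]], spacing)
    features = list(pos.features) + list(neg.features)
    values = np.hstack([pos_scaled.values[pairs[:, 0]],
                        neg_scaled.values[pairs[:, 1]]])
    joint = PeakMatrix(joint_grid, features, values)
    return CoregistrationResult(joint, pairs, np.array(dropped_pos, dtype=int),
                                dropped_neg)
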