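"""PLS-DA histology classification from a labelled spectral library.

Partial least squares discriminant analysis regresses a one-hot class
indicator matrix on column-centered peak intensities with an A-component
PLS2 (NIPALS) fit; a pixel is assigned the class with the largest
predicted score.  With A equal to the rank of X the fit coincides with
ordinary least squares, so few components act as the regularizer.

The high-level :class:`PixelClassifier` trains and predicts on the same
spatially augmented log-TIC representation the segmentation uses, which is
what makes single-pixel histology calls reliable under multiplicative
noise; the low-level functions operate on whatever matrix they are given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .core import HistologyLabel, PeakMatrix
from .segment import log_tic_transform, spatial_augment

#: Candidate component counts for cross-validation.  The augmented
#: representation multiplies the feature space ninefold, so useful
#: components extend past the usual single-spectrum range.
DEFAULT_CV_CANDIDATES = (4, 8, 12, 16)


@dataclass
class SpectralLibrary:
    """Labelled training spectra pooled across samples."""

    X: np.ndarray
    labels: list[HistologyLabel]
    feature_names: list[str]
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != len(self.labels):
            raise ValueError("one label per library row required")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature names must match columns")
        if not self.sample_ids:
            self.sample_ids = [0] * self.X.shape[0]
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("one sample id per row required")
        if self.X.shape[0] == 0:
            raise ValueError("library has zero labelled pixels")

    @property
    def classes(self) -> list[HistologyLabel]:
        return sorted(set(self.labels), key=lambda l: l.value)

    def class_counts(self) -> dict[HistologyLabel, int]:
        out: dict[HistologyLabel, int] = {}
        for l in self.labels:
            out[l] = out.get(l, 0) + 1
        return out


def build_spectral_library(datasets, include_mucin: bool = True
                           ) -> SpectralLibrary:
    """Pool labelled pixels from segmented, histology-mapped samples.

    ``datasets`` is a sequence of ``(PeakMatrix, SegmentationMap,
    SegmentHistologyMapping)`` triples.  Feature sets are intersected by
    name (order of the first sample preserved); every pixel whose cluster
    has a histology mapping contributes one row.  ``include_mucin=False``
    drops mucin/matrix rows, which are usually not wanted in training.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets supplied")
    common = [n for n in datasets[0][0].feature_names
              if all(n in pm.feature_names for pm, _, _ in datasets)]
    if not common:
        raise ValueError("empty intersection of feature names")
    rows, labels, sample_ids = [], [], []
    for sid, (pm, seg, mapping) in enumerate(datasets):
        sub = pm.select_features(common)
        pixel_labels = mapping.pixel_labels(seg)
        for i, lab in enumerate(pixel_labels):
            if lab is None:
                continue
            if not include_mucin and lab == HistologyLabel.MUCIN_MATRIX:
                continue
            rows.append(sub.values[i])
            labels.append(lab)
            sample_ids.append(sid)
    if not rows:
        raise ValueError("library has zero labelled pixels")
    return SpectralLibrary(np.vstack(rows), labels, common, sample_ids)


def library_from_annotations(pm: PeakMatrix,
                             annotation: list[HistologyLabel | None],
                             sample_id=0, include_mucin: bool = True,
                             X: np.ndarray | None = None) -> SpectralLibrary:
    """Library straight from a per-pixel annotation map (no segmentation).

    ``X`` optionally overrides the raw matrix values with a transformed
    representation of the same pixels (e.g. spatially augmented vectors).
    """
    if len(annotation) != len(pm.grid):
        raise ValueError("annotation length must match the pixel grid")
    values = pm.values if X is None else np.asarray(X, dtype=float)
    names = (pm.feature_names if X is None
             else [f"f{j}" for j in range(values.shape[1])])
    keep = [i for i, a in enumerate(annotation)
            if a is not None and (include_mucin or
                                  HistologyLabel(a) != HistologyLabel.MUCIN_MATRIX)]
    if not keep:
        raise ValueError("library has zero labelled pixels")
    return SpectralLibrary(values[keep],
                           [HistologyLabel(annotation[i]) for i in keep],
                           names, [sample_id] * len(keep))


def subsample_library(lib: SpectralLibrary, n_per_class: int,
                      seed: int = 0) -> SpectralLibrary:
    """Seeded per-class subsampling (class-imbalance utility)."""
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for c in lib.classes:
        idx = [i for i, l in enumerate(lib.labels) if l == c]
        if len(idx) > n_per_class:
            idx = list(rng.choice(idx, size=n_per_class, replace=False))
        keep.extend(sorted(idx))
    return SpectralLibrary(lib.X[keep], [lib.labels[i] for i in keep],
                           lib.feature_names,
                           [lib.sample_ids[i] for i in keep])


@dataclass
class PLSDAModel:
    """A trained PLS-DA classifier."""

    pls: PLSRegression
    class_order: list[HistologyLabel]
    feature_names: list[str]
    n_components: int

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.pls.predict(np.asarray(X, dtype=float)))

    def predict_labels(self, X: np.ndarray) -> list[HistologyLabel]:
        scores = self.predict_scores(X)
        # argmax takes the first maximum, i.e. ties break by class_order
        return [self.class_order[j] for j in np.argmax(scores, axis=1)]


def one_hot(labels: list[HistologyLabel],
            class_order: list[HistologyLabel]) -> np.ndarray:
    idx = {c: j for j, c in enumerate(class_order)}
    Y = np.zeros((len(labels), len(class_order)))
    for i, l in enumerate(labels):
        Y[i, idx[l]] = 1.0
    return Y


def train_plsda(lib: SpectralLibrary, n_components: int,
                scale: bool = False) -> PLSDAModel:
    """Fit an A-component PLS2 regression of one-hot labels on X.

    X and Y are column-centered by the fit (so the model is invariant to
    adding a constant to any feature); unit-variance scaling is off by
    default because TIC-normalized intensities already share a scale.
    Deterministic given its inputs and invariant to row order.
    """
    classes = lib.classes
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    max_rank = min(lib.X.shape[1], lib.X.shape[0] - 1)
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    Y = one_hot(lib.labels, classes)
    pls = PLSRegression(n_components=n_components, scale=scale)
    pls.fit(lib.X, Y)
    return PLSDAModel(pls, classes, list(lib.feature_names), n_components)


def cross_validate_components(lib: SpectralLibrary,
                              candidates=DEFAULT_CV_CANDIDATES,
                              folds: int = 5, seed: int = 0,
                              scale: bool = False
                              ) -> tuple[int, dict[int, tuple[float, float]]]:
    """Choose A by stratified k-fold accuracy with the one-standard-error rule.

    Returns ``(chosen_A, {A: (mean_accuracy, sd_accuracy)})``; the chosen A
    is the smallest candidate whose mean accuracy is within one standard
    error of the best candidate's.
    """
    candidates = sorted(set(int(a) for a in candidates))
    if not candidates:
        raise ValueError("no candidate component counts")
    if folds < 2:
        raise ValueError("folds must be at least 2")
    counts = lib.class_counts()
    small = [c for c, n in counts.items() if n < folds]
    if small:
        raise ValueError(f"classes with fewer rows than folds: {small}")
    y_str = np.array([l.value for l in lib.labels])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(lib.X, y_str))
    results: dict[int, tuple[float, float]] = {}
    for a in candidates:
        accs = []
        for train, test in splits:
            sub = SpectralLibrary(lib.X[train],
                                  [lib.labels[i] for i in train],
                                  lib.feature_names,
                                  [lib.sample_ids[i] for i in train])
            model = train_plsda(sub, a, scale=scale)
            pred = model.predict_labels(lib.X[test])
            truth = [lib.labels[i] for i in test]
            accs.append(np.mean([p == t for p, t in zip(pred, truth)]))
        results[a] = (float(np.mean(accs)), float(np.std(accs, ddof=1)))
    best_a = max(candidates, key=lambda a: results[a][0])
    best_mean, best_sd = results[best_a]
    se = best_sd / np.sqrt(folds)
    chosen = min(a for a in candidates if results[a][0] >= best_mean - se)
    return chosen, results


def predict_histology(model: PLSDAModel, pm: PeakMatrix
                      ) -> tuple[list[HistologyLabel], np.ndarray]:
    """Classify every pixel of a peak matrix; returns (labels, scores)."""
    missing = [n for n in model.feature_names if n not in pm.feature_names]
    if missing:
        raise ValueError(f"matrix lacks model features: {missing}")
    sub = pm.select_features(model.feature_names)
    scores = model.predict_scores(sub.values)
    labels = [model.class_order[j] for j in np.argmax(scores, axis=1)]
    return labels, scores


def save_model(model: PLSDAModel, path: str) -> None:
    """Serialize a trained model to a single portable file (joblib)."""
    import joblib

    joblib.dump({"pls": model.pls,
                 "class_order": [c.value for c in model.class_order],
                 "feature_names": model.feature_names,
                 "n_components": model.n_components}, path)


def load_model(path: str) -> PLSDAModel:
    import joblib

    data = joblib.load(path)
    return PLSDAModel(data["pls"],
                      [HistologyLabel(c) for c in data["class_order"]],
                      list(data["feature_names"]),
                      int(data["n_components"]))


def train_necrosis_subtyper(lib: SpectralLibrary, n_components: int = 2
                            ) -> PLSDAModel:
    """Two-class UN vs ILN model from a library's necrosis rows.

    Mirrors the workflow of mining the pooled necrosis segment after
    the six-histology segmentation has been established.
    """
    keep = [i for i, l in enumerate(lib.labels)
            if l in (HistologyLabel.USUAL_NECROSIS,
                     HistologyLabel.INFARCT_LIKE_NECROSIS)]
    if not keep:
        raise ValueError("library has no subtyped necrosis rows")
    sub = SpectralLibrary(lib.X[keep], [lib.labels[i] for i in keep],
                          lib.feature_names, [lib.sample_ids[i] for i in keep])
    return train_plsda(sub, n_components)


@dataclass
class TwoStageClassifier:
    """Six-class model plus a necrosis subtyper applied to necrosis calls."""

    stage1: PLSDAModel
    subtyper: PLSDAModel

    def predict_labels(self, X: np.ndarray) -> list[HistologyLabel]:
        labels = self.stage1.predict_labels(X)
        nec = [i for i, l in enumerate(labels)
               if l in (HistologyLabel.NECROSIS_UNSPECIFIED,
                        HistologyLabel.USUAL_NECROSIS,
                        HistologyLabel.INFARCT_LIKE_NECROSIS)]
        if nec:
            sub_labels = self.subtyper.predict_labels(np.asarray(X)[nec])
            for i, l in zip(nec, sub_labels):
                labels[i] = l
        return labels


def train_two_stage(lib: SpectralLibrary, n_components: int,
                    subtype_components: int = 2) -> TwoStageClassifier:
    """Train the two-stage variant: merge UN/ILN for stage 1, then subtype."""
    merged = [HistologyLabel.NECROSIS_UNSPECIFIED
              if l in (HistologyLabel.USUAL_NECROSIS,
                       HistologyLabel.INFARCT_LIKE_NECROSIS) else l
              for l in lib.labels]
    stage1_lib = SpectralLibrary(lib.X, merged, lib.feature_names,
                                 list(lib.sample_ids))
    stage1 = train_plsda(stage1_lib, n_components)
    subtyper = train_necrosis_subtyper(lib, subtype_components)
    return TwoStageClassifier(stage1, subtyper)


@dataclass
class PixelClassifier:
    """Histology classification on the spatially augmented representation.

    ``fit`` takes ``(PeakMatrix, per-pixel annotation)`` pairs, builds the
    augmented log-TIC library, optionally cross-validates the component
    count, and trains the PLS-DA model.  ``classify`` applies the same
    representation to a new lesion.
    """

    spatial_r: int = 1
    log: bool = True
    n_components: int | None = None
    cv_candidates: tuple = DEFAULT_CV_CANDIDATES
    cv_folds: int = 5
    seed: int = 0
    include_mucin: bool = True
    model: PLSDAModel | None = None
    cv_results: dict | None = None

    def _represent(self, pm: PeakMatrix) -> np.ndarray:
        X = log_tic_transform(pm.values) if self.log else pm.values
        return spatial_augment(X, pm.grid, self.spatial_r)

    def fit(self, annotated) -> "PixelClassifier":
        libs = []
        names = None
        for sid, (pm, annotation) in enumerate(annotated):
            if names is None:
                names = pm.feature_names
            elif pm.feature_names != names:
                raise ValueError("training matrices must share a feature set")
            libs.append(library_from_annotations(
                pm, annotation, sample_id=sid,
                include_mucin=self.include_mucin, X=self._represent(pm)))
        X = np.vstack([l.X for l in libs])
        labels = [lab for l in libs for lab in l.labels]
        sids = [s for l in libs for s in l.sample_ids]
        lib = SpectralLibrary(X, labels, libs[0].feature_names, sids)
        a = self.n_components
        if a is None:
            a, self.cv_results = cross_validate_components(
                lib, self.cv_candidates, self.cv_folds, self.seed)
        self.model = train_plsda(lib, a)
        return self

    def classify(self, pm: PeakMatrix
                 ) -> tuple[list[HistologyLabel], np.ndarray]:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        X = self._represent(pm)
        scores = self.model.predict_scores(X)
        labels = [self.model.class_order[j] for j in np.argmax(scores, axis=1)]
        return labels, scores
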