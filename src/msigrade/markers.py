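"""Univariate lipid-marker discovery: ROC a.u.c. and fold change per
feature per histology, with ranked marker tables.

A marker's discriminative power for one histology is measured against a
seeded random subset of pixels from all other histologies, stratified
equally across them so that no single rival histology dominates — which
suppresses markers that merely separate several histologies at once.  The
a.u.c. is the rank-based Mann-Whitney concordance probability; the fold
change is the ratio of mean target to mean rest intensity, summarized as
mean ± sd across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import FeatureDescriptor, HistologyLabel, PeakMatrix

DEFAULT_TOP_N = 14  # marker ions reported per study in the summary tile plot


@dataclass
class MarkerStats:
    feature: FeatureDescriptor
    topography: HistologyLabel
    fold_change_mean: float
    fold_change_sd: float
    auc: float
    single_sample: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")
        if self.fold_change_mean <= 0:
            raise ValueError("fold change must be positive")


def roc_auc(target: np.ndarray, rest: np.ndarray) -> float:
    """Area under the ROC curve of ``target`` vs ``rest`` intensities.

    Computed from ranks as the Mann-Whitney concordance probability
    ``P(target > rest) + P(target = rest)/2``; invariant under strictly
    monotone transforms of the intensities.
    """
    target = np.asarray(target, dtype=float)
    rest = np.asarray(rest, dtype=float)
    if target.size == 0 or rest.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([target, rest]))
    u = ranks[:target.size].sum() - target.size * (target.size + 1) / 2.0
    return float(u / (target.size * rest.size))


def sample_rest_pixels(labels, target: HistologyLabel, seed: int = 0
                       ) -> np.ndarray:
    """Seeded stratified subset of non-target pixels.

    Returns indices of ``min(n_target, n_rest)`` pixels drawn from the
    other histologies as evenly as possible (quota rotation in label
    order; classes smaller than their quota contribute everything and the
    shortfall moves to the remaining classes).  Unlabelled (``None``)
    pixels are ignored.
    """
    labels = list(labels)
    target = HistologyLabel(target)
    tgt_idx = [i for i, l in enumerate(labels) if l == target]
    by_class: dict[HistologyLabel, list[int]] = {}
    for i, l in enumerate(labels):
        if l is None or l == target:
            continue
        by_class.setdefault(HistologyLabel(l), []).append(i)
    if not tgt_idx:
        raise ValueError(f"no pixels labelled {target}")
    if not by_class:
        raise ValueError("no non-target pixels")
    n_rest = sum(len(v) for v in by_class.values())
    size = min(len(tgt_idx), n_rest)

    classes = sorted(by_class, key=lambda l: l.value)
    remaining = {c: len(by_class[c]) for c in classes}
    quota = {c: 0 for c in classes}
    left = size
    while left > 0:
        open_classes = [c for c in classes if remaining[c] > quota[c]]
        share = max(1, left // len(open_classes))
        for c in open_classes:
            take = min(share, remaining[c] - quota[c], left)
            quota[c] += take
            left -= take
            if left == 0:
                break

    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for c in classes:
        pool = by_class[c]
        if quota[c] >= len(pool):
            chosen.extend(pool)
        else:
            chosen.extend(rng.choice(pool, size=quota[c], replace=False))
    return np.array(sorted(chosen), dtype=int)


def fold_change(pm: PeakMatrix, labels, feature_name: str,
                target: HistologyLabel, sample_ids=None
                ) -> tuple[float, float, bool]:
    """Per-sample mean-intensity ratio of target vs all other histologies.

    Returns ``(mean, sd, single_sample)`` where the sd is across samples
    (ddof 1); with a single sample the sd is 0 and flagged.  Means use raw
    intensities; a zero rest mean is an error rather than infinity.
    """
    labels = list(labels)
    target = HistologyLabel(target)
    col = pm.column(feature_name)
    if sample_ids is None:
        sample_ids = [0] * len(labels)
    ratios = []
    for sid in sorted(set(sample_ids)):
        in_sample = np.array([s == sid for s in sample_ids])
        lab = np.array([l == target if l is not None else False
                        for l in labels])
        rest = np.array([l is not None and l != target for l in labels])
        t_mask = in_sample & lab
        r_mask = in_sample & rest
        if not t_mask.any() or not r_mask.any():
            continue  # sample lacks one of the groups
        r_mean = col[r_mask].mean()
        if r_mean <= 0:
            raise ValueError("rest mean intensity is zero")
        ratios.append(col[t_mask].mean() / r_mean)
    if not ratios:
        raise ValueError("no sample contains both target and rest pixels")
    if len(ratios) == 1:
        return float(ratios[0]), 0.0, True
    return (float(np.mean(ratios)), float(np.std(ratios, ddof=1)), False)


def rank_markers(pm: PeakMatrix, labels, top_n: int = DEFAULT_TOP_N,
                 seed: int = 0, sample_ids=None) -> pd.DataFrame:
    """Ranked discriminant-marker table per histology.

    For every feature x histology the a.u.c. is computed against the
    stratified rest subset (one seeded draw per histology), features are
    ranked per histology by a.u.c. descending, and the ``top_n`` rows are
    reported with their fold changes.  Deterministic given the seed.
    """
    labels = list(labels)
    present = sorted({HistologyLabel(l) for l in labels if l is not None},
                     key=lambda l: l.value)
    if len(present) < 2:
        raise ValueError("need at least two histologies")
    rows = []
    ss = np.random.SeedSequence(seed)
    class_seeds = {c: int(s.generate_state(1)[0] % (2**31))
                   for c, s in zip(present, ss.spawn(len(present)))}
    for topo in present:
        rest_idx = sample_rest_pixels(labels, topo, class_seeds[topo])
        tgt_idx = np.array([i for i, l in enumerate(labels) if l == topo])
        for j, feat in enumerate(pm.features):
            col = pm.values[:, j]
            auc = roc_auc(col[tgt_idx], col[rest_idx])
            rows.append((topo, feat, auc))
    out = []
    df = pd.DataFrame(rows, columns=["topography", "feature", "auc"])
    for topo, group in df.groupby("topography", sort=True):
        top = group.sort_values("auc", ascending=False).head(top_n)
        for _, r in top.iterrows():
            fc_mean, fc_sd, single = fold_change(
                pm, labels, r["feature"].name, topo, sample_ids)
            out.append({
                "topography": HistologyLabel(topo).value,
                "feature": r["feature"].name,
                "fold_change_mean": fc_mean,
                "fold_change_sd": fc_sd,
                "auc": r["auc"],
                "single_sample": single,
            })
    return pd.DataFrame(out)


def save_marker_table(table: pd.DataFrame, path: str) -> None:
    """Write the marker table as CSV (Topography, m/z, fold change, a.u.c.)."""
    export = table.rename(columns={
        "topography": "Topography", "feature": "m/z",
        "fold_change_mean": "FoldChangeMean", "fold_change_sd": "FoldChangeSD",
        "auc": "AUC"})
    cols = ["Topography", "m/z", "FoldChangeMean", "FoldChangeSD", "AUC"]
    export[cols].to_csv(path, index=False, float_format="%.6g")
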