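"""Spatial organization of functional cell classes.

The nearest neighbor index (NNI) of a class is the mean Euclidean distance
from each cell of that class to the nearest other cell of the same class;
values smaller than expected under random label placement indicate spatial
clustering.  Significance comes from a label-shuffle permutation test (1000
shuffled maps by default), with the one-sided p-value estimated with the
permutation-inclusive add-one correction.  ``simulate_clustered_map``
constructs positive controls by confining each class to 3-4 of 16 equal
sub-areas of the field, and ``starter_cell_ensembles`` measures how decoding
accuracy grows with spatially contiguous ensembles seeded at every cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import ResponseTable
from .decoding import classify_loo


@dataclass
class CellMap:
    """Cell positions (um) with categorical functional labels."""

    positions: np.ndarray                 # (n_cells, 2) x, y in um
    labels: np.ndarray                    # (n_cells,) categorical
    bounds: tuple[float, float, float, float] | None = None  # x0, y0, x1, y1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n_cells, 2)")
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions must align")
        if self.bounds is None:
            x0, y0 = self.positions.min(axis=0)
            x1, y1 = self.positions.max(axis=0)
            self.bounds = (float(x0), float(y0), float(x1), float(y1))

    @property
    def classes(self) -> list:
        return sorted(set(self.labels.tolist()))

    def to_csv(self, path) -> None:
        pd.DataFrame({"cell_id": np.arange(len(self.labels)),
                      "x_um": self.positions[:, 0],
                      "y_um": self.positions[:, 1],
                      "label": self.labels}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CellMap":
        df = pd.read_csv(path)
        return cls(positions=df[["x_um", "y_um"]].to_numpy(),
                   labels=df["label"].to_numpy())


def nearest_neighbor_index(cell_map: CellMap, class_label) -> float:
    """Mean distance from each class member to its nearest same-class cell.

    Returns NaN for classes with fewer than two members.
    """
    pts = cell_map.positions[cell_map.labels == class_label]
    if len(pts) < 2:
        return float("nan")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)           # k=1 is the point itself
    return float(d[:, 1].mean())


def _pooled_nni(positions: np.ndarray, labels: np.ndarray,
                classes: list) -> tuple[dict, float]:
    """Per-class NNIs and their class-size-weighted mean (valid classes)."""
    per_class: dict = {}
    num = den = 0.0
    for c in classes:
        pts = positions[labels == c]
        if len(pts) < 2:
            per_class[c] = float("nan")
            continue
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        nni = float(d[:, 1].mean())
        per_class[c] = nni
        num += nni * len(pts)
        den += len(pts)
    return per_class, (num / den if den else float("nan"))


def nni_shuffle_test(cell_map: CellMap, n_shuffles: int = 1000,
                     seed: int | None = None) -> dict:
    """One-sided permutation test for spatial clustering of each class.

    Labels are permuted over the fixed positions; p is the add-one estimate
    (#{shuffled NNI <= observed} + 1) / (n_shuffles + 1), small when the
    observed class is more tightly packed than label-shuffled maps.  Returns
    per-class p-values, the pooled (class-size-weighted) statistic and its p.
    """
    rng = np.random.default_rng(seed)
    classes = cell_map.classes
    obs, obs_pooled = _pooled_nni(cell_map.positions, cell_map.labels,
                                  classes)
    le_counts = {c: 0 for c in classes}
    le_pooled = 0
    labels = cell_map.labels.copy()
    for _ in range(n_shuffles):
        rng.shuffle(labels)
        null, null_pooled = _pooled_nni(cell_map.positions, labels, classes)
        for c in classes:
            if not np.isnan(null[c]) and null[c] <= obs[c]:
                le_counts[c] += 1
        if null_pooled <= obs_pooled:
            le_pooled += 1
    p = {c: (le_counts[c] + 1) / (n_shuffles + 1)
         if not np.isnan(obs[c]) else float("nan") for c in classes}
    return {"nni": obs, "p": p,
            "pooled_nni": obs_pooled,
            "pooled_p": (le_pooled + 1) / (n_shuffles + 1)}


def simulate_clustered_map(cell_map: CellMap, n_subareas: int = 16,
                           areas_per_class: int = 3,
                           seed: int | None = None,
                           constrained_classes: list | None = None
                           ) -> CellMap:
    """Reassign labels so each class occupies only a few random sub-areas.

    The field is divided into a sqrt(n_subareas) x sqrt(n_subareas) grid;
    every constrained class is confined to ``areas_per_class`` randomly
    chosen cells of that grid while class sizes are preserved.  Classes not
    in ``constrained_classes`` (default: all classes are constrained) are
    scattered over the remaining cells, emulating non-responsive background
    cells.  With all sub-areas allowed the procedure reduces to a plain
    label shuffle.
    """
    side = int(round(np.sqrt(n_subareas)))
    if side * side != n_subareas:
        raise ValueError("n_subareas must be a perfect square")
    if not 1 <= areas_per_class <= n_subareas:
        raise ValueError("areas_per_class out of range")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = cell_map.bounds
    eps = 1e-9
    ax = np.minimum((cell_map.positions[:, 0] - x0) / (x1 - x0 + eps)
                    * side, side - 1).astype(int)
    ay = np.minimum((cell_map.positions[:, 1] - y0) / (y1 - y0 + eps)
                    * side, side - 1).astype(int)
    subarea = ax * side + ay

    classes, counts = np.unique(cell_map.labels.astype(str),
                                return_counts=True)
    if constrained_classes is None:
        constrained = list(classes)
    else:
        constrained = [str(c) for c in constrained_classes]
    order = np.argsort(-counts)           # biggest classes placed first
    new_labels = np.full(len(cell_map.labels), None, dtype=object)
    unassigned = np.ones(len(cell_map.labels), dtype=bool)
    for k in order:
        if classes[k] not in constrained:
            continue
        cls = cell_map.labels[cell_map.labels.astype(str)
                              == classes[k]][0]   # original dtype value
        size = counts[k]
        pool = np.array([], dtype=int)
        for _ in range(50):   # redraw sub-areas if capacity is insufficient
            allowed = rng.choice(n_subareas, size=areas_per_class,
                                 replace=False)
            pool = np.flatnonzero(unassigned & np.isin(subarea, allowed))
            if len(pool) >= size:
                break
        if len(pool) < size:
            raise ValueError(
                f"class {cls!r} needs {size} cells but only {len(pool)} "
                "unassigned cells lie in its allowed sub-areas")
        chosen = rng.choice(pool, size=size, replace=False)
        new_labels[chosen] = cls
        unassigned[chosen] = False
    # unconstrained classes fill the remaining positions at random
    rest = [lab for lab in cell_map.labels
            if str(lab) not in constrained]
    rest_idx = np.flatnonzero(unassigned)
    perm = rng.permutation(len(rest_idx))
    for i, lab in zip(rest_idx[perm], rest):
        new_labels[i] = lab
    return CellMap(positions=cell_map.positions.copy(),
                   labels=new_labels, bounds=cell_map.bounds)


def starter_cell_ensembles(cell_map: CellMap, table: ResponseTable,
                           sizes: list[int], method: str = "lda-on-pcs"
                           ) -> pd.DataFrame:
    """LOO decoding accuracy of k-nearest-neighbor ensembles per starter cell.

    For every cell taken as a starter and every ensemble size k, the
    ensemble is the starter plus its k-1 nearest neighbors; trials are
    classified by odor identity from that subset of cells alone.
    """
    mat, meta = table.matrix()
    n_cells = mat.shape[0]
    if len(cell_map.positions) != n_cells:
        raise ValueError("cell map and response table must align")
    if max(sizes) > n_cells:
        raise ValueError("ensemble size exceeds the number of cells")
    labels = (meta["odorant"].astype(str) + "@"
              + meta["dilution"].astype(str)).to_numpy()
    tree = cKDTree(cell_map.positions)
    rows = []
    for starter in range(n_cells):
        _, order = tree.query(cell_map.positions[starter], k=n_cells)
        order = np.atleast_1d(order)
        for k in sizes:
            ensemble = order[:k]
            res = classify_loo(mat[ensemble].T, labels, method)
            rows.append({"starter": starter, "size": k,
                         "accuracy": res.accuracy, "chance": res.chance})
    return pd.DataFrame(rows)
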