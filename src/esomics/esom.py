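"""Emergent self-organizing map (ESOM) for composition-based contig binning.

An ESOM is a large self-organizing map — many more neurons than data points
— trained on a borderless (toroidal) grid so that cluster structure shows up
as valleys in the U-matrix (the per-neuron mean distance to neighboring
codebook vectors). Long contigs train the map; short contigs are projected
onto the frozen map afterwards. Bins are the connected low-U-matrix regions
that captured best-matching units, or an explicit neuron->bin mask standing
in for on-screen manual selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .composition import TnfMatrix

UNBINNED = "unbinned"


def toroidal_sq_distances(rows: int, cols: int, r: int, c: int) -> np.ndarray:
    """Squared toroidal grid distance from neuron (r, c) to every neuron.

    Returns a flat array of length rows*cols in row-major order.
    """
    dr = np.abs(np.arange(rows) - r)
    dr = np.minimum(dr, rows - dr)
    dc = np.abs(np.arange(cols) - c)
    dc = np.minimum(dc, cols - dc)
    return (dr[:, None] ** 2 + dc[None, :] ** 2).ravel()


class TetranucleotideESOM(BaseEstimator):
    """Toroidal emergent SOM trained online with a Gaussian neighborhood.

    Parameters
    ----------
    rows, cols : int
        Grid dimensions. The emergent-map convention wants rows*cols to be
        at least five times the number of training vectors; a smaller grid
        triggers a warning, not an error.
    epochs : int
        Full passes over the (shuffled) training data.
    lr_start, lr_end : float
        Linearly decaying learning rate.
    radius_start : float or None
        Initial Gaussian neighborhood radius; ``None`` means
        ``max(rows, cols) / 2``.
    radius_end : float
        Final neighborhood radius.
    random_state : int or None
        Seed for codebook initialization and epoch shuffling.

    Attributes
    ----------
    codebook_ : ndarray of shape (rows*cols, n_features)
        Neuron weight vectors (row-major grid order).
    training_log_ : list of float
        Mean quantization error (Euclidean distance to the BMU) after each
        epoch; the final entry never exceeds the first on converged runs.
    """

    def __init__(
        self,
        rows: int = 50,
        cols: int = 82,
        epochs: int = 20,
        lr_start: float = 0.5,
        lr_end: float = 0.1,
        radius_start: float | None = None,
        radius_end: float = 1.0,
        random_state: int | None = None,
    ):
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.radius_start = radius_start
        self.radius_end = radius_end
        self.random_state = random_state

    # -- internal helpers -------------------------------------------------
    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2D array")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def _schedule(self, epoch: int) -> tuple[float, float]:
        t = epoch / max(self.epochs - 1, 1)
        r0 = self.radius_start if self.radius_start is not None else max(self.rows, self.cols) / 2
        lr = self.lr_start + (self.lr_end - self.lr_start) * t
        radius = r0 + (self.radius_end - r0) * t
        return lr, radius

    def _quantization_error(self, X: np.ndarray) -> float:
        d2 = self._sq_dist_to_codebook(X)
        return float(np.sqrt(np.maximum(d2.min(axis=1), 0.0)).mean())

    def _sq_dist_to_codebook(self, X: np.ndarray) -> np.ndarray:
        cb = self.codebook_
        return (
            (X**2).sum(axis=1)[:, None]
            - 2.0 * X @ cb.T
            + (cb**2).sum(axis=1)[None, :]
        )

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y=None) -> "TetranucleotideESOM":
        """Train the map online; deterministic for a fixed ``random_state``."""
        if isinstance(X, TnfMatrix):
            X = X.vectors
        X = self._check_X(X)
        n, d = X.shape
        n_neurons = self.rows * self.cols
        if n_neurons < 5 * n:
            warnings.warn(
                f"grid of {n_neurons} neurons is below the emergent-map "
                f"convention of 5x the {n} training vectors",
                stacklevel=2,
            )
        rng = np.random.default_rng(self.random_state)
        lo, hi = X.min(axis=0), X.max(axis=0)
        codebook = rng.uniform(lo, hi, size=(n_neurons, d))
        self.codebook_ = codebook
        self.n_features_in_ = d
        self.training_log_ = []

        grid_r, grid_c = np.divmod(np.arange(n_neurons), self.cols)
        for epoch in range(self.epochs):
            lr, radius = self._schedule(epoch)
            two_sigma2 = 2.0 * radius * radius
            order = rng.permutation(n)
            for i in order:
                x = X[i]
                # BMU; ties resolved to the lowest neuron index by argmin
                d2 = ((codebook - x) ** 2).sum(axis=1)
                bmu = int(np.argmin(d2))
                g2 = toroidal_sq_distances(self.rows, self.cols, grid_r[bmu], grid_c[bmu])
                h = np.exp(-g2 / two_sigma2)
                codebook += (lr * h)[:, None] * (x - codebook)
            self.training_log_.append(self._quantization_error(X))
        return self

    def predict(self, X) -> np.ndarray:
        """Best-matching unit (flat neuron index) per vector; map is frozen."""
        if isinstance(X, TnfMatrix):
            X = X.vectors
        X = self._check_X(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, map was trained on {self.n_features_in_}"
            )
        return np.argmin(self._sq_dist_to_codebook(X), axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)

    def umatrix(self) -> np.ndarray:
        """Mean Euclidean distance to the 8 toroidal neighbors, per neuron."""
        cb = self.codebook_.reshape(self.rows, self.cols, -1)
        acc = np.zeros((self.rows, self.cols))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                shifted = np.roll(np.roll(cb, dr, axis=0), dc, axis=1)
                acc += np.linalg.norm(cb - shifted, axis=2)
        return acc / 8.0

    def bmu_coords(self, bmus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return np.divmod(np.asarray(bmus), self.cols)


@dataclass
class BinAssignment:
    """Per-contig bin labels with provenance.

    ``table`` columns: contig_id, bin, provenance ({training, projected}),
    bmu, bmu_row, bmu_col. Every input contig appears exactly once.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if len(self.table) and self.table["contig_id"].duplicated().any():
            raise ValueError("duplicate contig ids in bin assignment")

    def contigs_in_bin(self, label: str) -> list[str]:
        return self.table.loc[self.table["bin"] == label, "contig_id"].tolist()

    @property
    def bins(self) -> list[str]:
        labels = sorted(set(self.table["bin"]) - {UNBINNED})
        return labels


def assign_bmus(
    esom: TetranucleotideESOM,
    tnf_train: TnfMatrix,
    tnf_project: TnfMatrix | None = None,
) -> pd.DataFrame:
    """BMU table for training contigs plus optional projected short contigs."""
    frames = []
    for mat, prov in ((tnf_train, "training"), (tnf_project, "projected")):
        if mat is None or len(mat) == 0:
            continue
        bmu = esom.predict(mat)
        r, c = esom.bmu_coords(bmu)
        frames.append(
            pd.DataFrame(
                {
                    "contig_id": mat.contig_ids,
                    "provenance": prov,
                    "bmu": bmu,
                    "bmu_row": r,
                    "bmu_col": c,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _low_umatrix_components(
    esom: TetranucleotideESOM, umatrix_percentile: float
) -> np.ndarray:
    """Label low-U neurons by toroidal 8-connected component; -1 = high U."""
    um = esom.umatrix().ravel()
    thr = np.percentile(um, umatrix_percentile)
    low = um < thr
    g = nx.Graph()
    g.add_nodes_from(np.flatnonzero(low))
    rows, cols = esom.rows, esom.cols
    for idx in np.flatnonzero(low):
        r, c = divmod(idx, cols)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = ((r + dr) % rows) * cols + (c + dc) % cols
                if low[j]:
                    g.add_edge(idx, j)
    labels = np.full(rows * cols, -1, dtype=np.int64)
    comps = sorted(nx.connected_components(g), key=min)
    for k, comp in enumerate(comps):
        labels[list(comp)] = k
    return labels


def select_bins(
    esom: TetranucleotideESOM,
    assignments: pd.DataFrame,
    umatrix_percentile: float = 30.0,
    explicit_mask: Mapping[int, str] | None = None,
) -> BinAssignment:
    """Extract bins from the trained map.

    Automated mode: neurons whose U-matrix value falls below the given
    percentile form toroidal 8-connected components (the basin seeds);
    every other neuron is then assigned to its nearest seed component by
    toroidal grid distance, watershed-style, so a bin covers the whole
    basin around a valley rather than only its floor — the automated
    analog of drawing a polygon around a visible cluster. Every component
    that captured at least one BMU becomes a bin and contigs inherit their
    BMU's component. Manual mode: ``explicit_mask`` (flat neuron index ->
    bin label) overrides, emulating on-screen bin selection.
    """
    if explicit_mask is None and not (0 < umatrix_percentile < 100):
        raise ValueError("umatrix_percentile must be in (0, 100)")
    out = assignments.copy()
    if explicit_mask is not None:
        out["bin"] = [explicit_mask.get(int(b), UNBINNED) for b in out["bmu"]]
    else:
        labels = _low_umatrix_components(esom, umatrix_percentile)
        labeled = np.flatnonzero(labels >= 0)
        if len(labeled):
            rows_l, cols_l = np.divmod(labeled, esom.cols)
            for bmu in np.unique(out["bmu"].to_numpy()):
                if labels[bmu] >= 0:
                    continue
                r, c = divmod(int(bmu), esom.cols)
                dr = np.abs(rows_l - r)
                dr = np.minimum(dr, esom.rows - dr)
                dc = np.abs(cols_l - c)
                dc = np.minimum(dc, esom.cols - dc)
                nearest = labeled[np.argmin(dr**2 + dc**2)]
                labels[bmu] = labels[nearest]
        comp = labels[out["bmu"].to_numpy()]
        occupied = sorted({c for c in comp if c >= 0})
        remap = {c: f"bin_{i:03d}" for i, c in enumerate(occupied)}
        out["bin"] = [remap.get(int(c), UNBINNED) for c in comp]
    cols = ["contig_id", "bin", "provenance", "bmu", "bmu_row", "bmu_col"]
    return BinAssignment(out[cols].reset_index(drop=True))
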