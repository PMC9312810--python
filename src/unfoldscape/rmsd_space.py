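"""Trajectory representation in pairwise-RMSD space.

A trajectory is summarised by its pairwise Calpha RMSD matrix (every frame
optimally superposed on every other), reduced by classical (Torgerson)
multidimensional scaling to a low-dimensional "RMSD space". Displacements
between consecutive embedded frames are the MD step vectors; the native
state appears as a tight cluster of step-vector terminals, and the first
precipitous step that leaves the cluster and stays out marks the onset of
the unfolding transition (a leader-algorithm style test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "StepVectorSeries",
    "NativeExit",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "classical_mds",
    "step_vectors",
    "detect_native_exit",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Calpha RMSD matrix over frames (A)."""

    values: np.ndarray
    frame_indices: np.ndarray
    stride_used: int = 1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = v
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class Embedding:
    """Classical-MDS coordinates of frames in RMSD space (A per axis)."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    explained_fraction: float
    k: int


@dataclass
class StepVectorSeries:
    """Consecutive-frame displacements in the embedded RMSD space."""

    displacements: np.ndarray   # (T-1, k)
    norms: np.ndarray           # (T-1,)
    terminals: np.ndarray       # (T, k), the embedded frame positions
    frame_interval: float = 1.0


@dataclass
class NativeExit:
    """First departure from the native cluster; exit_frame None if no exit."""

    exit_frame: int | None
    exit_time: float | None
    threshold: float
    reference_window: tuple
    persistence: int
    cluster_radius: float = field(default=np.nan)

    @property
    def found(self) -> bool:
        return self.exit_frame is not None


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(X: np.ndarray, Y: np.ndarray, mask=None):
    """Optimal rigid superposition of Y onto X (SVD solution).

    Returns ``(rotation, translation, rmsd)`` such that
    ``Y @ rotation.T + translation`` best matches X in the least-squares
    sense. The rotation is proper (det +1, reflections excluded), so the
    RMSD is the minimum over all rigid motions.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if mask is not None:
        X = X[mask]
        Y = Y[mask]
    if X.shape != Y.shape:
        raise ValueError("selections must have equal atom counts")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 selected atoms")
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    Xc = X - xc
    Yc = Y - yc
    # collinear/coincident selections leave the rotation underdetermined
    if np.linalg.matrix_rank(Xc, tol=1e-8) < 2 or np.linalg.matrix_rank(Yc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear or coincident) selection")
    H = Yc.T @ Xc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    # explicit residual: accurate near zero, unlike the trace formula
    rmsd = float(np.sqrt(((Yc @ R.T - Xc) ** 2).sum() / n))
    t = xc - yc @ R.T
    return R, t, rmsd


def pairwise_rmsd_matrix(traj: Trajectory, mask=None, stride: int = 1) -> DistanceMatrix:
    """All-pairs minimum RMSD over Calpha atoms (the 2D-RMSD matrix).

    Vectorised over frame pairs via batched 3x3 SVDs of the cross
    covariance matrices; equivalent pair-by-pair to
    :func:`kabsch_superpose`.
    """
    if mask is None:
        mask = traj.topology.calpha_mask
    coords = traj.coords[::stride][:, mask, :]
    T, n, _ = coords.shape
    if T == 0:
        raise ValueError("trajectory empty after stride")
    if n < 3:
        raise ValueError("need at least 3 selected atoms")
    centred = coords - coords.mean(axis=1, keepdims=True)
    sq = (centred ** 2).sum(axis=(1, 2))
    D = np.zeros((T, T))
    for i in range(T - 1):
        H = np.einsum("ak,taj->tkj", centred[i], centred[i + 1:])
        U, S, Vt = np.linalg.svd(H)
        det = np.linalg.det(np.einsum("tij,tjk->tik", U, Vt))
        s_sum = S[:, 0] + S[:, 1] + np.sign(det) * S[:, 2]
        val = (sq[i] + sq[i + 1:] - 2.0 * s_sum) / n
        D[i, i + 1:] = np.sqrt(np.maximum(val, 0.0))
    D = D + D.T
    frame_idx = np.arange(traj.n_frames)[::stride]
    return DistanceMatrix(D, frame_idx, stride)


# ---------------------------------------------------------------------------
# classical multidimensional scaling
# ---------------------------------------------------------------------------


def classical_mds(D: DistanceMatrix | np.ndarray, k: int = 3) -> Embedding:
    """Torgerson scaling: B = -1/2 J D^2 J, eigendecomposition, top-k axes.

    Negative eigenvalues (RMSD matrices are near- but not exactly
    Euclidean) are clamped out of the embedding and logged;
    ``explained_fraction`` is the retained share of the positive spectrum.
    """
    values = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    T = values.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if T < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} frames, got {T}")
    D2 = values ** 2
    J = np.eye(T) - np.ones((T, T)) / T
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > max(1e-12, 1e-12 * abs(evals[0]))
    if not np.any(pos):
        if np.allclose(values, 0):
            return Embedding(np.zeros((T, k)), np.zeros(k), 1.0, k)
        raise ValueError("no positive eigenvalues: pathological distance matrix")
    neg_mag = float(-evals[evals < 0].sum())
    pos_sum = float(evals[pos].sum())
    if neg_mag > 0:
        logger.info("MDS: clamped negative eigenvalue mass %.3g (%.2f%% of positive)",
                    neg_mag, 100 * neg_mag / pos_sum)
    coords = np.zeros((T, k))
    lam = np.zeros(k)
    m = min(k, int(pos.sum()))
    lam[:m] = evals[:m]
    coords[:, :m] = evecs[:, :m] * np.sqrt(evals[:m])
    explained = float(lam.sum() / pos_sum)
    return Embedding(coords, lam, explained, k)


def step_vectors(emb: Embedding, frame_interval: float = 1.0) -> StepVectorSeries:
    """MD step vectors: exact differences of consecutive embedded frames."""
    terminals = np.asarray(emb.coords, dtype=float)
    if terminals.shape[0] < 2:
        raise ValueError("need at least 2 frames for step vectors")
    disp = np.diff(terminals, axis=0)
    norms = np.linalg.norm(disp, axis=1)
    return StepVectorSeries(disp, norms, terminals, frame_interval)


# ---------------------------------------------------------------------------
# native-exit detection
# ---------------------------------------------------------------------------


def detect_native_exit(series: StepVectorSeries, reference_window=None,
                       c: float = 5.0, m: int = 10,
                       radius_scale: float = 1.5) -> NativeExit:
    """First precipitous, persistent departure from the native cluster.

    A frame f is the exit iff its incoming step norm exceeds
    ``mean + c * SD`` of the reference-window step norms AND the embedded
    frame stays farther from the native-cluster centroid than the cluster
    radius for at least ``m`` subsequent frames (or to the end of the
    trajectory). The cluster radius is ``radius_scale`` times the largest
    centroid distance inside the reference window. Ties resolve to the
    lowest frame index; if no frame qualifies the result reports no exit.

    ``reference_window`` is a (start, stop) frame range (half-open);
    default is the first 5% of frames, at least 10.
    """
    T = series.terminals.shape[0]
    if reference_window is None:
        reference_window = (0, max(10, int(round(0.05 * T))))
    w0, w1 = int(reference_window[0]), int(reference_window[1])
    if w1 - w0 < 10:
        raise ValueError("reference window must span at least 10 frames")
    if w1 > T:
        raise ValueError("reference window longer than the trajectory")
    ref_norms = series.norms[w0:w1 - 1]  # steps internal to the window
    threshold = float(ref_norms.mean() + c * ref_norms.std())
    centroid = series.terminals[w0:w1].mean(axis=0)
    ref_dist = np.linalg.norm(series.terminals[w0:w1] - centroid, axis=1)
    radius = radius_scale * float(ref_dist.max())
    dist = np.linalg.norm(series.terminals - centroid, axis=1)
    for f in range(w1, T):
        if series.norms[f - 1] <= threshold:
            continue
        tail = dist[f: min(f + m, T)]
        if np.all(tail > radius):
            return NativeExit(f, f * series.frame_interval, threshold,
                              (w0, w1), m, radius)
    return NativeExit(None, None, threshold, (w0, w1), m, radius)
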