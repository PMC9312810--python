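"""Statistical free-energy landscape and reaction-coordinate statistics.

Populations of step-vector terminals on a grid give a statistical free
energy DeltaF_ij = -RT ln(P_ij / P0), with P0 the modal population, so the
most-visited bin sits at DeltaF = 0 and unvisited bins are infinitely
costly. A discrete unfolding reaction coordinate is traced from the native
modal bin toward the unfolded region by always taking the feasible
neighbour of least free-energy increase while moving closer to the end
bin -- on a smooth surface this is the steepest feasible direction,
perpendicular to the isoenergy contours. The path's profile yields the
activation free energy, a channel index measuring how extended the
barrier top is (the hallmark of a malleable transition state), a
thermal-stability test for post-barrier minima, and a transition-state
theory unfolding rate k_u = nu exp(-DeltaF‡ / RT) with the protein
prefactor nu = 1e6 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "LandscapeGrid",
    "ReactionPath",
    "RateEstimate",
    "population_grid",
    "free_energy",
    "extract_reaction_path",
    "barrier_stats",
    "tst_rate",
    "modal_bin",
    "farthest_occupied_bin",
]

#: gas constant in kcal / (mol K)
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass
class LandscapeGrid:
    """Binned terminal populations and (optionally) their free energies.

    ``counts`` is an integer array with one axis per landscape dimension;
    ``deltaF`` (kcal/mol) uses +inf as the empty-bin sentinel.
    """

    bounds: tuple              # per-axis (lo, hi) in A
    n_bins: tuple
    counts: np.ndarray
    RT: float | None = None
    temperature: float | None = None
    deltaF: np.ndarray | None = None
    axes: tuple = (0, 1)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != tuple(self.n_bins):
            raise ValueError("counts shape must match n_bins")

    @property
    def P0(self) -> int:
        return int(self.counts.max())

    @property
    def ndim(self) -> int:
        return self.counts.ndim

    @property
    def bin_widths(self) -> np.ndarray:
        return np.array([(hi - lo) / n for (lo, hi), n in
                         zip(self.bounds, self.n_bins)])

    def bin_center(self, idx) -> np.ndarray:
        w = self.bin_widths
        return np.array([self.bounds[d][0] + (idx[d] + 0.5) * w[d]
                         for d in range(self.ndim)])

    def marginalize(self, axis: int) -> "LandscapeGrid":
        """Sum counts over one axis (3D grid -> 2D landscape)."""
        counts = self.counts.sum(axis=axis)
        bounds = tuple(b for d, b in enumerate(self.bounds) if d != axis)
        n_bins = tuple(n for d, n in enumerate(self.n_bins) if d != axis)
        axes = tuple(a for d, a in enumerate(self.axes) if d != axis)
        return LandscapeGrid(bounds, n_bins, counts, axes=axes)


@dataclass
class ReactionPath:
    """Ordered grid path with its 1D free-energy profile."""

    bin_sequence: list           # list of bin-index tuples, grid neighbours
    arc_length: np.ndarray       # cumulative A along bin centers, increasing
    profile: np.ndarray          # DeltaF at each path point, kcal/mol
    RT: float
    deltaF_activation: float = field(init=False)

    def __post_init__(self):
        self.profile = np.asarray(self.profile, dtype=float)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        self.deltaF_activation = float(self.profile.max() - self.profile[0])


@dataclass
class RateEstimate:
    """TST unfolding rate k_u = prefactor * exp(-DeltaF‡/RT), s^-1."""

    k_u: float
    prefactor: float
    deltaF_activation: float
    temperature: float


def population_grid(terminals: np.ndarray, axes=(0, 1), n_bins=50,
                    bounds=None) -> LandscapeGrid:
    """Bin embedded step-vector terminals on a regular grid (counts only).

    Bins are half-open with the global top edge closed; default bounds are
    the data extent padded by one bin width on each side. ``n_bins`` may
    be an int (shared) or a per-axis sequence.
    """
    terminals = np.asarray(terminals, dtype=float)
    if terminals.ndim != 2 or terminals.shape[0] < 1:
        raise ValueError("need at least one terminal point")
    pts = terminals[:, list(axes)]
    d = pts.shape[1]
    if np.isscalar(n_bins):
        n_bins = (int(n_bins),) * d
    n_bins = tuple(int(n) for n in n_bins)
    if any(n < 2 for n in n_bins):
        raise ValueError("need at least 2 bins per axis")
    if bounds is None:
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        span = hi - lo
        if np.any(span == 0):
            bad = int(np.flatnonzero(span == 0)[0])
            raise ValueError(f"zero-extent axis {axes[bad]}: supply bounds explicitly")
        pad = span / np.array(n_bins)
        bounds = tuple((float(l - p), float(h + p))
                       for l, h, p in zip(lo, hi, pad))
    else:
        bounds = tuple((float(l), float(h)) for l, h in bounds)
        if any(h <= l for l, h in bounds):
            raise ValueError("bounds must have positive extent")
    counts = np.zeros(n_bins, dtype=int)
    idx = []
    for dim in range(d):
        lo, hi = bounds[dim]
        w = (hi - lo) / n_bins[dim]
        j = np.floor((pts[:, dim] - lo) / w).astype(int)
        j[pts[:, dim] == hi] = n_bins[dim] - 1  # closed top edge
        if np.any((j < 0) | (j >= n_bins[dim])):
            raise ValueError("points outside the supplied bounds")
        idx.append(j)
    np.add.at(counts, tuple(idx), 1)
    return LandscapeGrid(bounds, n_bins, counts, axes=tuple(axes))


def smooth_counts(grid: LandscapeGrid, sigma_bins: float) -> LandscapeGrid:
    """Gaussian-smoothed copy of a counts grid (display only).

    Quantitative analyses (paths, barriers, channel indices) run on the
    raw counts; smoothing redistributes population across bins and biases
    ΔF near sharp features.
    """
    from scipy.ndimage import gaussian_filter

    if sigma_bins <= 0:
        raise ValueError("sigma_bins must be positive")
    sm = gaussian_filter(grid.counts.astype(float), sigma=sigma_bins)
    return LandscapeGrid(grid.bounds, grid.n_bins, sm, axes=grid.axes)


def free_energy(grid: LandscapeGrid, temperature: float) -> LandscapeGrid:
    """Fill DeltaF = -RT ln(P / P0); empty bins get +inf.

    R = 1.9872e-3 kcal/(mol K). The modal bin(s) sit at exactly 0.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    counts = grid.counts
    if counts.max() < 1:
        raise ValueError("need at least one occupied bin")
    RT = GAS_CONSTANT_KCAL * temperature
    with np.errstate(divide="ignore"):
        deltaF = np.where(counts > 0,
                          -RT * np.log(counts / counts.max()),
                          np.inf)
    deltaF = np.where(counts > 0, np.maximum(deltaF, 0.0), np.inf)
    return LandscapeGrid(grid.bounds, grid.n_bins, counts, RT=RT,
                         temperature=temperature, deltaF=deltaF, axes=grid.axes)


def modal_bin(grid: LandscapeGrid, region_mask: np.ndarray | None = None):
    """Bin index of the highest count (ties: lowest linear index)."""
    counts = grid.counts
    if region_mask is not None:
        counts = np.where(region_mask, counts, -1)
    return tuple(int(i) for i in np.unravel_index(int(np.argmax(counts)),
                                                  counts.shape))


def dominant_component_modal_bin(grid: LandscapeGrid):
    """Modal bin of the connected occupied region holding the most counts.

    A precipitous native exit can leave the (briefly sampled) native
    cluster disconnected from the rest of the landscape; anchoring the
    reaction path in the dominant basin complex keeps the barrier
    statistics meaningful on such raggedly sampled landscapes.
    """
    if grid.deltaF is None:
        raise ValueError("grid has no free energies: call free_energy first")
    remaining = set(map(tuple, np.argwhere(grid.counts > 0)))
    best_bin, best_mass = None, -1
    while remaining:
        seed = next(iter(remaining))
        comp = _connected_component(grid.deltaF, seed)
        remaining -= comp
        mass = sum(int(grid.counts[b]) for b in comp)
        if mass > best_mass:
            best_mass = mass
            best_bin = min(comp, key=lambda b: (-grid.counts[b],
                                                np.ravel_multi_index(b, grid.counts.shape)))
    return best_bin


def farthest_occupied_bin(grid: LandscapeGrid, from_bin):
    """Occupied bin at the greatest grid (Chebyshev) distance from from_bin."""
    occ = np.argwhere(grid.counts > 0)
    dist = np.max(np.abs(occ - np.asarray(from_bin)), axis=1)
    return tuple(int(i) for i in occ[int(np.argmax(dist))])


def _neighbors(idx, shape):
    deltas = np.indices((3,) * len(shape)).reshape(len(shape), -1).T - 1
    out = []
    for d in deltas:
        if np.all(d == 0):
            continue
        nb = tuple(int(i + di) for i, di in zip(idx, d))
        if all(0 <= n < s for n, s in zip(nb, shape)):
            out.append(nb)
    return out


def _connected_component(dF, start):
    """8-connected occupied bins reachable from start (BFS)."""
    from collections import deque

    shape = dF.shape
    seen = {start}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        for nb in _neighbors(cur, shape):
            if np.isfinite(dF[nb]) and nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return seen


def _greedy_path(dF, start_bin, end_bin):
    """Steepest-feasible monotone walk; None if it dead-ends."""
    shape = dF.shape

    def chebyshev(a, b):
        return max(abs(x - y) for x, y in zip(a, b))

    path = [start_bin]
    visited = {start_bin}
    current = start_bin
    max_steps = 4 * int(np.prod(shape))
    while current != end_bin:
        if len(path) > max_steps:
            return None
        d_cur = chebyshev(current, end_bin)
        nbrs = _neighbors(current, shape)
        pool = [n for n in nbrs
                if np.isfinite(dF[n]) and chebyshev(n, end_bin) < d_cur]
        if not pool:
            pool = [n for n in nbrs if np.isfinite(dF[n])
                    and chebyshev(n, end_bin) == d_cur and n not in visited]
        if not pool:
            return None
        # least DeltaF increase; ties broken by lowest linear bin index
        pool.sort(key=lambda n: (dF[n], np.ravel_multi_index(n, shape)))
        current = pool[0]
        visited.add(current)
        path.append(current)
    return path


def _minimax_path(dF, start_bin, end_bin):
    """Path minimising the maximum DeltaF crossed (lowest-saddle route),
    with path length as the tie-break (Dijkstra on (max dF, steps))."""
    import heapq

    shape = dF.shape
    best = {start_bin: (dF[start_bin], 0)}
    prev = {}
    heap = [(dF[start_bin], 0, start_bin)]
    while heap:
        cost, steps, cur = heapq.heappop(heap)
        if cur == end_bin:
            break
        if (cost, steps) > best.get(cur, (np.inf, np.inf)):
            continue
        for nb in _neighbors(cur, shape):
            if not np.isfinite(dF[nb]):
                continue
            cand = (max(cost, dF[nb]), steps + 1)
            if cand < best.get(nb, (np.inf, np.inf)):
                best[nb] = cand
                prev[nb] = cur
                heapq.heappush(heap, (cand[0], cand[1], nb))
    if end_bin not in best:
        return None
    path = [end_bin]
    while path[-1] != start_bin:
        path.append(prev[path[-1]])
    return path[::-1]


def extract_reaction_path(grid: LandscapeGrid, start_bin=None,
                          end_bin=None) -> ReactionPath:
    """Trace the unfolding reaction coordinate across the landscape.

    From the native modal bin (default ``start_bin``) to ``end_bin``
    (default: the occupied bin farthest from the start within the start's
    8-connected occupied region), step to the finite-DeltaF grid
    neighbour of least free energy among those strictly closer
    (Chebyshev) to the end; if none is finite, lateral moves at equal
    distance are allowed. On a smooth surface this steepest feasible
    ascent/descent runs perpendicular to the isoenergy contours and
    crosses the barrier at its lowest saddle. If the monotone walk
    dead-ends on a raggedly sampled landscape, the lowest-saddle
    (minimax) route over occupied bins is taken instead. Empty bins are
    never entered; an explicitly requested end bin that is disconnected
    from the start raises an error naming the blocking region.
    """
    if grid.deltaF is None:
        raise ValueError("grid has no free energies: call free_energy first")
    dF = grid.deltaF
    if start_bin is None:
        start_bin = modal_bin(grid)
    start_bin = tuple(int(i) for i in start_bin)
    if not np.isfinite(dF[start_bin]):
        raise ValueError(f"start bin {start_bin} is unoccupied")
    component = _connected_component(dF, start_bin)
    if end_bin is None:
        comp = np.array(sorted(component))
        dist = np.max(np.abs(comp - np.asarray(start_bin)), axis=1)
        end_bin = tuple(int(i) for i in comp[int(np.argmax(dist))])
    end_bin = tuple(int(i) for i in end_bin)
    if not np.isfinite(dF[end_bin]):
        raise ValueError(f"end bin {end_bin} is unoccupied")
    if end_bin not in component:
        raise ValueError(
            f"start {start_bin} and end {end_bin} bins are disconnected: "
            f"no occupied route leaves the start's region of "
            f"{len(component)} bins")
    path = _greedy_path(dF, start_bin, end_bin)
    if path is None:
        path = _minimax_path(dF, start_bin, end_bin)
    if path is None:  # unreachable given the component check, kept as a guard
        raise ValueError(f"no route from {start_bin} to {end_bin}")

    centers = np.array([grid.bin_center(b) for b in path])
    if len(path) > 1:
        seglen = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
    else:
        arc = np.zeros(1)
    profile = np.array([dF[b] for b in path])
    RT = grid.RT if grid.RT is not None else 1.0
    return ReactionPath(path, arc, profile, RT)


def barrier_stats(path: ReactionPath, stability_threshold: float | None = None):
    """Activation free energy, channel index and post-barrier intermediates.

    channel index
        Fraction of the path's arc length whose DeltaF lies within RT of
        the barrier top (each point weighted by half its adjacent segment
        lengths). A sharply peaked barrier gives a small index; a flat,
        channel-like barrier top gives a large one.
    intermediates
        Each post-barrier local minimum of the profile is reported with
        well depth min(adjacent maxima) - minimum; it is a thermally
        stable intermediate iff the depth exceeds ``stability_threshold``
        (default RT -- wells shallower than the thermal energy are not
        stable states). The final path point is a boundary, not a minimum.
    """
    prof = path.profile
    if len(prof) == 0:
        raise ValueError("empty path")
    RT = path.RT
    if stability_threshold is None:
        stability_threshold = RT
    dF_act = float(prof.max() - prof[0])
    top = prof.max()

    # per-point arc weights: half the adjacent segment lengths
    if len(prof) > 1:
        seg = np.diff(path.arc_length)
        w = np.zeros(len(prof))
        w[:-1] += seg / 2
        w[1:] += seg / 2
        total = w.sum()
    else:
        w = np.ones(1)
        total = 1.0
    near_top = prof >= top - RT
    channel_index = float(w[near_top].sum() / total)

    intermediates = []
    barrier_idx = int(np.argmax(prof))
    post = prof[barrier_idx:]
    pos = path.arc_length[barrier_idx:]
    for i in range(1, len(post) - 1):   # final point is a boundary, excluded
        if post[i] <= post[i - 1] and post[i] <= post[i + 1] and \
                (post[i] < post[i - 1] or post[i] < post[i + 1]):
            left_max = float(post[:i].max())
            right_max = float(post[i + 1:].max())
            depth = min(left_max, right_max) - float(post[i])
            intermediates.append({
                "position": float(pos[i]),
                "deltaF": float(post[i]),
                "well_depth": depth,
                "stable": bool(depth > stability_threshold),
            })
    return dF_act, channel_index, intermediates


def tst_rate(deltaF_activation: float, temperature: float,
             prefactor: float = 1e6) -> RateEstimate:
    """Transition-state-theory rate k_u = prefactor * exp(-DeltaF‡/RT).

    The default prefactor is the protein value 1e6 s^-1.
    """
    if deltaF_activation < 0:
        raise ValueError("activation free energy must be non-negative")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    RT = GAS_CONSTANT_KCAL * temperature
    k = prefactor * np.exp(-deltaF_activation / RT)
    return RateEstimate(float(k), prefactor, deltaF_activation, temperature)
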