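"""Synthetic ground-truth generators.

Desk-scale stand-ins for cluster-scale thermal-unfolding MD: (i) Brownian
(overdamped Langevin) sampling on analytic 2D free-energy surfaces whose
barrier heights are known in closed form, (ii) a Calpha-only toy protein
(one ideal alpha-helix plus an antiparallel beta-hairpin) and unfolding
trajectories with a planted native phase, a molten-globule plateau of
prescribed radius-of-gyration expansion, and a progressive-disorder tail,
and (iii) mutant/wild-type frame ensembles with prescribed mean
native-contact shifts for phi-value recovery.

All generators are deterministic given (seed, parameters): each call owns
a single ``numpy.random.Generator``; no global state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numba import njit

from .core import Topology, Trajectory

__all__ = [
    "PotentialSpec",
    "SamplerConfig",
    "UnfoldingScenario",
    "brownian_sample",
    "make_toy_native",
    "make_unfolding_trajectory",
    "make_phi_ensembles",
]


# ---------------------------------------------------------------------------
# analytic potentials
# ---------------------------------------------------------------------------

_KIND_CODES = {"harmonic": 0, "double_well": 1, "channel": 2}


@dataclass
class PotentialSpec:
    """Analytic 2D potential with a closed-form barrier.

    kinds
    -----
    harmonic
        V = kappa/2 (x^2 + y^2); parameters: ``kappa`` (kcal/mol/A^2).
    double_well
        V = h ((x/a)^2 - 1)^2 + kappa_y/2 y^2; minima at x = +-a,
        barrier h at x = 0.
    channel
        double well whose barrier top is replaced by a flat plateau of
        length ``L`` at V = h: with u = sign(x) max(|x| - L/2, 0),
        V = h ((u/a)^2 - 1)^2 + kappa_y/2 y^2. Minima at |x| = L/2 + a;
        the flat top is the controllable analogue of an extended,
        channel-like transition state.
    """

    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown potential kind: {self.kind}")
        defaults = {"harmonic": {"kappa": 1.0},
                    "double_well": {"h": 1.0, "a": 1.0, "kappa_y": 1.0},
                    "channel": {"h": 1.0, "a": 1.0, "kappa_y": 1.0, "L": 2.0}}
        p = dict(defaults[self.kind])
        p.update(self.parameters)
        self.parameters = p
        for k, v in p.items():
            if v <= 0:
                raise ValueError(f"potential parameter {k} must be > 0")

    @property
    def analytic_barrier(self) -> float:
        """Closed-form barrier height Delta-F-dagger implied by parameters."""
        if self.kind == "harmonic":
            return 0.0
        return float(self.parameters["h"])

    @property
    def minima(self) -> np.ndarray:
        """(2, 2) array of the two well minima (x, y); one row for harmonic."""
        if self.kind == "harmonic":
            return np.array([[0.0, 0.0]])
        a = self.parameters["a"]
        off = a if self.kind == "double_well" else self.parameters["L"] / 2 + a
        return np.array([[-off, 0.0], [off, 0.0]])

    def energy(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        p = self.parameters
        if self.kind == "harmonic":
            return 0.5 * p["kappa"] * (x ** 2 + y ** 2)
        if self.kind == "double_well":
            return p["h"] * ((x / p["a"]) ** 2 - 1) ** 2 + 0.5 * p["kappa_y"] * y ** 2
        u = np.sign(x) * np.maximum(np.abs(x) - p["L"] / 2, 0.0)
        return p["h"] * ((u / p["a"]) ** 2 - 1) ** 2 + 0.5 * p["kappa_y"] * y ** 2

    def gradient(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        p = self.parameters
        if self.kind == "harmonic":
            return p["kappa"] * x, p["kappa"] * y
        if self.kind == "double_well":
            gx = 4 * p["h"] / p["a"] ** 2 * x * ((x / p["a"]) ** 2 - 1)
            return gx, p["kappa_y"] * y
        u = np.sign(x) * np.maximum(np.abs(x) - p["L"] / 2, 0.0)
        gx = 4 * p["h"] / p["a"] ** 2 * u * ((u / p["a"]) ** 2 - 1)
        return gx, p["kappa_y"] * y


@dataclass
class SamplerConfig:
    """Overdamped-Langevin sampler settings (kT in kcal/mol)."""

    kT: float = 0.9896
    dt: float = 0.01
    n_steps: int = 100_000
    friction: float = 1.0
    seed: int = 0
    initial_point: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.kT <= 0:
            raise ValueError("kT must be > 0")


@njit(cache=False)
def _em_loop(x0, y0, drift, amp, n_steps, noise, kind, h, a, ky, L, kappa, bound):
    out = np.empty((n_steps + 1, 2))
    out[0, 0] = x0
    out[0, 1] = y0
    x, y = x0, y0
    for i in range(n_steps):
        if kind == 0:
            gx = kappa * x
            gy = kappa * y
        else:
            if kind == 1:
                u = x
            else:
                au = abs(x) - L / 2
                if au < 0.0:
                    au = 0.0
                u = au if x >= 0 else -au
            gx = 4.0 * h / (a * a) * u * ((u / a) ** 2 - 1.0)
            gy = ky * y
        x = x - drift * gx + amp * noise[i, 0]
        y = y - drift * gy + amp * noise[i, 1]
        if abs(x) > bound or abs(y) > bound:
            return out[: i + 1], i
        out[i + 1, 0] = x
        out[i + 1, 1] = y
    return out, -1


def brownian_sample(potential: PotentialSpec, cfg: SamplerConfig,
                    bound: float = 1e6) -> np.ndarray:
    """Euler-Maruyama sampling of the overdamped Langevin equation.

    x <- x - (dt/gamma) grad V + sqrt(2 kT dt / gamma) xi,  xi ~ N(0, 1).

    Returns an (n_steps + 1, 2) array including the initial point.
    Raises if the walk diverges beyond ``bound`` (usually a too-large dt).
    """
    x0, y0 = float(cfg.initial_point[0]), float(cfg.initial_point[1])
    gx, gy = potential.gradient(x0, y0)
    if not (np.isfinite(gx) and np.isfinite(gy)):
        raise ValueError("potential gradient not finite at the initial point")
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal((cfg.n_steps, 2))
    p = potential.parameters
    drift = cfg.dt / cfg.friction
    amp = np.sqrt(2.0 * cfg.kT * cfg.dt / cfg.friction)
    out, bad = _em_loop(
        x0, y0, drift, amp, cfg.n_steps, noise, _KIND_CODES[potential.kind],
        p.get("h", 0.0), p.get("a", 1.0), p.get("kappa_y", 1.0),
        p.get("L", 0.0), p.get("kappa", 1.0), bound)
    if bad >= 0:
        raise FloatingPointError(
            f"Brownian walk diverged at step {bad} (|coord| > {bound:g}); "
            f"dt={cfg.dt} is the likely cause -- reduce it")
    return out


# ---------------------------------------------------------------------------
# toy protein
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5       # A per residue
_HELIX_RADIUS = 2.3     # A
_HELIX_TWIST = np.deg2rad(100.0)
_CA_SPACING = 3.8       # A along a strand
_STRAND_SEP = 4.8       # A between paired antiparallel strands


def _segment_layout(n_residues: int):
    """Residue index ranges for helix / loop / strand1 / turn / strand2."""
    if n_residues < 20:
        raise ValueError("toy protein needs at least 20 residues")
    base_h = max(8, round(0.4 * n_residues))
    n_s = (n_residues - base_h - 4) // 2
    n_h = n_residues - 4 - 2 * n_s
    if n_s < 3:
        raise ValueError("too few residues for strands")
    i = 0
    seg = {}
    seg["helix"] = (i, i + n_h); i += n_h
    seg["loop"] = (i, i + 2); i += 2
    seg["strand1"] = (i, i + n_s); i += n_s
    seg["turn"] = (i, i + 2); i += 2
    seg["strand2"] = (i, i + n_s); i += n_s
    assert i == n_residues
    return seg


def make_toy_native(n_residues: int = 30, seed: int = 0):
    """Build a Calpha-only toy native structure.

    One ideal alpha-helix (rise 1.5 A, radius 2.3 A, 100 deg/residue)
    followed by a short loop and an antiparallel two-strand hairpin
    (Calpha spacing 3.8 A along each strand, 4.8 A between strands),
    packed against the helix so that helix-sheet native contacts exist.
    Consecutive Calpha-Calpha distances all fall in 3.5-4.0 A.

    Returns ``(Topology, coords, segments)`` where ``segments`` maps
    segment names to 0-based residue index ranges (ground-truth labels).
    The construction is deterministic; ``seed`` is recorded but the
    native geometry is purely analytic.
    """
    seg = _segment_layout(n_residues)
    coords = np.zeros((n_residues, 3))
    h0, h1 = seg["helix"]
    n_h = h1 - h0
    # phase chosen so the last helix residue points toward +y
    phase = np.pi / 2 - _HELIX_TWIST * (n_h - 1)
    for j in range(n_h):
        th = phase + _HELIX_TWIST * j
        coords[h0 + j] = (_HELIX_RADIUS * np.cos(th), _HELIX_RADIUS * np.sin(th),
                          _HELIX_RISE * j)
    ztop = _HELIX_RISE * (n_h - 1)
    # loop: two residues bridging helix top to the sheet (spacings ~3.77 A)
    l0, _ = seg["loop"]
    coords[l0] = (0.0, 5.5, ztop - 2.0)
    coords[l0 + 1] = (0.0, 8.7, ztop)
    # strand 1 runs down along -z at y = 8.7
    s10, s11 = seg["strand1"]
    n_s = s11 - s10
    for j in range(n_s):
        coords[s10 + j] = (0.0, 8.7, ztop - _CA_SPACING * (j + 1))
    zend = ztop - _CA_SPACING * n_s
    # hairpin turn, out-of-plane in +y so consecutive spacings stay in range
    t0, _ = seg["turn"]
    coords[t0] = (0.6, 8.7 + 2.65, zend - 2.65)
    coords[t0 + 1] = (_STRAND_SEP - 0.6, 8.7 + 2.65, zend - 2.65)
    # strand 2 runs back up, paired with strand 1 at 4.8 A
    s20, s21 = seg["strand2"]
    for j in range(n_s):
        coords[s20 + j] = (_STRAND_SEP, 8.7, zend + _CA_SPACING * j)

    topology = Topology(
        atom_names=["CA"] * n_residues,
        residue_index_per_atom=np.arange(n_residues),
        residue_names=["ALA"] * n_residues,
        masses=np.full(n_residues, 12.011),
        calpha_mask=np.ones(n_residues, dtype=bool),
    )
    return topology, coords, seg


# ---------------------------------------------------------------------------
# unfolding trajectories
# ---------------------------------------------------------------------------


@dataclass
class UnfoldingScenario:
    """Planted three-phase unfolding: native, molten-globule plateau, disorder.

    The defaults emulate a 100 ns thermal-unfolding run saved every
    0.05 ns (2000 frames) with native exit at 1.2 ns, a molten-globule
    plateau extending to 35 ns with a 14% radius-of-gyration expansion,
    and progressive unfolding thereafter.
    """

    n_residues: int = 30
    native_frames: int = 24
    exit_frame: int = 24
    plateau_frames: int = 676
    disorder_frames: int = 1300
    expansion_factor: float = 1.14
    final_disorder: float = 0.9
    frame_interval: float = 0.05
    native_noise: float = 0.15       # A, per-coordinate Gaussian sd
    plateau_noise: float = 0.10
    plateau_wobble_deg: float = 3.0  # rigid-unit wobble in the plateau
    seed: int = 0

    def __post_init__(self):
        if self.exit_frame != self.native_frames:
            raise ValueError("exit_frame must equal native_frames (exit is the "
                             "first post-native frame)")
        if not (0 <= self.final_disorder <= 1):
            raise ValueError("final_disorder must lie in [0, 1]")
        if self.expansion_factor <= 1:
            raise ValueError("expansion_factor must exceed 1")
        if self.plateau_frames < 1 or self.native_frames < 1:
            raise ValueError("native and plateau phases need at least one frame")

    @property
    def n_frames(self) -> int:
        return self.native_frames + self.plateau_frames + self.disorder_frames


def _radius_of_gyration(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c ** 2).sum(axis=1).mean()))


def _expand_units(units, coords, target_rg):
    """Scale rigid-unit centroids about the global centroid to hit target Rg.

    With r_i = c_u(i) + d_i and centroids moved to cbar + lam (c_u - cbar),
    Rg^2(lam) is quadratic in lam; solve for the positive root.
    """
    cbar = coords.mean(axis=0)
    u = np.zeros_like(coords)
    d = np.zeros_like(coords)
    for idx in units:
        cu = coords[idx].mean(axis=0)
        u[idx] = cu - cbar
        d[idx] = coords[idx] - cu
    n = len(coords)
    # Rg^2(lam) relative to the frame centroid: the centroid of the moved
    # configuration stays at cbar because sum over atoms of u is ~0 only if
    # units are equally sized; recentre explicitly instead.
    a = (u ** 2).sum() / n
    b = 2.0 * (u * d).sum() / n
    c0 = (d ** 2).sum() / n
    # correct for the centroid shift: mean displacement m(lam) = lam * ubar
    ubar = u.mean(axis=0)
    dbar = d.mean(axis=0)  # ~0 by construction
    a -= (ubar ** 2).sum()
    b -= 2.0 * (ubar * dbar).sum()
    c0 -= (dbar ** 2).sum()
    disc = b ** 2 - 4 * a * (c0 - target_rg ** 2)
    if a <= 0 or disc < 0:
        raise ValueError("requested expansion is infeasible for this geometry")
    lam = (-b + np.sqrt(disc)) / (2 * a)
    if lam <= 0:
        raise ValueError("requested expansion is infeasible for this geometry")
    out = cbar + lam * u + d
    return out


def _rotation_matrix(axis, angle):
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _random_coil(n, rng, step=_CA_SPACING, min_dist=4.0, max_tries=200):
    """Self-avoiding random walk with fixed step length."""
    pts = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(max_tries):
            v = rng.standard_normal(3)
            v *= step / np.linalg.norm(v)
            cand = pts[i - 1] + v
            if i < 2 or np.min(np.linalg.norm(pts[: i - 1] - cand, axis=1)) >= min_dist:
                pts[i] = cand
                break
        else:
            raise RuntimeError("self-avoiding coil generation failed")
    return pts * 1.8  # swell the coil so it is clearly non-compact


def _plateau_frame(native, units, target_rg, wobble_rad, noise_sd, rng):
    """One molten-globule frame: rigid-unit wobble, exact-Rg expansion, noise."""
    coords = native.copy()
    for idx in units:
        cu = coords[idx].mean(axis=0)
        R = _rotation_matrix(rng.standard_normal(3),
                            rng.normal(0.0, wobble_rad))
        coords[idx] = (coords[idx] - cu) @ R.T + cu + rng.normal(0.0, 0.3, 3)
    coords = _expand_units(units, coords, target_rg)
    return coords + rng.normal(0.0, noise_sd, coords.shape)


def make_unfolding_trajectory(native_coords: np.ndarray, topology: Topology,
                              scenario: UnfoldingScenario,
                              segments: dict | None = None):
    """Generate a planted three-phase unfolding trajectory.

    Phases
    ------
    native : frames [0, exit_frame)
        Native coordinates plus small Gaussian noise; Calpha RMSD to the
        native stays well inside the native cluster.
    plateau : frames [exit_frame, exit_frame + plateau_frames)
        Two rigid units (helix+loop, hairpin) are translated apart so
        every frame's Rg/Rg_native matches ``expansion_factor`` (with
        +-0.5% frame-to-frame jitter); the units' internal geometry -- and
        hence secondary structure -- is preserved.
    disorder : remaining frames
        Morph from the expanded form toward a self-avoiding random coil,
        with a sqrt-in-time schedule reaching ``final_disorder``; mean
        native contacts decay monotonically. ``final_disorder = 0``
        reproduces plateau statistics to the end.

    Returns ``(Trajectory, ground_truth)`` where ``ground_truth`` records
    the planted exit frame, plateau range, target expansion and segment
    labels.
    """
    if segments is None:
        segments = _segment_layout(topology.n_residues)
    if native_coords.shape[0] != topology.n_atoms:
        raise ValueError("native frame does not match topology")
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    units = [np.arange(segments["helix"][0], segments["loop"][1]),
             np.arange(segments["strand1"][0], segments["strand2"][1])]
    rg_native = _radius_of_gyration(native_coords)
    wobble = np.deg2rad(sc.plateau_wobble_deg)

    frames = np.empty((sc.n_frames, topology.n_atoms, 3))
    for f in range(sc.native_frames):
        frames[f] = native_coords + rng.normal(0.0, sc.native_noise,
                                               native_coords.shape)
    plateau_end = sc.exit_frame + sc.plateau_frames
    for f in range(sc.exit_frame, plateau_end):
        target = rg_native * sc.expansion_factor * (1 + rng.normal(0.0, 0.005))
        frames[f] = _plateau_frame(native_coords, units, target, wobble,
                                   sc.plateau_noise, rng)
    if sc.disorder_frames > 0:
        coil = _random_coil(topology.n_atoms, rng)
        coil = coil - coil.mean(axis=0) + native_coords.mean(axis=0)
        nd = sc.disorder_frames
        for j in range(nd):
            t = sc.final_disorder * np.sqrt((j + 1) / nd)
            target = rg_native * sc.expansion_factor * (1 + rng.normal(0.0, 0.005))
            base = _plateau_frame(native_coords, units, target, wobble,
                                  sc.plateau_noise, rng)
            frames[plateau_end + j] = (1 - t) * base + t * coil

    traj = Trajectory(topology, frames, sc.frame_interval,
                      origin_label=f"synthetic-unfolding(seed={sc.seed})")
    # realized plateau contact retention: determined by the expansion
    # geometry (inter-unit contacts break, intra-unit ones survive), so it
    # is measured here and recorded as ground truth rather than configured
    ii, jj = np.triu_indices(topology.n_atoms, k=3)
    dn = np.linalg.norm(native_coords[ii] - native_coords[jj], axis=1)
    nat_pairs = np.column_stack([ii[dn <= 8.0], jj[dn <= 8.0]])
    plateau = frames[sc.exit_frame:plateau_end]
    q = [_frame_native_count(f, nat_pairs, 8.0) for f in plateau]
    plateau_q_mean = float(np.mean(q) / len(nat_pairs))
    ground_truth = {
        "plateau_contact_retention": plateau_q_mean,
        "exit_frame": sc.exit_frame,
        "plateau_range": (sc.exit_frame, plateau_end - 1),
        "expansion_factor": sc.expansion_factor,
        "rg_native": rg_native,
        "segments": {k: list(v) for k, v in segments.items()},
        "frame_interval": sc.frame_interval,
        "final_disorder": sc.final_disorder,
        "seed": sc.seed,
    }
    return traj, ground_truth


def write_ground_truth(ground_truth: dict, path) -> None:
    """JSON sidecar with the generator's planted labels."""
    with open(Path(path), "w") as fh:
        json.dump(ground_truth, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# phi-value ensembles
# ---------------------------------------------------------------------------


def _frame_native_count(frame, pairs, cutoff):
    d = np.linalg.norm(frame[pairs[:, 0]] - frame[pairs[:, 1]], axis=1)
    return int(np.sum(d <= cutoff))


def _adjust_frame(frame, pairs, cutoff, target, rng, max_attempts=20):
    """Break (or re-form) native contacts by local displacement until the
    frame's native-contact count equals ``target`` exactly."""
    for _ in range(max_attempts):
        work = frame.copy()
        guard = 0
        while guard < 200:
            guard += 1
            d = np.linalg.norm(work[pairs[:, 0]] - work[pairs[:, 1]], axis=1)
            q = int(np.sum(d <= cutoff))
            if q == target:
                return work
            if q > target:
                formed = np.flatnonzero(d <= cutoff)
                k = pairs[rng.choice(formed)]
                v = work[k[1]] - work[k[0]]
                work[k[1]] = work[k[0]] + v / np.linalg.norm(v) * (cutoff * 1.15)
            else:
                broken = np.flatnonzero(d > cutoff)
                if len(broken) == 0:
                    break
                k = pairs[broken[rng.integers(len(broken))]]
                v = work[k[1]] - work[k[0]]
                work[k[1]] = work[k[0]] + v / np.linalg.norm(v) * (cutoff * 0.85)
        # greedy overshoot or dead end: retry with a fresh ordering
    raise ValueError(f"could not realize native-contact target {target} "
                     "in a frame (requested shift unachievable?)")


def make_phi_ensembles(wt_ensembles: dict, shifts: dict, native_pairs: np.ndarray,
                       cutoff: float, seed: int = 0) -> dict:
    """Build mutant frame ensembles with prescribed mean native-contact shifts.

    Parameters
    ----------
    wt_ensembles : dict
        ``{"TS": (F, N, 3) array, "F": (F, N, 3) array}`` wild-type frames
        (transition-state and folded ensembles).
    shifts : dict
        ``{mutant_id: {"TS": float, "F": float}}`` requested change in the
        ensemble-mean native-contact count relative to wild type
        (non-positive: mutations delete contacts; zero leaves frames
        untouched).
    native_pairs : (P, 2) int array
        Calpha index pairs of the wild-type native contact set.
    cutoff : float
        Contact distance cutoff in A.

    Returns ``{mutant_id: {"TS": frames, "F": frames}}``; realized ensemble
    means land within +-0.5 contacts of the request. Wild-type frames are
    never modified in place.
    """
    native_pairs = np.asarray(native_pairs, dtype=int)
    rng = np.random.default_rng(seed)
    out = {}
    for mid in sorted(shifts):
        out[mid] = {}
        for ens_name in ("TS", "F"):
            frames = np.asarray(wt_ensembles[ens_name], dtype=float)
            shift = float(shifts[mid][ens_name])
            if shift == 0.0:
                out[mid][ens_name] = frames.copy()
                continue
            nf = len(frames)
            base_q = np.array([_frame_native_count(f, native_pairs, cutoff)
                               for f in frames])
            # per-frame integer targets whose mean realizes the requested shift
            lo = int(np.floor(shift))
            frac = shift - lo
            n_hi = int(round(frac * nf))
            deltas = np.full(nf, lo)
            deltas[:n_hi] += 1
            rng.shuffle(deltas)
            targets = base_q + deltas
            if np.any(targets < 0) or np.any(targets > len(native_pairs)):
                raise ValueError(f"shift {shift} unachievable for mutant {mid}")
            new_frames = np.empty_like(frames)
            for i in range(nf):
                new_frames[i] = _adjust_frame(frames[i], native_pairs, cutoff,
                                              int(targets[i]), rng)
            out[mid][ens_name] = new_frames
    return out
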