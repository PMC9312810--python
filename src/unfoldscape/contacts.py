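"""Native contacts, radius of gyration, molten-globule classification.

The transition-state ensemble of a two-state unfolder is characterised in
the plane of native-contact count versus total-contact count (after Pande
and Rokhsar's lattice-model analysis): native frames keep nearly all
native contacts at native compactness; molten-globule frames keep most
secondary structure and a fair share of native contacts but are expanded;
unfolded frames have lost both. The molten-globule demarcation delimits
the extended transition region, from the native-exit frame to the end of
the last molten-globule run.

Secondary structure is assigned from Calpha pseudo-geometry alone (the
toy systems carry no backbone N/O): helix from the characteristic
i->i+3 / i->i+4 Calpha distance windows of an ideal alpha-helix, strand
from local extension plus a paired partner strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory
from .rmsd_space import NativeExit

__all__ = [
    "ContactDefinition",
    "ContactSeries",
    "TransitionEnsemble",
    "SecondaryStructureTimeline",
    "native_contacts",
    "contact_timeseries",
    "radius_of_gyration",
    "assign_secondary_structure",
    "secondary_structure_timeline",
    "classify_molten_globule",
    "demarcate_transition",
]


@dataclass(frozen=True)
class ContactDefinition:
    """Calpha-Calpha contact criterion.

    Defaults: 8.0 A cutoff, sequence separation |i-j| >= 3, Calpha only --
    matching the Calpha-level resolution of the rest of the pipeline.
    """

    cutoff: float = 8.0
    min_sequence_separation: int = 3
    calpha_only: bool = True

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_sequence_separation < 1:
            raise ValueError("min_sequence_separation must be >= 1")


@dataclass
class ContactSeries:
    """Per-frame native / total contact counts and radius of gyration."""

    native_set: np.ndarray       # (P, 2) residue index pairs, i < j
    Q: np.ndarray                # per-frame native contacts present
    total: np.ndarray            # per-frame all contacts
    q_fraction: np.ndarray       # Q / |native_set|
    Rg: np.ndarray               # per-frame, A
    Rg_native: float

    @property
    def rg_ratio(self) -> np.ndarray:
        return self.Rg / self.Rg_native


@dataclass
class TransitionEnsemble:
    """Frames between native exit and the molten-globule upper demarcation."""

    frame_range: tuple           # (first, last), inclusive
    member_frames: np.ndarray
    criteria: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return len(self.member_frames) == 0


@dataclass
class SecondaryStructureTimeline:
    """Per-frame, per-residue labels in {H, E, C} plus native persistence."""

    labels: np.ndarray           # (frames, residues) of 'H'/'E'/'C'
    native_labels: np.ndarray    # (residues,)
    persistence: np.ndarray      # per-residue fraction of frames native-like

    def frame_persistence(self, structured_only: bool = True) -> np.ndarray:
        """Per-frame fraction of residues keeping their native label.

        With ``structured_only`` the fraction is taken over residues whose
        native label is H or E (coil staying coil carries no signal about
        retained structure).
        """
        if structured_only:
            sel = self.native_labels != "C"
            if not np.any(sel):
                sel = np.ones_like(self.native_labels, dtype=bool)
        else:
            sel = np.ones_like(self.native_labels, dtype=bool)
        return (self.labels[:, sel] == self.native_labels[sel]).mean(axis=1)


def _calpha_positions(topology, frame):
    return np.asarray(frame)[topology.calpha_mask]


def _pair_matrix(n, min_sep):
    i, j = np.triu_indices(n, k=min_sep)
    return i, j


def native_contacts(native_frame: np.ndarray, topology,
                    definition: ContactDefinition = ContactDefinition()) -> np.ndarray:
    """Native Calpha contact pairs (i < j, |i-j| >= separation, d <= cutoff).

    Returns a (P, 2) array of 0-based Calpha residue indices.
    """
    pos = _calpha_positions(topology, native_frame)
    n = len(pos)
    if n < definition.min_sequence_separation + 1:
        raise ValueError("too few residues for the requested sequence separation")
    i, j = _pair_matrix(n, definition.min_sequence_separation)
    d = np.linalg.norm(pos[i] - pos[j], axis=1)
    keep = d <= definition.cutoff
    return np.column_stack([i[keep], j[keep]])


def contact_timeseries(traj: Trajectory, native_set: np.ndarray,
                       definition: ContactDefinition = ContactDefinition(),
                       native_frame: np.ndarray | None = None) -> ContactSeries:
    """Per-frame native contacts (Q), total contacts and Rg.

    ``native_frame`` (default: not needed beyond the contact set) supplies
    Rg_native; if omitted the first frame's Rg is used as the reference.
    """
    native_set = np.asarray(native_set, dtype=int)
    ca = traj.calpha_coords()
    n = ca.shape[1]
    i, j = _pair_matrix(n, definition.min_sequence_separation)
    d_all = np.linalg.norm(ca[:, i, :] - ca[:, j, :], axis=2)
    total = (d_all <= definition.cutoff).sum(axis=1)
    if len(native_set):
        d_nat = np.linalg.norm(ca[:, native_set[:, 0], :] -
                               ca[:, native_set[:, 1], :], axis=2)
        Q = (d_nat <= definition.cutoff).sum(axis=1)
        qfrac = Q / len(native_set)
    else:
        Q = np.zeros(traj.n_frames, dtype=int)
        qfrac = np.zeros(traj.n_frames)
    masses = traj.topology.masses[traj.topology.calpha_mask]
    rg = np.array([radius_of_gyration(f, masses=masses) for f in ca])
    if native_frame is not None:
        rg_native = radius_of_gyration(_calpha_positions(traj.topology, native_frame),
                                       masses=masses)
    else:
        rg_native = float(rg[0])
    return ContactSeries(native_set, Q, total, qfrac, rg, rg_native)


def radius_of_gyration(frame: np.ndarray, mask=None, masses=None) -> float:
    """Mass-weighted radius of gyration in A.

    Rg = sqrt( sum_i m_i |r_i - rbar|^2 / sum_i m_i ), rbar the
    mass-weighted centroid. Unit masses by default.
    """
    pos = np.asarray(frame, dtype=float)
    if mask is not None:
        pos = pos[mask]
        if masses is not None:
            masses = np.asarray(masses)[mask]
    if len(pos) == 0:
        raise ValueError("empty selection")
    if masses is None:
        masses = np.ones(len(pos))
    masses = np.asarray(masses, dtype=float)
    com = (pos * masses[:, None]).sum(axis=0) / masses.sum()
    return float(np.sqrt((masses * ((pos - com) ** 2).sum(axis=1)).sum() / masses.sum()))


# ---------------------------------------------------------------------------
# Calpha-geometry secondary structure
# ---------------------------------------------------------------------------

#: Calpha pseudo-geometry windows of an ideal alpha-helix (A)
HELIX_D13 = (4.8, 5.6)
HELIX_D14 = (5.8, 6.6)
#: minimum i->i+2 distance of an extended strand and the max pairing distance
STRAND_D13_MIN = 6.4
STRAND_PAIR_MAX = 5.5


def assign_secondary_structure(frame: np.ndarray, topology) -> np.ndarray:
    """Per-residue {H, E, C} labels from Calpha geometry.

    H: within a 5-residue run whose i->i+3 and i->i+4 Calpha distances fit
    the ideal-helix windows. E: locally extended (i->i+2 >= 6.4 A over a
    3-residue run) with a nonlocal partner strand within 5.5 A for >= 3
    consecutive paired residues. Terminal residues that cannot satisfy the
    window rules default to C; H takes precedence over E.
    """
    pos = _calpha_positions(topology, frame)
    n = len(pos)
    if n < 5:
        raise ValueError("need at least 5 residues")
    labels = np.full(n, "C", dtype="<U1")

    d13 = np.linalg.norm(pos[:-3] - pos[3:], axis=1)
    d14 = np.linalg.norm(pos[:-4] - pos[4:], axis=1)
    helix_ok = np.zeros(n - 4, dtype=bool)
    for i in range(n - 4):
        helix_ok[i] = (HELIX_D13[0] <= d13[i] <= HELIX_D13[1] and
                       HELIX_D14[0] <= d14[i] <= HELIX_D14[1])
    # a lone window hit can be mimicked by turn geometry; require a run of
    # at least two consecutive hits before calling a helix (so the shortest
    # detectable helix is 6 residues)
    helix = np.zeros(n, dtype=bool)
    hits = np.flatnonzero(helix_ok)
    for i in hits:
        if helix_ok[i] and (i + 1 < len(helix_ok) and helix_ok[i + 1]
                            or i - 1 >= 0 and helix_ok[i - 1]):
            helix[i:i + 5] = True

    d12 = np.linalg.norm(pos[:-2] - pos[2:], axis=1)
    ext_ok = d12 >= STRAND_D13_MIN
    extended = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(ext_ok):
        extended[i:i + 3] = True
    # pairing: an extended residue with a nonlocal extended partner nearby
    paired = np.zeros(n, dtype=bool)
    ext_idx = np.flatnonzero(extended)
    if len(ext_idx) >= 2:
        sub = pos[ext_idx]
        dmat = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2)
        for a, r in enumerate(ext_idx):
            partners = ext_idx[(np.abs(ext_idx - r) >= 4) &
                               (dmat[a] <= STRAND_PAIR_MAX)]
            paired[r] = len(partners) > 0
    # strands need >= 3 consecutive paired residues
    strand = np.zeros(n, dtype=bool)
    run = 0
    for r in range(n + 1):
        if r < n and paired[r]:
            run += 1
        else:
            if run >= 3:
                strand[r - run:r] = True
            run = 0
    labels[strand] = "E"
    labels[helix] = "H"
    return labels


def secondary_structure_timeline(traj: Trajectory, native_frame: np.ndarray
                                 ) -> SecondaryStructureTimeline:
    """Assign labels for every frame; persistence is per-residue agreement
    with the native-frame labels."""
    native_labels = assign_secondary_structure(native_frame, traj.topology)
    labels = np.array([assign_secondary_structure(f, traj.topology)
                       for f in traj.coords])
    persistence = (labels == native_labels).mean(axis=0)
    return SecondaryStructureTimeline(labels, native_labels, persistence)


def classify_molten_globule(series: ContactSeries,
                            ss: SecondaryStructureTimeline,
                            q_lo: float = 0.6,
                            expansion_min: float = 1.05,
                            q_floor: float = 0.3,
                            q_hi: float = 0.8) -> np.ndarray:
    """Per-frame class in {native, molten_globule, unfolded}.

    native: q_fraction >= q_hi and Rg/Rg_native < expansion_min (compact,
    contacts intact). molten_globule: secondary-structure persistence
    (fraction of natively structured residues keeping their label) >= q_lo,
    Rg/Rg_native >= expansion_min, and q_fraction >= q_floor (expanded but
    structured). Everything else: unfolded.
    """
    for name, v in (("q_lo", q_lo), ("q_floor", q_floor), ("q_hi", q_hi)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    nf = len(series.Q)
    if ss.labels.shape[0] != nf:
        raise ValueError("contact series and secondary structure are not aligned")
    pers = ss.frame_persistence()
    ratio = series.rg_ratio
    out = np.full(nf, "unfolded", dtype="<U14")
    mg = (pers >= q_lo) & (ratio >= expansion_min) & (series.q_fraction >= q_floor)
    out[mg] = "molten_globule"
    nat = (series.q_fraction >= q_hi) & (ratio < expansion_min)
    out[nat] = "native"
    return out


def demarcate_transition(exit: NativeExit, classes: np.ndarray,
                         gap_tolerance: int = 10) -> TransitionEnsemble:
    """Transition-state ensemble between native exit and the end of the
    last contiguous molten-globule run.

    Runs separated by at most ``gap_tolerance`` non-molten-globule frames
    are merged; the merged run must start within ``gap_tolerance`` frames
    of the exit. Returns an empty ensemble (with a warning) if no
    molten-globule frames follow the exit.
    """
    classes = np.asarray(classes)
    nf = len(classes)
    if not exit.found or exit.exit_frame >= nf:
        raise ValueError("native exit frame must precede the trajectory end")
    first = int(exit.exit_frame)
    mg = np.flatnonzero(classes == "molten_globule")
    mg = mg[mg >= first]
    criteria = {"exit_frame": first, "gap_tolerance": int(gap_tolerance)}
    if len(mg) == 0 or mg[0] - first > gap_tolerance:
        warnings.warn("no molten-globule frames follow the native exit; "
                      "transition ensemble is empty", stacklevel=2)
        return TransitionEnsemble((first, first), np.array([], dtype=int), criteria)
    # merge runs separated by small gaps, starting from the exit
    last = int(mg[0])
    for f in mg[1:]:
        if f - last <= gap_tolerance + 1:
            last = int(f)
        else:
            break
    members = mg[mg <= last]
    return TransitionEnsemble((first, last), members, criteria)
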