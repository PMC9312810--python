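import dataclasses

import numpy as np
import pytest
from scipy import stats

import unfoldscape as u
from unfoldscape.synthetic import _frame_native_count


# ---------------------------------------------------------------------------
# Brownian sampler
# ---------------------------------------------------------------------------


def test_harmonic_variance_matches_boltzmann():
    """Equilibrium variance of x in a harmonic well is kT/kappa."""
    pot = u.PotentialSpec("harmonic", {"kappa": 1.0})
    cfg = u.SamplerConfig(kT=1.0, dt=0.01, n_steps=1_000_000, seed=11)
    xy = u.brownian_sample(pot, cfg)
    burn = xy[1000:]
    assert burn[:, 0].var() == pytest.approx(1.0, rel=0.05)
    assert burn[:, 1].var() == pytest.approx(1.0, rel=0.05)


def test_zero_temperature_fixed_point():
    pot = u.PotentialSpec("harmonic", {"kappa": 1.0})
    cfg = u.SamplerConfig(kT=1e-12, dt=0.01, n_steps=1000, seed=0,
                          initial_point=(0.0, 0.0))
    xy = u.brownian_sample(pot, cfg)
    assert np.abs(xy).max() < 1e-4


def test_double_well_occupancy_matches_quadrature():
    """Barrier-region occupancy agrees with Boltzmann weights computed by
    independent numerical quadrature of exp(-V/kT)."""
    kT = 1.0
    pot = u.PotentialSpec("double_well", {"h": 3 * kT, "a": 1.0, "kappa_y": 1.0})
    # dt small enough that the Euler-Maruyama discretization bias in the
    # barrier-region occupancy is well under the comparison tolerance
    cfg = u.SamplerConfig(kT=kT, dt=0.002, n_steps=2_000_000, seed=5,
                          initial_point=(-1.0, 0.0))
    xy = u.brownian_sample(pot, cfg)
    # quadrature oracle on the x marginal (y integrates out identically)
    x = np.linspace(-3, 3, 4001)
    w = np.exp(-pot.energy(x, np.zeros_like(x)) / kT)
    p_mid_exact = np.trapezoid(w[np.abs(x) <= 0.5], x[np.abs(x) <= 0.5]) / \
        np.trapezoid(w, x)
    p_mid = float((np.abs(xy[:, 0]) <= 0.5).mean())
    assert p_mid == pytest.approx(p_mid_exact, rel=0.10)
    # both wells visited, roughly evenly (symmetric potential)
    assert 0.35 < (xy[:, 0] > 0).mean() < 0.65


def test_harmonic_marginal_is_gaussian_ks():
    pot = u.PotentialSpec("harmonic", {"kappa": 1.0})
    cfg = u.SamplerConfig(kT=1.0, dt=0.01, n_steps=1_000_000, seed=3)
    xy = u.brownian_sample(pot, cfg)
    sub = xy[1000::200, 0]  # decorrelate (relaxation time ~ gamma/kappa/dt)
    stat = stats.kstest(sub, "norm", args=(0, 1)).statistic
    assert stat < 0.03


def test_sampler_reproducible_and_divergence_error():
    pot = u.PotentialSpec("double_well", {"h": 2.0, "a": 1.0})
    cfg = u.SamplerConfig(kT=1.0, dt=0.01, n_steps=2000, seed=42)
    assert np.array_equal(u.brownian_sample(pot, cfg), u.brownian_sample(pot, cfg))
    bad = u.SamplerConfig(kT=1.0, dt=50.0, n_steps=5000, seed=0,
                          initial_point=(1.5, 0.0))
    with pytest.raises(FloatingPointError, match="dt"):
        u.brownian_sample(pot, bad)


def test_potential_gradient_consistency():
    """Analytic gradients match central differences of the energy."""
    for kind in ("harmonic", "double_well", "channel"):
        pot = u.PotentialSpec(kind, {})
        rng = np.random.default_rng(1)
        pts = rng.uniform(-3, 3, (50, 2))
        gx, gy = pot.gradient(pts[:, 0], pts[:, 1])
        h = 1e-6
        ngx = (pot.energy(pts[:, 0] + h, pts[:, 1]) -
               pot.energy(pts[:, 0] - h, pts[:, 1])) / (2 * h)
        ngy = (pot.energy(pts[:, 0], pts[:, 1] + h) -
               pot.energy(pts[:, 0], pts[:, 1] - h)) / (2 * h)
        assert gx == pytest.approx(ngx, abs=1e-5)
        assert gy == pytest.approx(ngy, abs=1e-5)


def test_channel_barrier_is_flat_over_plateau():
    pot = u.PotentialSpec("channel", {"h": 3.0, "a": 1.0, "L": 2.0})
    x = np.linspace(-0.99, 0.99, 101)
    assert pot.energy(x, np.zeros_like(x)) == pytest.approx(3.0)
    assert pot.analytic_barrier == 3.0


# ---------------------------------------------------------------------------
# toy protein
# ---------------------------------------------------------------------------


def test_toy_native_geometry(toy):
    top, native, seg = toy
    assert top.n_atoms == 30 and top.calpha_mask.sum() == 30
    d = np.linalg.norm(np.diff(native, axis=0), axis=1)
    assert d.min() >= 3.5 and d.max() <= 4.0
    # determinism
    _, again, _ = u.make_toy_native(30, seed=0)
    assert np.array_equal(native, again)
    with pytest.raises(ValueError):
        u.make_toy_native(10)


def _pseudo_dihedral(p):
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(m @ n2, n1 @ n2))


def test_helix_pseudo_dihedral_regularity(toy):
    """Successive Calpha pseudo-dihedrals inside the helix are constant to
    within 2 degrees of the ideal-construction value."""
    top, native, seg = toy
    h0, h1 = seg["helix"]
    dihedrals = [_pseudo_dihedral(native[i:i + 4]) for i in range(h0, h1 - 3)]
    # oracle: the dihedral implied by the ideal helix parameters themselves
    t = np.deg2rad(100.0) * np.arange(4)
    ideal_pts = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t),
                                 1.5 * np.arange(4)])
    ideal = _pseudo_dihedral(ideal_pts)
    assert np.asarray(dihedrals) == pytest.approx(ideal, abs=2.0)


# ---------------------------------------------------------------------------
# unfolding trajectories
# ---------------------------------------------------------------------------


def test_unfolding_phase_postconditions(unfolding_fixture):
    traj, truth, native = unfolding_fixture
    exit_f = truth["exit_frame"]
    lo, hi = truth["plateau_range"]
    ca = traj.calpha_coords()
    # (i) native phase stays in the native cluster
    rmsds = [u.kabsch_superpose(native, f)[2] for f in ca[:exit_f]]
    assert max(rmsds) < 1.0
    # (ii) plateau Rg ratio tracks the configured expansion
    rg = np.array([u.radius_of_gyration(f) for f in ca])
    ratio = rg / truth["rg_native"]
    assert ratio[lo:hi + 1].mean() == pytest.approx(1.14, abs=0.02)
    assert np.all(np.abs(ratio[lo:hi + 1] - 1.14) < 0.03)
    # (iii) post-plateau native contacts decay monotonically in the mean
    defn = u.ContactDefinition()
    nset = u.native_contacts(native, traj.topology, defn)
    series = u.contact_timeseries(traj, nset, defn, native_frame=native)
    post = series.Q[hi + 1:]
    chunk = len(post) // 5
    means = [post[i * chunk:(i + 1) * chunk].mean() for i in range(5)]
    assert all(a >= b for a, b in zip(means, means[1:]))


def test_unfolding_reproducible_and_expansion_example(toy):
    top, native, seg = toy
    sc = u.UnfoldingScenario(native_frames=20, exit_frame=20, plateau_frames=40,
                             disorder_frames=0, expansion_factor=1.14,
                             frame_interval=0.1, seed=9)
    t1, _ = u.make_unfolding_trajectory(native, top, sc, seg)
    t2, _ = u.make_unfolding_trajectory(native, top, sc, seg)
    assert np.array_equal(t1.coords, t2.coords)
    rg_nat = u.radius_of_gyration(native)
    rg = np.array([u.radius_of_gyration(f) for f in t1.coords[20:]])
    assert (rg / rg_nat).mean() == pytest.approx(1.14, abs=0.02)


def test_zero_final_disorder_keeps_plateau_statistics(toy):
    top, native, seg = toy
    sc = u.UnfoldingScenario(native_frames=20, exit_frame=20, plateau_frames=60,
                             disorder_frames=60, final_disorder=0.0,
                             frame_interval=0.1, seed=4)
    traj, truth = u.make_unfolding_trajectory(native, top, sc, seg)
    rg = np.array([u.radius_of_gyration(f) for f in traj.calpha_coords()])
    ratio = rg / truth["rg_native"]
    plateau, tail = ratio[20:80], ratio[80:]
    assert tail.mean() == pytest.approx(plateau.mean(), abs=0.02)
    defn = u.ContactDefinition()
    nset = u.native_contacts(native, top, defn)
    s = u.contact_timeseries(traj, nset, defn, native_frame=native)
    assert s.Q[80:].mean() == pytest.approx(s.Q[20:80].mean(), abs=2.0)


def test_scenario_validation():
    with pytest.raises(ValueError):
        u.UnfoldingScenario(expansion_factor=0.9)
    with pytest.raises(ValueError):
        u.UnfoldingScenario(native_frames=10, exit_frame=12)
    with pytest.raises(ValueError):
        u.UnfoldingScenario(final_disorder=1.5)


# ---------------------------------------------------------------------------
# phi ensembles
# ---------------------------------------------------------------------------


def test_phi_ensembles_realize_requested_shifts(unfolding_fixture):
    traj, truth, native = unfolding_fixture
    defn = u.ContactDefinition()
    nset = u.native_contacts(native, traj.topology, defn)
    ca = traj.calpha_coords()
    wt = {"F": ca[:40], "TS": ca[60:120]}
    shifts = {"mA": {"TS": -4.0, "F": -9.0}, "mB": {"TS": 0.0, "F": -6.5}}
    mut = u.make_phi_ensembles(wt, shifts, nset, defn.cutoff, seed=2)
    for mid, req in shifts.items():
        for ens in ("TS", "F"):
            realized = np.mean([_frame_native_count(f, nset, defn.cutoff)
                                for f in mut[mid][ens]])
            base = np.mean([_frame_native_count(f, nset, defn.cutoff)
                            for f in wt[ens]])
            assert realized - base == pytest.approx(req[ens], abs=0.5)
    # zero shift leaves frames untouched
    assert np.array_equal(mut["mB"]["TS"], wt["TS"])


def test_phi_ensembles_unachievable_shift(unfolding_fixture):
    traj, truth, native = unfolding_fixture
    defn = u.ContactDefinition()
    nset = u.native_contacts(native, traj.topology, defn)
    wt = {"F": traj.calpha_coords()[:5], "TS": traj.calpha_coords()[60:65]}
    with pytest.raises(ValueError):
        u.make_phi_ensembles(wt, {"m": {"TS": 0.0, "F": -(len(nset) + 10.0)}},
                             nset, defn.cutoff, seed=0)
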