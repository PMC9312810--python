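import numpy as np
import pytest
from hypothesis import given, strategies as st

import unfoldscape as u
from unfoldscape.landscape import GAS_CONSTANT_KCAL

RT498 = GAS_CONSTANT_KCAL * 498.0


# ---------------------------------------------------------------------------
# population grid
# ---------------------------------------------------------------------------


def test_grid_identical_points():
    pts = np.tile([[0.3, 0.7]], (4, 1))
    grid = u.population_grid(pts, n_bins=2, bounds=((0, 1), (0, 1)))
    assert grid.counts.sum() == 4
    assert grid.counts.max() == 4
    assert (grid.counts > 0).sum() == 1


def test_grid_bin_centers():
    centers = np.array([[0.25, 0.25], [0.25, 0.75], [0.75, 0.25], [0.75, 0.75]])
    grid = u.population_grid(centers, n_bins=2, bounds=((0, 1), (0, 1)))
    assert np.all(grid.counts == 1)


def test_grid_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 1, (10_000, 2))
    bounds = ((0.0, 1.0), (0.0, 1.0))
    grid = u.population_grid(pts, n_bins=10, bounds=bounds)
    # brute-force loop oracle with the same convention: half-open bins,
    # closed global top edge
    oracle = np.zeros((10, 10), dtype=int)
    for x, y in pts:
        i = min(int(x * 10), 9) if x < 1.0 else 9
        j = min(int(y * 10), 9) if y < 1.0 else 9
        oracle[i, j] += 1
    assert np.array_equal(grid.counts, oracle)
    assert grid.counts.sum() == len(pts)


def test_grid_edge_rules():
    # interior upper edge goes to the higher bin; global max edge stays in
    pts = np.array([[0.5, 0.1], [1.0, 0.1]])
    grid = u.population_grid(pts, n_bins=2, bounds=((0, 1), (0, 1)))
    assert grid.counts[1, 0] == 2


def test_grid_errors():
    with pytest.raises(ValueError, match="zero-extent"):
        u.population_grid(np.tile([[0.5, 0.3]], (3, 1)), n_bins=4)
    with pytest.raises(ValueError):
        u.population_grid(np.random.default_rng(0).random((5, 2)), n_bins=1)


def test_default_bounds_pad_by_one_bin():
    pts = np.array([[0.0, 0.0], [1.0, 2.0]])
    grid = u.population_grid(pts, n_bins=4)
    assert grid.bounds[0] == pytest.approx((-0.25, 1.25))
    assert grid.bounds[1] == pytest.approx((-0.5, 2.5))


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------


def test_free_energy_uniform_counts_all_zero():
    grid = u.LandscapeGrid(((0, 1), (0, 1)), (3, 3), np.full((3, 3), 7))
    fe = u.free_energy(grid, 498.0)
    assert fe.deltaF == pytest.approx(0.0)


def test_free_energy_analytic_values():
    counts = np.array([[4, 2], [1, 0]])
    fe = u.free_energy(u.LandscapeGrid(((0, 1), (0, 1)), (2, 2), counts), 498.0)
    assert fe.RT == pytest.approx(0.9896, abs=2e-4)
    assert fe.deltaF[0, 0] == 0.0
    assert fe.deltaF[0, 1] == pytest.approx(fe.RT * np.log(2))
    assert fe.deltaF[1, 0] == pytest.approx(fe.RT * np.log(4))
    assert np.isinf(fe.deltaF[1, 1])


def test_free_energy_p0_over_e_gives_rt():
    counts = np.zeros((2, 2), dtype=float)
    counts[0, 0] = np.e * 1e6
    counts[0, 1] = 1e6
    fe = u.free_energy(u.LandscapeGrid(((0, 1), (0, 1)), (2, 2), counts), 300.0)
    assert fe.deltaF[0, 1] == pytest.approx(fe.RT, rel=1e-9)


@given(st.integers(0, 2 ** 31 - 1), st.floats(0.5, 4.0))
def test_free_energy_formula_and_temperature_scaling(seed, alpha):
    """DeltaF = -RT ln(P/P0) bin for bin; scaling T by alpha scales every
    DeltaF by exactly alpha."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 50, (6, 5))
    counts.flat[rng.integers(0, counts.size)] = 50  # ensure occupancy
    grid = u.LandscapeGrid(((0, 1), (0, 1)), (6, 5), counts)
    fe = u.free_energy(grid, 498.0)
    occ = counts > 0
    expected = -fe.RT * np.log(counts[occ] / counts.max())
    assert fe.deltaF[occ] == pytest.approx(np.maximum(expected, 0.0))
    assert fe.deltaF[occ].min() == 0.0
    fe2 = u.free_energy(grid, 498.0 * alpha)
    assert fe2.deltaF[occ] == pytest.approx(alpha * fe.deltaF[occ], rel=1e-12)
    assert np.array_equal(fe2.counts, fe.counts)


# ---------------------------------------------------------------------------
# reaction path
# ---------------------------------------------------------------------------


def _grid_from_potential(pot, n_bins=41, extent=2.0, temperature=498.0,
                         scale=1e6):
    """Counts proportional to exp(-V/RT) on a regular grid (exact Boltzmann
    populations, no sampling noise)."""
    RT = GAS_CONSTANT_KCAL * temperature
    xs = np.linspace(-extent, extent, n_bins)
    ys = np.linspace(-1.0, 1.0, 21)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    counts = np.round(scale * np.exp(-pot.energy(X, Y) / RT)).astype(int)
    grid = u.LandscapeGrid(((-extent, extent), (-1, 1)), (n_bins, 21), counts)
    return u.free_energy(grid, temperature)


def minimax_oracle(grid, start, end):
    """Independent lowest-saddle oracle via networkx bottleneck search."""
    import networkx as nx

    dF = grid.deltaF
    G = nx.Graph()
    occ = [tuple(b) for b in np.argwhere(np.isfinite(dF))]
    for b in occ:
        for nb in [(b[0] + dx, b[1] + dy) for dx in (-1, 0, 1)
                   for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]:
            if 0 <= nb[0] < dF.shape[0] and 0 <= nb[1] < dF.shape[1] and \
                    np.isfinite(dF[nb]):
                G.add_edge(b, nb, weight=max(dF[b], dF[nb]))
    # bottleneck shortest path: Dijkstra with max-cost accumulation
    import heapq
    best = {start: dF[start]}
    heap = [(dF[start], start)]
    while heap:
        cost, cur = heapq.heappop(heap)
        if cur == end:
            return cost
        if cost > best.get(cur, np.inf):
            continue
        for nb in G.neighbors(cur):
            cand = max(cost, dF[nb])
            if cand < best.get(nb, np.inf):
                best[nb] = cand
                heapq.heappush(heap, (cand, nb))
    raise AssertionError("oracle found no path")


def test_single_bin_path():
    counts = np.ones((4, 4), dtype=int)
    fe = u.free_energy(u.LandscapeGrid(((0, 1), (0, 1)), (4, 4), counts), 300.0)
    p = u.extract_reaction_path(fe, start_bin=(1, 1), end_bin=(1, 1))
    assert p.bin_sequence == [(1, 1)]
    assert p.deltaF_activation == 0.0


def test_double_well_barrier_and_oracle():
    """Analytic double well with h = 3.0 kcal/mol: the recovered barrier
    matches the saddle height and the minimax-path oracle."""
    pot = u.PotentialSpec("double_well", {"h": 3.0, "a": 1.0, "kappa_y": 3.0})
    fe = _grid_from_potential(pot)
    start = u.modal_bin(fe)
    mask = np.zeros(fe.counts.shape, bool)
    mask[fe.counts.shape[0] // 2:, :] = True
    end = u.modal_bin(fe, region_mask=mask)
    if end == start:  # modal bin was already on the right: flip regions
        mask = ~mask
        end = u.modal_bin(fe, region_mask=mask)
    p = u.extract_reaction_path(fe, start_bin=start, end_bin=end)
    assert 2.9 <= p.deltaF_activation <= 3.1
    oracle = minimax_oracle(fe, start, end)
    # agreement within one bin's DeltaF discretization along the path
    finite = fe.deltaF[np.isfinite(fe.deltaF)]
    bin_disc = np.abs(np.diff(p.profile)).max()
    assert abs(p.profile.max() - oracle) <= bin_disc + 1e-9


def test_channel_profile_has_flat_top():
    RT = RT498
    pot = u.PotentialSpec("channel", {"h": 3.0, "a": 1.0, "kappa_y": 3.0,
                                      "L": 2.0})
    fe = _grid_from_potential(pot, n_bins=61, extent=3.0)
    start = u.modal_bin(fe)
    # end: modal bin of the well on the opposite side of the plateau
    xc = np.array([fe.bin_center((i, 0))[0] for i in range(fe.n_bins[0])])
    start_x = fe.bin_center(start)[0]
    mask = np.zeros(fe.counts.shape, bool)
    mask[xc > 1.5 if start_x < 0 else xc < -1.5, :] = True
    end = u.modal_bin(fe, region_mask=mask)
    p = u.extract_reaction_path(fe, start_bin=start, end_bin=end)
    top = p.profile.max()
    near = p.profile >= top - RT / 2
    # the plateau spans L = 2.0 of x at bin width 0.1: the longest
    # consecutive run of near-top points must cover it
    best = cur = 0
    for flag in near:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    assert best >= 2.0 / 0.1  # L / bin_width


def test_disconnected_end_raises():
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 0] = 10
    counts[4, 4] = 5
    fe = u.free_energy(u.LandscapeGrid(((0, 1), (0, 1)), (5, 5), counts), 300.0)
    with pytest.raises(ValueError, match="disconnected"):
        u.extract_reaction_path(fe, start_bin=(0, 0), end_bin=(4, 4))


# ---------------------------------------------------------------------------
# barrier statistics
# ---------------------------------------------------------------------------


def _path_from_profile(profile, RT=1.0):
    arc = np.arange(len(profile), dtype=float)
    bins = [(i, 0) for i in range(len(profile))]
    return u.ReactionPath(bins, arc, np.asarray(profile, dtype=float), RT)


def test_barrier_stats_simple_peak():
    dF, ci, inter = u.barrier_stats(_path_from_profile([0, 3, 1]), 1.0)
    assert dF == 3.0
    assert not any(i["stable"] for i in inter)


def test_barrier_stats_shallow_intermediate():
    p = _path_from_profile([0, 3, 2.8, 3.0, 0.5], RT=1.0)
    dF, ci, inter = u.barrier_stats(p, stability_threshold=1.0)
    assert dF == 3.0
    assert len(inter) == 1
    assert inter[0]["well_depth"] == pytest.approx(0.2)
    assert not inter[0]["stable"]
    # points with DeltaF >= 3 - RT: indices 1,2,3 of 5 (arc-weighted)
    assert ci == pytest.approx(3.0 / 4.0)
    # a deep well IS stable at a smaller threshold
    _, _, inter2 = u.barrier_stats(p, stability_threshold=0.1)
    assert inter2[0]["stable"]


def test_channel_index_discriminates_plateau_from_peak():
    n = 41
    x = np.linspace(-2, 2, n)
    peak = 3.0 * np.exp(-x ** 2 / (2 * 0.1 ** 2))
    plateau = np.where(np.abs(x) < 1.0, 3.0, 0.0)
    _, ci_peak, _ = u.barrier_stats(_path_from_profile(peak, RT=1.0))
    _, ci_plateau, _ = u.barrier_stats(_path_from_profile(plateau, RT=1.0))
    assert ci_plateau > 3 * ci_peak


# ---------------------------------------------------------------------------
# TST rate
# ---------------------------------------------------------------------------


def test_tst_rate_values():
    assert u.tst_rate(0.0, 498.0).k_u == pytest.approx(1e6)
    RT = RT498
    assert u.tst_rate(RT, 498.0).k_u == pytest.approx(1e6 / np.e, rel=1e-12)
    r = u.tst_rate(3.8, 498.0)
    assert r.k_u == pytest.approx(1e6 * np.exp(-3.8 / RT), rel=1e-12)
    assert r.prefactor == 1e6
    with pytest.raises(ValueError):
        u.tst_rate(-1.0, 300.0)
    with pytest.raises(ValueError):
        u.tst_rate(1.0, -5.0)


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------


def test_smoothing_is_display_only_and_conserves_mass():
    from unfoldscape.landscape import smooth_counts

    rng = np.random.default_rng(0)
    counts = rng.integers(0, 40, (12, 12))
    grid = u.LandscapeGrid(((0, 1), (0, 1)), (12, 12), counts)
    sm = smooth_counts(grid, sigma_bins=1.0)
    assert sm.counts.sum() == pytest.approx(counts.sum(), rel=1e-6)
    assert not np.array_equal(sm.counts, counts)
    # the raw grid is untouched
    assert np.array_equal(grid.counts, counts)
    with pytest.raises(ValueError):
        smooth_counts(grid, sigma_bins=0.0)


def test_grid_conservation_on_fixture(embedded_fixture):
    _, _, steps = embedded_fixture
    grid = u.population_grid(steps.terminals, n_bins=30)
    assert grid.counts.sum() == steps.terminals.shape[0]
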