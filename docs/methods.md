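# Methods

This note documents the models, numerical choices and limitations of
`unfoldscape`. Units throughout: Å for coordinates, ns for time,
kcal/mol for energies, K for temperature; `R = 1.9872×10⁻³ kcal/(mol·K)`.

## RMSD-space representation

Every frame pair is optimally superposed on the Cα selection (Kabsch:
SVD of the cross-covariance, determinant-corrected so reflections are
excluded) and the resulting T×T distance matrix is reduced by classical
(Torgerson) MDS: double-centre the squared distances, eigendecompose,
keep the top *k* axes scaled by √λ. Optimal-superposition RMSD is a
metric, and the matrices are near- but not exactly Euclidean: negative
eigenvalues are clamped out of the embedding and logged with their
magnitude fraction; `explained_fraction` is the retained share of the
*positive* spectrum only. Default *k* = 3 — a 2D projection of a 3D RMSD
space is the conventional display — and the single-pair RMSD is computed
from the explicitly rotated coordinates rather than the trace identity,
which loses half the significant digits to cancellation near zero.

The pairwise matrix is O(T²); the implementation batches the 3×3 SVDs
row-wise. Striding is available for long trajectories (the stride and
original frame indices are stored on the matrix).

## Native-exit detection

Step-vector norms inside a native reference window (default: the first
5% of frames, minimum 10) define a threshold `mean + c·SD` (c = 5) and a
native-cluster centroid and radius (radius = 1.5 × the window's largest
centroid distance). The exit is the first frame whose incoming step
exceeds the threshold *and* which stays outside the cluster radius for
m = 10 consecutive frames; ties resolve to the lowest index. The
persistence test is what separates a precipitous exit from a transient
excursion. Both c and the window are deliberately conservative: on the
synthetic trajectories the exit step is an order of magnitude above the
native noise floor, so detection is exact to the frame, and stationary
native-only controls produce no false exits. The detection is invariant
under rigid rotation of the embedding and uniform time rescaling.

## Statistical free-energy landscape

Step-vector terminals of **all** frames are binned on a regular grid
(default 50×50 on the first two embedding axes; bounds = data extent
padded by one bin; half-open bins with the global top edge closed) and
converted to `ΔF = -RT ln(P/P₀)` with P₀ the modal count, so the modal
bin sits at exactly 0 and empty bins are +∞ (impassable; for display
they are capped at the maximum occupied ΔF + RT). No smoothing is
applied by default — an optional Gaussian smoother exists for display
only, and all quantitative checks run unsmoothed. Modal-bin ties break
to the lowest linear index. Scaling T by α scales every ΔF by exactly α.

## Reaction coordinate, barrier, channel index

The unfolding path starts at the landscape's dominant modal bin and runs
to the farthest occupied bin reachable through occupied 8-connected
neighbours. At each step the walker takes the finite-ΔF neighbour of
least free energy among those strictly closer (Chebyshev) to the end —
the discrete steepest feasible direction, perpendicular to isoenergy
contours on a smooth surface — with lateral moves permitted when no
closer neighbour is occupied. If the monotone walk dead-ends on a
raggedly sampled landscape it falls back to the lowest-saddle (minimax)
route, found by Dijkstra on accumulated maximum ΔF with path length as
tie-break. An explicitly requested end bin disconnected from the start
raises an error naming the blocking region.

Two robustness choices matter on single-trajectory landscapes:

- **Dominant component anchoring.** A precipitous native exit can leave
  the briefly sampled native cluster disconnected from the rest of the
  landscape (the jump crosses unsampled space). The pipeline therefore
  anchors the path in the connected occupied region holding the most
  counts, otherwise the "path" would be confined to a one- or two-bin
  native island.
- **Default end bin** is the farthest bin *within that component*, a
  rule exposed in configuration since no canonical definition of the
  unfolded endpoint exists.

From the 1D profile: `ΔF‡ = max(profile) − profile[0]`; the **channel
index** is the fraction of the path's arc length whose ΔF lies within RT
of the barrier top (each point weighted by half its adjacent segment
lengths). A sharp peak gives a small index, a flat channel-like top a
large one; on matched analytic surfaces of equal barrier the flat-top
channel scores higher in every seeded replicate tested. Post-barrier
local minima are reported with well depth = min(adjacent maxima) −
minimum, stable iff the depth exceeds a threshold (default RT at the
analysis temperature — a well shallower than the thermal energy is not a
stable state; interior minima only, the final point is a boundary). The
TST rate is `k_u = ν·exp(-ΔF‡/RT)` with the protein prefactor
ν = 10⁶ s⁻¹. (Note that at T = 498 K a 3.8 kcal/mol barrier gives
k_u ≈ 2.1×10⁴ s⁻¹; the formula is implemented exactly as stated and no
attempt is made to rescale it to published rate constants obtained under
other conventions.)

**Caveat — sparse landscapes.** On a grid populated by a single
trajectory, bin counts are small and Poisson fluctuations of order
`RT·ln(n±√n)` create spurious wells deeper than RT along the profile.
Barrier heights, channel indices and the intermediate test are
quantitative on densely sampled landscapes (the 10⁶-step Brownian
recoveries, or replicate-aggregated trajectories); on a single synthetic
trajectory they should be read as descriptive statistics. The replicate
runner exists precisely to average these quantities over independently
seeded runs, and its barrier spread drops below 2% of the mean at the
default (2000-frame) sampling density.

## Contacts, secondary structure, molten-globule demarcation

Contacts are Cα–Cα pairs within 8.0 Å at sequence separation |i−j| ≥ 3
(the criterion is configuration; a Cα scheme matches the Cα-level
resolution of the whole pipeline and the toy model). Q counts native-set
pairs currently formed; `total` counts all pairs within cutoff. Rg is
mass-weighted.

Secondary structure is assigned from Cα pseudo-geometry alone (the toy
systems have no backbone N/O): a residue is **H** inside a run where the
i→i+3 distance falls in 4.8–5.6 Å *and* i→i+4 in 5.8–6.6 Å — the windows
of an ideal α-helix (rise 1.5 Å, radius 2.3 Å, 100°/residue) — with at
least two consecutive window hits required, because an isolated hit can
be mimicked by hairpin-turn geometry (so the shortest detectable helix
is 6 residues). A residue is **E** if locally extended (i→i+2 ≥ 6.4 Å
over a 3-residue run) *and* paired with a nonlocal (|i−j| ≥ 4) extended
partner within 5.5 Å over ≥ 3 consecutive residues; everything else,
including terminals that cannot satisfy the windows, is **C**. H takes
precedence over E.

Frame classes: **native** iff q-fraction ≥ 0.8 and Rg/Rg_native < 1.05;
**molten globule** iff frame-level secondary-structure persistence
(fraction of natively structured residues keeping their label — coil
staying coil carries no signal) ≥ 0.6, Rg ratio ≥ 1.05, and q-fraction
≥ 0.3; otherwise **unfolded**. These thresholds encode the molten-globule
definition — native-like secondary structure without native packing —
and are configuration; all quantitative tests compare against generator
ground truth, not against the absolute thresholds. The transition-state
ensemble runs from the native-exit frame to the end of the last
contiguous molten-globule run, merging runs separated by ≤ 10 frames
(frame-level class flicker should not split one physical region); an
empty ensemble is returned with a warning if no molten-globule frames
follow the exit.

## φ-values

`φ = (⟨Q⟩_TS,mut − ⟨Q⟩_TS,wt)/(⟨Q⟩_F,mut − ⟨Q⟩_F,wt)`, computed over the
full native contact set of the wild type by default (a residue-local
variant is a flag away; mutants are represented operationally as
alternative trajectories against the wild-type native set). A
denominator below ε = 0.5 contacts — under the resolution of a single
contact — flags the value as undefined rather than raising, so batch
runs always complete; φ outside [0, 1] is flagged, never clipped.
Swapping mutant and wild type negates numerator and denominator and
leaves φ unchanged. The transition-state ensemble fed to φ is exactly
the demarcated molten-globule ensemble above.

## Synthetic generators

All generators own a single seeded `numpy.random.Generator`; everything
is bit-reproducible from (seed, parameters).

**Brownian sampler.** Euler–Maruyama on the overdamped Langevin
equation, `x ← x − (dt/γ)∇V + √(2kT·dt/γ)·ξ`, with a numba-compiled
inner loop (the update is inherently sequential). Surfaces: harmonic
(κ/2·r²), double well `h((x/a)²−1)² + κ_y/2·y²` (barrier exactly h at
x = 0), and a **channel** variant whose barrier top is replaced by a
flat plateau of length L at V = h (minima at |x| = L/2 + a) — the
controllable analogue of an extended, malleable transition state, with
analytically flat ground truth for the channel index. Defaults
kT = 0.9896 kcal/mol (RT at 498 K), γ = 1, dt = 0.005–0.01. The
discretization bias of Euler–Maruyama is O(dt): at dt = 0.01 the
barrier-region occupancy of the 3 kT double well is overweighted by
~15%, at dt = 0.002 by ~4%; quantitative occupancy comparisons use the
smaller step. Divergence (|coord| > 10⁶) raises an error naming dt.

**Toy protein.** Cα-only, ≥ 20 residues: an ideal α-helix, a 2-residue
loop, and an antiparallel β-hairpin (strand spacing 3.8 Å, inter-strand
4.8 Å, out-of-plane 2-residue turn) packed 6–8 Å from the helix so
helix–sheet native contacts exist. All consecutive Cα distances fall in
3.5–4.0 Å; segment index ranges are returned as ground-truth labels.

**Unfolding trajectories.** Three planted phases. *Native*: native
coordinates + Gaussian noise (σ = 0.15 Å). *Plateau*: two rigid units
(helix+loop, hairpin) are wobbled (~3°) and their centroids scaled apart
so that each frame's Rg/Rg_native equals the target expansion exactly
(the quadratic in the centroid-scaling factor is solved per frame;
±0.5% frame-to-frame jitter), preserving intra-unit geometry and hence
secondary structure. *Disorder*: morph toward a self-avoiding random
coil with a √t schedule to `final_disorder` — the √ schedule makes the
molten-globule → unfolded boundary sharp at the analysis resolution,
keeping the demarcation test well-posed. Mean native contacts decay
monotonically through the phase. The defaults emulate a 100 ns run
saved every 0.05 ns (2000 frames) with exit at 1.2 ns, plateau to 35 ns
and a 14% Rg expansion; scaled-down variants (300–1000 frames) are used
where many replicates are needed. The plateau's *contact retention* is
determined by the expansion geometry (inter-unit contacts break,
intra-unit ones survive), so the generator measures it at build time
with its own inline pair counting and records it in the ground-truth
sidecar instead of exposing a dial.

**φ ensembles.** Mutant frame sets are wild-type frames whose
native-contact count is moved to a per-frame integer target (the targets
average to the requested ensemble-mean shift) by displacing one partner
of a formed contact radially past the cutoff (or back inside, to
re-form); side effects on neighbouring contacts are handled by greedy
recomputation with seeded retries, and realized means land within ±0.5
contacts of the request or the construction errors out.

## What the synthetic data does and does not show

The generators reproduce the *phenomenology* the analysis is built to
detect — a tight native cluster, one precipitous exit, an expanded
plateau with intact secondary structure, monotone disordering — with
exact knowledge of every planted parameter. They are not molecular
mechanics: there is no force field, no solvent, no realistic kinetics,
and the plateau's rigid-unit expansion is a geometric idealization of a
molten globule. Passing tests therefore demonstrate that the analysis
chain recovers known structure from data of the assumed shape, not that
it would resolve these features in any particular real protein's MD.

## Other numerical choices

- Kabsch requires ≥ 3 non-collinear atoms; collinear or coincident
  selections raise (the rotation is underdetermined).
- A distance matrix that is exactly zero embeds at the origin; a matrix
  with no positive double-centred eigenvalues otherwise raises.
- Grid bins are half-open with the closed global top edge, so boundary
  points assign to the higher bin except at the extreme edge.
- Replicate seeds are spawned from the base seed via
  `numpy.random.SeedSequence` (deterministic, independent streams).
- PDB round-trips are exact to format precision (10⁻³ Å); DCD is
  float32; XTC compresses to 10⁻³ nm.
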