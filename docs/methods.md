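# Methods

## Model class

A biochemical model is a set of species, each with a diffusion coefficient
`D` (μm²/s; 0 = immobile), and mass-action reactions of order 1 or 2 with
rate constants in s⁻¹ (order 1) or (μM·s)⁻¹ (order 2). Geometry is an
unstructured tetrahedral mesh (μm scale). State is an integer molecule count
per (tet, species); each tet is treated as well mixed. Orders above 2 are
rejected loudly rather than silently mis-scaled; the unit bridge is fixed at
602.214076 molecules per μM·μm³ (exact, from the CODATA Avogadro constant).

The packaged benchmark model has ten diffusive species A–J with
D = 100, 90, …, 10 μm²/s, whole-mesh initial totals 1000, 2000, …, 10000
(55,000 molecules), and four reversible reactions A+B⇄C (kf 1000 (μM·s)⁻¹,
kb 100 s⁻¹), C+D⇄E (100, 10), F+G⇄H (10, 1), H+I⇄J (1, 1), stored as eight
irreversible records. Initial molecules are placed uniformly: each molecule
lands in a tet with probability proportional to its volume (a multinomial
draw from the run's seed). `make_benchmark(density_scale)` scales every
initial count (0.1× and 10× are the low/high molecule-density settings).

## Spatial discretization

The per-face hop rate of species S from tet i through interior face k is
`d_k = D·A_k/(h_k·V_i)` with `A_k` the shared-face area, `h_k` the distance
between the two tets' barycenters, and `V_i` the source volume; the local
rate is `d_S,tet = Σ_k d_k`. This is the standard finite-volume two-point
flux discretization of isotropic diffusion on a tet mesh; it is exact for
uniform meshes and first-order accurate on distorted ones. Generated cuboid
meshes split each grid cell into 6 tets (Kuhn subdivision, common main
diagonal), which is conforming across cells — a requirement for the
face-neighbor hop structure. Mesh connectivity is always rebuilt from the
tet list on load, never trusted from a file. Tets with volume below
1e-12 μm³ are rejected as degenerate (far below any realistic tet at μm
scale).

## Exact solver

All kinetic events — one instance per (tet, reaction) plus one per
(tet, diffusive species) — form a single continuous-time Markov jump
process. A diffusion instance carries the total propensity `d_S,tet·n` and
draws its destination face with probability `d_k/d_S,tet` at firing time;
this is distributionally identical to one event per face with fewer
propensity entries to maintain.

Selection routines, all sampling the same law:

* **Direct** (`direct_step`): linear cumulative table, O(N) selection. If the
  selection point falls beyond the table by more than ~16 ulp of a₀ an
  internal-consistency error is raised (drift between a₀ and the table).
* **Composition–rejection** (`cr_step`): events binned by propensity into
  power-of-two groups [2^(g−1), 2^g); a group is chosen proportionally to
  its sum, then uniform-choice/rejection inside the group. Events below a
  configurable floor (default 1e-12 s⁻¹) leave the structure entirely.
  Membership migrates at most once per propensity update.
* **Compiled tree** (`run_exact`, default): a Fenwick (binary-indexed) tree
  over the propensity array gives O(log N) selection and update inside a
  numba kernel; this is still the Direct method's distribution, only with an
  efficient running cumulative sum. NumPy `Generator` objects are passed
  into the kernel, so Python-side and kernel-side draws share one seeded
  stream. The kernel re-verifies the chosen event's propensity from counts
  and skips events that float drift has left dead, keeping counts
  nonnegative unconditionally.

Zero total propensity advances time to the run horizon (depleted-system
semantics, not an error). Dependency lists (`build_event_deps`) give, per
event, the events whose propensity reads any count it changes; for diffusion
instances the stored list conservatively covers the source tet and all face
neighbors, since the destination is drawn at firing time
(`diffusion_event_closure` gives the exact two-tet closure once the
destination is known).

## Operator-splitting solver

The run [0, t_end] is divided into windows of the constant diffusion time
window `τ = min 1/d_S,tet` over all diffusive (S, tet) with positive rate —
computed once at initialization, never updated (it depends only on model and
geometry, not on molecule counts). Finer meshes therefore mean both faster
local rates and more main-loop iterations. If no species diffuses anywhere
the configuration is rejected with a pointer to the pure-reaction exact
path.

Each window:

1. **Reaction SSA operator** — exact SSA restricted to reaction events, for
   the window. On every count change of a diffusive species the occupancy
   integral of that (tet, species) accrues (old count)·(elapsed); at the
   window end integrals are closed at the boundary. Mean occupancy over the
   window is thus exact for piecewise-constant counts, and products created
   mid-window accrue from their creation time.
2. **Diffusion operator** — per (tet, diffusive species), expected leavers
   `μ = mean-occupancy · d_S,tet · w` (w = window length), clamped to the
   current count; the integer draw is ⌊μ⌋ + Bernoulli(frac μ) (stochastic
   rounding — preserves the mean exactly while keeping integer counts).
   Leavers split among face neighbors jointly multinomially with weights
   `d_k/d_S,tet`, implemented as a chain of conditional binomials (exactly
   equivalent, and vectorizable across tets). This leaver rule is the single
   most consequential fidelity decision in the package: it preserves the
   mean-occupancy semantics of the window scheme with exact integer
   conservation.

A final partial window of length t_end − t is allowed; μ scales linearly
with the shortened window. The same rule lets a recording time split a
window so samples land exactly on the recording grid (the iteration counter
counts τ-grid windows, so the ⌈t_end/τ⌉ iteration contract is unaffected).

**Known limitation (window at the stability limit).** For the (tet, species)
pair that attains the minimum, `d_S,tet·τ = 1`: in one window the expected
number of leavers equals the occupancy. In the degenerate case of two
identical tets and a single species this makes the scheme swap essentially
the whole population back and forth each window instead of mixing. In
realistic meshes the binding pair is one tet among many and all other pairs
have `d·τ < 1`, so the effect is confined; the two-tet detailed-balance test
uses a faster pace-setter species for exactly this reason.

## Partition-parallel protocol

A partition maps each tet to one rank (linear barycenter-grid partitioner
with lexicographic bin index, or a Metis-style `.epart` file; `.graph`
export provides mesh connectivity to external partitioners). Derived
structure: per-rank hosted lists, face-adjacent neighbor-rank sets
(symmetric), and boundary tets (hosted tets with a neighbor hosted
elsewhere). Empty bins warn but are legal.

Each rank runs the windowed solver on its hosted tets with an independent
RNG stream derived from (master seed, rank) via `SeedSequence.spawn`; child
streams depend only on the rank index, so rank 0 of any run and the serial
split solver share a stream, making the one-rank parallel loop bitwise
identical to the serial split run at equal seed.

Cross-rank state flows only through **remote change buffers**, one per
neighbor rank: an append-only vector of integer triples (destination tet,
species, accumulated change) with a location marker per (tet, species).
Registration compares the marked entry's key; a match accumulates in place,
a mismatch (first use, or a marker gone stale across a flush) appends a
fresh entry and updates the marker — both amortized O(1). Buffer size is
bounded by (#remotely-hosted neighbor tets × #diffusive species), asserted
at every flush; the lower bound is an empty buffer when no cross-rank hop
occurred. Each rank sends exactly one (possibly empty) buffer to each
neighbor per window — the completion condition that replaces global
barriers — and applies received changes through per-(boundary tet, species)
dependency lists before the next window. Hosted reaction propensities are
refreshed from counts at each window start, which subsumes the deps-driven
refresh; the dependency tables remain the protocol surface and are verified
against the serial closure in the tests.

The in-process virtual-rank scheduler executes rank phases round-robin and
is fully deterministic; it is the canonical test target. Timing is
attributed per rank with a monotonic clock: T_comp (reaction SSA + local
diffusion), T_sync (receiving/applying buffers), T_idle (waiting — ~0
in-process, reported honestly), with T_total = T_comp + T_sync + T_idle.
Speedup S_p/q = T_q/T_p, efficiency E_p/q = S_p/q·q/p and weak-scaling
E_k = T_N,p/T_kN,kp are reporting features over these timers;
wall-clock-derived numbers are hardware-dependent and are not correctness
surfaces.

## Validation strategy and what it shows

The window approximation introduces small, controlled errors by design, so
cross-solver agreement is judged statistically while conservation laws are
checked exactly:

* **Exact checks** — per-species global totals under pure diffusion at every
  window boundary for 1–8 ranks; cross-rank sent = applied, every window;
  buffer bounds; τ versus an exhaustive brute-force scan; deps-maintained
  propensity tables versus full recomputation after every event.
* **Analytic oracles** — free-diffusion MSD versus 6Dt (10⁴ molecules, fine
  mesh, t chosen so the cloud spans many tets but stays far from the
  boundary; tolerance 5% covers the O(h²) barycenter-to-barycenter bias);
  single-event waiting times versus the exponential law; single-voxel
  binding equilibrium versus the exact CME transient (matrix exponential of
  the birth–death generator).
* **Statistical cross-solver checks** — split versus exact on the benchmark
  model (100 seeds, t_end = 1 s, 60-tet reduction of the 10×10×100 μm³
  box at full 55,000-molecule density): overlapping 95% CIs of per-species
  means plus per-(species, time) two-sample KS with Benjamini–Hochberg
  correction across the grid at level 0.01 (raw per-cell thresholds over
  dozens of true-null cells would false-alarm by construction; BH is the
  harness-wide multiplicity rule). The same instrument compares 2/4/8-rank
  runs against 1-rank.

The synthetic benchmark emulates a spatially homogeneous reaction–diffusion
system with uniform initial placement and near-uniform tet sizes. Passing
these tests shows the solvers agree in that regime; they do not probe strong
concentration gradients, highly distorted tets, or load imbalance, where the
window scheme's accuracy and the partitioning's efficiency degrade in ways
the timing reports (not the correctness tests) would surface.

## Problem sizes and numerical choices

Test and acceptance problem sizes are chosen for desk-scale determinism: the
7,500-tet (5,5,50) mesh exercises τ and partitioning; dynamical comparisons
use a 60-tet coarsening of the same box so that hundreds of seeded runs are
cheap while keeping full molecule density. Fenwick-tree float drift is
bounded by rebuilding the tree per run segment and re-verifying selected
events against counts; cumulative-selection overflow beyond ~16 ulp of a₀
raises instead of wrapping. Multinomial splitting guards the last live face
(p snapped to 1 within 1e-12) so conditional binomials never strand a
leaver. Seeds are explicit everywhere; there is no global RNG state.
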