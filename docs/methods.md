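# Methods

`morphogrow` simulates the growth of a two-dimensional cell cluster whose
cells secrete diffusible chemicals that regulate each other's secretion and
the cells' own growth rate. This note records the model, the numerical
choices, and the limits of what the simulations show.

## Model

**Chemical fields.** Each chemical i is secreted at a rate μ̃ᵢ(c̃) that may
be gated by the local concentrations of other chemicals through steep Hill
functions H(c | K, n) = cⁿ/(Kⁿ + cⁿ), and may be scaled by a linear factor
max(1 + b̃·c̃_reg, 0) with b̃ ≤ 0. Because secretion, diffusion and
degradation are fast compared with growth, the concentration fields are at
steady state for the current cluster shape:

    ∇̃²c̃ᵢ + μ̃ᵢ(c̃) − γr,ᵢ·c̃ᵢ = 0,     c̃ᵢ → 0 far from the cluster.

All quantities are dimensionless: lengths are rescaled by the diffusion
length √(D/γ) of the reference chemical, concentrations by the relevant
growth threshold, and time by the maximal growth rate (g_max = 1). The
remaining parameters per chemical are the effective secretion rate μ̃, the
degradation ratio γr (1 for the reference chemical), the secretion
thresholds K̃s, and the Hill exponents.

**Growth.** The cell growth rate is g(c̃) = Π H(c̃ⱼ | K_eff,ⱼ, nⱼ) over the
growth links; a negative exponent makes chemical j a growth inhibitor, a
positive one an activator. A *threshold regulator* lowers another
regulator's effective threshold linearly, K_eff = K̃g·max(1 − Σ a·c̃_mod, 0);
the clamp at zero is ours (a negative threshold is meaningless — the
inhibitor then simply blocks growth wherever it is present at all).

**Tissue flow.** The cluster is an incompressible cellular fluid:
∇·u = g with u = −∇P and P = 0 on the boundary, so ∇²P = −g inside and the
boundary advances with u_n = −∂P/∂n. The spatial pattern of g alone decides
the shape: uniform growth circularizes any cluster, a tip-localized growth
zone extrudes a rod, a shrinking tip zone sharpens into a cone, and a
split growth zone can nucleate several protrusions.

**Hill exponents as thresholds.** |n| = 100 by default, so each Hill factor
is within 10⁻² of a 0/1 step whenever the concentration is more than 10%
away from its threshold; n = 0 means "does not participate" and evaluates
to exactly 1. Hill factors are evaluated in log space
(expit(n·(ln c − ln K))) to avoid overflow.

**Circuits.** Secretion dependencies must be feedforward (a DAG); each
chemical's source field is its secretion rate evaluated on the
already-solved upstream fields, in topological order. Every named scheme —
`none`, `single_inhibitor`, `two_inhibitors`, `threshold_regulator`,
`activator_s2`, `inhibitor_cascade(q)` — is feedforward. A fixed-point
iterator for cyclic circuits is a possible extension, not implemented.

For the growth-activator variant (`activator_s2`) we fix the conventions:
Y is secreted constitutively (rate μ̃Y, degradation γr), Y inhibits the
secretion of X below threshold 1, and growth requires the activator X
*above* its rescaled threshold 1 (Hill exponent +100).

## Numerics

**Boundary.** The cluster outline is an explicit marker polygon
(front tracking), counterclockwise, resampled every step to a target
spacing h (default 0.05) with a periodic cubic spline through the markers —
chordal interpolation would systematically erode area. Sharp corners
(the initial cluster's back face, post-cut faces) are rounded at the h/10
scale by the spline; this is visible as a ≲0.005 overshoot at the back
corners and is inconsequential to the front dynamics.

**Interior quadrature.** The interior is covered by grid cells of size
h_mesh (default 0.06); cells straddling the boundary are clipped exactly
with polygon intersections, so the weights sum to the polygon area to
machine-level accuracy. Connected components of the growth zone are counted
on the cell raster (8-connectivity), which a brute-force flood fill
reproduces exactly.

**Field solve.** Concentrations are kernel sums over the quadrature cells
with the free-space Green's function (1/2π)K₀(√γr·r) of the modified
Helmholtz operator — no outer box, the far-field decay is exact. The log
singularity is handled by replacing the kernel with its exact mean over the
cell's equivalent disk whenever the target falls inside it. Accuracy on the
uniform-source disk against the closed-form Bessel solution:
max relative error ≈ 0.04% at h_mesh = 0.05, ≈ 0.02% at 0.025.

**Velocity solve.** P splits into the Newtonian potential of the
disk-smeared growth sources plus a harmonic single-layer correction with
piecewise-constant density on the polygon panels. Potential and gradient of
each straight panel are integrated analytically; the system is augmented by
an additive constant (and a zero-total-charge row) so it remains solvable
at unit logarithmic capacity. The interior normal derivative comes from the
single-layer jump relation at the panel midpoints — no off-boundary probes,
which keeps highly curved tips accurate. Two details matter near the
boundary: source disks that would poke outside the polygon are translated
inward until they fit (leaked source mass would otherwise bias ∮u_n ds
low), and the whole solve runs on a spline-refined copy of the boundary
(panel length h/3) before restriction to the markers. Disk oracles:
u_n = R/2 within 0.3%, concentric-patch a²/(2R) within 0.1%;
∮u_n ds = ∫g dA within ≈0.3% per step in scenario runs.

**Time stepping.** dt = α·h/max u_n with α = 0.4, further capped so the
predicted curvature term of the swept area (∮κ u_n² ds/2 per unit time)
stays below 1.5% of the flux — this keeps the per-step area balance
|ΔA − dt·∫g dA|/ΔA under 2%. A step whose advected polygon self-intersects
is rejected and retried with dt halved (at most 10 times). Fields are fully
re-solved every step (quasi-static limit); nothing is inherited. The
growth-zone-vanished stop condition (A_gz < h_mesh²) arms only after the
zone has once exceeded 4·h_mesh², so that configurations whose initial zone
is thinner than a cell (e.g. μ̃X = 10) can still creep open through the
Hill tails and develop their rod.

**Mirror symmetry.** All study scenarios are symmetric under ỹ → −ỹ, but
the symmetric state is dynamically *unstable* once the growth zone splits:
the two side lobes compete through the inhibitor field, and marker-level
noise (<0.5%) is enough to let one side win and grow a single tilted rod.
The simulator therefore averages the curve with its mirror image every step
(`symmetrize`, on by default), holding the dynamics on the symmetric branch
that the underlying model's figures depict. Disable it to study the
symmetry-broken branch.

**Front-half mask.** Growth (not secretion) is zeroed behind the fixed
lab-frame plane x̃ = x̃0/2, reflecting the focus on protrusions growing from
the cluster tip; the back half only supplies inhibitor. The protrusion
counter ignores radial maxima behind this plane (the static back face's
corners would otherwise register as spurious peaks).

**Protrusion counting.** Protrusions are prominence-filtered local maxima
of the cyclic centroid-distance signal (default prominence ỹ0/2). The count
is resolution-stable for all shipped scenarios. Note that topographic
prominence of a *symmetric pair* of equal peaks assigns the shallow middle
saddle to one of the twins: a pair is counted as 2 only once the saddle
between the twins is deeper than the threshold, which is the intended
geometric reading.

## Study conditions and problem sizes

Scenario defaults are the model's printed parameter sets; runs are sized
for a desktop CPU: boundary spacing h = 0.05 and mesh h_mesh = 0.06
(h = 0.04, h_mesh = 0.03 for the threshold-regulator family, whose growth
zones are thin slivers), with horizons t_max between 1.2 (circularization)
and 40–60 (protrusion growth; the μ̃X = 10 rod needs ≈ 12 time units of
creep before its zone opens). At these sizes the full scenario suite runs
in a few minutes.

## Knife-edge regimes and known limitations

- **Two-inhibitor tip protrusion.** At the two-inhibitor parameters
  μ̃X = 8, μ̃Y0 = 65, K̃s = 1, γr = 1, the steady-state c̃Y at the cluster
  tip is 0.997 — within 0.3% of the growth threshold (verified both with
  the package's Green's-function solver and an independent finite-
  difference solve). Whether the stalled middle protrusion becomes a
  prominent third finger is decided by sub-percent details at this knife
  edge. In this implementation the center-depleted zone yields the
  symmetric side-protrusion pair plus a short stalled tip stub: the
  geometric protrusion count is 2, with the third (middle) finger below
  the prominence threshold.
- **Long-horizon rod stability.** Growth with P = 0 on the boundary is a
  Laplacian-growth problem, and advancing fronts are morphologically
  unstable at small scales. The single-inhibitor rod is chemically
  stabilized near its tip, but over long horizons (t ≳ 15 at μ̃X = 8, tip
  beyond x̃ ≈ 2.3) the simulated rod widens slowly, its tip flattens, and it
  splits into a symmetric pair — an outcome that persists under boundary and
  mesh refinement, i.e. a property of the continuum model as posed rather
  than a discretization artifact. The shipped rod scenarios use the t ≤ 12
  window, where the rod is clean (single protrusion, width variation ≈ 2%)
  and the tip chemical environment has reached its quasi-steady plateau.
- The generator of shapes is deterministic; there is no biological noise,
  no cell-level granularity, no mechanics beyond Darcy flow, and no
  topology changes (a cluster cannot merge with itself or fragment).
  Passing tests show the continuum circuit model behaves as described, not
  that real engineered tissues would.
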