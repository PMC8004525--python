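# Methods

## Model and assumptions

The community is modelled by three coupled logistic-with-predation ODEs for
fox (V), cottontail (S) and hare (L) densities (per km², time in years):

    dV/dt = V (r − c_VV V − m + e a S + e b L)
    dS/dt = S (s − c_SS S − n − a V)
    dL/dt = L (u − c_LL L − p − b V)

Assumptions, and why they are defensible here:

* **Separate reproduction and mortality** (`r, m` instead of a single
  logistic growth rate): the calibration uses field quantities for each, and
  a species whose mortality exceeds reproduction must be expressible
  (negative net rate ⇒ extinction), which a bare logistic `r` cannot do.
* **Bilinear (Holling type I) predation**: fox densities are ~1–2.5/km² and
  lagomorph densities a few tens per km², well inside the linear regime of a
  saturating response, so no satiation term is included — and none is
  offered as an option.
* **No direct prey–prey competition**: cottontails and hares use different
  macro- and microhabitats; their only interaction is fox-mediated. The
  Jacobian's (S, L) entries are identically zero.
* **Closed, spatially homogeneous community**: no immigration, seasonality,
  stochasticity or spatial structure.

Each right-hand side carries its own population as a factor, so the
extinction faces are forward-invariant, and the total density V + S + L is
eventually bounded (each logistic surplus is negative above its capacity and
predation transfers biomass with efficiency e ≤ 1); the package audits this
numerically (`boundedness_audit`) rather than symbolically.

## Equilibria and stability

There are exactly eight equilibrium candidates, one per subset of persisting
species (E0 extinction; E1/E2/E4 single-species; E3/E5/E6 two-species; E7
coexistence), all with rational closed forms. Feasibility of a candidate is
the nonnegativity of its closed-form populations; the package uses the
population **numerators** as feasibility margins (the denominators are
positive), which makes every margin a polynomial of degree ≤ 2 in any single
rate. Stability is the corresponding closed-form inequality column: for
E0–E2, E4, E6 the eigenvalues are explicit; for E3 and E5 the 2×2
Routh–Hurwitz block is automatically stable when feasible, leaving one
transverse condition (`u < p + b·V3`, resp. `s < n + a·V5`); a feasible E7
is unconditionally stable (its Routh–Hurwitz inequalities reduce to sums of
positive terms). Tests cross-validate every closed-form verdict against
numerically computed Jacobian eigenvalues on 1000 random parameter sets.

Two consequences shape the whole package:

* **Uniqueness of the attractor.** Away from bifurcation boundaries exactly
  one candidate is feasible-and-stable; `classify` returns it and treats
  "zero or several" as a boundary diagnosis, not a result.
* **Global stability.** A weighted Volterra function
  `Σ w_i (x_i − x_i* − x_i* ln(x_i/x_i*))` has derivative `Pᵀ A P` with an
  equilibrium-independent symmetric matrix A (diagonal `−w_V c_VV`,
  `−w_S c_SS`, `−w_L c_LL`; fox–prey off-diagonals `a(e w_V − w_S)/2` and
  `b(e w_V − w_L)/2`). The default weights `(1, e, e)` annihilate both
  off-diagonal entries, so A is manifestly negative definite for positive
  competition coefficients — this weight choice is the package's own, made
  because it renders definiteness unconditional; `lyapunov_matrix` exposes
  the minors for any other weights. Global stability is additionally
  checked behaviourally: 50 random parameter sets × 20 random positive
  starts all converge to the classified attractor.

**Margin sign convention.** Every inequality is reported as
positive-when-satisfied (for strict `x < y` conditions the margin is
`y − x`), so feasibility and stability share one convention and the
threshold solver can root-find on any margin directly. Exact zeros are
classified *unsatisfied*: boundary parameters belong to the bifurcation
machinery.

## Bifurcations

Cycles are impossible (the Lyapunov argument; equivalently no equilibrium
admits a purely imaginary eigenvalue pair at biologically meaningful rates),
and all third-order partials of the vector field vanish, so pitchforks are
excluded a priori; only transcritical exchanges (and in principle
saddle-nodes, never observed) can occur. Two equilibria can exchange
stability only if their species sets are nested and differ by one species —
the exchange graph is the face lattice of the cube on {V, S, L}.

`threshold_solve` exploits the algebra: the exchanged species' numerator in
the larger equilibrium is affine or quadratic in the swept rate, so the
critical value is obtained from exact 3-point polynomial interpolation and
cross-checked against bisection (agreement required to 1e−9; the margin is
also required to change sign over the bracket, which makes brackets
containing two quadratic roots — the re-entrant coexistence windows —
resolvable by the sweep's grid refinement). At the solved point, one
Jacobian eigenvalue of each equilibrium in the pair must sit within 1e−6 of
zero. The same locus is also the transverse stability margin of the smaller
equilibrium (e.g. `S7 = 0` ⇔ `s = n + a·V5`); tests verify this coincidence
of two independently coded margins to 1e−9 on 1000 random sets.

**Sotomayor classification.** At each point the left/right null eigenvectors
w, v of the Jacobian (unit norm, first nonzero component positive) feed the
three transversality scalars `w·F_μ`, `w·(DF_μ v)`, `w·D²F(v,v)`, built from
the analytic parameter-derivative arrays of the vector field. One subtlety:
when the vanishing species' equation does not contain the swept rate (e.g.
the coexistence/hare-extinction exchange swept in the cottontail hunting
rate a), `w·(DF_μ v)` is *identically zero* even though a genuine
transcritical exchange occurs — the critical eigenvalue crosses zero through
motion of the equilibrium branch, which the fixed-state scalar cannot see.
The classifier therefore also computes the crossing speed dλ/dμ of the
near-zero eigenvalue along the boundary-equilibrium branch (central finite
difference, step 1e−6 relative) and calls a point transcritical when
`w·F_μ = 0`, `w·D²F(v,v) ≠ 0`, and either scalar certifies a nonzero
crossing. All scalars are reported per point; the pitchfork quantity is
emitted as an exact 0.

**Sweeps.** `sweep` classifies the attractor on a uniform grid, records
unclassifiable grid points as boundary samples, localizes each label change
with `threshold_solve` on the bracketing cell, and reports the compressed
label chain. With the reference rates and b = 0.5, sweeping a over
[0.005, 0.6] yields the re-entrant chain E7 → E3 → E7 → E5 with thresholds
0.017867, 0.228724, 0.272305 (the two outer E7 windows are the two roots of
the quadratic hare-numerator margin). Threshold values are specific to this
package's calibration and are documented output, not calibration targets.

## Life-history calibration

Rates derive from three field quantities per species: mortality is the
reciprocal mean lifespan (fox 3.5 y, cottontail 1.25 y — the mean, not the
5-year maximum — hare 5.5 y); reproduction is ln of the one-year
multiplication factor (3, 4.5, 5), the exponential rate realizing that
factor; intraspecific competition is (reproduction − mortality)/capacity
with capacities 1 fox, 100 cottontails, 30 hares per km², so each
single-species equilibrium lands exactly on its capacity. Conversion
e = 0.91. Values are stored as floats evaluated from the exact expressions
(ln 3, 2/7, …); tests compare at five significant digits. The hunting rates
a and b are deliberately left unset by the reference builder — they are the
scenario knobs.

## Numerical choices

* **Integrator**: LSODA, rtol 1e−9, atol 1e−30. The extreme absolute
  tolerance is deliberate: transients can carry a population many orders of
  magnitude below one individual per km² and back (harsh predation followed
  by recovery of a weakly viable species), and a conventional atol would
  absorb the dip at zero, stranding the run on an unstable boundary
  equilibrium. Tracking the dip in relative terms preserves the
  global-stability behaviour; the cost is about a 2× slowdown. The
  extinction faces remain exactly invariant (a component at exactly zero
  has zero derivative). This also means that *numerical* "effective
  extinction" events are reported from a 1e−6/km² threshold sustained for
  10 years, not from exact zeros.
* **Negativity policy**: undershoot is clamped at 0 below 1e−9 magnitude;
  anything beyond 1e−6 raises (integrator misuse).
* **Convergence**: a run is settled when both the right-hand side and the
  drift from the terminal state stay below 1e−8 over the final 50-year
  window of a 500-year horizon; ensemble runs that miss this are retried at
  8× and 64× the horizon (jitters near the coexistence boundary have a
  near-zero slow eigenvalue) before being excluded and tallied.
* **Tie-breaks**: null eigenvectors are unit-normalized with the first
  nonzero component positive; bin edges are open-left/closed-right (an
  exactly-on-edge record joins the lower bin — a measure-zero choice under
  continuous jitter).
* **Degenerate inputs**: zero competition coefficients raise (closed forms
  undefined); zero net reproduction rates make the regime taxonomy a
  boundary case and raise; margins exactly zero fail classification rather
  than being rounded either way.

## The ensemble (synthetic-data stage)

The generator emulates a multi-site survey: 500 parameter sets drawn
independently and uniformly within ±9% of the reference rates (all twelve
jittered, including a = 0.2 and b = 0.5; a switch can freeze the hunting
rates instead, since either reading of "all parameters" is defensible), each
integrated from the common post-introduction state (V, S, L) = (0.4, 1, 3)
per km². A record's steady state is the closed-form attractor, cross-checked
against the integrated terminal state to 1e−5 — the dual route (algebra vs.
ODE) is itself a test. Records are binned by steady cottontail density into
(1,3], (3,5], …, (11,13], and within each bin ordinary least squares of
ln(hare density) on fox density is solved directly from the normal
equations (np.polyfit and a known-line parameter-recovery oracle serve as
test cross-checks, not as the implementation). Hare densities below 1e−6
cannot enter the logarithm; such records are excluded from the fit and
counted, because at the reference calibration the attractor is hare-extinct
(E3) and the jitter straddles the E3/E7 boundary — hare extinction is the
dominant expression of hyperpredation here, so each bin reports its
extinct-hare fraction alongside the slope. With seed 0, that fraction rises
monotonically from 0% in the (1,3] bin to 99% in (11,13].

What the generator does **not** emulate: observation error (steady states
are exact), site-to-site habitat covariates, temporal sampling over a
survey window, demographic stochasticity, or spatial flows. Passing tests
therefore show that the *mechanism* produces the survey-style pattern under
idealized sampling, not that field data of finite precision would yield the
same regression coefficients.

## Known limitations

* Stability conditions are evaluated numerically (closed-form inequalities
  plus eigenvalue cross-validation); no symbolic Routh–Hurwitz reductions
  are attempted.
* Boundedness of the total density is audited along computed trajectories,
  not proved symbolically in code.
* Sweep threshold values depend on the calibration; only the transition
  *structure* (which equilibria exchange, in what order) is asserted by
  tests.
* Near a transcritical boundary the slow eigenvalue approaches zero and
  convergence times diverge; ensemble jitters landing there are excluded
  with a tally rather than forced to converge.
* The per-bin OLS slopes for surviving-hare records condition on survival,
  which can bias slopes upward in heavily censored bins; the extinct-hare
  fraction is the more faithful summary in that regime.
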