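# Methods

This note records the models implemented by `tumorfence`, the parameters
that matter, the conventions adopted where the design was genuinely open,
and what the synthetic-data tests do and do not establish.

## Fencing clusters

Cells are nodes; an undirected edge joins two cells whose centroids are at
Euclidean distance ≤ r_c, with the boundary inclusive and coincident
centroids (distance 0) connected. The default r_c = 30 μm is roughly three
cell diameters — a conservative "physical contact" radius for ~10 μm
cells measured centroid-to-centroid. A *phenotype cluster* is a connected
component of the subgraph induced by one non-tumor phenotype with at least
N_F = 3 members (pairs are too common by chance to call structure); a
cluster is *fencing* when any member has an edge to a tumor cell. Tumor
cells are never cluster members. Neighbor search uses a k-d tree
(`scipy.spatial.cKDTree`), which returns exactly the inclusive-radius pair
set; the test suite checks equality with an all-pairs O(n²) reference.

f_d, the number of phenotype cells in fencing clusters, is monotone:
shrinking r_c or raising N_F can only remove edges or clusters, never add
them.

## Permutation null, p-value, FDR and FPM

The null hypothesis is that the queried phenotype g is arranged no more
deliberately than any other non-tumor phenotype: every cell position and
every tumor cell stays fixed, and the multiset of non-tumor labels is
reassigned to the non-tumor positions by a uniformly random permutation.
Since only membership in g affects f_r, a uniform label permutation is
equivalent to drawing a uniformly random size-n_g subset of the non-tumor
positions; the implementation samples such subsets on a precomputed
contact graph (a consistency test verifies the equivalence against full
relabeling). One master seed feeds per-(slide, phenotype) substreams via
`numpy` SeedSequence, so cohort runs are reproducible and order-independent.

The p-value is the plain fraction of permutations with f_r ≥ f_d
(minimum resolvable p is 0, reported as "< 1/n_perm" in text output); the
default ensemble size is 1000, configurable upward — the estimator's
resolution, not its validity, is what grows with n_perm. Families for
Benjamini–Hochberg control (q = 0.05) are one (cohort, phenotype) across
slides. Slides enter analysis only with ≥ 50 g-cells and ≥ 50 tumor cells
(both configurable); below that the permutation distribution of f_r is too
coarse to rank.

FPM = max(0, (f_d − ⟨f_r⟩)/f_d). At f_d = 0 the formula divides by zero;
the value is defined as 0, the unique choice consistent with "no fencing"
and with mapping all fencing deficits to zero. FPM is 1 exactly when the
null never produces a fencing g-cell, and decreases monotonically as the
null mean rises.

Patients with several eligible slides contribute the mean of their slide
FPMs to association analyses (configurable).

## Outcome association

Group comparisons use the two-sample t-test on per-patient FPM; scans
across phenotypes report raw and BH-adjusted p-values. Response
correlations code responders 1 and non-responders 0 and use Pearson's r.
The density/FPM combination is c(r) = (1−r)·σ/σ_max + sign·r·M with the
minus sign as default; the plus variant is available behind a flag because
the two published descriptions of the score's r = 1 endpoint disagree in
sign, and neither is asserted here. σ_max and the Ripley maxima are
leave-self-in cohort maxima.

Ripley's K-cross is the plain intensity-normalized neighbor count
K = λ_b⁻¹·#{(a_i,b_j): d ≤ r_c}/N_a with **no edge correction** — it is
used as a per-slide covariate for comparison with the FPM, not as an
unbiased second-moment estimate, and the uncorrected form is what the FPM
is being compared against. Self-pairs are excluded in the auto case.
Survival splits patients at the cohort-mean FPM (high: FPM ≥ mean) and
compares the groups with the standard unweighted log-rank test
(`lifelines`), hypergeometric tie handling.

## Lattice model of boundary access

A single motile cell walks on a square lattice, a = 10 μm (one cell
diameter), strip width L = 230 μm periodic in x (the typical spacing
between neighboring fences on a tumor rim), reflecting top at
y_max = 1500 μm (far enough that a returning walker is irrelevant on the
horizons used; reflecting vs absorbing there is immaterial). The tumor
boundary is y = 0: hopping down from the first row of sites (y = a)
absorbs the walker. Waiting times are exponential with per-direction rate
D/a² = 0.025 min⁻¹ (D = 2.5 μm²/min, a T-cell-scale motility), so the
walk reproduces D exactly in the mean. Continuous time rather than fixed
steps was chosen because the chemotactic drift below (up to 5 μm/min)
cannot be represented with the diffusive step Δt = a²/4D = 10 min without
overshooting a lattice site per step.

**Fences.** A linear fence of length b occupies b/a consecutive sites of
the first row, centered in x. Any attempted move into a fence site is
rejected — time still advances — and counted as one reflection. A *hairy*
fence displaces a random half of its sites up by one row (their first-row
sites vacated), modeling the ragged chains seen in tissue; at equal length
it reduces access slightly, mostly at long horizons.

**Access ratio.** R_b(T) divides boundary arrivals with the fence by
arrivals without it. The no-fence reference starts from the full grid of
sites within 90 μm of the boundary (all columns × rows a…90 μm — 90 μm is
where the 2.5-day arrival probability crosses 1/2); the fenced run starts
from the same grid minus fence-occupied sites. The reference count has the
closed form S·Σᵢ erfc(yᵢ/√(4DT)) (image method) and is used analytically
by default; a simulated denominator agrees with it to ~0.1 %.

**Decomposition caveat.** Arrivals split into N_nr that never reflect off
the fence and N_r that reflect at least once. The identity
N_nr/N_nf = (L−b)/L is exact only for a fence that interacts with the
walker solely by blocking absorption in its columns: then a never-deflected
trajectory is a free trajectory, whose first-arrival column is uniform by
periodic symmetry. For the physically occupying fence implemented here, a
free trajectory can also traverse first-row fence sites laterally before
its first arrival, so the simulated N_nr/N_nf falls measurably below
(L−b)/L at long horizons (≈ 0.52 vs 0.61 at b = 90 μm, T = 2.5 d) and
approaches it as T → 0. The suite asserts the rigorous one-sided bound and
the short-horizon collapse; the two-sided identity at T = 2.5 d is kept as
a known-failing check of the idealized decomposition.

**Chemotaxis.** Fences of chemokine-secreting phenotypes are modeled by an
extra downward hop rate v(b)/a applied at heights y ≤ 50 μm — a typical
chemokine decay distance; the model's own figure-panel variant at 40 μm is
available via `ChemotaxisConfig(drift_depth=...)`. The drift law
v(b) = v_max·min(b, b_sat)/b_sat (v_max = 5 μm/min, b_sat = 150 μm) makes
drift grow with the amount of secreting fence and saturate; there is no
explicit chemokine field — the drift law *is* the model. The denominator
run has no fence and hence no drift. Scanning b at T = 12 h, access peaks
near 2× at b ≈ 30–50 μm before physical blockage wins.

## Interacting-cell-system (ICS) agent model

A Gillespie (direct-method) simulation on a 100 × 100 lattice of 10 μm
chambers covering 1 mm². Chamber capacity is 4 quarter-units: CD8 cells
take 1, tumor cells and TAMs 2, implanted fence cells 4 (full chamber,
frozen). Contact means same or edge-adjacent chamber. Channels: tumor
proliferation (k_C per cell; daughter placed in the first of the layers
{same chamber, 8, 16, 24 neighbors} with room, if need be expelling a CD8
cell to its nearest free chamber — removing it if none within three rings —
and aborting if the 49-chamber block is saturated); CD8 proliferation
(into the cell's own chamber) and recruitment (uniform over chambers with
room), both throttled by the logistic load (1 − (N_TC + N_Te)/N_cc) and
the kill feedback D_C/(D_12 + D_C), where D_C counts tumor kills in the
trailing 12 h window T_m (an exact sliding event log, recomputable at any
time); lysis at k_lys and exhaustion at k_exh per CD8–tumor contact pair
(k_exh_tam per CD8–TAM pair), exhausted cells removed immediately but
still counted in the load by default (configurable); TAM recruitment and
death; motility hops (CD8 rate divided by 33 while touching a TAM);
periodic boundaries with a 50 % removal draw for CD8 cells that cross.

Every rate constant ships as an overridable config value; the defaults are
package choices sized for ~10²–10³ agents, not literature claims. The
canonical fence-implantation experiment uses k_C = 2×10⁻⁴ min⁻¹ (≈ 2.4 d
tumor doubling), D_mot = 0.1 min⁻¹ (≈ 2.5 μm²/min CD8 motility),
k_lys = 4×10⁻³ min⁻¹ per contact pair, k_pro = 5×10⁻⁴, r_rec = 0.01,
N_cc = 300, no TAMs — isolating the spatial-exclusion mechanism. The
initial condition is a 300-cell tumor disc (radius 250 μm) ringed by 30
CD8 cells at 265–325 μm; the fenced variant implants 20 discs of fence
chambers (~50 μm diameter, the size/density scale of observed fences) on
boundary chambers, displacing residents to nearby free chambers. With 300
replicates per arm over 2.5 simulated days the fenced ensemble-mean tumor
population exceeds the control by ~5 % (≈ 7 standard errors) — fences
shield the tumor purely by excluding cytotoxic traffic.

## Synthetic data

Slides emulate a 1 mm² core: a central tumor disc (radius 300 μm, density
1500 mm⁻², homogeneous Poisson), non-tumor background phenotypes scattered
uniformly outside the disc (g at 300 mm⁻², "other" at 700 mm⁻²), and
planted fences — arcs of 8 g-cells spanning ~50 μm, 20 per slide, tangent
to the tumor rim at jittered angles, each with one tumor cell anchored
just inside the boundary so the planted structure meets the fencing
definition by construction. Matched *null* slides scatter the same
fence-cell budget uniformly instead; they calibrate the permutation test's
type-I error. Cohorts give responders 20 fences and non-responders 2, and
draw exponential survival with hazard ratio 0.3 for the high-fencing group
(administrative censoring at 3× the baseline mean). The pronounced ratio
is deliberate: the mean split on *estimated* FPM misclassifies some
patients, attenuating the observed contrast, and the generator's stated
effect size is the one at which the pipeline's power is demonstrated.

What passing tests show: the detector recovers planted structure, the null
is calibrated on exchangeable backgrounds, and the association pipeline
detects strong planted couplings. What they do not show: performance on
real tissue, where backgrounds are not Poisson (micro-anatomy, vessels,
segmentation artifacts correlate positions and labels), phenotype panels
are richer, and effect sizes are far smaller.

## Numerical conventions and problem sizes

Distance threshold inclusive; BH at q = 0.05; all RNG from
`numpy.random.default_rng` with explicit seeds, per-unit substreams
derived by SeedSequence. Monte-Carlo assertions use 3 standard errors.
The test suite runs scaled-down but statistically adequate sizes: 400
walkers per start site for the 2.5-day fence runs (~7×10⁴ arrivals per
fence length), 150 per site for the chemotaxis scan, 150 null slides at
400 permutations for calibration, 10 replicate cohorts of 80 patients for
power, and the full 300-replicate ICS experiment. The acceptance script
uses 600 and 300 walkers per site.

## Known limitations

Two-dimensional geometry only; linear fences on a straight boundary in
the minimal model; no explicit chemokine reaction–diffusion; no Cox
covariate adjustment; the ICS rate constants are plausible placeholders,
so its outputs are directional statements about mechanism, not calibrated
predictions.
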