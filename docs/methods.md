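# Methods

`saxstruct` implements the structural-inference chain used to characterize
flexible multi-domain proteins from SEC-SAXS data: reduction of an elution
frame series to one scattering curve, reciprocal- and real-space size
analysis, ab initio dummy-atom shape reconstruction, dual-space validation
of atomic models, envelope-restrained flexible fitting, and backbone
dihedral (PAV) comparison of model ensembles. This note records the models,
the defaults and their rationale, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## SEC-SAXS reduction

A SEC-SAXS injection yields one curve per elution frame on a common q grid
(default emulation: 512 points on 0.0026–0.340 Å⁻¹, 3 s frames). The
chromatogram is the trapezoidal integral of I over q per frame. Buffer
frames default to the 20 lowest-chromatogram frames preceding the main
peak — real beamline practice varies, and this is a documented assumption.

Per-frame Rg values come from Guinier fits in a *fixed* q window chosen
automatically on the strongest frame. Re-selecting the window per frame
adds frame-to-frame variance that the formal fit uncertainties do not
describe, which would defeat the homogeneity criterion below; a shared
window keeps frames statistically comparable.

Frame selection selects, among all contiguous windows inside the peak
region, the longest one whose Rg standard deviation σ⟨Rg⟩ is at most
κ × (median per-frame Rg uncertainty), with κ = 1 — i.e. a window is
"homogeneous" when its Rg scatter is within measurement error. Ties break
toward smaller σ⟨Rg⟩, then earlier start. If no 3-frame window qualifies,
the global σ⟨Rg⟩-minimizing 3-frame window is returned with a fallback
flag. An exhaustive O(n²) window search reproduces the selection exactly
(property-tested).

Averaging subtracts the mean buffer curve from the mean sample curve and
propagates uncertainties as standard errors of both means in quadrature.
Dataset similarity uses a reduced-χ² test with one fitted scale (analytic
weighted least squares, iterated three times because the combined variance
depends on the scale), N−1 degrees of freedom, and a χ² survival-function
p-value; the study convention α = 0.01 applies. Re-binning (linear, log, or
join-every-m) uses σ⁻²-weighted means within bins and σ_bin = (Σσ⁻²)^(−1/2).

## Guinier analysis

Weighted linear regression of ln I on q², iterated until q_max·Rg ≤ 1.3
(the customary globular-particle cutoff; elongated particles carry a
small negative bias at this cutoff, visible in the dumbbell benchmarks at
about −2%). Two refinements:

- *auto-start*: leading points are dropped while they deviate more than
  3× the robust residual scale from the fit line (beamstop or aggregation
  upturns). The scale is the MAD of the in-range residuals, floored at the
  formal σ, so noiseless data are handled sensibly.
- *curvature shrink*: if a quadratic term in q² is statistically
  significant (|z| > 3), the upper bound is reduced stepwise. On very
  precise data this removes the systematic ~2% bias the fixed 1.3 cutoff
  would leave; on noisy data it triggers rarely and the cutoff governs.

`rg_err` follows from the residual-scaled slope variance.

## Indirect Fourier transform

P(r) is expanded in the Moore sine basis a_k sin(kπr/Dmax), truncated at
k ≤ Dmax·q_max/π plus a 4-term buffer, so P(0) = P(Dmax) = 0 by
construction. The weighted least-squares system carries a second-derivative
smoothness penalty evaluated on the r grid (201 points by default). The
regularization weight α is scanned logarithmically (scaled by the
normal-matrix trace ratio) and set to the largest value whose weighted
residual stays within 2% of the best achievable — the corner where the
L-curve leaves its flat residual branch. This knee rule proved far more
stable than discrete curvature maximization on noisy scans.

Real-space parameters are moments: Rg² = ∫r²P dr / (2∫P dr),
I(0) = 4π∫P dr. A warning flag marks Dmax·q_min > π (data cannot constrain
Dmax).

### Dmax search

Fit quality is one-sided in Dmax: truncating real distances raises χ²
sharply, but oversizing costs almost nothing. The search therefore (1)
scans a coarse grid from 2·Rg up to min(2π/q_min, 8·Rg), scoring each IFT
by χ² + 4·(negative-area fraction) + 2·(tail-oscillation measure), and
locates the smallest Dmax on the score plateau; (2) re-runs the IFT with
30% headroom and reads Dmax as the largest r where P(r) exceeds 2% of its
peak. The 2% decay threshold was chosen from the estimator comparison on
analytic and simulated shapes (sphere, rod, three-domain), where it is the
only variant inside ±5% for compact and ±10% for elongated particles; the
1% variant chases regularization tails, and cumulative-quantile variants
bias low because true P(r) tails carry little mass.

### Quality score and molecular weight

The P(r) quality score is the geometric mean of four sub-scores in [0,1]:
back-transform fit exp(−|χ²−1|), positivity (1 − negative-area fraction),
smooth tail (1 − oscillation measure), and stability of the real-space Rg
under ±10% Dmax perturbation (exp(−10·relative shift)). It is a composite
in the spirit of regularized-IFT quality estimates, with equal weights as
a design choice — not a reproduction of any program's internal formula.

Molecular weight uses the Porod volume V = 2π²I(0)/Q with the invariant
Q = ∫q²I dq extended below q_min by the Guinier form and above q_max by a
q⁻⁴ tail whose constant is averaged over the top quarter of the q range
(wide enough to span the form-factor oscillations of compact particles);
MW = V / 1.6 Å³ Da⁻¹. This concentration-free route replaces empirical
consensus methods that require a training corpus; its accuracy on the
analytic sphere is within 5% and ±10% should be assumed in general.
Sequence MW uses the standard average residue-mass table plus one water.

## Theoretical profiles (Debye)

I(q) = Σᵢⱼ fᵢfⱼ sinc(q·dᵢⱼ) with one scatterer per residue at the Cα and
f = residue electron count (atom-level evaluation with elemental counts is
available). Pair distances are histogrammed at 0.1 Å so the cost is
O(n_bins × n_q); the binned sum agrees with the exact O(n²) sum within
0.5% (oracle-tested at n ≤ 300). Solvent excluded-volume and hydration-
shell terms are deliberately omitted: the package ranks models relative to
one another and validates against self-consistent synthetic data, so
absolute χ² values are not comparable with hydration-aware programs.
Profile fitting uses the closed-form weighted scale (optionally scale +
offset) and reduced χ² with N−1 (or N−2) degrees of freedom.

## Ab initio shape reconstruction

The search space is a hexagonally close-packed lattice of beads of radius
Dmax/20 filling the Dmax sphere. The annealer minimizes

    E = χ²(bead profile, data) + λ·(looseness + disconnectivity)

with single-bead flips restricted to occupied beads and their empty
boundary, geometric cooling (T ← 0.9·T per plateau), a start temperature
at which roughly half of uphill probes would be accepted, and a stop at
<1% acceptance or the move budget (default 60 000 moves; the profile,
neighbor counts, and connectivity are all updated incrementally).

Three choices matter and were fixed after explicit failure analysis on
the three-domain benchmark:

- *Fit band*: the bead profile is fitted only up to q = 8/Rg. Point
  scatterers have a flat self-term at high q, and fitting beyond the
  shape-information band drives the search toward inflated bead counts
  (the flat plateau scales as 1/N). A solid-sphere bead form factor
  exp(−q²r_b²/10) is applied on top.
- *Volume-informed start*: the initial occupancy count equals the Porod-
  volume estimate divided by the bead volume, so annealing optimizes
  shape rather than gross size.
- *Penalty weight*: λ = 0.1 × (start χ²)/(start penalty). Balancing the
  penalty 1:1 against the start χ² lets compactness dominate once χ² has
  collapsed, yielding over-fat shapes; at 10% the reconstructions track
  the true volume while staying compact and connected.

NSD(S₁,S₂) is the symmetric normalized spatial discrepancy with
nearest-neighbor normalization per set. Alignment searches centroid
superposition and principal-axis alignment over all 8 axis-sign
combinations — including improper ones, since scattering cannot
distinguish enantiomers — followed by Powell refinement over rotation and
translation. Averaging aligns all runs to the member with the lowest mean
NSD, excludes outliers by a leave-one-out mean + 2 SD rule (a plain
mean + 2 SD over so few values can never flag a single outlier), snaps
beads to a common lattice for fractional occupancies, and volume-corrects
to the median single-run bead count. Refinement restarts the annealer
cold (1% of the reference temperature) on the union support with the
≥70% occupancy core frozen, and never returns a configuration whose χ²
exceeds the start's.

## Dual-space validation and flexible fitting

A model is validated by (i) the reduced χ² of its Debye profile against
the experimental curve and (ii) the NSD between the envelope and its Cα
set; the customary bounds are NSD < 1 among reconstructions of the same
dataset and NSD < 3 between an envelope and a full-atom model. Splicing
of two overlapping construct models superposes the common region by
Kabsch (the "lever arm") and checks junction Cα–Cα distances against the
2.9–4.1 Å window. Two construct envelopes merge into one restraint by
aligning each to the Cα set of its residue range and taking the voxelwise
maximum of their Gaussian-kernel densities on one grid.

Flexible fitting is Cα-level energy minimization, not thermostatted MD:
full force fields, explicit solvent, and targeted-MD scheduling are out
of scope. The energy is

    U = −w·Σ ρ(xᵢ) + k_bond·Σ(|xᵢ₊₁−xᵢ| − 3.8)²
        + k_dom·Σ_domains |x − fit(ref)|² + Zn harmonic terms,

with trilinear map interpolation and analytic gradients, virtual Cα bonds
(pairs whose start separation exceeds 4.5 Å are treated as chain breaks),
per-domain rigidity toward Kabsch-superposed reference coordinates (a
targeted-MD surrogate; default k_dom = 20, strong enough that domains
move rigidly instead of being dented by voxel maxima), and optional
harmonic metal-site restraints (k = 50 energy/Å², r₀ = 2.5 Å, matching
Zn-coordination springs). w is auto-scaled so the typical map force
equals that of a bond stretched by 0.5 Å. Descent uses backtracking, so
the energy is non-increasing. Because per-atom map gradients vanish in
the flat interior of a smooth map, a final rigid-body polish runs a
6-dof Powell search per restrained domain maximizing the global map
correlation (with a soft bond term); this resolves the pose degeneracy
that stalls pure descent. CORR is the Pearson correlation between the
target map and the model's simulated density over the thresholded
support; RMSD series are reported against the start model.

## PAV descriptor and ensemble comparison

PAV_i = (180/π)·arccos(cos(ψᵢ + φᵢ)) folds both backbone dihedrals into a
single bounded descriptor in [0°, 180°] that depends only on φ+ψ and is
free of circular-wrapping artifacts. Dihedrals follow the IUPAC
convention from N/Cα/C atoms; first/last residues and chain breaks
(Cα–Cα > 4.5 Å) yield missing values. Profiles stack into a models ×
shared-residues matrix (residues missing from any model are excluded
column-wise — a documented choice), compared by column-centered PCA
(explained-variance fractions are defined as zero for an ensemble of
identical models) and average-linkage hierarchical clustering.

## Synthetic data: what it does and does not show

Toy structures are Cα chains threading lattice-filled spheres/ellipsoids
(3.8 Å spacing, boustrophedon ordering so consecutive residues are
bonded) joined by extended linkers; ground-truth Rg/Dmax are recorded in
a JSON manifest. The three-domain preset mirrors a PWWP2 / AWS-SET-postSET
/ PHD4 topology with 84/249/105 residues and sphere radii from the
residue counts at 134 Å³ per residue. Curves add Gaussian noise
σ(q) = a·I(q)·(1 + b·q/q_max) with defaults a = 0.01, b = 4 (synchrotron-
like high-q degradation); SEC-SAXS series superpose Gaussian elution
peaks (two peaks plus a leading shoulder are expressible) on a flat
buffer. A full-backbone helix generator (NeRF construction with exact
φ/ψ control) supports the dihedral analyses.

The simulators do not model inter-particle structure factors, radiation
damage, detector geometry, or solvent-contrast effects, and the toy
domains are homogeneous — so passing benchmarks demonstrate the internal
consistency and statistical calibration of the pipeline, not its accuracy
on real beamline data. Note one deliberate degeneracy: spherical toy
domains make per-atom recovery by flexible fitting ill-posed (any internal
rotation inside the lobe is equivalent), so fitting benchmarks use
ellipsoidal domains.

## Benchmark problem sizes

The end-to-end recovery benchmark simulates a 120-frame injection of the
three-domain stand-in (1087 residues), reduces it, scans Dmax, and runs
20 annealing reconstructions at twice the default move budget (120 000
moves, for well-converged ensembles) before averaging,
refinement, and dual-space validation; the flexible-fitting benchmark
uses the two-ellipsoid dumbbell with one domain rotated 30° out of its
density. Statistical contracts use 20 seeds × 200 points (χ²
calibration) and 200 replicate pairs (p-value uniformity). These sizes
were chosen to exercise every stage at realistic particle dimensions
while keeping a full run in the minutes range on one core.

## Known limitations

- Absolute χ² values are not comparable with hydration-aware profile
  programs (no excluded volume / hydration shell).
- Bead reconstructions inherit the usual SAXS ambiguities (enantiomer,
  near-symmetric rearrangements); a bent three-domain shape reconstructs
  with pairwise NSD ≈ 0.5–1.0, not bit-identically.
- The Guinier cutoff q·Rg ≤ 1.3 biases Rg by roughly −2% for elongated
  particles on noisy data; real-space Rg from P(r) is the more accurate
  estimator and is what the pipeline reports as primary.
- Porod-volume MW assumes a compact, homogeneous particle; flexible or
  elongated proteins can deviate beyond the nominal ±10%.
- Flexible fitting operates on Cα traces; side-chain packing, protonation
  states, and disulfide chemistry are outside its scope.
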