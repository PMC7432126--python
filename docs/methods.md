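# Methods

`paedeg` models the *comprehensive biodegradability* of phthalic acid ester
(PAE) plasticizers: how readily a compound is attacked by the degrading
enzymes of several plasticizer-degrading bacteria at once, summarized into a
single score, related to 3D molecular structure by a field-based QSAR, and
propagated through derivative design, environmental screening and
degradation-pathway energetics.

## Composite index (entropy weight method)

Input is a compounds × endpoints matrix `X` of enzyme-docking scores
(dimensionless), one endpoint per degrading enzyme.  Each column is range
normalized onto `[1 − a, 1]` with floor parameter `a = 0.9` by default:

    benefit:  Y = (1 − a) + a (X − Xmin) / (Xmax − Xmin)
    cost:     Y = (1 − a) + a (Xmax − X) / (Xmax − Xmin)

Docking scores are benefit-oriented (higher score, stronger predicted
binding), so the benefit branch is the default for every endpoint.  The
floor keeps all normalized values strictly positive so that the entropy in
the next step is defined; constant columns are an error, not silently
skipped, because their weight would be undefined.

Per-endpoint information entropy is computed **on the normalized values
directly**,

    E_j = −(1/ln m) Σ_i Y_ij ln Y_ij ,

not on column proportions `p_ij = Y_ij / Σ_i Y_ij` as in the textbook
entropy-weight method.  This is a deliberate reproduction choice: the
direct form is the one that regenerates the published worked table
(entropies near 1.8 for 17 compounds), whereas the proportion form keeps
`E ≤ 1`.  The textbook variant remains available via
`entropy_per_endpoint(..., use_proportions=True)`.  Because the direct form
can exceed 1, the difference coefficient is taken as the absolute
difference `H_j = |1 − E_j|` (the published worked table uses `E_j − 1`
where `E_j > 1`; the absolute form reproduces it and degrades gracefully
when `E < 1`).  Weights are `W_j = H_j / Σ H_j` and the composite score is
`Z_i = Σ_j W_j Y_ij`.

Properties relied on by the tests: `Z ∈ [1 − a, 1]`, `Σ W = 1`, invariance
of `W` and `Z` under per-column positive affine transforms of `X`
(min–max normalization removes location and scale, so only distribution
*shape* carries weight information), and monotonicity of `Z_i` in any
benefit score of compound `i` at fixed weights.

### Reproduction limits

All derived cells of the published worked table reproduce at the printed
precision from the printed raw scores **except** a handful whose printed
values are consistent only with unprinted extra digits of the raw inputs:
the third-endpoint entropy (computes to 1.498 vs printed 1.497), the weight
row (computes to 38.25/37.90/23.85 % vs printed 38.28/37.93/23.79 %, which
back-solve exactly to an unprinted E₃ ≈ 1.4967), one converted cell at a
rounding boundary and two composite scores one ulp off.  The reproduction
tests assert the printed values and report these cells as failures rather
than widening tolerances; the package's own outputs are the full-precision
recomputations.

## Alignment and similarity fields

Molecules sharing a scaffold are superposed by a least-squares rigid-body
fit (Kabsch solution via quaternion alignment) over ≥ 3 mapped,
non-collinear skeleton atoms; the fitted proper rotation and translation
are applied to all atoms.  Fields are evaluated on an axis-aligned grid
(default 2.0 Å spacing, 4.0 Å margin around the joint bounding box).  The
similarity field of probe `P` at grid point `q` is Gaussian-attenuated,

    f_P(q) = − Σ_atoms w_P w_atom exp(−α r²),   α = 0.3 Å⁻² by default,

with unit probe weight and atom weights: van der Waals radius cubed
(steric, proportional to volume), partial charge (electrostatic), an atomic
hydrophobicity parameter (hydrophobic) and 0/1 flags (H-bond donor and
acceptor fields).  The Gaussian form has no singularities at atom centres,
so no cutoffs are applied.  Per-atom properties come from a sidecar table:
the module deliberately contains no charge model or donor/acceptor
perception, which keeps the field stage a pure, testable function of its
inputs.  Probe blocks are each divided by the standard deviation of all
their entries (block scaling, so no probe dominates by magnitude), then
columns with standard deviation below `drop_sigma = 0.01` are dropped.

The exact field settings behind the published model statistics are not
documented upstream (proprietary engine); no attempt is made to reproduce
those statistics numerically.  Correctness is instead established against a
brute-force double-loop oracle, mirror/rigid-motion symmetries and
containment/decay properties.

## PLS and the validation battery

The regression is mean-centered NIPALS PLS (scikit-learn's implementation
behind the module surface).  Validation statistics use the standard
definitions: LOO `q² = 1 − PRESS/SS_tot` (SS about the full-sample mean),
optimal component count at the `q²` maximum with smallest-count
tie-breaking and a cap of `min(n − 2, 10)`; non-validated `R²`,
`SEE = sqrt(SS_res/(n − c − 1))` and `F = (R²/c)/((1 − R²)/(n − c − 1))`;
external `r²_pred = (SD − PRESS_test)/SD` about the training mean.  A
perfect fit reports `F = +inf`.

y-scrambling has no published protocol here, so the package defines one:
pairwise-swap fractions {0.2, 0.4, 0.6, 0.8, 1.0} of the response, 20
permutations per level, seed 1729, refitting and LOO-validating each
scrambled response at the unscrambled optimum component count.  `Q²` is the
intercept of the regression of scrambled `q²` on `r²(y_perm, y)` at
`r²yy = 0` (i.e. extrapolated to complete perturbation), `dq²/dr²yy` its
slope, and `cSDEP = sqrt(PRESS/n)` averaged over the full-perturbation
permutations.  Field-block contributions are
`Σ_{j∈B} |coef_j| · sd_j` per block, normalized across blocks; blocks are
named explicitly (`steric`, `electrostatic`, `hydrophobic`, `donor`,
`acceptor`) to avoid the donor/acceptor label ambiguity present in the
source tables.

## Derivative design, screening, pathway accounting

The substitution catalogue encodes the contour-map rules: small-volume
groups {‑CH₃, ‑OH, ‑H, ‑CN, ‑NH₂, ‑CHO} at ring position C1,
electropositive groups {‑CH₃, ‑CH₂CH₃, ‑CH(CH₃)₂, ‑C(CH₃)₃} at the H1
position, hydrophilic groups {‑OH, ‑CHO, ‑COOH, ‑NH₂, ‑COCH₃, ‑CONH₂} at
the ester C2 position, expanded to the published 30-derivative catalogue
(4 + 6 + 6 single, 6 doubled-C2, 8 H1×C2 doubles).  Derivatives are
bookkeeping records; no 3D structures are built.  Change rates are
`100 (new − parent)/parent` against the parent row *at the parent's printed
precision* (0.27/5.57/4.71/3.55), which is what reproduces the printed
rates.  The per-enzyme "ratio" triple is the share decomposition
`100 r_j / Σ r_j` of the per-endpoint change rates, computed at full
precision and rounded to 2 d.p. last; it is defined only when all three
endpoints improved, and its L1 distance to the entropy weights ranks how
evenly a derivative improves across enzymes.

Screening rules (all thresholds configurable): lowest vibrational frequency
> 0 (a true minimum), bioconcentration factor `BCF = 10^logBCF < 100`,
|logLC50 change| < 10 % (chosen because it cleanly separates the published
toxicity changes: 2.7–5.6 % vs ≥ 16 %), and composite biodegradability gain
> 15 %.  Persistence and migration changes are reported but not gating.
Change-rate sign conventions follow the published property table exactly:
`100 (parent − new)/parent` for total energy, logLC50 and logt½;
`100 (new − parent)/parent` for logKOA.

Pathway accounting sums chained step barriers (kJ/mol, quantum-chemistry
inputs) into path totals, computes per-path percent changes versus a
reference compound, and aggregates them across the Gram-negative and
Gram-positive routes by **summation** — the published convention, kept as
the default although summing percentages across paths has no physical
meaning; a mean aggregate is available behind `aggregate="mean"`.  The
consistency report pairs barrier changes with composite-biodegradability
changes and checks sign opposition.

## Synthetic data

The score-matrix generator controls each endpoint's entropy weight through
distribution shape (scale and location being invisible to min–max
normalization): every column carries a fixed low and a fixed high anchor
compound, and the dispersion multiplier `d_j` shrinks the bulk's spread
(`sd = 1/d_j`) so the normalized bulk concentrates near the
high-information region of the `−Y ln Y` curve.  Larger `d_j` therefore
yields a larger weight, which is the tested contract (an endpoint with
`d = 5` against two at `d = 1` wins the largest weight in ≥ 95 % of
replicates).

The molecule-set generator emulates an aligned congeneric series: a rigid
shared carbon-ring scaffold (identical coordinates and properties across
molecules, so alignment is trivially consistent) plus substituent
pseudo-atoms whose positions, charges and hydrophobicities move along
`n_latent = 3` latent factors (positional spread 0.5 Å, property spread 0.3
by default).  The response is `y = Xd β + ε` with `β` drawn in the span of
the leading right singular vectors of the realized descriptor matrix,
scaled to unit signal standard deviation, and `ε` Gaussian with relative
standard deviation `noise_sd`.  Placing `β` in the realized signal subspace
makes the planted model identifiable — an arbitrary coefficient vector in a
`p ≫ n` descriptor space is unrecoverable by any regression — so noiseless
runs support the exact-recovery checks (`q² > 0.999`, coefficient
correlation > 0.9).  What passing these tests does **not** show: recovery
of real structure–activity relationships, which are not exactly linear in
field descriptors, not low-rank, and not noise-free; the generator also
makes no attempt at realistic chemistry (no bonds, charges or conformers —
deliberately, since fields are pure functions of the sidecar properties).

Default problem sizes used by the tests and reproduction suite — 17–30
molecules, ~6-atom scaffolds, 2 Å grids giving a few hundred retained
descriptor columns, 10–20 scrambling permutations — were chosen as the
smallest sets on which the tested contrasts (noiseless vs noise, planted vs
null, scrambled vs unscrambled) are unambiguous.

## Numerical conventions

All computation is done in double precision; comparisons against printed
values round half-even to the printed decimals as the final step.
Component-count ties take the smaller count.  Degenerate inputs raise
typed errors naming the offender (constant endpoint columns, collinear
skeleton mappings, zero-variance responses, broken step chains, zero
parents in change rates).  Unicode minus signs in input tables are
normalized on read.  Seeds fully determine every stochastic output.
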