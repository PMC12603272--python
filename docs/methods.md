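# Methods

This note records the models implemented by `grooveqsar`, the defaults
and why they were chosen, and the limits of what the synthetic-data tests
demonstrate.

## Structures and alignment

A complex is a DNA decamer duplex plus one bound ligand.  The common
frame is built by matching backbone atoms (P, O5', C5', C4', C3', O3' —
the standard nucleic-acid sugar–phosphate definition; configurable) by
(chain, residue number, atom name) and solving the least-squares rigid
superposition (Kabsch, via SVD with reflections rejected).  The
reference is the first complex in dataset order unless one is named.
Fewer than three matches or collinear match sets are errors, since the
rotation is then under-determined.  Hydrogen addition and force-field
minimization are deliberately not implemented; `prepare_structure`
exposes a hook so a minimizer can be plugged in, and inputs are assumed
prepared.

Partial charges cannot be stored in standard PDB columns, so the package
follows the PQR convention of carrying them in the occupancy field
(`charge_from="occupancy"`, default; pass `None` to ignore).  All
coordinates are Å; PDB precision is 0.001 Å.

## Molecular interaction fields

At every node of a shared rectangular grid, two probe energies are
evaluated per ligand and summed over atoms:

* electrostatic: E(p) = Σᵢ 332.06·q_probe·qᵢ/(ε(rᵢ)·rᵢ) kcal/mol with the
  distance-dependent dielectric ε(r) = r (so the term decays as 1/r²);
* steric: Lennard-Jones 6-12 with r_min,ij = r_min,probe + r_vdW,i and
  ε_ij = √(ε_probe·εᵢ), using a small per-element parameter table.

Defaults are classical CoMFA practice: sp³ carbon probe (r_min 1.7 Å,
well depth 0.107 kcal/mol) carrying +1 e, grid spacing 2.0 Å, padding
4.0 Å, both energies clamped to ±30 kcal/mol (a grid point inside an
atom core therefore reads +30 steric).  All of these are parameters of
`ProbeParams`/`GridSpec`.  Stacking the per-ligand steric+electrostatic
rows and dropping columns whose standard deviation is below `min_sigma`
(default 0.05 kcal/mol, the conventional minimum-sigma filter) yields
the descriptor matrix.  Column metadata retains each column's grid point
and probe type; fields can be exported as OpenDX for inspection.

Note one consequence of ε(r) = r with a unit probe charge: the Coulomb
term is 0.13 kcal/mol even 50 Å away from a +1 e atom.  Far-field decay
to below 1e-3 kcal/mol requires several hundred Å; for realistic
fractional charges the practical reach is much shorter.

## PLS regression and validation

PLS1 by NIPALS on mean-centered X and y (no block scaling by default).
Components deflate X and y sequentially; the regression vector is
B = W(PᵀW)⁻¹q.  Predictions are ŷ = ȳ + (x − x̄)·B.  At full rank the
training predictions coincide with least squares (tested against the
pseudoinverse oracle).

Validation follows QSAR convention:

* q² (LOO) = 1 − PRESS/SS, with each sample predicted by a model refit
  without it.  The SS term references each sample to its own fold's
  training mean (the n−1 remaining responses); this is marginally more
  conservative than using the full-set mean.
* SDEP = √(PRESS/n).
* q²_ext and SDEP_ext use the same formulas on an external set, with SS
  referenced to the training-set mean.

Component count is chosen to maximize LOO q², ties broken toward fewer
components.  The three protocols: model 1 fits every record; model 2
fits ~80% and validates on the held-out ~20%; model 3 refits everything
with model 2's component count.  The split is seeded and grouped by
ligand id because the crystal datasets this emulates contain the same
ligand in several complexes — an ungrouped split would leak replicates
across the boundary and inflate q²_ext.

## Pose evaluation and rescoring

Symmetry-corrected RMSD minimizes over atom correspondences that
preserve the chemical element, solved per element class by the Hungarian
algorithm on squared distances; no rigid refit is applied, matching the
docking convention that pose and crystal ligand share the receptor
frame.  Optimal assignment handles the permutation symmetry of
chemically equivalent atoms without graph-automorphism enumeration; the
exhaustive enumeration is kept as a test oracle for ≤8 atoms.  Redocking
accuracy is the fraction of poses within a threshold, default 2.0 Å (the
field-standard success criterion).  Whether accuracy is quoted for
best-scored or best-RMSD poses is the caller's choice of input list; the
CLI reports all poses.

Rescoring treats the fitted QSAR models as an external scoring function:
the pose's ligand atoms are pushed through the same grid and probe
parameters the models were trained on, filtered by the model's column
mask, and predicted.  The reported pK_D is the unweighted arithmetic
mean over (model, pose) pairs, converted to K_D[nM] = 10^(−pK_D)·10⁹.
A "complex minimization" step before prediction is exposed only as the
same preparation hook as above.

## Binding-assay mathematics

Because the dissociation constants of interest (tens to hundreds of nM)
lie far below the working ligand concentration (10 µM), the hyperbolic
isotherm is invalid — ligand depletion is material — and the exact 1:1
quadratic solution is used throughout.  Simulated intensities are
F = F0 + Fmax·[LD]/L with multiplicative Gaussian noise of a given CV.

`fit_titration` estimates (K_D, Fmax, F0) by nonlinear least squares
with K_D parameterized in log10 space.  The saturation stoichiometry is
read as the D/L ratio where the empirical initial-rise line (fit to the
sub-stoichiometric points, delimited by a rise-then-plateau
piecewise-linear knot) meets the fitted plateau F0 + Fmax.  A pure knot
estimator was considered and is retained as `fit_breakpoint`, but when a
titration stops at the equivalence point — as the reference design does
(dsDNA 0–10 µM at 10 µM ligand) — the knot absorbs the isotherm's corner
rounding (width ≈ √(K_D·L)/L on the ratio axis) and reads ~7% low; the
asymptote intersection is unbiased there (1.017 noiseless at
K_D = 100 nM) while still tracking genuine non-1:1 stoichiometries
through the rise slope.

Two identifiability caveats, quantified in the tests: (i) with data only
up to D = L, K_D itself enters the curve solely through that corner
rounding, so at 2% intensity noise only its order of magnitude is
recoverable (the Cramér–Rao bound on the relative sd of K_D is ≈37% at
K_D = 100 nM); a super-stoichiometric design with K_D comparable to L
(e.g. K_D 2 µM, D to 30 µM) brings recovery inside 10%.  (ii) At exact
equimolarity the tight-binding limit approaches min(L, D) only as
L − √(L·K_D), a √(K_D/L) relative deficit, not arbitrarily fast.

Fluorescence polarization is FP = 1000(S − G·P)/(S + G·P) mP, with the
instrument factor G supplied by calibration.  Doubling time is
24·ln 2/ln(N₇₂/N₄₈) hours; equal counts are an error and a shrinking
population returns a negative value with a flag.

## Synthetic data: what it does and does not show

The generator emulates a *congeneric series*, which is what field-based
QSAR assumes: a shared scaffold of 9 substitution sites, of which each
of the n complexes (default 27) occupies a random subset (≥3) with its
own partial charges, all in one aligned frame, wrapped by a deterministic
two-strand helical backbone stand-in carrying standard backbone atom
names.  Sites sit on cell centers of a double-spacing sublattice — ≥4 Å
apart and 1.73 Å from the nearest grid node — and charges are drawn from
±0.2 e, so no single probe energy saturates the ±30 kcal/mol caps.
Under those two conditions the fields are exactly additive per site and
the descriptor rows live in a 19-dimensional affine subspace; with 21+
training rows a held-out analog's row lies in the training span, which
is what makes the noiseless exactness tests (r² = 1, q²_ext = 1,
held-out prediction within 0.1 pK_D) mathematically attainable.  pK_D is
linear in the descriptor row by construction, affinely rescaled so the
noiseless values span 5–9 (bracketing the 6.5–7.6 window typical of
tight minor-groove binders), plus N(0, sd²) noise, default sd 0.15 pK_D.

What this does **not** show about crystal data: real ligands are not
exactly additive point charges, real alignments carry error, real
affinities are heteroscedastic across laboratories, and a real series'
descriptor manifold is only approximately low-rank.  Passing tests
demonstrate the correctness of the machinery and the statistics under
the stated model, not the accuracy of any specific published model.

Pose sets are built by rigid translation along random unit vectors, so
the naive and symmetry-corrected RMSD equal the requested displacement
exactly.  Titration panels default to the reference conditions: ligand
10 µM, dsDNA 0–10 µM in 0.5 µM steps, 2% noise, seeded.

## Numerical choices and problem sizes

Deterministic seeding everywhere (`numpy.random.default_rng`); all
generators are pure functions of (parameters, seed).  The default test
and acceptance runs use a 6×6×6 grid (432 columns before filtering),
27-complex datasets, and 200-rerun empirical bands for the noisy
external-validation check — sizes chosen so the full suite exercises
every code path in well under a minute of compute while keeping every
statistical assertion inside its own simulation-derived tolerance.
Degenerate inputs (constant response, collinear backbones, empty
selections, saturated titrations) raise typed errors rather than
returning NaN.

## Known limitations

* No docking engine integration; pose files are inputs.
* Only steric and electrostatic probes (no hydrophobic/H-bond fields).
* No applicability-domain analysis, bootstrapping, or response
  scrambling beyond the permutation test in the suite.
* The FP module implements the measurement equation only; competition
  IC₅₀ fitting is out of scope.
* The stoichiometry read assumes a single binding transition; biphasic
  titrations will fit poorly (watch `residual_sd`).
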