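# Methods

## Bond detection

A hydrogen bond is counted in a frame when the donor–acceptor heavy-atom
distance is **strictly** below 3.5 Å and the angle between the donor→hydrogen
and hydrogen→acceptor directions (deviation of D-H···A from linearity) is
strictly below 30°. Donors are N/O atoms with a covalently attached hydrogen
(paired geometrically: H within 1.25 Å of an N/O of the same residue, so no
bond topology is needed and any protonation state works); acceptors are all
N/O atoms of the partner chain; both inter-chain directions are scanned.
Salt bridges use the inclusive "within 4 Å" rule on side-chain carboxylate
oxygens (Asp OD1/OD2, Glu OE1/OE2) versus side-chain basic nitrogens (Lys
NZ, Arg NE/NH1/NH2). The asymmetry — strict for H-bonds, inclusive for salt
bridges — is deliberate and boundary behaviour is tested.

Inputs without explicit hydrogens (crystal structures) are supported only
through an explicit flag (`allow_missing_hydrogens`), which substitutes the
heavy-atom criterion: D–A distance plus acceptor–donor–antecedent angle
> 90°. Without hydrogens the donor direction is ambiguous, so the fallback
may report a contact from both directions; the default mode requires
hydrogens.

Occupancy ω of a bond is the fraction of frames in which its criterion
holds. Frames are weighted equally regardless of timestamps (uniform saving
stride; the stride is a user parameter and is never inferred from the
input). Occupancy is kept per atom-level bond key; residue-pair aggregation
happens only inside the dissociation model, because a residue pair can host
several distinct H-bonds (M_ij > 1) and the model multiplies over them
individually. The detector always reports the full set of keys observed in
at least one frame — it never truncates to a "top-N" subset.

## Dissociation model

Each interface bond's survival over the observation window is modelled as an
independent Bernoulli event with probability ω. The complex dissociates when
no bond survives:

    P_D = Π_bonds (1 − ω) = Π_pairs (1 − p_ij) = Π_j (1 − P_j,L) = Π_j (1 − P_j,R)

These four factorizations are one algebraic identity; the implementation
computes all of them and asserts agreement to 1e-12 on every call. The
complement form 1 − Π_j (1 − P_j,L) is the probability that *some* residue
still binds — an association probability — and is exposed only behind an
explicit `as_printed=True` compatibility flag, because its values
(≈ 0.98 where the product form gives ≈ 0.02) are not a dissociation
probability. For the bundled Mac-1/GPIbα model tables the product form gives
0.0219 (Model I), 5.59e-4 (Model II) and 3.89e-4 (Model III). The first two
agree with the published single-significant-figure values (0.02, 0.0005);
the third does not (0.0009 was reported), and we document rather than force
the discrepancy — plausibly rounding of the two-decimal occupancies or bonds
missing from the printed table.

Products are evaluated as exponentiated sums of log1p(−ω), with ω = 1
short-circuited to an exact zero; the log-sum is also reported (`log_P_D`)
so that tables large enough to underflow a double remain exact. No kinetic
(off-rate, Bell/Dudko) interpretation is attached to P_D, and no correction
for geometric or timescale effects is attempted — the model is exactly the
independence assumption, nothing more.

f_D = P_D(f)/P_D(0) requires a zero-force reference condition; a zero
reference P_D raises rather than returning an infinity. The expected
simultaneous bond count is Σω, which equals the trajectory mean of the
per-frame bond count exactly (linearity), and that identity is tested.

## Structural metrics

- **Cα-RMSD** is computed after optimal proper-rotation (Kabsch)
  superposition by default, because the time-course RMSD of a *pulled*
  complex is dominated by trivial rigid drift otherwise; a
  `superpose=False` mode gives the raw RMSD. Superposition is delegated to
  scipy's rotation alignment; the RMSD is recomputed from the transformed
  coordinates.
- **SASA** uses Shrake–Rupley sphere sampling (biotite backend) with Bondi
  element radii and a 1.4 Å probe; the per-sphere point count (default 960)
  is the precision/speed knob. An isolated carbon sphere reproduces
  4π(1.7+1.4)² to better than 1%.
- **Buried interface SASA** is SASA(A) + SASA(B) − SASA(A∪B), *not* divided
  by two. The halved convention is equally common; the choice is recorded in
  output metadata and must be kept in mind when comparing absolute values.
- **Helix axis** is the leading principal component of the ordered Cα
  coordinates, sign-fixed N→C. Plain PCA carries a partial-turn bias for
  short helices (≈ 2° at 12 residues, < 1.5° beyond ~20); for the helix
  lengths this metric is meant for (the I-domain α1/α7 helices) the bias is
  well below the frame-to-frame angle fluctuation. The inter-helix angle θ
  uses oriented axes, so it ranges over [0°, 180°] and distinguishes
  parallel from antiparallel packing.
- **L_MB** is the distance from a chain's mass-weighted centroid (standard
  atomic masses, hydrogens included when present) to a tracked atom — e.g.
  the Cα of the β-switch residue D235 against the GPIbα body.

## Force-response analysis

Classification reduces an occupancy (or lifetime) series over increasing
forces to its significant trend: consecutive differences with |Δ| ≤ ε are
flat and dropped, adjacent equal signs merge, and the residual signature
maps (−) → slip, (+,−) → catch-slip, (−,+,−) → slip-catch-slip, (+,−,+) →
catch-slip-catch, empty → insensitive, anything else → other. The default
ε = 0.025 is the smallest round tolerance at which the bundled 11-bond force
panel falls into exactly the four published groups; it is a config knob.
Flat steps are dropped, not interpolated — the classification is qualitative
over few force levels by design.

Transition forces are the argmin/argmax of a per-force series, ties broken
toward the lowest force and reported. Segmented Pearson correlations are
computed on [min, split] and (split, max]; two-point segments are flagged as
degenerate (r = ±1 by construction) rather than reported as if informative,
and constant segments yield an undefined-r flag instead of NaN.

Bond-number histograms are fit by least-squares Gaussians on the
relative-frequency histogram of the integer counts; with only two distinct
observed values the fit is underdetermined and the Gaussian is
moment-matched instead (a single value is an error).

AFM lifetimes are binned into left-closed, right-open 7.5 pN bins anchored
at 0. The two-pathway off-rate k(f) = k_c e^(−x_c f/kBT) + k_s e^(x_s f/kBT)
(kBT = 4.28 pN·nm at 310 K) is fit to binned mean lifetimes by nonlinear
least squares on the *log* lifetime, which balances the catch and slip
regimes; the lifetime optimum has the closed form
f* = kBT/(x_c+x_s) · ln(k_c x_c / k_s x_s). The two-pathway machinery exists
to generate and recover synthetic catch–slip data — the classification of
real bonds rests on the empirical trend, not on this parametric form.

## Synthetic data: what it emulates, and what it does not

The interface-trajectory generator hosts each designed H-bond on a pair of
minimal PDB-legal glycines, 20 Å apart so designed bonds cannot cross-talk.
Bound geometry (2.9 Å, 10° deviation) satisfies the criteria; unbound
(5.5 Å) violates them. Per-frame states follow a two-state Markov chain with
stationary probability ω* and per-frame switching rate s (so estimators face
realistic autocorrelation; the effective sample count is n·s/(2−s), used by
the recovery tests as the binomial error scale). Default conditions for the
recovery checks: five bonds at ω* = 0.2–0.8, s = 0.5, 2000 frames.

Response-law tables use anchor occupancies whose steps (≥ 0.15) are large
against the classification tolerance, with optional Gaussian noise
(robustness tests use sd 0.02, the scale of the published run-to-run SDs).
Ramp-clamp traces rise at k·v (spring constant 13.89 pN/Å) until clamp or
rupture; AFM lifetimes are exponential with the two-pathway mean (default
parameters place the lifetime optimum near 31 pN, the experimentally
observed threshold scale).

What passing these tests shows: the detectors, estimators and fits recover
known ground truth through the full file-format round trip. What they do not
show: behaviour on real force-field trajectories — the toys have no
competing contacts, no correlated bond networks, no solvent, and rigid
non-bond geometry. Trajectory-scale published values (mean bond numbers,
RMSD plateaus, buried-SASA magnitudes, θ values, rupture forces of the real
complex) depend on unavailable trajectories and are therefore exercised as
invariants and synthetic recoveries, not as numeric targets.

## Numerical and interface choices

- Units: Å, ns, pN, Å² everywhere; residue ids are author numbering,
  verbatim from the input; altloc handling keeps the blank/first location.
- Selection expressions (`chain`/`resid`/`resname`/`name` with
  AND/OR/NOT and parentheses) resolve deterministically to sorted indices;
  empty selections are legal values, not errors.
- Problem sizes in tests and the acceptance script (2000-frame recovery
  runs, 100-seed robustness loops, 500 lifetimes per bin) were chosen as the
  smallest sizes at which the statistical bands above are meaningful.
- Known limitations: no π-stacking/cation–π/water-mediated contacts; no
  mmCIF; no secondary-structure assignment (helix ranges are user-given
  residue intervals); buried-SASA convention differences (×2) against other
  tools; the dissociation model ignores bond–bond correlation by
  construction.
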