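# Methods

This note records the models implemented in `enzstab`, the defaults and the
reasoning behind the design choices that were genuinely open.

## Two-state thermal unfolding (`enzstab.thermal`)

The model assumes a reversible, two-state transition of a monomer. The CD
observable at one wavelength is

y(T) = α(T)·(B_F(T) − B_U(T)) + B_U(T),

with linear baselines B_F(T) = ε_F + C_F·(T − 298.15 K) and
B_U(T) = ε_U + C_U·(T − 353.15 K), folded fraction
α = 1/(1 + exp(−ΔG·1000/(R·T))) and the Gibbs–Helmholtz free energy of
unfolding ΔG(T) = ΔH·(1 − T/T_m) − ΔC_p·((T_m − T) + T·ln(T/T_m)) in
kJ·mol⁻¹ (R = 8.314 J·mol⁻¹·K⁻¹).

Sign convention: ΔG is the *unfolding* free energy, positive below T_m, so
α is the folded fraction and the curve runs folded → unfolded with rising
temperature when ΔH > 0. Equivalent formulations that write K = exp(−ΔG/RT)
and α = K/(1+K) describe the *unfolded* fraction; the logistic used here is
the algebraically identical folded-fraction form and avoids that ambiguity.

Baseline anchoring at 25 °C and 80 °C keeps ε_F/ε_U interpretable as the
extrapolated folded/unfolded ellipticities at those temperatures regardless
of the fitted slopes. When an experimenter has fixed baseline values from
extrapolation, `fit_melting_curve` accepts them through the `fixed` mask.

Fitting uses lmfit's trust-region least squares with a numerical Jacobian.
Initialisation: T_m at the temperature where the signal crosses half the
end-to-end amplitude, ΔH = 250 kJ·mol⁻¹ (typical for a ~50 kDa globular
protein), baselines from the first/last decile means. ΔC_p is fixed at 0 by
default: with data from a single melt the ΔC_p term is nearly collinear with
ΔH and T_m, and freeing it mostly inflates the CIs; it can be freed or fixed
at a literature value via the mask. Confidence intervals are asymptotic,
estimate ± t(0.975, n−k)·SE from the Jacobian-based covariance — the same
convention commercial curve-fitting software reports.

Honesty of the convergence flag: a fit is reported converged only when the
optimizer succeeded, the fitted T_m lies inside the temperature grid and the
transition amplitude at T_m exceeds 3× the residual RMS. A constant (flat)
curve is reported as a fit failure before optimisation.

`compare_stability` reports ΔT_m = T_m(b) − T_m(a) and ΔG_a evaluated at
T_m(b). The latter is one of several constructions for "stability difference
at the melting point" found in the literature; it is exposed as a defined
quantity rather than matched to any particular published number, because the
construction behind such numbers is usually not recoverable from the printed
parameters.

Unit conversion: [θ] = θ_mdeg/(10·l·c) with l in cm and c in mol·L⁻¹ gives
molar ellipticity in deg·cm²·dmol⁻¹; mean-residue mode divides additionally
by the residue count. Both are provided since reports are often ambiguous
about which convention a given ellipticity uses.

## Michaelis–Menten kinetics (`enzstab.kinetics`)

Estimation is always a nonlinear least-squares fit of v = V_max·S/(K_m+S)
(scipy `curve_fit`, non-negative bounds, tolerances 1e−14 so that noiseless
data are recovered to numerical precision). The Lineweaver–Burk transform is
generated for plotting only, with the line drawn from the nonlinear
estimates (slope K_m/V_max, intercept 1/V_max): the double-reciprocal
regression itself weights small velocities pathologically and is never used
for estimation. Internal units are µM and µM·s⁻¹; k_cat = V_max/E₀ in s⁻¹
and k_cat/K_m is reported in s⁻¹·mM⁻¹. The SE of the efficiency uses
first-order propagation including the V_max–K_m covariance.

Specific activity follows the standard chromogenic-assay definition
(µmol product·min⁻¹·mg⁻¹) via Beer–Lambert. The p-nitrophenol extinction
coefficient defaults to 18,300 M⁻¹·cm⁻¹ (400 nm, alkaline stop); this is a
configurable default of this package, not a measured constant of any
particular study.

The two-sample comparison is the two-tailed homoscedastic (pooled-variance)
t test, df = n_a + n_b − 2. Groups with zero pooled variance and equal means
return t = 0, p = 1 rather than NaN.

## Structural statistics (`enzstab.contacts`)

PDB parsing is delegated to gemmi (first model only; mmCIF out of scope).
Alternate locations are resolved to the highest-occupancy conformer (ties:
first in file). Waters are retained but flagged, and excluded from contact
networks by default since published interaction diagrams for this kind of
analysis typically show only residue partners. Author residue numbering and
insertion codes are preserved throughout.

Contacts are distance-only: an edge is any pair of hydrogen-bond-capable
N/O atoms (fixed per-residue table: side-chain N/O plus backbone N and O;
every N/O atom for hetero ligands) within the cutoff, default 3.5 Å — the
convention of interactive viewers' polar-contact mode. No donor–acceptor
angle term is applied, deliberately, so results match what a
distance-function survey of deposited structures produces. An edge is a
salt bridge iff its two atoms belong to oppositely charged groups
(Arg NE/NH1/NH2, Lys NZ positive; Asp OD1/OD2, Glu OE1/OE2, C-terminal OXT
negative). Histidine is neutral by default — its protonation is pH- and
environment-dependent, and treating it as charged would reclassify
His–carboxylate hydrogen bonds as salt bridges; `his_charged=True` flips
this choice.

Normalized B-factors: mean B over the target residues' side-chain atoms
(side chain = atoms outside {N, CA, C, O, OXT}) divided by the mean B over
*all* atoms sharing the chain id. Multi-chain structures report per-chain
values plus their arithmetic mean; with several target residues the
combined value pools atoms before normalizing. Whole-chain targets with
`side_chain_only=False` give exactly 1.0, a useful self-check.

Superposition: Kabsch via SVD with a proper-rotation determinant
correction. `align_rmsd` pairs residues across structures by chain +
residue number + name (or by per-chain global sequence alignment when
numbering differs), then iterates: superpose, compute per-pair deviations,
discard pairs deviating more than `reject_sigma` (default 2.0) SDs above
the mean deviation, repeat up to `cycles` (default 5) times or until no
pair is rejected. A 1e−6 Å floor on rejectable deviations prevents a
numerically exact overlay from shedding pairs at machine precision. Both
knobs are exposed because outlier-rejection conventions differ between
alignment tools.

The homolog survey takes (label, structure, chain, position-of-residue-A,
position-of-residue-B) rows — positions typically produced by
`map_equivalent_residue`, which globally aligns a reference sequence to the
structure's chain sequence — and reports the minimum charged-group atom
distance and a salt-bridge verdict at 3.5 Å plus a 4.0 Å sensitivity
column. Unmappable rows are flagged, not dropped. A bridge additionally
requires the two residues to be of opposite formal charge, so e.g. a
histidine variant at the first position scores "absent" irrespective of
distance (under the default neutral-His convention).

## Sequence utilities (`enzstab.seqtools`)

Global alignment: Needleman–Wunsch with BLOSUM62, affine gaps (open 10,
extend 0.5) via Bio.Align. Percent identity = matches / aligned columns
*excluding terminal-gap columns*, so a tag or terminal extension does not
dilute identity. Published identity percentages depend on this unstated
denominator convention, which is why no attempt is made to match any
specific printed figure.

Molecular mass is the ProtParam-style sum of average (not monoisotopic)
residue masses plus one water, computed with Bio.SeqUtils; 'X' residues are
rejected because their mass is undefined. The 280 nm extinction coefficient
is Gill–von Hippel (5500·nW + 1490·nY + 125 per cystine), reported in both
the no-cystine and all-Cys-paired variants.

## Synthetic data (`enzstab.synthetic`)

Defaults encode the study conditions the package targets: melts with
T_m = 324.6 K (wild-type-like) on a 283.15–353.15 K grid at 0.5 K
(a 10–80 °C scan), ΔH = 300 kJ·mol⁻¹, ΔC_p = 0, baselines −580.7/−348.0,
additive Gaussian noise σ = 4 ellipticity units; kinetics with
k_cat = 55.6 s⁻¹, K_m = 135 µM, E₀ = 0.002 µM, 8 substrate levels linearly
spanning 0.5–5×K_m, triplicates, multiplicative Gaussian noise CV 5 %.
Noise models are the conventional choices for the two instruments: CD noise
is roughly signal-independent (additive), initial-rate errors scale with
the rate (multiplicative). All generators are bit-reproducible for a fixed
seed (numpy `default_rng`).

Toy structures place named atoms directly at requested coordinates. They
are *not* stereochemically valid residues — no bond geometry, no rotamers —
which is sufficient for exercising distance thresholds, charge
classification, B-factor arithmetic and superposition, but means passing
tests say nothing about handling of real-world disorder, symmetry mates,
alternate conformers beyond the occupancy rule, or non-standard residues.
The ligand stand-in uses residue name DNJ (1-deoxynojirimycin, an iminosugar
glucosidase inhibitor) with N/O atoms treated like any hetero ligand.
Multi-chain toys replicate one chain with a rigid offset, giving exact
cross-chain symmetry — useful as an identity check, unlike real crystals
where chains differ.

## Validation scale

The recovery suites run at desk scale: 10 melts per variant (σ = 4,
seeds derived from one base seed) for the T_m recovery check, 50 simulated
kinetics datasets for the K_m/k_cat check, 100–200 simulations for the
median-error properties. These sizes give Monte-Carlo standard errors an
order of magnitude below the tolerances being checked while keeping the
full suite in seconds.

## Known limitations

- Single-melt fits cannot separate ΔC_p from ΔH reliably; ΔC_p = 0 is a
  modelling choice, not a physical claim.
- Distance-only contacts over-count relative to angle-aware hydrogen-bond
  definitions; the cutoff is the dominant knob.
- The B-factor normalization is sensitive to what shares the chain id
  (waters, ligands); the per-chain all-atom mean is reported so users can
  audit it.
- `map_equivalent_residue` trusts one global alignment; structurally
  divergent homologs may need a structure-based mapping instead.
- The two-state model is an equilibrium description; scan-rate-dependent
  (kinetically controlled) unfolding is out of scope.
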