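# enzstab

Quantitative analysis of enzyme-variant stability/activity trade-offs, built
around the kind of question raised by naturally occurring active-site
mutations in glycoside hydrolases (e.g. a GH1 β-glucosidase in which the
otherwise invariant active-site arginine is replaced by histidine, removing a
salt bridge to the catalytic glutamate). The package answers three questions
about a pair of enzyme variants:

1. **How much less stable is one variant?** — two-state thermal-unfolding
   fits of CD melting curves.
2. **How do the kinetics differ?** — Michaelis–Menten fits with derived
   *k*cat, *K*m and *k*cat/*K*m.
3. **What changed structurally?** — polar-contact networks and salt-bridge
   classification at a 3.5 Å cutoff, normalized side-chain B-factors, and
   Cα superposition RMSD with outlier rejection, all from PDB files.

A synthetic-data module generates every input class with known ground truth,
so the whole pipeline is testable at desk scale without downloads.

## The models

**Thermal unfolding.** The ellipticity at a fixed wavelength is modelled as a
two-state folded/unfolded equilibrium with linear baselines:

```
y(T)  = α(T)·(B_F(T) − B_U(T)) + B_U(T)
B_F   = ε_F + C_F·(T − 298.15)          B_U = ε_U + C_U·(T − 353.15)
α(T)  = 1 / (1 + exp(−ΔG·1000/(R·T)))   (fraction folded)
ΔG(T) = ΔH·(1 − T/T_m) − ΔC_p·((T_m − T) + T·ln(T/T_m))
```

with ΔG the unfolding free energy in kJ·mol⁻¹, ΔH the van 't Hoff enthalpy,
R = 8.314 J·mol⁻¹·K⁻¹, and ε_F/ε_U the extrapolated folded/unfolded
ellipticities anchored at 25 °C and 80 °C. Fits are nonlinear least squares
(lmfit) with asymptotic 95 % confidence intervals; ΔC_p is held at 0 by
default (weakly identifiable from a single melt).

**Kinetics.** v = V_max·S/(K_m + S) by nonlinear least squares;
*k*cat = V_max/E₀; efficiency *k*cat/*K*m reported in s⁻¹·mM⁻¹.
Lineweaver–Burk transforms are provided for presentation only.

**Structure.** Polar contacts are N/O donor/acceptor atom pairs within a
distance cutoff (3.5 Å default); a contact is a *salt bridge* when both atoms
belong to oppositely charged side-chain groups (Arg/Lys vs Asp/Glu; His is
neutral by default). Normalized B-factors divide a residue's side-chain mean
B by the all-atom mean B of its chain. Superposition is Kabsch (SVD) with
iterative 2 σ outlier rejection over ≤ 5 cycles.

## Worked example

Simulate a wild-type-like melt (T_m = 324.6 K, baselines −580.7/−348.0,
noise σ = 4) and refit it with fixed baselines:

```bash
$ enzstab simulate melt --tm 324.6 --seed 1 --out wt_melt.tsv
$ enzstab fit-melt wt_melt.tsv --fix-baselines -580.7 -348.0
```

The fit report gives `tm = 324.62` K with a 95 % CI of (324.53, 324.71) and
`dH = 301.5` kJ·mol⁻¹ — the generator's truth (324.6 K, 300 kJ·mol⁻¹)
recovered to within a tenth of a kelvin, with a CI width comparable to what
a real instrument-noise melt supports.

Same for kinetics (truth *k*cat = 55.6 s⁻¹, *K*m = 135 µM, CV 5 % noise,
8 substrate levels spanning 0.5–5×K_m in triplicate):

```bash
$ enzstab simulate kinetics --seed 1 --out kin.csv
$ enzstab fit-kinetics kin.csv
```

returns `kcat = 55.73` s⁻¹, `km = 134.1` µM, `efficiency = 415.6` s⁻¹·mM⁻¹.

Structural analysis of a coordinate file:

```bash
$ enzstab analyze-structure model.pdb --residue A:75 --cutoff 3.5
$ enzstab bfactor model.pdb --residues 163:ASN,349:GLU
$ enzstab align wild_type.pdb variant.pdb --selection CA
```

The first lists every polar contact emanating from residue A:75 with its
classification (`salt_bridge` / `hydrogen_bond`); the second reports
per-chain and cross-chain normalized B-factors; the third prints the RMSD
and the number of Cα pairs retained after outlier rejection.

`enzstab run config.toml` chains all stages for a two-variant comparison and
writes `report.json` / `report.txt` plus per-stage CSVs (see
`tests/test_pipeline.py` for a complete config).

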