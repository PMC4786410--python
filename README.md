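# phasekit

Analysis toolkit for studying how multivalent arginine-rich linear motifs
(R-motifs) in nucleophosmin (NPM1) binding partners drive liquid-liquid
phase separation. It is aimed at structural biologists and biophysicists who
need to go from raw sequence sets, NMR titration/relaxation tables, and
small-angle scattering curves to the quantities that frame the
phase-separation argument: motif valency and enrichment, binding constants,
tumbling times and stoichiometry, and real-space correlation distances.

Four analysis stages, each a library module with a matching `phasekit`
subcommand, plus seeded synthetic-data generators so the entire pipeline is
testable offline:

| stage | module | what it computes |
|---|---|---|
| motif scanning | `phasekit.rmotif` | maximal R-motifs (arginines ≤ 2 residues apart), multivalency (two motifs ≤ 20 residues apart), Fisher-exact set enrichment, NoLS-interval overlap |
| titration fitting | `phasekit.binding` | per-residue and global K_D from ¹⁵N chemical-shift isotherms via the exact two-state quadratic Δω = Δω_max·fb(Pt, Lt, K_D), saturation-based isotherm selection, Monte-Carlo errors from a 10% ligand-concentration scale uncertainty |
| relaxation analysis | `phasekit.relax` | exponential decay fits, η_xy = (R₂,α − R₂,β)/2, Lipari–Szabo model-free fits J(ω) = 2/5[S²τc/(1+(ωτc)²) + (1−S²)τi/(1+(ωτi)²)] by grid search plus grouped global minimization, F-test model selection, Stokes–Einstein τc ratios |
| scattering analysis | `phasekit.sans` | Guinier R_g/I(0), regularized P(r) with P(0)=P(D_max)=0, mass M = I(0)·N_A/(c(Δρv̄)²), broad-peak fits I(q) = A/qⁿ + C/(1+(|q−q0|ξ)^m) + B, multi-Gaussian peaks, d = 2π/q |

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

```python
from phasekit import rmotif, binding, relax, sans, synthdata
import numpy as np

# 1. scan the divalent rpL5 peptide for R-motifs
rec = rmotif.ProteinRecord("rpL5", "RRRREGKTDYYARKRLV")
rep = rmotif.scan_record(rec)
print("motifs:", [(h.start, h.end, h.arg_count) for h in rep.hits],
      "multivalent:", rep.multivalent)

# 2. global K_D from 18 synthetic isotherms generated at K_D = 57 uM
dw_max = {f"res{k}": v for k, v in enumerate(np.linspace(0.3, 1.5, 18))}
series = synthdata.gen_titration(57.0, dw_max, pt=284.0, noise_sd=0.01, seed=0)
fit = binding.fit_global_kd(series, mc_reps=500, seed=0)
print(f"K_D = {fit.kd:.1f} +/- {fit.kd_sd:.1f} uM from {fit.n_isotherms} isotherms")

# 3. does doubling the peptide load explain the tumbling-time change?
print(f"predicted tau_c ratio = {relax.stokes_einstein_ratio(73.4, 95.6, 0.73, 2.0):.2f}")

# 4. pentamer mass from absolute forward scattering
m = sans.mass_from_i0(0.2344, sans.MassInputs(3.0, 3.0e10, 6.404e10, 0.73))
print(f"M = {m:.0f} kDa")
```

prints

```
motifs: [(1, 4, 4), (13, 15, 2)] multivalent: True
K_D = 57.7 +/- 6.5 uM from 18 isotherms
predicted tau_c ratio = 1.28
M = 76 kDa
```

Reading the output: the rpL5 peptide carries two R-motifs (residues 1–4 and
13–15) separated by 8 residues, so it is multivalent — the property required
for cross-linking NPM1 pentamers into a dense liquid phase. The global fit
recovers the dissociation constant the isotherms were generated with, and
its Monte-Carlo error is dominated by the assumed 10% uncertainty in the
absolute peptide concentration. A mass increase from 73.4 to 95.6 kDa (two
peptides per protomer) predicts a 28% longer rotational correlation time
under Stokes–Einstein scaling, and the absolute-scale forward scattering of
the apo protein corresponds to 76 kDa — a pentamer of 14.6 kDa subunits.

The same stages are available from the shell:

```
phasekit scan --fasta proteins.fasta --background proteome.fasta --nols nols.tsv
phasekit titrate --table titration.tsv --mc-reps 500 --conc-error 0.10 --seed 1
phasekit relax fit --rates rates.tsv --group core.txt --mc-reps 1000 --seed 1
phasekit relax stoichiometry --m1 73.4 --m2 95.6
phasekit sans pr --dat curve.dat --dmax 78.65
phasekit sans mass --i0 0.2344 --c 3.0 --rho-prot 3.0e10 --rho-solv 6.404e10
phasekit sans broadpeak --dat curve.dat
phasekit sans peaks --dat curve.dat --n 3
phasekit simulate titration --seed 1 --out simulated/
```

Every run writes its effective configuration next to its outputs, and every
stochastic routine takes an explicit seed.

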