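# filamech

Structure and mechanics analysis for actin-like filaments, built for
trajectory-scale ensembles (multi-model PDB, one point per residue, one
chain per subunit) and for meridional X-ray diffraction profiles.  It is
aimed at people studying how point mutations or ligands change thin-filament
mechanics: the same observables are computed that such studies report —
inter-subunit contact distances, coarse-grained subunit geometry,
helical twist/rise and crossover length, persistence length and flexural
rigidity, and the activation-induced shift of the TN3 meridional
reflection — with honest error bars for correlated time series.

Because real trajectories and beamline data are rarely shareable, the
package also generates every input it consumes with known ground truth:
an actin-like double helix (rise 27.5 Å, twist −166.7° per subunit)
fluctuating as a discrete wormlike chain of chosen persistence length, and
Poisson-noise diffraction profile pairs with a controllable relative peak
shift.  Every estimator is validated by recovering what the generator
injected.

## The core quantities

- **Contacts** — Euclidean distances between registry residue pairs in
  neighbouring subunits (longitudinal: subunit *i* → *i*+2 on one
  long-pitch strand; lateral: *i* → *i*+1), averaged over subunits and
  frames, SD by block averaging.
- **Coarse-grained geometry** — each subunit reduced to the centres of
  geometry R1–R4 of four rigid residue subgroups (SG1: 5–33, 80–147,
  334–349; SG2: 34–39, 52–69; SG3: 148–179, 273–333; SG4: 180–219,
  252–262); reported as bonds, angles, and the signed dihedral
  R2–R1–R3–R4.
- **Mechanics** — per-frame least-squares cylinder fit of the filament
  axis; crossover length 180°/|wrap(2φ)| × 2h; persistence length from
  tangent-correlation decay, −ln⟨cos θ(s)⟩ = s/Lp, on strand-step chords
  (with the discretisation corrections described in `docs/methods.md`);
  flexural rigidity κ = Lp·kB·T.
- **Block statistics** — block-average standard errors for correlated
  series, equilibration trimming, and a normality-gated two-group test
  (Kolmogorov–Smirnov gate at p < 0.05 → Mann-Whitney, else t-test).
- **Diffraction** — exposure summation, linear background subtraction,
  Gaussian peak fit in ±3 and ±4 px windows, small-angle pixel↔spacing
  mapping (d = λL/r), percent spacing change between relaxed and
  activated states (positive = extension).

## Worked example

```python
from filamech import synthetic, contacts, mechanics, diffraction as dfr
from filamech.synthetic import FlexParams, ProfileParams

template = synthetic.build_template_monomer(seed=0)
ens = synthetic.sample_flexible_ensemble(
    template, None, FlexParams(persistence_length=9.8, n_frames=500, seed=42))

print(contacts.table_to_frame(contacts.contact_table(ens), ens).head(3))
rep = mechanics.mechanics_report(ens)
print(f"Lp        = {rep.persistence_length} um")
print(f"crossover = {rep.crossover_length} A")
print(f"kappa     = {rep.flexural_rigidity:.3e} N m^2")

p = ProfileParams(relative_shift=0.0034, seed=7)
rel, act = synthetic.make_profile_pair(p)
sr = dfr.subtract_background(dfr.sum_profiles(rel))
sa = dfr.subtract_background(dfr.sum_profiles(act))
sc = dfr.spacing_change(dfr.fit_peak(sr, 4), dfr.fit_peak(sa, 4), sr.geometry, 0.0)
print(f"spacing change = {sc.percent_change:+.3f}%")
```

prints

```
            name  residue_a  residue_b     category    mean_A     sd_A  n_pairs  n_frames
D-loop to C-term         41        374 longitudinal 24.232866 0.106529       11       500
D-loop to C-term         61        374 longitudinal 24.251448 0.099947       11       500
D-loop to C-term         45        370 longitudinal 24.093502 0.095911       11       500
Lp        = 9.64 (1.24) um
crossover = 374.82 (2.56) A
kappa     = 4.125e-26 N m^2
spacing change = +0.341%
```

The 500-frame ensemble was generated at Lp = 9.8 μm, recovered here as
9.64 ± 1.24 μm; the ideal-geometry crossover for this helix is 372.2 Å;
the injected 0.34% relative peak shift comes back as +0.341% in
d-spacing.  Contact distances reflect the synthetic monomer's interface
placement (≈24 Å), with block-averaged SDs from the 0.5 Å per-residue
thermal jitter.

## Command line

The same pipeline is scriptable from the shell, driven by a YAML
configuration (print it with `filamech config`):

```
filamech simulate   --seed 1 --out runs/sim          # ensembles + profiles + manifest
filamech analyze    --seed 1 --in runs/sim --out runs/ana
filamech diffraction --seed 1 --in runs/sim --out runs/dif
filamech compare    --summary runs/ana/summary.json
```

The default configuration simulates two groups — a compliant "WT"
filament (Lp 9.8 μm, 0.34% activation shift) and a stiffer "MUT" filament
(Lp 17.2 μm, 0.16% shift), 2000 frames and 25 exposure pairs each — and
the analyze step ends with the normality-gated group comparison.

## Acceptance script

`scripts/acceptance.py` re-runs the full default two-group study from
scratch (simulate → analyze → diffraction) with the given seed, prints the
recovered persistence lengths, crossover lengths and spacing changes next
to their ground-truth values, and writes the JSON result file:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
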