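# ligbind

Ligand-observed NMR and equilibrium binding analysis for protein–ligand
systems, built around the workflow used to characterize how small drug-like
molecules (the worked system is the synthetic cathinone pair
3-/4-chloromethcathinone, 3-/4-CMC) bind human serum albumin (HSA).

It is aimed at NMR spectroscopists and DMPK scientists who have per-proton
peak intensities from saturation transfer difference (STD) and WaterLOGSY
experiments, total/free drug concentrations from equilibrium dialysis (ED) or
ultrafiltration (UF), and docking free energies — and who want the full
quantitative chain from those inputs to an epitope map, a binding-site
verdict, a binding degree and a thermodynamic consistency check.

## The model

For each ligand proton the STD amplification factor at saturation time *t* is

    η(t) = (I₀ − I_STD)/I₀ · ε,        ε = [ligand]/[protein]

and the build-up curve follows a saturating mono-exponential

    η(t) = STD_max · (1 − exp(−k_sat t)),       STD₀ = STD_max · k_sat

where STD₀, the initial slope, is the transfer measure insensitive to
per-proton differences in spin–lattice relaxation and intramolecular spin
diffusion. Normalizing STD₀ to the per-ligand maximum (100%) yields the
epitope-binding map: the larger the value, the closer that proton sits to the
protein surface.

Binding-site assignment uses competition with Sudlow-site probes (warfarin →
site I, diazepam → site II): per proton, the ratio
100 · STD₀(with probe)/STD₀(without), aggregated per probe by the median; the
probe with the stronger attenuation (smaller median) marks the main site.
WaterLOGSY responses are classified by sign inversion (binder) vs mere
attenuation (weak/ambiguous).

Separative measurements give the binding degree, 100 · (D_t − D_f)/D_t, and
mass-action equilibria (1:1 closed form; independent two-site with a
competing single-site probe, solved by Brent's method over an inner
closed-form quadratic) link dissociation constants to predicted bound
fractions. Free energies interconvert with Kd via ΔG = RT ln Kd at the 1 M
standard state.

A synthetic-data generator emulates all of these measurements at the standard
experimental conditions (20 µM protein, 800 µM ligand, saturation schedule
0.5–6 s, multiplicative intensity noise) with embedded ground truth, so every
stage of the chain can be scored for parameter recovery.

## Worked example

```python
from ligbind.io import run_pipeline

report = run_pipeline({
    "seed": 7,
    "simulate": {"ligands": ["3-CMC"], "dialysis": {"n_replicates": 5}},
})

for e in report.ligands["3-CMC"]["epitope_map"]["entries"]:
    print(f'{e["proton_id"]:>5s}  {e["chemical_shift_ppm"]:5.2f} ppm  '
          f'{e["normalized_STD0_percent"]:5.1f}%')
print(report.ligands["3-CMC"]["site_assignment"])
print(report.binding_degree)
```

prints

```
   H2   7.99 ppm  100.0%
   H4   7.87 ppm   85.0%
   H5   7.71 ppm   71.1%
   H6   7.53 ppm   63.3%
   CH   4.90 ppm   49.6%
 NCH3   2.69 ppm   37.2%
 CCH3   1.50 ppm   34.1%
{'main_site': 'site_II', 'secondary_site': 'site_I',
 'median_ratio_per_probe': {'diazepam': 49.3, 'warfarin': 70.9},
 'margin_percent': 21.6, 'ambiguous': False, 'statistic': 'median'}
{'ED': {'mean_percent': 79.49, 'sd_percent': 0.29, 'n': 5},
 'UF': {'mean_percent': 79.84, 'sd_percent': 0.24, 'n': 5}}
```

Reading: the aromatic protons dominate the epitope map (the ring is the main
binding moiety, the methyls trail it), diazepam attenuates STD₀ roughly
twice as strongly as warfarin so Sudlow site II is the main site with site I
secondary, and about 80% of the drug is protein-bound in both dialysis and
ultrafiltration replicates.

The same stages are available from the shell:

```sh
ligbind simulate --ligand 3-CMC --seed 1 --out intensities.csv
ligbind fit-buildup intensities.csv
ligbind epitope-map intensities.csv
ligbind binding-degree --simulate
ligbind kd -- -6.67        # -> Kd = 1.283e-05 M (micromolar)
ligbind run config.yaml --out report.json
```

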