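# flowmet

Multiparametric analysis of early tumor response to antiangiogenic
therapy from dual imaging channels: **perfusion CT** (dynamic
contrast-enhanced kinetics) and **FDG-PET** (glucose metabolism), with
CD31 **histology** as the microvascular reference. The package is
aimed at researchers running preclinical therapy-monitoring studies —
the kind where a decrease in perfusion precedes any change in tumor
size — who need the full measurement chain as tested, scriptable code
rather than vendor software.

Per tumor and time point it computes:

* **BF** (blood flow, mL/100 mL/min) by the *maximum slope* method:
  `BF = max_t(dC_t/dt) / max_t(C_a) × 6000`, the peak tissue
  enhancement rate over the arterial peak;
* **BV** (blood volume, mL/100 mL) and **PS** (permeability–surface
  product, mL/100 mL/min) by *Patlak graphical analysis*: OLS of
  `C_t/C_a` on `∫C_a/C_a` over a late equilibrated window —
  `PS = slope × 6000`, `BV = intercept × 100`;
* **SUVmax, SUVmean, TV, TLG** (`TLG = TV × SUVmean`) over the tumor
  VOI of the SUV volume;
* **GLCM texture**: the VOI is quantized to 128 gray levels between
  its SUV minimum and maximum, a 3D cooccurrence matrix is
  accumulated over the 13 unique neighbor directions, and
  `entropy = −Σ p log₂ p` and `homogeneity = Σ p/(1+|i−j|)` summarize
  local heterogeneity;
* **FMR** (flow-metabolic ratio) `= BF / SUVmax`, the
  perfusion–metabolism mismatch index;
* **MVD** (microvessel density): mean vessel count over the four most
  strongly stained high-power fields of a CD31 section (hot spots
  ranked at low magnification, counted at full resolution).

Because no raw data of this kind are publicly deposited, the package
ships a first-class **phantom generator** (`flowmet.phantom`) that
synthesizes dynamic CT series, SUV volumes, histology sections and
whole two-arm longitudinal cohorts with known ground truth, so every
stage is verified by parameter recovery. See `docs/methods.md` for the
forward model and all defaults.

## Worked example

```python
from flowmet import simulate_cohort
from flowmet.cohort import analyze_cohort

# two treatment rabbits at baseline, every tumor pinned to the
# reference group means, noiseless
scans = simulate_cohort(n_rabbits_per_group=2, days=(0,),
                        groups=("treatment",), mode="fixed", seed=1)
rec = analyze_cohort(scans)[0]
print(f"BF={rec.bf:.2f} BV={rec.bv:.2f} PS={rec.ps:.2f} "
      f"SUVmax={rec.suv_max:.2f} TLG={rec.tlg:.3f} FMR={rec.fmr:.2f}")
```

prints

```
BF=44.96 BV=25.24 PS=9.52 SUVmax=1.45 TLG=0.207 FMR=31.01
```

Reading these numbers: the ground truth was BF 36.16, BV 25.36,
PS 9.47, SUVmax 1.45. Patlak recovers BV within 0.5% and PS within
0.6%; SUVmax is exact by construction of the PET phantom; TLG is the
product TV × SUVmean of the voxelized tumor. BF reads high on this
phantom because maximum-slope flow is upward-biased by the leakage
fraction PS/BF when PS > 0 — a documented property of the
unidirectional-leakage forward model (at PS = 0 the same estimator
recovers BF within 2%). FMR is the per-tumor ratio BF/SUVmax.

The same chain is available from the shell:

```bash
flowmet simulate --fixed --seed 1 --out cohort_dir
flowmet perfusion --series cohort_dir/T1-L_d00/series.nii.gz \
    --tumor-mask cohort_dir/T1-L_d00/tumor_mask.nii.gz \
    --aorta-mask cohort_dir/T1-L_d00/aorta_mask.nii.gz --out perf.csv
flowmet cohort --fixed --seed 1 --out-dir report_dir
```

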