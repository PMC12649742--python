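# tractnmf

Data-driven analysis of white-matter connectivity from diffusion-MRI
tractography, built around three ingredients:

1. **NMF decomposition of connectivity matrices.** Surface-seeded
   probabilistic tractography yields, per subject hemisphere, a
   nonnegative matrix `V` (vertices × voxels) of visitation counts.
   Nonnegative matrix factorization of the transposed group average,
   `Vᵀ ≈ W H`, produces a white-matter factor `W` (voxels × K) and a
   gray-matter factor `H` (K × vertices): each component is a putative
   tract with a volumetric core and a surface termination profile.
   Group factors are projected to individual subjects by dual
   regression (two stages of nonnegative least squares).
2. **The orbitofrontal bias index (OBI).** For a reconstructed
   connection with gray termination map `g`, OFC mask `O` and
   prefrontal mask `P ⊇ O`,

   ```
   OBI = (Σ_O g / Σ_P g) ÷ (|O| / |P|)
   ```

   i.e. the OFC share of prefrontal termination intensity normalized by
   the OFC share of prefrontal size. A uniform termination gives
   OBI = 1; larger values mean the connection is more confined to
   orbitofrontal cortex.
3. **Nested-ANOVA variance partitioning.** OBI observations are
   arranged hierarchically — species / brain hemisphere (nested in
   species) / NMF component count K (replicates) — and a balanced
   two-level nested ANOVA splits the variance into percentage
   contributions of the three levels, with Bonferroni-corrected Welch
   t-tests between species.

The package is aimed at comparative neuroanatomists who want a
reproducible, scriptable version of this workflow. Because postmortem
tractography data of this kind are rarely shareable, the package ships
a first-class **synthetic cohort generator**: it plants
anterior temporal-frontal (ATF, uncinate-like) and
occipitotemporal-frontal (OTF, IFOF-like) bundles — plus distractor
bundles — into nonnegative low-rank-plus-noise matrices, with
species-level control of the fraction of prefrontal termination mass
falling inside OFC, hemisphere-level random effects on the log-odds
scale, and Poisson or truncated-Gaussian noise. Ground-truth loadings
are returned so every stage can be benchmarked against a known answer.

## Worked example

```python
import tractnmf as t

config = t.PipelineConfig(n_vertices=400, n_voxels=600,
                          k_list=[4, 8, 12, 16], seed=1,
                          write_outputs=False)
result = t.run_pipeline(config)

for cls in ("ATF", "OTF"):
    for sp, s in result.report["obi_summary"][cls].items():
        print(f"{cls} {sp:14s} OBI {s['mean']:.2f} +/- {s['sd']:.2f} (n={s['n']})")
    r = result.anova[cls]
    print(f"{cls} nested ANOVA: F={r.f_among:.2f} (df={r.df_among}), "
          f"p={r.p_among:.2e}; variance % (species/hemisphere/K) = "
          f"{r.var_percent[0]:.1f}/{r.var_percent[1]:.1f}/{r.var_percent[2]:.1f}")
```

prints

```
ATF lemur_like     OBI 3.69 +/- 0.15 (n=24)
ATF macaque_like   OBI 1.43 +/- 0.35 (n=24)
ATF squirrel_like  OBI 1.61 +/- 0.26 (n=24)
ATF nested ANOVA: F=205.67 (df=(2, 15)), p=1.25e-11; variance % (species/hemisphere/K) = 95.4/2.2/2.4
OTF lemur_like     OBI 2.85 +/- 0.23 (n=24)
OTF macaque_like   OBI 1.17 +/- 0.27 (n=24)
OTF squirrel_like  OBI 1.19 +/- 0.11 (n=24)
OTF nested ANOVA: F=145.95 (df=(2, 15)), p=1.47e-10; variance % (species/hemisphere/K) = 94.8/3.5/1.7
```

The default cohort plants a strong lemur-like orbitofrontal bias
(OFC fraction 0.93 for ATF) against two anthropoid-like species
(0.38 and 0.47), three subjects per species, two hemispheres each,
analyzed at four K values — hence 24 OBI observations per species and
connection class. The pipeline recovers the planted ordering (lemur
highest), and the nested ANOVA attributes most variance to species.

Each observation is produced end to end: cohort simulation → species
averaging (right hemispheres mirrored onto a canonical index frame) →
NMF per K → screening by temporal×prefrontal (ATF) or
occipital×prefrontal (OTF) ROI-mean products → contralateral zeroing
and anatomical filtering (endpoint mass, parietal/occipital ceilings,
tract-core orientation) → merging of split components → dual regression
→ OBI.

## Command line

```bash
tractnmf simulate --config cohort.json --out sim/ --seed 1
tractnmf run --config cohort.json --out run/ --seed 1
tractnmf anova --input run/obi.tsv --value-col obi
```

`tractnmf run` writes per-stage outputs (Matrix Market matrices with
JSON sidecars, factor and OBI tables as TSV, ANOVA results as JSON) and
a hashed run manifest; `--resume` reuses hash-verified decompositions.

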