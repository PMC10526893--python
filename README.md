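# nodalmap

Automated spatial analysis of lymph node metastasis distributions in
head-and-neck cancer cohorts, for radiation oncologists and medical image
analysts studying elective neck target volume design.

Where do nodal metastases actually occur?  Elective neck irradiation today
treats whole anatomically defined nodal level compartments; refining those
volumes requires cohort-scale maps of where macroscopic disease sits.
`nodalmap` implements two complementary, fully automated analyses over
planning-CT segmentations:

1. **Level classification.**  Given a per-patient nodal GTV mask and an
   autosegmented label volume of the 20 cervical nodal levels (1a, 6a, 6b,
   7a and bilateral 1b, 2, 3, 4a, 4b, 5, 7b, 8), individual metastases are
   isolated by anisotropy-aware erosion, connected-component analysis and
   geodesic reconstruction.  Each node's geometric center **c** is assigned
   to the level containing it, or — when it falls outside every level
   contour — to the level *L* minimizing

   d(c, L) = min over voxels v in L of ‖c − x(v)‖₂  (mm),

   with no distance cutoff, so every node receives a level.  Multireader
   review tables (confirm / correct-to verdicts) are combined by strict
   majority voting to evaluate the automated calls and build a consensus
   distribution.

2. **Template mapping and density estimation.**  Node centers are mapped
   through per-patient spatial transforms (affine + dense displacement
   field, e.g. from deformable registration to a cohort-average template
   CT) into a common anatomy.  The cohort 3D probability density is then
   estimated by kernel density estimation with isotropic Gaussian kernels,

   f̂(x) = (1/n) Σᵢ K_σ(‖x − cᵢ‖_p),   K_σ(r) ∝ exp(−r²/2σ²),

   with bandwidth σ = 4 mm and p = 2 by default.  Integrating f̂ over a
   nearest-level partition of the template predicts per-level involvement
   proportions, which are compared with the observed distribution by a
   Pearson chi-squared goodness-of-fit test.

A synthetic phantom module generates neck-like cohorts (mirror-symmetric
ellipsoidal level compartments on an anisotropic CT-like grid, smoothly
deformed per patient, with spherical nodes planted at known levels and the
true patient→template transforms retained) so that every stage is testable
end to end without patient data.

## Worked example

The package embeds the level-involvement table and expert-review outcomes
of a published 193-patient definitive-chemoradiation cohort with 449 nodal
metastases (counts and correction lists only; no imaging):

```python
from nodalmap.assignment import aggregate
from nodalmap.reference_cohort import build_assignments, build_votes
from nodalmap.review import majority_distribution, reader_agreement

assignments = build_assignments()          # 449 automated node-level calls
votes = build_votes(assignments)           # 3 readers x 449 verdicts

consensus, agreement = majority_distribution(assignments, votes)
per_reader, _ = reader_agreement(assignments, votes)

dist = aggregate(assignments)
level2 = dist.counts["2_L"] + dist.counts["2_R"]
print(f"automated vs consensus agreement: {100 * agreement:.1f}%")
for reader, frac in per_reader.items():
    print(f"  {reader}: {100 * frac:.1f}% confirmed")
print(f"combined level 2 involvement: {100 * level2 / dist.n_total:.1f}%")
print(dist.to_frame().head(7).to_string(index=False))
```

prints

```
automated vs consensus agreement: 100.0%
  expert1: 98.9% confirmed
  expert2: 100.0% confirmed
  expert3: 99.8% confirmed
combined level 2 involvement: 59.0%
level  count  proportion     display
   1a      0    0.000000    0 (0.0%)
 1b_L     17    0.037862   17 (3.8%)
 1b_R     17    0.037862   17 (3.8%)
  2_L    128    0.285078 128 (28.5%)
  2_R    137    0.305122 137 (30.5%)
  3_L     52    0.115813  52 (11.6%)
  3_R     51    0.113586  51 (11.4%)
```

Each reader dissents on at most a handful of nodes and no node is
corrected by two readers, so the strict-majority consensus reproduces the
automated distribution exactly: the automated method classifies all 449
nodes correctly under the consensus reference, with level 2 carrying 59.0%
of the disease burden.

## Command line

The stages are also exposed as subcommands operating on plain files
(NIfTI volumes, CSV tables, JSON configs):

```sh
nodalmap phantom --seed 7 --patients 20 --out cohort/
nodalmap extract --manifest cohort/masks_manifest.csv --out nodes.csv
nodalmap assign  --nodes nodes.csv --manifest cohort/levels_manifest.csv \
                 --out assignments.csv --distribution distribution.csv
nodalmap map     --nodes nodes.csv --manifest cohort/transforms_manifest.csv \
                 --out mapped.csv
nodalmap density --mapped mapped.csv --template-levels cohort/template_levels.nii.gz \
                 --out-density density.nii.gz --out-predicted predicted.csv
nodalmap run     --config config.json        # everything, with provenance
```

## Scope

Level autosegmentation (the upstream segmentation model), intensity-based
registration and average-template construction are *inputs* to these
analyses, not part of the package; the registration backend is a pluggable
contract with built-in `identity` and `synthetic` (phantom ground-truth)
backends, and the external recipe (rigid → affine → B-spline-SyN,
cross-correlation, cost-function masking over tumor/nodal GTVs) documented
in `nodalmap.mapping`.  See `docs/methods.md` for the full methods note.
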