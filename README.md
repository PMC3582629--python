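# osteolacuna

3D morphometry of osteocyte lacunae and statistical classification of
fibrous entheses (muscle attachments) in cortical bone volumes.

## The problem

Muscle attachments (entheses) leave few surface scars on bone, but they
reorganize the tissue underneath: extrinsic collagen fibres embed in the
periosteal cortex, and the population of osteocyte lacunae — the cavities
housing bone cells, resolvable in sub-micron micro-CT — changes in
density, volume, shape and orientation. Quantifying those lacunar
signatures in equally sized "virtual cubes" of bone makes it possible to
tell two attachment types apart without destroying the specimen:

* **UMFE** — unmediated fibrous enthesis: tendon fibres penetrate the
  bone directly. Lacunae are denser, larger, *stellate* (star-shaped),
  and differently oriented than in reference bone.
* **PMFE** — periosteally mediated fibrous enthesis: fibres attach via
  the periosteum. Lacunae keep their volume and compact shape; only
  their orientation shifts, with mildly elevated density.

This package implements that entire analysis as a tested library, for
researchers working with segmented µCT volumes of cortical bone (extant
or fossil), plus a phantom generator so everything runs and validates
without scan data.

## What it computes

For each analysis cube (isotropic voxels, size *s* in µm):

1. **Extraction** — threshold (fixed or Otsu), 26-connectivity labeling,
   then two filters: components below a physical volume cutoff (default
   5 µm³) are segmentation noise; components touching any cube face are
   edge-cut lacunae. Both are removed before any counting.
2. **Morphometry** per lacuna *i*: volume `V_i = n_i · s³`; centroid;
   maximum length as the 3D Feret diameter
   `F_i = max_{p,q ∈ i} ‖p − q‖` with its direction binned to the
   dominant referential axis (X, Y or Z); solidity
   `n_i / |hull(i) ∩ ℤ³|` with `solidity < 0.6` ⇒ stellate.
3. **Region statistics** for an attachment cube A vs a reference cube R
   of identical size: density ratio `ρ_A/ρ_R`; two-sided Mann-Whitney
   test on the volume samples (exact null for small tie-free samples,
   normal approximation with tie and continuity correction otherwise);
   Pearson χ² homogeneity test on the axis-orientation counts; stellate
   fraction. Verdicts "similar"/"different" at α = 0.05.
4. **Classification**: orientation different ∧ volume different ∧
   stellate ⇒ UMFE; orientation different ∧ volume similar ∧ compact ⇒
   PMFE; anything else is indeterminate with per-criterion diagnostics.
   Density elevation is reported as supporting evidence, never a gate.
5. **Field maps** (qualitative): Gaussian-smoothed lacuna density,
   label-painted volume, and |direction| RGB orientation maps.

Volumes are read and written as multi-page TIFF, NRRD (raw encoding) or
raw + JSON sidecar, with voxel size and origin always carried along.

## Worked example

```sh
python examples/03_compare_regions.py
```

```
attachment cube: 148 lacunae (140,702 per mm³)
reference  cube: 59 lacunae (56,090 per mm³)
density ratio: ×2.51
orientation: different  (chi² = 104.4, df = 2, p = 2.14e-23)
volume: different  (Mann-Whitney U = 6422, p = 1.26e-07)
stellate: yes  (stellate fraction 0.99)
```

A muscle-attachment cube holds 2.5× the lacuna density of plain
metaphyseal bone; its lacunae are differently oriented (χ² rejects
homogeneity of the axis counts), significantly larger (rank-sum test),
and almost all star-shaped — the unmediated-enthesis signature. Feeding
this comparison to the classifier (`examples/04_classify_entheses.py`):

```
desmognathus_umfe        ×2.51  orientation different volume different stellate yes -> UMFE
desmognathus_pmfe        ×1.80  orientation different volume similar   stellate no  -> PMFE
eusthenopteron_area1     ×1.56  orientation different volume similar   stellate no  -> PMFE
```

The other examples build phantoms (`01`), measure single cubes from
rendered grayscale (`02`) and export field maps (`05`).

## Layout

```
src/osteolacuna/
  volume_io.py      TIFF/NRRD/raw volumes, region cubes
  synthetic.py      phantom generator, presets, grayscale renderer
  extraction.py     binarize, label, noise + edge-cut filters
  morphometry.py    per-lacuna measures, cube profiles
  comparison.py     rank-sum, chi-square, qq diagnostic, comparisons
  classification.py enthesis decision rules, reports
  maps.py           density / volume / orientation fields
  pipeline.py       end-to-end drivers
examples/           one narrative script per capability
tests/              pytest suite (unit, property, end-to-end)
docs/methods.md     model, parameters, numerical choices, limitations
```
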