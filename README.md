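# paleocanal

Micro-CT analysis of vascular-canal microarchitecture in cortical bone,
built for the case where the scan itself cannot be redistributed: a
calibrated synthetic-microstructure generator stands in for the imaging
data, and every downstream stage — CT-style degradation, segmentation,
3D canal-network morphometry, resolution certification, and voxel
micro-finite-element homogenization — is reusable on real volumes.

The package targets the canal system reported for a pterosaur wing-bone
phalanx imaged at 2 µm voxels: canals occupying ~16 % of tissue volume,
mean vascular diameter 10.6 ± 2.0 µm, ~113 canal profiles per mm² of
transverse section, 63 % branching / 37 % terminal skeleton nodes, a
predominantly longitudinal orientation, and a three-zone radial
organisation (pore-rich core, cellular middle network, sparse outer
rim).  Its mechanical side asks what the canal phase does to the
homogenised orthotropic constants E_r, E_θ, E_z, G_rθ, G_θz, G_rz and
ν_ij of the bone wall when the canals are treated as solid bone
(pore-free control), a water-like liquid, or effectively-zero-stiffness
gas.

Intended users: palaeohistologists and bone-biomechanics researchers who
want a reproducible, scriptable version of the canal-morphometry and
image-based-FE workflow, and anyone needing a ground-truthed phantom
generator to validate such pipelines.

## What is in the box

| module | role |
| --- | --- |
| `paleocanal.synthetic` | ground-truth canal networks, voxelization with porosity calibration, CT degradation (PSF blur, beam-hardening cupping, noise), line-grating IQI phantoms |
| `paleocanal.segmentation` | non-local-means denoise → automatic hysteresis threshold → despeckle → sub-resolution removal |
| `paleocanal.network` | 3D skeletonization, canal-graph extraction, porosity / diameter / frequency / node / orientation / radial-profile statistics |
| `paleocanal.resolution` | modulation curves of grating phantoms and the MTF-limit resolution estimate |
| `paleocanal.microfe` | matrix-free voxel hexahedral elasticity solver, three-phase material assignment, effective engineering constants |
| `paleocanal.phase_report` | solid/liquid/gas comparison table with reduction-positive percent changes |
| `paleocanal.pipeline`, `paleocanal.cli` | configuration-driven end-to-end runs with seed fan-out and provenance; thin `paleocanal` command |

## Worked example

```python
from paleocanal import (GeneratorParams, ImagingParams, sample_canal_network,
                        rasterize_network, simulate_ct)
from paleocanal.network import build_graph, network_stats, skeletonize
from paleocanal.segmentation import dice, segment

params = GeneratorParams(domain_size=(200.0, 200.0, 400.0), seed=7)
net = sample_canal_network(params)          # ground-truth centerline network
truth = rasterize_network(net, params)      # voxel labels, porosity-calibrated
gray = simulate_ct(truth, ImagingParams(seed=8))   # CT-like degradation

label, prov = segment(gray, resolution=4.0)
stats = network_stats(label, build_graph(skeletonize(label), label))
print(dice(label, truth), stats.porosity, stats.diameter_mean_um,
      stats.frequency_mm2, stats.branching_frac)
```

prints (exactly this, from `examples/segment_and_measure.py`):

```
auto thresholds: low=0.243 high=0.632
Dice vs truth: 0.9894
porosity:          0.1600
mean diameter:     9.53 um (canals only, pores excluded)
frequency:         114.0 mm^-2
branching nodes:   66.7 %
```

Dice 0.99 means the recovered canal phase overlaps the ground truth
almost voxel-for-voxel; porosity, transverse frequency, and the
branching fraction land on the generator's targets.  On this reduced
200-µm-wide domain the diameter and node statistics carry a few percent
of small-sample scatter; the full study conditions (400 × 400 × 800 µm,
three seeds) recover 15.6 % porosity, 10.8 µm mean diameter,
110 mm⁻² frequency and 61–64 % branching nodes.

The mechanical side (`examples/homogenize_phases.py`, 32×32×64-element
block with longitudinal canals at 16 % porosity):

```
      constant    solid   liquid      gas   reduction vs solid [%]
           E_r   20.000   12.302   11.683   liquid +38.5, gas +41.6
           E_t   20.000   11.785   11.211   liquid +41.1, gas +43.9
           E_z   20.000   16.400   16.339   liquid +18.0, gas +18.3
          ...
  mean_density    2.000    1.886    1.636   liquid +5.7, gas +18.2
```

Longitudinal canals carry axial load in parallel, so the axial modulus
E_z drops far less than the transverse moduli — the qualitative
signature this kind of microarchitecture is prized for: large density
savings at a modest axial stiffness cost.

Each script in `examples/` is a short, narrated capability demo:
generation, segmentation + morphometry, IQI resolution, phase
homogenization, and the full pipeline.

## Command line

```bash
paleocanal run --seed 1 --outdir out/            # full pipeline
paleocanal synth --seed 1 --outdir out/          # synthetic volume only
paleocanal segment gray.tif --resolution-um 4
paleocanal network labels.tif
paleocanal fe labels.tif --scenario liquid
paleocanal iqi                                   # simulated IQI resolution report
```

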