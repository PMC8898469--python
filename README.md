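# glymphkit

Quantitative analysis of glymphatic transport, solute drainage and
perivascular AQP4 expression in mouse models of multiciliated-cell (MCC)
ciliopathy — the measurement pipeline behind contrast-enhanced T1-mapping
MRI studies of CSF dynamics, rebuilt as a tested, reusable Python package
and exercised end to end on synthetic phantoms and micrographs with known
ground truth.

## Who this is for

Groups quantifying CSF-tracer transport with variable-flip-angle T1
mapping (e.g., after cisterna-magna infusion of Gd-DOTA in hydrocephalic
mouse models), and groups measuring perivascular AQP4 polarization in
immunofluorescence micrographs, who want the full chain — signal model,
B1+ correction, cluster volumetrics, vessel metrics, group statistics —
as auditable library code rather than scanner-side scripts.

## What it computes

**T1 mapping.** The spoiled gradient-recalled echo steady state at
nominal flip angle θ and transmit scale B1 is

    S(θ) = M0 · sin(B1·θ) · (1 − E1) / (1 − E1·cos(B1·θ)),   E1 = exp(−TR/T1).

B1 is estimated voxel-wise by the double-angle method from a (α, 2α)
long-TR pair: B1 = arccos(S_2α / 2S_α) / α. T1 and M0 then come from the
classical linearization — regress S/sin(B1·θ) on S/tan(B1·θ) by
unweighted least squares; the slope is E1, so T1 = −TR/ln(slope).
Degenerate fits are masked invalid, never clipped.

**Glymphatic/drainage volumetrics.** Voxels with 1 ms ≤ T1 ≤ 1700 ms
(inclusive) are classified as tracer-reached; their summed volume within
an ROI (brain parenchyma, nasal cavity, deep cervical lymph nodes) is the
transport or drainage metric, optionally normalized as a percentage of
total intracranial volume or brain volume. Morphometry is exact label
bookkeeping: voxel count × voxel volume.

**AQP4 microscopy.** Vessels are segmented by robust-background
thresholding, classified as capillaries (< 10 µm equivalent diameter) or
small vessels by a rule-based classifier, and measured for the
polarization index (object maximum over the median of a 32.5 µm radially
expanded background annulus) and the radial coefficient of variation
(SD/mean of per-wedge mean intensity over 8 angular sectors). A
stereological area-fraction fractionator (100 µm counting frames on a
randomly placed 200 µm grid, markers every 10 µm) estimates AQP4+ area.

**Statistics.** Welch two-sample t-tests with Satterthwaite df, computed
either from raw samples or directly from printed summaries (mean,
SD/SEM, n); a random-intercept mixed model (REML via 1-D profiling of
the variance ratio) for per-vessel data clustered by animal; Pearson
correlation; and a harness that reproduces published comparison tables
from their printed per-group summaries.

**Synthetic data.** `phantom` generates compartmented 3D brain phantoms
(parenchyma reached/unreached by tracer, ventricles, olfactory bulb,
nasal cavity, lymph nodes) with prescribed T1/M0/B1 fields and simulates
the VFA series and double-angle pair under Rician noise; `micrograph`
renders annular vessels with exact prescribed polarization index and
radial CV. Both carry full ground truth, so every estimator is validated
by round trip.

## Worked example

Reproducing a published morphometry comparison from its printed group
summaries (p73⁻/⁻ knockout vs wild-type littermates; volumes in mm³,
ventricle fraction in %):

```python
from glymphkit.datasets import P73_MORPHOMETRY
from glymphkit.stats import reproduce_group_table

t = reproduce_group_table(P73_MORPHOMETRY)
print(t[["variable", "difference_1dp", "se_1dp", "p"]].to_string(index=False))
```

```
              variable  difference_1dp  se_1dp            p
               tiv_mm3            91.0     9.1 2.117054e-07
  brain_parenchyma_mm3           108.9     8.7 2.102205e-08
         cv_volume_mm3           -21.9     2.9 2.467895e-04
cv_fraction_of_tiv_pct            -6.3     0.8 2.031905e-04
    olfactory_bulb_mm3            11.5     0.7 5.514222e-10
```

The differences are control-minus-mutant: the knockouts have ~91 mm³
smaller intracranial volume, ~22 mm³ larger ventricles and hypoplastic
olfactory bulbs, each with the Welch SE and p recomputed from the
printed means and SEMs.

Full in-silico measurement chain on a phantom:

```python
import numpy as np
from glymphkit import (AcquisitionProtocol, compute_b1_map, fit_t1_volume,
                       RoiSet, threshold_t1_cluster, glymphatic_pct)
from glymphkit.phantom import (default_phantom_spec, make_brain_phantom,
                               simulate_vfa_series, simulate_dam_pair)

proto = AcquisitionProtocol()          # TR 16 ms, angles 2-30 deg, DAM 70 deg
truth = make_brain_phantom(default_phantom_spec((64, 64, 64), seed=0))
vfa = simulate_vfa_series(truth, proto, noise_sd=0.002, seed=1)
s1, s2 = simulate_dam_pair(truth, proto, noise_sd=0.002, seed=2)

b1 = compute_b1_map(s1, s2, proto.dam_angle_deg)
rois = RoiSet.from_phantom(truth)
t1 = fit_t1_volume(vfa, b1, rois.label_volume > 0, proto)
par = rois.mask("parenchyma_reached") | rois.mask("parenchyma_unreached")
cluster = threshold_t1_cluster(t1, par, "parenchyma", rois.voxel_size_mm)
pct = glymphatic_pct(cluster, truth.tiv_mm3, "TIV")
print(f"glymphatic transport: {cluster.volume_mm3:.3f} mm^3 = {pct:.1f}% of TIV")
print(f"ground truth reached: {truth.true_volumes_mm3['parenchyma_reached']:.3f} mm^3")
```

```
glymphatic transport: 116.844 mm^3 = 77.3% of TIV
ground truth reached: 116.617 mm^3
```

At this noise level the fitted tracer-window volume lands within 0.2% of
the generator's reached-compartment volume (exactly equal in the
noiseless limit).

A CLI mirrors the library (`glymphkit simulate mri`, `glymphkit fit-t1`,
`glymphkit quantify glymphatics|aqp4`, `glymphkit stats
welch|table|mixed`, `glymphkit run-all`); see `glymphkit --help`.

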