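#!/usr/bin/env python
"""Generate the synthetic study inputs: AVF geometries, CT volumes, waveforms.

Builds the day-7 and day-21 idealized end-to-side AVF models, exports their
lumen surfaces (STL) and contrast-CT-like volumes (NIfTI) to scratch/ (binary
artifacts), and writes the exact ground-truth sidecars and Doppler-style
waveform tables to results/inputs/.
"""

from pathlib import Path

from avf_hemoflow import io as hio
from avf_hemoflow.synthgen import (AVFShapeParams, make_avf_geometry,
                                   make_waveform, rasterize_to_ct)

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results" / "inputs"
SCRATCH = ROOT / "scratch" / "inputs"
RES.mkdir(parents=True, exist_ok=True)
SCRATCH.mkdir(parents=True, exist_ok=True)

# Doppler-like acquisition settings: heart rate 450/min; mean peak velocities
# chosen so the AVF site carries the day-7 flow (1.33 mL/min) and roughly
# doubles by day 21, with murine-arterial pulsatility.
WAVES = {
    "day7_avf": dict(mean_velocity=167.0, pulsatility_index=1.5),
    "day21_avf": dict(mean_velocity=253.0, pulsatility_index=1.5),
}

for day, params in [("day7", AVFShapeParams.day7()),
                    ("day21", AVFShapeParams.day21())]:
    geom = make_avf_geometry(params)
    surf = geom.surface()
    hio.save_surface_stl(surf, SCRATCH / f"{day}_lumen.stl")
    hio.save_ground_truth_json(geom, RES / f"{day}_ground_truth.json")
    vol = rasterize_to_ct(geom, noise_sd=30.0, seed=7 if day == "day7" else 21)
    hio.save_volume(vol, SCRATCH / f"{day}_ct.nii.gz")
    print(f"{day}: surface {len(surf.faces)} faces (watertight={surf.is_watertight}), "
          f"volume {vol.shape} at {vol.spacing[0]} mm voxels")

for name, kw in WAVES.items():
    wf = make_waveform(heart_rate=450.0, n_samples=128, shape="pulse", **kw)
    hio.save_waveform_csv(wf, RES / f"{name}_waveform.csv")
    print(f"{name}: period {wf.period:.4f} s, mean {wf.mean():.1f} mm/s")

print(f"wrote ground truth + waveforms to {RES}, binary volumes/surfaces to {SCRATCH}")
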