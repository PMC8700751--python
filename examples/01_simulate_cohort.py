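"""Generate a small labeled cohort of synthetic color-Doppler cines.

Each case directory holds the rendered RGB frames (frames.tif), the
calibration sidecar with the colorbar, the ROI mask, and an analytic
ground-truth sidecar recording the six flow parameters of the rendered
velocity field.
"""

import tempfile
from pathlib import Path

from dopplerquant import generate_cohort

out = Path(tempfile.mkdtemp()) / "cohort"
manifest = generate_cohort(n_malignant=2, n_inflammatory=2, seed=1, out_dir=out)

print(f"wrote {len(manifest)} cases under {out}\n")
print(manifest.round(3).to_string(index=False))
print(
    "\ntrue_tfv/true_tpi [cm/s] and true_tri are the tissue-perfusion ground"
    "\ntruth; true_fv [cm/s], true_ri, true_volf [mL/s] describe the main"
    "\nvessel; true_angle_deg is its Doppler angle to the beam.  Malignant"
    "\ncases show lower flow and a resistive index near 1 (diastolic no-flow)."
)
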