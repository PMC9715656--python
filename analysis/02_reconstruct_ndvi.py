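"""Reconstruct the NDVI time series and quantify the gain in fidelity.

Finding: QA masking + gap interpolation + upper-envelope smoothing roughly
halves the RMSE against the noiseless truth compared to the contaminated
input (10% negative outliers, 2% Gaussian noise, snow dips).
"""

import json

import numpy as np

from _common import SEED, outdir
from vegwater import GeneratorConfig
from vegwater.preprocess import reconstruct_cube
from vegwater.synthetic import generate_ndvi_cube

out = outdir("02_reconstruction")
cube, truth = generate_ndvi_cube(GeneratorConfig(seed=SEED))
rec = reconstruct_cube(cube)

rmse_contaminated = float(np.sqrt(np.mean((cube.ndvi - truth.clean_ndvi) ** 2)))
rmse_reconstructed = float(np.sqrt(np.mean((rec.smoothed - truth.clean_ndvi) ** 2)))
stats = {
    "mask_fraction": round(rec.mask_fraction, 4),
    "rmse_contaminated": round(rmse_contaminated, 4),
    "rmse_reconstructed": round(rmse_reconstructed, 4),
    "improvement_pct": round(100 * (1 - rmse_reconstructed
                                    / rmse_contaminated), 1),
    "skipped_pixels": int(rec.skipped.sum()),
}
(out / "reconstruction_stats.json").write_text(
    json.dumps(stats, indent=2, sort_keys=True) + "\n")

print("masked composites: %.1f%%" % (100 * stats["mask_fraction"]))
print("RMSE vs truth: contaminated %.4f -> reconstructed %.4f (-%.0f%%)"
      % (rmse_contaminated, rmse_reconstructed, stats["improvement_pct"]))
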