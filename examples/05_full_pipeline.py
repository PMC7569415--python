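"""Run the full demo pipeline and show where everything lands.

Simulates an eight-line panel, quantifies, extracts metrics, predicts the
cascade panel, infers phosphatase activity and runs the statistics, all
into one run directory with a manifest.
"""

import json
from pathlib import Path

from erk_rescale.pipeline import RunConfig, run_pipeline

out = Path("scratch/example_run")
manifest = run_pipeline(RunConfig(seed=0, n_cells=240), out)

print("stage counts:")
print(json.dumps(manifest["stages"], indent=2, sort_keys=True))
print("\noutputs:")
for f in sorted(out.iterdir()):
    print(" ", f.name)
print("\nre-running with the same config and seed reproduces every file "
      "byte for byte; the manifest records the config hash and seeds.")
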