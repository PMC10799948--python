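"""Run the whole configured pipeline on one synthetic session.

Executes behavior summary, HFA + ramping, encoding selection, spectral
slopes, theta nesting, connectivity and state-space decoding, writing CSV
and JSON artifacts plus a machine-readable summary.
"""

import json

from ieegdyn import pipeline

out = pipeline.run(
    {
        "sim": {"n_trials_per_context": 30, "n_channels": {"pfc": 3, "motor": 3}},
        "selection": {"n_perm": 100},
        "connectivity": {"n_perm": 100},
        "decode": {"n_perm": 10},
        "seed": 8,
    },
    out_dir="scratch/pipeline_demo",
)
summary = json.loads((out / "summary.json").read_text())
print(json.dumps(summary["stages"], indent=1, default=str))
print("artifacts in:", out)
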