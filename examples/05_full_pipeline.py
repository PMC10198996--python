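"""Run every stage end-to-end on the default synthetic fixture.

Equivalent to `novostart make-fixture` followed by `novostart run`; prints
the summary the pipeline writes to summary.json.
"""

import json
import tempfile

from novostart.pipeline import RunConfig, run_all
from novostart.synthetic_data import FixtureConfig, make_fixture

with tempfile.TemporaryDirectory() as tmp:
    paths, truth = make_fixture(FixtureConfig(seed=0), f"{tmp}/fixture")
    cfg = RunConfig.from_fixture(paths, truth, f"{tmp}/out", seed=0)
    summary = run_all(cfg)
    print(json.dumps(summary, indent=1, default=float))
    # startgain: SNV calls and occupancy-filter attrition; species: fixed
    # human-specific start codons (total / analyzable / CUG-origin); ribo:
    # occupancy folds and test p-values; kaks: omega fits and LRT p-values.
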