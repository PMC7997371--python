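#!/usr/bin/env python
"""Initial guess path from the end points only.

Morphs the closed reference into the wide-open end point under the model
energy (restrained stepwise minimization), resamples the chain into an
equispaced frame set, and adapts λ to the mean interframe displacement.
This is the path built *before* any information from the sampled
trajectories is used; 05_validate_projection.py shows its weakness.
"""

import json
import logging
from pathlib import Path

from pathmetad.pipeline import demo_config, stage_build_guess_path

logging.basicConfig(level=logging.INFO, format="%(message)s")

WORKDIR = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def main(seed: int = 7):
    cfg = demo_config(seed=seed)
    out = stage_build_guess_path(cfg, WORKDIR)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
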