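#!/usr/bin/env python
"""Refined transition path through the cluster centroids.

Orders the top centroids along the guess path by their S value, brackets
them with the closed reference and the wide-open end point, bridges
consecutive waypoints by restrained morphing, and resamples the
concatenated chain into an equispaced frame set with λ re-adapted.
"""

import json
import logging
from pathlib import Path

from pathmetad.pipeline import demo_config, stage_refine_path

logging.basicConfig(level=logging.INFO, format="%(message)s")

WORKDIR = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def main(seed: int = 7):
    cfg = demo_config(seed=seed)
    out = stage_refine_path(cfg, WORKDIR)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
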