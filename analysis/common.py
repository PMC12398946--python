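"""Shared helpers for the numbered analysis drivers.

The study-condition ensemble (21 x 2000 frames, seed 2026) is generated
once and cached under scratch/ so the drivers can be run in sequence
without regenerating; results tables go to results/.
"""

from __future__ import annotations

import pickle
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 2026


def get_ensemble():
    from putachannel.synthetic import SyntheticConfig, generate_ensemble

    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cache = SCRATCH / f"ensemble_seed{SEED}.pkl"
    if cache.exists():
        with cache.open("rb") as fh:
            return pickle.load(fh)
    cfg = SyntheticConfig(seed=SEED)
    ens, truth = generate_ensemble(cfg)
    with cache.open("wb") as fh:
        pickle.dump((cfg, ens, truth), fh)
    return cfg, ens, truth
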