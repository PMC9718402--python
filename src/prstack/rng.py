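"""Named, independent random substreams derived from one global seed.

Each pipeline stage draws from its own stream so changing one stage's
internals never perturbs another stage's draws.
"""

from __future__ import annotations

import numpy as np

_STREAMS = {
    "model": 0,        # variant scheme: MAFs, alleles, positions
    "genotypes": 1,    # target-cohort haplotypes
    "phenotypes": 2,   # liability noise, ages, sexes, prevalent flags
    "effects": 3,      # causal SNP choice and true betas
    "gwas": 4,         # independent GWAS cohort (genotypes + phenotypes)
    "design": 5,       # matched sampling and train/test split
    "stacking": 6,     # cross-validation fold assignment
    "test_design": 7,  # unmatched testing-control draw
}


def substream(seed: int, name: str) -> np.random.Generator:
    if name not in _STREAMS:
        raise KeyError(f"unknown random substream {name!r}")
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],))
    )
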