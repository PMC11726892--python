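import numpy as np
import pandas as pd
import pytest

from rremtools import simulate as sim


@pytest.fixture(scope="session")
def genome_small():
    return sim.generate_genome(seed=1, n_chromosomes=1,
                               chromosome_length=100_000, island_count=5)


@pytest.fixture(scope="session")
def design_two_groups():
    return sim.StudyDesign(groups=("WT", "DKO"),
                           effects={"DKO": [sim.EffectSpec(0.02, "p_h", 0.2)]},
                           seed=7)


@pytest.fixture(scope="session")
def study_small(genome_small, design_two_groups):
    """Genome + truth + fragments shared by calling/differential tests."""
    truths, ledger = sim.generate_truth(genome_small, design_two_groups)
    fragments = sim.digest_genome(genome_small)
    return {"genome": genome_small, "design": design_two_groups,
            "truths": truths, "ledger": ledger, "fragments": fragments}


def betabin_replicates(rng, p, depth_mean, n_reps, phi, contig="chr1",
                       spacing=50):
    """Beta-binomial replicate count tables for differential tests.

    p is the per-site mean level; phi the beta-binomial dispersion.
    Returns a list of count DataFrames in the calling-module layout.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    pos = np.arange(n) * spacing
    if phi > 0:
        s = 1.0 / phi - 1.0
        a, b = np.clip(p * s, 1e-6, None), np.clip((1 - p) * s, 1e-6, None)
    out = []
    for _ in range(n_reps):
        pi = rng.beta(a, b) if phi > 0 else p
        d = rng.poisson(depth_mean, n).clip(1)
        m = rng.binomial(d, np.clip(pi, 0, 1))
        out.append(pd.DataFrame({"contig": contig, "pos": pos,
                                 "n_modified": m, "n_unmodified": d - m,
                                 "depth": d}))
    return out
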