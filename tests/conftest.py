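import numpy as np
import pandas as pd
import pytest

import lipidpoe as lp


@pytest.fixture(scope="session")
def small_sim():
    """Small but fully featured synthetic dataset with a strong maternal effect."""
    cfg = lp.SimConfig(seed=11, n_families=300, n_snps=8, n_species=40,
                       effects=(lp.EffectSpec(0, 0, 1.5, "maternal-only"),),
                       cohort_fractions=(0.4, 0.6))
    return lp.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def toy_plsda():
    """Frozen 8-sample, 4-species matrix with a class-separating species."""
    rng = np.random.default_rng(42)
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
    X = rng.normal(size=(8, 4))
    X[:, 0] += 2.0 * y
    return X, y


def all_trio_configs():
    """All 27 complete trio genotype configurations."""
    return [(f, m, c) for f in (0, 1, 2) for m in (0, 1, 2) for c in (0, 1, 2)]


def brute_force_transmission(father, mother, child):
    """Enumerate gamete pairs producing the child genotype.

    Returns (paternal, maternal, consistent) with 'uninformative' when
    several distinct pairs survive for that parent.
    """
    def gametes(dosage):
        return {0: [0], 1: [0, 1], 2: [1]}[dosage]

    pairs = [(p, m) for p in gametes(father) for m in gametes(mother)
             if p + m == child]
    if not pairs:
        return "unknown", "unknown", False
    pats = {p for p, _ in pairs}
    mats = {m for _, m in pairs}
    allele = {0: "A", 1: "a"}
    pat = allele[pats.pop()] if len(pats) == 1 else "uninformative"
    mat = allele[mats.pop()] if len(mats) == 1 else "uninformative"
    return pat, mat, True
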