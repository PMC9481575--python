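import numpy as np
import pytest

import chromopull as cp


@pytest.fixture(scope="session")
def wlc_lambda():
    """Fixed DNA elasticity of the lambda template (Lp 50 nm, S 1500 pN)."""
    return cp.WLCParams(contour_bp=cp.LAMBDA_DNA_BP)


@pytest.fixture(scope="session")
def lambda_fiber_params():
    """Half-saturated lambda fiber: 125 nucleosomes, 49 folded."""
    return cp.FiberParams(
        k_fiber=0.25, dG1_kT=20.0, dG2_kT=4.5,
        N_total=125, N_folded=49, NRL_bp=197.0, L_DNA_bp=cp.LAMBDA_DNA_BP,
    )


@pytest.fixture(scope="session")
def lambda_fiber_trace():
    """One seeded half-saturated lambda-fiber stretching trace."""
    return cp.generate_trace(cp.FiberSpec(n_octamers=125, seed=42))


@pytest.fixture(scope="session")
def small_fiber_spec():
    """A 40-nucleosome fiber on a 12 kbp template (fast to simulate/fit)."""
    return cp.FiberSpec(n_octamers=40, L_DNA_bp=12_000, seed=0)


def random_valid_fiber_params(rng):
    """Draw one random FiberParams in the physically realistic regime.

    Stiffness 0.18-0.55 pN/nm, NRL 162-210 bp, tens of folded nucleosomes
    (or none): the regime of reconstituted fibers, where unstacking always
    gains extension under tension.
    """
    n_total = int(rng.integers(20, 150))
    n_folded = 0 if rng.random() < 0.15 else int(rng.integers(15, n_total + 1))
    L = int(n_total * 250 + rng.integers(2000, 30000))
    return cp.FiberParams(
        k_fiber=float(rng.uniform(0.2, 0.55)),
        dG1_kT=float(rng.uniform(5.0, 35.0)),
        dG2_kT=float(rng.uniform(1.0, 10.0)),
        N_total=n_total,
        N_folded=n_folded,
        NRL_bp=float(rng.uniform(162, 210)),
        L_DNA_bp=L,
    )
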