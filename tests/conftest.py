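"""Shared fixtures and PWM construction helpers."""

import numpy as np
import pytest

from chipmotif.pwm import PWM


def consensus_pwm(consensus: str, strong: float = 0.9, name: str = "p") -> PWM:
    """PWM with probability ``strong`` on the consensus letter per column."""
    probs = np.full((4, len(consensus)), (1.0 - strong) / 3.0)
    for j, base in enumerate(consensus):
        probs["ACGT".index(base), j] = strong
    return PWM(name, probs)


def random_pwm(rng: np.random.Generator, width: int, alpha: float = 0.5,
               name: str = "rand") -> PWM:
    """Random PWM with Dirichlet(alpha) columns (smaller alpha = sharper)."""
    probs = rng.dirichlet(np.full(4, alpha), size=width).T
    probs = np.clip(probs, 1e-3, None)
    probs /= probs.sum(axis=0)
    return PWM(name, probs)


@pytest.fixture(scope="session")
def planted_motif() -> PWM:
    """The canonical planted test motif: width 8, ~11 bits."""
    return consensus_pwm("TGACTCAT", 0.9, name="planted")


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Compile the numba kernels once so timing comparisons are clean."""
    from chipmotif import discover, simulate

    records, _ = simulate.sim_sequences(12, 40, rng=0)
    pwm0 = discover.dyad_to_pwm(discover.SpacedDyad("ACG", 1, "TGA"))
    discover.em_refine(pwm0, records, max_iter=2)
    discover.fitness(pwm0, records, p_threshold=0.5)
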