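import numpy as np
import pytest

from tetrachroma.synth import SyntheticCladeSpec, simulate_clade
from tetrachroma.visual import build_visual_system


@pytest.fixture(scope="session")
def uvs():
    return build_visual_system("UVS")


@pytest.fixture(scope="session")
def vs_violet():
    return build_visual_system("VS")


@pytest.fixture(scope="session")
def small_clade():
    """A 12-species redistributed synthetic clade (frozen seed)."""
    return simulate_clade(SyntheticCladeSpec(n_species=12, seed=7))


@pytest.fixture(scope="session")
def one_sided_clade():
    return simulate_clade(
        SyntheticCladeSpec(n_species=12, seed=7, assignment_model="one_sided")
    )


def random_smooth_spectra(n, seed):
    """Random smooth synthetic reflectances, analytic on any grid.

    Returns a list of callables wl -> reflectance so fine-grid oracles can
    evaluate the same spectrum off the canonical grid.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        kind = rng.integers(3)
        if kind == 0:  # sigmoid
            c, w, hi, lo = rng.uniform(400, 620), rng.uniform(15, 60), rng.uniform(0.3, 1.0), rng.uniform(0, 0.1)
            out.append(lambda wl, c=c, w=w, hi=hi, lo=lo: lo + (hi - lo) / (1 + np.exp(-(wl - c) / w)))
        elif kind == 1:  # gaussian bump
            c, w, hi, lo = rng.uniform(330, 670), rng.uniform(20, 80), rng.uniform(0.2, 0.9), rng.uniform(0, 0.1)
            out.append(lambda wl, c=c, w=w, hi=hi, lo=lo: lo + (hi - lo) * np.exp(-((wl - c) ** 2) / (2 * w**2)))
        else:  # smooth cosine ripple
            a, ph, base = rng.uniform(0.05, 0.3), rng.uniform(0, 2 * np.pi), rng.uniform(0.2, 0.6)
            out.append(lambda wl, a=a, ph=ph, base=base: base + a * np.cos(2 * np.pi * (wl - 300) / 400 + ph))
    return out
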