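import numpy as np
import pytest

from pricklemap.simulate import SimConfig, make_founder, self_cross


@pytest.fixture(scope="session")
def small_family():
    """A 40-progeny selfed family on a 2 Mb chromosome (triplex founder)."""
    cfg = SimConfig(
        chrom_length=2_000_000,
        genetic_length=0.5,
        n_snps=800,
        causal_pos=1_000_000,
        n_progeny=40,
        seed=11,
    )
    rng = np.random.default_rng(cfg.seed)
    founder = make_founder(cfg, rng)
    pop = self_cross(founder, rng=rng)
    return cfg, pop


def write_lines(path, text):
    path.write_text(text.lstrip("\n"))
    return str(path)
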