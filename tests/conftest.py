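import numpy as np
import pytest

from palaeokit import simulate as sim


@pytest.fixture(scope="session")
def small_ref():
    """A 2 kb random reference, shared across read-level tests."""
    return sim.random_reference(2000, seed=42, name="mt_ref")


@pytest.fixture(scope="session")
def demo_panel():
    """A scaled-down SNP capture panel with all three chromosome classes."""
    import pandas as pd
    from palaeokit.io import SnpPanel

    rng = np.random.default_rng(0)
    rows = []
    for chrom, n in [("1", 2000), ("2", 2000), ("X", 200), ("Y", 130)]:
        pos = np.sort(rng.choice(10_000_000, size=n, replace=False))
        rows.extend((chrom, int(p), "A", "G") for p in pos)
    return SnpPanel(targets=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]))
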