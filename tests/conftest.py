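import numpy as np
import pandas as pd
import pytest

from rescuekit.rescue import DEGTable


def make_deg_table(rows, name="test", universe_size=None):
    """rows: iterable of (gene_id, log2fc, pp)."""
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "pp"])
    return DEGTable(name, df, universe_size=universe_size)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def paper_shaped_sets():
    """Signed gene sets with the study-scale sizes and overlaps.

    Constructed from synthetic identifiers so classification and enrichment
    argument plumbing can be checked against the published counts:
    mutant 851 up / 558 down, treatment 1862 up / 2092 down, overlaps
    259 (up/down), 85 (down/up), 59 (up/up), 65 (down/down), universe 14488.
    """
    from rescuekit.rescue import SignedGeneSets

    ids = iter(f"g{i:05d}" for i in range(1, 20001))

    def take(n):
        return frozenset(next(ids) for _ in range(n))

    ru, rd, fu, fd = take(259), take(85), take(59), take(65)
    mut_only_up, mut_only_down = take(851 - 259 - 59), take(558 - 85 - 65)
    treat_only_up, treat_only_down = take(1862 - 85 - 59), take(2092 - 259 - 65)
    mut = SignedGeneSets(up=ru | fu | mut_only_up, down=rd | fd | mut_only_down)
    treat = SignedGeneSets(up=rd | fu | treat_only_up, down=ru | fd | treat_only_down)
    return mut, treat
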