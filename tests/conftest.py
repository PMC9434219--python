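import numpy as np
import pytest

import phenogp as pg
from phenogp import preprocess as pp


@pytest.fixture(scope="session")
def small_family():
    """One simulated family at desk scale with ground truth."""
    cfg = pg.SimConfig(n_individuals=60, n_markers=300, n_qtl=12, seed=7)
    return cfg, *pg.simulate_family(cfg)


@pytest.fixture(scope="session")
def qc_family(small_family):
    """The small family after missingness injection and full QC."""
    cfg, g, phen, tr, truth = small_family
    gm = pg.inject_missingness(g, cfg)
    g2, phen2, tr2, report = pg.qc_pipeline(gm, phen, tr)
    return pp.FamilyData(g2, phen2, tr2), report, truth


@pytest.fixture(scope="session")
def two_families():
    """A small two-family study (shared parent), QC'd."""
    cfg = pg.SimConfig(n_individuals=50, n_markers=250, n_qtl=10, seed=13)
    study = pg.simulate_study(cfg, sizes=(50, 64), family_ids=("A", "B"))
    fams = {}
    truths = {}
    for fid, (g, phen, tr, truth) in study.items():
        gm = pg.inject_missingness(g, cfg)
        g2, phen2, tr2, _ = pg.qc_pipeline(gm, phen, tr)
        fams[fid] = pp.FamilyData(g2, phen2, tr2)
        truths[fid] = truth
    return fams, truths


@pytest.fixture
def rng():
    return np.random.default_rng(123)
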