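"""Shared fixtures: fixture germlines/scaffolds, profiles estimated from
synthetic repertoires, and a small designed library.

Expensive fixtures are session-scoped; everything is seeded so the whole
suite is deterministic.
"""

import pytest

import cdrforge as cf
from cdrforge.regions import CdrRegion, Chain

GERMLINE_REGIONS = ["H1", "H2", "K1", "K2", "K3", "L1", "L2", "L3"]


@pytest.fixture(scope="session")
def germlines_raw() -> cf.GermlineCDRSet:
    return cf.germline_fixture()


@pytest.fixture(scope="session")
def germlines(germlines_raw) -> cf.GermlineCDRSet:
    """PTM-sanitized germline set (DG/NG replaced by SG), as used for design."""
    return cf.sanitize_germline(germlines_raw)


@pytest.fixture(scope="session")
def scaffolds() -> dict[Chain, cf.FrameworkScaffold]:
    return cf.scaffold_fixture()


@pytest.fixture(scope="session")
def bundle(germlines) -> cf.ProfileBundle:
    """Profiles estimated from moderate synthetic repertoires (n=3000)."""
    b = cf.ProfileBundle()
    for lbl in GERMLINE_REGIONS:
        region = CdrRegion.from_label(lbl)
        spec = cf.make_repertoire_spec(region, germlines, n=3000, seed=1)
        rep = cf.generate_natural_repertoire(spec, germlines)
        b.shm[region] = cf.build_shm_profile(rep, germlines)
        if region.is_light_cdr3:
            b.l3_tails[region] = cf.build_l3_tail_profile(rep)
    h3_rep = cf.generate_h3_repertoire(cf.make_h3_truth(seed=1), 4000, seed=2)
    b.h3 = cf.build_h3_profile(h3_rep)
    return b


@pytest.fixture(scope="session")
def designs(bundle, scaffolds) -> dict[CdrRegion, cf.DesignedRepertoire]:
    """A small designed library (300 sequences per region)."""
    config = cf.DesignConfig(targets={r: 300 for r in CdrRegion}, seed=9)
    return cf.design_library(config, bundle, scaffolds)
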