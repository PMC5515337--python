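import pytest

from felclone.breakpoints import make_exclusion_regions
from felclone.datamodel import Breakpoint
from felclone.io import (load_centromeres, load_cohort_a, load_cohort_b,
                         load_five_lesion_case, load_genome)


@pytest.fixture(scope="session")
def cohort_a():
    return load_cohort_a()


@pytest.fixture(scope="session")
def cohort_b():
    return load_cohort_b()


@pytest.fixture(scope="session")
def five_lesion_case():
    return load_five_lesion_case()


@pytest.fixture(scope="session")
def five_lesion_by_lesion(five_lesion_case):
    by = {}
    for m in five_lesion_case["mutations"]:
        by.setdefault(m.lesion_id, []).append(m)
    return by


@pytest.fixture(scope="session")
def default_exclusions():
    return make_exclusion_regions(load_genome(), load_centromeres())


def make_breakpoints(positions, chrom="chr1", left_cn=2, right_cn=1):
    """Breakpoint list from bare positions (or (chrom, pos) tuples)."""
    out = []
    for p in positions:
        c, pos = p if isinstance(p, tuple) else (chrom, p)
        out.append(Breakpoint(chrom=c, boundary_pos=int(pos),
                              left_cn=left_cn, right_cn=right_cn))
    return out
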