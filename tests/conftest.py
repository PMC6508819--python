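import numpy as np
import pytest

from homeokit.seqcore import DeletionSpec, NucSeq
from homeokit.synthetic_data import GenotypeConfig, apply_genotype, make_paralogs

# The two published query strings and their reverse complements (the
# deletion probe lacks one T of the TT run 32 nt in).
REF_PROBE = "CCATAACTAGAGCGAAGAAGACAGAACTAATGTTGAAGC"
REF_PROBE_RC = "GCTTCAACATTAGTTCTGTCTTCTTCGCTCTAGTTATGG"
ALT_PROBE = "CCATAACTAGAGCGAAGAAGACAGAACTAATGTGAAGC"
ALT_PROBE_RC = "GCTTCACATTAGTTCTGTCTTCTTCGCTCTAGTTATGG"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def homeologs():
    """Three ~95%-identical paralogs with three diploid copies per locus."""
    return make_paralogs(3, 2000, 0.05, rng=424242, ids=["Ch08", "Ch13", "Ch20"],
                         copies_per_paralog=3)


@pytest.fixture(scope="session")
def locus_variant(homeologs):
    """A 1-bp deletion site in Ch20 chosen where probe design succeeds."""
    from homeokit.errors import ProbeUniquenessError
    from homeokit.probe_design import design_probes

    for pos in range(900, 1100):
        spec = DeletionSpec(pos, 1)
        try:
            design_probes(homeologs, "Ch20", spec)
        except ProbeUniquenessError:
            continue
        return spec
    raise RuntimeError("no designable variant site found in fixture set")


@pytest.fixture(scope="session")
def probes(homeologs, locus_variant):
    from homeokit.probe_design import design_probes

    return design_probes(homeologs, "Ch20", locus_variant)


@pytest.fixture(scope="session")
def allele_pool_4of6(homeologs, locus_variant):
    """Target-locus allele pool at deletion fraction 4/6."""
    cfg = GenotypeConfig.from_label("(-,-,TT)")
    return apply_genotype(homeologs, "Ch20", locus_variant, cfg)


def naive_scan(haystack: str, needle: str) -> list[int]:
    """Character-by-character substring scan (independent oracle)."""
    hits = []
    n, m = len(haystack), len(needle)
    for i in range(n - m + 1):
        for j in range(m):
            if haystack[i + j] != needle[j]:
                break
        else:
            hits.append(i)
    return hits


def naive_revcomp(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(s))
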