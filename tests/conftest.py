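import numpy as np
import pytest

from spacerseq import (SiteDistribution, WT_REPEAT, build_genome_surrogate,
                       build_minimal_linear_target, build_pcrispr,
                       build_plasmid_locus, default_prespacer)
from spacerseq.locus import RulerElement


@pytest.fixture(scope="session")
def wt_repeat():
    return WT_REPEAT


@pytest.fixture(scope="session")
def ruler():
    return RulerElement()


@pytest.fixture(scope="session")
def prespacer():
    return default_prespacer()


@pytest.fixture(scope="session")
def pcrispr():
    """(name, sequence, annotation) of the synthetic CRISPR plasmid."""
    return build_pcrispr()


@pytest.fixture(scope="session")
def linear_target():
    return build_minimal_linear_target()


@pytest.fixture(scope="session")
def genome():
    return build_genome_surrogate()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def brute_force_hits(query, reference, max_mismatches, circular=False):
    """Independent oracle: exhaustive Hamming scan over offsets and strands.

    Returns the best-stratum {(offset, strand, mismatches)} set, mirroring
    the aligner's contract but computed by per-character comparison.
    """
    comp = dict(zip("ACGTN", "TGCAN"))
    rc = "".join(comp[c] for c in reversed(query))
    ref = reference + (reference[: len(query) - 1] if circular else "")
    n_starts = len(reference) if circular else len(reference) - len(query) + 1
    raw = []
    for strand, q in (("+", query), ("-", rc)):
        for off in range(n_starts):
            mm = 0
            for a, b in zip(q, ref[off: off + len(q)]):
                if a != b or a == "N" or b == "N":
                    mm += 1
            if mm <= max_mismatches:
                raw.append((off % len(reference), strand, mm))
    if not raw:
        return set()
    best = min(mm for _, _, mm in raw)
    return {t for t in raw if t[2] == best}
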