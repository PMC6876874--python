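import numpy as np
import pytest

from redigest import (
    REGISTRY,
    PAPER_PANEL,
    RegionSet,
    get_panel,
)
from redigest.motifs import IUPAC_CODES, is_palindromic, reverse_complement_motif


@pytest.fixture(scope="session")
def paper_panel():
    """The four-enzyme chromatin-fragmentation panel (AluI, SaqAI, MvaI, HinfI)."""
    return get_panel(PAPER_PANEL)


@pytest.fixture(scope="session")
def registry_panel():
    return list(REGISTRY.values())


def brute_force_scan(seq, panel, both_strands=True):
    """Naive position-by-position base-set containment scanner.

    Independent of the production scanner: checks every window of every
    motif (and, for non-palindromic motifs on both strands, the reverse
    complement) by direct set membership.  N in the sequence matches no code.
    """
    seq = seq.upper()
    hits = []
    for enz in panel:
        motifs = {enz.recognition: "+"}
        if both_strands and not is_palindromic(enz.recognition):
            motifs.setdefault(reverse_complement_motif(enz.recognition), "-")
        found = {}
        for motif, strand in sorted(motifs.items(), key=lambda kv: kv[1]):
            sets = [IUPAC_CODES[c] for c in motif]
            for p in range(len(seq) - len(motif) + 1):
                if all(seq[p + i] in sets[i] for i in range(len(motif))):
                    found.setdefault(p, strand)
        hits.extend((p, enz.name, s) for p, s in found.items())
    return sorted(hits)


@pytest.fixture()
def toy_track():
    """Three-class labelled segmentation of a 3,000 bp chromosome."""
    rs = RegionSet("states")
    rs.add("chr1", 0, 1000, "S1")
    rs.add("chr1", 1000, 2000, "S2")
    rs.add("chr1", 2000, 3000, "S3")
    rs.sort()
    return rs


@pytest.fixture()
def rng():
    return np.random.default_rng(20250920)
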