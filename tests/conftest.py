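import itertools

import pytest

from monodigest.digestion import CleavageRule, DigestConfig, Peptide, find_sites
from monodigest.fasta_io import Proteome, ProteinRecord


def brute_force_digest(accession, sequence, rule, config):
    """Independent oracle: enumerate all substrings with cleavage-valid
    boundaries and internal site count <= max_missed, then length-filter.

    Deliberately naive (O(n^2) over all substring windows) so it shares no
    logic with the production enumeration.
    """
    sites = set(find_sites(sequence, rule))
    valid = sites | {0, len(sequence)}
    out = []
    for a in range(len(sequence)):
        for b in range(a + 1, len(sequence) + 1):
            if a not in valid or b not in valid:
                continue
            internal = sum(1 for s in sites if a < s < b)
            if internal > config.max_missed:
                continue
            if not (config.min_len <= b - a <= config.max_len):
                continue
            out.append(Peptide(accession, a + 1, b, sequence[a:b], internal))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def random_sequence(rng, alphabet="ACDEFGHIKLMNPQRSTVWY", max_len=60):
    n = rng.integers(1, max_len + 1)
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def toy_proteome():
    return Proteome(
        records=[
            ProteinRecord("P1", "P1 first", "MAKRTT"),
            ProteinRecord("P2", "P2 second", "AAKAAR"),
        ]
    )
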