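from __future__ import annotations

import pytest

from hbrscout import seqio, uniqseg


@pytest.fixture(scope="session")
def fixtures():
    return seqio.load_paper_fixtures()


@pytest.fixture(scope="session")
def ecp():
    return seqio.hrnase3_mature()


@pytest.fixture(scope="session")
def ecp_segments(fixtures, ecp):
    """The 11 unique segments of mature human RNase3 located on its sequence."""
    segments = []
    for motif in fixtures.unique_motifs:
        i = ecp.residues.find(motif)
        assert i >= 0, motif
        assert ecp.residues.find(motif, i + 1) == -1, f"{motif} occurs twice"
        segments.append(
            uniqseg.UniqueSegment(ecp.id, i + 1, i + len(motif), motif, 1)
        )
    return segments


@pytest.fixture()
def toy_family():
    return seqio.SequenceFamily.of(
        [
            seqio.SequenceRecord("a", "NYRWRCKNQN"),
            seqio.SequenceRecord("b", "NYQRRCKNQN"),
        ]
    )
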