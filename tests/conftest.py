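import numpy as np
import pytest

from lineagevar.distances import DistanceMatrix
from lineagevar.taxdata import AA_LETTERS, Alignment, Lineage, SequenceRecord


def make_alignment(seqs, accessions=None, lineages=None):
    accessions = accessions or [f"S{i+1}" for i in range(len(seqs))]
    lineages = lineages or [None] * len(seqs)
    return Alignment(
        records=tuple(
            SequenceRecord(accession=a, residues=s, lineage=l)
            for a, s, l in zip(accessions, seqs, lineages)
        )
    )


def make_matrix(labels, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(
        labels=tuple(labels),
        d=d,
        comparable_sites=np.ones_like(d, dtype=np.int64),
    )


def lineage(*names):
    """Build a Lineage, padding missing trailing ranks with defaults."""
    defaults = ["Bacteria", "P1", "C1", "O1", "F1", "G1", "S1"]
    full = list(names) + defaults[len(names):]
    return Lineage(*full)


def random_alignment(rng, n, L, gap_rate=0.0, x_rate=0.0):
    letters = np.array(list(AA_LETTERS + "-X"))
    probs = np.full(22, (1 - gap_rate - x_rate) / 20)
    probs[20] = gap_rate
    probs[21] = x_rate
    seqs = [
        "".join(rng.choice(letters, size=L, p=probs)) for _ in range(n)
    ]
    return make_alignment(seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_alignment():
    return make_alignment(["ACDEF", "ACDEY", "AC-EF"])
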