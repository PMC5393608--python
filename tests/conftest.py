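import numpy as np
import pytest

from barcodekit.model import (
    AlignedSequence,
    BarcodeDataset,
    LocusAlignment,
    Specimen,
)


def make_dataset(rows, locus_seqs):
    """Dataset from [(id, species, genus), ...] and {locus: {id: residues}}."""
    specimens = [Specimen(*r) for r in rows]
    alignments = {
        locus: LocusAlignment(
            locus,
            [AlignedSequence(sid, locus, res) for sid, res in seqs.items()],
        )
        for locus, seqs in locus_seqs.items()
    }
    return BarcodeDataset(specimens, alignments)


def mutate(residues: str, positions, base: str) -> str:
    out = list(residues)
    for p in positions:
        out[p] = base
    return "".join(out)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def two_species_dataset():
    """Two species x two individuals with a clean barcode gap."""
    base = "ACGT" * 30
    far = mutate(base, range(0, 120, 10), "T")  # ~10% divergent
    return make_dataset(
        [
            ("a1", "Alpha one", "Alpha"),
            ("a2", "Alpha one", "Alpha"),
            ("b1", "Beta one", "Beta"),
            ("b2", "Beta one", "Beta"),
        ],
        {
            "rbcL": {
                "a1": base,
                "a2": mutate(base, [3], "A"),
                "b1": far,
                "b2": mutate(far, [7], "A"),
            }
        },
    )
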