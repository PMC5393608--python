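"""Readers and writers: aligned FASTA, specimen metadata TSV, Newick trees.

FASTA record ids are taken as the token up to the first whitespace; the rest
of the header line is ignored (the usual voucher-coded FASTA convention).
Lowercase residues are normalized to uppercase on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignedSequence,
    BarcodeDataset,
    DuplicateIdError,
    LocusAlignment,
    MetadataError,
    Specimen,
)
from .treebuild import SupportTree

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# aligned FASTA
# ---------------------------------------------------------------------------

def read_locus_alignment(path: PathLike, locus: str) -> LocusAlignment:
    """Read one locus alignment from a (possibly line-wrapped) FASTA file.

    Raises :class:`AlignmentShapeError` on ragged rows, :class:`AlphabetError`
    on illegal characters and :class:`DuplicateIdError` on repeated ids.
    """
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs.append(AlignedSequence(rec.id, locus, str(rec.seq).upper()))
    return LocusAlignment(locus, seqs)


def write_locus_alignment(aln: LocusAlignment, path: PathLike) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.specimen_id, description="") for s in aln
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# metadata TSV
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("specimen_id", "species", "genus")


def read_metadata(path: PathLike) -> List[Specimen]:
    """Read the specimen table (TSV with specimen_id, species, genus columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata {path}: missing column(s) {missing}")
    out: List[Specimen] = []
    seen = set()
    for row in df.itertuples(index=False):
        sid = str(row.specimen_id).strip()
        if sid in seen:
            raise DuplicateIdError(f"metadata {path}: duplicate specimen id {sid!r}")
        seen.add(sid)
        note = str(getattr(row, "collection_note", "")).strip() or None
        out.append(
            Specimen(sid, str(row.species).strip(), str(row.genus).strip(), note)
        )
    return out


def write_metadata(specimens: Iterable[Specimen], path: PathLike) -> None:
    rows = [
        {
            "specimen_id": s.specimen_id,
            "species": s.assigned_species,
            "genus": s.assigned_genus,
            "collection_note": s.collection_note or "",
        }
        for s in specimens
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_tree(path: PathLike) -> SupportTree:
    return SupportTree.from_newick(Path(path).read_text())


def write_tree(tree: SupportTree, path: PathLike) -> None:
    Path(path).write_text(tree.to_newick())


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

def read_dataset(
    metadata_path: PathLike, locus_paths: Dict[str, PathLike]
) -> BarcodeDataset:
    """Assemble a dataset from a metadata TSV plus one FASTA per locus."""
    specimens = read_metadata(metadata_path)
    alignments = {
        locus: read_locus_alignment(p, locus) for locus, p in locus_paths.items()
    }
    return BarcodeDataset(specimens, alignments)


#: conventional barcode ordering (slow plastid core first, nuclear last)
_LOCUS_ORDER = {n: k for k, n in enumerate(("rbcL", "matK", "trnH-psbA", "ITS2", "ITS"))}


def read_dataset_dir(directory: PathLike) -> BarcodeDataset:
    """Read a dataset laid out as ``metadata.tsv`` + ``<locus>.fasta`` files.

    Known barcode loci are ordered rbcL, matK, trnH-psbA, ITS2, ITS; any
    others follow alphabetically.
    """
    d = Path(directory)
    stems = sorted(
        (p.stem for p in d.glob("*.fasta")),
        key=lambda s: (_LOCUS_ORDER.get(s, len(_LOCUS_ORDER)), s),
    )
    locus_paths = {s: d / f"{s}.fasta" for s in stems}
    return read_dataset(d / "metadata.tsv", locus_paths)


def write_dataset_dir(dataset: BarcodeDataset, directory: PathLike) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_metadata(dataset.specimens.values(), d / "metadata.tsv")
    for locus, aln in dataset.alignments.items():
        write_locus_alignment(aln, d / f"{locus}.fasta")


def write_truth(truth, path: PathLike) -> None:
    """Serialize a simulator truth registry as JSON."""
    payload = {
        "true_species": truth.true_species,
        "true_genus": truth.true_genus,
        "swaps": [list(t) for t in truth.swaps],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: PathLike):
    from .simulate import SyntheticTruth

    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        true_species=payload["true_species"],
        true_genus=payload["true_genus"],
        swaps=[tuple(t) for t in payload["swaps"]],
    )
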