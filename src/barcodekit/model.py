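"""Core data types for multi-locus DNA-barcode datasets.

A dataset couples a specimen metadata table (specimen id, assigned species,
assigned genus) with one aligned matrix per barcode locus.  A specimen may
lack any given locus: sequencing recovery in barcoding surveys is well below
100% for most markers, and every downstream computation has to tolerate
ragged locus coverage.

Residue alphabet: ``A C G T N - ?`` (uppercase only).  ``-`` is an alignment
gap (an inferred indel), ``N`` an ambiguous base call, and ``?`` fill for an
unsampled region (used when concatenating loci into a supermatrix).  ``N``
and ``?`` are both treated as missing by analyses but preserved distinctly
on IO.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

ALPHABET = frozenset("ACGTN-?")
#: characters skipped under pairwise deletion
MISSING_FOR_ANALYSIS = frozenset("N-?")


class BarcodeError(Exception):
    """Base class for all barcodekit errors."""


class AlphabetError(BarcodeError):
    """A residue outside {A, C, G, T, N, -, ?} was encountered."""


class AlignmentShapeError(BarcodeError):
    """Sequences within one alignment do not share a common length."""


class DuplicateIdError(BarcodeError):
    """A specimen id occurred more than once where uniqueness is required."""


class MetadataError(BarcodeError):
    """Malformed or inconsistent specimen metadata."""


class InputError(BarcodeError):
    """An operation received arguments outside its domain."""


@dataclass(frozen=True)
class AlignedSequence:
    """One specimen's aligned sequence for one locus."""

    specimen_id: str
    locus: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlignmentShapeError(
                f"empty residues for {self.specimen_id!r}/{self.locus!r}"
            )
        bad = set(self.residues) - ALPHABET
        if bad:
            raise AlphabetError(
                f"illegal residue(s) {sorted(bad)} in {self.specimen_id!r}"
                f"/{self.locus!r}; allowed: {''.join(sorted(ALPHABET))}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        """Residues with gap and unsampled fill stripped (for local alignment)."""
        return self.residues.replace("-", "").replace("?", "")


@dataclass(frozen=True)
class Specimen:
    """A vouchered individual with its (possibly erroneous) a priori labels."""

    specimen_id: str
    assigned_species: str
    assigned_genus: str
    collection_note: Optional[str] = None

    def __post_init__(self) -> None:
        # For binomials ("Genus epithet") the genus column must agree with
        # the generic epithet; single-token species names are unconstrained.
        parts = self.assigned_species.split()
        if len(parts) >= 2 and self.assigned_genus and parts[0] != self.assigned_genus:
            raise MetadataError(
                f"specimen {self.specimen_id!r}: species "
                f"{self.assigned_species!r} is not in genus {self.assigned_genus!r}"
            )


class LocusAlignment:
    """An aligned set of sequences for a single locus.

    Sequences are kept in insertion order; ids are unique; all rows share
    one length (the number of alignment columns).
    """

    def __init__(self, locus: str, sequences: Iterable[AlignedSequence]):
        self.locus = locus
        self._seqs: Dict[str, AlignedSequence] = {}
        length: Optional[int] = None
        for seq in sequences:
            if seq.locus != locus:
                raise InputError(
                    f"sequence {seq.specimen_id!r} is for locus {seq.locus!r}, "
                    f"not {locus!r}"
                )
            if seq.specimen_id in self._seqs:
                raise DuplicateIdError(
                    f"duplicate specimen id {seq.specimen_id!r} in locus {locus!r}"
                )
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentShapeError(
                    f"locus {locus!r}: sequence {seq.specimen_id!r} has length "
                    f"{len(seq)}, expected {length}"
                )
            self._seqs[seq.specimen_id] = seq
        if length is None:
            raise InputError(f"locus {locus!r}: alignment has no sequences")
        self.length: int = length

    @property
    def ids(self) -> List[str]:
        return list(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __contains__(self, specimen_id: str) -> bool:
        return specimen_id in self._seqs

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self._seqs.values())

    def __getitem__(self, specimen_id: str) -> AlignedSequence:
        return self._seqs[specimen_id]

    def subset(self, specimen_ids: Sequence[str]) -> "LocusAlignment":
        return LocusAlignment(
            self.locus, [self._seqs[i] for i in specimen_ids if i in self._seqs]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocusAlignment):
            return NotImplemented
        return self.locus == other.locus and self._seqs == other._seqs

    def __repr__(self) -> str:
        return (
            f"<LocusAlignment {self.locus!r}: {len(self)} sequences x "
            f"{self.length} columns>"
        )


class BarcodeDataset:
    """Specimens plus per-locus alignments; the unit the pipeline consumes."""

    def __init__(
        self,
        specimens: Iterable[Specimen],
        alignments: Dict[str, LocusAlignment],
    ):
        self.specimens: Dict[str, Specimen] = {}
        for sp in specimens:
            if sp.specimen_id in self.specimens:
                raise DuplicateIdError(f"duplicate specimen id {sp.specimen_id!r}")
            self.specimens[sp.specimen_id] = sp
        self.alignments = dict(alignments)
        for locus, aln in self.alignments.items():
            for sid in aln.ids:
                if sid not in self.specimens:
                    raise MetadataError(
                        f"specimen {sid!r} in locus {locus!r} alignment is "
                        "absent from the metadata table"
                    )

    # -- basic accessors -------------------------------------------------
    @property
    def loci(self) -> List[str]:
        return list(self.alignments)

    @property
    def specimen_ids(self) -> List[str]:
        return list(self.specimens)

    def species_of(self, specimen_id: str) -> str:
        return self.specimens[specimen_id].assigned_species

    def genus_of(self, specimen_id: str) -> str:
        return self.specimens[specimen_id].assigned_genus

    def has_locus(self, specimen_id: str, locus: str) -> bool:
        return locus in self.alignments and specimen_id in self.alignments[locus]

    def has_any_locus(self, specimen_id: str, loci: Sequence[str]) -> bool:
        return any(self.has_locus(specimen_id, l) for l in loci)

    def label_of(self, specimen_id: str, level: str) -> str:
        if level == "species":
            return self.species_of(specimen_id)
        if level == "genus":
            return self.genus_of(specimen_id)
        raise InputError(f"unknown level {level!r}; expected 'species' or 'genus'")

    # -- groupings -------------------------------------------------------
    def members_by_label(self, level: str) -> Dict[str, List[str]]:
        """Map taxon label -> specimen ids carrying it (at species or genus level)."""
        out: Dict[str, List[str]] = defaultdict(list)
        for sid in self.specimens:
            out[self.label_of(sid, level)].append(sid)
        return dict(out)

    def species_labels(self) -> List[str]:
        return sorted({sp.assigned_species for sp in self.specimens.values()})

    def genus_labels(self) -> List[str]:
        return sorted({sp.assigned_genus for sp in self.specimens.values()})

    def relabel(self, new_species: Dict[str, str], genus_for: Dict[str, str]) -> "BarcodeDataset":
        """Return a copy with some specimens' species labels replaced.

        ``genus_for`` maps a species label to its genus (needed to keep the
        genus column consistent).
        """
        specs = []
        for sp in self.specimens.values():
            if sp.specimen_id in new_species:
                s = new_species[sp.specimen_id]
                specs.append(
                    Specimen(sp.specimen_id, s, genus_for.get(s, sp.assigned_genus),
                             sp.collection_note)
                )
            else:
                specs.append(sp)
        return BarcodeDataset(specs, self.alignments)

    def __repr__(self) -> str:
        return (
            f"<BarcodeDataset: {len(self.specimens)} specimens, "
            f"{len(self.alignments)} loci {self.loci}>"
        )
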