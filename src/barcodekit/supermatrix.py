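"""Marker concatenation and simple indel coding.

``concatenate`` builds a supermatrix: one row per specimen appearing in at
least one input locus, with loci laid out left to right in input order and
``?`` filling the block of any locus a specimen lacks.  The partition map
records each locus's half-open column interval so the original alignments
can be recovered exactly.

``simple_indel_coding`` recodes shared alignment gaps as binary characters
(the simple indel coding of Simmons & Ochoterena): each distinct internal
gap span - identical start and end columns - becomes one presence/absence
character; a sequence whose own gap strictly contains the span, or overlaps
it without identical boundaries, is scored as missing, as is any sequence
whose terminal missing region covers part of the span.  Terminal gaps model
recovery failure and ragged ends, not indel events, and are never coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .model import (
    AlignedSequence,
    BarcodeDataset,
    InputError,
    LocusAlignment,
    Specimen,
)

CONCAT_LOCUS = "concat"


@dataclass
class IndelTable:
    """Binary indel characters: one column per distinct internal gap span."""

    spans: List[Tuple[int, int]]  # half-open [start, end) column intervals
    states: Dict[str, str]  # specimen id -> string over {'0','1','?'}

    @property
    def n_characters(self) -> int:
        return len(self.spans)

    def write_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            header = "\t".join(f"indel_{s}_{e}" for s, e in self.spans)
            fh.write(f"specimen_id\t{header}\n")
            for sid, st in self.states.items():
                fh.write(f"{sid}\t" + "\t".join(st) + "\n")


@dataclass
class Supermatrix:
    """Concatenated alignment plus its partition map and optional indel block."""

    alignment: LocusAlignment
    partitions: Dict[str, Tuple[int, int]]
    indel_block: Optional[IndelTable] = None

    @property
    def length(self) -> int:
        return self.alignment.length

    def extract_partition(self, locus: str) -> LocusAlignment:
        """Recover one locus alignment (rows that are all-`?` are dropped)."""
        if locus not in self.partitions:
            raise InputError(f"no partition named {locus!r}")
        s, e = self.partitions[locus]
        seqs = []
        for row in self.alignment:
            chunk = row.residues[s:e]
            if set(chunk) == {"?"}:
                continue
            seqs.append(AlignedSequence(row.specimen_id, locus, chunk))
        return LocusAlignment(locus, seqs)

    def write_partitions(self, path: Union[str, Path]) -> None:
        """RAxML-style partition file (1-based inclusive intervals)."""
        with open(path, "w") as fh:
            for locus, (s, e) in self.partitions.items():
                fh.write(f"DNA, {locus} = {s + 1}-{e}\n")


def concatenate(
    loci: Sequence[LocusAlignment],
    specimens: Optional[Sequence[Specimen]] = None,
) -> Supermatrix:
    """Concatenate locus alignments into a supermatrix.

    Row order follows ``specimens`` when given (restricted to specimens
    present in at least one locus), otherwise first appearance across loci.
    """
    if not loci:
        raise InputError("concatenate requires at least one locus alignment")
    names = [a.locus for a in loci]
    if len(set(names)) != len(names):
        raise InputError(f"duplicate locus names in {names}")
    if specimens is not None:
        order = [s.specimen_id for s in specimens]
    else:
        order = []
        seen = set()
        for aln in loci:
            for sid in aln.ids:
                if sid not in seen:
                    seen.add(sid)
                    order.append(sid)
    order = [sid for sid in order if any(sid in aln for aln in loci)]

    partitions: Dict[str, Tuple[int, int]] = {}
    start = 0
    for aln in loci:
        partitions[aln.locus] = (start, start + aln.length)
        start += aln.length

    rows = []
    for sid in order:
        parts = []
        for aln in loci:
            parts.append(aln[sid].residues if sid in aln else "?" * aln.length)
        rows.append(AlignedSequence(sid, CONCAT_LOCUS, "".join(parts)))
    return Supermatrix(LocusAlignment(CONCAT_LOCUS, rows), partitions)


# ---------------------------------------------------------------------------
# simple indel coding
# ---------------------------------------------------------------------------

def _terminal_missing(residues: str) -> Tuple[int, int]:
    """(head, tail): columns of leading/trailing '-'/'?' treated as missing."""
    head = 0
    while head < len(residues) and residues[head] in "-?":
        head += 1
    tail = len(residues)
    while tail > head and residues[tail - 1] in "-?":
        tail -= 1
    return head, tail


def _internal_gap_runs(residues: str) -> List[Tuple[int, int]]:
    head, tail = _terminal_missing(residues)
    runs = []
    i = head
    while i < tail:
        if residues[i] == "-":
            j = i
            while j < tail and residues[j] == "-":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def simple_indel_coding(aln: LocusAlignment) -> IndelTable:
    """Simple indel coding of one alignment; see the module docstring."""
    per_seq_runs = {s.specimen_id: _internal_gap_runs(s.residues) for s in aln}
    spans = sorted({run for runs in per_seq_runs.values() for run in runs})

    states: Dict[str, str] = {}
    for seq in aln:
        sid = seq.specimen_id
        head, tail = _terminal_missing(seq.residues)
        runs = set(per_seq_runs[sid])
        chars = []
        for (s, e) in spans:
            if s < head or e > tail:
                chars.append("?")  # span touches a terminal missing region
            elif (s, e) in runs:
                chars.append("1")
            else:
                window = seq.residues[s:e]
                if "-" in window or "?" in window:
                    chars.append("?")  # enclosing/overlapping non-identical gap
                else:
                    chars.append("0")
        states[sid] = "".join(chars)
    return IndelTable(list(spans), states)


def with_indel_block(sm: Supermatrix) -> Supermatrix:
    """Attach an indel block coding each partition separately.

    Character spans are reported in supermatrix column coordinates.
    """
    spans: List[Tuple[int, int]] = []
    per_id: Dict[str, List[str]] = {sid: [] for sid in sm.alignment.ids}
    for locus, (offset, _) in sm.partitions.items():
        table = simple_indel_coding(sm.extract_partition(locus))
        spans.extend((s + offset, e + offset) for s, e in table.spans)
        for sid in per_id:
            if sid in table.states:
                per_id[sid].append(table.states[sid])
            else:
                per_id[sid].append("?" * table.n_characters)
    states = {sid: "".join(parts) for sid, parts in per_id.items()}
    sm.indel_block = IndelTable(spans, states)
    return sm
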