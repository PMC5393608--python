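"""Species/genus discrimination criteria and misidentification flagging.

Two evaluation methods are implemented:

*tree-based*
    a taxon succeeds when all of its individuals form a single clade in the
    NJ tree with bootstrap support strictly above the threshold (default
    50); species represented in the tree by a single individual cannot be
    tested and are excluded;

*similarity-based*
    every individual of the taxon must have its entire set of top-scoring
    database hits conspecific (species level) or congeneric (genus level).
    Scores are blastn-style local alignments (match +1, mismatch -2, gap
    open/extend -2.5) of gap-stripped sequences; for a multi-locus marker
    set the per-locus scores are summed over the loci both specimens carry.
    The query itself is excluded from its hit list only when its species has
    at least two individuals with data for the marker set - a singleton
    keeps its self-hit and therefore succeeds vacuously at species level.

Cohorts: ``n1`` evaluates every taxon with data; ``n2`` restricts to taxa
with at least two individuals carrying the marker set (singletons cannot be
tested meaningfully).

The misidentification workflow cross-checks, per specimen and per marker
set, its placement in the bootstrapped NJ tree against its top similarity
hits; a specimen is flagged when at least ``quorum`` marker-set analyses
agree it does not belong to its a priori species, and a corrected species
is proposed from its nearest labelled neighbours.  The morphological
re-examination that would confirm a flag is, by its nature, not automated:
the output is an audit report.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from ._kernels import sw_score, sw_score_linear
from .distances import DEFAULT_MODEL
from .model import BarcodeDataset, InputError, LocusAlignment
from .supermatrix import concatenate
from .treebuild import SupportTree, bootstrap_support, has_supported_monophyly

logger = logging.getLogger(__name__)

MarkerSet = Tuple[str, ...]


@dataclass(frozen=True)
class ScoringConfig:
    """blastn-like local alignment scoring used to rank hits."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -2.5
    gap_extend: float = -2.5
    #: half-width of the alignment band; None = full dynamic program.
    #: The default comfortably covers barcode-length sequences whose indels
    #: span a few dozen columns at most.
    band: Optional[int] = 50


DEFAULT_SCORING = ScoringConfig()


@dataclass
class HitList:
    """Ranked similarity hits for one query specimen."""

    query: str
    hits: List[Tuple[str, float]]  # (subject id, score), score non-increasing
    self_excluded: bool

    @property
    def top_set(self) -> Set[str]:
        if not self.hits:
            return set()
        best = self.hits[0][1]
        return {sid for sid, sc in self.hits if sc == best}


@dataclass(frozen=True)
class DiscriminationRecord:
    taxon: str
    level: str  # species | genus
    method: str  # tree | similarity
    marker_set: MarkerSet
    cohort: str  # n1 | n2
    success: bool
    reason: str


@dataclass
class RateSummary:
    successes: int
    total: int

    @property
    def rate(self) -> float:
        return self.successes / self.total


@dataclass
class MisidFlag:
    specimen_id: str
    #: marker set -> (nearest species, description of the criterion violated)
    evidence: Dict[MarkerSet, Tuple[str, str]]
    proposed_species: str
    n_markers_agreeing: int


@dataclass
class FlagReport:
    flags: List[MisidFlag]
    #: specimens with data for fewer marker sets than the quorum
    insufficient: List[str]
    #: per-specimen audit notes (violations below quorum etc.)
    notes: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# similarity scores
# ---------------------------------------------------------------------------

class ScoreTable:
    """All-pairs local-alignment scores for one marker set.

    ``matrix[i, j]`` is the summed per-locus score over loci both specimens
    carry; ``-inf`` marks pairs sharing no locus.  The diagonal holds
    self-alignment scores.
    """

    def __init__(self, ids: List[str], matrix: np.ndarray, marker_set: MarkerSet):
        self.ids = ids
        self.index = {sid: k for k, sid in enumerate(ids)}
        self.matrix = matrix
        self.marker_set = marker_set


def build_score_table(
    dataset: BarcodeDataset,
    marker_set: Sequence[str],
    scoring: ScoringConfig = DEFAULT_SCORING,
) -> ScoreTable:
    marker_set = tuple(marker_set)
    for locus in marker_set:
        if locus not in dataset.alignments:
            raise InputError(f"dataset has no locus {locus!r}")
    ids = [
        sid for sid in dataset.specimen_ids if dataset.has_any_locus(sid, marker_set)
    ]
    n = len(ids)
    total = np.full((n, n), -np.inf)
    shared = np.zeros((n, n), dtype=bool)
    band = -1 if scoring.band is None else scoring.band
    linear = scoring.gap_open == scoring.gap_extend
    for locus in marker_set:
        aln = dataset.alignments[locus]
        present = [k for k, sid in enumerate(ids) if sid in aln]
        seqs = [
            np.frombuffer(aln[ids[k]].ungapped().encode(), dtype=np.uint8)
            for k in present
        ]
        for a in range(len(present)):
            ia = present[a]
            for b in range(a, len(present)):
                ib = present[b]
                if linear:
                    sc = sw_score_linear(
                        seqs[a], seqs[b], scoring.match, scoring.mismatch,
                        scoring.gap_open, band,
                    )
                else:
                    sc = sw_score(
                        seqs[a], seqs[b], scoring.match, scoring.mismatch,
                        scoring.gap_open, scoring.gap_extend, band,
                    )
                for x, y in ((ia, ib), (ib, ia)) if ia != ib else ((ia, ia),):
                    if shared[x, y]:
                        total[x, y] += sc
                    else:
                        total[x, y] = sc
                        shared[x, y] = True
    return ScoreTable(ids, total, marker_set)


def _self_excluded(dataset: BarcodeDataset, table: ScoreTable, query: str) -> bool:
    """Self-hit exclusion applies only when the query's species has >= 2
    individuals with data for the marker set."""
    species = dataset.species_of(query)
    n_with_data = sum(
        1 for sid in table.ids if dataset.species_of(sid) == species
    )
    return n_with_data >= 2


def best_hits(
    query: str,
    dataset: BarcodeDataset,
    marker_set: Sequence[str],
    scoring: ScoringConfig = DEFAULT_SCORING,
    table: Optional[ScoreTable] = None,
) -> HitList:
    """Ranked hits of ``query`` against every reference with shared data.

    Hits are sorted by score descending, ties broken by subject id.  Pass a
    prebuilt :class:`ScoreTable` to avoid recomputing all-pairs scores.
    """
    marker_set = tuple(marker_set)
    if table is None:
        table = build_score_table(dataset, marker_set, scoring)
    if query not in table.index:
        raise InputError(f"query {query!r} has no sequence for {marker_set}")
    q = table.index[query]
    exclude_self = _self_excluded(dataset, table, query)
    pairs = []
    for sid in table.ids:
        if exclude_self and sid == query:
            continue
        sc = table.matrix[q, table.index[sid]]
        if np.isfinite(sc):
            pairs.append((sid, float(sc)))
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return HitList(query, pairs, exclude_self)


# ---------------------------------------------------------------------------
# similarity-based success
# ---------------------------------------------------------------------------

def similarity_success(
    dataset: BarcodeDataset,
    marker_set: Sequence[str],
    level: str = "species",
    cohort: str = "n1",
    scoring: ScoringConfig = DEFAULT_SCORING,
    table: Optional[ScoreTable] = None,
    include_vacuous_singletons: bool = True,
) -> List[DiscriminationRecord]:
    """Top-hit criterion per taxon: success iff every individual's entire
    top-scoring hit set is conspecific / congeneric.

    ``include_vacuous_singletons=False`` drops single-individual taxa from
    the ``n1`` cohort instead of letting them succeed through the retained
    self-hit (both readings of the criterion are defensible; the switch
    makes the choice explicit).
    """
    marker_set = tuple(marker_set)
    if cohort not in ("n1", "n2"):
        raise InputError(f"unknown cohort {cohort!r}")
    if table is None:
        table = build_score_table(dataset, marker_set, scoring)
    with_data = set(table.ids)

    groups: Dict[str, List[str]] = defaultdict(list)
    for sid in table.ids:
        groups[dataset.label_of(sid, level)].append(sid)

    skipped = [
        t for t in dataset.members_by_label(level) if t not in groups
    ]
    if skipped:
        logger.info(
            "similarity %s/%s: %d taxa with no data for %s dropped",
            level, cohort, len(skipped), marker_set,
        )

    records: List[DiscriminationRecord] = []
    for taxon in sorted(groups):
        members = groups[taxon]
        if cohort == "n2" and len(members) < 2:
            continue
        if (
            cohort == "n1"
            and len(members) < 2
            and not include_vacuous_singletons
        ):
            continue
        success = True
        reason = "all individuals' top hits are "
        reason += "conspecific" if level == "species" else "congeneric"
        for sid in members:
            hl = best_hits(sid, dataset, marker_set, scoring, table)
            top = hl.top_set
            if not top:
                success, reason = False, f"{sid} has no scoreable hit"
                break
            bad = {
                h for h in top if dataset.label_of(h, level) != taxon
            }
            if bad:
                offender = sorted(bad)[0]
                success = False
                reason = (
                    f"{sid}: top hit {offender} is "
                    f"{dataset.label_of(offender, level)}"
                )
                break
        records.append(
            DiscriminationRecord(
                taxon, level, "similarity", marker_set, cohort, success, reason
            )
        )
    return records


# ---------------------------------------------------------------------------
# tree-based success
# ---------------------------------------------------------------------------

def tree_success(
    tree: SupportTree,
    dataset: BarcodeDataset,
    level: str = "species",
    threshold: int = 50,
    cohort: str = "n2",
    marker_set: MarkerSet = (),
) -> List[DiscriminationRecord]:
    """Supported-monophyly criterion per taxon with >= 2 leaves in the tree.

    Taxa with fewer than two individuals in the tree cannot be tested for
    monophyly and are excluded (so tree-based cohorts are n2 by
    construction, whatever ``cohort`` label is recorded).
    """
    leaves = set(tree.leaf_labels)
    extra = leaves - set(dataset.specimen_ids)
    if extra:
        raise InputError(f"tree leaves not in dataset: {sorted(extra)[:5]}")
    groups: Dict[str, List[str]] = defaultdict(list)
    for sid in leaves:
        groups[dataset.label_of(sid, level)].append(sid)

    records: List[DiscriminationRecord] = []
    for taxon in sorted(groups):
        members = groups[taxon]
        if len(members) < 2:
            logger.info(
                "tree %s: taxon %s has %d leaf/leaves in tree; excluded",
                level, taxon, len(members),
            )
            continue
        ok = has_supported_monophyly(tree, members, threshold)
        if ok:
            reason = f"monophyletic with support > {threshold}"
        elif has_supported_monophyly(tree, members, None):
            reason = f"clade present but support <= {threshold}"
        else:
            reason = "individuals do not form a single clade"
        records.append(
            DiscriminationRecord(taxon, level, "tree", marker_set, cohort, ok, reason)
        )
    return records


def discrimination_rate(records: Sequence[DiscriminationRecord]) -> RateSummary:
    """successes / total for one homogeneous batch of records."""
    if not records:
        raise InputError("discrimination rate of an empty record set is undefined")
    keys = {(r.level, r.method, r.marker_set, r.cohort) for r in records}
    if len(keys) > 1:
        raise InputError(f"records mix evaluation settings: {sorted(keys)}")
    return RateSummary(sum(r.success for r in records), len(records))


# ---------------------------------------------------------------------------
# misidentification flagging
# ---------------------------------------------------------------------------

def _marker_alignment(
    dataset: BarcodeDataset, marker_set: MarkerSet
) -> Optional[LocusAlignment]:
    """Single- or multi-locus alignment over specimens with any data for it."""
    if len(marker_set) == 1:
        aln = dataset.alignments[marker_set[0]]
        return aln if len(aln) >= 3 else None
    sm = concatenate(
        [dataset.alignments[l] for l in marker_set],
        list(dataset.specimens.values()),
    )
    return sm.alignment if len(sm.alignment) >= 3 else None


def _neighbourhood(
    tree: SupportTree, sid: str, threshold: int, min_others: int = 2
) -> List[str]:
    """Leaves of the smallest supported clade around ``sid`` with at least
    ``min_others`` other members (fallback: the whole tree)."""
    fallback: List[str] = []
    for others, sup, is_root in tree.enclosing_clades(sid):
        fallback = others
        if len(others) < min_others:
            continue
        if is_root or (sup is not None and sup > threshold):
            return others
    return fallback


def _majority_label(
    dataset: BarcodeDataset,
    neighbours: Sequence[str],
    exclude: Set[str],
    tiebreak_scores: Optional[Dict[str, float]] = None,
) -> Optional[str]:
    pool = [n for n in neighbours if n not in exclude] or list(neighbours)
    if not pool:
        return None
    votes = Counter(dataset.species_of(n) for n in pool)
    top = votes.most_common()
    best = [sp for sp, c in top if c == top[0][1]]
    if len(best) == 1 or not tiebreak_scores:
        return sorted(best)[0] if len(best) > 1 else best[0]
    # tie: prefer the species with the highest-scoring supporting evidence
    def species_score(sp: str) -> float:
        return max(
            (tiebreak_scores.get(n, -np.inf) for n in pool
             if dataset.species_of(n) == sp),
            default=-np.inf,
        )
    return max(sorted(best), key=species_score)


def default_flag_marker_sets(dataset: BarcodeDataset) -> List[MarkerSet]:
    """Marker sets cross-checked by the flagging workflow.

    With the two slow plastid core barcodes present these are rbcL alone,
    matK alone, and the all-locus combination; otherwise each single locus
    plus the all-locus combination.
    """
    loci = dataset.loci
    all_set = tuple(loci)
    if "rbcL" in loci and "matK" in loci and len(loci) > 1:
        return [("rbcL",), ("matK",), all_set]
    sets: List[MarkerSet] = [(l,) for l in loci]
    if len(loci) > 1:
        sets.append(all_set)
    return sets


def flag_misidentifications(
    dataset: BarcodeDataset,
    marker_sets: Optional[Sequence[Sequence[str]]] = None,
    quorum: int = 2,
    threshold: int = 50,
    model: str = DEFAULT_MODEL,
    replicates: int = 1000,
    seed: int = 0,
    scoring: ScoringConfig = DEFAULT_SCORING,
) -> FlagReport:
    """Flag specimens whose molecular placement contradicts their label.

    Per marker set, a specimen violates conspecificity when (a) its labelled
    species fails supported monophyly in the bootstrapped NJ tree, (b) no
    member of its local supported clade (the smallest supported clade
    containing it and at least two other leaves) shares its label, and
    (c) all of its top similarity hits are heterospecific.  Condition (b)
    is deliberately conservative: a specimen still clustering with any of
    its labelled conspecifics is left to the morphological audit rather
    than flagged.  A flag is emitted when >= ``quorum`` marker sets agree;
    the proposed species is the majority nearest species across agreeing
    marker sets, recomputed with other flagged specimens' (suspect) labels
    set aside.
    """
    if marker_sets is None:
        sets = default_flag_marker_sets(dataset)
    else:
        sets = [tuple(m) for m in marker_sets]
    if quorum < 1:
        raise InputError("quorum must be >= 1")

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(sets))

    # pass 1: per-specimen, per-marker-set violation evidence
    evidence: Dict[str, Dict[MarkerSet, Tuple[List[str], str, str]]] = defaultdict(dict)
    available: Dict[str, int] = defaultdict(int)
    notes: List[str] = []
    tables: Dict[MarkerSet, ScoreTable] = {}
    for k, mset in enumerate(sets):
        aln = _marker_alignment(dataset, mset)
        if aln is None:
            notes.append(f"marker set {mset}: fewer than 3 sequences; skipped")
            continue
        tree = bootstrap_support(
            aln, model=model, replicates=replicates, seed=int(sub_seeds[k])
        )
        table = build_score_table(dataset, mset, scoring)
        tables[mset] = table
        species_leaves: Dict[str, List[str]] = defaultdict(list)
        for sid in tree.leaf_labels:
            species_leaves[dataset.species_of(sid)].append(sid)
        for sid in tree.leaf_labels:
            available[sid] += 1
            own = dataset.species_of(sid)
            if has_supported_monophyly(tree, species_leaves[own], threshold):
                continue
            neighbours = _neighbourhood(tree, sid, threshold)
            if not neighbours or any(
                dataset.species_of(n) == own for n in neighbours
            ):
                continue  # still clusters with a labelled conspecific
            q = table.index.get(sid)
            scores = (
                {n: float(table.matrix[q, table.index[n]])
                 for n in neighbours if n in table.index}
                if q is not None
                else {}
            )
            nearest = _majority_label(dataset, neighbours, set(), scores)
            if nearest is None:
                continue
            hl = best_hits(sid, dataset, mset, scoring, table)
            top = hl.top_set
            if not top or any(dataset.species_of(h) == own for h in top):
                continue
            detail = (
                f"outside supported clade of {own}; nearest neighbours are "
                f"{nearest}; top hits {sorted(top)[:3]} all heterospecific"
            )
            evidence[sid][mset] = (neighbours, nearest, detail)

    # quorum + audit
    flagged_ids = {
        sid for sid, ev in evidence.items() if len(ev) >= quorum
    }
    insufficient = sorted(
        sid for sid, n_av in available.items()
        if n_av < quorum and sid in evidence
    )
    for sid, ev in sorted(evidence.items()):
        if sid not in flagged_ids and sid not in insufficient:
            notes.append(
                f"{sid}: violation on {len(ev)} of {available[sid]} marker "
                f"set(s); below quorum {quorum}; not flagged"
            )
    for sid in insufficient:
        notes.append(f"{sid}: insufficient data ({available[sid]} marker sets)")

    # pass 2: proposals with flagged specimens' labels set aside
    flags: List[MisidFlag] = []
    for sid in sorted(flagged_ids):
        votes: List[str] = []
        ev_out: Dict[MarkerSet, Tuple[str, str]] = {}
        for mset, (neighbours, _, detail) in evidence[sid].items():
            table = tables[mset]
            q = table.index.get(sid)
            scores = (
                {n: float(table.matrix[q, table.index[n]])
                 for n in neighbours if n in table.index}
                if q is not None
                else {}
            )
            nearest = _majority_label(
                dataset, neighbours, flagged_ids - {sid}, scores
            )
            ev_out[mset] = (nearest, detail)
            votes.append(nearest)
        tally = Counter(votes).most_common()
        best = sorted(sp for sp, c in tally if c == tally[0][1])
        flags.append(MisidFlag(sid, ev_out, best[0], len(ev_out)))
    return FlagReport(flags, insufficient, notes)


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[DiscriminationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "level": r.level,
                "method": r.method,
                "marker_set": "+".join(r.marker_set),
                "cohort": r.cohort,
                "success": r.success,
                "reason": r.reason,
            }
            for r in records
        ]
    )


def write_records_tsv(
    records: Sequence[DiscriminationRecord], path: Union[str, Path]
) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_flags_tsv(
    report: FlagReport, dataset: BarcodeDataset, path: Union[str, Path]
) -> None:
    """Original label -> proposed label, one row per flagged specimen."""
    rows = []
    for f in report.flags:
        rows.append(
            {
                "specimen_id": f.specimen_id,
                "original_species": dataset.species_of(f.specimen_id),
                "proposed_species": f.proposed_species,
                "n_markers_agreeing": f.n_markers_agreeing,
                "evidence": "; ".join(
                    f"{'+'.join(m)}: {sp}" for m, (sp, _) in f.evidence.items()
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "specimen_id", "original_species", "proposed_species",
            "n_markers_agreeing", "evidence",
        ],
    ).to_csv(path, sep="\t", index=False)
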