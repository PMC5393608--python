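"""Rate arithmetic, recovery reports, and whole-pipeline evaluation.

Percentages are printed the way barcoding surveys tabulate them: 100 x
successes / sampled, rounded half-up to one decimal (e.g. 381/412 -> 92.5).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .discrimination import (
    DEFAULT_SCORING,
    DiscriminationRecord,
    ScoringConfig,
    build_score_table,
    discrimination_rate,
    similarity_success,
    tree_success,
    _marker_alignment,
)
from .distances import DEFAULT_MODEL
from .model import BarcodeDataset, InputError
from .treebuild import SupportTree, bootstrap_support

import numpy as np

logger = logging.getLogger(__name__)

MarkerSet = Tuple[str, ...]

#: canonical single-locus order and combination ladder for five-barcode data
CANONICAL_LOCI = ("rbcL", "matK", "trnH-psbA", "ITS2", "ITS")
CANONICAL_COMBOS = (
    ("rbcL", "matK"),
    ("rbcL", "matK", "trnH-psbA"),
    ("rbcL", "matK", "trnH-psbA", "ITS2"),
    ("rbcL", "matK", "trnH-psbA", "ITS"),
)


def compute_rate(successes: int, sampled: int) -> float:
    """Percentage rounded half-up to one decimal."""
    if sampled == 0:
        raise InputError("rate undefined for zero sampled")
    if successes < 0 or successes > sampled:
        raise InputError(f"successes {successes} outside [0, {sampled}]")
    pct = Decimal(100 * successes) / Decimal(sampled)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class RecoveryReport:
    """Per-locus sequencing recovery, at individual, species and genus level.

    A species or genus counts as recovered for a locus when at least one of
    its individuals carries that locus.
    """

    counts: Dict[str, Dict[str, Tuple[int, int]]]  # locus -> level -> (succ, tot)

    def percentage(self, locus: str, level: str) -> float:
        s, t = self.counts[locus][level]
        return compute_rate(s, t)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for locus, levels in self.counts.items():
            row: Dict[str, object] = {"locus": locus}
            for level, (s, t) in levels.items():
                row[f"{level}_recovered"] = s
                row[f"{level}_sampled"] = t
                row[f"{level}_pct"] = compute_rate(s, t)
            rows.append(row)
        return pd.DataFrame(rows)


def recovery_report(dataset: BarcodeDataset) -> RecoveryReport:
    if not dataset.alignments:
        raise InputError("dataset has no loci")
    species = dataset.members_by_label("species")
    genera = dataset.members_by_label("genus")
    n_ind, n_sp, n_gen = len(dataset.specimens), len(species), len(genera)
    counts: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for locus, aln in dataset.alignments.items():
        have = set(aln.ids)
        counts[locus] = {
            "individuals": (len(have), n_ind),
            "species": (
                sum(1 for m in species.values() if have & set(m)), n_sp
            ),
            "genera": (
                sum(1 for m in genera.values() if have & set(m)), n_gen
            ),
        }
    return RecoveryReport(counts)


# ---------------------------------------------------------------------------
# whole-pipeline evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalConfig:
    marker_sets: Optional[Tuple[MarkerSet, ...]] = None  # None = defaults
    model: str = DEFAULT_MODEL
    replicates: int = 1000
    seed: int = 0
    threshold: int = 50
    methods: Tuple[str, ...] = ("tree", "similarity")
    cohorts: Tuple[str, ...] = ("n1", "n2")
    levels: Tuple[str, ...] = ("species", "genus")
    scoring: ScoringConfig = DEFAULT_SCORING


@dataclass
class EvalSummary:
    rates: pd.DataFrame
    records: List[DiscriminationRecord]
    trees: Dict[MarkerSet, SupportTree]
    log: List[str]

    def to_json(self) -> str:
        """Rates keyed method -> marker set -> level -> cohort."""
        out: Dict[str, Dict[str, Dict[str, Dict[str, object]]]] = {}
        for row in self.rates.itertuples(index=False):
            out.setdefault(row.method, {}).setdefault(
                row.marker_set, {}
            ).setdefault(row.level, {})[row.cohort] = {
                "successes": int(row.successes),
                "total": int(row.total),
                "pct": row.pct,
            }
        return json.dumps(out, indent=1, sort_keys=True)


def default_marker_sets(dataset: BarcodeDataset) -> List[MarkerSet]:
    """Each single locus, then the standard combination ladder when the five
    canonical barcodes are present, else the all-locus combination."""
    loci = dataset.loci
    sets: List[MarkerSet] = [(l,) for l in loci]
    if set(CANONICAL_LOCI) <= set(loci):
        sets.extend(CANONICAL_COMBOS)
    elif len(loci) > 1:
        sets.append(tuple(loci))
    return sets


def evaluate(dataset: BarcodeDataset, config: EvalConfig = EvalConfig()) -> EvalSummary:
    """Run both discrimination methods over marker sets, levels and cohorts.

    Deterministic given (dataset, config): per-marker-set bootstrap seeds
    are spawned from ``config.seed``.
    """
    sets = (
        [tuple(m) for m in config.marker_sets]
        if config.marker_sets is not None
        else default_marker_sets(dataset)
    )
    for mset in sets:
        for locus in mset:
            if locus not in dataset.alignments:
                raise InputError(f"marker set {mset}: locus {locus!r} not in dataset")

    rng = np.random.default_rng(config.seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(sets))

    records: List[DiscriminationRecord] = []
    trees: Dict[MarkerSet, SupportTree] = {}
    log: List[str] = []
    rows = []
    for k, mset in enumerate(sets):
        aln = _marker_alignment(dataset, mset)
        if aln is None:
            log.append(f"marker set {mset}: fewer than 3 sequences; skipped")
            continue
        batches: Dict[Tuple[str, str, str], List[DiscriminationRecord]] = {}
        if "tree" in config.methods:
            tree = bootstrap_support(
                aln, model=config.model, replicates=config.replicates,
                seed=int(sub_seeds[k]),
            )
            trees[mset] = tree
            for level in config.levels:
                recs = tree_success(
                    tree, dataset, level, config.threshold,
                    cohort="n2", marker_set=mset,
                )
                batches[("tree", level, "n2")] = recs
        if "similarity" in config.methods:
            table = build_score_table(dataset, mset, config.scoring)
            for level in config.levels:
                for cohort in config.cohorts:
                    recs = similarity_success(
                        dataset, mset, level, cohort, config.scoring, table
                    )
                    batches[("similarity", level, cohort)] = recs
        for (method, level, cohort), recs in batches.items():
            records.extend(recs)
            if not recs:
                log.append(
                    f"{method}/{level}/{cohort}/{'+'.join(mset)}: no testable taxa"
                )
                continue
            rs = discrimination_rate(recs)
            rows.append(
                {
                    "marker_set": "+".join(mset),
                    "method": method,
                    "level": level,
                    "cohort": cohort,
                    "successes": rs.successes,
                    "total": rs.total,
                    "pct": compute_rate(rs.successes, rs.total),
                }
            )
    rates = pd.DataFrame(
        rows,
        columns=[
            "marker_set", "method", "level", "cohort",
            "successes", "total", "pct",
        ],
    )
    return EvalSummary(rates, records, trees, log)
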