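"""Pairwise genetic distances on aligned sequences.

All distances use pairwise deletion: a column contributes to a pair only
when both sequences carry a determinate base (A/C/G/T) there.  Available
models:

``p``
    uncorrected proportion of differing comparable sites,
``jc``
    Jukes-Cantor 1969, ``d = -3/4 ln(1 - 4p/3)``,
``k2p``
    Kimura 1980 two-parameter, ``d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]`` with
    P and Q the transition and transversion proportions (the conventional
    default in barcoding studies; the package default).

A pair is *undefined* when it shares no comparable column or the model's
log argument leaves its domain (saturation).  Matrix construction either
raises, keeps NaN, or imputes undefined entries with the largest defined
distance plus an epsilon so that neighbour joining stays runnable; imputed
pairs are recorded on the result for audit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from ._kernels import MODEL_IDS, distance_matrix_kernel, encode, pairwise_counts
from .model import AlignedSequence, InputError, LocusAlignment

logger = logging.getLogger(__name__)

DEFAULT_MODEL = "k2p"


def _check_pair(a: AlignedSequence, b: AlignedSequence) -> None:
    if len(a) != len(b):
        raise InputError(
            f"sequences {a.specimen_id!r} and {b.specimen_id!r} have different "
            f"lengths ({len(a)} vs {len(b)})"
        )
    if a.locus != b.locus:
        raise InputError(f"loci differ: {a.locus!r} vs {b.locus!r}")


def _counts(a: AlignedSequence, b: AlignedSequence) -> Tuple[int, int, int]:
    _check_pair(a, b)
    comp, ts, tv = pairwise_counts(encode(a.residues), encode(b.residues))
    return int(comp), int(ts), int(tv)


def p_distance(a: AlignedSequence, b: AlignedSequence) -> Optional[float]:
    """Uncorrected distance; ``None`` when no column is comparable."""
    comp, ts, tv = _counts(a, b)
    if comp == 0:
        return None
    return (ts + tv) / comp


def jc_distance(a: AlignedSequence, b: AlignedSequence) -> Optional[float]:
    """Jukes-Cantor distance; ``None`` when undefined (p >= 3/4 or no overlap)."""
    comp, ts, tv = _counts(a, b)
    if comp == 0:
        return None
    p = (ts + tv) / comp
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def k2p_distance(a: AlignedSequence, b: AlignedSequence) -> Optional[float]:
    """Kimura two-parameter distance; ``None`` when saturated or no overlap."""
    comp, ts, tv = _counts(a, b)
    if comp == 0:
        return None
    P, Q = ts / comp, tv / comp
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric specimen-by-specimen distance matrix.

    ``values`` may contain NaN for undefined pairs unless an imputation or
    error policy was applied at construction.
    """

    ids: List[str]
    values: np.ndarray
    model: str = DEFAULT_MODEL
    undefined_pairs: List[Tuple[str, str]] = field(default_factory=list)
    imputed: bool = False

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match ids")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def write_tsv(self, path: Union[str, Path]) -> None:
        """PHYLIP-like square matrix: count line, then one row per specimen."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{sid}\t{row}\n")


def distance_matrix(
    aln: LocusAlignment,
    model: str = DEFAULT_MODEL,
    undefined: str = "impute",
    epsilon: float = 1e-3,
) -> DistanceMatrix:
    """All-pairs distances for one alignment (or a concatenated supermatrix).

    ``undefined`` is the policy for pairs with no comparable columns or a
    saturated model: ``"impute"`` (default; max defined distance + epsilon),
    ``"keep"`` (NaN entries) or ``"error"``.
    """
    if len(aln) < 2:
        raise InputError("distance matrix requires at least 2 sequences")
    if model not in MODEL_IDS:
        raise InputError(f"unknown model {model!r}; choose from {sorted(MODEL_IDS)}")
    ids = aln.ids
    codes = np.vstack([encode(aln[i].residues) for i in ids])
    values = distance_matrix_kernel(codes, MODEL_IDS[model])
    mask = np.isnan(values)
    undefined_pairs = [
        (ids[i], ids[j]) for i, j in zip(*np.where(np.triu(mask, 1)))
    ]
    dm = DistanceMatrix(ids, values, model, undefined_pairs)
    if undefined_pairs:
        if undefined == "error":
            raise InputError(
                f"{len(undefined_pairs)} undefined pair(s), e.g. "
                f"{undefined_pairs[0]}"
            )
        if undefined == "impute":
            impute_undefined(dm, epsilon)
        elif undefined != "keep":
            raise InputError(f"unknown undefined-pair policy {undefined!r}")
    return dm


def impute_undefined(dm: DistanceMatrix, epsilon: float = 1e-3) -> DistanceMatrix:
    """Replace NaN entries with (max defined distance + epsilon), in place."""
    mask = np.isnan(dm.values)
    if not mask.any():
        return dm
    off_diag = ~np.eye(len(dm.ids), dtype=bool)
    defined = dm.values[~mask & off_diag]
    if defined.size == 0:
        raise InputError("no defined off-diagonal distance to impute from")
    ceiling = float(defined.max()) + epsilon
    dm.values[mask] = ceiling
    dm.imputed = True
    logger.warning(
        "imputed %d undefined distance pair(s) with %.6g",
        len(dm.undefined_pairs),
        ceiling,
    )
    return dm
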