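"""Synthetic multi-locus barcode datasets with a known truth registry.

The generator emulates the statistical structure a barcoding survey of a
species-rich tree family presents to the evaluation pipeline:

* a genus/species hierarchy - genera as deep clades, species as subclades,
  individuals as a star within each species (no intraspecific genealogy);
* per-locus rate multipliers reproducing the usual divergence ordering of
  plant barcodes (rbcL least variable ... ITS most variable);
* per-locus missingness (sequencing recovery below 100%);
* shared deletion spans in the fast loci, so indel coding has work to do;
* a configurable rate of planted specimen label swaps - specimens whose
  recorded species is wrong - with the truth recorded for validation.

Sequences evolve along the hierarchy under a Kimura two-parameter process
with transition/transversion ratio 2 and uniform rates across sites.
Branch lengths are chosen so the configured intra/inter-specific
divergences are the expected *pairwise* substitution distances between
conspecific, congeneric and cross-genus individuals respectively (realized
p-distances sit slightly below them, since multiple hits go unseen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .model import AlignedSequence, BarcodeDataset, InputError, LocusAlignment, Specimen

_BASES = "ACGT"
# K2P instantaneous rates normalized to 1 substitution/site/unit time with
# transition/transversion ratio alpha/(2 beta) = 2
_ALPHA, _BETA = 2.0 / 3.0, 1.0 / 6.0


@dataclass(frozen=True)
class LocusModel:
    """One simulated barcode locus."""

    name: str
    length: int
    rate_multiplier: float = 1.0
    indel_rate: float = 0.0  # expected gap events per species clade
    missingness: float = 0.0  # probability a specimen lacks this locus

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness <= 1.0:
            raise InputError(f"locus {self.name!r}: missingness outside [0,1]")
        if self.length < 1 or self.rate_multiplier <= 0 or self.indel_rate < 0:
            raise InputError(f"locus {self.name!r}: invalid parameters")


@dataclass(frozen=True)
class SimulationConfig:
    n_genera: int = 10
    species_per_genus: Union[int, Tuple[int, int]] = 4
    #: int = exact count per species; (lo, hi) = truncated-geometric draw
    individuals_per_species: Union[int, Tuple[int, int]] = (1, 9)
    loci: Tuple[LocusModel, ...] = (
        LocusModel("rbcL", 665),
        LocusModel("matK", 746, rate_multiplier=1.2),
    )
    inter_species_divergence: float = 0.05
    intra_species_divergence: float = 0.002
    inter_genus_multiplier: float = 4.0
    swap_rate: float = 0.0
    seed: int = 0
    #: optional explicit per-species individual counts (overrides the range)
    species_counts: Optional[Tuple[int, ...]] = None
    #: optional explicit per-genus species counts (overrides species_per_genus)
    genus_sizes: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.swap_rate <= 1.0:
            raise InputError("swap_rate outside [0,1]")
        if self.inter_genus_multiplier < 1.0:
            raise InputError("inter_genus_multiplier must be >= 1")
        if min(self.intra_species_divergence, self.inter_species_divergence) < 0:
            raise InputError("divergences must be non-negative")
        if not self.loci:
            raise InputError("at least one locus is required")

    @property
    def n_species(self) -> int:
        if self.genus_sizes is not None:
            return int(sum(self.genus_sizes))
        if isinstance(self.species_per_genus, int):
            return self.n_genera * self.species_per_genus
        raise InputError("species count is random; simulate to realize it")


@dataclass
class SyntheticTruth:
    """True labels plus the planted-swap registry."""

    true_species: Dict[str, str]
    true_genus: Dict[str, str]
    #: (specimen_id, original/true species, assigned/wrong species)
    swaps: List[Tuple[str, str, str]]

    @property
    def swapped_ids(self) -> set:
        return {s[0] for s in self.swaps}


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _k2p_substitution_probs(t: float) -> Tuple[float, float]:
    """(transition prob, each-transversion prob) after branch length t."""
    if t <= 0:
        return 0.0, 0.0
    e1 = np.exp(-4.0 * _BETA * t)
    e2 = np.exp(-2.0 * (_ALPHA + _BETA) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 * (1.0 - e1)
    return p_ts, p_tv_each


def _evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of K2P evolution on a coded (0..3) sequence."""
    p_ts, p_tv = _k2p_substitution_probs(t)
    u = rng.random(seq.size)
    out = seq.copy()
    out[u < p_ts] ^= 2  # transition: A<->G, C<->T
    m1 = (u >= p_ts) & (u < p_ts + p_tv)
    out[m1] ^= 1  # transversion: A<->C, G<->T
    m2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[m2] ^= 3  # transversion: A<->T, C<->G
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


def _draw_count(spec, rng: np.random.Generator) -> int:
    """Individuals per species: exact int or truncated-geometric in [lo, hi].

    The geometric ratio 0.72 gives a mean of about 3 on the default 1-9
    range, matching a survey averaging three samples per species with many
    singletons.
    """
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    weights = 0.72 ** np.arange(lo, hi + 1)
    weights /= weights.sum()
    return int(rng.choice(np.arange(lo, hi + 1), p=weights))


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> Tuple[BarcodeDataset, SyntheticTruth]:
    """Generate a labelled dataset plus its truth registry.

    Deterministic for a fixed config (one RNG seeded by ``config.seed``
    drives tree shape, evolution, indels, missingness and label swaps).
    """
    rng = np.random.default_rng(config.seed)

    # ---- taxonomy scaffold -------------------------------------------
    if config.genus_sizes is not None:
        genus_sizes = list(config.genus_sizes)
    elif isinstance(config.species_per_genus, int):
        genus_sizes = [config.species_per_genus] * config.n_genera
    else:
        lo, hi = config.species_per_genus
        genus_sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_genera)]

    genera = [f"G{g + 1:02d}" for g in range(len(genus_sizes))]
    species: List[Tuple[str, str]] = []  # (species label, genus)
    for genus, size in zip(genera, genus_sizes):
        for s in range(size):
            species.append((f"{genus}S{s + 1:02d}", genus))

    if config.species_counts is not None:
        if len(config.species_counts) != len(species):
            raise InputError(
                f"species_counts has {len(config.species_counts)} entries for "
                f"{len(species)} species"
            )
        counts = list(config.species_counts)
    else:
        counts = [
            _draw_count(config.individuals_per_species, rng) for _ in species
        ]

    specimens: List[Tuple[str, str, str]] = []  # (id, species, genus)
    for (sp_label, genus), k in zip(species, counts):
        for i in range(k):
            specimens.append((f"{sp_label}I{i + 1}", sp_label, genus))

    # ---- branch lengths ----------------------------------------------
    # chosen so expected pairwise divergences match the configuration:
    # conspecific individuals ~ intra, congeneric heterospecifics ~ inter,
    # different genera ~ inter * multiplier
    genus_branch = (
        config.inter_species_divergence
        * (config.inter_genus_multiplier - 1.0)
        / 2.0
    )
    species_branch = max(
        config.inter_species_divergence - config.intra_species_divergence, 0.0
    ) / 2.0
    individual_branch = config.intra_species_divergence / 2.0

    # ---- evolve each locus -------------------------------------------
    alignments: Dict[str, LocusAlignment] = {}
    for locus in config.loci:
        mult = locus.rate_multiplier
        root = rng.integers(0, 4, size=locus.length).astype(np.int64)
        genus_seq = {
            g: _evolve(root, genus_branch * mult, rng) for g in genera
        }
        rows: Dict[str, np.ndarray] = {}
        species_members: Dict[str, List[str]] = {}
        for (sp_label, genus), k in zip(species, counts):
            anc = _evolve(genus_seq[genus], species_branch * mult, rng)
            members = []
            for i in range(k):
                sid = f"{sp_label}I{i + 1}"
                rows[sid] = _evolve(anc, individual_branch * mult, rng)
                members.append(sid)
            species_members[sp_label] = members

        residues = {sid: _decode(seq) for sid, seq in rows.items()}

        # indels: shared deletion spans within a species clade
        if locus.indel_rate > 0:
            for sp_label, members in species_members.items():
                n_events = rng.poisson(locus.indel_rate)
                for _ in range(n_events):
                    span = int(rng.integers(1, 6))
                    if locus.length <= span + 2:
                        continue
                    start = int(rng.integers(1, locus.length - span - 1))
                    n_carriers = int(rng.integers(1, len(members) + 1))
                    carriers = rng.choice(
                        len(members), size=n_carriers, replace=False
                    )
                    for c in carriers:
                        sid = members[int(c)]
                        r = residues[sid]
                        residues[sid] = (
                            r[:start] + "-" * span + r[start + span:]
                        )

        # missingness: drop specimen x locus independently
        kept = [
            sid
            for sid, _, _ in specimens
            if rng.random() >= locus.missingness
        ]
        alignments[locus.name] = LocusAlignment(
            locus.name,
            [AlignedSequence(sid, locus.name, residues[sid]) for sid in kept],
        )

    # ---- planted label swaps -----------------------------------------
    genus_for = {sp: g for sp, g in species}
    true_species = {sid: sp for sid, sp, _ in specimens}
    true_genus = {sid: g for sid, _, g in specimens}
    swaps: List[Tuple[str, str, str]] = []
    assigned: Dict[str, str] = dict(true_species)
    all_species = [sp for sp, _ in species]
    for sid, sp, _ in specimens:
        if config.swap_rate > 0 and rng.random() < config.swap_rate:
            others = [s for s in all_species if s != sp]
            wrong = others[int(rng.integers(0, len(others)))]
            assigned[sid] = wrong
            swaps.append((sid, sp, wrong))

    metadata = [
        Specimen(sid, assigned[sid], genus_for[assigned[sid]])
        for sid, _, _ in specimens
    ]
    dataset = BarcodeDataset(metadata, alignments)
    truth = SyntheticTruth(true_species, true_genus, swaps)
    return dataset, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _paper_like_species_counts() -> Tuple[int, ...]:
    """133 species totalling 409 individuals: 22 singletons plus 111 species
    of 2-9 individuals (mean just under 3.5), interleaved across genera."""
    counts = (
        [1] * 22 + [2] * 41 + [3] * 30 + [4] * 15 + [5] * 9
        + [6] * 7 + [7] * 5 + [8] * 3 + [9] * 1
    )
    assert sum(counts) == 409 and len(counts) == 133
    # stride permutation (gcd(8, 133) = 1) spreads sizes across genera
    return tuple(counts[(i * 8) % 133] for i in range(133))


_PRESETS = {
    "strong_gap": dict(
        n_genera=10,
        species_per_genus=4,
        individuals_per_species=3,
        loci=(
            LocusModel("rbcL", 665, rate_multiplier=1.0),
            LocusModel("matK", 746, rate_multiplier=1.2),
        ),
        inter_species_divergence=0.05,
        intra_species_divergence=0.002,
        inter_genus_multiplier=4.0,
    ),
    "weak_gap": dict(
        n_genera=10,
        species_per_genus=4,
        individuals_per_species=3,
        loci=(
            LocusModel("rbcL", 665, rate_multiplier=1.0),
            LocusModel("matK", 746, rate_multiplier=1.2),
        ),
        inter_species_divergence=0.015,
        intra_species_divergence=0.01,
        inter_genus_multiplier=4.0,
    ),
    "paper_like": dict(
        genus_sizes=(30, 25, 20, 15, 10, 8, 7, 6, 5, 3, 2, 2),
        n_genera=12,
        species_counts=_paper_like_species_counts(),
        individuals_per_species=(1, 9),
        loci=(
            LocusModel("rbcL", 665, rate_multiplier=1.0,
                       indel_rate=0.0, missingness=0.075),
            LocusModel("matK", 746, rate_multiplier=1.3,
                       indel_rate=0.1, missingness=0.075),
            LocusModel("trnH-psbA", 508, rate_multiplier=2.0,
                       indel_rate=0.4, missingness=0.216),
            LocusModel("ITS2", 420, rate_multiplier=2.5,
                       indel_rate=0.2, missingness=0.447),
            LocusModel("ITS", 845, rate_multiplier=3.0,
                       indel_rate=0.3, missingness=0.609),
        ),
        inter_species_divergence=0.02,
        intra_species_divergence=0.004,
        inter_genus_multiplier=3.0,
    ),
}


def preset(name: str, **overrides) -> SimulationConfig:
    """Named study conditions: ``strong_gap``, ``weak_gap``, ``paper_like``.

    ``strong_gap`` (intra 0.002, inter 0.05) is the perfect-barcode-gap
    limit; ``weak_gap`` (intra 0.01, inter 0.015) overlaps intra- and
    inter-specific divergences; ``paper_like`` mirrors a 409-specimen,
    133-species, 12-genus survey with five loci whose rate multipliers and
    missingness follow the usual plant-barcode hierarchy.
    """
    if name not in _PRESETS:
        raise InputError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return SimulationConfig(**params)
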