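"""Synthetic kinase families with planted SDR–substrate couplings.

The generator emulates the core assumption of catalytic-domain-based
specificity prediction: kinases with the same residue at a
specificity-determining alignment column share the same substrate preference
at the coupled window offset.  A :class:`PlantedModel` fixes an alignment of
``K`` kinases over ``L`` columns in which

* each *planted* column draws residues uniformly from a diverse pool spanning
  charge classes (acidic, basic, hydrophobic), and its coupled substrate
  offset samples, with probability ``gamma``, from a per-residue conditional
  distribution (charge-consistent by default, e.g. domain E ↔ substrate R) and
  otherwise from the flank background;
* every other column is conserved: a dominant neutral residue with the
  remaining mass spread over a neutral pool;
* non-coupled window offsets sample from the flank background, and the window
  center from a fixed S/T/Y acceptor distribution.

``gamma = 0`` makes peptides independent of the domains; ``gamma = 1`` with
the default point-mass conditionals plants a deterministic coupling.  All
draws run through one seeded :class:`numpy.random.Generator`, so equal seeds
give byte-identical outputs, and the exact per-kinase sampling distributions
are returned as ground-truth profile matrices for oracle comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alphabets import (
    ACCEPTORS,
    AMINO_ACIDS,
    N_OFFSETS,
    N_SUBSTRATE,
    OFFSETS,
    SUBSTRATE_ALPHABET,
    SUBSTRATE_INDEX,
    offset_to_col,
)
from .io_formats import AlignedDomainSet, KinaseSubstrateRecord, PhosphositeRegion
from .matrices import ProfileMatrix
from .sdr import SDRMap

__all__ = [
    "PlantedCoupling",
    "PlantedModel",
    "SyntheticDataset",
    "RecoveryReport",
    "generate",
    "recovery_report",
    "FLANK_BACKGROUND",
    "CENTER_DISTRIBUTION",
    "CHARGE_CONSISTENT_MAP",
    "CHARGE_INCONSISTENT_MAP",
]

#: Flank background over the 21 substrate symbols ('x' carries no mass):
#: smoothed human-proteome amino-acid frequencies.
_FLANK_FREQS = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}
FLANK_BACKGROUND: np.ndarray = np.zeros(N_SUBSTRATE)
for _aa, _f in _FLANK_FREQS.items():
    FLANK_BACKGROUND[SUBSTRATE_INDEX[_aa]] = _f
FLANK_BACKGROUND = FLANK_BACKGROUND / FLANK_BACKGROUND.sum()
FLANK_BACKGROUND.setflags(write=False)

#: Acceptor distribution at the window center (S/T/Y), phosphoproteome-like.
CENTER_DISTRIBUTION: np.ndarray = np.zeros(N_SUBSTRATE)
for _aa, _f in zip(ACCEPTORS, (0.60, 0.25, 0.15)):
    CENTER_DISTRIBUTION[SUBSTRATE_INDEX[_aa]] = _f
CENTER_DISTRIBUTION.setflags(write=False)

#: Charge-consistent residue map: domain residue -> preferred substrate
#: residue (acid<->base, hydrophobic<->hydrophobic), so both the mutual-
#: information and the charge-dependency detector carry signal.
CHARGE_CONSISTENT_MAP: dict[str, str] = {
    "E": "R", "D": "K", "K": "E", "R": "D", "L": "I", "F": "V",
}

#: Charge-inconsistent alternative: same mutual information, but targets that
#: are neutral under the interaction matrix, silencing the charge detector.
CHARGE_INCONSISTENT_MAP: dict[str, str] = {
    "E": "N", "D": "Q", "K": "M", "R": "A", "L": "W", "F": "C",
}

#: Neutral residues used for conserved (non-planted) columns.  The pool
#: deliberately excludes charged, hydrophobic-class and hydroxyl residues so
#: interaction-matrix signal is confined to the planted couplings.
NEUTRAL_POOL: str = "AGNQMWCP"


def _point_mass(symbol: str) -> np.ndarray:
    v = np.zeros(N_SUBSTRATE)
    v[SUBSTRATE_INDEX[symbol]] = 1.0
    return v


@dataclass
class PlantedCoupling:
    """One planted SDR column and its per-residue substrate conditionals."""

    column: int
    residue_pool: str
    conditional: dict[str, np.ndarray]  # domain residue -> 21-vector

    def __post_init__(self) -> None:
        for res in self.residue_pool:
            if res not in self.conditional:
                raise ValueError(f"no conditional for pool residue {res!r}")
        for res, vec in self.conditional.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (N_SUBSTRATE,) or (vec < 0).any() or abs(vec.sum() - 1) > 1e-9:
                raise ValueError(f"conditional for residue {res!r} is not stochastic")
            self.conditional[res] = vec


@dataclass
class PlantedModel:
    """Study conditions of one synthetic kinase family."""

    seed: int = 0
    n_kinases: int = 200
    n_peptides: int = 30
    alignment_length: int = 100
    gamma: float = 1.0
    conservation: float = 0.9
    planted: dict[int, PlantedCoupling] = field(default_factory=dict)
    flank_background: np.ndarray = field(default_factory=lambda: FLANK_BACKGROUND.copy())
    center_distribution: np.ndarray = field(default_factory=lambda: CENTER_DISTRIBUTION.copy())

    def __post_init__(self) -> None:
        if self.n_kinases < 2:
            raise ValueError("need at least 2 kinases")
        if self.n_peptides < 1:
            raise ValueError("need at least 1 peptide per kinase")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        columns = [c.column for c in self.planted.values()]
        if len(set(columns)) != len(columns):
            raise ValueError("planted columns must be distinct")
        for offset, coupling in self.planted.items():
            if offset not in OFFSETS:
                raise ValueError(f"planted offset {offset} outside -7..+7")
            if not 0 <= coupling.column < self.alignment_length:
                raise ValueError(f"planted column {coupling.column} outside alignment")
            if offset == 0:
                for res, vec in coupling.conditional.items():
                    mass = sum(vec[SUBSTRATE_INDEX[a]] for a in ACCEPTORS)
                    if abs(mass - 1.0) > 1e-9:
                        raise ValueError(
                            "a coupling at offset 0 must distribute over S/T/Y only"
                        )

    @classmethod
    def default(
        cls,
        seed: int = 0,
        gamma: float = 1.0,
        planted_offsets: Sequence[int] = (-3,),
        charge_consistent: bool = True,
        n_kinases: int = 200,
        n_peptides: int = 30,
        alignment_length: int = 100,
        conservation: float = 0.9,
    ) -> "PlantedModel":
        """The standard family: deterministic charge-consistent couplings.

        Planted columns sit at deterministic positions starting at 2L/5
        (40, 47, 54, ... for L = 100), one per requested offset, each with
        the 6-residue pool E/D/K/R/L/F and a point-mass conditional per
        residue.
        """
        residue_map = CHARGE_CONSISTENT_MAP if charge_consistent else CHARGE_INCONSISTENT_MAP
        start = (2 * alignment_length) // 5
        planted = {}
        for rank, offset in enumerate(planted_offsets):
            planted[offset] = PlantedCoupling(
                column=start + 7 * rank,
                residue_pool="".join(residue_map),
                conditional={res: _point_mass(tgt) for res, tgt in residue_map.items()},
            )
        return cls(
            seed=seed,
            n_kinases=n_kinases,
            n_peptides=n_peptides,
            alignment_length=alignment_length,
            gamma=gamma,
            conservation=conservation,
            planted=planted,
        )


@dataclass
class SyntheticDataset:
    """Generated family: alignment, pair records and ground-truth profiles."""

    model: PlantedModel
    domains: AlignedDomainSet
    records: list[KinaseSubstrateRecord]
    truth_profiles: dict[str, ProfileMatrix]


def generate(model: PlantedModel) -> SyntheticDataset:
    """Draw one synthetic family from a :class:`PlantedModel`."""
    rng = np.random.default_rng(model.seed)
    K, L, n = model.n_kinases, model.alignment_length, model.n_peptides
    kinase_ids = [f"KIN{k:04d}" for k in range(K)]
    planted_cols = {c.column: offset for offset, c in model.planted.items()}

    # --- domains: column by column, deterministic order of rng consumption
    align = np.empty((K, L), dtype="U1")
    for i in range(L):
        if i in planted_cols:
            pool = list(model.planted[planted_cols[i]].residue_pool)
            align[:, i] = rng.choice(pool, size=K)
        else:
            pool = list(NEUTRAL_POOL)
            dominant = rng.choice(pool)
            minors = [r for r in pool if r != dominant]
            p = np.full(len(pool), (1 - model.conservation) / len(minors))
            p[pool.index(dominant)] = model.conservation
            align[:, i] = rng.choice(pool, size=K, p=p)
    domains = AlignedDomainSet({kid: "".join(align[k]) for k, kid in enumerate(kinase_ids)})

    # --- per-kinase per-offset sampling distributions (= truth profiles)
    truth = np.empty((K, N_SUBSTRATE, N_OFFSETS))
    for offset in OFFSETS:
        j = offset_to_col(offset)
        base = model.center_distribution if offset == 0 else model.flank_background
        if offset in model.planted:
            coupling = model.planted[offset]
            for k in range(K):
                cond = coupling.conditional[align[k, coupling.column]]
                truth[k, :, j] = model.gamma * cond + (1 - model.gamma) * base
        else:
            truth[:, :, j] = base

    # --- peptides: one categorical draw block per (offset, distribution)
    peptides = np.empty((K, n, N_OFFSETS), dtype=np.intp)
    for offset in OFFSETS:
        j = offset_to_col(offset)
        if offset in model.planted:
            coupling = model.planted[offset]
            col = align[:, coupling.column]
            for res in sorted(set(col)):
                members = np.flatnonzero(col == res)
                p = truth[members[0], :, j]
                draws = rng.choice(N_SUBSTRATE, size=(len(members), n), p=p)
                peptides[members, :, j] = draws
        else:
            p = truth[0, :, j]
            peptides[:, :, j] = rng.choice(N_SUBSTRATE, size=(K, n), p=p)

    records = []
    for k, kid in enumerate(kinase_ids):
        for r in range(n):
            symbols = "".join(SUBSTRATE_ALPHABET[c] for c in peptides[k, r])
            records.append(KinaseSubstrateRecord(kid, PhosphositeRegion(symbols)))

    truth_profiles = {
        kid: ProfileMatrix(kid, truth[k], n_observations=n)
        for k, kid in enumerate(kinase_ids)
    }
    return SyntheticDataset(model, domains, records, truth_profiles)


@dataclass
class RecoveryReport:
    """How well SDR selection and prediction recovered the planted model."""

    planted_rank: dict[int, int | None]  # offset -> 1-based rank in the SDR map
    m: int
    sse_predicted: dict[str, float] = field(default_factory=dict)
    sse_baseline: dict[str, float] = field(default_factory=dict)

    @property
    def top1_rate(self) -> float:
        ranks = list(self.planted_rank.values())
        return sum(r == 1 for r in ranks) / len(ranks) if ranks else float("nan")

    @property
    def topm_rate(self) -> float:
        ranks = list(self.planted_rank.values())
        return sum(r is not None for r in ranks) / len(ranks) if ranks else float("nan")

    @property
    def mean_sse_predicted(self) -> float:
        return float(np.mean(list(self.sse_predicted.values())))

    @property
    def mean_sse_baseline(self) -> float:
        return float(np.mean(list(self.sse_baseline.values())))

    @property
    def beats_baseline_everywhere(self) -> bool:
        return all(
            self.sse_predicted[k] < self.sse_baseline[k] for k in self.sse_predicted
        )


def recovery_report(
    model: PlantedModel,
    sdr_map: SDRMap,
    predictions: Mapping[str, ProfileMatrix] | None = None,
    truth_profiles: Mapping[str, ProfileMatrix] | None = None,
    background: np.ndarray | None = None,
) -> RecoveryReport:
    """Summarize planted-column recovery and, optionally, profile SSE.

    The baseline matrix replicates the supplied background vector (or the
    model's flank background) in every window column; prediction quality is
    the SSE of each predicted profile against the generator's ground truth.
    """
    ranks: dict[int, int | None] = {}
    for offset, coupling in model.planted.items():
        rank = None
        for pos, sel in enumerate(sdr_map.selections(offset), start=1):
            if sel.column == coupling.column:
                rank = pos
                break
        ranks[offset] = rank
    report = RecoveryReport(planted_rank=ranks, m=sdr_map.m)
    if predictions is not None:
        if truth_profiles is None:
            raise ValueError("truth_profiles required to score predictions")
        from .evaluation import sse  # local import avoids a cycle

        bg = model.flank_background if background is None else np.asarray(background)
        baseline = np.tile(bg[:, None], (1, N_OFFSETS))
        for kid, predicted in predictions.items():
            truth = truth_profiles[kid]
            report.sse_predicted[kid] = sse(predicted, truth)
            report.sse_baseline[kid] = sse(baseline, truth.probs)
    return report
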