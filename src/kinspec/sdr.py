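"""Specificity-determining residue (SDR) inference.

An SDR is a catalytic-domain alignment column whose residue contacts one
substrate window position and shapes which peptides a kinase phosphorylates.
Candidate columns are scored per substrate offset by the product

    C_c(i, j) = I(i, j) · C(i, j)

of the mutual information ``I`` between the domain column and the substrate
position (in bits) and the *charge dependency* ``C``, the average
residue-interaction score between the residues found in the domain column and
the substrate symbols observed at the offset.  The product form is what makes
strongly conserved charged columns — high ``C`` but zero ``I`` — lose to
columns that actually covary with the substrate position.  Per offset the
top-``m`` columns with strictly positive C_c are kept (m = 7, matching the
maximal number of substrate-contacting residues seen in kinase–peptide
co-crystal structures) and their C_c values, normalized to sum 1, become
interaction weights.

Two variants are supported: *consensus-based* (substrate positions summarized
by each kinase's consensus symbol) and *profile-based* (each kinase
contributes its full profile column, via maximum-likelihood joint
distributions over domain residue × substrate symbol).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from .alphabets import (
    AMINO_ACIDS,
    DOMAIN_ALPHABET,
    DOMAIN_INDEX,
    GAP,
    GAP_CODE,
    N_DOMAIN,
    N_OFFSETS,
    N_SUBSTRATE,
    OFFSETS,
    SUBSTRATE_ALPHABET,
    SUBSTRATE_INDEX,
    X_CODE,
    offset_to_col,
)
from .io_formats import AlignedDomainSet
from .matrices import ConsensusSequence, ProfileMatrix

__all__ = [
    "ResidueInteractionMatrix",
    "default_interaction_matrix",
    "ColumnDistribution",
    "JointDistribution",
    "SDRSelection",
    "SDRMap",
    "mutual_information",
    "charge_dependency",
    "expected_interaction",
    "combined_dependency",
    "consensus_codes",
    "column_distributions_profile_based",
    "find_sdrs",
    "DEFAULT_M",
]

#: Maximal number of SDRs kept per substrate offset.
DEFAULT_M: int = 7

_ACIDIC = "DE"
_BASIC = "KR"
_HYDROPHOBIC = "FILV"
_HYDROXYL = "STY"


@dataclass
class ResidueInteractionMatrix:
    """Pairwise residue interaction scores R(substrate symbol, domain residue).

    Shape (21, 21): rows are substrate symbols (20 amino acids + 'x'), columns
    are domain symbols (20 amino acids + gap).  The 'x' row and the gap column
    are identically zero, and the amino-acid block is symmetric except for the
    substrate-side-only glycine (and proline) rows.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SUBSTRATE, N_DOMAIN):
            raise ValueError(f"interaction matrix must be 21x21, got {self.values.shape}")

    def score(self, substrate_symbol: str, domain_symbol: str) -> float:
        """Look up R for one substrate symbol / domain residue pair."""
        sub = SUBSTRATE_INDEX[substrate_symbol.upper() if substrate_symbol != "x" else "x"]
        dom = DOMAIN_INDEX[GAP if domain_symbol == "-" else domain_symbol]
        return float(self.values[sub, dom])

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("substrate\\domain\t" + "\t".join(DOMAIN_ALPHABET) + "\n")
            for i, sym in enumerate(SUBSTRATE_ALPHABET):
                fh.write(sym + "\t" + "\t".join(format(v, "g") for v in self.values[i]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueInteractionMatrix":
        rows = []
        with Path(path).open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[1:] != list(DOMAIN_ALPHABET):
                raise ValueError("interaction TSV columns must be the domain alphabet")
            labels = []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                labels.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
        if labels != list(SUBSTRATE_ALPHABET):
            raise ValueError("interaction TSV rows must be the substrate alphabet")
        return cls(np.array(rows))


def default_interaction_matrix(
    g_score: float = 0.5, p_score: float = 0.0
) -> ResidueInteractionMatrix:
    """Charge/hydrophobicity interaction scores.

    Like charges repel (−2), opposite charges attract (+2); histidine carries
    a weaker positive charge (+1 with acidic, −1 with basic residues and
    itself); hydrophobic residues attract each other (+2) and repel charged
    residues (−1); the hydroxyl residues S/T/Y weakly bind each other (+0.5)
    and are neutral otherwise.  Substrate-side glycine is favored against any
    domain residue (``g_score``, default +0.5: a small residue opens a pocket
    for the catalytic domain); substrate-side proline defaults to neutral
    (``p_score``).  Both are substrate-side only because the 3-D context of
    domain residues is unknown, so those two rows break the otherwise
    symmetric amino-acid block.
    """
    core = np.zeros((len(AMINO_ACIDS), len(AMINO_ACIDS)))
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    def fill(group_a: str, group_b: str, value: float) -> None:
        for a in group_a:
            for b in group_b:
                core[idx[a], idx[b]] = value
                core[idx[b], idx[a]] = value

    fill(_ACIDIC, _ACIDIC, -2.0)
    fill(_BASIC, _BASIC, -2.0)
    fill(_ACIDIC, _BASIC, +2.0)
    fill("H", _ACIDIC, +1.0)
    fill("H", _BASIC + "H", -1.0)
    fill(_HYDROPHOBIC, _HYDROPHOBIC, +2.0)
    fill(_HYDROPHOBIC, _ACIDIC + _BASIC, -1.0)
    fill(_HYDROXYL, _HYDROXYL, +0.5)

    values = np.zeros((N_SUBSTRATE, N_DOMAIN))
    values[: len(AMINO_ACIDS), : len(AMINO_ACIDS)] = core
    # substrate-side-only rows
    values[SUBSTRATE_INDEX["G"], : len(AMINO_ACIDS)] = g_score
    values[SUBSTRATE_INDEX["P"], : len(AMINO_ACIDS)] = p_score
    # 'x' row and gap column identically zero
    values[X_CODE, :] = 0.0
    values[:, GAP_CODE] = 0.0
    return ResidueInteractionMatrix(values)


# ---------------------------------------------------------------------------
# distributions


@dataclass
class ColumnDistribution:
    """Probability vector of one alignment column or substrate offset."""

    position: int | str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if abs(self.probs.sum() - 1.0) > 1e-9 or (self.probs < 0).any():
            raise ValueError("column distribution must be a probability vector")


@dataclass
class JointDistribution:
    """Joint p(x, y) over domain symbol × substrate symbol for one pair."""

    probs: np.ndarray  # shape (21 domain, 21 substrate)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_DOMAIN, N_SUBSTRATE):
            raise ValueError("joint must be 21x21 (domain x substrate)")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("joint must be a probability table")

    @property
    def domain_marginal(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    @property
    def substrate_marginal(self) -> np.ndarray:
        return self.probs.sum(axis=0)


def mutual_information(joint: JointDistribution | np.ndarray) -> float:
    """Mutual information of a joint table, in bits (≥ 0).

    I = Σ_{p(x,y)>0} p(x,y)·log₂(p(x,y) / (p₁(x)·p₂(y))); floating-point
    round-off can produce tiny negatives which are clamped to zero.
    """
    p = joint.probs if isinstance(joint, JointDistribution) else np.asarray(joint, float)
    p1 = p.sum(axis=1)
    p2 = p.sum(axis=0)
    mask = p > 0
    outer = np.outer(p1, p2)
    terms = p[mask] * np.log2(p[mask] / outer[mask])
    return max(0.0, float(terms.sum()))


def charge_dependency(
    domain_column: Sequence[str],
    substrate_column: Sequence[str],
    interaction: ResidueInteractionMatrix,
) -> float:
    """Mean interaction score over index-aligned (domain, substrate) pairs.

    ``C = (1/n) Σ_k R(y_k, x_k)``; gap and 'x' symbols contribute zero through
    the zero row/column of the interaction matrix.  Consensus case is folded
    to uppercase (letter case encodes confidence, not identity).
    """
    if len(domain_column) != len(substrate_column):
        raise ValueError("columns must be index-aligned over the same kinases")
    n = len(domain_column)
    if n == 0:
        raise ValueError("charge dependency needs at least one kinase")
    total = 0.0
    for x, y in zip(domain_column, substrate_column):
        y = y if y == "x" else y.upper()
        total += interaction.values[SUBSTRATE_INDEX[y], DOMAIN_INDEX[GAP if x == "-" else x]]
    return total / n


def expected_interaction(
    joint: JointDistribution | np.ndarray, interaction: ResidueInteractionMatrix
) -> float:
    """Charge dependency as the expectation of R under a joint table.

    ``Σ_{x,y} p(x, y)·R(y, x)`` — reduces exactly to the mean-over-kinases
    form when the joint is an empirical count table, and extends it to the
    profile-based variant's fractional joints.
    """
    p = joint.probs if isinstance(joint, JointDistribution) else np.asarray(joint, float)
    return float((p * interaction.values.T).sum())


def combined_dependency(mi: float, charge: float, mode: str = "product") -> float:
    """Correlation–charge dependency C_c combining the two detectors.

    The default product I·C zeroes out fully conserved columns (I = 0)
    regardless of their charge score; ``mode="sum"`` gives the alternative
    I + C reading.
    """
    if mi < 0:
        raise ValueError("mutual information must be >= 0")
    if mode == "product":
        return mi * charge
    if mode == "sum":
        return mi + charge
    raise ValueError(f"unknown combination mode {mode!r}")


# ---------------------------------------------------------------------------
# SDR maps


@dataclass(frozen=True)
class SDRSelection:
    """One selected domain column for one substrate offset."""

    column: int  # 0-based alignment column
    weight: float
    mi: float
    charge: float
    combined: float


@dataclass
class SDRMap:
    """Per substrate offset: selected domain columns with interaction weights.

    Offsets with no strictly positive correlation–charge dependency carry an
    empty list and are *uninformative* (their weight sum is 0; predictions
    fall back to the background there).
    """

    offsets: dict[int, list[SDRSelection]]
    m: int = DEFAULT_M
    variant: str = "consensus"

    def selections(self, offset: int) -> list[SDRSelection]:
        return self.offsets.get(offset, [])

    def is_uninformative(self, offset: int) -> bool:
        return not self.offsets.get(offset)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "m": self.m,
            "variant": self.variant,
            "offsets": {
                str(o): [
                    {
                        "column": s.column,
                        "weight": s.weight,
                        "mi": s.mi,
                        "charge": s.charge,
                        "combined": s.combined,
                    }
                    for s in self.offsets.get(o, [])
                ]
                for o in OFFSETS
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SDRMap":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        offsets = {
            int(o): [SDRSelection(**sel) for sel in sels]
            for o, sels in payload["offsets"].items()
        }
        return cls(offsets=offsets, m=payload["m"], variant=payload["variant"])


SubstrateInfo = Mapping[str, Union[ConsensusSequence, ProfileMatrix]]


def consensus_codes(consensus: ConsensusSequence) -> np.ndarray:
    """Substrate-alphabet codes of a consensus (case folded, 'x' kept)."""
    return np.fromiter(
        (SUBSTRATE_INDEX[c if c == "x" else c.upper()] for c in consensus.symbols),
        dtype=np.intp,
        count=N_OFFSETS,
    )


def column_distributions_profile_based(
    domains: AlignedDomainSet,
    profiles: Mapping[str, ProfileMatrix],
    column: int,
    offset: int,
) -> tuple[ColumnDistribution, ColumnDistribution, JointDistribution]:
    """Maximum-likelihood distributions for one (domain column, offset) pair.

    p₁(x) is the empirical residue distribution of the alignment column,
    p₂(y) the average profile column across kinases, and the joint couples
    each kinase's observed domain residue with its full profile column:
    p(x, y) = (1/w) Σ_k ⟦a_{k,i} = x⟧ · q^k_{y,j}.  Marginal consistency
    holds by construction.
    """
    ids = [k for k in domains.kinase_ids if k in profiles]
    if not ids:
        raise ValueError("no kinase has both a domain and a profile")
    A = domains.encoded(ids)
    j = offset_to_col(offset)
    joint = np.zeros((N_DOMAIN, N_SUBSTRATE))
    for row, kid in enumerate(ids):
        joint[A[row, column]] += profiles[kid].probs[:, j]
    joint /= len(ids)
    jd = JointDistribution(joint)
    return (
        ColumnDistribution(column, jd.domain_marginal),
        ColumnDistribution(offset, jd.substrate_marginal),
        jd,
    )


def _iter_joints_consensus(A: np.ndarray, Y: np.ndarray, column: int) -> np.ndarray:
    """Empirical joint count tables (domain x substrate) for one column."""
    n = A.shape[0]
    flat = A[:, column][:, None] * N_SUBSTRATE + Y  # Y: (n, 15)
    joints = np.zeros((N_OFFSETS, N_DOMAIN, N_SUBSTRATE))
    for j in range(N_OFFSETS):
        joints[j] = np.bincount(
            flat[:, j], minlength=N_DOMAIN * N_SUBSTRATE
        ).reshape(N_DOMAIN, N_SUBSTRATE)
    return joints / n


def find_sdrs(
    domains: AlignedDomainSet,
    substrate_info: SubstrateInfo,
    interaction: ResidueInteractionMatrix | None = None,
    m: int = DEFAULT_M,
    combine_mode: str = "product",
    min_combined: float = 0.0,
) -> SDRMap:
    """Select the top-m SDR columns per substrate offset by C_c = I·C.

    ``substrate_info`` maps kinase ids either to consensus sequences
    (consensus-based variant) or to profile matrices (profile-based variant);
    only kinases present in both the alignment and ``substrate_info`` train
    the statistics.  Columns are ranked by C_c (ties by column index),
    restricted to C_c strictly greater than ``min_combined`` (default 0), and
    their C_c values normalized to sum 1 as interaction weights.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if interaction is None:
        interaction = default_interaction_matrix()
    ids = [k for k in sorted(substrate_info) if k in domains]
    if len(ids) < 2:
        raise ValueError("substrate_info must cover at least 2 aligned kinases")
    first = substrate_info[ids[0]]
    variant = "profile" if isinstance(first, ProfileMatrix) else "consensus"
    A = domains.encoded(ids)
    L = domains.alignment_length
    R_t = interaction.values.T  # (domain, substrate)

    if variant == "consensus":
        Y = np.stack([consensus_codes(substrate_info[k]) for k in ids])  # type: ignore[arg-type]
    else:
        Q = np.stack([substrate_info[k].probs for k in ids])  # type: ignore[union-attr]

    mi = np.zeros((L, N_OFFSETS))
    charge = np.zeros((L, N_OFFSETS))
    n = len(ids)
    for i in range(L):
        if variant == "consensus":
            joints = _iter_joints_consensus(A, Y, i)
        else:
            grouped = np.zeros((N_DOMAIN, N_SUBSTRATE, N_OFFSETS))
            np.add.at(grouped, A[:, i], Q)
            joints = np.moveaxis(grouped, 2, 0) / n
        for j in range(N_OFFSETS):
            mi[i, j] = mutual_information(joints[j])
            charge[i, j] = float((joints[j] * R_t).sum())

    combined = np.array(
        [
            [combined_dependency(mi[i, j], charge[i, j], combine_mode) for j in range(N_OFFSETS)]
            for i in range(L)
        ]
    )

    offsets: dict[int, list[SDRSelection]] = {}
    for j, offset in enumerate(OFFSETS):
        cc = combined[:, j]
        candidates = np.flatnonzero(cc > min_combined)
        # rank by descending C_c, ties by ascending column index
        order = candidates[np.lexsort((candidates, -cc[candidates]))][:m]
        total = cc[order].sum()
        offsets[offset] = [
            SDRSelection(
                column=int(i),
                weight=float(cc[i] / total),
                mi=float(mi[i, j]),
                charge=float(charge[i, j]),
                combined=float(cc[i]),
            )
            for i in order
        ]
    return SDRMap(offsets=offsets, m=m, variant=variant)
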