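"""Evaluation procedures: matrix SSE, threshold-0 classification, ranking.

Predicted and empirical profiles are compared by the sum of squared
entry-wise differences (SSE).  The classifier accepts a candidate 15-mer for
a kinase when its additive PSSM score is ≥ 0 and rejects it otherwise;
negatives are random 15-mers with flanks uniform over the 20 amino acids and
the center uniform over S/T/Y (non-acceptor centers would not be valid
phosphosite regions).  For per-site ranking, all kinases are sorted by
descending PSSM score with deterministic lexicographic tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alphabets import AMINO_ACIDS, ACCEPTORS, N_OFFSETS
from .io_formats import KinaseSubstrateRecord, PhosphositeRegion
from .matrices import ProfileMatrix, PSSM, score_region

__all__ = [
    "ConfusionSummary",
    "RankedKinase",
    "sse",
    "generate_negatives",
    "classify",
    "confusion",
    "pool_confusions",
    "rank_kinases",
    "rank_histogram",
    "split_train_test",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/FP/FN/TN counts with the derived accuracy/sensitivity/specificity."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        """(TP+TN)/total; nan when no examples were evaluated."""
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def sensitivity(self) -> float:
        """TP/(TP+FN); nan (undefined) without positive examples."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        """TN/(TN+FP); nan (undefined) without negative examples."""
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")


@dataclass(frozen=True)
class RankedKinase:
    kinase_id: str
    score: float
    rank: int  # 1-based


def sse(a: ProfileMatrix | np.ndarray, b: ProfileMatrix | np.ndarray) -> float:
    """Sum of squared entry-wise differences between two 21×15 matrices."""
    av = a.probs if isinstance(a, ProfileMatrix) else np.asarray(a, float)
    bv = b.probs if isinstance(b, ProfileMatrix) else np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch {av.shape} vs {bv.shape}")
    return float(((av - bv) ** 2).sum())


def generate_negatives(
    n: int,
    seed: int | np.random.Generator,
    center_alphabet: str = ACCEPTORS,
    flank_alphabet: str = AMINO_ACIDS,
) -> list[PhosphositeRegion]:
    """Seeded uniform-random negative phosphosite regions.

    Flank offsets draw uniformly from ``flank_alphabet`` (default: the 20
    amino acids, no 'x' — physical surface peptides have residues); the
    center draws uniformly from ``center_alphabet`` (default S/T/Y, so every
    negative is a valid region).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flanks = rng.integers(0, len(flank_alphabet), size=(n, N_OFFSETS))
    centers = rng.integers(0, len(center_alphabet), size=n)
    out = []
    for row, c in zip(flanks, centers):
        symbols = [flank_alphabet[k] for k in row]
        symbols[7] = center_alphabet[c]
        out.append(PhosphositeRegion("".join(symbols)))
    return out


def classify(pssm: PSSM, region: PhosphositeRegion) -> bool:
    """Accept (True) iff the additive PSSM score is ≥ 0."""
    return score_region(pssm, region) >= 0


def confusion(
    pssm: PSSM,
    positives: Iterable[PhosphositeRegion],
    negatives: Iterable[PhosphositeRegion],
) -> ConfusionSummary:
    """Threshold-0 confusion counts for one kinase's classifier."""
    tp = fn = fp = tn = 0
    for region in positives:
        if classify(pssm, region):
            tp += 1
        else:
            fn += 1
    for region in negatives:
        if classify(pssm, region):
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


def pool_confusions(summaries: Iterable[ConfusionSummary]) -> ConfusionSummary:
    """Element-wise sum of per-kinase confusion counts."""
    tp = fp = fn = tn = 0
    for s in summaries:
        tp, fp, fn, tn = tp + s.tp, fp + s.fp, fn + s.fn, tn + s.tn
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


def rank_kinases(pssms: Sequence[PSSM], region: PhosphositeRegion) -> list[RankedKinase]:
    """All kinases sorted by descending score; ties by kinase id (stable)."""
    scored = sorted(
        ((score_region(p, region), p.kinase_id) for p in pssms),
        key=lambda t: (-t[0], t[1]),
    )
    return [RankedKinase(kid, s, rank) for rank, (s, kid) in enumerate(scored, start=1)]


def rank_histogram(ranks: Iterable[int], n_bins: int | None = None) -> dict[int, int]:
    """Histogram of the rank achieved by the annotated kinase per site."""
    hist: dict[int, int] = {}
    for r in ranks:
        hist[r] = hist.get(r, 0) + 1
    if n_bins is not None:
        hist = {r: hist.get(r, 0) for r in range(1, n_bins + 1)}
    return hist


def split_train_test(
    records: Sequence[KinaseSubstrateRecord], n_test: int = 5
) -> tuple[list[KinaseSubstrateRecord], list[KinaseSubstrateRecord]]:
    """Hold out the ``n_test`` kinases with the most pairs as the test set.

    Mirrors the evaluation scheme in which the best-characterized kinases —
    whose empirical profiles are most trustworthy — are reserved for testing.
    Ties in pair count break by kinase id for determinism.
    """
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.kinase_id] = counts.get(rec.kinase_id, 0) + 1
    test_ids = set(sorted(counts, key=lambda k: (-counts[k], k))[:n_test])
    train = [r for r in records if r.kinase_id not in test_ids]
    test = [r for r in records if r.kinase_id in test_ids]
    return train, test
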