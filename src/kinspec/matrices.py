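"""Profile matrices, background frequencies, smoothed PSSMs and consensus calls.

A kinase's *profile matrix* holds the observed probability of each of the 21
substrate symbols at each of the 15 window offsets across its confirmed
phosphosites.  The *background* is the pooled symbol frequency over all
confirmed phosphosite regions, excluding the offsets −3, −2, 0 and +1 that are
strongly biased by kinase recognition itself.  The PSSM transform

    M(i, j) = sign(P(i, j) − B(i)) · |P(i, j) − B(i)|^e,   e = 1.2 by default

keeps every entry finite (the classical log-odds transform blows up on the
many zero profile entries seen with small substrate counts) while preserving
the positive/negative-determinant logic: an entry is positive exactly when a
residue is enriched over background at that offset.  A candidate 15-mer is
scored by summing the 15 looked-up PSSM entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alphabets import (
    AMINO_ACIDS,
    N_OFFSETS,
    N_SUBSTRATE,
    OFFSETS,
    SUBSTRATE_ALPHABET,
    offset_to_col,
)
from .io_formats import KinaseSubstrateRecord, MatrixFile, PhosphositeRegion

__all__ = [
    "ProfileMatrix",
    "BackgroundFrequencies",
    "PSSM",
    "ConsensusSequence",
    "DEFAULT_EXCLUDED_OFFSETS",
    "DEFAULT_EXPONENT",
    "build_profile",
    "profile_from_codes",
    "compute_background",
    "build_pssm",
    "log_odds_matrix",
    "score_region",
    "score_regions",
    "build_consensus",
]

#: Offsets excluded from the background tally (kinase-recognition biased).
DEFAULT_EXCLUDED_OFFSETS: frozenset[int] = frozenset({-3, -2, 0, 1})

#: Smoothing exponent of the PSSM transform.
DEFAULT_EXPONENT: float = 1.2

_STOCHASTIC_TOL = 1e-9


@dataclass
class ProfileMatrix:
    """Column-stochastic 21×15 substrate-symbol probability matrix."""

    kinase_id: str
    probs: np.ndarray
    n_observations: int | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_SUBSTRATE, N_OFFSETS):
            raise ValueError(f"profile must be 21x15, got {self.probs.shape}")
        if (self.probs < -_STOCHASTIC_TOL).any():
            raise ValueError("profile entries must be non-negative")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=_STOCHASTIC_TOL, rtol=0.0):
            raise ValueError(f"profile columns must sum to 1, got {colsums}")

    def column(self, offset: int) -> np.ndarray:
        return self.probs[:, offset_to_col(offset)]

    def to_matrix_file(self) -> MatrixFile:
        return MatrixFile(self.kinase_id, "profile", self.probs.copy())

    @classmethod
    def from_matrix_file(cls, mf: MatrixFile) -> "ProfileMatrix":
        return cls(mf.kinase_id, mf.values)


@dataclass
class BackgroundFrequencies:
    """Pooled substrate-symbol frequencies over phosphosite regions."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (N_SUBSTRATE,):
            raise ValueError(f"background must have 21 entries, got {self.freqs.shape}")
        if (self.freqs < 0).any():
            raise ValueError("background frequencies must be non-negative")
        if abs(self.freqs.sum() - 1.0) > _STOCHASTIC_TOL:
            raise ValueError("background frequencies must sum to 1")

    def __getitem__(self, symbol: str) -> float:
        return float(self.freqs[SUBSTRATE_ALPHABET.index(symbol)])


@dataclass
class PSSM:
    """Position-specific scoring matrix with positive/negative determinants."""

    kinase_id: str
    scores: np.ndarray
    exponent: float = DEFAULT_EXPONENT
    background: BackgroundFrequencies | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (N_SUBSTRATE, N_OFFSETS):
            raise ValueError(f"PSSM must be 21x15, got {self.scores.shape}")
        if not np.isfinite(self.scores).all():
            raise ValueError("PSSM entries must all be finite")

    def to_matrix_file(self) -> MatrixFile:
        return MatrixFile(self.kinase_id, "pssm", self.scores.copy())


@dataclass(frozen=True)
class ConsensusSequence:
    """15-symbol profile summary: uppercase strong, lowercase weak, 'x' none."""

    kinase_id: str
    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) != N_OFFSETS:
            raise ValueError("consensus must have 15 symbols")

    def at(self, offset: int) -> str:
        return self.symbols[offset_to_col(offset)]

    def __str__(self) -> str:
        return self.symbols


# ---------------------------------------------------------------------------


def profile_from_codes(
    kinase_id: str, codes: np.ndarray, pseudocount: float = 0.0
) -> ProfileMatrix:
    """Build a profile from an (n, 15) array of substrate-symbol codes."""
    codes = np.asarray(codes)
    if codes.ndim != 2 or codes.shape[1] != N_OFFSETS:
        raise ValueError("codes must have shape (n, 15)")
    n = codes.shape[0]
    if n < 1:
        raise ValueError("at least one phosphosite region is required")
    counts = np.zeros((N_SUBSTRATE, N_OFFSETS))
    for j in range(N_OFFSETS):
        counts[:, j] = np.bincount(codes[:, j], minlength=N_SUBSTRATE)
    probs = (counts + pseudocount) / (n + N_SUBSTRATE * pseudocount)
    return ProfileMatrix(kinase_id, probs, n_observations=n)


def build_profile(
    records: Sequence[KinaseSubstrateRecord], pseudocount: float = 0.0
) -> ProfileMatrix:
    """Maximum-likelihood profile of one kinase's confirmed phosphosites.

    Entry (i, j) is ``(count of symbol i at offset j + pseudocount) /
    (n + 21·pseudocount)``.  The default pseudocount 0 keeps the raw observed
    frequencies (zeros included); pass a positive value for Laplace smoothing.
    """
    if not records:
        raise ValueError("cannot build a profile from zero records")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    kinase_ids = {r.kinase_id for r in records}
    if len(kinase_ids) != 1:
        raise ValueError(f"records mix kinase ids: {sorted(kinase_ids)}")
    codes = np.stack([r.region.codes for r in records])
    return profile_from_codes(kinase_ids.pop(), codes, pseudocount)


def compute_background(
    regions: Iterable[PhosphositeRegion],
    excluded_offsets: frozenset[int] | set[int] = DEFAULT_EXCLUDED_OFFSETS,
) -> BackgroundFrequencies:
    """Pooled symbol frequencies over all regions at non-excluded offsets."""
    excluded = set(excluded_offsets)
    kept_cols = [offset_to_col(o) for o in OFFSETS if o not in excluded]
    if not kept_cols:
        raise ValueError("excluded_offsets covers every window position")
    counts = np.zeros(N_SUBSTRATE)
    n_regions = 0
    for region in regions:
        counts += np.bincount(region.codes[kept_cols], minlength=N_SUBSTRATE)
        n_regions += 1
    if n_regions == 0:
        raise ValueError("at least one region is required")
    return BackgroundFrequencies(counts / counts.sum())


def build_pssm(
    profile: ProfileMatrix,
    background: BackgroundFrequencies,
    exponent: float = DEFAULT_EXPONENT,
    form: str = "power",
) -> PSSM:
    """Smoothed PSSM from a profile and the background.

    ``form="power"`` (default): M = sign(P−B)·|P−B|^exponent, finite
    everywhere, zero exactly where P = B.  The alternative log-odds form is
    available via :func:`log_odds_matrix` but is not finite on zero profile
    entries and therefore never used on the prediction path.
    """
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    if form != "power":
        raise ValueError(f"unknown PSSM form {form!r}; see log_odds_matrix")
    diff = profile.probs - background.freqs[:, None]
    scores = np.sign(diff) * np.abs(diff) ** exponent
    return PSSM(profile.kinase_id, scores, exponent=exponent, background=background)


def log_odds_matrix(
    profile: ProfileMatrix, background: BackgroundFrequencies
) -> np.ndarray:
    """Classical log₂-odds matrix log₂(P/B); reference only.

    Contains −inf wherever the profile has a zero entry (and ±nan where the
    background is itself zero), which is precisely why the power-smoothed
    transform is used for scoring.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(profile.probs / background.freqs[:, None])


def score_region(pssm: PSSM, region: PhosphositeRegion) -> float:
    """Additive kinase specificity score: Σ_j M(r_j, j) over the 15 offsets."""
    return float(pssm.scores[region.codes, np.arange(N_OFFSETS)].sum())


def score_regions(pssm: PSSM, codes: np.ndarray) -> np.ndarray:
    """Vectorized scores for an (n, 15) array of region codes."""
    codes = np.asarray(codes)
    return pssm.scores[codes, np.arange(N_OFFSETS)].sum(axis=1)


def build_consensus(
    profile: ProfileMatrix,
    upper_threshold: float = 0.15,
    lower_threshold: float = 0.08,
) -> ConsensusSequence:
    """Call the consensus sequence of a profile.

    Per column the most probable amino acid (the 'x' row never wins; ties
    break by fixed alphabet order via argmax) is emitted uppercase when its
    probability ≥ ``upper_threshold``, lowercase when in
    [``lower_threshold``, ``upper_threshold``), and as the don't-care symbol
    'x' below that.  Closed lower boundaries make the three bands partition
    [0, 1].
    """
    if not 0 < lower_threshold <= upper_threshold:
        raise ValueError("need 0 < lower_threshold <= upper_threshold")
    aa_block = profile.probs[: len(AMINO_ACIDS), :]
    winners = aa_block.argmax(axis=0)
    probs = aa_block[winners, np.arange(N_OFFSETS)]
    out = []
    for win, p in zip(winners, probs):
        aa = AMINO_ACIDS[win]
        if p >= upper_threshold:
            out.append(aa)
        elif p >= lower_threshold:
            out.append(aa.lower())
        else:
            out.append("x")
    return ConsensusSequence(profile.kinase_id, "".join(out))
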