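"""Profile and PSSM prediction for kinases from their catalytic domain alone.

Given the SDR map learned on kinases with substrate data, each substrate
offset of a query kinase is predicted as a weighted mixture of conditional
substrate-symbol distributions, one per selected SDR column:

    P̂(y, j) = Σ_l w_{j,l} · P(Y_j = y | X_{i_l} = a_query[i_l])

with the interaction weights w taken from the SDR map (columns with higher
correlation–charge dependency dominate the estimate).  A query residue never
observed at an SDR column in training — or a gap — backs off to the training
marginal of the offset, and offsets with no informative SDR fall back to the
background frequencies, so predictions degrade gracefully toward the
observed substrate composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .alphabets import (
    GAP_CODE,
    N_OFFSETS,
    N_SUBSTRATE,
    OFFSETS,
    encode_domain,
    offset_to_col,
)
from .io_formats import AlignedDomainSet
from .matrices import (
    DEFAULT_EXPONENT,
    BackgroundFrequencies,
    ConsensusSequence,
    ProfileMatrix,
    PSSM,
    build_pssm,
)
from .sdr import SDRMap, SubstrateInfo, consensus_codes

__all__ = [
    "ConditionalTable",
    "PredictedSpecificity",
    "fit_conditionals",
    "predict_profile",
    "predict_all",
]


@dataclass
class ConditionalTable:
    """P(substrate symbol at offset j | domain residue at SDR column i).

    ``given[(offset, column)]`` maps each domain-residue code observed at the
    column in training to a 21-vector over substrate symbols;
    ``backoff[(offset, column)]`` holds the training marginal used for
    unseen residues and gaps.
    """

    given: dict[tuple[int, int], dict[int, np.ndarray]] = field(default_factory=dict)
    backoff: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    variant: str = "consensus"

    def distribution(self, offset: int, column: int, residue_code: int) -> tuple[np.ndarray, bool]:
        """Conditional for a query residue; returns (vector, backed_off)."""
        table = self.given[(offset, column)]
        if residue_code != GAP_CODE and residue_code in table:
            return table[residue_code], False
        return self.backoff[(offset, column)], True


@dataclass
class PredictedSpecificity:
    """Predicted profile + PSSM for one kinase, with per-offset diagnostics."""

    kinase_id: str
    profile: ProfileMatrix
    pssm: PSSM
    diagnostics: dict[int, dict] = field(default_factory=dict)


def fit_conditionals(
    domains: AlignedDomainSet,
    substrate_info: SubstrateInfo,
    sdr_map: SDRMap,
    interaction_unused=None,
) -> ConditionalTable:
    """Estimate the SDR-conditioned substrate distributions from training data.

    Consensus variant: plain conditional frequencies of consensus symbols
    among kinases sharing the domain residue.  Profile variant: the Bayes
    conditional p(x, y)/p₁(x) of the maximum-likelihood joint, i.e. the
    average profile column of the kinases sharing the residue.  Only residues
    observed at the column are stored; gaps route to the backoff marginal.
    """
    ids = [k for k in sorted(substrate_info) if k in domains]
    if not ids:
        raise ValueError("no kinase has both a domain and substrate information")
    A = domains.encoded(ids)
    first = substrate_info[ids[0]]
    variant = "profile" if isinstance(first, ProfileMatrix) else "consensus"

    if variant == "consensus":
        Y = np.stack([consensus_codes(substrate_info[k]) for k in ids])  # type: ignore[arg-type]
    else:
        Q = np.stack([substrate_info[k].probs for k in ids])  # type: ignore[union-attr]

    table = ConditionalTable(variant=variant)
    for offset in OFFSETS:
        j = offset_to_col(offset)
        for sel in sdr_map.selections(offset):
            i = sel.column
            col = A[:, i]
            if (col == GAP_CODE).all():
                raise ValueError(
                    f"SDR column {i} selected for offset {offset:+d} is entirely "
                    "gapped in the training alignment"
                )
            cond: dict[int, np.ndarray] = {}
            if variant == "consensus":
                marginal = np.bincount(Y[:, j], minlength=N_SUBSTRATE).astype(float)
                for x in np.unique(col):
                    if x == GAP_CODE:
                        continue
                    sub = Y[col == x, j]
                    counts = np.bincount(sub, minlength=N_SUBSTRATE).astype(float)
                    cond[int(x)] = counts / counts.sum()
            else:
                marginal = Q[:, :, j].sum(axis=0)
                for x in np.unique(col):
                    if x == GAP_CODE:
                        continue
                    block = Q[col == x, :, j].sum(axis=0)
                    cond[int(x)] = block / block.sum()
            table.given[(offset, i)] = cond
            table.backoff[(offset, i)] = marginal / marginal.sum()
    return table


def predict_profile(
    query_domain: str | np.ndarray,
    sdr_map: SDRMap,
    conditionals: ConditionalTable,
    background: BackgroundFrequencies,
    kinase_id: str = "query",
    alignment_length: int | None = None,
) -> tuple[ProfileMatrix, dict[int, dict]]:
    """Predict one kinase's 21×15 profile from its aligned catalytic domain.

    Returns the column-stochastic profile (columns renormalized to absorb
    floating-point drift) and a per-offset diagnostic recording which SDR
    columns fired and which backed off.
    """
    codes = (
        encode_domain(query_domain) if isinstance(query_domain, str) else np.asarray(query_domain)
    )
    if alignment_length is not None and codes.shape[0] != alignment_length:
        raise ValueError(
            f"query domain length {codes.shape[0]} != alignment length {alignment_length}"
        )
    probs = np.zeros((N_SUBSTRATE, N_OFFSETS))
    diagnostics: dict[int, dict] = {}
    for offset in OFFSETS:
        j = offset_to_col(offset)
        selections = sdr_map.selections(offset)
        if not selections:
            probs[:, j] = background.freqs
            diagnostics[offset] = {"mode": "background", "fired": [], "backed_off": []}
            continue
        fired, backed = [], []
        column = np.zeros(N_SUBSTRATE)
        for sel in selections:
            vec, backed_off = conditionals.distribution(offset, sel.column, int(codes[sel.column]))
            column += sel.weight * vec
            (backed if backed_off else fired).append(sel.column)
        probs[:, j] = column / column.sum()
        diagnostics[offset] = {"mode": "mixture", "fired": fired, "backed_off": backed}
    return ProfileMatrix(kinase_id, probs), diagnostics


def predict_all(
    domains: AlignedDomainSet,
    sdr_map: SDRMap,
    conditionals: ConditionalTable,
    background: BackgroundFrequencies,
    exponent: float = DEFAULT_EXPONENT,
) -> tuple[list[PredictedSpecificity], dict[str, str]]:
    """Predict profile + PSSM for every domain in the set.

    Per-kinase failures are collected (not raised) and reported in the second
    return value; output is deterministically ordered by kinase id.
    """
    predictions: list[PredictedSpecificity] = []
    failures: dict[str, str] = {}
    for kid in sorted(domains.kinase_ids):
        try:
            profile, diag = predict_profile(
                domains[kid],
                sdr_map,
                conditionals,
                background,
                kinase_id=kid,
                alignment_length=domains.alignment_length,
            )
            pssm = build_pssm(profile, background, exponent=exponent)
            predictions.append(PredictedSpecificity(kid, profile, pssm, diag))
        except ValueError as exc:
            failures[kid] = str(exc)
    return predictions, failures
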