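"""Model/Results interface tying the pipeline together.

:class:`KinaseSpecificityModel` holds the data (kinase–phosphosite pairs and
the aligned catalytic domains) and the modelling choices; :meth:`fit` learns
the background, the per-kinase empirical profiles, the SDR map and the
SDR-conditioned substrate distributions, and returns a
:class:`SpecificityResults` carrying the estimates together with prediction,
scoring, evaluation and plotting methods::

    model = KinaseSpecificityModel.from_files("pairs.tsv", "domains.fasta")
    results = model.fit()
    print(results.summary())
    predicted = results.predict("KIN0007")
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabets import OFFSETS
from .evaluation import sse
from .io_formats import (
    AlignedDomainSet,
    KinaseSubstrateRecord,
    PhosphositeRegion,
    iter_kinase_groups,
    read_aligned_domains,
    read_pairs,
    read_proteins,
    write_matrix,
)
from .matrices import (
    DEFAULT_EXCLUDED_OFFSETS,
    DEFAULT_EXPONENT,
    BackgroundFrequencies,
    ConsensusSequence,
    ProfileMatrix,
    PSSM,
    build_consensus,
    build_profile,
    build_pssm,
    compute_background,
    score_region,
)
from .prediction import (
    ConditionalTable,
    PredictedSpecificity,
    fit_conditionals,
    predict_all,
    predict_profile,
)
from .sdr import (
    DEFAULT_M,
    ResidueInteractionMatrix,
    SDRMap,
    default_interaction_matrix,
    find_sdrs,
)

__all__ = ["KinaseSpecificityModel", "SpecificityResults"]


class KinaseSpecificityModel:
    """Substrate-specificity model over a kinase family.

    Parameters
    ----------
    records
        Experimentally confirmed kinase–phosphosite pairs.
    domains
        Fixed-length gapped catalytic-domain alignment covering (at least)
        the kinases to be predicted.
    variant
        ``"profile"`` (default; uses full profile columns, the more accurate
        module) or ``"consensus"`` (summarizes each kinase by its consensus
        sequence first).
    min_peptides
        Minimal number of confirmed peptides for a kinase to enter SDR
        training (default 10 — below that, empirical profiles and consensus
        calls are too noisy to trust).
    exponent, pseudocount, m, excluded_offsets, interaction, combine_mode
        Passed through to the corresponding pipeline stages.
    """

    def __init__(
        self,
        records: Sequence[KinaseSubstrateRecord],
        domains: AlignedDomainSet,
        variant: str = "profile",
        min_peptides: int = 10,
        pseudocount: float = 0.0,
        exponent: float = DEFAULT_EXPONENT,
        m: int = DEFAULT_M,
        excluded_offsets: Iterable[int] = DEFAULT_EXCLUDED_OFFSETS,
        interaction: ResidueInteractionMatrix | None = None,
        combine_mode: str = "product",
        consensus_upper: float = 0.15,
        consensus_lower: float = 0.08,
    ) -> None:
        if variant not in ("profile", "consensus"):
            raise ValueError(f"unknown variant {variant!r}")
        if not records:
            raise ValueError("at least one kinase-substrate record is required")
        self.records = list(records)
        self.domains = domains
        self.variant = variant
        self.min_peptides = min_peptides
        self.pseudocount = pseudocount
        self.exponent = exponent
        self.m = m
        self.excluded_offsets = frozenset(excluded_offsets)
        self.interaction = interaction or default_interaction_matrix()
        self.combine_mode = combine_mode
        self.consensus_upper = consensus_upper
        self.consensus_lower = consensus_lower

    @classmethod
    def from_files(
        cls,
        pairs_path: str | Path,
        domains_path: str | Path,
        proteins_path: str | Path | None = None,
        **kwargs,
    ) -> "KinaseSpecificityModel":
        proteins = read_proteins(proteins_path) if proteins_path else None
        records = read_pairs(pairs_path, proteins=proteins)
        domains = read_aligned_domains(domains_path)
        return cls(records, domains, **kwargs)

    def fit(self) -> "SpecificityResults":
        """Learn background, profiles, SDR map and conditionals."""
        profiles: dict[str, ProfileMatrix] = {}
        counts: dict[str, int] = {}
        for kid, group in iter_kinase_groups(self.records):
            profiles[kid] = build_profile(group, pseudocount=self.pseudocount)
            counts[kid] = len(group)
        background = compute_background(
            (r.region for r in self.records), self.excluded_offsets
        )
        training_ids = sorted(
            kid
            for kid, c in counts.items()
            if c >= self.min_peptides and kid in self.domains
        )
        if len(training_ids) < 2:
            raise ValueError(
                f"need >= 2 aligned kinases with >= {self.min_peptides} peptides; "
                f"got {len(training_ids)}"
            )
        consensus = {
            kid: build_consensus(
                profiles[kid], self.consensus_upper, self.consensus_lower
            )
            for kid in training_ids
        }
        if self.variant == "consensus":
            substrate_info = consensus
        else:
            substrate_info = {kid: profiles[kid] for kid in training_ids}
        sdr_map = find_sdrs(
            self.domains,
            substrate_info,
            interaction=self.interaction,
            m=self.m,
            combine_mode=self.combine_mode,
        )
        conditionals = fit_conditionals(self.domains, substrate_info, sdr_map)
        return SpecificityResults(
            model=self,
            background_=background,
            profiles_=profiles,
            pair_counts_=counts,
            consensus_=consensus,
            training_ids_=training_ids,
            sdr_map_=sdr_map,
            conditionals_=conditionals,
        )


@dataclass
class SpecificityResults:
    """Fitted estimates plus prediction, scoring and evaluation methods."""

    model: KinaseSpecificityModel
    background_: BackgroundFrequencies
    profiles_: dict[str, ProfileMatrix]
    pair_counts_: dict[str, int]
    consensus_: dict[str, ConsensusSequence]
    training_ids_: list[str]
    sdr_map_: SDRMap
    conditionals_: ConditionalTable

    # -- prediction ---------------------------------------------------------

    def predict(self, kinase_id: str) -> PredictedSpecificity:
        """Predict profile + PSSM for one aligned kinase."""
        domains = self.model.domains
        profile, diag = predict_profile(
            domains[kinase_id],
            self.sdr_map_,
            self.conditionals_,
            self.background_,
            kinase_id=kinase_id,
            alignment_length=domains.alignment_length,
        )
        pssm = build_pssm(profile, self.background_, exponent=self.model.exponent)
        return PredictedSpecificity(kinase_id, profile, pssm, diag)

    def predict_all(self) -> tuple[list[PredictedSpecificity], dict[str, str]]:
        """Predict every kinase in the alignment (sorted; failures collected)."""
        return predict_all(
            self.model.domains,
            self.sdr_map_,
            self.conditionals_,
            self.background_,
            exponent=self.model.exponent,
        )

    def empirical_pssm(self, kinase_id: str) -> PSSM:
        """PSSM built from a kinase's empirical (substrate-data) profile."""
        return build_pssm(
            self.profiles_[kinase_id], self.background_, exponent=self.model.exponent
        )

    def score(self, kinase_id: str, region: PhosphositeRegion) -> float:
        """Additive specificity score of a region under a predicted PSSM."""
        return score_region(self.predict(kinase_id).pssm, region)

    # -- evaluation ---------------------------------------------------------

    def sse_table(self, kinase_ids: Iterable[str] | None = None) -> dict[str, float]:
        """SSE of predicted vs empirical profile per kinase (sorted keys)."""
        ids = sorted(kinase_ids) if kinase_ids is not None else self.training_ids_
        return {kid: sse(self.predict(kid).profile, self.profiles_[kid]) for kid in ids}

    def summary(self) -> str:
        """Plain-text fit summary."""
        m = self.model
        informative = [o for o in OFFSETS if not self.sdr_map_.is_uninformative(o)]
        lines = [
            "Kinase substrate specificity model",
            "==================================",
            f"variant:              {m.variant}",
            f"kinases with pairs:   {len(self.profiles_)}",
            f"aligned domains:      {len(m.domains)} (L = {m.domains.alignment_length})",
            f"training kinases:     {len(self.training_ids_)} (>= {m.min_peptides} peptides)",
            f"PSSM exponent:        {m.exponent}",
            f"SDRs per offset (m):  {m.m}",
            f"informative offsets:  {len(informative)} of {len(OFFSETS)}",
            "",
            "offset  n_sdr  top column  weight    C_c",
        ]
        for o in OFFSETS:
            sels = self.sdr_map_.selections(o)
            if sels:
                top = sels[0]
                lines.append(
                    f"{o:+6d}  {len(sels):5d}  {top.column:10d}  "
                    f"{top.weight:6.3f}  {top.combined:8.4f}"
                )
            else:
                lines.append(f"{o:+6d}      0           -       -         -")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, outdir: str | Path, predictions: bool = True) -> None:
        """Write matrices, SDR map and a small JSON manifest to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sdr_map_.to_json(outdir / "sdr_map.json")
        manifest = {
            "variant": self.model.variant,
            "exponent": self.model.exponent,
            "m": self.model.m,
            "min_peptides": self.model.min_peptides,
            "n_training_kinases": len(self.training_ids_),
            "training_kinases": self.training_ids_,
            "failures": {},
        }
        if predictions:
            preds, failures = self.predict_all()
            manifest["failures"] = failures
            for pred in preds:
                write_matrix(
                    pred.profile.to_matrix_file(),
                    outdir / f"{pred.kinase_id}.profile.tsv",
                )
                write_matrix(
                    pred.pssm.to_matrix_file(), outdir / f"{pred.kinase_id}.pssm.tsv"
                )
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    # -- plotting -----------------------------------------------------------

    def plot_sse_histogram(self, ax=None, bins: int = 30):
        """Histogram of per-kinase SSE (predicted vs empirical profiles)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        values = list(self.sse_table().values())
        ax.hist(values, bins=bins)
        ax.set_xlabel("sum of squared differences")
        ax.set_ylabel("number of kinases")
        ax.set_title(f"Predicted vs empirical profiles ({self.model.variant} variant)")
        return ax
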