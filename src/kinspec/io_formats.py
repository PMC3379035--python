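"""Readers, writers and domain types for all on-disk artifacts.

The package speaks four plain-text formats:

* **pair TSV** — experimentally confirmed kinase–phosphosite pairs, either
  ``kinase_id<TAB>peptide15`` or ``kinase_id<TAB>protein_id<TAB>site`` (with a
  side FASTA supplying the protein sequences);
* **aligned FASTA** — fixed-length gapped catalytic-domain sequences, one per
  kinase (gap ``~`` on output; ``~`` and ``-`` accepted on input);
* **matrix TSV** — a labelled 21×15 profile or PSSM for one kinase;
* **FASTA** — plain protein sequences for phosphosite-window extraction.

Site coordinates in files are 1-based; every in-memory interface speaks the
offset labels −7..+7 with the phospho-acceptor at offset 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import (
    ACCEPTORS,
    AMBIGUOUS_RESIDUES,
    AMINO_ACIDS,
    DOMAIN_ALPHABET,
    GAP,
    N_OFFSETS,
    OFFSETS,
    REGION_LENGTH,
    SUBSTRATE_ALPHABET,
    SUBSTRATE_INDEX,
    encode_domain,
    encode_substrate,
    offset_to_col,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhosphositeRegion",
    "KinaseSubstrateRecord",
    "AlignedDomainSet",
    "MatrixFile",
    "PairFormatError",
    "read_pairs",
    "write_pairs",
    "read_aligned_domains",
    "write_aligned_domains",
    "read_proteins",
    "extract_region",
    "read_matrix",
    "write_matrix",
]


class PairFormatError(ValueError):
    """A malformed or invariant-violating row in a pair table."""


@dataclass(frozen=True)
class PhosphositeRegion:
    """A 15-symbol phosphosite window, offsets −7..+7, acceptor at offset 0.

    Symbols are drawn from the 21-letter substrate alphabet (20 amino acids
    plus ``x`` for unknown residues and chain-terminus padding).
    """

    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) != REGION_LENGTH:
            raise ValueError(
                f"phosphosite region must have length {REGION_LENGTH}, "
                f"got {len(self.symbols)} ({self.symbols!r})"
            )
        for pos, sym in enumerate(self.symbols):
            if sym not in SUBSTRATE_INDEX:
                raise ValueError(
                    f"symbol {sym!r} at offset {pos - 7:+d} not in substrate alphabet"
                )
        if self.symbols[7] not in ACCEPTORS:
            raise ValueError(
                f"center residue {self.symbols[7]!r} is not a phospho-acceptor (S/T/Y)"
            )

    def at(self, offset: int) -> str:
        """Symbol at a given offset in −7..+7."""
        return self.symbols[offset_to_col(offset)]

    @property
    def codes(self) -> np.ndarray:
        """Integer codes over the substrate alphabet, one per offset."""
        return encode_substrate(self.symbols)

    def __str__(self) -> str:
        return self.symbols


@dataclass(frozen=True)
class KinaseSubstrateRecord:
    """One experimentally confirmed kinase–phosphosite pair."""

    kinase_id: str
    region: PhosphositeRegion
    protein_id: str | None = None
    site: int | None = None  # 1-based position in the source protein

    def __post_init__(self) -> None:
        if not self.kinase_id:
            raise ValueError("kinase_id must be non-empty")


@dataclass
class AlignedDomainSet:
    """Fixed-length gapped catalytic-domain sequences, one per kinase."""

    entries: dict[str, str]
    alignment_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("alignment contains no sequences")
        lengths = {len(s) for s in self.entries.values()}
        if len(lengths) != 1:
            bad = sorted(self.entries, key=lambda k: len(self.entries[k]))[-1]
            raise ValueError(
                f"ragged alignment: sequence {bad!r} has length "
                f"{len(self.entries[bad])}, others {sorted(lengths)}"
            )
        normalized = {}
        for kid, seq in self.entries.items():
            seq = seq.replace("-", GAP)
            for pos, sym in enumerate(seq):
                if sym not in DOMAIN_ALPHABET:
                    raise ValueError(
                        f"illegal character {sym!r} at column {pos + 1} of {kid!r} "
                        "(domains must be fully specified or gapped)"
                    )
            normalized[kid] = seq
        self.entries = normalized
        self.alignment_length = lengths.pop()

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, kinase_id: str) -> bool:
        return kinase_id in self.entries

    def __getitem__(self, kinase_id: str) -> str:
        return self.entries[kinase_id]

    @property
    def kinase_ids(self) -> list[str]:
        return list(self.entries)

    def encoded(self, kinase_ids: Sequence[str] | None = None) -> np.ndarray:
        """Integer-coded alignment, shape (n_kinases, L), gap = code 20."""
        ids = self.kinase_ids if kinase_ids is None else list(kinase_ids)
        return np.stack([encode_domain(self.entries[k]) for k in ids])


@dataclass
class MatrixFile:
    """A labelled 21×15 matrix (profile or PSSM) for one kinase."""

    kinase_id: str
    kind: Literal["profile", "pssm"]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(SUBSTRATE_ALPHABET), N_OFFSETS):
            raise ValueError(f"matrix must be 21x15, got {self.values.shape}")
        if self.kind not in ("profile", "pssm"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")


# ---------------------------------------------------------------------------
# phosphosite-window extraction


def extract_region(protein: str, site: int) -> PhosphositeRegion:
    """Cut the 15-mer window centered on a 1-based S/T/Y ``site``.

    Window positions falling outside the protein are padded with ``x`` so
    that N- and C-terminal sites still yield full-length training regions;
    ambiguous residues (B, Z, U, O, X, J) also map to ``x``.
    """
    protein = protein.upper()
    if not 1 <= site <= len(protein):
        raise ValueError(f"site {site} out of range 1..{len(protein)}")
    center = protein[site - 1]
    if center not in ACCEPTORS:
        raise ValueError(f"residue {center!r} at site {site} is not S, T or Y")
    out = []
    for offset in OFFSETS:
        pos = site + offset  # 1-based
        if pos < 1 or pos > len(protein):
            out.append("x")
            continue
        sym = protein[pos - 1]
        if sym in AMBIGUOUS_RESIDUES or sym not in AMINO_ACIDS:
            sym = "x"
        out.append(sym)
    return PhosphositeRegion("".join(out))


# ---------------------------------------------------------------------------
# pair tables

_PEPTIDE_HEADER = ("kinase_id", "peptide15")
_SITE_HEADER = ("kinase_id", "protein_id", "site")


def _parse_pair_row(
    fields: list[str], proteins: dict[str, str] | None
) -> KinaseSubstrateRecord:
    if len(fields) == 2:
        kid, pep = fields
        return KinaseSubstrateRecord(kid, PhosphositeRegion(pep))
    if len(fields) == 3:
        kid, pid, site_s = fields
        if proteins is None:
            raise PairFormatError(
                "row references a protein sequence but no protein FASTA was given"
            )
        if pid not in proteins:
            raise PairFormatError(f"protein {pid!r} not found in the supplied FASTA")
        site = int(site_s)
        return KinaseSubstrateRecord(
            kid, extract_region(proteins[pid], site), protein_id=pid, site=site
        )
    raise PairFormatError(f"expected 2 or 3 tab-separated fields, got {len(fields)}")


def read_pairs(
    path: str | Path,
    proteins: dict[str, str] | None = None,
    on_error: Literal["raise", "warn"] = "raise",
    dedupe: bool = False,
) -> list[KinaseSubstrateRecord]:
    """Read a kinase–phosphosite pair TSV.

    Two schemas are accepted (an optional header row naming the columns is
    skipped): ``kinase_id, peptide15`` or ``kinase_id, protein_id, site`` with
    ``proteins`` supplying the sequences.  With ``on_error="warn"`` invariant-
    violating rows are logged with their line number and skipped instead of
    aborting the read; ``dedupe=True`` drops exact (kinase, peptide)
    duplicates, keeping first occurrence.
    """
    path = Path(path)
    records: list[KinaseSubstrateRecord] = []
    seen: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and tuple(f.strip() for f in fields) in (
                _PEPTIDE_HEADER,
                _SITE_HEADER,
            ):
                continue
            try:
                rec = _parse_pair_row([f.strip() for f in fields], proteins)
            except (PairFormatError, ValueError) as exc:
                msg = f"{path.name}:{lineno}: {exc}"
                if on_error == "raise":
                    raise PairFormatError(msg) from None
                logger.warning("skipping bad pair row %s", msg)
                continue
            key = (rec.kinase_id, rec.region.symbols)
            if dedupe and key in seen:
                continue
            seen.add(key)
            records.append(rec)
    if not records:
        logger.warning("pair table %s produced no records", path)
    return records


def write_pairs(records: Iterable[KinaseSubstrateRecord], path: str | Path) -> None:
    """Write pair records as a two-column ``kinase_id<TAB>peptide15`` TSV."""
    with Path(path).open("w") as fh:
        fh.write("kinase_id\tpeptide15\n")
        for rec in records:
            fh.write(f"{rec.kinase_id}\t{rec.region.symbols}\n")


# ---------------------------------------------------------------------------
# aligned domains and plain FASTA


def read_aligned_domains(path: str | Path) -> AlignedDomainSet:
    """Read a multiple-sequence-aligned FASTA of catalytic domains."""
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in entries:
            raise ValueError(f"duplicate kinase id {rec.id!r} in {path}")
        entries[rec.id] = str(rec.seq).upper()
    return AlignedDomainSet(entries)


def write_aligned_domains(domains: AlignedDomainSet, path: str | Path) -> None:
    """Write an :class:`AlignedDomainSet` as aligned FASTA (gap ``~``)."""
    recs = [
        SeqRecord(Seq(seq), id=kid, description="")
        for kid, seq in domains.entries.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_proteins(path: str | Path) -> dict[str, str]:
    """Read plain protein sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# matrix TSV

_OFFSET_LABELS = [f"{o:+d}" if o else "0" for o in OFFSETS]


def write_matrix(matrix: MatrixFile, path: str | Path) -> None:
    """Write a matrix TSV; full ``repr`` precision so round-trips are exact."""
    with Path(path).open("w") as fh:
        fh.write(f"# kinase_id: {matrix.kinase_id}\n")
        fh.write(f"# kind: {matrix.kind}\n")
        fh.write("residue\t" + "\t".join(_OFFSET_LABELS) + "\n")
        for row, sym in enumerate(SUBSTRATE_ALPHABET):
            vals = "\t".join(format(v, ".17g") for v in matrix.values[row])
            fh.write(f"{sym}\t{vals}\n")


def read_matrix(path: str | Path) -> MatrixFile:
    """Read a matrix TSV written by :func:`write_matrix`."""
    path = Path(path)
    kinase_id, kind = "", "profile"
    rows: list[list[float]] = []
    labels: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# kinase_id:"):
                kinase_id = line.split(":", 1)[1].strip()
                continue
            if line.startswith("# kind:"):
                kind = line.split(":", 1)[1].strip()
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "residue":
                if fields[1:] != _OFFSET_LABELS:
                    raise ValueError(
                        f"{path.name}: header offsets must be -7..+7, got {fields[1:]}"
                    )
                continue
            labels.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    if labels != list(SUBSTRATE_ALPHABET):
        raise ValueError(
            f"{path.name}: row labels must be the 21-symbol substrate alphabet "
            f"in fixed order, got {labels}"
        )
    return MatrixFile(kinase_id, kind, np.array(rows))  # type: ignore[arg-type]


def iter_kinase_groups(
    records: Iterable[KinaseSubstrateRecord],
) -> Iterator[tuple[str, list[KinaseSubstrateRecord]]]:
    """Group pair records by kinase id (sorted for deterministic output)."""
    groups: dict[str, list[KinaseSubstrateRecord]] = {}
    for rec in records:
        groups.setdefault(rec.kinase_id, []).append(rec)
    for kid in sorted(groups):
        yield kid, groups[kid]
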