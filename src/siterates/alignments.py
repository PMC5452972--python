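"""Codon and amino-acid alignments with FASTA round-tripping.

Alignments are stored as integer state matrices (``n_taxa x n_sites``):
codon states index into :data:`siterates.genetic_code.SENSE_CODONS`,
amino-acid states into :data:`siterates.genetic_code.AMINO_ACIDS`.
Gapless, stop-free data only — the simulation and inference machinery in
this package operates on complete columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    AA_INDEX,
    AMINO_ACIDS,
    CODON_AA_INDEX,
    CODON_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
)

__all__ = ["CodonAlignment", "AminoAcidAlignment"]


def _check_shape(labels, states) -> None:
    if len(labels) == 0 or states.shape[1] == 0:
        raise ValueError("alignment must contain at least one taxon and one site")
    if len(labels) != states.shape[0]:
        raise ValueError("number of labels does not match number of rows")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels")


@dataclass
class CodonAlignment:
    """Taxa x sites matrix of sense-codon states (no gaps, no stops)."""

    labels: list[str]
    states: np.ndarray  # (n_taxa, n_sites) indices into SENSE_CODONS

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.intp)
        _check_shape(self.labels, self.states)
        if self.states.min() < 0 or self.states.max() >= len(SENSE_CODONS):
            raise ValueError("codon state indices out of range")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    def sequence(self, row: int) -> str:
        return "".join(SENSE_CODONS[s] for s in self.states[row])

    @classmethod
    def from_sequences(cls, labels: list[str], seqs: list[str]) -> "CodonAlignment":
        if not seqs:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: sequences differ in length")
        (seqlen,) = lengths
        if seqlen == 0 or seqlen % 3:
            raise ValueError(f"sequence length {seqlen} is not a positive multiple of 3")
        states = np.empty((len(seqs), seqlen // 3), dtype=np.intp)
        for r, s in enumerate(seqs):
            s = s.upper()
            for k in range(0, seqlen, 3):
                codon = s[k : k + 3]
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"stop codon {codon} in sequence {labels[r]!r} at codon {k // 3 + 1}"
                    )
                try:
                    states[r, k // 3] = CODON_INDEX[codon]
                except KeyError:
                    raise ValueError(
                        f"invalid codon {codon!r} in sequence {labels[r]!r}"
                    ) from None
        return cls(labels=list(labels), states=states)

    def translate(self) -> "AminoAcidAlignment":
        """Position-wise standard-code translation; shape is preserved."""
        return AminoAcidAlignment(labels=list(self.labels), states=CODON_AA_INDEX[self.states])

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.sequence(r)), id=lab, description="")
            for r, lab in enumerate(self.labels)
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        labels, seqs = _read_fasta(path)
        return cls.from_sequences(labels, seqs)

    def reordered(self, labels: list[str]) -> "CodonAlignment":
        """Rows permuted into the given label order."""
        pos = {lab: r for r, lab in enumerate(self.labels)}
        try:
            rows = [pos[lab] for lab in labels]
        except KeyError as exc:
            raise ValueError(f"taxon {exc.args[0]!r} not in alignment") from None
        return CodonAlignment(labels=list(labels), states=self.states[rows])


@dataclass
class AminoAcidAlignment:
    """Taxa x sites matrix of amino-acid states (20-letter alphabet)."""

    labels: list[str]
    states: np.ndarray  # (n_taxa, n_sites) indices into AMINO_ACIDS

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.intp)
        _check_shape(self.labels, self.states)
        if self.states.min() < 0 or self.states.max() >= len(AMINO_ACIDS):
            raise ValueError("amino-acid state indices out of range")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    def sequence(self, row: int) -> str:
        return "".join(AMINO_ACIDS[s] for s in self.states[row])

    @classmethod
    def from_sequences(cls, labels: list[str], seqs: list[str]) -> "AminoAcidAlignment":
        if not seqs:
            raise ValueError("empty alignment")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("ragged alignment: sequences differ in length")
        states = np.empty((len(seqs), len(seqs[0])), dtype=np.intp)
        for r, s in enumerate(seqs):
            for k, aa in enumerate(s.upper()):
                try:
                    states[r, k] = AA_INDEX[aa]
                except KeyError:
                    raise ValueError(
                        f"invalid residue {aa!r} in sequence {labels[r]!r}"
                    ) from None
        return cls(labels=list(labels), states=states)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.sequence(r)), id=lab, description="")
            for r, lab in enumerate(self.labels)
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path) -> "AminoAcidAlignment":
        labels, seqs = _read_fasta(path)
        return cls.from_sequences(labels, seqs)

    def reordered(self, labels: list[str]) -> "AminoAcidAlignment":
        pos = {lab: r for r, lab in enumerate(self.labels)}
        try:
            rows = [pos[lab] for lab in labels]
        except KeyError as exc:
            raise ValueError(f"taxon {exc.args[0]!r} not in alignment") from None
        return AminoAcidAlignment(labels=list(labels), states=self.states[rows])


def _read_fasta(path) -> tuple[list[str], list[str]]:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"empty or non-FASTA file: {path}")
    return [r.id for r in records], [str(r.seq) for r in records]
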