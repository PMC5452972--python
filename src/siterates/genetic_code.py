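"""The universal genetic code restricted to the 61 sense codons.

Provides the codon ordering used throughout the package (alphabetical over
the 61 sense codons), codon -> amino-acid translation, and the synonymy and
single-nucleotide-neighbour predicates that codon substitution models are
built from.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

#: The 61 sense codons in alphabetical order; this ordering indexes every
#: 61-dimensional vector and 61x61 matrix in the package.
SENSE_CODONS: tuple[str, ...] = tuple(
    c
    for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: codon -> one-letter amino acid (sense codons only).
CODON_TO_AA: dict[str, str] = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: amino-acid index (0..19, ARNDCQEGHILKMFPSTWYV order) for each sense codon.
CODON_AA_INDEX: np.ndarray = np.array(
    [AA_INDEX[CODON_TO_AA[c]] for c in SENSE_CODONS], dtype=np.intp
)


def is_synonymous(codon_a: str, codon_b: str) -> bool:
    """True if both sense codons encode the same amino acid."""
    return CODON_TO_AA[codon_a] == CODON_TO_AA[codon_b]


def is_neighbor(codon_a: str, codon_b: str) -> bool:
    """True iff the codons differ at exactly one nucleotide position."""
    return sum(x != y for x, y in zip(codon_a, codon_b)) == 1


def _build_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(SENSE_CODONS)
    neighbor = np.zeros((n, n), dtype=bool)
    diff_pos = np.full((n, n), -1, dtype=np.int8)
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if a[p] != b[p]]
            if len(diffs) == 1:
                neighbor[i, j] = True
                diff_pos[i, j] = diffs[0]
    synonymous = CODON_AA_INDEX[:, None] == CODON_AA_INDEX[None, :]
    np.fill_diagonal(synonymous, False)
    return neighbor, synonymous, diff_pos


#: NEIGHBOR[i, j]: codons i, j differ at exactly one position.
#: SYNONYMOUS[i, j]: codons i != j encode the same amino acid.
#: DIFF_POSITION[i, j]: the differing position (0..2) for neighbours, else -1.
NEIGHBOR, SYNONYMOUS, DIFF_POSITION = _build_masks()

#: TARGET_NUC[i, j]: index into NUCLEOTIDES of the nucleotide j carries at the
#: position where neighbours i, j differ; -1 for non-neighbours.
TARGET_NUC: np.ndarray = np.full_like(DIFF_POSITION, -1)
for _i, _a in enumerate(SENSE_CODONS):
    for _j, _b in enumerate(SENSE_CODONS):
        _p = DIFF_POSITION[_i, _j]
        if _p >= 0:
            TARGET_NUC[_i, _j] = NUCLEOTIDES.index(_b[_p])
del _i, _j, _a, _b, _p


def translate_codon(codon: str) -> str:
    """Translate one sense codon; raises ``ValueError`` on stops/invalid."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} is not allowed in codon alignments")
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"invalid codon {codon!r}") from None
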