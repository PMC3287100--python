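"""Standard genetic code lookup tables.

Everything downstream (composition, RSCU, ENC, the simulator) indexes into
these frozen tables rather than re-deriving the code.  Codons are spelled in
the DNA alphabet throughout; RNA input is normalized to DNA at ingestion.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES: tuple[str, ...] = ("A", "C", "G", "T")

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)

#: the three stop codons (TAA, TAG, TGA)
STOP_CODONS: tuple[str, ...] = tuple(sorted(_standard.stop_codons))

#: 61 sense codons, alphabetical
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: all 64 codons, alphabetical
ALL_CODONS: tuple[str, ...] = tuple(sorted(SENSE_CODONS + STOP_CODONS))

#: amino acid -> alphabetical list of its codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    _aa = CODON_TO_AA[_codon]
    AA_TO_CODONS[_aa] = AA_TO_CODONS.get(_aa, ()) + (_codon,)

#: number of synonymous codons per amino acid (1, 2, 3, 4 or 6)
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: Met and Trp — single-codon amino acids carrying no synonymous information
SINGLE_CODON_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, d in DEGENERACY.items() if d == 1)
)

#: the 59 synonymous sense codons (61 minus ATG and TGG), alphabetical
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in SINGLE_CODON_AAS
)

#: amino acids with >= 2 synonymous codons, alphabetical
MULTI_CODON_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, d in DEGENERACY.items() if d > 1)
)

#: degeneracy class k -> amino acids in that class (9, 1, 5 and 3 families)
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(sorted(aa for aa, d in DEGENERACY.items() if d == k))
    for k in (2, 3, 4, 6)
}

#: all 20 amino acids, alphabetical
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))

assert len(SENSE_CODONS) == 61
assert len(SYNONYMOUS_CODONS) == 59
assert [len(v) for v in DEGENERACY_CLASSES.values()] == [9, 1, 5, 3]


def is_ambiguous(codon: str) -> bool:
    """True if the triplet contains any symbol outside {A, C, G, T}."""
    return any(b not in "ACGT" for b in codon)
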