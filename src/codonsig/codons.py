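"""Genetic-code constants and small sequence utilities shared across modules.

The analysis restricts itself to the 59 synonymous codons: all sense codons
except ATG (Met) and TGG (Trp), which admit no synonymous alternative, and
the three stop codons. Codon identities are kept in the DNA alphabet; tRNA
anticodons are handled in the RNA alphabet with explicit conversion.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_BACTERIAL = CodonTable.unambiguous_dna_by_id[11]

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(_BACTERIAL.stop_codons)

#: codon (DNA) -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_BACTERIAL.forward_table)

#: one-letter amino acid -> tuple of codons, all 20 amino acids
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

#: amino acids with >= 2 codons; the 59 synonymous codons live here
DEGENERATE_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: codons for aa, codons in AA_TO_CODONS.items() if len(codons) > 1
}

#: the 59 codons in a fixed, reproducible order (family-major, alphabetical)
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for aa in sorted(DEGENERATE_FAMILIES) for c in DEGENERATE_FAMILIES[aa]
)
assert len(SYNONYMOUS_CODONS) == 59

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SYNONYMOUS_CODONS)}
FAMILY_ORDER: tuple[str, ...] = tuple(sorted(DEGENERATE_FAMILIES))
CODON_FAMILY: dict[str, str] = {
    c: aa for aa, codons in DEGENERATE_FAMILIES.items() for c in codons
}

#: three-letter names of the nine twofold-degenerate amino acids and their
#: codon pairs (third-position pyrimidine/purine pairs)
TWOFOLD_FAMILIES: dict[str, tuple[str, str]] = {
    "Phe": ("TTT", "TTC"),
    "Tyr": ("TAT", "TAC"),
    "His": ("CAT", "CAC"),
    "Gln": ("CAA", "CAG"),
    "Asn": ("AAT", "AAC"),
    "Lys": ("AAA", "AAG"),
    "Asp": ("GAT", "GAC"),
    "Glu": ("GAA", "GAG"),
    "Cys": ("TGT", "TGC"),
}

THREE_TO_ONE = {
    "Phe": "F", "Tyr": "Y", "His": "H", "Gln": "Q", "Asn": "N",
    "Lys": "K", "Asp": "D", "Glu": "E", "Cys": "C",
}

_DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ambiguity N preserved)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def codon_to_anticodon(codon_dna: str) -> str:
    """Watson-Crick anticodon (RNA, 5'->3') of a DNA codon."""
    return dna_to_rna(reverse_complement(codon_dna))


def anticodon_to_codon(anticodon_rna: str) -> str:
    """DNA codon read by an RNA anticodon under strict Watson-Crick pairing."""
    return reverse_complement(rna_to_dna(anticodon_rna))


def translate(cds: str) -> str:
    """Translate an in-frame CDS; terminal stop is dropped, internal stop -> '*'."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    cds = normalize(cds)
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append(CODON_TO_AA.get(codon, "X"))
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


def normalize(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def iter_codons(cds: str):
    """Yield successive triplets of an in-frame CDS."""
    for i in range(0, len(cds) - len(cds) % 3, 3):
        yield cds[i : i + 3]


def has_internal_stop(cds: str) -> bool:
    """True if any in-frame codon before the last is a stop codon."""
    codons = list(iter_codons(cds))
    return any(c in STOP_CODONS for c in codons[:-1])
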