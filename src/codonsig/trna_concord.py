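"""Concordance of HE-derived optimal codons with tRNA-gene-implied optima.

For the nine twofold-degenerate amino acids the two codons differ only at
the third position, and a genome encoding tRNAs for only one of the two
possible anticodons reads one codon by Watson-Crick pairing (tRNA-optimal)
and the other by wobble. Independently, the codon over-represented in the
genome's HE genes (two-tailed Fisher exact on pooled codon counts,
P < 0.001) is the expression-derived optimal codon. Genomes where the two
calls disagree for at least 3 of the 9 testable families are flagged: their
expression-like codon bias may not reflect translational selection.

tRNA anticodon inventories are consumed as input (TSV); tRNA gene scanning
is out of scope.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .codons import TWOFOLD_FAMILIES, anticodon_to_codon, iter_codons, normalize, STOP_CODONS
from .cog_enrich import fisher_two_tailed
from .he_predict import ExpressionCall
from .seqio import GeneRecord

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 1e-3
DEFAULT_FLAG_MIN_DISAGREE = 3


@dataclass
class TwofoldFamilyCall:
    amino_acid: str  # three-letter name
    he_optimal: str | None  # DNA codon, None = not significant / untestable
    trna_optimal: str | None  # DNA codon, None = undetermined
    @property
    def testable(self) -> bool:
        return self.he_optimal is not None and self.trna_optimal is not None

    @property
    def disagree(self) -> bool:
        return self.testable and self.he_optimal != self.trna_optimal


@dataclass
class GenomeConcordance:
    genome_id: str
    calls: list[TwofoldFamilyCall]
    @property
    def n_testable(self) -> int:
        return sum(c.testable for c in self.calls)

    @property
    def n_disagree(self) -> int:
        return sum(c.disagree for c in self.calls)

    def flagged(self, min_disagree: int = DEFAULT_FLAG_MIN_DISAGREE) -> bool:
        return self.n_disagree >= min_disagree


def _pooled_counts(genes: list[GeneRecord]) -> Counter:
    counts: Counter = Counter()
    for g in genes:
        codons = list(iter_codons(normalize(g.cds)))[1:]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        counts.update(codons)
    return counts


def he_optimal_codons(
    genes: list[GeneRecord],
    calls: list[ExpressionCall],
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> dict[str, str | None]:
    """Expression-derived optimal codon per twofold family.

    Pools codon counts over HE genes and over non-HE genes (unweighted by
    gene length) and tests each family's 2x2 table; the codon with the
    higher HE proportion is optimal when the two-tailed Fisher P is below
    the threshold, else the family call is None.
    """
    he_ids = {c.gene_id for c in calls if c.label == "HE"}
    non_ids = {c.gene_id for c in calls if c.label != "HE"}
    he_counts = _pooled_counts([g for g in genes if g.gene_id in he_ids])
    non_counts = _pooled_counts([g for g in genes if g.gene_id in non_ids])
    result: dict[str, str | None] = {}
    for aa, (c1, c2) in TWOFOLD_FAMILIES.items():
        a, b = he_counts[c1], he_counts[c2]
        c, d = non_counts[c1], non_counts[c2]
        if a + b == 0 or c + d == 0:
            result[aa] = None
            continue
        p = fisher_two_tailed(a, b, c, d)
        if p >= p_threshold:
            result[aa] = None
            continue
        result[aa] = c1 if a / (a + b) > c / (c + d) else c2
    return result


def trna_optimal_codons(
    anticodons: list[tuple[str, str]] | pd.DataFrame,
) -> dict[str, str | None]:
    """tRNA-implied optimal codon per twofold family.

    ``anticodons`` is a list of (three-letter amino acid, anticodon RNA
    5'->3') rows, or a DataFrame with ``amino_acid``/``anticodon`` columns.
    If exactly one of a family's two possible anticodons is present, the
    Watson-Crick matched codon is optimal; both or neither -> None. Rows
    whose anticodon does not decode the stated amino acid are rejected and
    logged.
    """
    if isinstance(anticodons, pd.DataFrame):
        anticodons = list(zip(anticodons["amino_acid"], anticodons["anticodon"]))
    present: dict[str, set[str]] = {aa: set() for aa in TWOFOLD_FAMILIES}
    for aa, anticodon in anticodons:
        if aa not in TWOFOLD_FAMILIES:
            continue
        codon = anticodon_to_codon(anticodon)
        if codon not in TWOFOLD_FAMILIES[aa]:
            logger.warning("anticodon %s inconsistent with %s; row rejected", anticodon, aa)
            continue
        present[aa].add(anticodon.upper().replace("T", "U"))
    result: dict[str, str | None] = {}
    for aa, (c1, c2) in TWOFOLD_FAMILIES.items():
        found = present[aa]
        if len(found) == 1:
            result[aa] = anticodon_to_codon(next(iter(found)))
        else:
            result[aa] = None
    return result


def concordance(
    genome_id: str,
    he_calls: dict[str, str | None],
    trna_calls: dict[str, str | None],
) -> GenomeConcordance:
    """Combine the two per-family call sets for one genome."""
    calls = [
        TwofoldFamilyCall(aa, he_calls.get(aa), trna_calls.get(aa))
        for aa in TWOFOLD_FAMILIES
    ]
    return GenomeConcordance(genome_id, calls)


def concordance_frame(results: list[GenomeConcordance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "n_testable": r.n_testable,
                "n_disagree": r.n_disagree,
                "flagged": r.flagged(),
            }
            for r in results
        ]
    )
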