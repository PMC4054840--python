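"""Reading genomes and gene tables; codon-usage and background feature vectors.

A genome is a multi-record FASTA plus a TSV gene table. The table either
gives 1-based inclusive coordinates on a FASTA record (``seq_id``, ``start``,
``end``, ``strand``) or carries the sequences directly in ``cds`` /
``upstream`` / ``downstream`` columns (annotation-free mode). Internally all
coordinates are 0-based half-open; the 1-based convention applies to the
table only.

Codon usage is summarised per gene as fractions within each degenerate
amino-acid family over the 59 synonymous codons. The local mutational
background of a gene is summarised the same way from pseudo-codons read in
all three frames on both strands of its flanking intergenic DNA, which makes
the background strand-symmetric.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .codons import (
    CODON_INDEX,
    DEGENERATE_FAMILIES,
    FAMILY_ORDER,
    SYNONYMOUS_CODONS,
    has_internal_stop,
    iter_codons,
    normalize,
    reverse_complement,
)

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = [
    "gene_id", "seq_id", "start", "end", "strand",
    "cog_ids", "is_reference_he", "cds", "upstream", "downstream",
]

DEFAULT_MIN_CODONS = 30
DEFAULT_INTERGENIC_SPAN = 400  # nt per side


@dataclass
class GeneRecord:
    """One protein-coding gene with its flanking intergenic context."""

    gene_id: str
    genome_id: str
    strand: str  # '+' or '-'
    cds: str  # coding strand, in frame
    upstream_intergenic: str = ""
    downstream_intergenic: str = ""
    cog_ids: frozenset[str] = frozenset()
    is_reference_he: bool = False


@dataclass
class LoadReport:
    n_loaded: int = 0
    n_rejected: int = 0
    reasons: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.n_rejected += 1
        self.reasons[reason] += 1


@dataclass
class CodonUsageVector:
    """Per-family normalized codon fractions over the 59 synonymous codons.

    Families absent from the gene are imputed family-uniform and recorded in
    ``absent_families`` so classifiers can carry a presence mask alongside
    the fixed-dimension fraction vector.
    """

    freqs: dict[str, float]
    n_codons: int
    present_families: frozenset[str]
    is_short: bool = False

    @property
    def absent_families(self) -> frozenset[str]:
        return frozenset(FAMILY_ORDER) - self.present_families

    def as_array(self, include_mask: bool = True) -> np.ndarray:
        """Fixed-order feature vector: 59 fractions (+ 18 presence flags)."""
        vec = np.array([self.freqs[c] for c in SYNONYMOUS_CODONS])
        if include_mask:
            mask = np.array(
                [1.0 if aa in self.present_families else 0.0 for aa in FAMILY_ORDER]
            )
            vec = np.concatenate([vec, mask])
        return vec


#: background vectors share the shape and normalization of codon vectors
BackgroundUsageVector = CodonUsageVector


def _normalize_counts(counts: Counter) -> tuple[dict[str, float], frozenset[str]]:
    freqs: dict[str, float] = {}
    present: set[str] = set()
    for aa, codons in DEGENERATE_FAMILIES.items():
        total = sum(counts[c] for c in codons)
        if total > 0:
            present.add(aa)
            for c in codons:
                freqs[c] = counts[c] / total
        else:
            uniform = 1.0 / len(codons)
            for c in codons:
                freqs[c] = uniform
    return freqs, frozenset(present)


def codon_frequencies(cds: str, min_codons: int = DEFAULT_MIN_CODONS) -> CodonUsageVector:
    """Codon-usage vector of an in-frame CDS.

    The start codon and a terminal stop codon are excluded from counting, as
    are codons containing ambiguity characters and the single-codon families
    (ATG, TGG).
    """
    cds = normalize(cds)
    codons = list(iter_codons(cds))
    if codons:
        codons = codons[1:]  # drop start codon
    from .codons import STOP_CODONS

    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts = Counter(c for c in codons if c in CODON_INDEX)
    n = sum(counts.values())
    freqs, present = _normalize_counts(counts)
    return CodonUsageVector(freqs, n, present, is_short=n < min_codons)


def background_frequencies(intergenic: str) -> BackgroundUsageVector:
    """Pseudo-codon composition of intergenic DNA.

    Triplets are read at every offset in all three frames on both strands
    and pooled, then normalized per family exactly like codon usage. Since
    both strands are pooled the result is invariant to reverse complement.
    """
    seq = normalize(intergenic)
    counts: Counter = Counter()
    for s in (seq, reverse_complement(seq)):
        for i in range(len(s) - 2):
            triplet = s[i : i + 3]
            if triplet in CODON_INDEX:
                counts[triplet] += 1
    n = sum(counts.values())
    freqs, present = _normalize_counts(counts)
    return BackgroundUsageVector(freqs, n, present, is_short=n == 0)


def extract_intergenic(record: GeneRecord, max_span: int = DEFAULT_INTERGENIC_SPAN) -> str:
    """Concatenate up to ``max_span`` nt of each flank nearest the gene.

    The upstream flank contributes its 3' end (adjacent to the gene start),
    the downstream flank its 5' end. Empty result is valid.
    """
    if max_span < 0:
        raise ValueError("max_span must be >= 0")
    up = record.upstream_intergenic[-max_span:] if max_span else ""
    down = record.downstream_intergenic[:max_span] if max_span else ""
    return up + down


def _row_sequences(row, seqs: dict[str, str], neighbors) -> tuple[str, str, str]:
    """Resolve (cds, upstream, downstream) for one gene-table row."""
    if isinstance(row.get("cds"), str) and row["cds"]:
        up = row.get("upstream") if isinstance(row.get("upstream"), str) else ""
        down = row.get("downstream") if isinstance(row.get("downstream"), str) else ""
        return normalize(row["cds"]), normalize(up), normalize(down)

    seq_id = row["seq_id"]
    if seq_id not in seqs:
        raise KeyError(f"sequence id {seq_id!r} not present in FASTA")
    genome = seqs[seq_id]
    start, end = int(row["start"]) - 1, int(row["end"])  # to 0-based half-open
    if start < 0 or end > len(genome) or start >= end:
        raise ValueError("coordinates out of range")
    cds = genome[start:end]
    left_bound, right_bound = neighbors(seq_id, start, end)
    left = genome[left_bound:start]
    right = genome[end:right_bound]
    if row["strand"] == "-":
        cds = reverse_complement(cds)
        up, down = reverse_complement(right), reverse_complement(left)
    else:
        up, down = left, right
    return cds, up, down


def load_genome(
    fasta_path,
    gene_table_path,
    genome_id: str | None = None,
    min_codons: int = DEFAULT_MIN_CODONS,
) -> tuple[list[GeneRecord], LoadReport]:
    """Load GeneRecords from a FASTA + gene-table pair.

    Rows whose CDS length is not a multiple of 3 or that contain an internal
    stop codon are rejected and counted in the report; a missing FASTA id is
    a hard error. Minus-strand genes are reverse-complemented to the coding
    strand. Intergenic flanks extend to the nearest annotated neighbor.
    """
    table = pd.read_csv(gene_table_path, sep="\t", dtype=str, keep_default_na=False)
    seqs = {rec.id: normalize(str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if genome_id is None:
        genome_id = str(gene_table_path)

    # per-contig sorted gene intervals, for bounding intergenic flanks
    intervals: dict[str, list[tuple[int, int]]] = {}
    for _, row in table.iterrows():
        if isinstance(row.get("cds"), str) and row["cds"]:
            continue
        try:
            s, e = int(row["start"]) - 1, int(row["end"])
        except (ValueError, KeyError):
            continue
        intervals.setdefault(row["seq_id"], []).append((s, e))
    for v in intervals.values():
        v.sort()

    def neighbors(seq_id: str, start: int, end: int) -> tuple[int, int]:
        left, right = 0, len(seqs[seq_id])
        for s, e in intervals.get(seq_id, []):
            if (s, e) == (start, end):
                continue
            if e <= start:
                left = max(left, e)
            if s >= end:
                right = min(right, s)
        return left, right

    records: list[GeneRecord] = []
    report = LoadReport()
    for _, row in table.iterrows():
        try:
            cds, up, down = _row_sequences(row, seqs, neighbors)
        except KeyError:
            raise
        except ValueError as exc:
            report.reject(str(exc))
            continue
        if len(cds) % 3 != 0:
            report.reject("length not divisible by 3")
            continue
        if has_internal_stop(cds):
            report.reject("internal stop codon")
            continue
        if set(cds) - set("ACGTN"):
            report.reject("non-nucleotide characters")
            continue
        cogs = frozenset(c for c in str(row.get("cog_ids", "")).split(",") if c)
        records.append(
            GeneRecord(
                gene_id=row["gene_id"],
                genome_id=genome_id,
                strand=row.get("strand", "+") or "+",
                cds=cds,
                upstream_intergenic=up,
                downstream_intergenic=down,
                cog_ids=cogs,
                is_reference_he=str(row.get("is_reference_he", "0")) in ("1", "yes", "True"),
            )
        )
        report.n_loaded += 1
    return records, report


def write_gene_table(records: list[GeneRecord], path) -> None:
    """Write records in annotation-free mode (explicit sequence columns).

    Reloading the written table (with any FASTA) reproduces the records;
    coordinates in this mode are not used. The file header documents the
    1-based inclusive convention used by coordinate-mode tables.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "seq_id": "",
                "start": "",
                "end": "",
                "strand": r.strand,
                "cog_ids": ",".join(sorted(r.cog_ids)),
                "is_reference_he": "1" if r.is_reference_he else "0",
                "cds": r.cds,
                "upstream": r.upstream_intergenic,
                "downstream": r.downstream_intergenic,
            }
        )
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
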