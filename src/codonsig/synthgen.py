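"""Synthetic worlds with planted codon bias and phenotype structure.

The generator emulates the statistical structure the analysis assumes in
real data, with full ground truth:

* genomes whose non-HE genes draw codons from the family-conditional
  distribution implied by an iid GC-parameterized background (the same
  composition their intergenic DNA is drawn from), while planted HE genes
  mix that distribution with a point mass on a designated optimal codon per
  family, with weight ``bias_strength`` — so codon-level bias is the only
  HE signal;
* a taxonomy built as a random nested partition of the organisms, exported
  as binary group-membership indicators;
* phenotypes generated along a directed chain (taxonomy group -> phenotype
  A -> phenotype B) with specified agreement, so a "confounded" phenotype
  literally carries no information beyond its parent;
* COG memberships with causal links (HE probability depends on the listed
  phenotype) and confounded links (HE depends only on the parent phenotype
  while the listed child merely correlates with it).

Every emitted artifact loads back through the seqio / cog_enrich readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import DEGENERATE_FAMILIES, TWOFOLD_FAMILIES, THREE_TO_ONE, codon_to_anticodon, reverse_complement
from .cog_enrich import NO, YES, PhenotypeMatrix, assemble_features
from .seqio import GeneRecord

#: roughly enterobacterial amino-acid frequencies (normalized at use)
AA_FREQS = {
    "L": 0.100, "A": 0.095, "G": 0.074, "V": 0.071, "I": 0.060,
    "S": 0.058, "E": 0.058, "R": 0.055, "T": 0.054, "D": 0.053,
    "K": 0.044, "P": 0.044, "N": 0.040, "F": 0.039, "Q": 0.039,
    "Y": 0.029, "M": 0.028, "H": 0.023, "W": 0.014, "C": 0.012,
}

@dataclass
class PhenotypeSpec:
    """One generated phenotype: agreement with a parent variable.

    ``parent`` may name a taxonomy feature, another phenotype, or be None
    (iid Bernoulli(0.5)); ``agreement`` is the probability that the value
    copies the parent's.
    """

    name: str
    parent: str | None = None
    agreement: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.agreement <= 1.0:
            raise ValueError("agreement must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class LinkSpec:
    """A planted COG-phenotype link.

    For a causal link the genes' HE probability follows the listed
    phenotype. For a confounded link it follows ``parent`` (the true
    cause); the listed phenotype is the correlated child.
    """

    cog_id: str
    phenotype: str
    p_he_positive: float
    p_he_negative: float
    kind: str = "causal"  # or "confounded"
    parent: str | None = None

    def __post_init__(self):
        if self.kind not in ("causal", "confounded"):
            raise ValueError("kind must be causal or confounded")
        if self.kind == "confounded" and self.parent is None:
            raise ValueError("confounded link needs a parent phenotype")


@dataclass
class SynthConfig:
    n_genomes: int = 40
    n_genes_per_genome: int = 200
    gc: float = 0.5
    he_fraction: float = 0.1
    bias_strength: float = 0.7
    intergenic_len: int = 200
    n_cogs: int = 20
    taxonomy_group_sizes: tuple[int, ...] | None = None  # None: two even domains
    n_taxonomy_features: int = 70
    n_phenotypes: int = 24
    phenotype_specs: tuple[PhenotypeSpec, ...] = ()
    link_specs: tuple[LinkSpec, ...] = ()
    missing_rate: float = 0.05
    paralog_rate: float = 0.05
    min_protein_len: int = 100  # uniform length, mean ~250 aa as in real
    max_protein_len: int = 400  # bacterial proteomes
    n_reference: int = 15
    seed: int = 0

    def __post_init__(self):
        for name, v in (("gc", self.gc), ("he_fraction", self.he_fraction),
                        ("bias_strength", self.bias_strength)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    he_labels: dict[str, bool]  # gene_id -> planted label
    optimal_codons: dict[str, str]  # family (one-letter aa) -> optimal codon
    causal_links: list[LinkSpec]
    confounded_links: list[LinkSpec]
    phenotype_graph: dict[str, tuple[str | None, float]]
    cog_genes: dict[str, list[tuple[str, str]]]  # cog -> [(genome, gene)]


@dataclass
class SynthWorld:
    config: SynthConfig
    matrix: PhenotypeMatrix
    cog_genes: dict[str, list[tuple[str, str]]]
    truth: GroundTruth
    genomes: dict[str, list[GeneRecord]] = field(default_factory=dict)
    trna: pd.DataFrame | None = None

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for genome_id, records in self.genomes.items():
            write_genome_fasta(records, self.config, out / f"{genome_id}.fasta",
                               out / f"{genome_id}.genes.tsv",
                               seed=self.config.seed)
        self.matrix.to_tsv(out / "phenotypes.tsv")
        if self.trna is not None:
            self.trna.to_csv(out / "trna.tsv", sep="\t", index=False)
        truth = {
            "he_labels": self.truth.he_labels,
            "optimal_codons": self.truth.optimal_codons,
            "causal_links": [asdict(l) for l in self.truth.causal_links],
            "confounded_links": [asdict(l) for l in self.truth.confounded_links],
            "phenotype_graph": self.truth.phenotype_graph,
            "cog_genes": self.truth.cog_genes,
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# phenotypes and taxonomy


def _nested_taxonomy(organisms: list[str], n_features: int, group_sizes, rng) -> pd.DataFrame:
    """Binary membership indicators from a random nested partition.

    Top-level groups play the role of domains; each group of 4+ organisms
    is recursively halved (phylum/class/order-like levels) until enough
    groups exist. In worlds too small for ``n_features`` distinct groups,
    indicators cycle over the available groups.
    """
    if group_sizes is None:
        half = len(organisms) // 2
        group_sizes = (half, len(organisms) - half)
    if sum(group_sizes) != len(organisms):
        raise ValueError("taxonomy group sizes must sum to n_genomes")
    order = list(rng.permutation(organisms))
    groups: list[list[str]] = []
    start = 0
    for size in group_sizes:
        if size > 0:
            groups.append(order[start : start + size])
        start += size
    queue = [g for g in groups if len(g) >= 4]
    while len(groups) < n_features and queue:
        members = queue.pop(0)
        cut = len(members) // 2
        shuffled = list(rng.permutation(members))
        for part in (shuffled[:cut], shuffled[cut:]):
            groups.append(part)
            if len(part) >= 4:
                queue.append(part)
    cols: dict[str, pd.Series] = {}
    for i in range(n_features):
        members = set(groups[i % len(groups)])
        cols[f"tax_{i:03d}"] = pd.Series(
            [YES if o in members else NO for o in organisms], index=organisms
        )
    return pd.DataFrame(cols)


def simulate_phenotypes(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[PhenotypeMatrix, dict[str, tuple[str | None, float]]]:
    """Taxonomy indicators + phenotypes with specified parent agreement.

    Returns the full organism x feature matrix (phenotypes, 6 discretized
    descriptors, taxonomy indicators) and the generative graph
    {phenotype: (parent, agreement)}.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    organisms = [f"g{i:03d}" for i in range(config.n_genomes)]
    taxonomy = _nested_taxonomy(
        organisms, config.n_taxonomy_features, config.taxonomy_group_sizes, rng
    )

    specs = list(config.phenotype_specs)
    while len(specs) < config.n_phenotypes:
        parent = f"tax_{int(rng.integers(config.n_taxonomy_features)):03d}"
        specs.append(
            PhenotypeSpec(
                name=f"phen_{len(specs):02d}",
                parent=parent,
                agreement=float(rng.uniform(0.6, 0.9)),
                missing_rate=config.missing_rate,
            )
        )

    values: dict[str, pd.Series] = {}
    graph: dict[str, tuple[str | None, float]] = {}
    for spec in specs:
        if spec.parent is None:
            base = pd.Series(
                np.where(rng.random(len(organisms)) < 0.5, YES, NO), index=organisms
            )
        else:
            if spec.parent in values:
                parent_vals = values[spec.parent]
            elif spec.parent in taxonomy.columns:
                parent_vals = taxonomy[spec.parent]
            else:
                raise KeyError(f"unknown parent {spec.parent!r} for {spec.name}")
            agree = rng.random(len(organisms)) < spec.agreement
            flipped = parent_vals.map({YES: NO, NO: YES})
            base = parent_vals.where(pd.Series(agree, index=organisms), flipped)
        if spec.missing_rate > 0:
            miss = rng.random(len(organisms)) < spec.missing_rate
            base = base.mask(pd.Series(miss, index=organisms))
        values[spec.name] = base
        graph[spec.name] = (spec.parent, spec.agreement)

    phen = pd.DataFrame(values)
    gc = pd.Series(
        np.clip(rng.normal(config.gc, 0.03, len(organisms)), 0.2, 0.8), index=organisms
    )
    mean_len = 3 * (config.min_protein_len + config.max_protein_len) / 2
    genome_size = pd.Series(
        config.n_genes_per_genome * (mean_len + config.intergenic_len)
        * rng.uniform(0.9, 1.1, len(organisms)),
        index=organisms,
    )
    matrix = assemble_features(phen, gc, genome_size, taxonomy)
    return matrix, graph


# ---------------------------------------------------------------------------
# COGs, links, labels


def plant_links(
    config: SynthConfig,
    matrix: PhenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], GroundTruth]:
    """Assign genes to COGs and decide planted HE labels per gene.

    Each of ``n_cogs`` COGs holds one ortholog per genome (occasionally a
    paralog pair). Genes of link COGs get HE with the specified probability
    given the driving phenotype's value in their genome (the listed
    phenotype for causal links, the parent for confounded ones; organisms
    with the driver missing fall back to the baseline rate). All remaining
    genes are HE with probability ``he_fraction``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    organisms = matrix.organisms
    links = {l.cog_id: l for l in config.link_specs}
    cog_ids = sorted(set(f"COG{i:04d}" for i in range(config.n_cogs)) | set(links))
    cog_genes: dict[str, list[tuple[str, str]]] = {c: [] for c in cog_ids}
    he_labels: dict[str, bool] = {}
    counters = {g: 0 for g in organisms}

    def new_gene(genome: str) -> str:
        gid = f"{genome}_gene{counters[genome]:04d}"
        counters[genome] += 1
        return gid

    for cog in cog_ids:
        link = links.get(cog)
        driver = None
        if link is not None:
            driver = link.phenotype if link.kind == "causal" else link.parent
        for genome in organisms:
            n_copies = 1 + (rng.random() < config.paralog_rate)
            for _ in range(n_copies):
                gene = new_gene(genome)
                cog_genes[cog].append((genome, gene))
                if link is None:
                    p = config.he_fraction
                else:
                    v = matrix.value(genome, driver)
                    p = (
                        link.p_he_positive
                        if v == YES
                        else link.p_he_negative
                        if v == NO
                        else config.he_fraction
                    )
                he_labels[gene] = bool(rng.random() < p)

    # fill each genome to its gene budget with COG-less genes
    for genome in organisms:
        while counters[genome] < config.n_genes_per_genome:
            gene = new_gene(genome)
            he_labels[gene] = bool(rng.random() < config.he_fraction)

    truth = GroundTruth(
        he_labels=he_labels,
        optimal_codons={},
        causal_links=[l for l in config.link_specs if l.kind == "causal"],
        confounded_links=[l for l in config.link_specs if l.kind == "confounded"],
        phenotype_graph={},
        cog_genes=cog_genes,
    )
    return cog_genes, truth


# ---------------------------------------------------------------------------
# sequences


def _background_family_dists(gc: float) -> dict[str, np.ndarray]:
    """Within-family codon distribution implied by iid GC-parameterized DNA."""
    p_nt = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    dists = {}
    for aa, codons in DEGENERATE_FAMILIES.items():
        w = np.array([np.prod([p_nt[nt] for nt in c]) for c in codons])
        dists[aa] = w / w.sum()
    return dists


def pick_optimal_codons(rng: np.random.Generator) -> dict[str, str]:
    """Designate one optimal codon per degenerate family."""
    return {
        aa: codons[int(rng.integers(len(codons)))]
        for aa, codons in DEGENERATE_FAMILIES.items()
    }


def _sample_cds(
    rng, protein_len: int, he: bool, bias: float,
    bg_dists: dict[str, np.ndarray], optimal: dict[str, str],
) -> str:
    aas = list(AA_FREQS)
    p = np.array(list(AA_FREQS.values()))
    protein = rng.choice(aas, size=protein_len, p=p / p.sum())
    codons = []
    for aa in protein:
        fam = DEGENERATE_FAMILIES.get(aa)
        if fam is None:  # Met or Trp
            codons.append("ATG" if aa == "M" else "TGG")
            continue
        dist = bg_dists[aa]
        if he and bias > 0:
            dist = dist * (1 - bias)
            dist = dist.copy()
            dist[fam.index(optimal[aa])] += bias
        codons.append(fam[int(rng.choice(len(fam), p=dist))])
    return "ATG" + "".join(codons) + "TAA"


def _random_dna(rng, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def simulate_genome(
    config: SynthConfig,
    genome_id: str,
    gene_plan: list[tuple[str, frozenset, bool, bool]],
    optimal: dict[str, str],
    rng: np.random.Generator | None = None,
) -> list[GeneRecord]:
    """Generate GeneRecords for one genome.

    ``gene_plan`` rows are (gene_id, cog_ids, he_label, is_reference_he).
    Intergenic flanks are iid GC-parameterized DNA shared between adjacent
    genes, mirroring a real gene-dense genome layout.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bg_dists = _background_family_dists(config.gc)
    spacers = [
        _random_dna(rng, config.intergenic_len, config.gc)
        for _ in range(len(gene_plan) + 1)
    ]
    records = []
    for i, (gene_id, cogs, he, is_ref) in enumerate(gene_plan):
        protein_len = int(rng.integers(config.min_protein_len, config.max_protein_len + 1))
        cds = _sample_cds(rng, protein_len, he, config.bias_strength, bg_dists, optimal)
        strand = "+" if rng.random() < 0.5 else "-"
        up, down = spacers[i], spacers[i + 1]
        if strand == "-":
            up, down = reverse_complement(down), reverse_complement(up)
        records.append(
            GeneRecord(
                gene_id=gene_id,
                genome_id=genome_id,
                strand=strand,
                cds=cds,
                upstream_intergenic=up,
                downstream_intergenic=down,
                cog_ids=frozenset(cogs),
                is_reference_he=is_ref,
            )
        )
    return records


def write_genome_fasta(
    records: list[GeneRecord], config: SynthConfig, fasta_path, table_path, seed: int = 0
) -> None:
    """Emit a coordinate-mode FASTA + gene table reproducing the records.

    Genes are laid out left to right with their upstream flank preceding
    them (in genome orientation); minus-strand genes are stored reverse
    complemented in the genome string.
    """
    parts: list[str] = []
    rows = []
    pos = 0
    genome_id = records[0].genome_id if records else "genome"
    for i, r in enumerate(records):
        up = r.upstream_intergenic if r.strand == "+" else reverse_complement(r.downstream_intergenic)
        parts.append(up)
        pos += len(up)
        genomic = r.cds if r.strand == "+" else reverse_complement(r.cds)
        start = pos + 1  # 1-based inclusive
        parts.append(genomic)
        pos += len(genomic)
        rows.append(
            {
                "gene_id": r.gene_id,
                "seq_id": genome_id,
                "start": start,
                "end": pos,
                "strand": r.strand,
                "cog_ids": ",".join(sorted(r.cog_ids)),
                "is_reference_he": "1" if r.is_reference_he else "0",
                "cds": "",
                "upstream": "",
                "downstream": "",
            }
        )
    if records:
        last = records[-1]
        tail = (
            last.downstream_intergenic
            if last.strand == "+"
            else reverse_complement(last.upstream_intergenic)
        )
        parts.append(tail)
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome_id}\n")
        seq = "".join(parts)
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def trna_inventory(optimal: dict[str, str]) -> pd.DataFrame:
    """tRNA anticodon TSV rows consistent with the planted optimal codons.

    For each twofold family only the Watson-Crick anticodon of the optimal
    codon is present, making the tRNA-implied optimum equal the planted one.
    """
    rows = []
    one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
    for aa3, (c1, c2) in TWOFOLD_FAMILIES.items():
        opt = optimal[THREE_TO_ONE[aa3]]
        rows.append(
            {
                "amino_acid": aa3,
                "anticodon": codon_to_anticodon(opt),
                "copy_number": 1,
            }
        )
    return pd.DataFrame(rows)


def simulate_world(config: SynthConfig, sequences: bool = True) -> SynthWorld:
    """Generate a full world: matrix, COGs, labels, and (optionally) sequences."""
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(4)]
    matrix, graph = simulate_phenotypes(config, rngs[0])
    cog_genes, truth = plant_links(config, matrix, rngs[1])
    truth.phenotype_graph = graph
    optimal = pick_optimal_codons(rngs[2])
    truth.optimal_codons = optimal

    genomes: dict[str, list[GeneRecord]] = {}
    trna = None
    if sequences:
        gene_rng = rngs[3]
        # per-genome gene plans from the COG assignment + filler genes
        plans: dict[str, list[tuple[str, frozenset, bool, bool]]] = {
            g: [] for g in matrix.organisms
        }
        gene_cogs: dict[str, set[str]] = {}
        for cog, members in cog_genes.items():
            for genome, gene in members:
                gene_cogs.setdefault(gene, set()).add(cog)
        all_genes: dict[str, list[str]] = {g: [] for g in matrix.organisms}
        for gene in truth.he_labels:
            genome = gene.split("_gene")[0]
            all_genes[genome].append(gene)
        for genome, genes in all_genes.items():
            he_genes = [g for g in sorted(genes) if truth.he_labels[g]]
            ref = set(
                gene_rng.choice(
                    he_genes, size=min(config.n_reference, len(he_genes)), replace=False
                )
            )
            for gene in sorted(genes):
                plans[genome].append(
                    (
                        gene,
                        frozenset(gene_cogs.get(gene, ())),
                        truth.he_labels[gene],
                        gene in ref,
                    )
                )
        for gi, genome in enumerate(matrix.organisms):
            sub = np.random.default_rng(np.random.SeedSequence([config.seed, 7919, gi]))
            genomes[genome] = simulate_genome(config, genome, plans[genome], optimal, sub)
        trna = trna_inventory(optimal)
    return SynthWorld(config, matrix, cog_genes, truth, genomes, trna)
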