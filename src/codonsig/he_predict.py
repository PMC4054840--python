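"""Predict highly expressed (HE) genes from codon bias versus local background.

Two coupled constructions per genome:

* **Paired classifier runs.** A Random Forest is trained to discriminate a
  reference set of known HE genes (ribosomal proteins, chaperones) from a
  size-matched bootstrap of other genes, once on codon-usage vectors and
  once on the pseudo-codon composition of the genes' flanking intergenic
  DNA. Averaged over runs, the two probabilities (``codon_score``,
  ``background_score``) quantify how reference-like a gene's codon usage is
  relative to what its local composition alone would suggest; the codon
  score is the ranking statistic for HE-ness.

* **Codon-paired sign test.** Significance comes from a paired test at the
  codon level: every countable codon of a gene is compared with a fresh
  draw from the gene's own intergenic background (same amino-acid family),
  both scored by the log-preference of the reference set over the local
  background. Under the null (codons drawn from the local composition) each
  pair is an independent fair coin, so wins follow Binomial(n, 1/2)
  exactly, and the hundreds of per-gene trials give the test enough
  resolution for very stringent FDR thresholds (q <= 1e-12 by default).
  Ties (equal preference) are excluded. P values are Benjamini-Hochberg
  corrected across the genes of the genome.

A sign test across classifier runs was considered and rejected: a gene's
fixed codon vector makes run outcomes persistent rather than independent,
which badly inflates significance on null data (see docs/methods.md).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .codons import (
    CODON_FAMILY,
    CODON_INDEX,
    DEGENERATE_FAMILIES,
    STOP_CODONS,
    iter_codons,
    normalize,
)
from .seqio import GeneRecord, background_frequencies, codon_frequencies, extract_intergenic

logger = logging.getLogger(__name__)

DEFAULT_N_RUNS = 200
DEFAULT_Q_THRESHOLD = 1e-12
DEFAULT_MIN_REFERENCE = 10


@dataclass
class ClassifierConfig:
    """Random Forest settings shared by the HE predictor and the confounder test."""

    n_estimators: int = 500
    max_features: str | float = "sqrt"

    def build(self, seed: int, oob: bool = False) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            bootstrap=True,
            oob_score=oob,
            n_jobs=1,
            random_state=seed,
        )


@dataclass
class ReferenceSet:
    """Genes flagged as known-HE (reference) in one genome."""

    gene_ids: frozenset[str]

    @classmethod
    def from_records(cls, genes: list[GeneRecord]) -> "ReferenceSet":
        return cls(frozenset(g.gene_id for g in genes if g.is_reference_he))


@dataclass
class ExpressionCall:
    gene_id: str
    codon_score: float  # mean classifier probability across runs
    background_score: float
    n_runs: int  # paired sign-test trials (codon positions compared)
    n_wins: int  # trials where the gene codon beats its background draw
    n_ties: int  # excluded equal-preference pairs
    sign_p: float
    q_value: float
    label: str  # 'HE' or 'nonHE'


@dataclass
class ScorePairs:
    """Per-genome paired scores: classifier runs plus codon-level sign trials."""

    gene_ids: list[str]
    codon: np.ndarray  # (n_genes, n_runs) classifier probabilities
    background: np.ndarray  # (n_genes, n_runs)
    trial_wins: np.ndarray  # (n_genes,) codon-paired trials won
    trial_losses: np.ndarray  # (n_genes,)
    trial_ties: np.ndarray  # (n_genes,) excluded pairs

    @property
    def n_runs(self) -> int:
        return self.codon.shape[1]


class GenomeSkipped(RuntimeError):
    """Raised when a genome cannot be analysed (e.g. reference set too small)."""


def _oob_mean_scores(clf, train_idx, X_all) -> np.ndarray:
    """Probability of the positive class for every gene, out-of-bag where trained.

    Genes present in the training set are scored only by trees whose
    bootstrap sample excluded them (the forest's OOB decision function);
    the rare training gene never left out of bag falls back to the
    full-forest probability. Duplicate bootstrap rows of one gene are
    averaged.
    """
    scores = clf.predict_proba(X_all)[:, 1]
    oob = clf.oob_decision_function_[:, 1]
    sums: dict[int, list[float]] = {}
    for row, gene_idx in enumerate(train_idx):
        if not math.isnan(oob[row]):
            sums.setdefault(int(gene_idx), []).append(float(oob[row]))
    for gene_idx, vals in sums.items():
        scores[gene_idx] = float(np.mean(vals))
    return scores


def _countable_codons(cds: str) -> list[str]:
    codons = list(iter_codons(normalize(cds)))[1:]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return [c for c in codons if c in CODON_INDEX]


def _preference_scores(
    ref_counts: np.ndarray, pseudocount: float = 0.5
) -> dict[str, float]:
    """Per-codon preference of the reference set (smoothed family fractions).

    Only the within-family ordering matters for the paired comparison. The
    background plays no role in the score: the control for local
    composition is that the partner codon of each pair is *drawn* from the
    gene's own intergenic background. Mixing the background into the score
    as well would correlate the score's estimation noise with the draw
    distribution and bias the comparison.
    """
    scores: dict[str, float] = {}
    for aa, codons in DEGENERATE_FAMILIES.items():
        idx = [CODON_INDEX[c] for c in codons]
        ref = ref_counts[idx] + pseudocount
        ref = ref / ref.sum()
        for c, r in zip(codons, ref):
            scores[c] = float(r)
    return scores


def _pseudo_codon_counts(intergenic: str) -> np.ndarray:
    """Raw pseudo-codon counts (59,) over both strands, all frames."""
    from .codons import reverse_complement

    counts = np.zeros(59)
    seq = normalize(intergenic)
    for s in (seq, reverse_complement(seq)):
        for i in range(len(s) - 2):
            j = CODON_INDEX.get(s[i : i + 3])
            if j is not None:
                counts[j] += 1
    return counts


def codon_paired_trials(
    genes: list[GeneRecord],
    reference: ReferenceSet,
    seed: int = 0,
    intergenic_span: int = 400,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired codon-vs-background sign-test trials for every gene.

    Every countable codon of a gene is paired with one fresh codon drawn
    from the family-conditional pseudo-codon composition of the gene's own
    intergenic flank; the codon preferred by the reference set wins (equal
    preference is a tie, excluded). Under the null hypothesis that a gene's
    codons are drawn from its local background composition, observed codon
    and drawn codon are identically distributed within each family, so for
    any fixed preference ordering wins and losses are exactly symmetric and
    the win count is Binomial(n, 1/2).

    Returns (wins, losses, ties) arrays aligned with ``genes``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5167]))
    ref_counts = np.zeros(59)
    for g in genes:
        if g.gene_id in reference.gene_ids:
            for c in _countable_codons(g.cds):
                ref_counts[CODON_INDEX[c]] += 1
    pref = _preference_scores(ref_counts)
    n = len(genes)
    wins = np.zeros(n, dtype=int)
    losses = np.zeros(n, dtype=int)
    ties = np.zeros(n, dtype=int)
    for gi, g in enumerate(genes):
        bg_counts = _pseudo_codon_counts(extract_intergenic(g, intergenic_span))
        gene_codons = _countable_codons(g.cds)
        from collections import Counter

        by_family: dict[str, Counter] = {}
        for c in gene_codons:
            by_family.setdefault(CODON_FAMILY[c], Counter())[c] += 1
        for aa, counter in by_family.items():
            fam = DEGENERATE_FAMILIES[aa]
            idx = [CODON_INDEX[c] for c in fam]
            bg = bg_counts[idx] + 0.5
            bg = bg / bg.sum()
            for codon, m in counter.items():
                draw = rng.multinomial(m, bg)
                s_obs = pref[codon]
                for other, k in zip(fam, draw):
                    if k == 0:
                        continue
                    s_alt = pref[other]
                    if s_obs > s_alt:
                        wins[gi] += k
                    elif s_obs < s_alt:
                        losses[gi] += k
                    else:
                        ties[gi] += k
    return wins, losses, ties


def paired_scores(
    genes: list[GeneRecord],
    reference: ReferenceSet | None = None,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
    classifier: ClassifierConfig | None = None,
    min_reference: int = DEFAULT_MIN_REFERENCE,
    intergenic_span: int = 400,
) -> ScorePairs:
    """Paired codon/background classifier scores plus codon-level sign trials.

    Each run trains classifier A on codon-usage vectors and classifier B on
    background vectors of the same training genes (reference positives plus
    an equal-size bootstrap of non-reference negatives) and scores every
    gene with both, out-of-bag for training genes. The codon-paired trials
    feeding the sign test are computed once (see ``codon_paired_trials``).
    """
    if classifier is None:
        classifier = ClassifierConfig()
    if reference is None:
        reference = ReferenceSet.from_records(genes)
    gene_ids = [g.gene_id for g in genes]
    ref_idx = np.array([i for i, g in enumerate(genes) if g.gene_id in reference.gene_ids])
    other_idx = np.array([i for i, g in enumerate(genes) if g.gene_id not in reference.gene_ids])
    if len(ref_idx) < min_reference:
        raise GenomeSkipped(
            f"reference set has {len(ref_idx)} genes, below minimum {min_reference}"
        )
    if len(other_idx) == 0:
        raise ValueError("degenerate genome: every gene is in the reference set")

    X_codon = np.vstack([codon_frequencies(g.cds).as_array() for g in genes])
    X_bg = np.vstack(
        [
            background_frequencies(extract_intergenic(g, intergenic_span)).as_array()
            for g in genes
        ]
    )

    master = np.random.SeedSequence(seed)
    run_seeds = master.generate_state(2 * n_runs) % (2**31 - 1)
    n_genes = len(genes)
    codon_scores = np.empty((n_genes, n_runs))
    bg_scores = np.empty((n_genes, n_runs))
    for r in range(n_runs):
        rng = np.random.default_rng(run_seeds[2 * r])
        neg = rng.choice(other_idx, size=len(ref_idx), replace=True)
        train_idx = np.concatenate([ref_idx, neg])
        y = np.concatenate([np.ones(len(ref_idx)), np.zeros(len(neg))]).astype(int)
        clf_seed = int(run_seeds[2 * r + 1])
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
            warnings.filterwarnings("ignore", message="invalid value encountered in divide")
            clf_a = classifier.build(clf_seed, oob=True).fit(X_codon[train_idx], y)
            clf_b = classifier.build(clf_seed, oob=True).fit(X_bg[train_idx], y)
        codon_scores[:, r] = _oob_mean_scores(clf_a, train_idx, X_codon)
        bg_scores[:, r] = _oob_mean_scores(clf_b, train_idx, X_bg)
    t_wins, t_losses, t_ties = codon_paired_trials(
        genes, reference, seed=seed, intergenic_span=intergenic_span
    )
    return ScorePairs(gene_ids, codon_scores, bg_scores, t_wins, t_losses, t_ties)


def sign_test_label(
    pairs: ScorePairs, q_threshold: float = DEFAULT_Q_THRESHOLD
) -> list[ExpressionCall]:
    """Label genes HE/nonHE by the one-tailed binomial sign test.

    Trials are the paired codon-vs-background comparisons carried by
    ``pairs`` (ties excluded). A gene is HE iff its Benjamini-Hochberg q
    value is at or below the threshold and it won a majority of non-tied
    trials.
    """
    wins = pairs.trial_wins
    trials = pairs.trial_wins + pairs.trial_losses
    p = np.ones(len(wins), dtype=float)
    nonzero = trials > 0
    p[nonzero] = stats.binom.sf(wins[nonzero] - 1, trials[nonzero], 0.5)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    calls = []
    for i, gid in enumerate(pairs.gene_ids):
        majority = wins[i] > trials[i] / 2
        label = "HE" if (q[i] <= q_threshold and majority) else "nonHE"
        calls.append(
            ExpressionCall(
                gene_id=gid,
                codon_score=float(pairs.codon[i].mean()),
                background_score=float(pairs.background[i].mean()),
                n_runs=int(trials[i] + pairs.trial_ties[i]),
                n_wins=int(wins[i]),
                n_ties=int(pairs.trial_ties[i]),
                sign_p=float(p[i]),
                q_value=float(q[i]),
                label=label,
            )
        )
    return calls


@dataclass
class CaiTable:
    """Relative adaptiveness w per codon, max-normalized within each family."""

    w: dict[str, float]

    @classmethod
    def from_reference(cls, reference_cds: list[str]) -> "CaiTable":
        from collections import Counter

        counts: Counter = Counter()
        for cds in reference_cds:
            cds = normalize(cds)
            codons = list(iter_codons(cds))[1:]
            if codons and codons[-1] in STOP_CODONS:
                codons = codons[:-1]
            counts.update(c for c in codons if c in CODON_INDEX)
        w: dict[str, float] = {}
        for aa, codons in DEGENERATE_FAMILIES.items():
            vals = {c: (counts[c] if counts[c] > 0 else 0.5) for c in codons}
            top = max(vals.values())
            for c in codons:
                w[c] = vals[c] / top
        return cls(w)


def compute_cai(cds: str, table: CaiTable) -> float:
    """Codon adaptation index: geometric mean of w over countable codons.

    Met/Trp and stop codons are excluded; the start codon and terminal stop
    are not counted. Raises ValueError when no codon is countable.
    """
    cds = normalize(cds)
    codons = list(iter_codons(cds))[1:]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    logs = [math.log(table.w[c]) for c in codons if c in CODON_INDEX]
    if not logs:
        raise ValueError("CAI undefined: no countable codons")
    return math.exp(sum(logs) / len(logs))


@dataclass
class HeSummary:
    n_genes: int
    n_he: int
    fraction_he: float


def he_summary(calls: list[ExpressionCall]) -> HeSummary:
    if not calls:
        raise ValueError("no expression calls")
    n_he = sum(1 for c in calls if c.label == "HE")
    return HeSummary(len(calls), n_he, n_he / len(calls))
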