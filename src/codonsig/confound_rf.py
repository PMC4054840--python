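"""Randomization test for independent phenotype contribution within a COG.

A strong COG-phenotype enrichment can be an artifact of phylogeny or of a
correlated phenotype. To test whether a phenotype carries information about
the HE labels of a COG's genes beyond everything else, a Random Forest is
trained to predict each gene's HE/non-HE label from all organism features
(phenotypes + genome descriptors + taxonomy indicators), its cross-validated
AUC recorded, and then the tested feature alone is shuffled (genome-wise,
so paralogs of one genome keep a common value) and the cross-validated AUC
remeasured, 30 times. The original AUC is expressed as a Z score against
the shuffled distribution and converted to a one-tailed P via the normal
CDF; the phenotype contributes independently when P < 1e-2.

If shuffling does not hurt the AUC, whatever the feature knew about the
labels was recoverable from the remaining features: the association is
confounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cog_enrich import NO, YES, PhenotypeMatrix
from .he_predict import ClassifierConfig

logger = logging.getLogger(__name__)

DEFAULT_N_SHUFFLES = 30
DEFAULT_N_FOLDS = 10
DEFAULT_P_THRESHOLD = 1e-2

_ENCODING = {NO: 0, YES: 1, None: 2}


class UntestableDataset(RuntimeError):
    """Raised when a COG dataset cannot support the randomization test."""


@dataclass
class CogDataset:
    """One instance per gene of a COG; features are the gene's organism descriptors."""

    cog_id: str
    features: pd.DataFrame  # instances x features, values yes/no/NaN
    y: np.ndarray  # 1 = HE, 0 = nonHE
    genome_ids: np.ndarray

    def __post_init__(self):
        if len(self.features) != len(self.y) or len(self.y) != len(self.genome_ids):
            raise ValueError("instances, labels and genome ids must align")

    @property
    def testable(self) -> bool:
        return len(np.unique(self.y)) == 2

    def encoded(self) -> np.ndarray:
        """Ordinal encoding no=0, yes=1, missing=2 (trees split on it natively)."""
        df = self.features
        out = np.full(df.shape, 2, dtype=np.int8)
        out[(df == YES).to_numpy()] = 1
        out[(df == NO).to_numpy()] = 0
        return out


def build_cog_dataset(
    cog_id: str,
    cog_genes: dict[str, list[tuple[str, str]]],
    he_labels: dict[str, bool],
    matrix: PhenotypeMatrix,
) -> CogDataset:
    """Assemble the per-gene dataset for one COG.

    Genomes in which the tested phenotype is missing are retained:
    missingness is an explicit category, and dropping those genes would
    discard label information the other features may explain.
    """
    if cog_id not in cog_genes:
        raise KeyError(f"COG {cog_id!r} not found")
    genes = cog_genes[cog_id]
    if not genes:
        raise ValueError(f"COG {cog_id!r} is empty")
    rows, labels, genomes = [], [], []
    for genome_id, gene_id in genes:
        rows.append(matrix.df.loc[genome_id])
        labels.append(1 if he_labels[gene_id] else 0)
        genomes.append(genome_id)
    features = pd.DataFrame(rows).reset_index(drop=True)
    ds = CogDataset(cog_id, features, np.array(labels), np.array(genomes))
    if not ds.testable:
        logger.warning("COG %s has a single-class label set; untestable", cog_id)
    return ds


def cv_auc(
    dataset: CogDataset,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    classifier: ClassifierConfig | None = None,
    X: np.ndarray | None = None,
) -> float:
    """Pooled out-of-fold AUC of a Random Forest on the COG dataset.

    Folds are stratified; when the minority class has fewer members than
    ``n_folds`` the fold count is reduced (logged). Deterministic under
    ``seed``.
    """
    if classifier is None:
        classifier = ClassifierConfig()
    if not dataset.testable:
        raise UntestableDataset(f"COG {dataset.cog_id}: single-class labels")
    if X is None:
        X = dataset.encoded()
    y = dataset.y
    min_class = int(np.bincount(y).min())
    folds = min(n_folds, min_class)
    if folds < n_folds:
        logger.info(
            "COG %s: reducing folds %d -> %d (minority class size)",
            dataset.cog_id, n_folds, folds,
        )
    if folds < 2:
        raise UntestableDataset(f"COG {dataset.cog_id}: minority class too small")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = np.empty(len(y))
    for k, (train, test) in enumerate(skf.split(X, y)):
        clf = classifier.build(seed + k).fit(X[train], y[train])
        pooled[test] = clf.predict_proba(X[test])[:, 1]
    return float(roc_auc_score(y, pooled))


def shuffle_feature(dataset: CogDataset, feature: str, seed: int) -> CogDataset:
    """Permute one feature column genome-wise; everything else untouched.

    All instances (paralogs) of a genome receive the value of a single
    other genome, preserving the within-genome tying of organism
    descriptors.
    """
    if feature not in dataset.features.columns:
        raise KeyError(f"feature {feature!r} not in dataset")
    rng = np.random.default_rng(seed)
    genomes = pd.unique(dataset.genome_ids)
    current = {
        g: dataset.features[feature].iloc[int(np.argmax(dataset.genome_ids == g))]
        for g in genomes
    }
    permuted = rng.permutation(genomes)
    new_value = {g: current[p] for g, p in zip(genomes, permuted)}
    features = dataset.features.copy()
    features[feature] = [new_value[g] for g in dataset.genome_ids]
    return CogDataset(dataset.cog_id, features, dataset.y.copy(), dataset.genome_ids.copy())


@dataclass
class RandomizationVerdict:
    cog_id: str
    phenotype: str
    auc_original: float
    auc_shuffled: np.ndarray
    z: float
    p_one_tailed: float
    independent: bool
    degenerate: bool = False


def randomization_test(
    dataset: CogDataset,
    phenotype: str,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    classifier: ClassifierConfig | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> RandomizationVerdict:
    """Run the shuffle test for one COG/phenotype pair.

    Z = (AUC_original - mean(AUC_shuffled)) / sd(AUC_shuffled);
    P = 1 - Phi(Z), one-tailed for a consistent AUC drop under shuffling.
    A near-zero shuffled spread is flagged degenerate (P collapses to 0 or 1).
    """
    if not dataset.testable:
        raise UntestableDataset(f"COG {dataset.cog_id}: single-class labels")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_shuffles + 1) % (2**31 - 1)
    auc_orig = cv_auc(dataset, n_folds, int(seeds[0]), classifier)
    shuffled = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = shuffle_feature(dataset, phenotype, int(seeds[2 * i + 1]))
        shuffled[i] = cv_auc(perm, n_folds, int(seeds[2 * i + 2]), classifier)
    sd = float(shuffled.std(ddof=1))
    mean = float(shuffled.mean())
    degenerate = sd < 1e-9
    if degenerate:
        z = float("inf") if auc_orig > mean else float("-inf")
        p = 0.0 if auc_orig > mean else 1.0
    else:
        z = (auc_orig - mean) / sd
        p = float(stats.norm.sf(z))
    return RandomizationVerdict(
        cog_id=dataset.cog_id,
        phenotype=phenotype,
        auc_original=auc_orig,
        auc_shuffled=shuffled,
        z=z,
        p_one_tailed=p,
        independent=bool(p < p_threshold),
        degenerate=degenerate,
    )
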