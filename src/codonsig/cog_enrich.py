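"""COG x phenotype enrichment screen for highly expressed genes.

Organisms are annotated with binary features (phenotypes, discretized
genome descriptors, taxonomy indicators) that may be missing. For each
orthologous group (COG) and phenotype, genes of organisms with the
phenotype are compared against genes of organisms without it in a 2x2
table of HE / non-HE counts; a COG passes the screen when the fold change
in HE fraction is at least two-fold (or at most 0.5-fold depletion) and
the two-tailed Fisher exact P is below 1e-2. The screen-level false
discovery rate is estimated as expected false positives over observed
positives: 100 * alpha * n_tested / n_significant.

Counting is gene-level: each gene (including paralogs within a genome) is
one observation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

YES, NO, MISSING = "yes", "no", "NA"

DEFAULT_ALPHA = 1e-2
DEFAULT_FOLD_MIN = 2.0
DEFAULT_COG_MIN = 20
DEFAULT_COG_MAX = 10_000


class PhenotypeMatrix:
    """Organism x feature matrix of {yes, no, missing} values.

    Thin wrapper over a pandas DataFrame (index = genome ids, columns =
    feature names, values 'yes'/'no'/NaN) with TSV round-trip helpers.
    """

    def __init__(self, df: pd.DataFrame):
        if df.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        bad = set(df.stack().unique()) - {YES, NO}
        if bad:
            raise ValueError(f"values outside yes/no/NA: {sorted(bad)}")
        self.df = df

    @property
    def organisms(self) -> list[str]:
        return list(self.df.index)

    @property
    def features(self) -> list[str]:
        return list(self.df.columns)

    def value(self, organism: str, feature: str):
        v = self.df.at[organism, feature]
        return None if pd.isna(v) else v

    def groups(self, feature: str) -> tuple[set[str], set[str]]:
        """(positive organisms, negative organisms); missing excluded."""
        if feature not in self.df.columns:
            raise KeyError(f"phenotype {feature!r} not in matrix")
        col = self.df[feature]
        return set(col.index[col == YES]), set(col.index[col == NO])

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(df.where(df.notna() & (df != MISSING)))

    def to_tsv(self, path) -> None:
        self.df.fillna(MISSING).to_csv(path, sep="\t")


def discretize(value: float, quartiles: tuple[float, float, float]) -> tuple[bool, bool, bool]:
    """Encode a continuous value as cumulative quartile-threshold indicators.

    Returns (value >= Q1, value >= Q2, value >= Q3). Values outside the
    observed range simply saturate the indicators (clamping), and are the
    caller's concern to log.
    """
    q1, q2, q3 = quartiles
    return (value >= q1, value >= q2, value >= q3)


def descriptor_features(gc: pd.Series, genome_size: pd.Series) -> pd.DataFrame:
    """Six binary features discretizing GC content and genome size.

    Quartile boundaries are computed once over the analysed genome set;
    each descriptor becomes three cumulative indicators (>=Q1, >=Q2, >=Q3).
    """
    out = {}
    for name, series in (("gc", gc), ("genome_size", genome_size)):
        qs = tuple(np.percentile(series.to_numpy(dtype=float), [25, 50, 75]))
        for i, q in enumerate(qs, start=1):
            out[f"{name}_ge_q{i}"] = series.astype(float).ge(q).map({True: YES, False: NO})
    return pd.DataFrame(out, index=gc.index)


def assemble_features(
    phenotypes: pd.DataFrame, gc: pd.Series, genome_size: pd.Series, taxonomy: pd.DataFrame
) -> PhenotypeMatrix:
    """Join phenotype, descriptor, and taxonomy blocks into one matrix."""
    desc = descriptor_features(gc, genome_size)
    df = pd.concat([phenotypes, desc, taxonomy], axis=1)
    return PhenotypeMatrix(df)


def filter_cogs(
    cog_genes: dict[str, list], min_total: int = DEFAULT_COG_MIN, max_total: int = DEFAULT_COG_MAX
) -> dict[str, list]:
    """Retain COGs whose total gene count (over all genomes) is in [min, max]."""
    return {
        cog: genes
        for cog, genes in cog_genes.items()
        if min_total <= len(genes) <= max_total
    }


def fisher_two_tailed_margins(r1: int, r2: int, c1: int) -> np.ndarray:
    """Two-tailed Fisher P for every table with the given margins.

    Returns the P value for each feasible count ``a`` (HE genes in the
    first group) in the support of Hypergeom(n=r1+r2, K=c1, draws=r1),
    ordered by ``a``. Degenerate margins give all-ones.
    """
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return np.ones(hi - lo + 1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    # sum of point probabilities <= observed, with relative slack for ties
    mask = pmf[None, :] <= pmf[:, None] * (1 + 1e-7)
    return np.minimum(mask @ pmf, 1.0)


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact P for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities not exceeding the observed one
    (with 1e-7 relative slack for floating-point ties). A degenerate margin
    returns P = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative count")
    lo = max(0, (a + c) - (c + d))
    return float(fisher_two_tailed_margins(a + b, c + d, a + c)[a - lo])


@dataclass
class EnrichmentRecord:
    cog_id: str
    phenotype: str
    a: int  # HE genes in phenotype-positive organisms
    b: int  # non-HE genes in positive organisms
    c: int  # HE genes in negative organisms
    d: int  # non-HE genes in negative organisms
    fold: float | None  # (a/(a+b)) / (c/(c+d)); None when undefined
    p_two_tailed: float
    passes: bool


@dataclass
class ScreenSummary:
    phenotype: str
    n_tested: int
    n_significant: int
    alpha: float
    fdr_estimate: float | None  # percent


def estimate_screen_fdr(n_tested: int, n_significant: int, alpha: float) -> float:
    """Expected-false-positive FDR of the screen, as a percentage."""
    if n_significant <= 0:
        raise ValueError("FDR estimate undefined when nothing is significant")
    return 100.0 * alpha * n_tested / n_significant


def _fold(a: int, b: int, c: int, d: int) -> float | None:
    if a + b == 0 or c + d == 0:
        return None
    p_pos = a / (a + b)
    p_neg = c / (c + d)
    if p_neg == 0:
        return math.inf if a > 0 else None  # 0/0: no HE genes anywhere
    return p_pos / p_neg


def screen_phenotype(
    cog_genes: dict[str, list[tuple[str, str]]],
    he_labels: dict[str, bool],
    matrix: PhenotypeMatrix,
    phenotype: str,
    alpha: float = DEFAULT_ALPHA,
    fold_min: float = DEFAULT_FOLD_MIN,
) -> tuple[list[EnrichmentRecord], ScreenSummary]:
    """Screen retained COGs for HE enrichment/depletion in one phenotype.

    ``cog_genes`` maps COG id -> list of (genome_id, gene_id); ``he_labels``
    maps gene_id -> bool. Organisms with the phenotype missing are excluded.
    Records with an undefined fold (a phenotype group with no genes, or no
    HE genes on either side) do not count toward n_tested.
    """
    pos, neg = matrix.groups(phenotype)
    records: list[EnrichmentRecord] = []
    n_tested = n_sig = 0
    for cog_id, genes in sorted(cog_genes.items()):
        a = b = c = d = 0
        for genome_id, gene_id in genes:
            he = he_labels[gene_id]
            if genome_id in pos:
                a += he
                b += not he
            elif genome_id in neg:
                c += he
                d += not he
        if (a + b) == 0 or (c + d) == 0:
            continue  # no representatives in one group: not testable
        fold = _fold(a, b, c, d)
        p = fisher_two_tailed(a, b, c, d)
        defined = fold is not None
        passes = bool(
            defined and (fold >= fold_min or fold <= 1.0 / fold_min) and p < alpha
        )
        records.append(EnrichmentRecord(cog_id, phenotype, a, b, c, d, fold, p, passes))
        if defined:
            n_tested += 1
            n_sig += passes
    fdr = estimate_screen_fdr(n_tested, n_sig, alpha) if n_sig > 0 else None
    return records, ScreenSummary(phenotype, n_tested, n_sig, alpha, fdr)


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cog_id": r.cog_id,
                "phenotype": r.phenotype,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "fold": r.fold if r.fold is not None else np.nan,
                "p_two_tailed": r.p_two_tailed,
                "passes": r.passes,
            }
            for r in records
        ]
    )
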