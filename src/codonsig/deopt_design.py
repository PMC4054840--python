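"""Design synonymous codon-de-optimized gene variants.

Codon optimality is a codon's usage percentage among its synonymous
alternatives in a reference set of ribosomal-protein CDSs (percentages sum
to 100 within each amino-acid family). A replacement codon must reduce the
original codon's optimality by at least 30% (new <= 70% of original) while
staying at or above 3% to avoid extremely rare codons.

Variants are built iteratively: each step proposes ``n_samples`` random
candidates replacing ``step_size`` not-yet-changed eligible codons and
keeps the candidate whose 42-nt-window mRNA folding free-energy profile is
closest (RMSD) to the wild type, so that de-optimization does not create or
destroy stable mRNA structure. Changed codons are frozen. Eligibility is
always evaluated against the original codon's optimality.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .codons import (
    CODON_FAMILY,
    CODON_TO_AA,
    DEGENERATE_FAMILIES,
    AA_TO_CODONS,
    STOP_CODONS,
    iter_codons,
    normalize,
    translate,
)
from .folding import FoldingBackend, FoldingProfile, folding_profile, get_backend, profile_r, profile_rmsd

logger = logging.getLogger(__name__)


@dataclass
class CodonOptimalityTable:
    """Usage percentage of each codon among synonymous alternatives (sums to 100)."""

    percent: dict[str, float]

    @classmethod
    def from_reference(cls, rp_cds_list: list[str]) -> "CodonOptimalityTable":
        if not rp_cds_list:
            raise ValueError("at least one reference CDS required")
        counts: Counter = Counter()
        for cds in rp_cds_list:
            codons = list(iter_codons(normalize(cds)))
            if codons and codons[-1] in STOP_CODONS:
                codons = codons[:-1]
            counts.update(c for c in codons if c in CODON_TO_AA)
        percent: dict[str, float] = {}
        for aa, codons in AA_TO_CODONS.items():
            total = sum(counts[c] for c in codons)
            if total == 0:
                for c in codons:
                    percent[c] = 0.0
                logger.warning("amino acid %s absent from reference set", aa)
            else:
                for c in codons:
                    percent[c] = 100.0 * counts[c] / total
        return cls(percent)


@dataclass
class DesignConstraints:
    reduction_factor: float = 0.7  # new optimality <= 70% of the original
    floor_percent: float = 3.0  # never below 3% usage
    step_size: int | None = None  # codons replaced per search step (None = auto)
    n_samples: int = 100  # candidates per step

    def __post_init__(self):
        if not 0 < self.reduction_factor < 1:
            raise ValueError("reduction_factor must be in (0, 1)")
        if self.floor_percent <= 0:
            raise ValueError("floor_percent must be positive")

    def resolved_step(self, n_target: int) -> int:
        """Default step: ~n_target/3, clamped to [1, 7] (5-of-15 / 7-of-21 pattern)."""
        if self.step_size is not None:
            return self.step_size
        return max(1, min(7, round(n_target / 3)))


def eligible_replacements(
    codon: str, table: CodonOptimalityTable, constraints: DesignConstraints
) -> set[str]:
    """Synonymous codons satisfying the reduction and floor rules."""
    codon = normalize(codon)
    aa = CODON_FAMILY.get(codon)
    if aa is None:
        return set()
    ceiling = constraints.reduction_factor * table.percent[codon]
    return {
        c
        for c in DEGENERATE_FAMILIES[aa]
        if c != codon
        and table.percent[c] <= ceiling
        and table.percent[c] >= constraints.floor_percent
    }


@dataclass
class DesignVariant:
    sequence: str
    changed_positions: tuple[int, ...]  # codon indices, 0-based
    profile: FoldingProfile
    rmsd_to_wt: float
    r_to_wt: float
    mean_optimality: float

    @property
    def n_changed(self) -> int:
        return len(self.changed_positions)


def _mean_optimality(codons: list[str], table: CodonOptimalityTable) -> float:
    vals = [table.percent[c] for c in codons if c in CODON_FAMILY]
    return float(np.mean(vals)) if vals else float("nan")


def _split_codons(cds: str) -> list[str]:
    cds = normalize(cds)
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    return list(iter_codons(cds))


def _mutable_positions(codons: list[str], table, constraints) -> dict[int, set[str]]:
    """Codon index -> non-empty eligible replacement set (start codon excluded)."""
    out = {}
    for i, codon in enumerate(codons):
        if i == 0 or codon in STOP_CODONS:
            continue
        repl = eligible_replacements(codon, table, constraints)
        if repl:
            out[i] = repl
    return out


def design_variant(
    cds: str,
    n_target: int,
    table: CodonOptimalityTable,
    constraints: DesignConstraints | None = None,
    backend: FoldingBackend | None = None,
    seed: int = 0,
    prepend_rbs: bool = True,
) -> DesignVariant:
    """Profile-preserving de-optimization with exactly ``n_target`` changes.

    Raises ValueError when fewer than ``n_target`` codons have any eligible
    replacement (the message states the feasibility bound).
    """
    if constraints is None:
        constraints = DesignConstraints()
    if backend is None:
        backend = get_backend()
    codons = _split_codons(cds)
    eligible = _mutable_positions(codons, table, constraints)
    if n_target > len(eligible):
        raise ValueError(
            f"n_target {n_target} infeasible: only {len(eligible)} codons "
            "have an eligible suboptimal replacement"
        )
    wt_profile = folding_profile(cds, backend, prepend_rbs=prepend_rbs)
    rng = np.random.default_rng(seed)
    current = list(codons)
    changed: list[int] = []
    if n_target == 0:
        prof = folding_profile("".join(current), backend, prepend_rbs=prepend_rbs)
        return DesignVariant(
            "".join(current), (), prof, 0.0, profile_r(prof, wt_profile),
            _mean_optimality(current[1:], table),
        )
    step = constraints.resolved_step(n_target)
    while len(changed) < n_target:
        k = min(step, n_target - len(changed))
        available = sorted(set(eligible) - set(changed))
        best_rmsd, best_codons, best_positions = None, None, None
        for _ in range(constraints.n_samples):
            positions = rng.choice(available, size=k, replace=False)
            cand = list(current)
            for p in positions:
                choices = sorted(eligible[p])
                cand[p] = choices[rng.integers(len(choices))]
            prof = folding_profile("".join(cand), backend, prepend_rbs=prepend_rbs)
            rmsd = profile_rmsd(prof, wt_profile)
            if best_rmsd is None or rmsd < best_rmsd:
                best_rmsd, best_codons, best_positions = rmsd, cand, list(positions)
        current = best_codons
        changed.extend(int(p) for p in best_positions)
    seq = "".join(current)
    assert translate(seq) == translate(normalize(cds))
    prof = folding_profile(seq, backend, prepend_rbs=prepend_rbs)
    return DesignVariant(
        sequence=seq,
        changed_positions=tuple(sorted(changed)),
        profile=prof,
        rmsd_to_wt=profile_rmsd(prof, wt_profile),
        r_to_wt=profile_r(prof, wt_profile),
        mean_optimality=_mean_optimality(current[1:], table),
    )


def random_deoptimize(
    cds: str,
    n_changed: int,
    table: CodonOptimalityTable,
    constraints: DesignConstraints | None = None,
    backend: FoldingBackend | None = None,
    seed: int = 0,
    prepend_rbs: bool = True,
) -> DesignVariant:
    """Unconstrained comparator: same eligibility rules, no profile guidance.

    Picks ``n_changed`` random eligible codons and random eligible
    replacements in one shot, ignoring the folding profile entirely. Used
    to quantify how much the profile-guided search preserves mRNA
    structure.
    """
    if constraints is None:
        constraints = DesignConstraints()
    if backend is None:
        backend = get_backend()
    codons = _split_codons(cds)
    wt_profile = folding_profile(cds, backend, prepend_rbs=prepend_rbs)
    eligible = _mutable_positions(codons, table, constraints)
    if n_changed > len(eligible):
        raise ValueError(f"n_changed {n_changed} infeasible: {len(eligible)} eligible")
    rng = np.random.default_rng(seed)
    positions = rng.choice(sorted(eligible), size=n_changed, replace=False)
    for p in positions:
        choices = sorted(eligible[int(p)])
        codons[int(p)] = choices[rng.integers(len(choices))]
    seq = "".join(codons)
    prof = folding_profile(seq, backend, prepend_rbs=prepend_rbs)
    return DesignVariant(
        sequence=seq,
        changed_positions=tuple(sorted(int(p) for p in positions)),
        profile=prof,
        rmsd_to_wt=profile_rmsd(prof, wt_profile),
        r_to_wt=profile_r(prof, wt_profile),
        mean_optimality=_mean_optimality(codons[1:], table),
    )


def abolish_site(
    cds: str, motif: str, table: CodonOptimalityTable,
    constraints: DesignConstraints | None = None,
) -> str:
    """Remove a DNA motif by a single synonymous codon change.

    Prefers a replacement satisfying the de-optimization eligibility rules;
    falls back to any synonymous codon (logged) if none is eligible. Raises
    ValueError when no synonymous single-codon change can break the motif.
    """
    if constraints is None:
        constraints = DesignConstraints()
    cds = normalize(cds)
    motif = normalize(motif)
    if motif not in cds:
        return cds
    codons = _split_codons(cds)
    start = cds.index(motif)
    first_codon = start // 3
    last_codon = (start + len(motif) - 1) // 3
    fallbacks: list[str] = []
    for idx in range(first_codon, last_codon + 1):
        original = codons[idx]
        aa = CODON_FAMILY.get(original)
        if aa is None:
            continue
        preferred = sorted(eligible_replacements(original, table, constraints))
        others = sorted(set(DEGENERATE_FAMILIES[aa]) - {original} - set(preferred))
        for pool, eligible_pool in ((preferred, True), (others, False)):
            for repl in pool:
                trial = list(codons)
                trial[idx] = repl
                seq = "".join(trial)
                if motif not in seq:
                    if not eligible_pool:
                        fallbacks.append(seq)
                        continue
                    return seq
    if fallbacks:
        logger.warning("motif %s abolished with a non-eligible synonymous codon", motif)
        return fallbacks[0]
    raise ValueError(f"no synonymous single-codon change can abolish {motif}")
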