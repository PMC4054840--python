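"""Sliding-window mRNA folding free-energy profiles.

The design module assesses a candidate synonymous variant by the minimum
free energy (MFE) of every 42-nt window along the transcript, with a fixed
14-nt Shine-Dalgarno-containing ribosome binding site (AGGAGGUAAAACAU)
prepended before the AUG. Two interchangeable backends compute the window
MFE:

* ``ViennaBackend`` (default when the ViennaRNA Python bindings are
  importable): full Turner-parameter MFE via ``RNA.fold``.
* ``SimpleNNBackend``: a compact nearest-neighbor-flavoured dynamic program
  with per-pair energies (GC -3, AU -2, GU -1 kcal/mol), a hairpin-loop
  penalty, an interior/bulge penalty, a minimum hairpin loop of 3 nt, and
  no multibranch loops (a deliberate simplification that is adequate
  inside a 42-nt window). Its exact energy model is simple enough to be
  checked against exhaustive structure enumeration on short sequences.

Both backends are deterministic and return MFE <= 0 (the open chain has
energy zero). Window results are memoised, which matters in the design
search where candidate variants share most of their windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codons import dna_to_rna

WINDOW_LEN = 42
RBS = "AGGAGGUAAAACAU"  # 14 nt, prepended before the AUG

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
HAIRPIN_PENALTY = 3.5
INTERIOR_PENALTY = 1.5
MIN_HAIRPIN_LOOP = 3
MAX_INTERIOR = 3  # max unpaired nt per side of an interior loop / bulge


@dataclass
class FoldingProfile:
    """Ordered window MFE values along a transcript.

    ``coords`` give each window's start relative to the A of the start
    codon at +1 (no position 0; RBS positions are negative).
    """

    window_len: int
    dg: np.ndarray  # kcal/mol, one per window start
    coords: np.ndarray

    def __len__(self) -> int:
        return len(self.dg)


class FoldingBackend:
    """MFE of a single RNA window; subclasses implement ``_fold``."""

    def __init__(self) -> None:
        self._cache: dict[str, float] = {}

    def window_mfe(self, seq_rna: str) -> float:
        hit = self._cache.get(seq_rna)
        if hit is None:
            hit = self._cache[seq_rna] = self._fold(seq_rna)
        return hit

    def _fold(self, seq: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class ViennaBackend(FoldingBackend):
    """Turner-model MFE via the ViennaRNA ``RNA.fold`` bindings."""

    def __init__(self) -> None:
        super().__init__()
        import RNA  # deferred so the module imports without the bindings

        self._rna = RNA

    def _fold(self, seq: str) -> float:
        return float(self._rna.fold(seq)[1])


class SimpleNNBackend(FoldingBackend):
    """Simplified nearest-neighbor dynamic program (no multibranch loops).

    V(i, j): best energy of a structure closed by pair (i, j) =
        e(i, j) + min(hairpin penalty,
                      min over inner pair (k, l) with at most MAX_INTERIOR
                      unpaired nt on each side: V(k, l)
                          + 0 if exactly stacked else interior penalty)
    W(j): best energy of a prefix, allowing any number of exterior helices.
    Interior loops and bulges wider than MAX_INTERIOR per side are outside
    the model (the usual bounded-loop restriction of folding programs).
    """

    def _fold(self, seq: str) -> float:
        n = len(seq)
        NEG = float("inf")
        V = [[NEG] * n for _ in range(n)]
        for span in range(MIN_HAIRPIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                e = PAIR_ENERGY.get((seq[i], seq[j]))
                if e is None:
                    continue
                best = HAIRPIN_PENALTY
                for k in range(i + 1, min(i + 2 + MAX_INTERIOR, j - MIN_HAIRPIN_LOOP)):
                    for l in range(max(k + MIN_HAIRPIN_LOOP + 1, j - 1 - MAX_INTERIOR), j):
                        if V[k][l] == NEG:
                            continue
                        loop = 0.0 if (k == i + 1 and l == j - 1) else INTERIOR_PENALTY
                        best = min(best, V[k][l] + loop)
                V[i][j] = e + best
        W = [0.0] * (n + 1)
        for j in range(n):
            W[j + 1] = W[j]
            for i in range(0, j):
                if V[i][j] != NEG:
                    W[j + 1] = min(W[j + 1], W[i] + V[i][j])
        return min(0.0, W[n])


def get_backend(name: str | None = None) -> FoldingBackend:
    """Backend factory: 'vienna', 'simple', or None for the best available."""
    if name == "simple":
        return SimpleNNBackend()
    if name == "vienna":
        return ViennaBackend()
    if name is None:
        try:
            return ViennaBackend()
        except ImportError:
            return SimpleNNBackend()
    raise ValueError(f"unknown folding backend {name!r}")


def folding_profile(
    cds: str,
    backend: FoldingBackend | None = None,
    prepend_rbs: bool = True,
    window_len: int = WINDOW_LEN,
    rbs: str = RBS,
) -> FoldingProfile:
    """Window MFE profile of a CDS (RBS-prepended transcript by default).

    The transcript is the RBS followed by the CDS in RNA alphabet; windows
    of ``window_len`` nt advance one nucleotide at a time, giving
    len(transcript) - window_len + 1 values. Raises ValueError when the
    transcript is shorter than one window.
    """
    if backend is None:
        backend = get_backend()
    prefix = rbs if prepend_rbs else ""
    transcript = prefix + dna_to_rna(cds)
    if len(transcript) < window_len:
        raise ValueError(
            f"transcript length {len(transcript)} shorter than window {window_len}"
        )
    n_windows = len(transcript) - window_len + 1
    dg = np.empty(n_windows)
    coords = np.empty(n_windows, dtype=int)
    offset = len(prefix)
    for i in range(n_windows):
        dg[i] = backend.window_mfe(transcript[i : i + window_len])
        rel = i - offset
        coords[i] = rel + 1 if rel >= 0 else rel
    return FoldingProfile(window_len, dg, coords)


def profile_rmsd(p1: FoldingProfile, p2: FoldingProfile) -> float:
    """Root mean square deviation between two equal-length profiles (kcal/mol)."""
    if len(p1) != len(p2):
        raise ValueError("profile length mismatch")
    return float(np.sqrt(np.mean((p1.dg - p2.dg) ** 2)))


def profile_r(p1: FoldingProfile, p2: FoldingProfile) -> float:
    """Pearson correlation between two profiles; NaN when either is constant."""
    if len(p1) != len(p2):
        raise ValueError("profile length mismatch")
    if np.std(p1.dg) == 0 or np.std(p2.dg) == 0:
        return float("nan")
    return float(np.corrcoef(p1.dg, p2.dg)[0, 1])
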