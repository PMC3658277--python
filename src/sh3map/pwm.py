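"""Position weight matrices for SH3 binding specificity.

A PWM is built from a set of manually aligned phage-display peptides for one
SH3 domain (dual-specificity domains contribute one peptide group, and hence
one PWM, per specificity).  The probability matrix is stored together with an
odds matrix normalised so that a uniform column contributes a factor of 1: a
completely non-specific PWM therefore scores every peptide exactly 1, and
scores are directly comparable across PWMs of different lengths.

Construction pipeline (``build_pwm``):

1. raw residue counts per column; a gap contributes 1/20 of a count to every
   residue of its column (gaps are non-specific);
2. an entropy-proportional pseudocount ``kappa * H_j / ln 20`` is added to
   every residue of column *j*, where ``H_j`` is the Shannon entropy (nats)
   of the raw column frequencies — noisy, non-specific columns are smoothed
   toward uniform while sharp columns are left essentially untouched;
3. residues whose integer count is not significantly above the 1/20
   background (one-sided binomial test, p > alpha) have their frequencies
   replaced by their joint mean, preserving total column mass — this removes
   small fluctuations among non-specific residues;
4. columns are renormalised to probabilities and the odds matrix is
   ``20 * prob``;
5. low-specificity flanking columns (normalised entropy >= trim_threshold)
   are trimmed iteratively from both ends; interior columns are never
   removed and at least one column is always retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alphabet import AMINO_ACIDS, GAP, LN20, N_AA, encode, is_valid_peptide

__all__ = [
    "AlignedPeptideSet",
    "PWM",
    "MotifHit",
    "build_pwm",
    "score_peptide",
    "scan_protein",
    "rank_in_proteome",
    "find_binding_motifs",
]


@dataclass(frozen=True)
class AlignedPeptideSet:
    """Equal-length aligned peptides selected by phage display for one domain."""

    domain_id: str
    peptides: tuple[str, ...]
    group_label: str = ""

    def __post_init__(self) -> None:
        if len(self.peptides) < 1:
            raise ValueError(f"{self.domain_id}: peptide set is empty")
        length = len(self.peptides[0])
        if length < 1:
            raise ValueError(f"{self.domain_id}: zero-length peptides")
        for pep in self.peptides:
            if len(pep) != length:
                raise ValueError(
                    f"{self.domain_id}: peptides have unequal lengths "
                    f"({len(pep)} vs {length})"
                )
            if not is_valid_peptide(pep):
                raise ValueError(f"{self.domain_id}: invalid residue in {pep!r}")
        object.__setattr__(self, "peptides", tuple(self.peptides))

    @property
    def length(self) -> int:
        return len(self.peptides[0])

    @property
    def key(self) -> str:
        return f"{self.domain_id}#{self.group_label}" if self.group_label else self.domain_id


@dataclass(frozen=True)
class PWM:
    """Per-position amino-acid probability model of one SH3 specificity.

    ``prob`` and ``odds`` are 20 x m arrays in alphabetical residue order;
    ``odds = 20 * prob`` so a uniform column has odds 1 everywhere.
    """

    domain_id: str
    prob: np.ndarray
    group_label: str = ""
    trim_record: tuple[int, int] = (0, 0)
    provenance: str = ""

    def __post_init__(self) -> None:
        prob = np.asarray(self.prob, dtype=float)
        if prob.ndim != 2 or prob.shape[0] != N_AA or prob.shape[1] < 1:
            raise ValueError("prob must be a 20 x m matrix with m >= 1")
        colsums = prob.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("each probability column must sum to 1")
        object.__setattr__(self, "prob", prob)

    @property
    def m(self) -> int:
        return self.prob.shape[1]

    @property
    def odds(self) -> np.ndarray:
        return N_AA * self.prob

    @property
    def key(self) -> str:
        return f"{self.domain_id}#{self.group_label}" if self.group_label else self.domain_id

    @property
    def consensus(self) -> str:
        """Highest-probability residue per column (smallest alphabetical on ties)."""
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.prob, axis=0))

    def column_entropy(self, normalized: bool = True) -> np.ndarray:
        h = np.array([_entropy(col) for col in self.prob.T])
        return h / LN20 if normalized else h

    @classmethod
    def uniform(cls, m: int, domain_id: str = "uniform") -> "PWM":
        return cls(domain_id=domain_id, prob=np.full((N_AA, m), 1.0 / N_AA))


@dataclass(frozen=True, order=True)
class MotifHit:
    """A scored candidate binding site: one PWM-width window on a protein.

    Coordinates are 1-based and inclusive (``start`` .. ``start + length - 1``).
    """

    protein_id: str = field(compare=False)
    start: int
    length: int = field(compare=False)
    peptide: str = field(compare=False)
    score: float = field(compare=False)
    genome_rank: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start is 1-based and must be >= 1")
        if self.score < 0:
            raise ValueError("score must be nonnegative")

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def _entropy(freqs: np.ndarray) -> float:
    """Shannon entropy in nats of a frequency vector (normalised internally)."""
    f = np.asarray(freqs, dtype=float)
    total = f.sum()
    if total <= 0:
        return LN20
    p = f / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def build_pwm(
    peps: AlignedPeptideSet,
    alpha: float = 0.05,
    kappa: float = 1.0,
    trim_threshold: float = 0.76,
    provenance: str = "",
) -> PWM:
    """Build a PWM from aligned phage peptides.

    Parameters
    ----------
    peps
        Aligned, equal-length peptides (gap character ``-`` allowed).
    alpha
        Significance level for the per-residue binomial test against the
        1/20 background; residues not significant at this level are averaged
        with each other within their column.
    kappa
        Scale of the entropy-proportional pseudocount; 0 disables smoothing.
    trim_threshold
        Normalised-entropy cutoff on [0, 1]; flanking columns at or above it
        are removed.
    """
    n_pep = len(peps.peptides)
    length = peps.length

    counts = np.zeros((N_AA, length))
    int_counts = np.zeros((N_AA, length), dtype=np.int64)
    for pep in peps.peptides:
        for j, ch in enumerate(pep):
            if ch == GAP:
                counts[:, j] += 1.0 / N_AA
            else:
                i = AMINO_ACIDS.index(ch)
                counts[i, j] += 1.0
                int_counts[i, j] += 1

    # entropy of the raw column frequencies drives the pseudocount
    raw_entropy = np.array([_entropy(counts[:, j]) for j in range(length)])
    beta = kappa * raw_entropy / LN20

    smoothed = counts + beta[np.newaxis, :]

    # one-sided binomial test of the integer count (gap-derived fractional
    # counts are excluded, i.e. rounded down) against background 1/20
    pvals = stats.binom.sf(int_counts - 1, n_pep, 1.0 / N_AA)
    nonsig = pvals > alpha
    for j in range(length):
        mask = nonsig[:, j]
        if mask.any():
            smoothed[mask, j] = smoothed[mask, j].mean()

    prob = smoothed / smoothed.sum(axis=0, keepdims=True)

    # iterative flank trimming on the final normalised column entropies
    norm_entropy = np.array([_entropy(prob[:, j]) for j in range(length)]) / LN20
    left, right = 0, length - 1
    if np.all(norm_entropy >= trim_threshold):
        keep = int(np.argmin(norm_entropy))  # smallest index wins ties
        warnings.warn(
            f"{peps.key}: all columns above entropy threshold; "
            f"retaining single minimum-entropy column {keep}",
            stacklevel=2,
        )
        left = right = keep
    else:
        while left < right and norm_entropy[left] >= trim_threshold:
            left += 1
        while right > left and norm_entropy[right] >= trim_threshold:
            right -= 1

    return PWM(
        domain_id=peps.domain_id,
        group_label=peps.group_label,
        prob=prob[:, left : right + 1],
        trim_record=(left, length - 1 - right),
        provenance=provenance,
    )


def score_peptide(pwm: PWM, peptide: str) -> float:
    """Normalised PWM score of a peptide of exactly the PWM's width.

    The score is the product over columns of the odds ``20 * p_ij``, i.e. the
    raw probability product normalised by 20^-m.  Residues outside the
    20-letter alphabet (X, *, ...) contribute a neutral factor of 1.
    """
    if len(peptide) != pwm.m:
        raise ValueError(f"peptide length {len(peptide)} != PWM width {pwm.m}")
    codes = encode(peptide)
    odds_ext = np.vstack([pwm.odds, np.ones((1, pwm.m))])
    return float(np.prod(odds_ext[codes, np.arange(pwm.m)]))


def _window_scores(pwm: PWM, protein: str) -> np.ndarray:
    """Scores of all full windows of width m along the protein (empty if short)."""
    m = pwm.m
    if len(protein) < m:
        return np.empty(0)
    codes = encode(protein)
    odds_ext = np.vstack([pwm.odds, np.ones((1, m))])
    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    return odds_ext[windows, np.arange(m)].prod(axis=1)


def scan_protein(pwm: PWM, protein: str, protein_id: str = "") -> tuple[MotifHit, list[MotifHit]]:
    """Score every window of the protein; return the best hit and all windows.

    Ties for the best score are broken by the smallest start.  A protein
    shorter than the PWM yields a degenerate best hit with score 0 and an
    empty window list.
    """
    scores = _window_scores(pwm, protein)
    if scores.size == 0:
        best = MotifHit(protein_id=protein_id, start=1, length=pwm.m,
                        peptide="", score=0.0)
        return best, []
    hits = [
        MotifHit(protein_id=protein_id, start=j + 1, length=pwm.m,
                 peptide=protein[j : j + pwm.m], score=float(s))
        for j, s in enumerate(scores)
    ]
    best_idx = int(np.argmax(scores))  # argmax returns the first maximum
    return hits[best_idx], hits


def best_score(pwm: PWM, protein: str) -> float:
    """Best window score along a protein (0 for proteins shorter than m)."""
    scores = _window_scores(pwm, protein)
    return float(scores.max()) if scores.size else 0.0


def rank_in_proteome(pwm: PWM, proteome: dict[str, str]) -> "pd.DataFrame":
    """Rank every proteome protein by its best window score under the PWM.

    Rank 1 is the highest score; tied scores all receive the minimum rank of
    the tied block.  Returns a DataFrame with columns
    ``protein_id, score, rank`` sorted by rank then protein_id.
    """
    import pandas as pd

    if not proteome:
        raise ValueError("proteome is empty")
    ids = list(proteome)
    scores = np.array([best_score(pwm, proteome[p]) for p in ids])
    ranks = pd.Series(scores).rank(method="min", ascending=False).astype(int)
    table = pd.DataFrame({"protein_id": ids, "score": scores, "rank": ranks.values})
    return table.sort_values(["rank", "protein_id"], kind="stable").reset_index(drop=True)


def find_binding_motifs(pwm: PWM, protein: str, T: float = 1000.0,
                        protein_id: str = "") -> list[MotifHit]:
    """All windows scoring at least *T*, sorted by start position.

    Windows at or above the threshold count as bona fide binding motifs; a
    protein may carry several for the same domain.
    """
    scores = _window_scores(pwm, protein)
    return [
        MotifHit(protein_id=protein_id, start=j + 1, length=pwm.m,
                 peptide=protein[j : j + pwm.m], score=float(s))
        for j, s in enumerate(scores)
        if s >= T
    ]
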