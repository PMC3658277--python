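"""PWM-to-PWM similarity and the SH3 specificity tree.

Two PWMs are compared by sliding one over the other without gaps.  For each
offset the two matrices span a union alignment; wherever a PWM has no column
the uniform distribution (1/20 per residue) is substituted, reflecting that
flanking positions of a phage-derived PWM are non-specific.  The aligned
distance is the root-mean-square Euclidean distance per union column,
minimised over offsets.  Because even non-specific columns show some
similarity, the completely unaligned distance (no overlapping columns) is
used as a baseline and the similarity is

    sim(a, b) = (d_unaligned - d_aligned) / d_unaligned

clamped to [0, 1].  The specificity tree is average-linkage agglomerative
clustering on the dissimilarity 1 - sim, with deterministic lexicographic
tie-breaking, exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import N_AA
from .pwm import PWM

__all__ = [
    "SimilarityMatrix",
    "pwm_pair_distance",
    "pwm_similarity",
    "build_specificity_tree",
]

_UNIFORM = np.full(N_AA, 1.0 / N_AA)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric PWM similarity matrix with the best alignment offset per pair."""

    ids: tuple[str, ...]
    sim: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        sim = np.asarray(self.sim, dtype=float)
        n = len(self.ids)
        if sim.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")
        if not np.allclose(sim, sim.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(sim), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if sim.min() < -1e-12 or sim.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")
        object.__setattr__(self, "sim", np.clip(sim, 0.0, 1.0))
        object.__setattr__(self, "ids", tuple(self.ids))

    @classmethod
    def from_pwms(cls, pwms: list[PWM], min_overlap: int = 1) -> "SimilarityMatrix":
        ids = tuple(p.key for p in pwms)
        n = len(pwms)
        sim = np.eye(n)
        offsets = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                s = pwm_similarity(pwms[i], pwms[j], min_overlap=min_overlap)
                _, _, off = pwm_pair_distance(pwms[i], pwms[j], min_overlap=min_overlap)
                sim[i, j] = sim[j, i] = s
                offsets[i, j] = off
                offsets[j, i] = -off
        return cls(ids=ids, sim=sim, offsets=offsets)


def _offset_distance(pa: np.ndarray, pb: np.ndarray, k: int,
                     norm_inside_sqrt: bool = True) -> float:
    """Distance of PWMs a, b at offset k (b shifted right by k columns vs a)."""
    ma, mb = pa.shape[1], pb.shape[1]
    start = min(0, k)
    end = max(ma, k + mb)
    n = end - start
    ss = 0.0
    for c in range(start, end):
        va = pa[:, c] if 0 <= c < ma else _UNIFORM
        vb = pb[:, c - k] if 0 <= c - k < mb else _UNIFORM
        diff = va - vb
        ss += float(diff @ diff)
    if norm_inside_sqrt:
        return float(np.sqrt(ss / n))
    return float(np.sqrt(ss) / n)


def pwm_pair_distance(a: PWM, b: PWM, min_overlap: int = 1,
                      norm_inside_sqrt: bool = True) -> tuple[float, float, int]:
    """Aligned and unaligned distances between two PWMs.

    Returns ``(d_aligned, d_unaligned, best_offset)``.  The aligned distance
    is minimised over all ungapped offsets with at least ``min_overlap``
    overlapping columns (ties broken by the smallest offset); the unaligned
    distance uses zero overlap, comparing every informative column to the
    uniform distribution over ``m_a + m_b`` union columns.
    """
    pa, pb = a.prob, b.prob
    ma, mb = pa.shape[1], pb.shape[1]
    if not 1 <= min_overlap <= min(ma, mb):
        raise ValueError("min_overlap must be in [1, min(m_a, m_b)]")

    # zero-overlap baseline: each matrix faces uniform columns only
    ss_un = float(((pa - _UNIFORM[:, None]) ** 2).sum()
                  + ((pb - _UNIFORM[:, None]) ** 2).sum())
    n_un = ma + mb
    d_un = (np.sqrt(ss_un / n_un) if norm_inside_sqrt else np.sqrt(ss_un) / n_un)

    d_al = np.inf
    best_offset = 0
    for k in range(min_overlap - mb, ma - min_overlap + 1):
        d = _offset_distance(pa, pb, k, norm_inside_sqrt)
        if d < d_al - 1e-15:
            d_al, best_offset = d, k
    return float(d_al), float(d_un), best_offset


def pwm_similarity(a: PWM, b: PWM, min_overlap: int = 1) -> float:
    """Similarity (d_un - d_al)/d_un clamped to [0, 1]; 1 if both uniform."""
    d_al, d_un, _ = pwm_pair_distance(a, b, min_overlap=min_overlap)
    if d_un == 0.0:
        return 1.0
    return float(np.clip((d_un - d_al) / d_un, 0.0, 1.0))


def build_specificity_tree(matrix: SimilarityMatrix) -> str:
    """Average-linkage tree on 1 - similarity, returned as a Newick string.

    Deterministic: at every step the pair with the smallest average distance
    merges; exact ties are broken by the lexicographically smallest (and then
    second-smallest) member id, so permuting the input order leaves the
    Newick string unchanged.  Branch lengths are the difference between a
    cluster's merge height and its child's merge height (leaves sit at 0).
    """
    ids = matrix.ids
    n = len(ids)
    if n < 2:
        raise ValueError("at least two PWMs are required to build a tree")

    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((ids[i], ids[j]))] = 1.0 - matrix.sim[i, j]

    # cluster id -> (sorted members tuple, newick, height)
    clusters: dict[str, tuple[tuple[str, ...], str, float]] = {
        name: ((name,), name, 0.0) for name in ids
    }

    def avg_dist(ca: str, cb: str) -> float:
        members_a, members_b = clusters[ca][0], clusters[cb][0]
        total = sum(dist[frozenset((x, y))] for x in members_a for y in members_b)
        return total / (len(members_a) * len(members_b))

    while len(clusters) > 1:
        names = sorted(clusters)
        best = None
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                d = avg_dist(names[i], names[j])
                key = (d, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, names[i], names[j])
        (height, *_), ca, cb = best
        first, second = sorted((ca, cb), key=lambda c: clusters[c][0][0])
        mem_f, nwk_f, h_f = clusters[first]
        mem_s, nwk_s, h_s = clusters[second]
        newick = f"({nwk_f}:{height - h_f:.6g},{nwk_s}:{height - h_s:.6g})"
        merged_members = tuple(sorted(mem_f + mem_s))
        new_name = merged_members[0]
        del clusters[ca], clusters[cb]
        clusters[new_name] = (merged_members, newick, height)

    (_, newick, _), = clusters.values()
    return newick + ";"
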