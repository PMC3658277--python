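"""Assembly of the high-confidence SH3 interactome from raw Y2H candidates.

A candidate bait-prey pair survives filtering when it is supported by at
least one independent line of evidence beyond a single yeast colony:

* ``multi_colony`` — observed in two or more independent positive colonies;
* ``literature``   — a single colony, but the pair occurs in a published
  interactome, the interolog set, a functional network, or is otherwise
  known to be functionally related;
* ``motif``        — a single colony, but the prey carries a clear sequence
  match (normalised PWM score >= T) to the bait domain's phage-derived
  specificity; only SH3-domain baits are eligible.

Afterwards, sticky activation-domain transcription-factor preys — TFs
connected to more than ``tf_degree_max`` distinct baits in the kept network —
are removed wholesale, since such promiscuity is a known Y2H artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Y2HCandidate",
    "EvidenceAnnotation",
    "Edge",
    "SH3Network",
    "FilterReport",
    "filter_candidates",
    "phage_overlap_enrichment",
]

logger = logging.getLogger(__name__)

EVIDENCE_CLASSES = ("multi_colony", "literature", "motif")

SH3_BAIT_TYPE = "sh3_domain"


@dataclass(frozen=True)
class Y2HCandidate:
    """One raw screen observation of a bait-prey pair."""

    bait_id: str
    prey_id: str
    colony_count: int
    library: str = "ORFeome"
    bait_type: str = SH3_BAIT_TYPE  # sh3_domain | full_length | fragment

    def __post_init__(self) -> None:
        if self.colony_count < 1:
            raise ValueError("colony_count must be >= 1")


@dataclass(frozen=True)
class EvidenceAnnotation:
    """Supporting evidence for one bait-prey pair."""

    in_WI8: bool = False
    in_interolog_set: bool = False
    in_WormNet: bool = False
    literature_functional: bool = False
    pwm_score: float | None = None
    best_peptide: str | None = None
    start: int | None = None
    rank: int | None = None
    prey_is_TF: bool = False

    @property
    def any_literature(self) -> bool:
        return (self.in_WI8 or self.in_interolog_set or self.in_WormNet
                or self.literature_functional)


@dataclass(frozen=True)
class Edge:
    bait_id: str
    prey_id: str
    evidence_class: str
    colony_count: int
    bait_type: str = SH3_BAIT_TYPE
    pwm_score: float | None = None
    best_peptide: str | None = None
    start: int | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise ValueError(f"unknown evidence class {self.evidence_class!r}")


class SH3Network:
    """Filtered interactome: unique (bait, prey) edges with evidence classes."""

    def __init__(self, edges: list[Edge]):
        seen: set[tuple[str, str]] = set()
        for e in edges:
            key = (e.bait_id, e.prey_id)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
        self.edges: tuple[Edge, ...] = tuple(edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    @property
    def baits(self) -> set[str]:
        return {e.bait_id for e in self.edges}

    @property
    def preys(self) -> set[str]:
        return {e.prey_id for e in self.edges}

    def by_bait(self, bait_id: str) -> list[Edge]:
        return [e for e in self.edges if e.bait_id == bait_id]

    def by_prey(self, prey_id: str) -> list[Edge]:
        return [e for e in self.edges if e.prey_id == prey_id]

    def prey_degree(self, prey_id: str) -> int:
        """Number of distinct baits connected to the prey."""
        return len({e.bait_id for e in self.edges if e.prey_id == prey_id})

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in EVIDENCE_CLASSES}
        for e in self.edges:
            counts[e.evidence_class] += 1
        return counts


@dataclass
class FilterReport:
    network: SH3Network
    counts_before_tf_removal: dict[str, int] = field(default_factory=dict)
    counts_after_tf_removal: dict[str, int] = field(default_factory=dict)
    n_candidates: int = 0
    n_dropped_unsupported: int = 0
    tf_preys_removed: tuple[str, ...] = ()


def _deduplicate(cands: list[Y2HCandidate]) -> dict[tuple[str, str], Y2HCandidate]:
    """Merge repeat observations of the same pair, summing colony counts."""
    merged: dict[tuple[str, str], Y2HCandidate] = {}
    for c in cands:
        key = (c.bait_id, c.prey_id)
        if key in merged:
            prev = merged[key]
            merged[key] = Y2HCandidate(
                bait_id=c.bait_id, prey_id=c.prey_id,
                colony_count=prev.colony_count + c.colony_count,
                library=prev.library, bait_type=prev.bait_type,
            )
        else:
            merged[key] = c
    return merged


def filter_candidates(
    cands: list[Y2HCandidate],
    ev: dict[tuple[str, str], EvidenceAnnotation],
    T: float = 1000.0,
    tf_degree_max: int = 5,
) -> FilterReport:
    """Filter raw Y2H candidates into the high-confidence network.

    ``ev`` maps (bait_id, prey_id) to supporting evidence; pairs without an
    entry are treated as having none.  Unsupported single-colony pairs are
    dropped silently (logged at DEBUG).
    """
    merged = _deduplicate(cands)
    kept: list[Edge] = []
    n_dropped = 0
    for (bait, prey), cand in sorted(merged.items()):
        e = ev.get((bait, prey), EvidenceAnnotation())
        pwm_fields = dict(pwm_score=e.pwm_score, best_peptide=e.best_peptide,
                          start=e.start, rank=e.rank)
        if cand.colony_count >= 2:
            cls = "multi_colony"
        elif e.any_literature:
            cls = "literature"
        elif (cand.bait_type == SH3_BAIT_TYPE and e.pwm_score is not None
              and e.pwm_score >= T):
            cls = "motif"
        else:
            n_dropped += 1
            logger.debug("dropped unsupported single-colony pair %s-%s", bait, prey)
            continue
        kept.append(Edge(bait_id=bait, prey_id=prey, evidence_class=cls,
                         colony_count=cand.colony_count, bait_type=cand.bait_type,
                         **pwm_fields))

    before = SH3Network(kept)
    counts_before = before.class_counts()

    # sticky-TF removal on the kept network
    tf_preys = {e.prey_id for e in kept
                if ev.get((e.bait_id, e.prey_id), EvidenceAnnotation()).prey_is_TF}
    removed_tfs = tuple(sorted(
        p for p in tf_preys if before.prey_degree(p) > tf_degree_max
    ))
    final_edges = [e for e in kept if e.prey_id not in removed_tfs]
    network = SH3Network(final_edges)

    return FilterReport(
        network=network,
        counts_before_tf_removal=counts_before,
        counts_after_tf_removal=network.class_counts(),
        n_candidates=len(merged),
        n_dropped_unsupported=n_dropped,
        tf_preys_removed=removed_tfs,
    )


def phage_overlap_enrichment(
    net: SH3Network,
    ranks: dict[str, dict[str, int]],
    proteome_size: int,
    n_random: int = 100_000,
    seed: int | None = None,
) -> tuple[np.ndarray, float, float]:
    """Enrichment of network preys among top PWM-ranked proteome proteins.

    ``ranks`` maps bait (SH3 domain) id to a {protein_id: genome rank} table.
    Edges whose bait has no rank table are ignored; edges of evidence class
    ``motif`` are excluded so that motif-rescued interactions do not bias the
    statistic.  Returns ``(curve, auc, p_value)`` where ``curve[x-1]`` is the
    fraction of eligible edges with prey rank <= x, ``auc`` is the mean of
    the curve (0.5 under uniform ranks), and the p-value comes from
    re-assigning uniform random ranks to each edge (add-one estimator).
    """
    edge_ranks = []
    for e in net:
        if e.evidence_class == "motif":
            continue
        table = ranks.get(e.bait_id)
        if table is None or e.prey_id not in table:
            continue
        edge_ranks.append(table[e.prey_id])
    if not edge_ranks:
        raise ValueError("no eligible edges: no bait has phage-derived ranks")

    r = np.asarray(edge_ranks, dtype=np.int64)
    if r.min() < 1 or r.max() > proteome_size:
        raise ValueError("ranks must lie in [1, proteome_size]")

    xs = np.arange(1, proteome_size + 1)
    curve = np.searchsorted(np.sort(r), xs, side="right") / r.size

    def auc_of(rank_vec: np.ndarray) -> np.ndarray:
        # mean over x of F(x) = mean over edges of (P - rank + 1)/P
        return 1.0 - (rank_vec - 1).mean(axis=-1) / proteome_size

    auc = float(auc_of(r))
    rng = np.random.default_rng(seed)
    null_ranks = rng.integers(1, proteome_size + 1, size=(n_random, r.size))
    null_auc = auc_of(null_ranks)
    p = (1.0 + np.count_nonzero(null_auc >= auc)) / (1.0 + n_random)
    return curve, auc, float(p)
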