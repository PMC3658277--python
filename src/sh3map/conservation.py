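"""Cross-species interaction conservation and rewiring classification.

The network of one species is projected into another through an ortholog
map (many-to-many allowed), the overlap with a reference interactome is
tested against a hypergeometric null over a corrected universe of possible
bait-prey pairs, and each non-conserved SH3-mediated interaction is
classified at binding-site resolution into one of three rewiring scenarios:

    (i)   the ligand motif is conserved but the SH3 specificity is not;
    (ii)  the specificity is conserved but the binding motif is not;
    (iii) neither is conserved.

Interactions whose source domain lacks a specificity profile, or whose
target carries no confident motif (PWM score >= T), cannot be mapped at this
resolution and are called ``unmappable``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy import stats

from .pwm import PWM, find_binding_motifs
from .tree import pwm_similarity

__all__ = [
    "OrthologMap",
    "ConservationResult",
    "RewiringCall",
    "universe_size",
    "project_by_orthology",
    "conservation_test",
    "best_motif_match",
    "ungapped_identity",
    "classify_rewiring",
]

logger = logging.getLogger(__name__)

SCENARIOS = ("i", "ii", "iii", "conserved_both", "unmappable")


class OrthologMap:
    """Many-to-many gene correspondence between species A and species B."""

    def __init__(self, pairs: set[tuple[str, str]] | list[tuple[str, str]]):
        self.pairs: frozenset[tuple[str, str]] = frozenset(pairs)
        self._a_to_b: dict[str, set[str]] = {}
        self._b_to_a: dict[str, set[str]] = {}
        for a, b in self.pairs:
            self._a_to_b.setdefault(a, set()).add(b)
            self._b_to_a.setdefault(b, set()).add(a)

    def orthologs_of(self, gene_a: str) -> set[str]:
        return set(self._a_to_b.get(gene_a, set()))

    def back_orthologs_of(self, gene_b: str) -> set[str]:
        return set(self._b_to_a.get(gene_b, set()))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ConservationResult:
    n_baits_conserved: int
    n_preys_conserved: int
    n_bp: int
    universe: int
    n_A_interactions: int
    n_B_interactions: int
    n_overlap: int
    p_value: float

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_A_interactions, self.n_B_interactions):
            raise ValueError("overlap exceeds one of the interaction counts")
        if self.universe < max(self.n_A_interactions, self.n_B_interactions):
            raise ValueError("universe smaller than an interaction count")


@dataclass(frozen=True)
class RewiringCall:
    domain_id: str
    target_id: str
    source_species: str
    scenario: str
    specificity_conserved: bool | None = None
    motif_conserved: bool | None = None
    best_motif: str | None = None
    best_match: str | None = None
    identity: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


def universe_size(n_baits: int, n_preys: int, n_bp: int) -> int:
    """Corrected count of possible bait-prey interactions.

    ``n_baits * n_preys`` overcounts pairs of proteins that act both as bait
    and as prey (each such unordered pair appears in both orientations), so
    ``n_bp * (n_bp - 1) / 2`` is subtracted, where ``n_bp`` is the number of
    conserved baits that also act as preys.
    """
    if min(n_baits, n_preys, n_bp) < 0:
        raise ValueError("counts must be nonnegative")
    if n_bp > min(n_baits, n_preys):
        raise ValueError("n_bp cannot exceed min(n_baits, n_preys)")
    return n_baits * n_preys - n_bp * (n_bp - 1) // 2


def project_by_orthology(
    net,
    omap: OrthologMap,
    sh3_only: bool = True,
) -> tuple[set[frozenset[str]], set[str], set[str], int]:
    """Project a network into the other species through the ortholog map.

    An edge projects iff both endpoints have at least one ortholog; every
    ortholog combination is emitted (undirected, as frozenset endpoint pairs,
    deduplicated).  Returns ``(projected_edges, conserved_baits,
    conserved_preys, n_bp)`` where the conserved sets are the species-B
    orthologs of network baits/preys and ``n_bp`` counts species-B proteins
    occurring on both sides.
    """
    projected: set[frozenset[str]] = set()
    conserved_baits: set[str] = set()
    conserved_preys: set[str] = set()
    for e in net:
        if sh3_only and getattr(e, "bait_type", "sh3_domain") != "sh3_domain":
            continue
        bait_protein = getattr(e, "bait_protein", None) or e.bait_id
        bo = omap.orthologs_of(bait_protein)
        po = omap.orthologs_of(e.prey_id)
        conserved_baits |= bo
        conserved_preys |= po
        if bo and po:
            for b in bo:
                for p in po:
                    if b != p:
                        projected.add(frozenset((b, p)))
    n_bp = len(conserved_baits & conserved_preys)
    return projected, conserved_baits, conserved_preys, n_bp


def conservation_test(
    projected: set[frozenset[str]],
    reference: set[frozenset[str]],
    universe: int,
    counts: tuple[int, int, int] = (0, 0, 0),
) -> ConservationResult:
    """One-sided hypergeometric test of overlap between two interaction sets.

    ``projected`` are this study's interactions mapped into the other
    species; ``reference`` is the published interactome there, already
    restricted to the conserved-protein universe.  The p-value is the upper
    tail P(X >= overlap) drawing |projected| pairs from a population of
    ``universe`` possible pairs of which |reference| are reference positives.
    """
    n_a = len(projected)
    n_b = len(reference)
    overlap = len(projected & reference)
    if universe < max(n_a, n_b):
        raise ValueError("universe smaller than an interaction count")
    p = float(stats.hypergeom.sf(overlap - 1, universe, n_b, n_a))
    n_baits, n_preys, n_bp = counts
    return ConservationResult(
        n_baits_conserved=n_baits, n_preys_conserved=n_preys, n_bp=n_bp,
        universe=universe, n_A_interactions=n_a, n_B_interactions=n_b,
        n_overlap=overlap, p_value=p,
    )


def ungapped_identity(query: str, subject: str) -> tuple[float, int]:
    """Best ungapped alignment identity of ``query`` within ``subject``.

    The query slides along the subject; identity is the fraction of query
    positions matching the subject at the best offset (ties: smallest
    start).  When the subject is shorter than the query, overhanging offsets
    are allowed and overhang positions count as mismatches.  Returns
    ``(identity, start)`` with a 1-based start (may be < 1 for overhang on
    the left).
    """
    m = len(query)
    if m < 1:
        raise ValueError("query must be non-empty")
    n = len(subject)
    if n >= m:
        offsets = range(0, n - m + 1)
    else:
        offsets = range(-(m - 1), n)
    best_ident, best_start = -1.0, 1
    for k in offsets:
        matches = sum(
            1
            for i in range(m)
            if 0 <= k + i < n and query[i] == subject[k + i]
        )
        ident = matches / m
        if ident > best_ident + 1e-12:
            best_ident, best_start = ident, k + 1
    return best_ident, best_start


def best_motif_match(motif: str, ortholog_seq: str) -> tuple[float, int]:
    """Most similar ungapped match of a binding motif in an ortholog sequence."""
    return ungapped_identity(motif, ortholog_seq)


def classify_rewiring(
    domain_id: str,
    target_id: str,
    *,
    domain_pwm: PWM | None,
    ortholog_domain_pwm: PWM | None,
    domain_seq: str | None = None,
    ortholog_domain_seq: str | None = None,
    ortholog_has_sh3: bool = True,
    target_seq: str | None = None,
    ortholog_target_seqs: list[str] | None = None,
    source_species: str = "A",
    sim_threshold: float = 0.5,
    id_threshold: float = 0.5,
    T: float = 1000.0,
    context: int = 15,
) -> RewiringCall:
    """Classify one non-conserved SH3 interaction into a rewiring scenario.

    Specificity conservation is judged by PWM similarity when both domains
    have specificity profiles, falling back to ungapped domain sequence
    identity otherwise; a missing SH3 domain in the ortholog means the
    specificity is not conserved.  Motif conservation holds when any
    confident binding motif on the target (score >= T under the source
    domain's PWM) has an ungapped match of identity >= ``id_threshold`` in an
    ortholog of the target.  Identity is measured over a stretch of
    ``context`` residues centred on the motif (clipped at the protein ends),
    so that a 50% cutoff on a short high-scoring window is backed by its
    sequence neighbourhood rather than a handful of residues.
    """

    def call(scenario: str, **kw) -> RewiringCall:
        return RewiringCall(domain_id=domain_id, target_id=target_id,
                            source_species=source_species, scenario=scenario, **kw)

    if domain_pwm is None:
        return call("unmappable", note="no specificity profile for source domain")
    if target_seq is None:
        logger.debug("%s-%s: missing target sequence", domain_id, target_id)
        return call("unmappable", note="missing target sequence")

    motifs = find_binding_motifs(domain_pwm, target_seq, T=T, protein_id=target_id)
    if not motifs:
        return call("unmappable", note="no confident binding motif on target")

    if not ortholog_target_seqs:
        logger.debug("%s-%s: missing ortholog target sequence", domain_id, target_id)
        return call("unmappable", note="missing ortholog target sequence")

    # motif conservation: most conserved motif across all ortholog sequences
    best = (-1.0, None, None)  # identity, motif stretch, matched region
    for hit in motifs:
        s0 = hit.start - 1
        width = max(hit.length, context)
        ext_start = max(0, s0 - (width - hit.length) // 2)
        ext_end = min(len(target_seq), ext_start + width)
        ext_start = max(0, ext_end - width)
        stretch = target_seq[ext_start:ext_end]
        for seq in ortholog_target_seqs:
            ident, start = best_motif_match(stretch, seq)
            if ident > best[0]:
                k = start - 1
                match = seq[max(0, k) : max(0, k) + len(stretch)]
                best = (ident, stretch, match)
    identity, best_motif, match_region = best
    motif_conserved = identity >= id_threshold

    # specificity conservation
    if not ortholog_has_sh3:
        specificity_conserved = False
    elif ortholog_domain_pwm is not None:
        specificity_conserved = (
            pwm_similarity(domain_pwm, ortholog_domain_pwm) >= sim_threshold
        )
    elif domain_seq and ortholog_domain_seq:
        shorter, longer = sorted((domain_seq, ortholog_domain_seq), key=len)
        ident, _ = ungapped_identity(shorter, longer)
        specificity_conserved = ident >= id_threshold
    else:
        logger.debug("%s-%s: no basis to assess specificity; calling not conserved",
                     domain_id, target_id)
        specificity_conserved = False

    if specificity_conserved and motif_conserved:
        scenario = "conserved_both"
    elif motif_conserved:
        scenario = "i"
    elif specificity_conserved:
        scenario = "ii"
    else:
        scenario = "iii"
    return call(
        scenario,
        specificity_conserved=specificity_conserved,
        motif_conserved=motif_conserved,
        best_motif=best_motif,
        best_match=match_region,
        identity=identity,
    )
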