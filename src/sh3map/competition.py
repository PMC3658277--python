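"""Binding-site clustering and motif-competition statistics.

Predicted binding motifs on one protein frequently overlap (a proline-rich
stretch yields several high-scoring windows), so neighbouring sites within
``min_sep`` residues are collapsed into one.  The collapsed counts feed the
competition analysis: the number of clustered motifs on a target versus the
number of distinct SH3-containing proteins binding it, and — on the bait
side — the number of SH3 domains in a protein versus its interaction degree,
both tested with Spearman rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .pwm import MotifHit, find_binding_motifs

__all__ = [
    "cluster_motif_sites",
    "MotifClusterTable",
    "build_cluster_table",
    "competitive_pairs",
    "spearman_association",
]


def cluster_motif_sites(hits: list[MotifHit], min_sep: int = 10) -> list[MotifHit]:
    """Collapse neighbouring motif sites to enforce a minimal separation.

    Greedy left-to-right over hits sorted by start: a site is accepted iff
    its start is at least ``min_sep`` residues after the start of the
    previously accepted site; a run of sites violating the separation forms
    one cluster, represented by its highest-scoring member (ties: smallest
    start).  Acceptance decisions use the start of the site that opened the
    cluster, so choosing the representative afterwards cannot reshuffle
    clusters.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: (h.start, -h.score))
    clusters: list[list[MotifHit]] = [[ordered[0]]]
    anchors = [ordered[0].start]
    for h in ordered[1:]:
        if h.start - anchors[-1] >= min_sep:
            clusters.append([h])
            anchors.append(h.start)
        else:
            clusters[-1].append(h)
    return [max(c, key=lambda h: (h.score, -h.start)) for c in clusters]


@dataclass(frozen=True)
class MotifClusterTable:
    """Per-target and per-bait-protein tables behind the competition plots."""

    targets: pd.DataFrame  # prey_id, n_motifs, n_sh3_partners
    baits: pd.DataFrame    # protein_id, n_sh3_domains, degree


def build_cluster_table(
    net,
    pwms: dict[str, "PWM"],
    proteome: dict[str, str],
    domain_to_protein: dict[str, str] | None = None,
    T: float = 1000.0,
    min_sep: int = 10,
    per_domain: bool = False,
) -> MotifClusterTable:
    """Tabulate clustered binding motifs against interaction counts.

    Only edges whose bait domain has a PWM and whose prey carries at least
    one motif scoring >= T are mapped at binding-site resolution.  By
    default each prey's motifs are the clustered union over the PWMs of its
    interacting domains (``per_domain=True`` clusters per domain instead and
    sums).  ``domain_to_protein`` maps bait domain ids to their parent
    SH3-containing protein (identity when omitted).
    """
    d2p = domain_to_protein or {}

    prey_hits: dict[str, list[MotifHit]] = {}
    prey_partners: dict[str, set[str]] = {}
    prey_domain_hits: dict[str, dict[str, list[MotifHit]]] = {}
    mapped_edges = 0
    for e in net:
        pwm = pwms.get(e.bait_id)
        seq = proteome.get(e.prey_id)
        if pwm is None or seq is None:
            continue
        hits = find_binding_motifs(pwm, seq, T=T, protein_id=e.prey_id)
        if not hits:
            continue
        mapped_edges += 1
        prey_hits.setdefault(e.prey_id, []).extend(hits)
        prey_partners.setdefault(e.prey_id, set()).add(d2p.get(e.bait_id, e.bait_id))
        prey_domain_hits.setdefault(e.prey_id, {})[e.bait_id] = hits

    rows = []
    for prey in sorted(prey_hits):
        if per_domain:
            n_motifs = sum(
                len(cluster_motif_sites(h, min_sep=min_sep))
                for h in prey_domain_hits[prey].values()
            )
        else:
            n_motifs = len(cluster_motif_sites(prey_hits[prey], min_sep=min_sep))
        rows.append({"prey_id": prey, "n_motifs": n_motifs,
                     "n_sh3_partners": len(prey_partners[prey])})
    targets = pd.DataFrame(rows, columns=["prey_id", "n_motifs", "n_sh3_partners"])

    # bait side: SH3-domain count per protein vs total interaction degree
    protein_domains: dict[str, set[str]] = {}
    protein_degree: dict[str, set[str]] = {}
    for e in net:
        prot = d2p.get(e.bait_id, e.bait_id)
        protein_domains.setdefault(prot, set()).add(e.bait_id)
        protein_degree.setdefault(prot, set()).add(e.prey_id)
    baits = pd.DataFrame(
        [
            {"protein_id": p, "n_sh3_domains": len(protein_domains[p]),
             "degree": len(protein_degree[p])}
            for p in sorted(protein_domains)
        ],
        columns=["protein_id", "n_sh3_domains", "degree"],
    )
    return MotifClusterTable(targets=targets, baits=baits)


def competitive_pairs(
    net,
    pwms: dict[str, "PWM"],
    proteome: dict[str, str],
    T: float = 1000.0,
    min_sep: int = 10,
) -> pd.DataFrame:
    """Domain pairs binding the same target: competitive when their accepted
    sites overlap in residue span, coincident when they bind disjoint sites."""
    per_target: dict[str, dict[str, list[MotifHit]]] = {}
    for e in net:
        pwm = pwms.get(e.bait_id)
        seq = proteome.get(e.prey_id)
        if pwm is None or seq is None:
            continue
        hits = find_binding_motifs(pwm, seq, T=T, protein_id=e.prey_id)
        if hits:
            per_target.setdefault(e.prey_id, {})[e.bait_id] = (
                cluster_motif_sites(hits, min_sep=min_sep)
            )
    rows = []
    for target in sorted(per_target):
        domains = sorted(per_target[target])
        for i in range(len(domains)):
            for j in range(i + 1, len(domains)):
                sites_i = per_target[target][domains[i]]
                sites_j = per_target[target][domains[j]]
                overlap = any(
                    a.start <= b.end and b.start <= a.end
                    for a in sites_i for b in sites_j
                )
                rows.append({
                    "prey_id": target, "domain_a": domains[i],
                    "domain_b": domains[j],
                    "relationship": "competitive" if overlap else "coincident",
                })
    return pd.DataFrame(rows, columns=["prey_id", "domain_a", "domain_b",
                                       "relationship"])


def spearman_association(x, y) -> tuple[float, float, float]:
    """Spearman rank correlation with ties; returns (rho, rho^2, p).

    Two-sided p-value via the t-approximation, or the exact permutation
    distribution for n <= 9.  Constant input vectors are an error (rho is
    undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant vector")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= 9:
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, rho * rho, float(p)
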