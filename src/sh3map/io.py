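"""Readers and writers for the pipeline's interchange formats.

Everything is plain text: tab-separated tables for peptides, PWMs, edge
lists, ortholog maps and motif hits; FASTA for proteomes; OBO for the
ontology; GAF-style tables for annotations; Newick for the specificity tree.
PWM files round-trip bit-exactly at six decimals: the writer adjusts the
largest entry of each column so the rounded column sums to exactly 1.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS, N_AA
from .conservation import OrthologMap, RewiringCall
from .gosim import AnnotationCorpus
from .network import Edge, EvidenceAnnotation, SH3Network, Y2HCandidate
from .pwm import PWM, AlignedPeptideSet, MotifHit

__all__ = [
    "read_peptides", "write_peptides",
    "read_pwm", "write_pwm", "read_pwm_dir", "write_pwm_dir",
    "read_fasta", "write_fasta",
    "read_candidates", "write_candidates",
    "read_evidence", "write_evidence",
    "read_network", "write_network", "write_mitab",
    "read_ortholog_map", "write_ortholog_map",
    "read_reference_ppis", "write_reference_ppis",
    "write_rewiring_calls",
    "read_obo", "write_obo", "read_gaf", "write_gaf", "read_corpus",
    "read_id_list", "write_id_list",
    "write_motif_hits",
    "read_similarity_matrix", "write_similarity_matrix",
]


# ---------------------------------------------------------------- peptides

def read_peptides(path) -> list[AlignedPeptideSet]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sets = []
    for (domain, group), sub in df.groupby(["domain_id", "group_label"], sort=True):
        sets.append(AlignedPeptideSet(
            domain_id=domain, group_label=group, peptides=tuple(sub["peptide"]),
        ))
    return sets


def write_peptides(sets: list[AlignedPeptideSet], path) -> None:
    rows = [
        {"domain_id": s.domain_id, "group_label": s.group_label, "peptide": p}
        for s in sets for p in s.peptides
    ]
    pd.DataFrame(rows, columns=["domain_id", "group_label", "peptide"]).to_csv(
        path, sep="\t", index=False)


# --------------------------------------------------------------------- PWM

def write_pwm(pwm: PWM, path) -> None:
    """20 x m probability matrix, 6 decimals, columns summing to exactly 1."""
    prob = pwm.prob.copy()
    rounded = np.round(prob, 6)
    for j in range(prob.shape[1]):
        gap = 1.0 - rounded[:, j].sum()
        i_max = int(np.argmax(rounded[:, j]))
        rounded[i_max, j] = round(rounded[i_max, j] + gap, 6)
    lines = ["aa\t" + "\t".join(str(j + 1) for j in range(pwm.m))]
    for i, aa in enumerate(AMINO_ACIDS):
        lines.append(aa + "\t" + "\t".join(f"{rounded[i, j]:.6f}" for j in range(pwm.m)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pwm(path, domain_id: str | None = None, group_label: str = "") -> PWM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.loc[list(AMINO_ACIDS)]
    if domain_id is None:
        stem = Path(path).stem
        domain_id, _, group_label = stem.partition("#")
    return PWM(domain_id=domain_id, group_label=group_label,
               prob=df.to_numpy(dtype=float))


def write_pwm_dir(pwms: list[PWM], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for pwm in pwms:
        write_pwm(pwm, directory / f"{pwm.key}.pwm.tsv")


def read_pwm_dir(directory) -> dict[str, PWM]:
    pwms = {}
    for path in sorted(Path(directory).glob("*.pwm.tsv")):
        stem = path.name[: -len(".pwm.tsv")]
        domain_id, _, group = stem.partition("#")
        pwm = read_pwm(path, domain_id=domain_id, group_label=group)
        pwms[pwm.key] = pwm
    return pwms


# ------------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------- Y2H candidates

_CAND_COLS = ["bait_id", "bait_type", "prey_id", "colony_count", "library"]


def write_candidates(cands: list[Y2HCandidate], path) -> None:
    rows = [{"bait_id": c.bait_id, "bait_type": c.bait_type, "prey_id": c.prey_id,
             "colony_count": c.colony_count, "library": c.library} for c in cands]
    pd.DataFrame(rows, columns=_CAND_COLS).to_csv(path, sep="\t", index=False)


def read_candidates(path) -> list[Y2HCandidate]:
    df = pd.read_csv(path, sep="\t", dtype={"colony_count": int})
    return [
        Y2HCandidate(bait_id=r.bait_id, prey_id=r.prey_id,
                     colony_count=int(r.colony_count), library=r.library,
                     bait_type=r.bait_type)
        for r in df.itertuples()
    ]


_EV_COLS = ["bait_id", "prey_id", "in_WI8", "in_interolog_set", "in_WormNet",
            "literature_functional", "pwm_score", "best_peptide", "start",
            "rank", "prey_is_TF"]


def write_evidence(ev: dict[tuple[str, str], EvidenceAnnotation], path) -> None:
    rows = []
    for (bait, prey), e in sorted(ev.items()):
        rows.append({
            "bait_id": bait, "prey_id": prey,
            "in_WI8": int(e.in_WI8), "in_interolog_set": int(e.in_interolog_set),
            "in_WormNet": int(e.in_WormNet),
            "literature_functional": int(e.literature_functional),
            "pwm_score": "" if e.pwm_score is None else f"{e.pwm_score:.6g}",
            "best_peptide": e.best_peptide or "",
            "start": "" if e.start is None else e.start,
            "rank": "" if e.rank is None else e.rank,
            "prey_is_TF": int(e.prey_is_TF),
        })
    pd.DataFrame(rows, columns=_EV_COLS).to_csv(path, sep="\t", index=False)


def read_evidence(path) -> dict[tuple[str, str], EvidenceAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.itertuples():
        out[(r.bait_id, r.prey_id)] = EvidenceAnnotation(
            in_WI8=bool(r.in_WI8), in_interolog_set=bool(r.in_interolog_set),
            in_WormNet=bool(r.in_WormNet),
            literature_functional=bool(r.literature_functional),
            pwm_score=None if pd.isna(r.pwm_score) else float(r.pwm_score),
            best_peptide=None if pd.isna(r.best_peptide) else str(r.best_peptide),
            start=None if pd.isna(r.start) else int(r.start),
            rank=None if pd.isna(r.rank) else int(r.rank),
            prey_is_TF=bool(r.prey_is_TF),
        )
    return out


# ------------------------------------------------------------ SH3 network

_NET_COLS = ["bait_id", "bait_type", "prey_id", "colony_count", "evidence_class",
             "pwm_score", "best_peptide", "start", "rank"]


def write_network(net: SH3Network, path) -> None:
    rows = []
    for e in net:
        rows.append({
            "bait_id": e.bait_id, "bait_type": e.bait_type, "prey_id": e.prey_id,
            "colony_count": e.colony_count, "evidence_class": e.evidence_class,
            "pwm_score": "" if e.pwm_score is None else f"{e.pwm_score:.6g}",
            "best_peptide": e.best_peptide or "",
            "start": "" if e.start is None else e.start,
            "rank": "" if e.rank is None else e.rank,
        })
    pd.DataFrame(rows, columns=_NET_COLS).to_csv(path, sep="\t", index=False)


def read_network(path) -> SH3Network:
    df = pd.read_csv(path, sep="\t")
    edges = []
    for r in df.itertuples():
        edges.append(Edge(
            bait_id=r.bait_id, bait_type=r.bait_type, prey_id=r.prey_id,
            colony_count=int(r.colony_count), evidence_class=r.evidence_class,
            pwm_score=None if pd.isna(r.pwm_score) else float(r.pwm_score),
            best_peptide=None if pd.isna(r.best_peptide) else str(r.best_peptide),
            start=None if pd.isna(r.start) else int(r.start),
            rank=None if pd.isna(r.rank) else int(r.rank),
        ))
    return SH3Network(edges)


def write_mitab(net: SH3Network, path) -> None:
    """Minimal PSI-MITAB export: interactor ids and interaction type only."""
    lines = ["#ID(A)\tID(B)\tInteraction type"]
    for e in net:
        lines.append(f"{e.bait_id}\t{e.prey_id}\t"
                     'psi-mi:"MI:0915"(physical association)')
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------- orthologs

def write_ortholog_map(omap: OrthologMap, path, source: str = "union") -> None:
    rows = [{"gene_A": a, "gene_B": b, "source": source}
            for a, b in sorted(omap.pairs)]
    pd.DataFrame(rows, columns=["gene_A", "gene_B", "source"]).to_csv(
        path, sep="\t", index=False)


def read_ortholog_map(path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return OrthologMap({(r.gene_A, r.gene_B) for r in df.itertuples()})


def write_reference_ppis(edges: set[frozenset[str]], path, source: str = "ref") -> None:
    rows = [dict(zip(("id_A", "id_B"), sorted(e))) | {"source": source}
            for e in sorted(edges, key=lambda e: sorted(e))]
    pd.DataFrame(rows, columns=["id_A", "id_B", "source"]).to_csv(
        path, sep="\t", index=False)


def read_reference_ppis(path) -> set[frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {frozenset((r.id_A, r.id_B)) for r in df.itertuples()}


_REWIRE_COLS = ["domain_id", "target_id", "source_species", "scenario",
                "specificity_conserved", "motif_conserved", "best_motif",
                "best_match", "identity", "note"]


def write_rewiring_calls(calls: list[RewiringCall], path) -> None:
    rows = []
    for c in calls:
        rows.append({
            "domain_id": c.domain_id, "target_id": c.target_id,
            "source_species": c.source_species, "scenario": c.scenario,
            "specificity_conserved": "" if c.specificity_conserved is None
                                      else int(c.specificity_conserved),
            "motif_conserved": "" if c.motif_conserved is None
                                else int(c.motif_conserved),
            "best_motif": c.best_motif or "", "best_match": c.best_match or "",
            "identity": "" if c.identity is None else f"{c.identity:.4f}",
            "note": c.note,
        })
    pd.DataFrame(rows, columns=_REWIRE_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- ontology

def read_obo(path) -> nx.DiGraph:
    """OBO file -> DiGraph with child -> parent is_a/part_of edges."""
    import obonet

    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, namespace=data.get("namespace", "biological_process"))
    for child, parent, key in multi.edges(keys=True):
        if key in ("is_a", "part_of"):
            g.add_edge(child, parent, relation=key)
    return g


def write_obo(ontology: nx.DiGraph, path, name: str = "synthetic-ontology") -> None:
    lines = ["format-version: 1.2", f"ontology: {name}", ""]
    for term in sorted(ontology.nodes):
        data = ontology.nodes[term]
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {data.get('name', term)}")
        lines.append(f"namespace: {data.get('namespace', 'biological_process')}")
        for _, parent, edata in sorted(ontology.out_edges(term, data=True)):
            rel = edata.get("relation", "is_a")
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! {parent}")
            else:
                lines.append(f"relationship: {rel} {parent} ! {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_gaf(annotations: dict[str, set[str]], path,
              evidence_code: str = "IDA") -> None:
    rows = [{"gene": g, "term": t, "evidence_code": evidence_code}
            for g in sorted(annotations) for t in sorted(annotations[g])]
    pd.DataFrame(rows, columns=["gene", "term", "evidence_code"]).to_csv(
        path, sep="\t", index=False)


def read_gaf(path, exclude_evidence: set[str] | None = None) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if exclude_evidence:
        df = df[~df["evidence_code"].isin(exclude_evidence)]
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.gene, set()).add(r.term)
    return out


def read_corpus(obo_path, gaf_path,
                exclude_evidence: set[str] | None = None) -> AnnotationCorpus:
    return AnnotationCorpus(read_obo(obo_path),
                            read_gaf(gaf_path, exclude_evidence))


# ------------------------------------------------------------------- lists

def read_id_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def write_id_list(ids, path) -> None:
    Path(path).write_text("\n".join(ids) + "\n")


# ------------------------------------------------------------- motif hits

def write_motif_hits(hits: list[MotifHit], path) -> None:
    rows = [{"protein_id": h.protein_id, "start": h.start, "end": h.end,
             "peptide": h.peptide, "score": f"{h.score:.6g}",
             "rank": "" if h.genome_rank is None else h.genome_rank}
            for h in hits]
    pd.DataFrame(rows, columns=["protein_id", "start", "end", "peptide",
                                "score", "rank"]).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------ similarity matrix

def write_similarity_matrix(matrix, path) -> None:
    df = pd.DataFrame(matrix.sim, index=list(matrix.ids), columns=list(matrix.ids))
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_similarity_matrix(path):
    from .tree import SimilarityMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    sim = df.to_numpy(dtype=float)
    sim = (sim + sim.T) / 2.0  # 6-decimal storage can break exact symmetry
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(ids=tuple(df.index), sim=sim,
                            offsets=np.zeros_like(sim, dtype=int))
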