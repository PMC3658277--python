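"""Seeded synthetic-data generators with ground-truth ledgers.

The generators emit every input the pipeline consumes — aligned peptide
tables, PWMs, a proteome with planted binding motifs, a raw Y2H candidate
table with false positives and sticky transcription-factor preys, an
ortholog map with per-interaction rewiring-scenario ground truth, a small
ontology with planted functional modules, and seed/negative lists — so that
every analysis stage can be exercised end-to-end and checked against what
was planted.

Default condition choices (documented in the methods note): roughly forty
aligned peptides per domain with 10% residue noise, a proteome of a few
hundred proteins with log-normal lengths (median 400 residues), about eight
true interactions per SH3 domain, a 50% single-colony false-positive rate
over true edges, zero-truncated Poisson colony counts giving ~70% of true
edges two or more colonies, 80% ortholog coverage, and a rewiring-scenario
mixture dominated by joint loss of specificity and motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .alphabet import AMINO_ACIDS, N_AA
from .conservation import OrthologMap
from .network import EvidenceAnnotation, SH3_BAIT_TYPE, Y2HCandidate
from .pwm import PWM, AlignedPeptideSet, best_score, build_pwm, scan_protein

__all__ = ["WorldConfig", "SyntheticWorld", "gen_pwm", "sample_peptides",
           "random_protein", "gen_world"]

CLASS_PATTERNS = {
    "I": "+XXPXXP",   # charged anchor then two prolines
    "II": "PXXPX+",   # two prolines then a charged anchor
}

SCENARIOS_ORDER = ("i", "ii", "iii", "conserved_both")


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world; defaults are the documented conditions."""

    n_domains: int = 12
    class_mixture: tuple[float, float, float] = (0.4, 0.4, 0.2)  # I, II, atypical
    pwm_length: int = 10
    sharpness: float = 0.9
    pwm_coverage: float = 0.85        # fraction of domains with phage data
    peptides_per_domain: int = 40
    peptide_noise: float = 0.1

    n_proteins: int = 300
    protein_length_median: float = 400.0
    protein_length_sigma: float = 0.5

    edges_per_domain: int = 8
    n_bait_prey_edges: int = 2        # edges whose prey is another SH3 protein
    fp_rate: float = 0.5
    colony_lambda: float = 2.0        # zero-truncated Poisson for true edges
    lit_flag_rate: float = 0.5
    n_sticky_tfs: int = 2
    sticky_tf_baits: int = 8
    tf_degree_max: int = 5
    T: float = 1000.0

    ortholog_coverage: float = 0.8
    multi_ortholog_rate: float = 0.05
    scenario_mixture: dict[str, float] = field(default_factory=lambda: {
        "i": 0.10, "ii": 0.29, "iii": 0.56, "conserved_both": 0.05,
    })
    n_extra_reference_edges: int = 30

    n_modules: int = 4
    annotation_coverage: float = 0.7

    n_seed_module: int = 40
    n_negatives: int = 40
    n_background: int = 200
    p_in: float = 0.35
    p_out: float = 0.01

    def validate(self) -> None:
        total = sum(self.scenario_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scenario mixture sums to {total}, not 1")
        if set(self.scenario_mixture) - set(SCENARIOS_ORDER):
            raise ValueError("unknown scenario in mixture")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        if self.pwm_length < 4:
            raise ValueError("pwm_length must be >= 4")


def gen_pwm(m: int, sharpness: float, class_label: str, seed,
            x_weight: float = 0.55) -> PWM:
    """Generator PWM of width *m* for a specificity class.

    Class I and II place the canonical charged/proline anchors of the
    +XXPXXP and PXXPX+ consensus patterns (left-aligned, padded with
    non-specific positions); the atypical class draws random anchors
    including both flanks.  ``sharpness`` in (0, 1] interpolates each anchor
    column between uniform and deterministic.  Non-anchor positions carry a
    mild domain-specific preference of weight ``x_weight * sharpness`` for a
    random residue, mirroring the secondary selectivity real SH3 profiles
    show outside their anchors; this keeps different domains of the same
    class distinguishable at the motif level.
    """
    rng = np.random.default_rng(seed)
    prob = np.full((N_AA, m), 1.0 / N_AA)

    if class_label in CLASS_PATTERNS:
        pattern = CLASS_PATTERNS[class_label]
        if m < len(pattern):
            raise ValueError(f"m={m} shorter than class {class_label} pattern")
        anchors = []
        for j, ch in enumerate(pattern):
            if ch == "P":
                anchors.append((j, "P"))
            elif ch == "+":
                anchors.append((j, rng.choice(["R", "K"])))
    elif class_label == "atypical":
        interior = rng.choice(np.arange(1, m - 1), size=max(1, m - 6), replace=False)
        positions = sorted({0, m - 1, *interior.tolist()})
        anchors = [(j, rng.choice(list(AMINO_ACIDS))) for j in positions]
    else:
        raise ValueError(f"unknown class label {class_label!r}")

    anchor_pos = {j for j, _ in anchors}
    for j, aa in anchors:
        col = np.full(N_AA, (1.0 - sharpness) / N_AA)
        col[AMINO_ACIDS.index(aa)] += sharpness
        prob[:, j] = col
    for j in range(m):
        if j in anchor_pos:
            continue
        w = x_weight * sharpness
        col = np.full(N_AA, (1.0 - w) / N_AA)
        col[rng.integers(0, N_AA)] += w
        prob[:, j] = col
    return PWM(domain_id=f"gen-{class_label}", prob=prob)


def sample_peptides(pwm: PWM, n: int, noise_rate: float, seed,
                    domain_id: str | None = None,
                    group_label: str = "") -> AlignedPeptideSet:
    """Draw aligned peptides column-independently from a PWM, with noise.

    Each residue is replaced by a uniformly random one with probability
    ``noise_rate``, emulating weak or spurious phage selectants.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    cols = [rng.choice(20, size=n, p=pwm.prob[:, j]) for j in range(pwm.m)]
    draws = np.stack(cols, axis=1)
    noise_mask = rng.random(draws.shape) < noise_rate
    draws[noise_mask] = rng.integers(0, 20, size=int(noise_mask.sum()))
    peptides = tuple("".join(aa[row]) for row in draws)
    return AlignedPeptideSet(domain_id=domain_id or pwm.domain_id,
                             group_label=group_label, peptides=peptides)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)])


@dataclass
class RewiringTruth:
    domain_id: str
    target_id: str
    scenario: str
    ortholog_domain_pwm: PWM | None
    ortholog_domain_seq: str
    ortholog_has_sh3: bool


@dataclass
class SyntheticWorld:
    """All pipeline inputs plus the ground truth they were generated from."""

    config: WorldConfig
    master_seed: int

    domain_ids: list[str]
    domain_class: dict[str, str]
    domain_protein: dict[str, str]
    domain_seqs: dict[str, str]
    generator_pwms: dict[str, PWM]          # only domains with phage data
    peptide_sets: list[AlignedPeptideSet]

    proteome: dict[str, str]
    planted_motifs: list[tuple[str, str, int]]  # (protein, domain, start 1-based)

    true_edges: set[tuple[str, str]]
    candidates: list[Y2HCandidate]
    evidence: dict[tuple[str, str], EvidenceAnnotation]

    ortholog_map: OrthologMap
    proteome_b: dict[str, str]
    rewiring_truth: list[RewiringTruth]
    reference_b_edges: set[frozenset[str]]

    ontology: nx.DiGraph
    annotations: dict[str, set[str]]

    function_graph: nx.Graph
    seeds: set[str]
    negatives: set[str]

    def scenario_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in SCENARIOS_ORDER}
        for t in self.rewiring_truth:
            counts[t.scenario] += 1
        return counts

    def write(self, directory) -> None:
        from . import io

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        io.write_peptides(self.peptide_sets, directory / "peptides.tsv")
        io.write_pwm_dir(list(self.generator_pwms.values()),
                         directory / "generator_pwms")
        io.write_fasta(self.proteome, directory / "proteome_a.fasta")
        io.write_fasta(self.proteome_b, directory / "proteome_b.fasta")
        io.write_candidates(self.candidates, directory / "candidates.tsv")
        io.write_evidence(self.evidence, directory / "evidence.tsv")
        io.write_ortholog_map(self.ortholog_map, directory / "orthologs.tsv")
        io.write_reference_ppis(self.reference_b_edges,
                                directory / "reference_b_edges.tsv")
        io.write_obo(self.ontology, directory / "ontology.obo")
        io.write_gaf(self.annotations, directory / "annotations.tsv")
        io.write_id_list(sorted(self.seeds), directory / "seeds.txt")
        io.write_id_list(sorted(self.negatives), directory / "negatives.txt")
        import pandas as pd

        pd.DataFrame(
            [{"bait_id": b, "prey_id": p} for b, p in sorted(self.true_edges)]
        ).to_csv(directory / "truth_edges.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"protein_id": p, "domain_id": d, "start": s}
             for p, d, s in self.planted_motifs]
        ).to_csv(directory / "truth_motifs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"domain_id": t.domain_id, "target_id": t.target_id,
              "scenario": t.scenario} for t in self.rewiring_truth]
        ).to_csv(directory / "truth_scenarios.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"domain_id": d, "protein_id": self.domain_protein[d],
              "class": self.domain_class[d], "sequence": self.domain_seqs[d]}
             for d in self.domain_ids]
        ).to_csv(directory / "domains.tsv", sep="\t", index=False)
        # per-interaction ortholog context for the rewiring stage
        opwm_dir = directory / "ortholog_pwms"
        opwm_dir.mkdir(exist_ok=True)
        ctx_rows = []
        for t in self.rewiring_truth:
            pwm_file = ""
            if t.ortholog_domain_pwm is not None:
                pwm_file = f"{t.domain_id}@{t.target_id}.pwm.tsv"
                io.write_pwm(t.ortholog_domain_pwm, opwm_dir / pwm_file)
            ctx_rows.append({
                "domain_id": t.domain_id, "target_id": t.target_id,
                "ortholog_has_sh3": int(t.ortholog_has_sh3),
                "ortholog_domain_seq": t.ortholog_domain_seq,
                "ortholog_pwm_file": pwm_file,
            })
        pd.DataFrame(ctx_rows).to_csv(directory / "rewire_context.tsv",
                                      sep="\t", index=False)
        nx.write_edgelist(self.function_graph,
                          directory / "function_graph.tsv", delimiter="\t",
                          data=False)


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws via rejection (lam ~ 2, cheap)."""
    out = np.zeros(size, dtype=int)
    todo = np.arange(size)
    while todo.size:
        draws = rng.poisson(lam, size=todo.size)
        ok = draws >= 1
        out[todo[ok]] = draws[ok]
        todo = todo[~ok]
    return out


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    aa = np.array(list(AMINO_ACIDS))
    arr = np.array(list(seq))
    mask = rng.random(len(seq)) < rate
    arr[mask] = aa[rng.integers(0, 20, size=int(mask.sum()))]
    return "".join(arr)


def _split_counts(n: int, fractions: list[float]) -> list[int]:
    """Largest-remainder apportionment of n into integer counts."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def gen_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate the full synthetic study: same seed, byte-identical world."""
    config = config or WorldConfig()
    config.validate()
    ss = np.random.SeedSequence(seed)
    (ss_pwm, ss_pep, ss_prot, ss_net, ss_screen, ss_orth, ss_onto,
     ss_func) = ss.spawn(8)

    # --- domains and specificity models -----------------------------------
    n_i, n_ii, n_atyp = _split_counts(config.n_domains, list(config.class_mixture))
    classes = ["I"] * n_i + ["II"] * n_ii + ["atypical"] * n_atyp
    domain_ids = [f"SH3-{i + 1:02d}" for i in range(config.n_domains)]
    domain_class = dict(zip(domain_ids, classes))
    domain_protein = {d: d.replace("SH3-", "SP-") for d in domain_ids}

    n_with_pwm = max(1, int(round(config.pwm_coverage * config.n_domains)))
    pwm_children = ss_pwm.spawn(config.n_domains)
    rng_pwm = np.random.default_rng(ss_pwm)
    generator_pwms: dict[str, PWM] = {}
    for idx, d in enumerate(domain_ids[:n_with_pwm]):
        pwm = gen_pwm(config.pwm_length, config.sharpness, domain_class[d],
                      pwm_children[idx])
        generator_pwms[d] = replace(pwm, domain_id=d, provenance="X12")
    domain_seqs = {d: random_protein(60, rng_pwm) for d in domain_ids}

    pep_children = ss_pep.spawn(len(generator_pwms))
    peptide_sets = [
        sample_peptides(generator_pwms[d], config.peptides_per_domain,
                        config.peptide_noise, child, domain_id=d)
        for d, child in zip(generator_pwms, pep_children)
    ]

    # --- proteome with planted motifs --------------------------------------
    rng_prot = np.random.default_rng(ss_prot)
    lengths = np.clip(rng_prot.lognormal(
        np.log(config.protein_length_median), config.protein_length_sigma,
        size=config.n_proteins), 80, 2500).astype(int)
    proteome = {f"P{i + 1:04d}": random_protein(int(L), rng_prot)
                for i, L in enumerate(lengths)}
    # SH3 proteins are proteome members too (their domain sequence embedded)
    for d in domain_ids:
        sp = domain_protein[d]
        flank = random_protein(150, rng_prot)
        proteome[sp] = flank + domain_seqs[d] + random_protein(150, rng_prot)

    rng_net = np.random.default_rng(ss_net)
    prey_pool = [p for p in proteome if p.startswith("P")]
    true_edges: set[tuple[str, str]] = set()
    planted: list[tuple[str, str, int]] = []
    for d in domain_ids:
        preys = rng_net.choice(prey_pool, size=config.edges_per_domain,
                               replace=False)
        for prey in preys:
            true_edges.add((d, str(prey)))
    # a few baits that also act as preys
    sp_ids = [domain_protein[d] for d in domain_ids]
    for _ in range(config.n_bait_prey_edges):
        d = str(rng_net.choice(domain_ids))
        sp = str(rng_net.choice([s for s in sp_ids if s != domain_protein[d]]))
        true_edges.add((d, sp))

    occupied: dict[str, list[tuple[int, int]]] = {}
    for d, prey in sorted(true_edges):
        pwm = generator_pwms.get(d)
        if pwm is None:
            continue
        seq = proteome[prey]
        taken = occupied.setdefault(prey, [])
        for _ in range(100):  # avoid overwriting a previously planted site
            start0 = int(rng_net.integers(20, len(seq) - pwm.m - 20))
            if all(start0 + pwm.m <= lo or start0 >= hi for lo, hi in taken):
                break
        taken.append((start0, start0 + pwm.m))
        proteome[prey] = seq[:start0] + pwm.consensus + seq[start0 + pwm.m:]
        planted.append((prey, d, start0 + 1))

    # --- Y2H screen: colonies, false positives, sticky TFs ------------------
    rng_screen = np.random.default_rng(ss_screen)
    ordered_true = sorted(true_edges)
    colonies = _zt_poisson(rng_screen, config.colony_lambda, len(ordered_true))
    candidates: list[Y2HCandidate] = []
    evidence: dict[tuple[str, str], EvidenceAnnotation] = {}

    def pwm_evidence(domain: str, prey: str) -> dict:
        pwm = generator_pwms.get(domain)
        if pwm is None:
            return dict(pwm_score=None, best_peptide=None, start=None)
        best, _ = scan_protein(pwm, proteome[prey], protein_id=prey)
        return dict(pwm_score=best.score, best_peptide=best.peptide,
                    start=best.start)

    for (d, prey), nc in zip(ordered_true, colonies):
        candidates.append(Y2HCandidate(bait_id=d, prey_id=prey,
                                       colony_count=int(nc)))
        lit = nc == 1 and rng_screen.random() < config.lit_flag_rate
        evidence[(d, prey)] = EvidenceAnnotation(
            literature_functional=bool(lit), **pwm_evidence(d, prey))

    n_fp = int(round(config.fp_rate * len(ordered_true)))
    fp_pairs: set[tuple[str, str]] = set()
    while len(fp_pairs) < n_fp:
        d = str(rng_screen.choice(domain_ids))
        prey = str(rng_screen.choice(prey_pool))
        if (d, prey) not in true_edges:
            fp_pairs.add((d, prey))
    for d, prey in sorted(fp_pairs):
        candidates.append(Y2HCandidate(bait_id=d, prey_id=prey, colony_count=1))
        evidence[(d, prey)] = EvidenceAnnotation(**pwm_evidence(d, prey))

    used_preys = {p for _, p in true_edges} | {p for _, p in fp_pairs}
    tf_pool = [p for p in prey_pool if p not in used_preys]
    sticky_tfs = [str(p) for p in rng_screen.choice(
        tf_pool, size=config.n_sticky_tfs, replace=False)]
    for tf in sticky_tfs:
        baits = rng_screen.choice(
            domain_ids, size=min(config.sticky_tf_baits, len(domain_ids)),
            replace=False)
        for d in baits:
            d = str(d)
            candidates.append(Y2HCandidate(bait_id=d, prey_id=tf, colony_count=2))
            evidence[(d, tf)] = EvidenceAnnotation(
                prey_is_TF=True, **pwm_evidence(d, tf))

    # --- orthologs, species B, rewiring ground truth ------------------------
    rng_orth = np.random.default_rng(ss_orth)
    pairs: set[tuple[str, str]] = set()
    for prot in sorted(proteome):
        if rng_orth.random() < config.ortholog_coverage:
            pairs.add((prot, f"y_{prot}"))
            if rng_orth.random() < config.multi_ortholog_rate:
                pairs.add((prot, f"y_{prot}b"))
    omap = OrthologMap(pairs)

    eligible = [
        (d, prey) for d, prey in sorted(true_edges)
        if d in generator_pwms and omap.orthologs_of(domain_protein[d])
        and omap.orthologs_of(prey)
    ]
    order = list(rng_orth.permutation(len(eligible)))
    fractions = [config.scenario_mixture.get(s, 0.0) for s in SCENARIOS_ORDER]
    counts = _split_counts(len(eligible), fractions)
    scenario_of: dict[tuple[str, str], str] = {}
    pos = 0
    for scen, cnt in zip(SCENARIOS_ORDER, counts):
        for idx in order[pos:pos + cnt]:
            scenario_of[eligible[idx]] = scen
        pos += cnt

    # ortholog proteome B: start from fresh random sequences of equal length
    proteome_b: dict[str, str] = {}
    for a, b in sorted(omap.pairs):
        proteome_b[b] = random_protein(len(proteome[a]), rng_orth)

    other_class = {"I": "II", "II": "I", "atypical": "I"}
    truth_rows: list[RewiringTruth] = []
    reference_b: set[frozenset[str]] = set()
    motif_start = {(p, d): s for p, d, s in planted}
    rewire_children = ss_orth.spawn(max(1, len(eligible)))
    for i, (d, prey) in enumerate(sorted(scenario_of)):
        scen = scenario_of[(d, prey)]
        pwm = generator_pwms[d]
        spec_cons = scen in ("ii", "conserved_both")
        motif_cons = scen in ("i", "conserved_both")
        # ortholog specificity profiles are phage-derived too: rebuild them
        # from sampled peptides so both species' PWMs share the estimator
        child_a, child_b = rewire_children[i].spawn(2)
        if spec_cons:
            o_gen = pwm
            o_seq = domain_seqs[d]
        else:
            o_gen = gen_pwm(config.pwm_length, config.sharpness,
                            other_class[domain_class[d]], child_a)
            o_seq = _mutate(domain_seqs[d], 0.7, rng_orth)
        o_peps = sample_peptides(o_gen, config.peptides_per_domain,
                                 config.peptide_noise, child_b,
                                 domain_id=f"y_{d}")
        o_pwm = build_pwm(o_peps)
        if motif_cons:
            s0 = motif_start[(prey, d)] - 1
            for ob in sorted(omap.orthologs_of(prey)):
                seq = proteome_b[ob]
                proteome_b[ob] = seq[:s0] + pwm.consensus + seq[s0 + pwm.m:]
        if scen == "conserved_both":
            for obait in sorted(omap.orthologs_of(domain_protein[d])):
                for oprey in sorted(omap.orthologs_of(prey)):
                    if obait != oprey:
                        reference_b.add(frozenset((obait, oprey)))
        truth_rows.append(RewiringTruth(
            domain_id=d, target_id=prey, scenario=scen,
            ortholog_domain_pwm=o_pwm, ortholog_domain_seq=o_seq,
            ortholog_has_sh3=True))

    b_proteins = sorted(proteome_b)
    for _ in range(config.n_extra_reference_edges):
        a, b = rng_orth.choice(b_proteins, size=2, replace=False)
        reference_b.add(frozenset((str(a), str(b))))

    # --- ontology with planted functional modules ---------------------------
    rng_onto = np.random.default_rng(ss_onto)
    onto = nx.DiGraph()
    root = "GO:0000001"
    onto.add_node(root, namespace="biological_process", name="root process")
    leaf_terms: list[str] = []
    for m in range(config.n_modules):
        mid = f"GO:00001{m + 1:02d}"
        onto.add_node(mid, namespace="biological_process", name=f"module {m + 1}")
        onto.add_edge(mid, root, relation="is_a")
        for l in range(2):
            leaf = f"GO:0001{m + 1:02d}{l + 1}"
            onto.add_node(leaf, namespace="biological_process",
                          name=f"module {m + 1} leaf {l + 1}")
            onto.add_edge(leaf, mid, relation="is_a")
            leaf_terms.append(leaf)
    generic = "GO:0000999"
    onto.add_node(generic, namespace="biological_process", name="generic process")
    onto.add_edge(generic, root, relation="is_a")

    domain_module = {d: i % config.n_modules for i, d in enumerate(domain_ids)}
    annotations: dict[str, set[str]] = {}
    for d, prey in sorted(true_edges):
        if rng_onto.random() < config.annotation_coverage:
            m = domain_module[d]
            leaf = leaf_terms[2 * m + int(rng_onto.integers(0, 2))]
            annotations.setdefault(prey, set()).add(leaf)
            annotations.setdefault(domain_protein[d], set()).add(leaf)
    for prot in sorted(proteome):
        if prot not in annotations and rng_onto.random() < 0.3:
            annotations[prot] = {generic}

    # --- function-prediction graph with a planted seed module ---------------
    rng_func = np.random.default_rng(ss_func)
    seeds = {f"E{i + 1:03d}" for i in range(config.n_seed_module)}
    negatives = {f"N{i + 1:03d}" for i in range(config.n_negatives)}
    background = {f"B{i + 1:03d}" for i in range(config.n_background)}
    g = nx.Graph()
    g.add_nodes_from(sorted(seeds | negatives | background))
    seed_list = sorted(seeds)
    for i in range(len(seed_list)):
        for j in range(i + 1, len(seed_list)):
            if rng_func.random() < config.p_in:
                g.add_edge(seed_list[i], seed_list[j])
    others = sorted(negatives | background)
    everyone = sorted(g.nodes)
    for v in others:
        for u in everyone:
            if u != v and rng_func.random() < config.p_out:
                g.add_edge(v, u)

    return SyntheticWorld(
        config=config, master_seed=seed,
        domain_ids=domain_ids, domain_class=domain_class,
        domain_protein=domain_protein, domain_seqs=domain_seqs,
        generator_pwms=generator_pwms, peptide_sets=peptide_sets,
        proteome=proteome, planted_motifs=planted,
        true_edges=true_edges, candidates=candidates, evidence=evidence,
        ortholog_map=omap, proteome_b=proteome_b,
        rewiring_truth=truth_rows, reference_b_edges=reference_b,
        ontology=onto, annotations=annotations,
        function_graph=g, seeds=seeds, negatives=negatives,
    )
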