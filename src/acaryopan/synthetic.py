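"""Simulated genome collections with known ground truth.

The generator emulates a clade of closely related cyanobacterial genomes
descended from a known species tree: a Yule ingroup plus two divergent
outgroups; an ancestral gene repertoire evolving by per-branch Poisson gene
gain (fresh sequence, no back-gain) and exponential loss; one multi-gene
"plasmid block" gained/lost as a unit; one horizontally transferred gene
cassette copied from the donor lineage into a non-sister recipient clade with
the donor's contemporaneous sequence state; nucleotide divergence under a
GTR+Gamma process.  It also simulates OD750 growth trajectories
(logistic-with-lag, additive Gaussian noise, detection floor 0.001).

All randomness flows from the config seed; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .growth import GrowthSeries
from .phylo import AlignmentMatrix, SubstModel
from .seqio import AnnotatedGenome, CDSRecord, write_genome_dir

OD_DETECTION_FLOOR = 0.001
SPACER_FRACTION = 0.15  # of total genome length
STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA
CODE_NT = "ACGT"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated collection."""

    n_ingroup: int = 10
    n_outgroup: int = 2
    n_ancestral_genes: int = 500
    mean_gene_len: int = 600  # nt, forced to multiples of 3
    gene_gain_rate: float = 1.0  # gains per gene per unit branch length
    gene_loss_rate: float = 3.0  # losses per gene per unit branch length
    subst_params: SubstModel = field(
        default_factory=lambda: SubstModel(
            exchangeabilities=(1.0, 2.0, 1.0, 1.0, 2.0, 1.0),
            freqs=(0.28, 0.22, 0.22, 0.28), alpha=1.0))
    plasmid_block_size: int = 20
    hgt_cassette_size: int = 3
    ingroup_height: float = 0.03  # root-to-tip substitutions/site (<=10% pairwise)
    outgroup_depth: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name in ("n_ingroup", "n_outgroup", "n_ancestral_genes",
                     "mean_gene_len", "plasmid_block_size", "hgt_cassette_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.gene_gain_rate < 0 or self.gene_loss_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class GroundTruth:
    species_tree: dendropy.Tree
    ortholog_table: pd.DataFrame  # genes x genomes, bool
    events: list  # (branch key, gene or unit id, 'gain'|'loss')
    trait_table: pd.DataFrame  # traits x strains, columns in tip order
    hgt_donor_label: str
    hgt_recipient_tips: list


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class _SimNode:
    __slots__ = ("children", "birth", "length", "label")

    def __init__(self, birth: float):
        self.children = []
        self.birth = birth
        self.length = 0.0
        self.label = None

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.10f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10f}"


def simulate_species_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) rooted binary tree, contemporaneous labelled tips."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)
    t = 0.0
    root = _SimNode(0.0)
    active = [_SimNode(0.0), _SimNode(0.0)]
    root.children = list(active)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(0, len(active)))
        parent = active.pop(i)
        parent.length = t - parent.birth
        kids = [_SimNode(t), _SimNode(t)]
        parent.children = kids
        active.extend(kids)
    t += rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t - node.birth
    # deterministic tip labels in preorder
    counter = [0]

    def label(node):
        if not node.children:
            counter[0] += 1
            node.label = f"T{counter[0]:02d}"
        for c in node.children:
            label(c)

    label(root)
    tree = dendropy.Tree.get(data=root.newick() + ";", schema="newick")
    tree.is_rooted = True
    # guard against zero-length pendant edges (possible only at float limits)
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length <= 0:
            e.length = 1e-9
    return tree


def _scale_tree(tree: dendropy.Tree, target_height: float) -> None:
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    h = max(depths)
    f = target_height / h
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= f


def build_collection_tree(cfg: SimulationConfig) -> dendropy.Tree:
    """Ingroup Yule tree scaled to cfg.ingroup_height plus divergent outgroups.

    Outgroup tips are labelled OUT1..OUTk; the first outgroup is the closest.
    The ingroup shape is resampled (deterministically from the seed) until it
    contains a 3-tip clade, so the transferred cassette reaches enough
    genomes for an informative topology contrast (donor + 3 recipients).
    """
    ingroup = None
    for attempt in range(1000):
        cand = simulate_species_tree(cfg.n_ingroup, cfg.seed + 104729 * attempt)
        sizes = {len(n.leaf_nodes())
                 for n in cand.preorder_internal_node_iter()}
        if cfg.n_ingroup == 3 or 3 in sizes:
            ingroup = cand
            break
    if ingroup is None:
        raise RuntimeError("could not sample an ingroup tree with a "
                           "3-tip clade")
    _scale_tree(ingroup, cfg.ingroup_height)
    inner = ingroup.as_string(schema="newick", suppress_rooting=True)
    inner = inner.strip().rstrip(";")
    stem = cfg.outgroup_depth
    nw = f"({inner}:{stem * 0.5:.10f},OUT1:{stem:.10f})"
    for k in range(2, cfg.n_outgroup + 1):
        nw = f"({nw}:{stem * 0.5:.10f},OUT{k}:{stem * (1 + 0.5 * (k - 1)):.10f})"
    tree = dendropy.Tree.get(data=nw + ";", schema="newick")
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _random_gene(rng: np.random.Generator, length_nt: int) -> np.ndarray:
    """Random CDS: ATG + random sense codons + TAA, as int8 codes."""
    n_codons = max(length_nt // 3, 4)
    codons = rng.integers(0, 4, size=(n_codons, 3)).astype(np.int8)
    codons[0] = (0, 3, 2)  # ATG
    codons[-1] = (3, 0, 0)  # TAA
    _revert_stops(codons[1:-1], None, rng)
    return codons.reshape(-1)


def _revert_stops(codons: np.ndarray, parent_codons, rng) -> None:
    """Replace in-frame stop codons in place (parent codon, or resample)."""
    while True:
        is_stop = ((codons[:, 0] == 3) & (codons[:, 1] == 0) & (codons[:, 2] == 0)) | \
                  ((codons[:, 0] == 3) & (codons[:, 1] == 0) & (codons[:, 2] == 2)) | \
                  ((codons[:, 0] == 3) & (codons[:, 1] == 2) & (codons[:, 2] == 0))
        if not is_stop.any():
            return
        idx = np.flatnonzero(is_stop)
        if parent_codons is not None:
            codons[idx] = parent_codons[idx]
            return
        codons[idx] = rng.integers(0, 4, size=(idx.size, 3))


def _evolve_block(seq: np.ndarray, site_cat: np.ndarray, t: float,
                  model: SubstModel, rng: np.random.Generator) -> np.ndarray:
    """Evolve a concatenated int8 sequence for branch length t under GTR+G."""
    rates, _ = model.category_rates()
    child = seq.copy()
    for ci, rate in enumerate(rates):
        P = model.transition_matrix(t, rate)
        cum = np.cumsum(P, axis=1)
        in_cat = site_cat == ci
        for s in range(4):
            sel = in_cat & (seq == s)
            k = int(sel.sum())
            if k == 0:
                continue
            u = rng.random(k)
            child[sel] = np.searchsorted(cum[s], u).astype(np.int8)
    return child


def _fix_cds_stops(child: np.ndarray, parent: np.ndarray,
                   gene_spans: list) -> None:
    """Revert substitutions that created internal stop codons, per gene."""
    for lo, hi in gene_spans:
        c = child[lo:hi].reshape(-1, 3)
        p = parent[lo:hi].reshape(-1, 3)
        _revert_stops(c[1:-1], p[1:-1], None)
        child[lo:hi] = c.reshape(-1)


def simulate_alignment(tree: dendropy.Tree, n_sites: int, model: SubstModel,
                       seed: int) -> AlignmentMatrix:
    """Evolve a root-random alignment down the tree (no indels)."""
    rng = np.random.default_rng(seed)
    root_seq = rng.choice(4, size=n_sites, p=np.asarray(model.freqs)).astype(np.int8)
    _, weights = model.category_rates()
    site_cat = rng.integers(0, len(weights), size=n_sites)
    states = {tree.seed_node: root_seq}
    tips = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        states[node] = _evolve_block(states[node.parent_node], site_cat, t,
                                     model, rng)
        if node.is_leaf():
            tips[node.taxon.label] = states[node]
    taxa = sorted(tips)
    return AlignmentMatrix(taxa, np.vstack([tips[t] for t in taxa]))


# ---------------------------------------------------------------------------
# genome collection
# ---------------------------------------------------------------------------

def _branch_key(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def evolve_genomes(tree: dendropy.Tree, cfg: SimulationConfig):
    """Simulate the gene repertoire and sequences of every tip genome.

    Returns (list of AnnotatedGenome, GroundTruth).  Tips named OUT* are the
    outgroups; the HGT cassette's donor is OUT1 and its recipient is a small
    ingroup clade (non-sister to the donor).
    """
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(tips) < cfg.n_ingroup:
        raise ValueError("tree has fewer tips than cfg.n_ingroup")
    rng = np.random.default_rng(cfg.seed + 1)
    model = cfg.subst_params
    _, weights = model.category_rates()
    ncat = len(weights)

    glen = cfg.mean_gene_len - (cfg.mean_gene_len % 3)
    n_anc = cfg.n_ancestral_genes
    block_ids = [f"pls{i:04d}" for i in range(cfg.plasmid_block_size)]
    anc_ids = [f"anc{i:04d}" for i in range(n_anc)]
    cassette_ids = [f"hgt{i:04d}" for i in range(cfg.hgt_cassette_size)]

    # ancestral sequences: ordinary genes, the plasmid block, the cassette
    seqs0 = {}
    for gid in anc_ids + block_ids + cassette_ids:
        length = int(rng.integers(glen // 2, glen * 3 // 2)) // 3 * 3
        seqs0[gid] = _random_gene(rng, max(length, 90))

    donor = "OUT1" if "OUT1" in tips else tips[-1]
    ingroup_tips = [t for t in tips if not t.startswith("OUT")]
    # recipient: a small all-ingroup clade, preferring 3 tips (donor plus
    # three recipients keeps the cassette topology test informative), never
    # the whole ingroup
    recipient_node = None
    for want in (3, 2):
        for node in tree.preorder_internal_node_iter():
            sub = [lf.taxon.label for lf in node.leaf_iter()]
            if len(sub) == want and len(sub) < len(ingroup_tips) and \
                    all(t in ingroup_tips for t in sub):
                recipient_node = node
        if recipient_node is not None:
            break
    if recipient_node is None:
        raise ValueError("no suitable recipient clade in tree")
    recipient_tips = [lf.taxon.label for lf in recipient_node.leaf_iter()]

    # depth bookkeeping for the HGT transfer time
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    donor_leaf = next(lf for lf in tree.leaf_node_iter()
                      if lf.taxon.label == donor)
    transfer_depth = depth[recipient_node.parent_node] + \
        0.5 * (recipient_node.edge.length or 0.0)
    transfer_depth = min(transfer_depth, depth[donor_leaf] * 0.95)

    # per-gene site categories, fixed across the tree
    site_cat = {gid: rng.integers(0, ncat, size=s.size)
                for gid, s in seqs0.items()}

    events = []
    # presence + sequence state per node for ordinary genes and the block
    gene_state = {}  # node -> dict gid -> np.ndarray
    gain_counter = [0]
    presence_rows: dict = {}

    def evolve_gene(gid, parent_seq, t, local_rng):
        child = _evolve_block(parent_seq, site_cat[gid], t, model, local_rng)
        _fix_cds_stops(child, parent_seq, [(0, child.size)])
        return child

    root_state = {gid: seqs0[gid] for gid in anc_ids}
    root_state["__block__"] = True
    gene_state[tree.seed_node] = root_state

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = gene_state[node.parent_node]
        t = node.edge.length or 0.0
        state = {}
        # ordinary genes: loss then substitution
        p_loss = 1.0 - math.exp(-cfg.gene_loss_rate * t)
        for gid, seq in parent_state.items():
            if gid == "__block__":
                continue
            if rng.random() < p_loss:
                events.append((_branch_key(node), gid, "loss"))
                continue
            state[gid] = evolve_gene(gid, seq, t, rng)
        # gains: fresh genes
        n_genes = len(parent_state) - 1
        n_gain = rng.poisson(cfg.gene_gain_rate * n_genes * t)
        for _ in range(n_gain):
            gid = f"gain{gain_counter[0]:05d}"
            gain_counter[0] += 1
            length = int(rng.integers(glen // 2, glen * 3 // 2)) // 3 * 3
            seqs0[gid] = _random_gene(rng, max(length, 90))
            site_cat[gid] = rng.integers(0, ncat, size=seqs0[gid].size)
            state[gid] = seqs0[gid]
            events.append((_branch_key(node), gid, "gain"))
        # plasmid block: all-or-nothing loss
        if parent_state.get("__block__"):
            if rng.random() < p_loss:
                state["__block__"] = False
                events.append((_branch_key(node), "plasmid_block", "loss"))
            else:
                state["__block__"] = True
        else:
            state["__block__"] = False
        gene_state[node] = state

    # block sequences evolve like a linked unit along block-bearing lineages
    block_state = {tree.seed_node: {g: seqs0[g] for g in block_ids}}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        block_state[node] = {g: evolve_gene(g, s, t, rng)
                             for g, s in block_state[node.parent_node].items()}

    # HGT cassette: evolves along the donor path; copied at transfer_depth
    donor_path = []
    nd = donor_leaf
    while nd is not None:
        donor_path.append(nd)
        nd = nd.parent_node
    donor_path.reverse()  # root ... donor tip
    cass_state = {g: seqs0[g] for g in cassette_ids}
    cass_at_transfer = None
    d_prev = 0.0
    for nd in donor_path[1:]:
        d_next = depth[nd]
        if cass_at_transfer is None and d_next >= transfer_depth:
            dt = transfer_depth - d_prev
            cass_at_transfer = {g: evolve_gene(g, s, dt, rng)
                                for g, s in cass_state.items()}
            cass_state = {g: evolve_gene(g, s, d_next - transfer_depth, rng)
                          for g, s in cass_at_transfer.items()}
        else:
            cass_state = {g: evolve_gene(g, s, d_next - d_prev, rng)
                          for g, s in cass_state.items()}
        d_prev = d_next
    if cass_at_transfer is None:
        cass_at_transfer = cass_state
    donor_cassette = cass_state
    events.append((_branch_key(recipient_node), "hgt_cassette", "gain"))

    # evolve cassette within the recipient clade from the transferred state
    cass_by_tip = {donor: donor_cassette}
    rec_states = {recipient_node: cass_at_transfer}
    extra = max(depth[recipient_node] - transfer_depth, 0.0)
    rec_states[recipient_node] = {g: evolve_gene(g, s, extra, rng)
                                  for g, s in cass_at_transfer.items()}
    for node in recipient_node.preorder_iter():
        if node is recipient_node:
            continue
        t = node.edge.length or 0.0
        rec_states[node] = {g: evolve_gene(g, s, t, rng)
                            for g, s in rec_states[node.parent_node].items()}
        if node.is_leaf():
            cass_by_tip[node.taxon.label] = rec_states[node]

    # secondary within-ingroup transfer: the cassette spreads from the first
    # recipient tip's lineage (midway along its terminal branch) to an
    # ingroup tip outside the recipient clade.  This carrier nests inside
    # the recipient clade in the cassette's gene tree while sitting outside
    # it in the species tree, which is what makes the transfer detectable
    # from the carriers alone.
    second_recipient = None
    rec_set = set(recipient_tips)
    candidates = sorted(t for t in ingroup_tips if t not in rec_set)
    if candidates:
        second_recipient = candidates[0]
        src_leaf = min((lf for lf in recipient_node.leaf_iter()),
                       key=lambda lf: lf.taxon.label)
        half = 0.5 * (src_leaf.edge.length or 0.0)
        src_mid = {g: evolve_gene(g, s, half, rng)
                   for g, s in rec_states[src_leaf.parent_node].items()}
        cass_by_tip[second_recipient] = {
            g: evolve_gene(g, s, half, rng) for g, s in src_mid.items()}
        second_leaf = next(lf for lf in tree.leaf_node_iter()
                           if lf.taxon.label == second_recipient)
        events.append((_branch_key(second_leaf), "hgt_cassette", "gain"))

    # assemble per-tip genomes
    genomes = []
    all_gene_ids = anc_ids + [f"gain{i:05d}" for i in range(gain_counter[0])] \
        + block_ids + cassette_ids
    presence = pd.DataFrame(False, index=all_gene_ids, columns=tips)
    for leaf in tree.leaf_node_iter():
        tip = leaf.taxon.label
        state = gene_state[leaf]
        parts = {gid: seq for gid, seq in state.items() if gid != "__block__"}
        if state.get("__block__"):
            parts.update(block_state[leaf])
        if tip in cass_by_tip:
            parts.update(cass_by_tip[tip])
        genomes.append(_assemble_genome(tip, parts, cfg, rng))
        presence.loc[list(parts), tip] = True

    trait_rows = {
        "plasmid_block": {t: int(gene_state[lf].get("__block__", False))
                          for lf in tree.leaf_node_iter()
                          for t in [lf.taxon.label]},
        "hgt_cassette": {t: int(t in cass_by_tip) for t in tips},
    }
    trait_table = pd.DataFrame(trait_rows).T[tips]
    all_recipients = recipient_tips + ([second_recipient]
                                       if second_recipient else [])
    gt = GroundTruth(species_tree=tree, ortholog_table=presence,
                     events=events, trait_table=trait_table,
                     hgt_donor_label=donor,
                     hgt_recipient_tips=all_recipients)
    return genomes, gt


def _assemble_genome(strain: str, parts: dict, cfg: SimulationConfig,
                     rng: np.random.Generator) -> AnnotatedGenome:
    """One contig: genes in id order, random strands, 15% spacer DNA."""
    gene_ids = sorted(parts)
    gene_total = sum(parts[g].size for g in gene_ids)
    spacer_total = int(gene_total * SPACER_FRACTION / (1.0 - SPACER_FRACTION))
    n_gaps = len(gene_ids) + 1
    gap_len = spacer_total // n_gaps
    pieces = []
    cds = []
    pos = 0
    for gid in gene_ids:
        spacer = rng.integers(0, 4, size=gap_len).astype(np.int8)
        pieces.append(spacer)
        pos += gap_len
        seq = parts[gid]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            pieces.append(seq)
        else:
            pieces.append(_revcomp_codes(seq))
        cds.append(CDSRecord(gid, "contig1", pos, pos + seq.size, strand))
        pos += seq.size
    pieces.append(rng.integers(0, 4, size=gap_len).astype(np.int8))
    contig = "".join(CODE_NT[c] for c in np.concatenate(pieces))
    return AnnotatedGenome(strain, {"contig1": contig}, cds)


def _revcomp_codes(seq: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0], dtype=np.int8)
    return comp[seq][::-1]


def simulate_collection(cfg: SimulationConfig):
    """Convenience wrapper: collection tree + evolve_genomes."""
    tree = build_collection_tree(cfg)
    return tree, *evolve_genomes(tree, cfg)


# ---------------------------------------------------------------------------
# traits and growth curves
# ---------------------------------------------------------------------------

def _labelling_is_unique_optimum(tree, tip_states, internal_states,
                                 n_changes: int) -> bool:
    """True when no other internal labelling has <= ``n_changes`` changes.

    Exhaustive over all 2^(n internal nodes) labellings; only used at
    generation time on small trees.
    """
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    if len(internals) > 20:
        raise ValueError("tree too large for exhaustive identifiability check")
    truth = tuple(internal_states[id(n)] for n in internals)
    for bits in itertools.product((0, 1), repeat=len(internals)):
        if bits == truth:
            continue
        lab = dict(zip((id(n) for n in internals), bits))
        changes = 0
        for node in tree.preorder_node_iter():
            p = node.parent_node
            if p is None:
                continue
            s = tip_states[node.taxon.label] if node.is_leaf() \
                else lab[id(node)]
            if s != lab[id(p)]:
                changes += 1
                if changes > n_changes:
                    break
        if changes <= n_changes:
            return False
    return True


def simulate_trait_events(tree: dendropy.Tree, n_events: int, seed: int):
    """Place gain/loss events on branches so parsimony recovers them exactly.

    Candidate placements use mutually non-adjacent branches (no parent/child
    or sibling pairs); a placement is accepted only if the implied labelling
    is the *unique* minimum-change labelling of the resulting tip states,
    verified by exhaustive enumeration of internal labellings.  Returns (tip
    states dict, event list [(branch key, kind)]).
    """
    rng = np.random.default_rng(seed)
    nodes = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
    for _ in range(500):
        chosen = []
        cand = list(nodes)
        rng.shuffle(cand)
        for node in cand:
            ok = True
            for c in chosen:
                if node.parent_node is c or c.parent_node is node or \
                        node.parent_node is c.parent_node:
                    ok = False
                    break
            if ok:
                chosen.append(node)
            if len(chosen) == n_events:
                break
        if len(chosen) < n_events:
            continue
        toggled = set(id(n) for n in chosen)
        states = {}
        node_states = {}
        kinds = {}

        def walk(node, state):
            if id(node) in toggled:
                kinds[id(node)] = "gain" if state == 0 else "loss"
                state = 1 - state
            if node.is_leaf():
                states[node.taxon.label] = state
            else:
                node_states[id(node)] = state
            for c in node.child_nodes():
                walk(c, state)

        walk(tree.seed_node, 0)
        if not (0 < sum(states.values()) and all(k in kinds for k in toggled)):
            continue
        if _labelling_is_unique_optimum(tree, states, node_states, n_events):
            events = [(_branch_key(n), kinds[id(n)]) for n in chosen]
            return states, events
    raise RuntimeError("could not place identifiable events")


def simulate_od_series(rate: float, lag: float, carrying_od: float,
                       noise_sd: float, interval: float, n_points: int,
                       seed: int, od0: float = 0.01, strain: str = "sim",
                       treatment: str = "none",
                       replicate: str = "r1") -> GrowthSeries:
    """Logistic-with-lag OD750 trajectory with additive Gaussian noise.

    The trajectory is floored at the detection limit (0.001).  An infinite
    carrying OD gives pure exponential growth.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points, dtype=float) * interval
    te = np.clip(t - lag, 0.0, None)
    if math.isinf(carrying_od):
        od = od0 * np.exp(rate * te)
    else:
        g = np.exp(rate * te)
        od = carrying_od * od0 * g / (carrying_od + od0 * (g - 1.0))
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=n_points)
    od = np.clip(od, OD_DETECTION_FLOOR, None)
    return GrowthSeries(strain, treatment, replicate, t, od)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_collection(out_dir: str, tree: dendropy.Tree, genomes: list,
                     gt: GroundTruth) -> None:
    """Per-strain FASTA/GFF3 plus collection-level tree, tables, event log."""
    os.makedirs(out_dir, exist_ok=True)
    for g in genomes:
        write_genome_dir(g, os.path.join(out_dir, g.strain))
    with open(os.path.join(out_dir, "species_tree.nwk"), "w") as fh:
        fh.write(tree.as_string(schema="newick"))
    gt.ortholog_table.astype(int).to_csv(
        os.path.join(out_dir, "ortholog_table.tsv"), sep="\t",
        index_label="gene")
    gt.trait_table.to_csv(os.path.join(out_dir, "trait_table.tsv"), sep="\t",
                          index_label="trait")
    pd.DataFrame(gt.events, columns=["branch", "unit", "event"]).to_csv(
        os.path.join(out_dir, "events.tsv"), sep="\t", index=False)
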