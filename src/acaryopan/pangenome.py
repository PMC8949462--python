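"""Presence/absence calling and core-genome set algebra.

The two search directions are merged into per-genome nonredundant gene sets
keyed by reference CDS ids; a gene belongs to the core when it is detected in
at least ``min_genomes`` of the ingroup genomes (n-1 of n by default), to the
strict core when detected in all of them, and to the unique core when it is a
core gene absent from every designated outgroup genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import AnnotatedGenome


@dataclass
class PresenceMatrix:
    """Boolean genes x genomes table with per-cell evidence provenance."""

    table: pd.DataFrame  # bool, index=gene ids, columns=strain ids
    evidence: dict = field(default_factory=dict)  # (gene, genome) -> 'nt'|'prot'|'both'

    def __post_init__(self):
        if self.table.dtypes.ne(bool).any():
            self.table = self.table.astype(bool)
        for (g, s), ev in self.evidence.items():
            if not self.table.at[g, s]:
                raise ValueError(f"evidence for absent cell ({g}, {s})")

    def to_tsv(self, path: str) -> None:
        self.table.astype(int).to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read_tsv(cls, path: str) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene").astype(bool)
        return cls(df)


@dataclass
class CoreSets:
    core: set
    strict_core: set
    unique_core: set
    venn: dict  # 7 region counts over {core, outgroup1, outgroup2}

    def summary_json(self) -> str:
        return json.dumps({
            "n_core": len(self.core),
            "n_strict_core": len(self.strict_core),
            "n_unique_core": len(self.unique_core),
            "venn": self.venn,
        }, indent=2, sort_keys=True)


def assign_protein_hits_to_reference_genes(hits: list,
                                           reference: AnnotatedGenome,
                                           min_overlap_frac: float = 0.5) -> dict:
    """Credit direction-2 hits (reference nucleotide coordinates) to CDS.

    A hit credits reference gene g iff its target span overlaps g's CDS span
    by >= min_overlap_frac of the shorter of the two intervals, either strand.
    Returns {genome id: set of credited reference gene ids}.
    """
    by_contig: dict = {}
    for r in reference.cds:
        by_contig.setdefault(r.contig, []).append(r)
    out: dict = {}
    for h in hits:
        if h.target_contig not in reference.contigs:
            raise ValueError(
                f"hit contig {h.target_contig!r} absent from reference "
                f"{reference.strain!r} — coordinate mismatch")
        hs, he = h.target_span
        for r in by_contig.get(h.target_contig, ()):
            ov = min(he, r.end) - max(hs, r.start)
            shorter = min(he - hs, r.length)
            if shorter > 0 and ov >= min_overlap_frac * shorter:
                out.setdefault(_hit_genome(h), set()).add(r.gene_id)
    return out


def _hit_genome(h) -> str:
    # for direction-2 hits the query comes from the target genome; callers
    # tag query ids as "<genome>|<protein id>"
    return h.query_id.split("|", 1)[0]


def merge_nonredundant(nt_presence: dict, prot_presence: dict) -> dict:
    """Union the two directions into per-genome nonredundant gene sets.

    Inputs map genome id -> iterable of reference gene ids (duplicates fine).
    Returns {genome: {gene: 'nt'|'prot'|'both'}}.
    """
    out: dict = {}
    for genome, genes in nt_presence.items():
        d = out.setdefault(genome, {})
        for g in genes:
            d[g] = "nt"
    for genome, genes in prot_presence.items():
        d = out.setdefault(genome, {})
        for g in genes:
            d[g] = "both" if d.get(g) == "nt" else d.get(g, "prot")
    return out


def build_presence_matrix(merged: dict, gene_ids: list, genome_ids: list) -> PresenceMatrix:
    """Assemble the matrix from merged per-genome gene sets."""
    arr = np.zeros((len(gene_ids), len(genome_ids)), dtype=bool)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    evidence = {}
    for j, genome in enumerate(genome_ids):
        for g, ev in merged.get(genome, {}).items():
            if g in gidx:
                arr[gidx[g], j] = True
                evidence[(g, genome)] = ev
    table = pd.DataFrame(arr, index=gene_ids, columns=genome_ids)
    return PresenceMatrix(table, evidence)


def core_sets(m: PresenceMatrix, min_genomes: int,
              outgroup_presence: dict) -> CoreSets:
    """Core / strict-core / unique-core sets and the 3-way Venn partition.

    ``outgroup_presence`` maps each outgroup strain id to the set of reference
    gene ids detected in it (the matrix columns are ingroup genomes only).
    """
    n = m.table.shape[1]
    if min_genomes > n:
        raise ValueError(f"min_genomes={min_genomes} exceeds {n} genomes")
    row_sums = m.table.sum(axis=1)
    core = set(m.table.index[row_sums >= min_genomes])
    strict = set(m.table.index[row_sums == n])
    og_names = list(outgroup_presence)
    og_union = set().union(*outgroup_presence.values()) if outgroup_presence else set()
    unique_core = core - og_union
    sets = {"core": core}
    for name in og_names[:2]:
        sets[name] = set(outgroup_presence[name])
    venn = _venn3_counts(sets)
    return CoreSets(core, strict, unique_core, venn)


def _venn3_counts(sets: dict) -> dict:
    """Region counts for up to 3 labelled sets ('A', 'A&B', ... keys)."""
    names = list(sets)
    universe = set().union(*sets.values()) if sets else set()
    venn = {}
    from itertools import combinations
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) \
                if k < len(names) else set()
            venn["&".join(combo)] = len(inside - outside)
    venn["union"] = len(universe)
    return venn


def call_presence(reference: AnnotatedGenome, genomes: list,
                  max_e: float = 0.01, min_identity: float = 50.0,
                  min_coverage: float = 0.5, min_overlap_frac: float = 0.5,
                  exhaustive: bool = False) -> PresenceMatrix:
    """Run both search directions for every genome and build the matrix.

    Direction 1: each reference CDS (blastn-style) vs each target assembly,
    E <= max_e.  Direction 2: each target protein (tblastn-style) vs the
    six-frame reference genome with the 50%/50% identity/coverage filters,
    credited to reference CDS by coordinate overlap.
    """
    from .alignment import ScoringScheme
    from .homology import (GenomeIndex, ReferenceFrameIndex,
                           search_gene_vs_genome, search_protein_vs_reference)

    s_nt = ScoringScheme.nucleotide()
    s_pr = ScoringScheme.protein()
    ref_cds = {r.gene_id: reference.cds_seq(r) for r in reference.cds}
    ridx = ReferenceFrameIndex(reference, s_pr)

    nt_presence: dict = {}
    prot_hits: list = []
    for genome in genomes:
        gidx = GenomeIndex(genome, s_nt)
        found = set()
        for gene_id, seq in ref_cds.items():
            if search_gene_vs_genome(gene_id, seq, genome, s_nt, max_e,
                                     exhaustive=exhaustive, index=gidx):
                found.add(gene_id)
        nt_presence[genome.strain] = found
        for r in genome.cds:
            prot = genome.protein_seq(r)
            if not prot:
                continue
            hits = search_protein_vs_reference(
                f"{genome.strain}|{r.gene_id}", prot, ridx, max_e=max_e,
                min_identity=min_identity, min_coverage=min_coverage,
                exhaustive=exhaustive)
            prot_hits.extend(hits)
    prot_presence = assign_protein_hits_to_reference_genes(
        prot_hits, reference, min_overlap_frac)
    merged = merge_nonredundant(nt_presence, prot_presence)
    return build_presence_matrix(merged, list(ref_cds),
                                 [g.strain for g in genomes])
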