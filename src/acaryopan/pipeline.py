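"""End-to-end orchestration of the analysis stages with a run manifest.

``run_pipeline`` executes the selected stages in fixed order —
simulate -> search -> pangenome -> tree -> shtest -> traits -> ironclust ->
growth — against a plain-file directory layout (one subdirectory per stage
under the output directory), logging to stderr and emitting a JSON manifest
with the configuration hash, seeds, library versions, and a SHA-256 checksum
of every file each stage wrote.  Reruns with the same configuration reproduce
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__

log = logging.getLogger("acaryopan")

STAGES = ("simulate", "search", "pangenome", "tree", "shtest", "traits",
          "ironclust", "growth")

# one-line rationale for each analysis default, echoed into the manifest
DEFAULT_NOTES = {
    "max_e": "E-value cutoff 0.01 applied to both search directions",
    "min_identity": "tblastn-direction hits additionally need >= 50% identity",
    "min_coverage": "tblastn-direction hits additionally need >= 50% query coverage",
    "core_missing_allowance": "core genes may be absent from at most 1 genome",
    "bootstrap_B": "RELL/bootstrap replicate count",
    "min_doublings": "growth rates reported only after >= 3 population doublings",
    "alpha": "significance level for the SH test verdict",
}


class PipelineError(RuntimeError):
    """A stage could not run; the message names the stage and the problem."""


@dataclass
class RunConfig:
    """Stage selection plus every stage parameter, with conventional defaults."""

    stages: tuple = STAGES
    seed: int = 0
    # search / pangenome
    max_e: float = 0.01
    min_identity: float = 50.0
    min_coverage: float = 0.5
    min_overlap_frac: float = 0.5
    core_missing_allowance: int = 1
    # congruence / clustering
    bootstrap_B: int = 1000
    au_B_per_scale: int = 200
    alpha: float = 0.05
    shtest_gene: str = ""  # empty -> first hgt* gene present in >= 4 strains
    # growth
    min_doublings: float = 3.0
    # simulate stage
    sim_n_ingroup: int = 6
    sim_n_outgroup: int = 2
    sim_n_genes: int = 60
    sim_mean_gene_len: int = 300

    def __post_init__(self):
        self.stages = tuple(self.stages)
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise PipelineError(
                f"unknown stage(s) {bad}; valid stages: {list(STAGES)}")
        if self.max_e <= 0:
            raise PipelineError("max_e must be positive")
        if self.core_missing_allowance < 0:
            raise PipelineError("core_missing_allowance must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"unknown config keys {sorted(unknown)}; "
                                f"valid keys: {sorted(known)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksum_dir(root: str) -> dict:
    out = {}
    for dirpath, _, files in os.walk(root):
        for name in sorted(files):
            p = os.path.join(dirpath, name)
            out[os.path.relpath(p, root)] = _sha256(p)
    return dict(sorted(out.items()))


def _library_versions() -> dict:
    import Bio
    import dendropy
    import numba
    import scipy
    return {
        "python": platform.python_version(),
        "acaryopan": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "biopython": Bio.__version__,
        "dendropy": dendropy.__version__,
        "numba": numba.__version__,
    }


# ---------------------------------------------------------------------------
# shared helpers over the directory layout
# ---------------------------------------------------------------------------

def _strain_dirs(data_dir: str) -> list:
    """Strain ids found as genome subdirectories of ``data_dir``."""
    out = []
    for name in sorted(os.listdir(data_dir)):
        sub = os.path.join(data_dir, name)
        if os.path.isdir(sub) and os.path.exists(
                os.path.join(sub, f"{name}.fna")):
            out.append(name)
    return out


def _load_genomes(data_dir: str) -> dict:
    from .seqio import read_genome_dir
    strains = _strain_dirs(data_dir)
    if not strains:
        raise PipelineError(f"no genome subdirectories under {data_dir}")
    return {s: read_genome_dir(s, os.path.join(data_dir, s)) for s in strains}


def _reference_strain(strains: list) -> str:
    ingroup = [s for s in strains if not s.startswith("OUT")]
    if not ingroup:
        raise PipelineError("no ingroup strains (all strain ids start OUT)")
    return ingroup[0]


def _gene_alignment(genomes: dict, gene_ids: list, strains: list):
    """Equal-length CDS of the given genes concatenated per strain.

    Strains missing any of the genes, and genes whose copies differ in
    length across strains, are dropped (the simulator mutates without
    indels, so orthologous copies are alignable as-is).
    """
    from .phylo import AlignmentMatrix, concatenate
    per_strain_cds = {}
    for s in strains:
        per_strain_cds[s] = {r.gene_id: genomes[s].cds_seq(r)
                             for r in genomes[s].cds}
    blocks = []
    for gid in gene_ids:
        seqs = {s: per_strain_cds[s][gid] for s in strains
                if gid in per_strain_cds[s]}
        if len(seqs) < len(strains):
            continue
        if len({len(x) for x in seqs.values()}) != 1:
            continue
        blocks.append(AlignmentMatrix.from_dict(seqs))
    if not blocks:
        raise PipelineError("no shared equal-length genes to align")
    return concatenate(blocks)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: str) -> str:
    from .synthetic import (SimulationConfig, simulate_collection,
                            simulate_od_series, write_collection)
    sim = SimulationConfig(n_ingroup=cfg.sim_n_ingroup,
                           n_outgroup=cfg.sim_n_outgroup,
                           n_ancestral_genes=cfg.sim_n_genes,
                           mean_gene_len=cfg.sim_mean_gene_len,
                           seed=cfg.seed)
    tree, genomes, truth = simulate_collection(sim)
    write_collection(out, tree, genomes, truth)
    # OD table: the plasmid-block trait confers growth under the salt
    # treatment; control growth is uniform
    rows = []
    block = truth.trait_table.loc["plasmid_block"]
    for i, g in enumerate(genomes):
        for treatment in ("control", "salt"):
            if treatment == "control":
                rate = 0.03
            else:
                rate = 0.03 if int(block.get(g.strain, 0)) else 0.004
            for rep in range(1, 4):
                series = simulate_od_series(
                    rate=rate, lag=6.0, carrying_od=0.8, noise_sd=0.0005,
                    interval=12.0, n_points=20,
                    seed=cfg.seed + 7919 * i + 101 * rep
                    + (0 if treatment == "control" else 13),
                    strain=g.strain, treatment=treatment,
                    replicate=f"r{rep}")
                for t, od in zip(series.time_h, series.od):
                    rows.append((g.strain, treatment, f"r{rep}",
                                 float(t), float(od)))
    pd.DataFrame(rows, columns=["strain", "treatment", "replicate",
                                "time_h", "od750"]).to_csv(
        os.path.join(out, "od.tsv"), sep="\t", index=False,
        float_format="%.6g")
    return out


def _stage_search(cfg: RunConfig, data_dir: str, out: str) -> None:
    from .alignment import ScoringScheme
    from .homology import (GenomeIndex, ReferenceFrameIndex, hits_to_tabular,
                           search_gene_vs_genome, search_protein_vs_reference)
    genomes = _load_genomes(data_dir)
    ref_id = _reference_strain(list(genomes))
    reference = genomes[ref_id]
    s_nt = ScoringScheme.nucleotide()
    s_pr = ScoringScheme.protein()
    ref_cds = {r.gene_id: reference.cds_seq(r) for r in reference.cds}
    ridx = ReferenceFrameIndex(reference, s_pr)
    with open(os.path.join(out, "reference.txt"), "w") as fh:
        fh.write(ref_id + "\n")
    for strain, genome in genomes.items():
        gidx = GenomeIndex(genome, s_nt)
        nt_hits = []
        for gid, seq in ref_cds.items():
            nt_hits.extend(search_gene_vs_genome(
                gid, seq, genome, s_nt, cfg.max_e, index=gidx))
        with open(os.path.join(out, f"{strain}.nt.tsv"), "w") as fh:
            fh.write(hits_to_tabular(nt_hits))
        prot_hits = []
        for r in genome.cds:
            prot = genome.protein_seq(r)
            if prot:
                prot_hits.extend(search_protein_vs_reference(
                    f"{strain}|{r.gene_id}", prot, ridx, max_e=cfg.max_e,
                    min_identity=cfg.min_identity,
                    min_coverage=cfg.min_coverage))
        with open(os.path.join(out, f"{strain}.prot.tsv"), "w") as fh:
            fh.write(hits_to_tabular(prot_hits))
        log.info("search: %s -> %d nt / %d prot hits", strain,
                 len(nt_hits), len(prot_hits))


def presence_from_hits(hits_dir: str, reference, strains: list,
                       min_overlap_frac: float = 0.5):
    """Rebuild the presence matrix from per-strain tabular hit files."""
    from .homology import read_hits_tabular
    from .pangenome import (assign_protein_hits_to_reference_genes,
                            build_presence_matrix, merge_nonredundant)
    gene_ids = [r.gene_id for r in reference.cds]
    known = set(gene_ids)
    nt_presence = {}
    prot_hits = []
    for strain in strains:
        nt_path = os.path.join(hits_dir, f"{strain}.nt.tsv")
        prot_path = os.path.join(hits_dir, f"{strain}.prot.tsv")
        if not (os.path.exists(nt_path) and os.path.exists(prot_path)):
            raise PipelineError(f"pangenome: missing hit files for {strain} "
                                f"under {hits_dir}")
        nt_presence[strain] = {h.query_id
                               for h in read_hits_tabular(nt_path)
                               if h.query_id in known}
        prot_hits.extend(read_hits_tabular(prot_path))
    prot_presence = assign_protein_hits_to_reference_genes(
        prot_hits, reference, min_overlap_frac)
    merged = merge_nonredundant(nt_presence, prot_presence)
    return build_presence_matrix(merged, gene_ids, strains)


def _stage_pangenome(cfg: RunConfig, data_dir: str, hits_dir: str,
                     out: str) -> None:
    from .pangenome import core_sets
    genomes = _load_genomes(data_dir)
    strains = list(genomes)
    ref_id = _reference_strain(strains)
    ingroup = [s for s in strains if not s.startswith("OUT")]
    outgroups = [s for s in strains if s.startswith("OUT")]
    pm_all = presence_from_hits(hits_dir, genomes[ref_id], strains,
                                cfg.min_overlap_frac)
    pm = type(pm_all)(pm_all.table[ingroup],
                      {k: v for k, v in pm_all.evidence.items()
                       if k[1] in ingroup})
    pm.to_tsv(os.path.join(out, "presence_matrix.tsv"))
    og_presence = {og: set(pm_all.table.index[pm_all.table[og]])
                   for og in outgroups}
    cs = core_sets(pm, len(ingroup) - cfg.core_missing_allowance, og_presence)
    with open(os.path.join(out, "core_summary.json"), "w") as fh:
        fh.write(cs.summary_json() + "\n")
    rows = [(g, int(g in cs.core), int(g in cs.strict_core),
             int(g in cs.unique_core)) for g in sorted(pm.table.index)]
    pd.DataFrame(rows, columns=["gene", "core", "strict_core",
                                "unique_core"]).to_csv(
        os.path.join(out, "core_sets.tsv"), sep="\t", index=False)


def _stage_tree(cfg: RunConfig, data_dir: str, pangenome_dir: str,
                out: str) -> None:
    from .pangenome import PresenceMatrix
    from .phylo import (neighbor_joining, pairwise_distance,
                        write_alignment_fasta, write_distance_tsv)
    pm_path = os.path.join(pangenome_dir, "presence_matrix.tsv")
    if not os.path.exists(pm_path):
        raise PipelineError(f"tree: missing {pm_path} (run pangenome first)")
    pm = PresenceMatrix.read_tsv(pm_path)
    genomes = _load_genomes(data_dir)
    strains = list(genomes)
    strict = [g for g in pm.table.index
              if pm.table.loc[g].all() and not g.startswith(("hgt", "pls"))]
    aln = _gene_alignment(genomes, strict, strains)
    write_alignment_fasta(aln, os.path.join(out, "core_alignment.fasta"))
    d = pairwise_distance(aln, "JC")
    write_distance_tsv(d, aln.taxa, os.path.join(out, "distances.tsv"))
    tree = neighbor_joining(d, aln.taxa)
    with open(os.path.join(out, "species_tree.nwk"), "w") as fh:
        fh.write(tree.as_string(schema="newick"))


def _stage_shtest(cfg: RunConfig, data_dir: str, tree_dir: str,
                  out: str) -> None:
    from .congruence import hgt_verdict
    from .phylo import read_alignment_fasta
    sp_path = os.path.join(tree_dir, "core_alignment.fasta")
    if not os.path.exists(sp_path):
        raise PipelineError(f"shtest: missing {sp_path} (run tree first)")
    species_aln = read_alignment_fasta(sp_path)
    genomes = _load_genomes(data_dir)
    if cfg.shtest_gene:
        genes = [cfg.shtest_gene]
    else:
        # test the whole mobile cassette: all hgt-prefixed genes present in
        # >= 4 strains, concatenated (the cassette transfers as one unit)
        counts: dict = {}
        for g in genomes.values():
            for r in g.cds:
                if r.gene_id.startswith("hgt"):
                    counts[r.gene_id] = counts.get(r.gene_id, 0) + 1
        genes = sorted(g for g, c in counts.items() if c >= 4)
        if not genes:
            raise PipelineError("shtest: no candidate gene present in >= 4 "
                                "strains; set shtest_gene explicitly")
    carriers = [s for s in genomes
                if all(gid in {r.gene_id for r in genomes[s].cds}
                       for gid in genes)]
    gene_aln = _gene_alignment(genomes, genes, carriers)
    report = hgt_verdict(species_aln, gene_aln, B=cfg.bootstrap_B,
                         seed=cfg.seed, alpha=cfg.alpha)
    report["gene"] = ",".join(genes)
    with open(os.path.join(out, "shtest.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage_traits(cfg: RunConfig, data_dir: str, tree_dir: str,
                  out: str) -> None:
    import dendropy

    from .traits import dollo_reconstruction, fitch_parsimony, trait_column
    trait_path = os.path.join(data_dir, "trait_table.tsv")
    tree_path = os.path.join(tree_dir, "species_tree.nwk")
    for p, hint in ((trait_path, "trait_table.tsv in the data directory"),
                    (tree_path, "species_tree.nwk (run tree first)")):
        if not os.path.exists(p):
            raise PipelineError(f"traits: missing {hint}: {p}")
    df = pd.read_csv(trait_path, sep="\t", index_col="trait")
    tree = dendropy.Tree.get(path=tree_path, schema="newick")
    rows = []
    for trait in df.index:
        states = {s: (None if pd.isna(v) else int(v))
                  for s, v in df.loc[trait].items()}
        fitch = fitch_parsimony(tree, states)
        dollo = dollo_reconstruction(tree, states)
        for key, kind in fitch.events:
            rows.append((trait, "fitch", key, kind))
        for key, kind in dollo.events:
            rows.append((trait, "dollo", key, kind))
        rows.append((trait, "summary",
                     f"fitch_changes={fitch.n_changes}",
                     f"dollo_events={len(dollo.events)}"))
    pd.DataFrame(rows, columns=["trait", "method", "branch", "event"]).to_csv(
        os.path.join(out, "trait_events.tsv"), sep="\t", index=False)


def _stage_ironclust(cfg: RunConfig, data_dir: str, pangenome_dir: str,
                     out: str) -> None:
    from .profiles import (cluster_support, dendrogram_newick, hcluster,
                           read_category_counts)
    counts_path = os.path.join(data_dir, "category_counts.tsv")
    if os.path.exists(counts_path):
        counts = read_category_counts(counts_path)
    else:
        # derive a category table from the presence matrix: gene-id prefix
        # classes act as the functional categories
        from .pangenome import PresenceMatrix
        pm_path = os.path.join(pangenome_dir, "presence_matrix.tsv")
        if not os.path.exists(pm_path):
            raise PipelineError("ironclust: need category_counts.tsv in the "
                                f"data directory or {pm_path}")
        pm = PresenceMatrix.read_tsv(pm_path)
        prefix = pm.table.index.str.replace(r"\d+$", "", regex=True)
        counts = pm.table.astype(int).groupby(prefix).sum().T
        counts.index.name = "strain"
    if counts.shape[0] >= 3:
        support = cluster_support(counts.astype(float),
                                  B_per_scale=cfg.au_B_per_scale,
                                  seed=cfg.seed)
        support.table().to_csv(os.path.join(out, "cluster_support.tsv"),
                               sep="\t", index=False)
        # per-merge AU labels in merge order
        newick = dendrogram_newick(support.linkage, support.strains,
                                   support.au)
    else:
        Z = hcluster(counts.astype(float))
        newick = dendrogram_newick(Z, list(counts.index))
    with open(os.path.join(out, "dendrogram.nwk"), "w") as fh:
        fh.write(newick + "\n")


def _stage_growth(cfg: RunConfig, data_dir: str, out: str) -> None:
    from .growth import compare_rates, estimates_table, fit_rate, read_od_table
    od_path = os.path.join(data_dir, "od.tsv")
    if not os.path.exists(od_path):
        raise PipelineError(f"growth: missing OD table {od_path}")
    series = read_od_table(od_path)
    estimates = [fit_rate(s, min_doublings=cfg.min_doublings) for s in series]
    estimates_table(estimates).to_csv(os.path.join(out, "rates.tsv"),
                                      sep="\t", index=False,
                                      float_format="%.8g")
    groups: dict = {}
    for e in estimates:
        if e.status == "estimated":
            groups.setdefault(f"{e.strain}:{e.treatment}", []).append(e.rate)
    strains = sorted({e.strain for e in estimates})
    pairs = [(f"{s}:control", f"{s}:salt") for s in strains
             if f"{s}:control" in groups or f"{s}:salt" in groups]
    compare_rates(groups, pairs).to_csv(
        os.path.join(out, "comparisons.tsv"), sep="\t", index=False,
        float_format="%.8g")


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig, input_dir: str | None, out_dir: str) -> dict:
    """Run the selected stages and return (and write) the run manifest."""
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": _library_versions(),
        "default_notes": DEFAULT_NOTES,
        "stages": {},
    }
    data_dir = input_dir
    stage_dir = {s: os.path.join(out_dir, s) for s in STAGES}

    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        out = stage_dir[stage]
        os.makedirs(out, exist_ok=True)
        log.info("stage %s -> %s", stage, out)
        if stage == "simulate":
            data_dir = _stage_simulate(cfg, out)
        elif data_dir is None:
            raise PipelineError(
                f"{stage}: no input data (enable the simulate stage or pass "
                "an input directory)")
        elif stage == "search":
            _stage_search(cfg, data_dir, out)
        elif stage == "pangenome":
            _stage_pangenome(cfg, data_dir, stage_dir["search"], out)
        elif stage == "tree":
            _stage_tree(cfg, data_dir, stage_dir["pangenome"], out)
        elif stage == "shtest":
            _stage_shtest(cfg, data_dir, stage_dir["tree"], out)
        elif stage == "traits":
            _stage_traits(cfg, data_dir, stage_dir["tree"], out)
        elif stage == "ironclust":
            _stage_ironclust(cfg, data_dir, stage_dir["pangenome"], out)
        elif stage == "growth":
            _stage_growth(cfg, data_dir, out)
        manifest["stages"][stage] = {"files": _checksum_dir(out)}

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
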