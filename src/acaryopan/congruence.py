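"""Shimodaira-Hasegawa topology-congruence test and the HGT verdict built on it.

The SH test asks whether candidate topologies explain an alignment
significantly worse than the best candidate.  The null distribution is
obtained by RELL resampling: per-site log-likelihoods are bootstrapped
(no branch-length re-optimization), each topology's replicate totals are
centered on their own mean, and the p-value for topology T is the fraction of
replicates in which ``max_T' centered(T') - centered(T)`` is at least the
observed ``lnL(best) - lnL(T)``.

With exactly two topologies the test is still the SH max-over-set form
(two-sided in the SH sense).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo import (AlignmentMatrix, SubstModel, neighbor_joining,
                    optimize_branch_lengths, pairwise_distance, site_loglik)


@dataclass
class SHResult:
    """Per-topology optimized lnL, delta versus best, and SH p-value."""

    names: list
    lnl: np.ndarray
    delta: np.ndarray  # lnL(best) - lnL(T), >= 0
    p_values: np.ndarray
    B: int
    seed: int

    @property
    def best(self) -> str:
        return self.names[int(np.argmin(self.delta))]

    def as_dict(self) -> dict:
        return {name: {"lnL": float(l), "delta": float(d), "p": float(p)}
                for name, l, d, p in zip(self.names, self.lnl, self.delta,
                                         self.p_values)}


def sh_test(site_lls: dict, B: int = 1000, seed: int = 0) -> SHResult:
    """SH test on per-site log-likelihood vectors of >= 2 candidate topologies.

    ``site_lls`` maps topology name -> 1-D array of per-site lnL, all on the
    same sites.
    """
    if len(site_lls) < 2:
        raise ValueError("need >= 2 topologies")
    if B < 100:
        raise ValueError("B must be >= 100")
    names = list(site_lls)
    mat = np.vstack([np.asarray(site_lls[n], dtype=float) for n in names])
    if np.unique([len(v) for v in site_lls.values()]).size != 1:
        raise ValueError("site-count mismatch across topologies")
    ntop, nsites = mat.shape
    totals = mat.sum(axis=1)
    delta = totals.max() - totals

    rng = np.random.default_rng(seed)
    rep_totals = np.empty((ntop, B))
    for b in range(B):
        idx = rng.integers(0, nsites, size=nsites)
        rep_totals[:, b] = mat[:, idx].sum(axis=1)
    centered = rep_totals - rep_totals.mean(axis=1, keepdims=True)
    rep_delta = centered.max(axis=0)[None, :] - centered  # (ntop, B)
    p = (rep_delta >= delta[:, None] - 1e-12).mean(axis=1)
    return SHResult(names, totals, delta, p, B, seed)


def _build_topology(aln: AlignmentMatrix):
    try:
        d = pairwise_distance(aln, "JC")
    except ValueError:
        d = pairwise_distance(aln, "p")
    return neighbor_joining(d, aln.taxa)


def hgt_verdict(species_alignment: AlignmentMatrix,
                gene_alignment: AlignmentMatrix,
                model: SubstModel | None = None, B: int = 1000,
                seed: int = 0, alpha: float = 0.05) -> dict:
    """Two-hypothesis HGT procedure on a species and a gene alignment.

    Builds one topology from each alignment (restricted to the shared taxa),
    optimizes branch lengths of both on the *gene* alignment, and runs the SH
    test on the gene alignment's per-site log-likelihoods.  Vertical
    inheritance predicts the gene data cannot reject the species topology;
    rejection (p < alpha for the species topology) is reported as consistent
    with horizontal transfer.
    """
    if model is None:
        model = SubstModel(alpha=1.0)
    shared = [t for t in species_alignment.taxa if t in set(gene_alignment.taxa)]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared taxa for an informative contrast")
    sp_aln = species_alignment.subset(shared)
    gn_aln = gene_alignment.subset(shared)
    species_tree = _build_topology(sp_aln)
    gene_tree = _build_topology(gn_aln)

    lls = {}
    lnls = {}
    for name, tree in (("species", species_tree), ("gene", gene_tree)):
        lnls[name] = optimize_branch_lengths(tree, gn_aln, model)
        lls[name] = site_loglik(tree, gn_aln, model).per_site
    res = sh_test(lls, B=B, seed=seed)
    d = res.as_dict()
    p_species = d["species"]["p"]
    verdict = ("congruent (vertical inheritance not rejected)"
               if p_species >= alpha else "incongruent (consistent with HGT)")
    return {
        "verdict": verdict,
        "alpha": alpha,
        "p_species": p_species,
        "delta_lnl_species": d["species"]["delta"],
        "topologies": d,
        "n_shared_taxa": len(shared),
        "note": ("both topologies evaluated on the gene alignment; "
                 "RELL with B=%d" % B),
    }
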