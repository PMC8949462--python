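"""Desk-scale tree machinery: distances, neighbor joining, GTR+Gamma(+I)
per-site log-likelihoods by Felsenstein pruning, and nonparametric bootstrap.

Trees are :class:`dendropy.Tree` objects throughout (branch lengths in
expected substitutions per site); alignments are :class:`AlignmentMatrix`,
a thin integer-coded matrix over {A, C, G, T, -, N}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 4}
CODE_NT = "ACGT-"


@dataclass
class AlignmentMatrix:
    """Aligned equal-length sequences; codes 0-3 = ACGT, 4 = gap/missing."""

    taxa: list
    data: np.ndarray  # int8, shape (n_taxa, n_sites)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("data shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_dict(cls, seqs: dict) -> "AlignmentMatrix":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise ValueError("sequences differ in length")
        data = np.array([[NT_CODE[c] for c in seqs[t].upper()] for t in taxa],
                        dtype=np.int8)
        return cls(taxa, data)

    def to_dict(self) -> dict:
        return {t: "".join(CODE_NT[c] for c in row)
                for t, row in zip(self.taxa, self.data)}

    def subset(self, taxa: list) -> "AlignmentMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return AlignmentMatrix(list(taxa), self.data[idx])


def read_alignment_fasta(path: str) -> AlignmentMatrix:
    from .seqio import read_fasta
    return AlignmentMatrix.from_dict(read_fasta(path))


def write_alignment_fasta(aln: AlignmentMatrix, path: str) -> None:
    from .seqio import write_fasta
    write_fasta(aln.to_dict(), path)


def read_alignment_phylip(path: str) -> AlignmentMatrix:
    """Relaxed sequential PHYLIP: header 'ntaxa nsites', then 'name  seq'."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("PHYLIP header must be 'ntaxa nsites'")
        n_taxa, n_sites = int(header[0]), int(header[1])
        seqs = {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            seqs[name] = "".join(seq.split())
    if len(seqs) != n_taxa or any(len(s) != n_sites for s in seqs.values()):
        raise ValueError("PHYLIP body does not match header dimensions")
    return AlignmentMatrix.from_dict(seqs)


def write_alignment_phylip(aln: AlignmentMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(aln.taxa)} {aln.n_sites}\n")
        for taxon, seq in aln.to_dict().items():
            fh.write(f"{taxon}  {seq}\n")


def write_distance_tsv(d: np.ndarray, labels: list, path: str) -> None:
    import pandas as pd
    pd.DataFrame(d, index=labels, columns=labels).to_csv(
        path, sep="\t", index_label="taxon", float_format="%.10g")


def read_distance_tsv(path: str):
    import pandas as pd
    df = pd.read_csv(path, sep="\t", index_col="taxon")
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix rows and columns disagree")
    return df.to_numpy(dtype=float), list(df.index)


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

class SaturatedDistanceError(ValueError):
    """Jukes-Cantor correction undefined (p >= 3/4) for some pair."""


def pairwise_distance(aln: AlignmentMatrix, correction: str = "p") -> np.ndarray:
    """Pairwise distance matrix; gap/N columns excluded per pair.

    correction 'p' = raw proportion of differing sites; 'JC' applies
    -(3/4) ln(1 - 4p/3).
    """
    if len(aln.taxa) < 2:
        raise ValueError("need >= 2 taxa")
    if correction not in ("p", "JC"):
        raise ValueError(f"unknown correction {correction!r}")
    x = aln.data
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (x[i] < 4) & (x[j] < 4)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable sites for pair "
                                 f"({aln.taxa[i]}, {aln.taxa[j]})")
            p = float((x[i][ok] != x[j][ok]).sum()) / m
            if correction == "JC":
                if p >= 0.75:
                    raise SaturatedDistanceError(
                        f"saturated distance (p={p:.3f}) for pair "
                        f"({aln.taxa[i]}, {aln.taxa[j]})")
                p = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return d


def neighbor_joining(d: np.ndarray, labels: list) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    Ties in the Q matrix are broken by the lexicographically smallest index
    pair (deterministic).  On additive matrices the generating topology and
    branch lengths are recovered exactly.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    # working nodes as newick fragments
    nodes = [f"{lab}" for lab in labels]
    active = list(range(n))
    D = d.copy()
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        vj = D[i, j] - vi
        vi = max(vi, 0.0)
        vj = max(vj, 0.0)
        new = f"({nodes[i]}:{vi:.12g},{nodes[j]}:{vj:.12g})"
        # distances from new node u: d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    vi = max(0.5 * (D[i, j] + D[i, k] - D[j, k]), 0.0)
    vj = max(0.5 * (D[i, j] + D[j, k] - D[i, k]), 0.0)
    vk = max(0.5 * (D[i, k] + D[j, k] - D[i, j]), 0.0)
    newick = (f"({nodes[i]}:{vi:.12g},{nodes[j]}:{vj:.12g},"
              f"{nodes[k]}:{vk:.12g});")
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def select_single_copy(copy_counts) -> list:
    """Gene ids with exactly one credited locus in every genome.

    ``copy_counts``: pandas DataFrame genes x genomes of integer hit counts.
    """
    mask = (copy_counts == 1).all(axis=1)
    return list(copy_counts.index[mask])


def concatenate(alignments: list) -> AlignmentMatrix:
    """Concatenate alignments sharing the same taxon set (any order)."""
    taxa = alignments[0].taxa
    blocks = [a.subset(taxa).data for a in alignments]
    return AlignmentMatrix(list(taxa), np.hstack(blocks))


# ---------------------------------------------------------------------------
# GTR + Gamma + invariant sites
# ---------------------------------------------------------------------------

@dataclass
class SubstModel:
    """GTR exchangeabilities (AC, AG, AT, CG, CT, GT), base frequencies
    (A, C, G, T), gamma shape with ``ncat`` discrete categories, and a
    proportion of invariant sites."""

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: float = math.inf  # inf = no rate variation
    ncat: int = 4
    p_inv: float = 0.0
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if not (self.alpha > 0):
            raise ValueError("alpha must be positive")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")

    @classmethod
    def jc(cls, **kw) -> "SubstModel":
        return cls(**kw)

    def rate_matrix(self) -> np.ndarray:
        """GTR Q normalized to one expected substitution per unit time."""
        a, b, c, d, e, f = self.exchangeabilities
        pi = np.asarray(self.freqs)
        R = np.array([[0, a, b, c],
                      [a, 0, d, e],
                      [b, d, 0, f],
                      [c, e, f, 0]], dtype=float)
        Q = R * pi[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def _eigen(self):
        if self._eig is None:
            pi = np.asarray(self.freqs)
            Q = self.rate_matrix()
            sp = np.sqrt(pi)
            S = (sp[:, None] * Q) / sp[None, :]
            w, U = np.linalg.eigh((S + S.T) / 2.0)
            left = U.T * sp[None, :]
            right = (1.0 / sp)[:, None] * U
            self._eig = (w, right, left)
        return self._eig

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(rate * t * Q); rows sum to 1."""
        w, right, left = self._eigen()
        P = (right * np.exp(w * rate * t)[None, :]) @ left
        return np.clip(P, 0.0, None)

    def category_rates(self) -> tuple:
        """Discrete-gamma category rates (mean of each quantile interval)
        and their weights; rescaled so non-invariant sites have mean rate
        1 / (1 - p_inv)."""
        if math.isinf(self.alpha):
            rates = np.ones(1)
            weights = np.ones(1)
        else:
            c = self.ncat
            a = self.alpha
            edges = gamma_dist.ppf(np.linspace(0, 1, c + 1), a, scale=1.0 / a)
            cdf_up = gamma_dist.cdf(edges, a + 1, scale=1.0 / a)
            rates = (cdf_up[1:] - cdf_up[:-1]) * c
            weights = np.full(c, 1.0 / c)
        if self.p_inv > 0:
            rates = rates / (1.0 - self.p_inv)
        return rates, weights


@dataclass
class SiteLogLikelihoods:
    per_site: np.ndarray

    @property
    def total(self) -> float:
        return float(self.per_site.sum())


def _compress(aln: AlignmentMatrix):
    patterns, inverse = np.unique(aln.data, axis=1, return_inverse=True)
    return patterns, np.asarray(inverse).ravel()


def _tip_partials(column_codes: np.ndarray) -> np.ndarray:
    """(n_patterns, 4) partials for one taxon: unit vector or all-ones."""
    npat = column_codes.shape[0]
    part = np.zeros((npat, 4))
    obs = column_codes < 4
    part[np.arange(npat)[obs], column_codes[obs]] = 1.0
    part[~obs] = 1.0
    return part


def site_loglik(tree: dendropy.Tree, aln: AlignmentMatrix,
                model: SubstModel) -> SiteLogLikelihoods:
    """Per-site log-likelihoods by Felsenstein pruning under GTR+Gamma(+I)."""
    if aln.n_sites == 0:
        raise ValueError("zero-length alignment")
    tip_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = tip_names - set(aln.taxa)
    if missing:
        raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
    order = [t for t in aln.taxa if t in tip_names]
    sub = aln.subset(order)
    patterns, inverse = _compress(sub)
    tidx = {t: i for i, t in enumerate(order)}
    npat = patterns.shape[1]
    pi = np.asarray(model.freqs)
    rates, weights = model.category_rates()

    mixed = np.zeros(npat)
    for rate, wgt in zip(rates, weights):
        partials = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                partials[node] = _tip_partials(patterns[tidx[node.taxon.label]])
            else:
                part = np.ones((npat, 4))
                for child in node.child_nodes():
                    t = child.edge.length or 0.0
                    P = model.transition_matrix(t, rate)
                    part *= partials[child] @ P.T
                partials[node] = part
        mixed += wgt * (partials[tree.seed_node] @ pi)

    if model.p_inv > 0:
        inv = np.zeros(npat)
        for k in range(npat):
            col = patterns[:, k]
            obs = col[col < 4]
            if obs.size == 0:
                inv[k] = 1.0
            elif (obs == obs[0]).all():
                inv[k] = pi[obs[0]]
        mixed = model.p_inv * inv + (1.0 - model.p_inv) * mixed
    with np.errstate(divide="ignore"):
        per_pattern = np.log(mixed)
    if not np.all(np.isfinite(per_pattern)):
        raise FloatingPointError("zero site likelihood encountered")
    return SiteLogLikelihoods(per_pattern[inverse])


def _edge_contexts(tree, patterns, tidx, model, rates):
    """Inside/outside partials per rate category for single-edge likelihoods.

    For each rate and each non-root node ``v`` (head of edge ``v``), computes
    ``inside[v]`` -- the conditional likelihood of the data below ``v`` given
    the state at ``v`` -- and ``out[v]`` -- the likelihood of all other data
    given the state at ``v``'s parent, excluding edge ``v`` itself.  The
    per-pattern likelihood is then ``(out[v] @ P(t) * inside[v]).sum(1)``, so
    a trial length for edge ``v`` costs one 4x4 contraction per pattern.
    """
    npat = patterns.shape[1]
    pi = np.asarray(model.freqs)
    per_rate = []
    for rate in rates:
        inside = {}
        down = {}  # child partials propagated through the child's edge
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                inside[node] = _tip_partials(patterns[tidx[node.taxon.label]])
            else:
                part = np.ones((npat, 4))
                for child in node.child_nodes():
                    t = child.edge.length or 0.0
                    down[child] = inside[child] @ model.transition_matrix(t, rate).T
                    part *= down[child]
                inside[node] = part
        above = {tree.seed_node: np.broadcast_to(pi, (npat, 4))}
        out = {}
        for node in tree.preorder_node_iter():
            kids = node.child_nodes()
            for child in kids:
                sib = above[node].copy()
                for other in kids:
                    if other is not child:
                        sib *= down[other]
                out[child] = sib
                t = child.edge.length or 0.0
                above[child] = sib @ model.transition_matrix(t, rate)
        per_rate.append((inside, out))
    return per_rate


def optimize_branch_lengths(tree: dendropy.Tree, aln: AlignmentMatrix,
                            model: SubstModel, tol: float = 1e-6,
                            max_sweeps: int = 20,
                            max_len: float = 20.0,
                            bl_tol: float = 1e-7) -> float:
    """Coordinate-wise Brent optimization of branch lengths in place.

    Each branch is optimized against cached inside/outside partials, which
    are refreshed after every branch update, so the ascent is exact and
    monotone.  ``bl_tol`` is the absolute tolerance on each branch length;
    values much finer than the statistical uncertainty (roughly
    1/sqrt(n_sites)) only add likelihood evaluations.  Returns the optimized
    total log-likelihood.
    """
    tree = tree  # modified in place
    tip_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = tip_names - set(aln.taxa)
    if missing:
        raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
    order = [t for t in aln.taxa if t in tip_names]
    sub = aln.subset(order)
    patterns, inverse = _compress(sub)
    counts = np.bincount(inverse, minlength=patterns.shape[1]).astype(float)
    tidx = {t: i for i, t in enumerate(order)}
    rates, weights = model.category_rates()

    inv_term = np.zeros(patterns.shape[1])
    if model.p_inv > 0:
        pi = np.asarray(model.freqs)
        for k in range(patterns.shape[1]):
            col = patterns[:, k]
            obs = col[col < 4]
            if obs.size == 0:
                inv_term[k] = 1.0
            elif (obs == obs[0]).all():
                inv_term[k] = pi[obs[0]]
    scale = 1.0 - model.p_inv

    nodes = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
    cur = site_loglik(tree, aln, model).total
    for _ in range(max_sweeps):
        prev = cur
        for node in nodes:
            per_rate = _edge_contexts(tree, patterns, tidx, model, rates)

            def neg(t):
                mixed = np.zeros(patterns.shape[1])
                for rate, wgt, (inside, out) in zip(rates, weights, per_rate):
                    P = model.transition_matrix(t, rate)
                    mixed += wgt * ((out[node] @ P) * inside[node]).sum(axis=1)
                mixed = model.p_inv * inv_term + scale * mixed
                with np.errstate(divide="ignore"):
                    return -float(counts @ np.log(mixed))

            res = minimize_scalar(neg, bounds=(1e-9, max_len), method="bounded",
                                  options={"xatol": bl_tol})
            if -res.fun >= -neg(node.edge.length or 0.0):
                node.edge.length = float(res.x)
        cur = site_loglik(tree, aln, model).total
        if cur - prev < tol:
            break
    return cur


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree, taxa: list) -> set:
    """Non-trivial splits as frozensets of the smaller side's taxon labels."""
    out = set()
    all_taxa = frozenset(taxa)
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1:
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_support(aln: AlignmentMatrix, builder, B: int,
                      seed: int) -> dict:
    """Nonparametric bootstrap support (%) for each split of the point tree.

    ``builder`` maps an AlignmentMatrix to a dendropy tree.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    point = builder(aln)
    splits = _bipartitions(point, aln.taxa)
    counts = {sp: 0 for sp in splits}
    for _ in range(B):
        idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
        rep = AlignmentMatrix(list(aln.taxa), aln.data[:, idx])
        rep_splits = _bipartitions(builder(rep), aln.taxa)
        for sp in splits:
            if sp in rep_splits:
                counts[sp] += 1
    return {sp: 100.0 * c / B for sp, c in counts.items()}


def nj_builder(correction: str = "JC"):
    """Convenience tree-building procedure for bootstrap_support."""
    def build(aln: AlignmentMatrix) -> dendropy.Tree:
        return neighbor_joining(pairwise_distance(aln, correction), aln.taxa)
    return build
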