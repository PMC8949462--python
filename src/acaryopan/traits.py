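"""Parsimony mapping of binary traits onto a phylogeny.

Fitch parsimony gives the minimum number of state changes with unrestricted
gains and losses; Dollo parsimony constrains a complex trait to at most one
gain and asks for the minimum number of subsequent losses.  Comparing the two
is the standard way of contrasting a vertical-inheritance-plus-loss scenario
with repeated independent acquisition.

Tip states are {0, 1}; unknown tips are treated as uninformative (excluded
from the set operations at their parent), never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

PRESENT, ABSENT, UNKNOWN = 1, 0, None


@dataclass
class EventReconstruction:
    """Minimum-change labelling of a rooted tree for one binary trait."""

    n_changes: int
    events: list  # (child tip-set frozenset label, 'gain'|'loss') per branch
    ancestral_states: dict  # node key -> 0/1
    ambiguous: bool
    method: str = "fitch"
    extra: dict = field(default_factory=dict)

    @property
    def n_gains(self) -> int:
        return sum(1 for _, kind in self.events if kind == "gain")

    @property
    def n_losses(self) -> int:
        return sum(1 for _, kind in self.events if kind == "loss")


def _node_key(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def fitch_parsimony(tree: dendropy.Tree, states: dict) -> EventReconstruction:
    """Minimum-change reconstruction of a binary trait (Hartigan's algorithm).

    ``states`` maps tip label -> 0/1/None.  Hartigan's generalization of
    Fitch parsimony is used so multifurcating nodes (e.g. the trifurcating
    root of a neighbor-joining tree) are counted correctly: each node keeps
    the states held by the most children, adding one change per child
    excluded.  The returned labelling keeps the parent's state whenever
    optimal (changes pushed tipward); ``ambiguous`` is set when the root
    state is not determined.
    """
    known = {k: v for k, v in states.items() if v is not None}
    if not known:
        raise ValueError("all tips unknown")
    for v in known.values():
        if v not in (0, 1):
            raise ValueError(f"states must be binary, got {v!r}")

    # up pass: per-node set of states attainable in a minimum-change labelling
    up: dict = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = states.get(node.taxon.label)
            up[node] = {0, 1} if v is None else {v}
        else:
            kids = node.child_nodes()
            k = {s: sum(1 for c in kids if s in up[c]) for s in (0, 1)}
            best = max(k.values())
            up[node] = {s for s in (0, 1) if k[s] == best}
            changes += len(kids) - best

    # down pass: keep the parent's state when it is optimal for the child
    final: dict = {}
    root = tree.seed_node
    root_set = up[root]
    ambiguous = len(root_set) > 1
    final[root] = min(root_set)  # deterministic pick at the root
    events = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = final[node.parent_node]
        cand = up[node]
        if parent_state in cand:
            final[node] = parent_state
        else:
            final[node] = next(iter(cand))  # binary states: singleton here
            kind = "gain" if final[node] == 1 else "loss"
            events.append((_node_key(node), kind))
    recon = EventReconstruction(
        n_changes=changes, events=events,
        ancestral_states={_node_key(n): final[n] for n in tree.preorder_node_iter()},
        ambiguous=ambiguous, method="fitch")
    if len(events) != changes:
        # the down-pass labelling always realizes the minimum; mismatch is a bug
        raise AssertionError("labelling does not realize the parsimony count")
    return recon


def _loss_events(node, present_set, states, final, events) -> None:
    """Label minimal losses below a node assumed present.

    A subtree with only unknown tips is uninformative and inherits presence;
    a subtree whose known tips are all absent is one loss event.
    """
    for child in node.child_nodes():
        if child in present_set:
            final[child] = 1
            _loss_events(child, present_set, states, final, events)
            continue
        has_known = any(states.get(lf.taxon.label) is not None
                        for lf in child.leaf_iter())
        if has_known:
            events.append((_node_key(child), "loss"))
            for nd in child.preorder_iter():
                final[nd] = 0
        else:
            for nd in child.preorder_iter():
                final[nd] = 1


def _mrca(tree, tip_labels):
    """Most recent common ancestor of the named tips under the seed root."""
    start = next(lf for lf in tree.leaf_node_iter()
                 if lf.taxon.label in tip_labels)
    node = start
    while not tip_labels <= {lf.taxon.label for lf in node.leaf_iter()}:
        node = node.parent_node
    return node


def dollo_reconstruction(tree: dendropy.Tree, states: dict,
                         root_state: str = "infer") -> EventReconstruction:
    """Dollo parsimony: at most one gain, minimum losses.

    ``root_state`` 'present' forces presence at the root (0 gains);
    'absent' places the single gain at the MRCA of the present tips;
    'infer' reports whichever needs fewer total events (ties -> absent root,
    i.e. the single-gain scenario).  The result's ``extra['fitch_changes']``
    carries the unrestricted Fitch count for comparison.
    """
    if root_state not in ("present", "absent", "infer"):
        raise ValueError(f"bad root_state {root_state!r}")
    known = {k: v for k, v in states.items() if v is not None}
    present_tips = {k for k, v in known.items() if v == 1}
    fitch = fitch_parsimony(tree, states)

    def reconstruct(gain_node, n_gains):
        # present on every node of the spanning structure between gain_node
        # and the present tips; minimal losses cover the remaining subtrees
        present_set = set()
        if present_tips:
            for leaf in tree.leaf_node_iter():
                lbl = leaf.taxon.label
                if lbl in present_tips:
                    nd = leaf
                    while nd is not None:
                        present_set.add(nd)
                        if nd is gain_node:
                            break
                        nd = nd.parent_node
        final = {}
        events = []
        if n_gains:
            events.append((_node_key(gain_node), "gain"))
        for nd in tree.preorder_node_iter():
            final.setdefault(nd, 0)
        if gain_node is not None:
            final[gain_node] = 1
            _loss_events(gain_node, present_set, states, final, events)
        # unknown tips ride along with their reconstructed parent state
        n_losses = sum(1 for _, k in events if k == "loss")
        return EventReconstruction(
            n_changes=n_gains + n_losses, events=events,
            ancestral_states={_node_key(n): final[n]
                              for n in tree.preorder_node_iter()},
            ambiguous=False, method="dollo",
            extra={"fitch_changes": fitch.n_changes,
                   "gains": n_gains, "losses": n_losses})

    if not present_tips:
        if root_state == "present":
            # everything lost: one loss per root child subtree
            return reconstruct(tree.seed_node, 0)
        rec = EventReconstruction(0, [], {_node_key(n): 0 for n in
                                          tree.preorder_node_iter()},
                                  False, "dollo",
                                  {"fitch_changes": fitch.n_changes,
                                   "gains": 0, "losses": 0})
        return rec

    mrca = _mrca(tree, present_tips)
    if root_state == "present":
        return reconstruct(tree.seed_node, 0)
    if root_state == "absent":
        return reconstruct(mrca, 1)
    rec_gain = reconstruct(mrca, 1)
    rec_root = reconstruct(tree.seed_node, 0)
    return rec_gain if rec_gain.n_changes <= rec_root.n_changes else rec_root


def covariation(trait_a: dict, trait_b: dict) -> dict:
    """Agreement between two binary trait columns over non-unknown strains.

    Returns the agreement fraction, the discordant strain list, and whether
    the traits completely co-vary (agreement 1.0).
    """
    if set(trait_a) != set(trait_b):
        raise ValueError("strain sets differ")
    compared = [s for s in trait_a
                if trait_a[s] is not None and trait_b[s] is not None]
    if not compared:
        raise ValueError("no strains with both traits known")
    discordant = sorted(s for s in compared if trait_a[s] != trait_b[s])
    agreement = 1.0 - len(discordant) / len(compared)
    return {"agreement": agreement, "discordant": discordant,
            "complete": not discordant, "n_compared": len(compared)}


def read_trait_matrix(path: str) -> pd.DataFrame:
    """Strains x traits TSV with cells {0, 1, NA} -> DataFrame of 0/1/None."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.where(df.notna(), None)


def trait_column(df: pd.DataFrame, trait: str) -> dict:
    col = df[trait]
    return {s: (None if v is None or pd.isna(v) else int(v))
            for s, v in col.items()}
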