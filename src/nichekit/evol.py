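"""Ancestral niche reconstruction over discretized environmental bins.

Each environmental variable is split into equal-width bins spanning the
union of all taxa's accessible (M) value ranges; each taxon's niche is
coded per bin as present / absent / uncertain, where "uncertain" marks
bins wholly outside that taxon's accessible environmental range — a
taxon cannot provide evidence about conditions it never had access to.
Ancestral states are then reconstructed per bin by parsimony (Hartigan's
generalization of Fitch, exact on polytomies), with uncertain tips
treated as missing (compatible with both states).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

PRESENT = 1
ABSENT = 0
UNCERTAIN = -1

# bitmask state sets: bit 1 = absent, bit 2 = present
_SET_OF = {ABSENT: 0b01, PRESENT: 0b10, UNCERTAIN: 0b11}


@dataclass
class NicheBinTable:
    """Per-variable niche coding: taxa x bins over {present, absent,
    uncertain}."""

    variable: str
    bin_edges: np.ndarray          # (n_bins + 1,)
    taxa: list[str]
    states: np.ndarray             # (n_taxa, n_bins) of {1, 0, -1}

    @property
    def n_bins(self) -> int:
        return self.states.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def to_dataframe(self):
        import pandas as pd
        cols = [f"bin_{i}" for i in range(self.n_bins)]
        return pd.DataFrame(self.states, index=self.taxa, columns=cols)


@dataclass
class AncestralStates:
    """Reconstruction output: per-node bin states and per-branch changes."""

    tree: dendropy.Tree
    node_ids: list[str]            # tips by label, internals by node id
    node_states: np.ndarray        # (n_nodes, n_bins) of {1, 0, -1 ambiguous}
    branch_changes: dict[str, tuple[int, int]]  # child id -> (gained, lost)
    changes_per_bin: np.ndarray    # (n_bins,) minimum change counts
    skipped_bins: list[int] = field(default_factory=list)

    def states_of(self, node_id: str) -> np.ndarray:
        return self.node_states[self.node_ids.index(node_id)]


def build_bin_table(occ_values: dict[str, np.ndarray],
                    m_values: dict[str, np.ndarray],
                    n_bins: int = 20, trim: float = 0.05,
                    variable: str = "") -> NicheBinTable:
    """Code each taxon's niche over equal-width environmental bins.

    Bin edges span the union of all taxa's M value ranges. Per taxon, the
    occupied interval is the [trim/2, 1 - trim/2] quantile range of its
    occurrence values (a 5% total trim by default, to resist outliers); a
    bin is *present* if it overlaps the occupied interval, *uncertain* if
    it lies wholly outside the taxon's M value range, else *absent*.
    Absent bins strictly between two present bins are recoded present
    (niches are assumed interval-shaped), so present bins form one
    contiguous run.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    taxa = list(occ_values)
    if set(taxa) != set(m_values):
        raise ValueError("occ_values and m_values must cover the same taxa")
    for t in taxa:
        if len(np.atleast_1d(occ_values[t])) == 0:
            raise ValueError(f"taxon {t!r} has no occurrence values")
        if len(np.atleast_1d(m_values[t])) == 0:
            raise ValueError(f"taxon {t!r} has no accessible-area values")
    lo = min(float(np.min(m_values[t])) for t in taxa)
    hi = max(float(np.max(m_values[t])) for t in taxa)
    if hi <= lo:
        raise ValueError("degenerate global environmental range")
    edges = np.linspace(lo, hi, n_bins + 1)
    states = np.empty((len(taxa), n_bins), dtype=int)
    for ti, t in enumerate(taxa):
        occ = np.asarray(occ_values[t], dtype=float)
        occ_lo, occ_hi = np.quantile(occ, [trim / 2.0, 1.0 - trim / 2.0])
        m_lo, m_hi = float(np.min(m_values[t])), float(np.max(m_values[t]))
        if m_hi <= lo or m_lo >= hi:
            raise ValueError(f"taxon {t!r} M range disjoint from global range")
        for b in range(n_bins):
            e0, e1 = edges[b], edges[b + 1]
            if e0 < occ_hi and e1 > occ_lo:
                states[ti, b] = PRESENT
            elif e1 <= m_lo or e0 >= m_hi:
                states[ti, b] = UNCERTAIN
            else:
                states[ti, b] = ABSENT
        pres = np.flatnonzero(states[ti] == PRESENT)
        if pres.size == 0:
            # point niche sitting on a bin edge: mark the nearest bin
            mid = 0.5 * (occ_lo + occ_hi)
            b = int(np.clip(np.searchsorted(edges, mid) - 1, 0, n_bins - 1))
            states[ti, b] = PRESENT
        else:
            # interval smoothing: fill interior gaps in the present run
            inner = states[ti, pres[0]:pres[-1] + 1]
            inner[inner == ABSENT] = PRESENT
    return NicheBinTable(variable, edges, taxa, states)


def graft_taxon(tree: dendropy.Tree, new_tip: str,
                sister: str) -> dendropy.Tree:
    """Attach a missing taxon as sister to an existing tip.

    A new internal node is inserted at the midpoint of the sister's
    terminal branch; the new tip hangs from it with branch length equal
    to the remaining half, so both daughters end contemporaneously with
    the sister's original depth. The input tree is not modified.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if sister not in tips:
        raise KeyError(f"sister tip {sister!r} not found")
    if new_tip in tips:
        raise ValueError(f"tip {new_tip!r} already present")
    out = tree.clone(depth=1)
    leaf = next(l for l in out.leaf_node_iter() if l.taxon.label == sister)
    length = leaf.edge.length
    if length is None:
        raise ValueError("sister branch has no length")
    if length == 0:
        logger.warning("grafting %s onto a zero-length branch", new_tip)
    parent = leaf.parent_node
    parent.remove_child(leaf)
    joint = parent.new_child(edge_length=length / 2.0)
    leaf.edge.length = length / 2.0
    joint.add_child(leaf)
    taxon = out.taxon_namespace.require_taxon(label=new_tip)
    joint.new_child(taxon=taxon, edge_length=length / 2.0)
    return out


def _node_ids(tree: dendropy.Tree) -> dict[dendropy.Node, str]:
    ids = {}
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = f"node{k}"
            k += 1
    return ids


def reconstruct_bins(table: NicheBinTable, tree: dendropy.Tree,
                     method: str = "parsimony") -> AncestralStates:
    """Parsimony ancestral reconstruction of each bin's presence state.

    Per bin, a two-pass (postorder set construction, preorder
    resolution) parsimony reconstruction over {present, absent} with
    uncertain tips treated as missing data. Nodes whose state set is not
    unique after resolution are labelled ambiguous. Bins where every tip
    is uncertain are skipped and reported. Branch changes (bins gained /
    lost) are counted from resolved parent-to-child flips only.
    """
    if method != "parsimony":
        raise ValueError(f"unknown reconstruction method {method!r}")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != set(table.taxa):
        raise ValueError("bin-table taxa do not match tree tips")
    ids = _node_ids(tree)
    nodes = list(tree.preorder_node_iter())
    node_index = {n: i for i, n in enumerate(nodes)}
    n_bins = table.n_bins
    node_states = np.full((len(nodes), n_bins), UNCERTAIN, dtype=int)
    changes_per_bin = np.zeros(n_bins, dtype=int)
    gained = {ids[n]: 0 for n in nodes if n.parent_node is not None}
    lost = {ids[n]: 0 for n in nodes if n.parent_node is not None}
    skipped = []

    tip_rows = {t: table.row(t) for t in table.taxa}
    for b in range(n_bins):
        if all(tip_rows[t][b] == UNCERTAIN for t in table.taxa):
            skipped.append(b)
            continue
        # postorder: Hartigan state sets (exact for polytomies)
        upper = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                upper[node] = _SET_OF[tip_rows[node.taxon.label][b]]
            else:
                count = {0b01: 0, 0b10: 0}
                k = 0
                for child in node.child_nodes():
                    k += 1
                    for s in (0b01, 0b10):
                        if upper[child] & s:
                            count[s] += 1
                best = max(count.values())
                upper[node] = sum(s for s in (0b01, 0b10) if count[s] == best)
                changes_per_bin[b] += k - best
        # preorder resolution
        resolved = {}
        for node in tree.preorder_node_iter():
            vs = upper[node]
            parent = node.parent_node
            if parent is None:
                state = _mask_to_state(vs)
            else:
                p = resolved[parent]
                if p != UNCERTAIN and (vs & _SET_OF[p]) == _SET_OF[p]:
                    state = p
                else:
                    state = _mask_to_state(vs)
            resolved[node] = state
            if node.is_leaf():
                node_states[node_index[node], b] = tip_rows[node.taxon.label][b]
            else:
                node_states[node_index[node], b] = state
        # resolved parent->child flips
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            p, c = resolved[parent], resolved[node]
            if node.is_leaf() and tip_rows[node.taxon.label][b] == UNCERTAIN:
                continue
            if p == UNCERTAIN or c == UNCERTAIN:
                continue
            if p == ABSENT and c == PRESENT:
                gained[ids[node]] += 1
            elif p == PRESENT and c == ABSENT:
                lost[ids[node]] += 1
    branch_changes = {nid: (gained[nid], lost[nid]) for nid in gained}
    return AncestralStates(tree, [ids[n] for n in nodes], node_states,
                           branch_changes, changes_per_bin, skipped)


def _mask_to_state(mask: int) -> int:
    if mask == 0b01:
        return ABSENT
    if mask == 0b10:
        return PRESENT
    return UNCERTAIN


@dataclass
class BranchChange:
    child_id: str
    is_terminal: bool
    gained: int
    lost: int

    @property
    def net(self) -> int:
        return self.gained - self.lost

    @property
    def contraction_dominated(self) -> bool:
        return self.lost > self.gained


def summarize_evolution(anc: AncestralStates) -> list[BranchChange]:
    """Per-branch niche expansion/contraction report.

    A terminal branch is "contraction-dominated" when the taxon lost
    more bins than it gained relative to its reconstructed ancestor —
    the signature of a descendant occupying a subset of the ancestral
    niche.
    """
    ids = _node_ids(anc.tree)
    report = []
    for node in anc.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        nid = ids[node]
        g, l = anc.branch_changes[nid]
        report.append(BranchChange(nid, node.is_leaf(), g, l))
    return report
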