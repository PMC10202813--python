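"""Per-case parsimony phylogenies and temporal tiering of somatic events.

Tumors of one autopsy case are leaves; each somatic event (SNV/indel/SV) is a
binary presence/absence character with an implicit all-absent outgroup (the
patient's normal tissue). Temporal tiers follow the sharing pattern alone:

* early — present in every tumor of the case (truncal),
* late — private to exactly one tumor,
* intermediate — shared by a proper subset (requires >= 3 tumors).

Tree inference is maximum parsimony: Fitch small parsimony summed over
events, with exhaustive topology search up to 7 leaves (outgroup included)
and nearest-neighbour-interchange hill climbing with random restarts beyond
that. Equally parsimonious topologies are broken deterministically by the
lexicographically smallest canonical newick string.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ramscape.rng import substream

OUTGROUP = "normal"


# --- presence matrices and tiering -----------------------------------------

def build_presence_matrix(mutations: pd.DataFrame, tumors: list[str],
                          min_alt_reads: int = 3) -> pd.DataFrame:
    """Events x tumors 0/1 matrix from a per-case mutation table.

    An event is present in a tumor when that tumor's row shows
    ``t_alt_reads >= min_alt_reads`` (read-noise floor). Events absent from
    every tumor after thresholding are dropped.
    """
    sub = mutations[mutations["sample"].isin(tumors)]
    present = sub[sub["t_alt_reads"] >= min_alt_reads]
    mat = (
        present.assign(one=1)
        .pivot_table(index="mutation_id", columns="sample", values="one",
                     aggfunc="max", fill_value=0)
        .reindex(columns=tumors, fill_value=0)
    )
    mat = mat[mat.sum(axis=1) > 0].astype(int)
    mat.columns.name = None
    return mat


def tier_events(matrix: pd.DataFrame) -> pd.Series:
    """Assign early/intermediate/late to each event row of a 0/1 matrix.

    Tiers are a function of the sharing pattern only, hence invariant to
    column order and to any inferred tree. A single-tumor case has no
    defined tiering.
    """
    n = matrix.shape[1]
    if n < 2:
        raise ValueError("tiering requires >= 2 tumors per case")
    counts = matrix.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("matrix contains all-zero event rows")
    tiers = pd.Series("intermediate", index=matrix.index, dtype=object)
    tiers[counts == n] = "early"
    tiers[counts == 1] = "late"
    return tiers


# --- Fitch scoring over bitmask state sets ----------------------------------

# A tree over leaf indices 0..k-1 is a nested tuple: a leaf is an int, an
# internal node a pair (left, right). The tree is rooted at the outgroup,
# which is implicit (state 0 for every event), so the root's child is the
# whole tumor topology.

def _fitch_sets(tree, leaf_states: np.ndarray):
    """Postorder Fitch pass. leaf_states: (n_leaves, n_events) in {1, 2}
    encoding state-0 as bit 1 and state-1 as bit 2. Returns (sets, changes)."""
    if isinstance(tree, (int, np.integer)):
        return leaf_states[tree], np.zeros(leaf_states.shape[1], dtype=np.int64)
    left, right = tree
    ls, lc = _fitch_sets(left, leaf_states)
    rs, rc = _fitch_sets(right, leaf_states)
    inter = ls & rs
    union = ls | rs
    disjoint = inter == 0
    return np.where(disjoint, union, inter), lc + rc + disjoint


def fitch_score(tree, leaf_states: np.ndarray) -> int:
    """Total parsimony changes for a tumor topology rooted at the outgroup.

    The outgroup contributes one extra change for any event whose root state
    set excludes state 0 (i.e., the event must arise on the trunk).
    """
    sets, changes = _fitch_sets(tree, leaf_states)
    root_extra = (sets & 1) == 0
    return int(changes.sum() + root_extra.sum())


def encode_leaf_states(matrix: pd.DataFrame) -> np.ndarray:
    """Encode a 0/1 events x tumors matrix as Fitch bit sets (tumors x events)."""
    return (matrix.to_numpy().T.astype(np.int64) + 1)


# --- topology enumeration and search ----------------------------------------

def _all_topologies(k: int):
    """All rooted binary topologies over leaves 0..k-1 by stepwise addition.

    Rooted trees over the tumors correspond one-to-one with unrooted trees
    over tumors + outgroup; count is (2k-3)!!.
    """
    trees = [0]
    for leaf in range(1, k):
        new = []
        for t in trees:
            new.extend(_insert_everywhere(t, leaf))
        trees = new
    return trees


def _insert_everywhere(tree, leaf):
    out = [(tree, leaf)]
    if not isinstance(tree, (int, np.integer)):
        left, right = tree
        out.extend((l2, right) for l2 in _insert_everywhere(left, leaf))
        out.extend((left, r2) for r2 in _insert_everywhere(right, leaf))
    return out


def _newick(tree, names) -> str:
    if isinstance(tree, (int, np.integer)):
        return names[tree]
    parts = sorted((_newick(c, names) for c in tree))
    return "(" + ",".join(parts) + ")"


def _nni_neighbors(tree):
    """All one-step nearest-neighbour-interchange rearrangements."""
    out = []
    if isinstance(tree, (int, np.integer)):
        return out
    left, right = tree
    # swap grandchildren across this node
    if not isinstance(left, (int, np.integer)):
        a, b = left
        out.append(((a, right), b))
        out.append(((b, right), a))
    if not isinstance(right, (int, np.integer)):
        c, d = right
        out.append((c, (d, left)))
        out.append((d, (c, left)))
    for i, sub in enumerate((left, right)):
        for nb in _nni_neighbors(sub):
            out.append((nb, right) if i == 0 else (left, nb))
    return out


def _random_topology(k: int, rng) -> tuple:
    tree = 0
    for leaf in range(1, k):
        spots = _insert_everywhere(tree, leaf)
        tree = spots[rng.integers(len(spots))]
    return tree


@dataclass
class ParsimonyTree:
    topology: tuple                  # nested tuple over tumor indices
    leaf_names: list[str]
    score: int

    @property
    def newick(self) -> str:
        """Canonical rooted newick with the outgroup as sister to all tumors."""
        return f"({_newick(self.topology, self.leaf_names)},{OUTGROUP});"


def infer_parsimony_tree(matrix: pd.DataFrame, exhaustive_max_leaves: int = 7,
                         n_restarts: int = 10, seed: int = 0) -> ParsimonyTree:
    """Maximum-parsimony topology for one case's tumors.

    Exhaustive search when tumors + outgroup <= ``exhaustive_max_leaves``;
    otherwise NNI hill climbing from ``n_restarts`` random topologies.
    Ties break on the lexicographically smallest canonical newick.
    """
    tumors = list(matrix.columns)
    k = len(tumors)
    if k < 2:
        raise ValueError("tree inference requires >= 2 tumors")
    states = encode_leaf_states(matrix)

    def better(cand, best):
        if best is None or cand[0] < best[0]:
            return True
        return cand[0] == best[0] and cand[1] < best[1]

    best = None
    if k + 1 <= exhaustive_max_leaves:
        for topo in _all_topologies(k):
            cand = (fitch_score(topo, states), _newick(topo, tumors), topo)
            if better(cand, best):
                best = cand
    else:
        rng = substream(seed, "phylo-nni")
        for _ in range(n_restarts):
            topo = _random_topology(k, rng)
            score = fitch_score(topo, states)
            improved = True
            while improved:
                improved = False
                for nb in _nni_neighbors(topo):
                    s = fitch_score(nb, states)
                    if s < score or (s == score
                                     and _newick(nb, tumors) < _newick(topo, tumors)):
                        if s < score:
                            topo, score = nb, s
                            improved = True
            cand = (score, _newick(topo, tumors), topo)
            if better(cand, best):
                best = cand
    return ParsimonyTree(topology=best[2], leaf_names=tumors, score=best[0])


# --- branch annotation -------------------------------------------------------

def annotate_branch_events(tree: ParsimonyTree, matrix: pd.DataFrame,
                           driver_list: list[str] | None = None,
                           gene_of_event: pd.Series | None = None) -> pd.DataFrame:
    """Place each event's gain(s) on tree branches via Fitch reconstruction.

    Branches are named by the sorted tumor set below them ("T1|T2"); the
    trunk (branch incident to the outgroup) carries events present in all
    tumors. Events whose minimal reconstruction needs more than one gain are
    flagged as homoplastic with every gain branch listed. Driver-gene events
    (via ``gene_of_event`` mapping into ``driver_list``) are flagged.
    """
    drivers = set(driver_list or [])
    names = tree.leaf_names
    rows = []

    def leaves_below(node):
        if isinstance(node, (int, np.integer)):
            return [node]
        return leaves_below(node[0]) + leaves_below(node[1])

    for event, presence in matrix.iterrows():
        carried = {i for i, t in enumerate(names) if presence[t] == 1}
        if not carried:
            raise ValueError(f"event {event} absent from every tumor")
        gains = _gain_branches(tree.topology, carried)
        branch_labels = ["|".join(sorted(names[i] for i in sorted(b)))
                         for b in gains]
        gene = gene_of_event.get(event) if gene_of_event is not None else None
        rows.append({
            "event": event,
            "branches": ";".join(branch_labels),
            "n_gains": len(gains),
            "homoplasy": len(gains) > 1,
            "is_driver": gene in drivers,
        })
    return pd.DataFrame(rows).set_index("event")


def _gain_branches(topology, carried: set) -> list[frozenset]:
    """Branches (as leaf sets below them) where a binary character gains,
    under a minimal Fitch reconstruction rooted at the absent outgroup."""
    sets = {}

    def down(node):
        if isinstance(node, (int, np.integer)):
            s = {1 if node in carried else 0}
            sets[_key(node)] = s
            return s
        ls, rs = down(node[0]), down(node[1])
        s = ls & rs or ls | rs
        sets[_key(node)] = s
        return s

    def _key(node):
        return tuple(sorted(_leaves(node)))

    def _leaves(node):
        if isinstance(node, (int, np.integer)):
            return [node]
        return _leaves(node[0]) + _leaves(node[1])

    down(topology)
    gains = []

    def up(node, parent_state):
        s = sets[_key(node)]
        state = parent_state if parent_state in s else min(s)
        if parent_state == 0 and state == 1:
            gains.append(frozenset(_leaves(node)))
        if not isinstance(node, (int, np.integer)):
            up(node[0], state)
            up(node[1], state)

    up(topology, 0)  # outgroup/root state is absent
    return gains
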