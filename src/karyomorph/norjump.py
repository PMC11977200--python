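"""Minimum-change ("jump") counting for NOR chromosome states on a
species tree.

The NOR-bearing chromosome of each species is treated as an unordered
categorical character: any relocation between chromosomes costs one jump.
Uniform-cost Sankoff dynamic programming handles polytomies natively and,
on binary trees, reduces to Fitch parsimony.  Leaves without a recorded
state (e.g., an outgroup with no homologous chromosome labels) are pruned
before counting.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Callable, Optional, Sequence

import dendropy

from .types import (
    JumpReport,
    NorStateMap,
    ParsimonyResult,
    ValidationError,
    parse_subgenome,
)

INF = math.inf


def _node_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return "{" + ",".join(leaves) + "}"


def _pruned(tree: dendropy.Tree, states: dict[str, str]) -> dendropy.Tree:
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = sorted(set(states) - labels)
    if missing:
        raise ValidationError(f"species not in tree: {missing}")
    keep = sorted(labels & set(states))
    if len(keep) < 2:
        raise ValidationError("need >= 2 leaves with NOR states")
    pruned = tree.extract_tree_with_taxa_labels(keep)
    # collapse degree-2 internal nodes introduced by pruning
    pruned.suppress_unifurcations()
    return pruned


def fitch_parsimony(
    tree: dendropy.Tree, state_map: NorStateMap
) -> ParsimonyResult:
    """Minimum number of NOR relocations under unordered parsimony.

    Returns the change count, the full most-parsimonious ancestral state
    set of every node, the edges on which a change is forced in all / is
    possible in at least one most-parsimonious reconstruction, and one
    deterministic reconstruction (lexicographic-minimum tie-break).
    """
    states = dict(state_map.states)
    if not states:
        raise ValidationError("no leaf has a NOR state")
    work = _pruned(tree, states)
    alphabet = sorted(set(states.values()))
    ns = len(alphabet)
    index = {s: k for k, s in enumerate(alphabet)}

    nodes = list(work.postorder_node_iter())
    down: dict[dendropy.Node, list[float]] = {}
    for node in nodes:
        if node.is_leaf():
            vec = [INF] * ns
            vec[index[states[node.taxon.label]]] = 0.0
            down[node] = vec
        else:
            vec = []
            for s in range(ns):
                total = 0.0
                for child in node.child_nodes():
                    total += min(
                        down[child][t] + (0.0 if t == s else 1.0) for t in range(ns)
                    )
                vec.append(total)
            down[node] = vec

    root = work.seed_node
    min_changes = int(min(down[root]))

    # up-pass: up[v][s] = min cost of the whole tree given v has state s
    up: dict[dendropy.Node, list[float]] = {root: list(down[root])}
    for node in work.preorder_node_iter():
        if node is root:
            continue
        parent = node.parent_node
        # parent's optimal cost excluding this child's subtree contribution
        excl = []
        for t in range(ns):
            contrib = min(
                down[node][u] + (0.0 if u == t else 1.0) for u in range(ns)
            )
            excl.append(up[parent][t] - contrib)
        vec = []
        for s in range(ns):
            vec.append(
                down[node][s]
                + min(excl[t] + (0.0 if t == s else 1.0) for t in range(ns))
            )
        up[node] = vec

    ancestral_sets = {
        _node_key(node): frozenset(
            alphabet[s] for s in range(ns) if up[node][s] == min_changes
        )
        for node in nodes
    }

    # per-edge change analysis over all most-parsimonious reconstructions
    edges_forced: list[tuple[str, str]] = []
    edges_possible: list[tuple[str, str]] = []
    for node in work.preorder_node_iter():
        if node is root:
            continue
        parent = node.parent_node
        excl = []
        for t in range(ns):
            contrib = min(
                down[node][u] + (0.0 if u == t else 1.0) for u in range(ns)
            )
            excl.append(up[parent][t] - contrib)
        cost_same = min(excl[t] + down[node][t] for t in range(ns))
        cost_diff = min(
            (
                excl[t] + 1.0 + down[node][s]
                for t in range(ns)
                for s in range(ns)
                if s != t
            ),
            default=INF,
        )
        edge = (_node_key(parent), _node_key(node))
        if cost_diff == min_changes:
            edges_possible.append(edge)
        if cost_same > min_changes:
            edges_forced.append(edge)

    # one deterministic reconstruction: lexicographic-minimum optimal state
    reconstruction: dict[str, str] = {}
    chosen: dict[dendropy.Node, int] = {}
    root_state = min(
        (s for s in range(ns) if down[root][s] == min_changes),
        key=lambda s: alphabet[s],
    )
    chosen[root] = root_state
    reconstruction[_node_key(root)] = alphabet[root_state]
    changes: list[tuple[str, str, str, str]] = []
    for node in work.preorder_node_iter():
        if node is root:
            continue
        ps = chosen[node.parent_node]
        best = min(
            range(ns),
            key=lambda s: (
                down[node][s] + (0.0 if s == ps else 1.0),
                alphabet[s],
            ),
        )
        chosen[node] = best
        reconstruction[_node_key(node)] = alphabet[best]
        if best != ps:
            changes.append(
                (
                    _node_key(node.parent_node),
                    _node_key(node),
                    alphabet[ps],
                    alphabet[best],
                )
            )

    return ParsimonyResult(
        min_changes=min_changes,
        ancestral_sets=ancestral_sets,
        edges_forced=sorted(edges_forced),
        edges_possible=sorted(edges_possible),
        reconstruction=reconstruction,
        changes=changes,
    )


def classify_jumps(
    result: ParsimonyResult,
    subgenome_parser: Callable[[str], str] = parse_subgenome,
) -> JumpReport:
    """Label each inferred NOR relocation as intra- or inter-subgenome.

    A jump such as 3L -> 4L stays within the L-subgenome (intra); 4L -> 6S
    crosses subgenomes (inter).  Changes involving a state without a
    subgenome suffix (e.g., "7") are reported but left unclassified.
    """
    intra = inter = unclassified = 0
    events = []
    for parent, child, src, dst in result.changes:
        tag_src = subgenome_parser(src)
        tag_dst = subgenome_parser(dst)
        if tag_src == "none" or tag_dst == "none":
            cls = "n/a"
            unclassified += 1
        elif tag_src == tag_dst:
            cls = "intra"
            intra += 1
        else:
            cls = "inter"
            inter += 1
        events.append(
            {
                "edge": (parent, child),
                "from_state": src,
                "to_state": dst,
                "subgenome_class": cls,
                "subgenomes": f"{tag_src}->{tag_dst}",
            }
        )
    return JumpReport(
        intra_subgenome=intra,
        inter_subgenome=inter,
        unclassified=unclassified,
        events=events,
    )
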