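"""Phylogenetic distribution of dynamic-class phenotypes.

Makes the qualitative observation that dynamic classes recur across a
species phylogeny ("paraphyly") testable: the Fitch small-parsimony count of
trait state changes on the tree is compared with its null distribution under
random reshuffling of leaf labels. A trait that is monophyletic per state
needs exactly (number of states - 1) changes; clustered (phylogenetically
conserved) traits sit below the permutation null, random ones within it.

Multifurcations are handled by the standard Fitch generalisation
(intersection over all children when nonempty, else union). Unlabeled
leaves are pruned before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


@dataclass
class MonophylyReport:
    per_state_monophyly: dict[str, bool]
    observed_transitions: int
    null_transitions: np.ndarray
    z_score: float
    p_value: float  # one-sided: observed fewer transitions than null


def _pruned_copy(tree: dendropy.Tree, traits: dict[str, str]) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.is_rooted = True  # parsimony and MRCA are computed on the rooted shape
    keep = [lf.taxon for lf in t.leaf_node_iter() if lf.taxon and lf.taxon.label in traits]
    if len(keep) < 2:
        raise ValueError("need >=2 labeled leaves")
    t.retain_taxa(keep)
    return t


def fitch_transitions(tree: dendropy.Tree, traits: dict[str, str]) -> int:
    """Minimum number of trait state changes on the tree (Fitch parsimony).

    0 iff every state's leaves form a single uniform block (e.g. all leaves
    share one state); a trait monophyletic per state costs one change per
    additional state.
    """
    states = set(traits.values())
    if len(states) <= 1:
        return 0
    t = _pruned_copy(tree, traits)
    changes = 0
    sets: dict[int, frozenset] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset([traits[node.taxon.label]])
            continue
        # Hartigan's generalisation: keep the states held by the largest
        # number of children; each child outside that majority costs one
        # change. Reduces to classic Fitch (intersection/union) on binary
        # nodes and stays exactly minimal on polytomies.
        counts: dict[str, int] = {}
        children = node.child_nodes()
        for c in children:
            for s in sets[id(c)]:
                counts[s] = counts.get(s, 0) + 1
        top = max(counts.values())
        sets[id(node)] = frozenset(s for s, v in counts.items() if v == top)
        changes += len(children) - top
    return changes


def _is_monophyletic(tree: dendropy.Tree, traits: dict[str, str], state: str) -> bool:
    t = _pruned_copy(tree, traits)
    state_taxa = {lbl for lbl, s in traits.items() if s == state}
    if len(state_taxa) == 1:
        return True
    mrca = t.mrca(taxon_labels=state_taxa)
    under = {lf.taxon.label for lf in mrca.leaf_iter()}
    return under == state_taxa


def monophyly_fraction(
    tree: dendropy.Tree, traits: dict[str, str], n_perm: int = 999, seed: int = 0
) -> MonophylyReport:
    """Per-state monophyly plus a label-permutation null for Fitch transitions."""
    states = sorted(set(traits.values()))
    mono = {s: _is_monophyletic(tree, traits, s) for s in states}
    obs = fitch_transitions(tree, traits)
    rng = np.random.default_rng(seed)
    labels = sorted(traits)
    values = [traits[k] for k in labels]
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(len(values))
        shuffled = {labels[j]: values[perm[j]] for j in range(len(labels))}
        null[i] = fitch_transitions(tree, shuffled)
    sd = null.std(ddof=1)
    z = float((obs - null.mean()) / sd) if sd > 0 else 0.0
    p = float((np.sum(null <= obs) + 1.0) / (n_perm + 1.0))
    return MonophylyReport(mono, obs, null, z, p)


def report_table(report: MonophylyReport) -> pd.DataFrame:
    rows = [
        {
            "state": s,
            "monophyletic": mono,
            "observed_transitions": report.observed_transitions,
            "null_mean": float(report.null_transitions.mean()),
            "null_sd": float(report.null_transitions.std(ddof=1)),
            "z_score": report.z_score,
            "p_value": report.p_value,
        }
        for s, mono in report.per_state_monophyly.items()
    ]
    return pd.DataFrame(rows)


def read_tree(path: str, outgroup: str | None = None) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=path, schema="newick")
    if outgroup is not None:
        og = tree.find_node_with_taxon_label(outgroup)
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not found in tree")
        tree.to_outgroup_position(og, update_bipartitions=True)
    return tree
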