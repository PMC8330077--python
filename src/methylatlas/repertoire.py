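"""Gene-repertoire matrices and Dollo-parsimony ancestral reconstruction.

A species x gene-family count matrix plus a rooted (possibly polytomous)
species tree let us infer which families the last common ancestors
possessed. Under Dollo parsimony a family is gained exactly once and can
only be lost thereafter: the gain is placed at the most recent common
ancestor (MRCA) of all species possessing the family, every node on a path
from that origin to a possessing leaf is scored present, and each maximal
edge into an all-absent subtree counts as one loss event.

Polytomies are treated as hard (simultaneous divergence): a present
polytomy node losing the family in several children accrues one loss per
absent child subtree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import pandas as pd

__all__ = [
    "SpeciesTree",
    "RepertoireMatrix",
    "DolloReconstruction",
    "load_tree",
    "load_matrix",
    "dollo_reconstruct",
    "ancestral_repertoire",
    "repertoire_summary",
    "platynereis_repertoire",
    "demo_metazoan_tree",
    "demo_metazoan_matrix",
]

SpeciesTree = dendropy.Tree


@dataclass(frozen=True)
class DolloReconstruction:
    """Single-gain minimal-loss history of one family on a species tree."""

    family: str
    node_states: dict  # node id -> bool (present)
    origin_node: str | None
    loss_edges: tuple[tuple[str, str], ...]  # (parent id, child id)

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


class RepertoireMatrix:
    """Species x family gene-count matrix (rows species, columns families)."""

    def __init__(self, counts: pd.DataFrame):
        if (counts.values < 0).any():
            raise ValueError("gene counts must be non-negative")
        if counts.index.has_duplicates:
            raise ValueError("duplicate species rows")
        self.counts = counts.astype(int)

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence view (count >= 1)."""
        return self.counts >= 1

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="species")


def load_tree(source: str, is_path: bool = True) -> SpeciesTree:
    """Read a newick species tree, forcing rooted interpretation.

    Internal node labels (e.g. clade names such as 'Metazoa') are kept and
    addressable by :func:`ancestral_repertoire`.
    """
    kwargs = dict(
        schema="newick",
        rooting="force-rooted",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
    )
    if is_path:
        return dendropy.Tree.get(path=source, **kwargs)
    return dendropy.Tree.get(data=source, **kwargs)


def load_matrix(path) -> RepertoireMatrix:
    """Read a species-rows x family-columns count TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RepertoireMatrix(df)


def _node_id(node: dendropy.Node, index: int) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return f"node{index}"


def _indexed_nodes(tree: SpeciesTree) -> dict[int, str]:
    """Stable id per node: taxon/label when present, else preorder index."""
    ids: dict[int, str] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        ids[id(node)] = _node_id(node, i)
    return ids


def dollo_reconstruct(tree: SpeciesTree, presence: dict) -> DolloReconstruction:
    """Dollo reconstruction of one family from leaf presence bits.

    ``presence`` maps every leaf label to a boolean. The origin is the MRCA
    of possessing leaves; a node is present iff it descends from (or is)
    the origin and its subtree contains a possessing leaf; losses are the
    maximal present-parent -> absent-child edges.
    """
    ids = _indexed_nodes(tree)
    leaves = {node.taxon.label: node for node in tree.leaf_node_iter()}
    for label in presence:
        if label not in leaves:
            raise ValueError(f"leaf {label!r} in presence vector but not in tree")
    missing = set(leaves) - set(presence)
    if missing:
        raise ValueError(f"presence undefined for leaves: {sorted(missing)}")

    possessors = [label for label, bit in presence.items() if bit]
    if not possessors:
        return DolloReconstruction(
            family="",
            node_states={ids[id(n)]: False for n in tree.preorder_node_iter()},
            origin_node=None,
            loss_edges=(),
        )
    if len(possessors) == 1:
        origin = leaves[possessors[0]]
    else:
        origin = tree.mrca(taxon_labels=possessors)

    # postorder: does this subtree contain a possessing leaf?
    has_possessor: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            has_possessor[id(node)] = bool(presence[node.taxon.label])
        else:
            has_possessor[id(node)] = any(
                has_possessor[id(c)] for c in node.child_nodes()
            )

    in_origin_subtree: dict[int, bool] = {}
    for node in tree.preorder_node_iter():
        if node is origin:
            in_origin_subtree[id(node)] = True
        else:
            parent = node.parent_node
            in_origin_subtree[id(node)] = (
                parent is not None and in_origin_subtree[id(parent)]
            )

    states = {
        ids[id(n)]: in_origin_subtree[id(n)] and has_possessor[id(n)]
        for n in tree.preorder_node_iter()
    }
    losses = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if states[ids[id(parent)]] and not states[ids[id(node)]]:
            losses.append((ids[id(parent)], ids[id(node)]))
    return DolloReconstruction(
        family="",
        node_states=states,
        origin_node=ids[id(origin)],
        loss_edges=tuple(losses),
    )


def ancestral_repertoire(
    tree: SpeciesTree,
    matrix: RepertoireMatrix,
    node_label: str,
) -> set:
    """Families inferred present at a named internal node under Dollo."""
    ids = _indexed_nodes(tree)
    if node_label not in ids.values():
        raise ValueError(f"no tree node labelled {node_label!r}")
    tree_leaves = {n.taxon.label for n in tree.leaf_node_iter()}
    missing = set(matrix.species) - tree_leaves
    if missing:
        raise ValueError(f"matrix species not in tree: {sorted(missing)}")
    pres = matrix.presence()
    out = set()
    for family in matrix.families:
        bits = {sp: bool(pres.loc[sp, family]) for sp in matrix.species}
        # leaves absent from the matrix are scored absent
        for leaf in tree_leaves - set(bits):
            bits[leaf] = False
        rec = dollo_reconstruct(tree, bits)
        if rec.node_states.get(node_label, False):
            out.add(family)
    return out


def repertoire_summary(matrix: RepertoireMatrix) -> pd.DataFrame:
    """Per-species totals: gene count, families present, single-copy families."""
    if matrix.counts.empty:
        raise ValueError("empty repertoire matrix")
    c = matrix.counts
    return pd.DataFrame(
        {
            "total_genes": c.sum(axis=1),
            "families_present": (c >= 1).sum(axis=1),
            "single_copy_families": (c == 1).sum(axis=1),
        }
    )


# ---------------------------------------------------------------------------
# packaged fixtures (text-derived)
# ---------------------------------------------------------------------------

#: The 17 DNA-methylation / NuRD gene families-subfamilies surveyed:
#: writers (Dnmt), modifiers (Tet, Tdg), readers (Mbd, Uhrf) and NuRD
#: remodeller/deacetylase components (Chd3/4/5, Hdac1/2, Mta, Rbbp, Gatad2).
FAMILIES: tuple[str, ...] = (
    "Dnmt1",
    "Dnmt2",
    "Dnmt3",
    "Tet",
    "Tdg",
    "Uhrf",
    "Mbd1/2/3",
    "Mbd4",
    "Chd1/2",
    "Chd3/4/5",
    "Chd6/7/8/9",
    "Hdac1/2",
    "Hdac3",
    "Hdac8",
    "Rbbp4/7",
    "Mta1/2/3",
    "Gatad2",
)

# Platynereis dumerilii gene counts: single-copy for every family except
# the Chd3/4/5 subfamily, which has four members (six chd genes in total).
_PDUM_COUNTS = {f: (4 if f == "Chd3/4/5" else 1) for f in FAMILIES}

_DEMO_TREE_NEWICK = (
    "((((Homo_sapiens,Ciona_intestinalis)Deuterostomia,"
    "Drosophila_melanogaster,Platynereis_dumerilii)Bilateria,"
    "Nematostella_vectensis)Eumetazoa,Amphimedon_queenslandica)Metazoa;"
)

# Synthetic demo matrix: a 6-species stand-in encoding the per-clade
# presence statements of the survey (full Mbd repertoire in sponges,
# cnidarians and bilaterians; dipteran losses of Dnmt1/Dnmt3/Uhrf), not a
# transcription of any published 54-species figure.
_DEMO_COUNTS = {
    "Homo_sapiens": {
        **{f: 1 for f in FAMILIES},
        "Dnmt3": 3, "Tet": 3, "Uhrf": 2, "Mbd1/2/3": 3, "Chd3/4/5": 3,
        "Chd1/2": 2, "Chd6/7/8/9": 4, "Hdac1/2": 2, "Rbbp4/7": 2, "Mta1/2/3": 3,
    },
    "Ciona_intestinalis": {f: 1 for f in FAMILIES},
    "Drosophila_melanogaster": {
        **{f: 1 for f in FAMILIES},
        "Dnmt1": 0, "Dnmt3": 0, "Uhrf": 0,
    },
    "Platynereis_dumerilii": dict(_PDUM_COUNTS),
    "Nematostella_vectensis": {f: 1 for f in FAMILIES},
    "Amphimedon_queenslandica": {f: 1 for f in FAMILIES},
}


def platynereis_repertoire() -> RepertoireMatrix:
    """The text-derived single-species P. dumerilii repertoire vector."""
    df = pd.DataFrame.from_dict(
        {"Platynereis_dumerilii": _PDUM_COUNTS}, orient="index", columns=list(FAMILIES)
    )
    return RepertoireMatrix(df)


def demo_metazoan_tree() -> SpeciesTree:
    """Small rooted metazoan demo tree with labelled internal clades."""
    return load_tree(_DEMO_TREE_NEWICK, is_path=False)


def demo_metazoan_matrix() -> RepertoireMatrix:
    """Synthetic 6-species demo matrix matching :func:`demo_metazoan_tree`."""
    df = pd.DataFrame.from_dict(_DEMO_COUNTS, orient="index", columns=list(FAMILIES))
    return RepertoireMatrix(df)
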