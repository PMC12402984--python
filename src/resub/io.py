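"""Reading and writing alignments, dated trees, traces and score matrices."""

from __future__ import annotations

import numpy as np

from .likelihood import Alignment, TimeTree
from .substitution import Alphabet, ValidationError, protein_alphabet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_newick_dated",
    "write_newick",
    "read_score_matrix",
    "blosum62",
]


def read_fasta(path, alphabet: Alphabet | None = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are uppercased; duplicate identifiers and residues outside
    the alphabet (plus gap/ambiguity codes) are rejected with the
    offending record named.
    """
    from Bio import SeqIO

    alphabet = alphabet if alphabet is not None else protein_alphabet()
    taxa: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in taxa:
            raise ValidationError(f"{path}: duplicate sequence identifier {rec.id!r}")
        taxa.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not taxa:
        raise ValidationError(f"{path}: no FASTA records found")
    try:
        return Alignment(tuple(taxa), tuple(seqs), alphabet)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_newick_dated(path, schema: str | None = None, require_ultrametric: bool = True,
                      tol: float = 1e-6) -> TimeTree:
    """Read a rooted, binary, dated tree (Newick or NEXUS).

    Branch lengths are in time units; node heights are reconstructed with
    the most recent leaf at height zero.  With ``require_ultrametric``
    (the default) any leaf off height zero beyond ``tol`` is an error;
    disable it for serially sampled trees.  Polytomies are rejected.
    """
    import dendropy

    if schema is None:
        with open(path) as fh:
            head = fh.read(512).lstrip().lower()
        schema = "nexus" if head.startswith("#nexus") else "newick"
    dtree = dendropy.Tree.get(path=str(path), schema=schema, rooting="force-rooted")
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    depth = np.zeros(len(nodes))
    for nd in nodes:
        if nd.parent_node is not None:
            if nd.edge.length is None:
                raise ValidationError(f"{path}: branch lengths are required")
            depth[index[id(nd)]] = depth[index[id(nd.parent_node)]] + nd.edge.length
    leaf_ids = [index[id(nd)] for nd in nodes if nd.is_leaf()]
    span = depth[leaf_ids].max()
    heights = span - depth
    heights[np.abs(heights) <= tol] = 0.0
    if require_ultrametric:
        for nd in nodes:
            if nd.is_leaf() and heights[index[id(nd)]] > tol:
                label = nd.taxon.label if nd.taxon else "?"
                raise ValidationError(
                    f"{path}: tree is not ultrametric; leaf {label!r} sits "
                    f"{heights[index[id(nd)]]:.3g} above the present"
                )
    labels: list[str | None] = [
        (nd.taxon.label if nd.taxon else None) if nd.is_leaf() else None for nd in nodes
    ]
    parent = np.array(
        [index[id(nd.parent_node)] if nd.parent_node else -1 for nd in nodes], dtype=int
    )
    try:
        return TimeTree(parent, heights, labels)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None


def write_newick(tree: TimeTree, path=None) -> str:
    """Serialise a TimeTree to Newick with branch lengths in time units."""

    def render(node: int) -> str:
        if tree.is_leaf(node):
            body = tree.labels[node] or f"n{node}"
        else:
            body = "(" + ",".join(render(c) for c in tree.children[node]) + ")"
        p = tree.parent[node]
        if p < 0:
            return body
        return f"{body}:{tree.heights[p] - tree.heights[node]:.12g}"

    text = render(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_score_matrix(path):
    """Read an NCBI-format substitution score matrix (e.g. BLOSUM62)."""
    from Bio.Align import substitution_matrices

    with open(path) as fh:
        return substitution_matrices.read(fh)


def blosum62():
    """The standard BLOSUM62 amino acid score matrix."""
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")
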