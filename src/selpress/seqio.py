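"""Reading, writing and validating codon alignments, trees and annotations.

Conventions
-----------
* Codon sites are 1-based in all reports and error messages, 0-based
  internally.
* Gap ("---") and ambiguous codons are missing data.
* Foreground branches are tagged in Newick with a ``#1`` suffix on the node
  (tip or internal) label.  A tag on an internal node marks the whole clade
  below it **plus its stem branch** as foreground, mirroring how clades are
  marked for branch models ("up to, and including, the last common
  ancestor").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO

from .codon_model import genetic_code


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Well-formed input that violates a biological invariant."""


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

GAP_CODE = -1


@dataclass
class CodonAlignment:
    """taxa x codon-site matrix over sense codons; -1 encodes gap/ambiguous."""

    taxa: list[str]
    codes: np.ndarray  # (n_taxa, n_sites) int16
    genetic_code_id: int = 1

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.taxa.index(taxon)]

    def codon_string(self, taxon: str) -> str:
        code = genetic_code(self.genetic_code_id)
        return "".join(
            code.codons[c] if c >= 0 else "---" for c in self.row(taxon)
        )

    def protein(self, taxon: str, gap_char: str = "-") -> str:
        """One-letter amino-acid sequence; missing codons become gap_char."""
        code = genetic_code(self.genetic_code_id)
        return "".join(
            code.amino_acids[c] if c >= 0 else gap_char for c in self.row(taxon)
        )

    def subset_sites(self, start: int, stop: int) -> "CodonAlignment":
        """Codon columns [start, stop) in 0-based coordinates."""
        return CodonAlignment(list(self.taxa), self.codes[:, start:stop].copy(),
                              self.genetic_code_id)

    def subset_taxa(self, taxa: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(list(taxa), self.codes[idx].copy(),
                              self.genetic_code_id)


def _encode_sequence(name: str, seq: str, code) -> list[int]:
    if len(seq) % 3 != 0:
        raise FormatError(
            f"sequence {name!r} has length {len(seq)}, not divisible by 3"
        )
    n_sites = len(seq) // 3
    out = []
    for s in range(n_sites):
        codon = seq[3 * s: 3 * s + 3].upper().replace("U", "T")
        if codon in code.index:
            out.append(code.index[codon])
        elif codon in code.stop_codons:
            if s == n_sites - 1:
                warnings.warn(
                    f"terminal stop codon in {name!r} treated as missing data",
                    stacklevel=3,
                )
                out.append(GAP_CODE)
            else:
                raise ValidationError(
                    f"internal stop codon {codon} in taxon {name!r} "
                    f"at codon site {s + 1}"
                )
        else:
            out.append(GAP_CODE)  # gap or ambiguity -> missing
    return out


def codon_alignment_from_sequences(
    records: list[tuple[str, str]], genetic_code_id: int = 1
) -> CodonAlignment:
    """Build a validated alignment from (name, nucleotide string) pairs."""
    if not records:
        raise FormatError("no sequences")
    names = [n for n, _ in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate taxa: {dupes}")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise FormatError(f"sequences have unequal lengths {sorted(lengths)}")
    code = genetic_code(genetic_code_id)
    rows = [_encode_sequence(n, s, code) for n, s in records]
    return CodonAlignment(names, np.array(rows, dtype=np.int16), genetic_code_id)


def read_codon_alignment(path, genetic_code_id: int = 1) -> CodonAlignment:
    """Read a codon-aligned FASTA file."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return codon_alignment_from_sequences(records, genetic_code_id)


def write_codon_alignment(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for taxon in aln.taxa:
            fh.write(f">{taxon}\n{aln.codon_string(taxon)}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    label: str | None = None
    length: float | None = None  # branch above this node; None = unset
    foreground: bool = False
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False)

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted tree with branch lengths and per-branch foreground flags.

    Every non-root node carries the branch (edge) leading to it; ``branch_id``
    is the tip label for terminal branches and a stable ``n<k>`` postorder
    index for internal branches.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._index()

    def _index(self) -> None:
        for i, node in enumerate(self.postorder()):
            node.branch_id = node.label if node.is_tip else f"n{i}"
            for child in node.children:
                child.parent = node
        self.root.parent = None

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def visit(node: TreeNode) -> None:
            for c in node.children:
                visit(c)
            out.append(node)

        visit(self.root)
        return out

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def branches(self) -> list[TreeNode]:
        """All non-root nodes, i.e. one per branch."""
        return [n for n in self.postorder() if n.parent is not None]

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length, node.foreground)
            new.children = [clone(c) for c in node.children]
            return new

        return PhyloTree(clone(self.root))

    def find_tip(self, label: str) -> TreeNode:
        for t in self.tips():
            if t.label == label:
                return t
        raise ValidationError(f"tip {label!r} not in tree")

    def mrca(self, tip_labels) -> TreeNode:
        tip_labels = set(tip_labels)
        if not tip_labels:
            raise ValidationError("empty tip set")
        missing = tip_labels - set(self.tip_labels)
        if missing:
            raise ValidationError(f"tips not in tree: {sorted(missing)}")
        node_sets: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                node_sets[id(node)] = {node.label}
            else:
                node_sets[id(node)] = set().union(
                    *(node_sets[id(c)] for c in node.children)
                )
            if tip_labels <= node_sets[id(node)]:
                return node
        raise ValidationError("mrca not found")  # pragma: no cover

    def clade_tips(self, node: TreeNode) -> set[str]:
        return {t.label for t in self.postorder() if t.is_tip
                and self._is_descendant(t, node)}

    @staticmethod
    def _is_descendant(node: TreeNode, ancestor: TreeNode) -> bool:
        while node is not None:
            if node is ancestor:
                return True
            node = node.parent
        return False

    # -- foreground marking -------------------------------------------------

    def mark_clade(self, tip_set) -> "PhyloTree":
        """Return a copy with the clade of ``tip_set`` (and its stem) marked.

        ``tip_set`` must be monophyletic: its MRCA's tip set must equal it.
        """
        tip_set = set(tip_set)
        if not tip_set:
            raise ValidationError("empty tip set")
        new = self.copy()
        mrca = new.mrca(tip_set)
        clade = new.clade_tips(mrca)
        if clade != tip_set:
            raise ValidationError(
                f"tip set is not monophyletic: clade of its MRCA also "
                f"contains {sorted(clade - tip_set)}"
            )
        for node in new.postorder():
            node.foreground = False

        def mark(node: TreeNode) -> None:
            node.foreground = True
            for c in node.children:
                mark(c)

        mark(mrca)  # marks the clade plus the MRCA's own (stem) branch
        if mrca.parent is None:
            raise ValidationError(
                "cannot mark the whole tree as foreground (no background left)"
            )
        return new

    # -- structure edits ----------------------------------------------------

    def prune_to_taxa(self, keep) -> "PhyloTree":
        """Restrict to ``keep`` tips, suppressing unifurcations (lengths add)."""
        keep = set(keep)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValidationError(f"tips not in tree: {sorted(missing)}")
        new = self.copy()

        def prune(node: TreeNode) -> TreeNode | None:
            if node.is_tip:
                return node if node.label in keep else None
            kept = [c for c in (prune(c) for c in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if child.length is not None and node.length is not None:
                    child.length += node.length
                elif node.length is not None:
                    child.length = node.length
                child.foreground = child.foreground or node.foreground
                return child
            node.children = kept
            return node

        root = prune(new.root)
        if root is None:
            raise ValidationError("pruning removed all tips")
        root.length = None
        return PhyloTree(root)

    # -- Newick -------------------------------------------------------------

    def newick(self, include_foreground: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            # tag only the maximal foreground nodes; the reader propagates
            # a tag to the whole subtree, so clade-shaped marks round-trip
            tag = ""
            if (include_foreground and node.foreground
                    and node.parent is not None and not node.parent.foreground):
                tag = "#1"
            label = node.label or ""
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                body = f"({inner}){label}{tag}"
            else:
                body = f"{label}{tag}"
            if node.length is not None:
                body += f":{node.length:.10g}"
            return body

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self.tip_labels)} tips)"


_FG_TAG = "#1"


def _from_dendropy(dnode) -> TreeNode:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    fg = False
    if label and label.endswith(_FG_TAG):
        label = label[: -len(_FG_TAG)]
        fg = True
    node = TreeNode(label=label or None, length=dnode.edge.length,
                    foreground=fg)
    node.children = [_from_dendropy(c) for c in dnode.child_nodes()]
    return node


def read_tree(source, alignment: CodonAlignment | None = None) -> PhyloTree:
    """Read a single rooted Newick tree.

    ``source`` is a path or a Newick string.  ``#1`` suffix tags on node
    labels mark foreground clades (the tagged node's subtree plus its stem).
    If ``alignment`` is given, tree tips must cover the alignment's taxa.
    """
    text = str(source)
    if "(" not in text:
        with open(text) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate tip labels: {exc}") from exc
        raise FormatError(f"unreadable Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = None
    tree = PhyloTree(root)

    # propagate clade tags downward
    def propagate(node: TreeNode, fg: bool) -> None:
        node.foreground = node.foreground or fg
        for c in node.children:
            propagate(c, node.foreground)

    propagate(tree.root, False)
    tree.root.foreground = False

    labels = tree.tip_labels
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate tip labels: {dupes}")
    if alignment is not None:
        validate_taxa(tree, alignment)
    return tree


def validate_taxa(tree: PhyloTree, aln: CodonAlignment) -> None:
    """Tree tips must be a superset of alignment taxa (prune afterwards)."""
    missing = set(aln.taxa) - set(tree.tip_labels)
    if missing:
        raise ValidationError(
            f"alignment taxa missing from tree: {sorted(missing)}"
        )


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# Domain annotations
# ---------------------------------------------------------------------------


@dataclass
class DomainAnnotation:
    """Per-species 1-based codon index of the first mature-domain codon."""

    boundaries: dict[str, int]

    def boundary(self, species: str) -> int:
        try:
            return self.boundaries[species]
        except KeyError:
            raise ValidationError(f"no cleavage boundary for {species!r}")


def read_domain_annotation(path) -> DomainAnnotation:
    """TSV with columns species, boundary (header optional)."""
    boundaries: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"line {line_no}: expected 2 columns")
            if line_no == 1 and not parts[1].lstrip("-").isdigit():
                continue  # header
            species, boundary = parts[0], int(parts[1])
            if boundary <= 1:
                raise ValidationError(
                    f"{species}: boundary must be > 1 (cleaved domain empty)"
                )
            boundaries[species] = boundary
    if not boundaries:
        raise FormatError("no annotation rows")
    return DomainAnnotation(boundaries)


def write_domain_annotation(ann: DomainAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tboundary\n")
        for sp, b in ann.boundaries.items():
            fh.write(f"{sp}\t{b}\n")
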