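"""File formats and shared domain types.

Protein alignments (FASTA, relaxed PHYLIP), Newick trees, and binary
species x trait presence/absence matrices (TSV) are the three currencies
every downstream stage trades in.  Trees are represented as
:class:`dendropy.Tree` objects throughout; alignments and trait matrices
get thin dedicated containers because the downstream numerics want
array views rather than sequence records.

Character conventions: the 20 amino-acid one-letter codes plus ``-``,
``X`` and ``?``.  The three non-residue symbols are all treated as a
single "missing" state by every likelihood and distance computation.
Sites are 0-based internally and 1-based in written reports.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

__all__ = [
    "AMINO_ACIDS",
    "MISSING_CODE",
    "FormatError",
    "Alignment",
    "TraitMatrix",
    "Hypothesis",
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_tree",
    "tree_from_newick",
    "tree_splits",
    "label_internal_nodes",
    "read_trait_matrix",
    "write_trait_matrix",
    "read_hypotheses",
]

#: Canonical residue order used for integer encoding.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Integer code shared by '-', 'X' and '?' (one marginalized missing state).
MISSING_CODE = 20

_MISSING_CHARS = frozenset("-X?")
_ALPHABET = frozenset(AMINO_ACIDS) | _MISSING_CHARS
_CODE_OF = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE_OF.update({c: MISSING_CODE for c in _MISSING_CHARS})


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class Alignment:
    """Taxa x sites character matrix over the amino-acid alphabet.

    Parameters
    ----------
    taxa:
        Ordered unique taxon labels, one per row.
    chars:
        ``(n_taxa, n_sites)`` array of single uppercase characters.
    """

    taxa: list[str]
    chars: np.ndarray

    def __post_init__(self) -> None:
        self.chars = np.asarray(self.chars, dtype="U1")
        if self.chars.ndim != 2:
            raise FormatError("alignment character matrix must be 2-D")
        if len(self.taxa) != self.chars.shape[0]:
            raise FormatError("taxon count does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise FormatError(f"duplicate taxon name(s): {', '.join(dup)}")
        if any(not t for t in self.taxa):
            raise FormatError("empty taxon name")
        if self.n_taxa < 2:
            raise FormatError("alignment needs at least 2 taxa")
        if self.n_sites < 1:
            raise FormatError("alignment needs at least 1 site")
        bad = set(np.unique(self.chars)) - _ALPHABET
        if bad:
            raise FormatError(f"illegal characters in alignment: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return self.chars.shape[0]

    @property
    def n_sites(self) -> int:
        return self.chars.shape[1]

    def encoded(self) -> np.ndarray:
        """Integer-encoded matrix: 0..19 residues, 20 missing (int8)."""
        lut = np.full(128, -1, dtype=np.int8)
        for ch, code in _CODE_OF.items():
            lut[ord(ch)] = code
        return lut[self.chars.view(np.uint32).astype(np.intp) & 0x7F]

    def sequence(self, taxon: str) -> str:
        return "".join(self.chars[self.taxa.index(taxon)])

    def subset_sites(self, keep: np.ndarray) -> "Alignment":
        """New alignment restricted to the given site indices, in order."""
        keep = np.asarray(keep, dtype=int)
        return Alignment(list(self.taxa), self.chars[:, keep])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.chars.shape == other.chars.shape
            and bool((self.chars == other.chars).all())
        )


@dataclass
class TraitMatrix:
    """Species x trait binary (0/1) presence/absence matrix.

    ``data`` is a pandas DataFrame indexed by species with trait columns;
    ``categories`` optionally maps a subset of traits to functional
    category labels (e.g. the ten hyphal-morphogenesis categories).
    """

    data: pd.DataFrame
    categories: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise FormatError("duplicate species or trait labels")
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise FormatError(
                f"non-binary cell at species {self.data.index[bad[0]]!r}, "
                f"trait {self.data.columns[bad[1]]!r}"
            )
        self.data = self.data.astype(np.int8)
        if self.categories is not None:
            unknown = set(self.categories.index) - set(self.data.columns)
            if unknown:
                raise FormatError(
                    f"category map names unknown trait(s): {sorted(unknown)[:5]}"
                )
            if (self.categories.astype(str) == "").any():
                raise FormatError("empty category name in category map")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def category_sizes(self) -> pd.Series:
        if self.categories is None:
            raise ValueError("no category map attached")
        return self.categories.value_counts()


@dataclass(frozen=True)
class Hypothesis:
    """A named unrooted split: ``clade`` is one side of the bipartition."""

    name: str
    clade: frozenset

    def validate(self, taxa) -> None:
        taxa = set(taxa)
        missing = self.clade - taxa
        if missing:
            raise ValueError(
                f"hypothesis {self.name!r} names taxa absent from the tree set: "
                f"{sorted(missing)}"
            )
        if not (2 <= len(self.clade) <= len(taxa) - 2):
            raise ValueError(
                f"hypothesis {self.name!r} is a trivial split "
                f"({len(self.clade)} of {len(taxa)} taxa)"
            )


# ---------------------------------------------------------------------------
# Alignment I/O


def _alignment_from_pairs(pairs) -> Alignment:
    taxa, rows = [], []
    for name, seq in pairs:
        taxa.append(name)
        rows.append(seq.upper())
    if not rows:
        raise FormatError("no sequences found")
    n = len(rows[0])
    for name, row in zip(taxa, rows):
        if len(row) != n:
            raise FormatError(
                f"ragged alignment: row {name!r} has {len(row)} sites, expected {n}"
            )
    chars = np.array([list(r) for r in rows], dtype="U1")
    return Alignment(taxa, chars)


def read_alignment(path, dialect: str = "fasta") -> Alignment:
    """Read a protein alignment (``fasta`` or ``phylip-relaxed``).

    Lowercase residues are uppercased; taxon order follows the file.
    """
    if dialect == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        return _alignment_from_pairs((r.id, str(r.seq)) for r in records)
    if dialect == "phylip-relaxed":
        try:
            msa = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as exc:
            raise FormatError(f"bad relaxed PHYLIP file {path}: {exc}") from exc
        return _alignment_from_pairs((r.id, str(r.seq)) for r in msa)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_alignment(aln: Alignment, path, dialect: str = "fasta") -> None:
    rows = ["".join(row) for row in aln.chars]
    with open(path, "w", newline="\n") as fh:
        if dialect == "fasta":
            for name, seq in zip(aln.taxa, rows):
                fh.write(f">{name}\n{seq}\n")
        elif dialect == "phylip-relaxed":
            fh.write(f" {aln.n_taxa} {aln.n_sites}\n")
            width = max(len(t) for t in aln.taxa)
            for name, seq in zip(aln.taxa, rows):
                fh.write(f"{name:<{width}}  {seq}\n")
        else:
            raise ValueError(f"unknown alignment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Trees


def tree_from_newick(text: str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree.

    Internal node labels are kept verbatim (typical use: support values).
    """
    if text.count("(") != text.count(")"):
        # locate the first offending position for the error message
        depth = 0
        offset = len(text)
        for i, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            if depth < 0:
                offset = i
                break
        raise FormatError(f"unbalanced parentheses in Newick (near offset {offset})")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def read_tree(path, rooted: bool | None = None) -> dendropy.Tree:
    with open(path) as fh:
        return tree_from_newick(fh.read(), rooted=rooted)


def write_tree(tree: dendropy.Tree, path=None) -> str:
    """Serialize to Newick; returns the text, optionally writing it."""
    text = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    )
    if path is not None:
        with open(path, "w", newline="\n") as fh:
            fh.write(text)
    return text


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def tree_splits(tree: dendropy.Tree) -> set:
    """Non-trivial unrooted splits as frozensets of leaf labels.

    Each split is normalized to the side *not* containing the
    lexicographically smallest label, so complementary duplicates can
    never occur and rooted/unrooted views of the same topology yield
    identical sets.
    """
    labels = leaf_labels(tree)
    all_set = frozenset(labels)
    ref = min(labels)
    n = len(labels)
    splits: set = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not (2 <= len(side) <= n - 2):
            continue
        if ref in side:
            side = all_set - side
        splits.add(side)
    return splits


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "N") -> dendropy.Tree:
    """Assign stable preorder labels to unlabelled internal nodes.

    Existing labels (internal or leaf) are never reused, so node labels
    are unique afterwards.
    """
    used = {lf.taxon.label for lf in tree.leaf_node_iter()}
    used |= {
        n.label for n in tree.preorder_node_iter() if not n.is_leaf() and n.label
    }
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label:
            continue
        while f"{prefix}{i}" in used:
            i += 1
        node.label = f"{prefix}{i}"
        used.add(node.label)
    return tree


# ---------------------------------------------------------------------------
# Trait matrices


def read_trait_matrix(path, category_path=None) -> TraitMatrix:
    """Read a species x trait 0/1 TSV; optional trait->category TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    categories = None
    if category_path is not None:
        cat = pd.read_csv(
            category_path, sep="\t", header=None, names=["trait", "category"]
        )
        if len(cat):
            categories = pd.Series(
                cat["category"].astype(str).values, index=cat["trait"].astype(str)
            )
    return TraitMatrix(df, categories)


def write_trait_matrix(matrix: TraitMatrix, path, category_path=None) -> None:
    with open(path, "w", newline="\n") as fh:
        matrix.data.to_csv(fh, sep="\t")
    if category_path is not None and matrix.categories is not None:
        with open(category_path, "w", newline="\n") as fh:
            for trait, category in matrix.categories.items():
                fh.write(f"{trait}\t{category}\n")


def read_hypotheses(path) -> list[Hypothesis]:
    """Read hypotheses: one per line, ``name<TAB>leaf1,leaf2,...``."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, leaves = line.split("\t")
            out.append(Hypothesis(name, frozenset(leaves.split(","))))
    return out
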