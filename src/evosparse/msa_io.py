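"""Reading and validation of alignments, partition files, trees and tables.

The input side of evolutionary sparse learning: a multiple sequence
alignment (FASTA or relaxed sequential PHYLIP), a partition of alignment
positions into named groups (genes), and a binary response defined either
by an internal branch of a phylogeny (the clade below it is the +1 class)
or by an explicit taxon-to-class table.

All user-facing position coordinates are 1-based.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDE_STATES = "ACGT"
AMINO_ACID_STATES = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-?")

# IUPAC ambiguity codes mapped to their constituent unambiguous states.
NUCLEOTIDE_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
AMINO_ACID_AMBIGUITY = {
    "B": "DN", "Z": "EQ", "J": "IL", "X": AMINO_ACID_STATES,
}


class AlignmentError(ValueError):
    """Malformed alignment: ragged rows, bad identifiers or characters."""


class PartitionError(ValueError):
    """Malformed or inconsistent group/partition definition."""


class TreeError(ValueError):
    """Branch lookup failures and degenerate bipartitions."""


def alphabet_states(alphabet: str) -> str:
    if alphabet == "nucleotide":
        return NUCLEOTIDE_STATES
    if alphabet == "amino_acid":
        return AMINO_ACID_STATES
    raise ValueError(f"unknown alphabet {alphabet!r}")


def ambiguity_map(alphabet: str) -> dict[str, str]:
    return NUCLEOTIDE_AMBIGUITY if alphabet == "nucleotide" else AMINO_ACID_AMBIGUITY


@dataclass
class Alignment:
    """S equal-length sequences over a nucleotide or amino-acid alphabet.

    Rows are stored uppercase; ``U`` is normalized to ``T`` for nucleotide
    data. ``'?'`` and ``'-'`` are both treated as missing/gap.
    """

    taxa: list[str]
    rows: list[str]
    alphabet: str

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("taxa and rows differ in length")
        if not self.rows:
            raise AlignmentError("empty alignment")
        if any(not t for t in self.taxa):
            raise AlignmentError("empty taxon identifier")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon identifiers: {dupes}")
        p = len(self.rows[0])
        if p < 1:
            raise AlignmentError("alignment has zero length")
        for name, row in zip(self.taxa, self.rows):
            if len(row) != p:
                raise AlignmentError(
                    f"ragged alignment: {name!r} has length {len(row)}, expected {p}"
                )
        allowed = (
            set(alphabet_states(self.alphabet))
            | set(ambiguity_map(self.alphabet))
            | GAP_CHARS
        )
        for name, row in zip(self.taxa, self.rows):
            bad = set(row) - allowed
            if bad:
                raise AlignmentError(
                    f"characters outside {self.alphabet} alphabet in {name!r}: "
                    f"{sorted(bad)}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        """Number of aligned positions p."""
        return len(self.rows[0])


def _normalize(seq: str, alphabet: str) -> str:
    seq = seq.upper().replace(".", "-")
    if alphabet == "nucleotide":
        seq = seq.replace("U", "T")
    return seq


def read_alignment(path, alphabet: str = "nucleotide") -> Alignment:
    """Read a FASTA (or relaxed sequential PHYLIP) alignment.

    Sequences are uppercased and, for nucleotide data, ``U`` is mapped to
    ``T``. Validation of row lengths, identifiers and characters happens in
    the :class:`Alignment` constructor.
    """
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    fmt = "fasta"
    if not first.startswith(">") and len(first.split()) == 2:
        try:
            int(first.split()[0]), int(first.split()[1])
            fmt = "phylip-relaxed"
        except ValueError:
            pass
    records = list(SeqIO.parse(path, fmt))
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    taxa = [r.id for r in records]
    rows = [_normalize(str(r.seq), alphabet) for r in records]
    return Alignment(taxa=taxa, rows=rows, alphabet=alphabet)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.taxa, aln.rows):
            fh.write(f">{name}\n{row}\n")


@dataclass
class GroupMap:
    """Named groups (genes) of alignment positions with per-group weights.

    Positions are 1-based, possibly non-contiguous within a group, and no
    position may belong to two groups. The default group weight is
    sqrt(p(g)), the number of positions in the group — the usual
    sparse-group-lasso convention.
    """

    names: list[str]
    positions: list[tuple[int, ...]]
    weights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.positions):
            raise PartitionError("names and position sets differ in length")
        if len(set(self.names)) != len(self.names):
            raise PartitionError("duplicate group names")
        if not self.weights:
            self.weights = [math.sqrt(len(p)) for p in self.positions]
        if len(self.weights) != len(self.names):
            raise PartitionError("weights and names differ in length")
        seen: dict[int, str] = {}
        for name, poss, w in zip(self.names, self.positions, self.weights):
            if not poss:
                raise PartitionError(f"group {name!r} is empty")
            if w <= 0:
                raise PartitionError(f"group {name!r} has non-positive weight")
            for i in poss:
                if i < 1:
                    raise PartitionError(f"position {i} in group {name!r} is < 1")
                if i in seen:
                    raise PartitionError(
                        f"position {i} appears in groups {seen[i]!r} and {name!r}"
                    )
                seen[i] = name

    @property
    def n_groups(self) -> int:
        return len(self.names)

    def position_to_group(self) -> dict[int, str]:
        return {
            i: name for name, poss in zip(self.names, self.positions) for i in poss
        }

    def covered_positions(self) -> set[int]:
        return {i for poss in self.positions for i in poss}


_RAXML_LINE = re.compile(
    r"^\s*[A-Za-z0-9_.+]+\s*,\s*(?P<name>[^=\s][^=]*?)\s*=\s*(?P<ranges>[\d\s,\-\\/]+)\s*$"
)


def _parse_ranges(text: str, name: str) -> tuple[int, ...]:
    out: list[int] = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        # "start-end" possibly with a "\3" codon stride suffix is out of scope;
        # accept plain ranges and single positions.
        m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", part)
        if m:
            a, b = int(m.group(1)), int(m.group(2))
            if b < a:
                raise PartitionError(f"inverted range {part!r} in group {name!r}")
            out.extend(range(a, b + 1))
            continue
        if part.isdigit():
            out.append(int(part))
            continue
        raise PartitionError(f"unparseable range {part!r} in group {name!r}")
    return tuple(out)


def read_partitions(path, p: int, drop_ungrouped: bool = False) -> GroupMap:
    """Read a RAxML-style partition file or a 2-column (position, group) TSV.

    Every position in [1, p] must be covered unless ``drop_ungrouped`` is
    set, in which case uncovered positions are excluded (and counted in the
    log). Indices beyond ``p`` raise; overlapping groups raise.
    """
    names: list[str] = []
    positions: dict[str, list[int]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    raxml = any(_RAXML_LINE.match(ln) for ln in lines)
    if raxml:
        for ln in lines:
            m = _RAXML_LINE.match(ln)
            if not m:
                raise PartitionError(f"unparseable partition line: {ln!r}")
            name = m.group("name").strip()
            if name not in positions:
                names.append(name)
                positions[name] = []
            positions[name].extend(_parse_ranges(m.group("ranges"), name))
    else:
        for ln in lines:
            fields = re.split(r"[\t,]| +", ln.strip())
            fields = [f for f in fields if f]
            if len(fields) != 2:
                raise PartitionError(f"expected 2 columns, got {ln!r}")
            pos_s, name = fields
            if not pos_s.isdigit():
                if pos_s.lower() in {"position", "pos", "site"}:
                    continue  # header
                raise PartitionError(f"non-integer position {pos_s!r}")
            if name not in positions:
                names.append(name)
                positions[name] = []
            positions[name].append(int(pos_s))

    for name, poss in positions.items():
        over = [i for i in poss if i > p]
        if over:
            raise PartitionError(
                f"group {name!r} references positions beyond alignment "
                f"length {p}: {over[:5]}"
            )
    gmap = GroupMap(
        names=names, positions=[tuple(sorted(positions[n])) for n in names]
    )
    uncovered = set(range(1, p + 1)) - gmap.covered_positions()
    if uncovered:
        if not drop_ungrouped:
            raise PartitionError(
                f"{len(uncovered)} alignment positions are not assigned to any "
                "group (pass drop_ungrouped=True to exclude them)"
            )
        logger.info("dropping %d ungrouped alignment positions", len(uncovered))
    return gmap


def read_tree(path) -> dendropy.Tree:
    """Read a newick tree; leaf labels must be unique."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate leaf labels in tree")
    return tree


def clade_members(tree: dendropy.Tree, branch) -> set[str]:
    """Leaf labels on the focal side of an internal branch.

    ``branch`` is either an internal node/edge label or an iterable of
    taxon names whose most recent common ancestor defines the clade. The
    complement of the returned set is the other class.
    """
    all_leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    node = None
    if isinstance(branch, str):
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            if nd.label == branch or (nd.edge and nd.edge.label == branch):
                node = nd
                break
        if node is None:
            raise TreeError(f"no internal branch labelled {branch!r}")
    else:
        wanted = set(branch)
        missing = wanted - all_leaves
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        taxa = [
            leaf.taxon
            for leaf in tree.leaf_node_iter()
            if leaf.taxon.label in wanted
        ]
        tree.is_rooted = True  # MRCA is taken relative to the seed node
        node = tree.mrca(taxa=taxa)
        if node is None:
            raise TreeError("could not resolve MRCA for the given taxa")
    members = {leaf.taxon.label for leaf in node.leaf_iter()}
    if not members or members == all_leaves:
        raise TreeError(
            "branch induces a degenerate bipartition (one side is empty)"
        )
    return members


def iter_internal_bipartitions(tree: dendropy.Tree):
    """Yield (node, frozenset-of-leaf-labels-below) for each internal branch.

    Branches whose below-set is empty or the whole leaf set are skipped
    (they do not induce a bipartition).
    """
    all_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    seen: set[frozenset] = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(leaf.taxon.label for leaf in nd.leaf_iter())
        if not below or below == all_leaves:
            continue
        key = min(below, all_leaves - below, key=sorted)
        if key in seen:
            continue
        seen.add(key)
        yield nd, below


def read_classes(path, positive_label: str = "+1") -> tuple[list[str], set[str]]:
    """Read a 2-column taxon→class TSV; returns (taxa in file order, positives).

    Labels equal to ``positive_label`` (or ``+1``/``1`` by default) are the
    +1 class; all other labels form the −1 class.
    """
    taxa: list[str] = []
    positives: set[str] = set()
    pos_labels = {positive_label}
    if positive_label == "+1":
        pos_labels.add("1")
    with open(path) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"expected 2 tab-separated columns, got {ln!r}")
            taxon, label = fields[0].strip(), fields[1].strip()
            if taxon.lower() in {"taxon", "sequence", "name"} and not taxa:
                continue
            taxa.append(taxon)
            if label in pos_labels:
                positives.add(taxon)
    if not taxa:
        raise ValueError(f"empty class table {path}")
    return taxa, positives


def read_categories(path, groups: GroupMap) -> dict[str, set[str]]:
    """Read a 2-column category→group TSV (overlapping categories allowed)."""
    cats: dict[str, set[str]] = {}
    known = set(groups.names)
    with open(path) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"expected 2 tab-separated columns, got {ln!r}")
            cat, grp = fields[0].strip(), fields[1].strip()
            if grp not in known:
                raise PartitionError(
                    f"category {cat!r} references unknown group {grp!r}"
                )
            cats.setdefault(cat, set()).add(grp)
    return cats
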