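"""Readers, writers and validation for alignments, trees and tabular inputs.

All downstream computation works on two small in-memory containers defined
here: :class:`Alignment` (names + residue matrix) and :class:`Phylogeny`
(rooted node structure with branch lengths in expected substitutions per
site). Parsing of the standard formats is delegated to Biopython (FASTA,
relaxed PHYLIP) and DendroPy (Newick); the containers only add the
validation the analysis needs (unique names, legal residue alphabet,
non-negative branch lengths, tip/alignment binding).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Residue order used throughout (matches the packaged replacement-matrix data).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: Codes treated as missing data (uniform partial likelihood downstream).
MISSING_CODES = {"-", "X"}
MISSING = -1


class FormatError(ValueError):
    """Raised when a file cannot be parsed in the declared format."""


class ValidationError(ValueError):
    """Raised when parsed content violates a container invariant."""


@dataclass
class Alignment:
    """A protein multiple alignment with a validated alphabet.

    Sites are 1-based in all user-facing labels (the first residue of the
    ligand-binding-domain alignment is position 1, so mutation labels such
    as ``V43A`` index directly into it). Internally residues are stored as
    integer codes into :data:`AMINO_ACIDS`; gaps and ``X`` are ``-1``.
    """

    names: list[str]
    codes: np.ndarray  # (nseq, nsites) int8; -1 = missing

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValidationError("residue matrix must be 2-D")
        if len(self.names) != self.codes.shape[0]:
            raise ValidationError(
                f"{len(self.names)} names for {self.codes.shape[0]} rows"
            )
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValidationError(f"duplicate sequence names: {dupes}")
        bad = (self.codes < -1) | (self.codes >= 20)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"illegal residue code in row {self.names[r]!r}, column {c + 1}"
            )

    @property
    def nseq(self) -> int:
        return self.codes.shape[0]

    @property
    def nsites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, name: str) -> str:
        row = self.codes[self.names.index(name)]
        return "".join("-" if c == MISSING else AMINO_ACIDS[c] for c in row)

    def row(self, name: str) -> np.ndarray:
        return self.codes[self.names.index(name)]

    @classmethod
    def from_sequences(cls, names: Sequence[str], seqs: Sequence[str]) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        mat = np.empty((len(seqs), lengths.pop() if lengths else 0), dtype=np.int8)
        for i, s in enumerate(seqs):
            for j, ch in enumerate(s.upper()):
                if ch in MISSING_CODES:
                    mat[i, j] = MISSING
                elif ch in AA_INDEX:
                    mat[i, j] = AA_INDEX[ch]
                else:
                    raise ValidationError(
                        f"illegal residue {ch!r} in row {names[i]!r}, column {j + 1}"
                    )
        return cls(list(names), mat)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.names == other.names and np.array_equal(self.codes, other.codes)


@dataclass
class Node:
    """One node of a rooted phylogeny; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float = 0.0
    length_missing: bool = False
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None
    index: int = -1  # assigned by Phylogeny._reindex

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Phylogeny:
    """Rooted tree with branch lengths in expected substitutions per site.

    The node list is kept in postorder (tips first within each clade, root
    last), which is the traversal order the pruning algorithm needs.
    """

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    def _reindex(self) -> None:
        self.nodes: list[Node] = list(self._postorder(self.root))
        for i, nd in enumerate(self.nodes):
            nd.index = i
        names = [nd.name for nd in self.tips()]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for nd in self.nodes:
            if nd is not self.root and nd.length < 0:
                raise ValidationError(
                    f"negative branch length {nd.length} above node {nd.name!r}"
                )

    @staticmethod
    def _postorder(node: Node) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(node, False)]
        while stack:
            nd, expanded = stack.pop()
            if expanded:
                yield nd
            else:
                stack.append((nd, True))
                for child in reversed(nd.children):
                    stack.append((child, False))

    def tips(self) -> list[Node]:
        return [nd for nd in self.nodes if nd.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [nd for nd in self.nodes if not nd.is_tip]

    @property
    def tip_names(self) -> list[str]:
        return [nd.name for nd in self.tips()]

    def find(self, name: str) -> Node:
        for nd in self.nodes:
            if nd.name == name:
                return nd
        raise KeyError(f"no node labelled {name!r}")

    def branches(self) -> list[Node]:
        """Every node that carries a branch (everything but the root)."""
        return [nd for nd in self.nodes if nd is not self.root]

    def bind(self, alignment: Alignment) -> None:
        """Check tip labels are exactly the alignment's names."""
        tips, rows = set(self.tip_names), set(alignment.names)
        if tips != rows:
            only_tree = sorted(tips - rows)
            only_aln = sorted(rows - tips)
            raise ValidationError(
                "tree and alignment labels differ; "
                f"tree-only: {only_tree}, alignment-only: {only_aln}"
            )

    def copy(self) -> "Phylogeny":
        def clone(nd: Node) -> Node:
            new = Node(nd.name, nd.length, nd.length_missing)
            for ch in nd.children:
                new.add(clone(ch))
            return new

        return Phylogeny(clone(self.root))

    def newick(self) -> str:
        def fmt(nd: Node) -> str:
            label = _quote_label(nd.name) if nd.name else ""
            if nd.is_tip:
                inner = label
            else:
                inner = "(" + ",".join(fmt(c) for c in nd.children) + ")" + label
            if nd is self.root:
                return inner
            return inner if nd.length_missing else f"{inner}:{nd.length:.17g}"

        return fmt(self.root) + ";"

    def __len__(self) -> int:
        return len(self.nodes)


def _quote_label(name: str) -> str:
    if any(ch in name for ch in "()[]{}:;,= \t'\""):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------------
# file-level readers / writers


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a protein alignment from FASTA or relaxed sequential PHYLIP."""
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise ValueError(f"unsupported alignment format {format!r}")
    path = Path(path)
    try:
        if fmt == "fasta":
            records = list(SeqIO.parse(str(path), "fasta"))
        else:
            records = list(AlignIO.read(str(path), fmt))
    except (ValueError, IndexError) as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise FormatError(f"no sequences found in {path}")
    names = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return Alignment.from_sequences(names, seqs)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise ValueError(f"unsupported alignment format {format!r}")
    records = [
        SeqRecord(Seq(aln.sequence(name)), id=name, description="")
        for name in aln.names
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, fmt)


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        nd = Node(
            name=label,
            length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
            length_missing=dnode.edge.length is None,
        )
        for dchild in dnode.child_nodes():
            nd.add(convert(dchild))
        return nd

    return Phylogeny(convert(dtree.seed_node))


def read_tree(path_or_string: str | Path) -> Phylogeny:
    """Read a Newick tree (quoted labels supported, branch lengths optional).

    Absent branch lengths default to 0.0 and are flagged ``length_missing``
    on the node. Support values embedded in internal labels are kept verbatim
    as labels: support is something this package produces, never consumes.
    """
    text = None
    p = Path(str(path_or_string))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_string)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick: {exc}") from exc
    return _from_dendropy(dtree)


def write_tree(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# tabular inputs

TABLE_SCHEMAS: dict[str, dict] = {
    # reporter-assay dose-response points; conc_M = 0 marks vehicle controls
    "dose_response": {
        "required": ["receptor", "hormone", "conc_M", "replicate", "response"],
        "numeric": ["conc_M", "response"],
    },
    # per-mutant stability predictions, one column per independent run
    "ddg": {"required": ["mutant"], "numeric_prefix": "run", "numeric": []},
    # pairing of mutant labels with fitted log10 EC50 values
    "ec50": {"required": ["mutant", "logEC50"], "numeric": ["logEC50"]},
}


class SchemaError(ValueError):
    """Raised when a table is missing required columns."""


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a delimited table (comma or tab, sniffed) against a named schema."""
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; know {sorted(TABLE_SCHEMAS)}")
    spec = TABLE_SCHEMAS[schema]
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        import warnings

        warnings.warn(f"{path} is empty; returning empty record set")
        return pd.DataFrame(columns=spec["required"])
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(_io.StringIO(text), sep=sep, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    numeric = list(spec["numeric"])
    if "numeric_prefix" in spec:
        numeric += [c for c in df.columns if c.startswith(spec["numeric_prefix"])]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        df[col] = converted
    return df
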