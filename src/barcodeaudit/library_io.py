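"""Reading and writing of reference libraries and trees.

A reference library couples an aligned FASTA file with a specimen metadata
table (TSV, tab-separated, header row, UTF-8; required columns
``specimen_id`` and ``species``, optional ``sex`` and ``region``). Inputs
must be pre-aligned: every sequence must have the same length. IUPAC
ambiguity codes other than N are mapped to N with a logged warning; U is
mapped to T and lowercase bases are uppercased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentLengthError,
    EmptyInputError,
    MetadataJoinError,
    NewickParseError,
)
from .tree import Tree, TreeNode

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN-")
UNAMBIGUOUS = frozenset("ACGT")
_AMBIGUITY = frozenset("RYSWKMBDHV")
SEXES = ("male", "female", "unknown")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned barcode sequence plus its specimen metadata."""

    specimen_id: str
    species: str
    sequence: str
    sex: str = "unknown"
    region: Optional[str] = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise ValueError(
                f"record {self.specimen_id!r}: invalid characters {sorted(bad)}"
            )
        if not set(self.sequence) & UNAMBIGUOUS:
            raise ValueError(
                f"record {self.specimen_id!r} has no unambiguous base"
            )


@dataclass
class ReferenceLibrary:
    """Ordered collection of equal-length :class:`SequenceRecord`."""

    records: List[SequenceRecord]
    alignment_length: int = field(init=False)
    species_index: Dict[str, List[str]] = field(init=False)

    def __post_init__(self):
        if not self.records:
            raise EmptyInputError("reference library has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            ref_len = len(self.records[0].sequence)
            bad = [r.specimen_id for r in self.records if len(r.sequence) != ref_len]
            raise AlignmentLengthError(
                f"sequences are not all the same length (lengths seen: "
                f"{sorted(lengths)}); offending ids: {', '.join(bad)}",
                offending_ids=bad,
            )
        self.alignment_length = lengths.pop()
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")
        self.species_index = {}
        for r in self.records:
            self.species_index.setdefault(r.species, []).append(r.specimen_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species(self) -> List[str]:
        return list(self.species_index)

    @property
    def singletons(self) -> List[str]:
        return [s for s, ids in self.species_index.items() if len(ids) == 1]

    def record(self, specimen_id: str) -> SequenceRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    def subset(self, specimen_ids: Iterable[str]) -> "ReferenceLibrary":
        keep = set(specimen_ids)
        return ReferenceLibrary([r for r in self.records if r.specimen_id in keep])


def _normalize_sequence(raw: str, specimen_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    if set(seq) & _AMBIGUITY:
        n_amb = sum(seq.count(c) for c in _AMBIGUITY)
        logger.warning(
            "record %s: %d IUPAC ambiguity code(s) mapped to N", specimen_id, n_amb
        )
        seq = "".join("N" if c in _AMBIGUITY else c for c in seq)
    return seq


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    for col in ("specimen_id", "species"):
        if col not in df.columns:
            raise ValueError(f"metadata table missing required column {col!r}")
    if df.empty:
        raise EmptyInputError(f"metadata table {path} has no rows")
    return df


def read_fasta(path, metadata) -> ReferenceLibrary:
    """Assemble a validated :class:`ReferenceLibrary` from FASTA + TSV.

    Records are returned in FASTA file order. Every FASTA id must appear in
    the metadata table; metadata rows without a FASTA record are ignored.
    """
    fasta_records = list(SeqIO.parse(str(path), "fasta"))
    if not fasta_records:
        raise EmptyInputError(f"FASTA file {path} contains no sequences")

    meta = read_metadata(metadata)
    by_id: Dict[str, dict] = {}
    for row in meta.to_dict("records"):
        by_id[str(row["specimen_id"])] = row

    missing = [r.id for r in fasta_records if r.id not in by_id]
    if missing:
        raise MetadataJoinError(
            f"{len(missing)} FASTA id(s) missing from metadata: "
            + ", ".join(missing[:20])
            + ("..." if len(missing) > 20 else ""),
            missing_ids=missing,
        )

    records = []
    for fr in fasta_records:
        row = by_id[fr.id]
        sex = row.get("sex")
        sex = sex if isinstance(sex, str) and sex in SEXES else "unknown"
        region = row.get("region")
        region = region if isinstance(region, str) and region else None
        records.append(
            SequenceRecord(
                specimen_id=fr.id,
                species=str(row["species"]),
                sequence=_normalize_sequence(str(fr.seq), fr.id),
                sex=sex,
                region=region,
            )
        )
    return ReferenceLibrary(records)


def write_fasta(lib: ReferenceLibrary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in lib.records:
            fh.write(f">{r.specimen_id}\n{r.sequence}\n")


def write_metadata(lib: ReferenceLibrary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("specimen_id\tspecies\tsex\tregion\n")
        for r in lib.records:
            fh.write(f"{r.specimen_id}\t{r.species}\t{r.sex}\t{r.region or ''}\n")


# ----------------------------------------------------------------------
# newick
# ----------------------------------------------------------------------

def write_newick(tree: Tree, path) -> None:
    """Serialize with branch lengths to 6 decimals and supports as internal
    node labels."""
    if tree.n_leaves() < 2:
        raise ValueError("tree must have at least 2 leaves")
    if any(not n for n in tree.leaf_names()):
        raise ValueError("all leaf labels must be non-empty")
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def parse_newick(text: str) -> Tree:
    """Parse a newick string into a :class:`Tree`.

    Missing branch lengths become 0; numeric internal node labels are
    interpreted as support values.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            "newick string must end with ';'", offset=len(stripped)
        )
    if stripped.count("(") != stripped.count(")"):
        # locate the first offending paren depth excursion for the offset
        depth = 0
        offset = None
        for i, ch in enumerate(stripped):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    offset = i
                    break
        if offset is None:
            offset = len(stripped)
        raise NewickParseError(
            f"unbalanced parentheses in newick string (offset {offset})",
            offset=offset,
        )
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        offset = getattr(exc, "col_num", None)
        raise NewickParseError(f"newick parse error: {exc}", offset=offset) from exc

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(name=name)
        else:
            node = TreeNode()
            label = dnode.label
            if label is not None:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            for child in dnode.child_nodes():
                node.add_child(convert(child))
        node.length = float(dnode.edge.length) if dnode.edge.length is not None else 0.0
        return node

    root = convert(dtree.seed_node)
    return Tree(root, rooted=False)


def read_newick(path) -> Tree:
    return parse_newick(Path(path).read_text(encoding="utf-8"))
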