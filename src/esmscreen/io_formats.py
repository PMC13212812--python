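"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTA (sequences and alignments), transmembrane-topology output in
two dialects (per-residue "threeline" strings and GFF3-like region tables),
tab-separated reports, and Newick trees.

Conventions: coordinates are 1-based inclusive throughout, matching
UniProt/GFF3 usage; sequences are uppercased on input; 'X' is an accepted
ambiguity code. Writers emit UTF-8 with LF line endings and, where the format
tolerates it, a comment header carrying the tool version and config hash.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "AMINO_ACIDS",
    "SEQUENCE_ALPHABET",
    "FAMILIES",
    "REGION_LABELS",
    "FormatError",
    "ProteinRecord",
    "TopologyAnnotation",
    "Msa",
    "read_fasta",
    "write_fasta",
    "read_topology",
    "write_topology_threeline",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "write_newick",
    "read_phosphosite_annotations",
]

TOOL_NAME = "esmscreen"

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Residues accepted in an unaligned protein sequence ('X' = unknown).
SEQUENCE_ALPHABET = AMINO_ACIDS | {"X"}
#: Recognised P-type ATPase subfamily labels.
FAMILIES = frozenset({"P1B", "P2A", "P2B", "P2C", "P4", "P5", "unknown"})
#: Topology region labels after dialect normalisation.
REGION_LABELS = frozenset({"inside", "outside", "TMhelix", "signal", "beta"})

# per-residue topology characters -> canonical region labels;
# periplasm ('P') is non-cytoplasmic, hence mapped to outside.
_CHAR_TO_LABEL = {
    "I": "inside",
    "O": "outside",
    "M": "TMhelix",
    "S": "signal",
    "B": "beta",
    "P": "outside",
}
_GFF_TO_LABEL = {
    "inside": "inside",
    "outside": "outside",
    "TMhelix": "TMhelix",
    "signal": "signal",
    "periplasm": "outside",
    "beta": "beta",
}
_FAMILY_RE = re.compile(r"\bfamily=(\S+)")


class FormatError(ValueError):
    """An input file violates its format contract."""


@dataclass
class ProteinRecord:
    """One protein sequence with its identifier and subfamily label."""

    id: str
    sequence: str
    description: str = ""
    family: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein id must be a non-empty token")
        if not self.sequence:
            raise FormatError(f"{self.id}: empty sequence")
        if self.family not in FAMILIES:
            raise FormatError(f"{self.id}: unknown family label {self.family!r}")
        bad = [
            (i + 1, c)
            for i, c in enumerate(self.sequence)
            if c not in SEQUENCE_ALPHABET
        ]
        if bad:
            pos, c = bad[0]
            raise FormatError(
                f"{self.id}: non-amino-acid character {c!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TopologyAnnotation:
    """Ordered, contiguous labelled regions over a protein's coordinates.

    Regions are (label, start, end) with 1-based inclusive coordinates; region
    i+1 starts at end_i + 1 and the first region starts at 1.
    """

    protein_id: str
    regions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if not self.regions:
            raise FormatError(f"{self.protein_id}: topology has no regions")
        expected_start = 1
        for label, start, end in self.regions:
            if label not in REGION_LABELS:
                raise FormatError(
                    f"{self.protein_id}: unknown region label {label!r}"
                )
            if start != expected_start:
                raise FormatError(
                    f"{self.protein_id}: region starting at {start} leaves a "
                    f"gap after position {expected_start - 1}"
                )
            if start > end:
                raise FormatError(
                    f"{self.protein_id}: region {label} has start {start} > end {end}"
                )
            expected_start = end + 1

    @property
    def length(self) -> int:
        return self.regions[-1][2]

    def to_string(self) -> str:
        """Per-residue topology string (inverse of the threeline dialect)."""
        label_to_char = {
            "inside": "I",
            "outside": "O",
            "TMhelix": "M",
            "signal": "S",
            "beta": "B",
        }
        return "".join(
            label_to_char[label] * (end - start + 1)
            for label, start, end in self.regions
        )


@dataclass
class Msa:
    """A protein multiple sequence alignment ('-' gaps, equal-length rows)."""

    records: list[tuple[str, str]]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FormatError("alignment needs at least 2 sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            for rid, seq in self.records:
                if len(seq) != len(self.records[0][1]):
                    raise FormatError(
                        f"ragged alignment: sequence {rid!r} has length "
                        f"{len(seq)}, expected {len(self.records[0][1])}"
                    )
        self.n_columns = len(self.records[0][1])
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate alignment id {dup!r}")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]


def _comment_header(config_hash: str | None) -> str:
    from . import __version__

    tag = f"; {TOOL_NAME} v{__version__}"
    if config_hash:
        tag += f" config_hash={config_hash}"
    return tag + " coordinates=1-based-inclusive\n"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences from FASTA.

    Sequences are uppercased, '*' stop characters stripped, and the subfamily
    parsed from an optional ``family=<label>`` key in the description. Leading
    ';' or '#' comment lines before the first header are ignored.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            rid = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            seq = seq.upper().replace("*", "")
            m = _FAMILY_RE.search(desc)
            family = m.group(1) if m else "unknown"
            if family not in FAMILIES:
                raise FormatError(f"{rid}: unknown family label {family!r}")
            if "-" in seq or "." in seq:
                raise FormatError(
                    f"{rid}: gap characters are not allowed in unaligned "
                    "sequences (use read_alignment for alignments)"
                )
            if rid in seen:
                raise FormatError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            records.append(
                ProteinRecord(id=rid, sequence=seq, description=desc, family=family)
            )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[ProteinRecord],
    path: str | Path,
    *,
    config_hash: str | None = None,
    width: int = 60,
) -> None:
    """Write records as FASTA, preserving ids, descriptions and family tags."""
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        out.write(_comment_header(config_hash))
        for rec in records:
            desc = rec.description
            if rec.family != "unknown" and f"family={rec.family}" not in desc:
                desc = (desc + f" family={rec.family}").strip()
            header = f">{rec.id} {desc}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Topology

def _runs_to_regions(protein_id: str, topo_string: str) -> TopologyAnnotation:
    regions: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(topo_string) + 1):
        if i == len(topo_string) or topo_string[i] != topo_string[start]:
            char = topo_string[start]
            if char not in _CHAR_TO_LABEL:
                raise FormatError(
                    f"{protein_id}: unknown topology character {char!r} "
                    f"at position {start + 1}"
                )
            label = _CHAR_TO_LABEL[char]
            # merge adjacent runs mapping to the same label (e.g. O then P)
            if regions and regions[-1][0] == label:
                regions[-1] = (label, regions[-1][1], i)
            else:
                regions.append((label, start + 1, i))
            start = i
    return TopologyAnnotation(protein_id=protein_id, regions=regions)


def _read_topology_threeline(handle: io.TextIOBase) -> dict[str, TopologyAnnotation]:
    annotations: dict[str, TopologyAnnotation] = {}
    lines = [ln.rstrip("\n") for ln in handle]
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise FormatError(f"expected '>' header, got {header!r}")
        rid = header[1:].split("|")[0].split()[0]
        if i + 2 >= len(lines):
            raise FormatError(f"{rid}: truncated threeline record")
        seq, topo = lines[i + 1], lines[i + 2]
        if len(seq) != len(topo):
            raise FormatError(
                f"{rid}: topology string length {len(topo)} does not match "
                f"sequence length {len(seq)}"
            )
        if rid in annotations:
            raise FormatError(f"duplicate topology id {rid!r}")
        annotations[rid] = _runs_to_regions(rid, topo)
        i += 3
    return annotations


def _read_topology_gff3(handle: io.TextIOBase) -> dict[str, TopologyAnnotation]:
    annotations: dict[str, TopologyAnnotation] = {}
    pending: dict[str, list[tuple[str, int, int]]] = {}
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line == "//":
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 4:
            raise FormatError(
                f"line {lineno}: expected 4 fields "
                f"(protein_id, label, start, end), got {len(fields)}"
            )
        rid, raw_label, s, e = fields
        if raw_label not in _GFF_TO_LABEL:
            raise FormatError(f"line {lineno}: unknown label {raw_label!r}")
        label = _GFF_TO_LABEL[raw_label]
        try:
            start, end = int(s), int(e)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinate") from exc
        regs = pending.setdefault(rid, [])
        if regs and regs[-1][0] == label and start == regs[-1][2] + 1:
            regs[-1] = (label, regs[-1][1], end)
        else:
            regs.append((label, start, end))
    for rid, regs in pending.items():
        annotations[rid] = TopologyAnnotation(protein_id=rid, regions=regs)
    return annotations


def read_topology(
    path: str | Path, dialect: str = "threeline"
) -> dict[str, TopologyAnnotation]:
    """Parse transmembrane-topology annotations.

    ``threeline``: per protein a ``>id`` header, the sequence, and a
    per-residue topology string over {I, O, M, S, B, P}. ``gff3``: region
    lines ``protein_id  label  start  end`` with '#' comments and ``//`` or
    blank record separators. Both dialects normalise to the same region
    labels; DeepTMHMM's periplasm calls map to ``outside``.
    """
    if dialect not in {"threeline", "gff3"}:
        raise ValueError(f"unknown topology dialect {dialect!r}")
    with open(path, encoding="utf-8") as handle:
        if dialect == "threeline":
            return _read_topology_threeline(handle)
        return _read_topology_gff3(handle)


def write_topology_threeline(
    entries: Sequence[tuple[ProteinRecord, TopologyAnnotation]],
    path: str | Path,
    *,
    config_hash: str | None = None,
) -> None:
    """Write (sequence, topology) pairs in the threeline dialect."""
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        out.write("#" + _comment_header(config_hash)[1:])
        for rec, topo in entries:
            if topo.length != len(rec):
                raise FormatError(
                    f"{rec.id}: topology length {topo.length} does not match "
                    f"sequence length {len(rec)}"
                )
            out.write(f">{rec.id}\n{rec.sequence}\n{topo.to_string()}\n")


# ---------------------------------------------------------------------------
# Alignments

def read_alignment(path: str | Path) -> Msa:
    """Read an aligned FASTA; '.' gaps are normalised to '-'."""
    records: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for title, seq in SimpleFastaParser(handle):
            rid = title.split()[0]
            seq = seq.upper().replace(".", "-")
            bad = [
                (i + 1, c)
                for i, c in enumerate(seq)
                if c not in SEQUENCE_ALPHABET and c != "-"
            ]
            if bad:
                pos, c = bad[0]
                raise FormatError(
                    f"{rid}: invalid alignment character {c!r} at column {pos}"
                )
            records.append((rid, seq))
    if len(records) < 2:
        raise FormatError(f"{path}: alignment needs at least 2 sequences")
    return Msa(records=records)


def write_alignment(
    msa: Msa, path: str | Path, *, config_hash: str | None = None, width: int = 60
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        out.write(_comment_header(config_hash))
        for rid, seq in msa.records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)

def write_newick(
    tree, path: str | Path, *, config_hash: str | None = None
) -> None:
    """Serialise a dendropy tree as Newick.

    Branch lengths are written to 6 decimals; integer bootstrap supports, when
    present as internal-node labels, are preserved. The file ends with ';' and
    a newline, preceded by a bracketed comment header.
    """
    newick = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        suppress_leaf_node_labels=False,
    ).strip()
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        header = _comment_header(config_hash).strip()[2:]
        out.write(f"[{header}]\n")
        out.write(newick + "\n")


def read_newick(path: str | Path):
    """Parse a Newick file back into an (unrooted) dendropy tree."""
    import dendropy

    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Curated phosphosite annotations

def read_phosphosite_annotations(path: str | Path) -> dict[str, set[int]]:
    """Read a curated phosphosite table: protein_id<TAB>position<TAB>residue."""
    sites: dict[str, set[int]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise FormatError(
                    f"line {lineno}: expected protein_id, position, residue"
                )
            rid, pos, residue = fields
            if residue.upper() not in {"S", "T", "Y"}:
                raise FormatError(
                    f"line {lineno}: residue {residue!r} is not S/T/Y"
                )
            try:
                sites.setdefault(rid, set()).add(int(pos))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer position") from exc
    return sites
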