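"""Sequence and label-table input/output.

Every downstream stage of the genotyping pipeline relies on the alphabet
contract established here: residues are uppercased, RNA is folded into the
DNA alphabet (U -> T), and alignment gap characters are stripped, because
the composition-vector representation consumes ungapped sequence.  IUPAC
ambiguity codes are retained in the record; k-mer counting skips windows
that contain them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

Alphabet = Literal["DNA", "PROTEIN"]

DNA_CANONICAL = frozenset("ACGT")
DNA_AMBIGUOUS = frozenset("NRYSWKMBDHV")
PROTEIN_CANONICAL = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_AMBIGUOUS = frozenset("XBZJUO")

_DNA_CHARS = DNA_CANONICAL | DNA_AMBIGUOUS
_PROTEIN_CHARS = PROTEIN_CANONICAL | PROTEIN_AMBIGUOUS
_GAP_CHARS = "-."


class SequenceIOError(ValueError):
    """Raised for malformed sequence or label input."""


def canonical_characters(alphabet: Alphabet) -> frozenset[str]:
    """Characters that participate in k-mer counting for *alphabet*."""
    return DNA_CANONICAL if alphabet == "DNA" else PROTEIN_CANONICAL


def allowed_characters(alphabet: Alphabet) -> frozenset[str]:
    return _DNA_CHARS if alphabet == "DNA" else _PROTEIN_CHARS


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled biological sequence with a validated alphabet."""

    id: str
    residues: str
    alphabet: Alphabet = "DNA"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceIOError("sequence record requires a non-empty id")
        if not self.residues:
            raise SequenceIOError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - allowed_characters(self.alphabet)
        if bad:
            raise SequenceIOError(
                f"record {self.id!r} contains characters outside the "
                f"{self.alphabet} alphabet: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabelTable:
    """Mapping of sample id to a partition label (e.g. an expert clade)."""

    labels: dict[str, str]
    source: str = ""

    def __post_init__(self) -> None:
        for sid, lab in self.labels.items():
            if not lab:
                raise SequenceIOError(f"blank label for id {sid!r}")

    def __getitem__(self, sid: str) -> str:
        return self.labels[sid]

    def __len__(self) -> int:
        return len(self.labels)

    def ids(self) -> list[str]:
        return list(self.labels)

    def values_for(self, ids: Iterable[str]) -> list[str]:
        return [self.labels[i] for i in ids]


def canonicalize(residues: str, alphabet: Alphabet | None = None) -> str:
    """Uppercase, strip gap characters, and fold U->T for nucleotide input.

    Idempotent: applying it twice gives the same string.
    """
    s = residues.upper()
    for g in _GAP_CHARS:
        s = s.replace(g, "")
    if alphabet in (None, "DNA"):
        # Only fold U->T when the string is plausibly nucleotide; for a
        # declared PROTEIN alphabet U is selenocysteine and must survive.
        if alphabet == "DNA" or set(s) <= (_DNA_CHARS | {"U"}):
            s = s.replace("U", "T")
    return s


def infer_alphabet(residue_strings: Iterable[str]) -> Alphabet:
    """Infer DNA vs PROTEIN from the union of characters across records."""
    chars: set[str] = set()
    for s in residue_strings:
        chars |= set(s)
    return "DNA" if chars <= _DNA_CHARS else "PROTEIN"


def read_fasta(
    path: str | Path,
    alphabet_policy: Literal["auto", "DNA", "PROTEIN"] = "auto",
    skip_invalid: bool = False,
) -> list[SequenceRecord]:
    """Read a multi-FASTA file into validated :class:`SequenceRecord` objects.

    Headers are split at the first whitespace into id and description.
    Residues are canonicalized (uppercase, gaps stripped, U->T for
    nucleotides).  With ``alphabet_policy="auto"`` the alphabet is inferred
    from the union of characters in the whole file.  ``skip_invalid`` drops
    records whose residues fall outside the alphabet instead of raising.
    """
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise SequenceIOError(f"{path}: no FASTA records found")

    if alphabet_policy == "auto":
        alphabet = infer_alphabet(canonicalize(str(r.seq)) for r in raw)
    else:
        alphabet = alphabet_policy

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for r in raw:
        sid = r.id
        if sid in seen:
            raise SequenceIOError(f"{path}: duplicate sequence id {sid!r}")
        seen.add(sid)
        desc = r.description[len(sid) :].strip() if r.description else ""
        residues = canonicalize(str(r.seq), alphabet)
        try:
            records.append(
                SequenceRecord(id=sid, residues=residues, alphabet=alphabet, description=desc)
            )
        except SequenceIOError:
            if skip_invalid:
                continue
            raise
    if not records:
        raise SequenceIOError(f"{path}: every record was skipped as invalid")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as wrapped multi-FASTA (inverse of :func:`read_fasta`)."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


def read_labels(path: str | Path, source: str | None = None) -> LabelTable:
    """Read a two-column id<TAB>label table; a header row is tolerated.

    A first row reading ``id<TAB>label`` (case-insensitive, or starting with
    ``#``) is treated as a header.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise SequenceIOError(f"{path}:{lineno}: expected two tab-separated columns")
            sid, label = row[0].strip(), row[1].strip()
            if lineno == 1 and (sid.startswith("#") or (sid.lower(), label.lower()) == ("id", "label")):
                continue
            rows.append((sid, label))
    if not rows:
        raise SequenceIOError(f"{path}: empty label table")
    labels: dict[str, str] = {}
    for sid, label in rows:
        if sid in labels:
            raise SequenceIOError(f"{path}: duplicate id {sid!r} in label table")
        if not label:
            raise SequenceIOError(f"{path}: blank label for id {sid!r}")
        labels[sid] = label
    return LabelTable(labels=labels, source=source or str(path))


def write_labels(table: LabelTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid, label in table.labels.items():
            fh.write(f"{sid}\t{label}\n")
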