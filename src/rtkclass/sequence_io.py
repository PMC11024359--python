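"""Read/write FASTA, grouped alignments, and domain-annotation tables.

Identifier convention: transcriptome-style headers such as
``GeclaM_EVm001193t2`` carry a species code before the first underscore; a
trailing ``*`` (or a ``partial`` token in the description) marks a partial
sequence.  Internal coordinates are 0-based half-open; all files and reports
use 1-based inclusive coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from rtkclass.alphabet import ALN_ALPHABET, SEQ_ALPHABET

__all__ = [
    "SequenceRecord",
    "GroupedAlignment",
    "DomainAnnotation",
    "DOMAIN_VOCAB",
    "FastaError",
    "RaggedAlignmentError",
    "MissingGroupError",
    "DomainTableError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_domains",
]

#: controlled vocabulary of domain labels used by the architecture rules
DOMAIN_VOCAB = frozenset(
    {"RECEPTOR_L", "FURIN_LIKE", "FN3", "TM", "TK", "IG_LIKE", "CADHERIN", "GF_IV"}
)

# species-code bearing transcriptome identifier, e.g. GeclaM_EVm001193t2/2
_CRUSTOME_RE = re.compile(r"^([A-Za-z0-9]+)_[Ee][Vv]m\d+t\d+(?:/\d+)?$")

_PARTIAL_TOKEN_DEFAULT = "*"


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


class RaggedAlignmentError(ValueError):
    """Alignment rows of unequal length."""


class MissingGroupError(KeyError):
    """Alignment ids without a group label."""


class DomainTableError(ValueError):
    """Malformed domain-annotation table."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence plus parsed header metadata."""

    id: str
    residues: str
    species_code: str = ""
    is_partial: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in SEQ_ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def species_code_of(seq_id: str) -> str:
    """Species prefix of a transcriptome-style id, or '' if not one."""
    m = _CRUSTOME_RE.match(seq_id)
    return m.group(1) if m else ""


def _record_from_header(header_id: str, description: str, residues: str,
                        partial_token: str = _PARTIAL_TOKEN_DEFAULT) -> SequenceRecord:
    is_partial = False
    seq_id = header_id
    if partial_token and seq_id.endswith(partial_token):
        seq_id = seq_id[: -len(partial_token)]
        is_partial = True
    desc_rest = description[len(header_id):].strip() if description.startswith(header_id) else description
    if "partial" in desc_rest.lower():
        is_partial = True
    return SequenceRecord(
        id=seq_id,
        residues=residues.upper(),
        species_code=species_code_of(seq_id),
        is_partial=is_partial,
        description=desc_rest,
    )


def read_fasta(path, strict: bool = True, partial_token: str = _PARTIAL_TOKEN_DEFAULT):
    """Read a protein FASTA file.

    With ``strict=True`` (default) returns a list of :class:`SequenceRecord`
    and raises on the first invalid record.  With ``strict=False`` returns
    ``(records, errors)`` where ``errors`` is a list of messages, one per
    rejected record, so that every entry in the file is accounted for.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    errors: list[str] = []
    seen: set[str] = set()
    n_entries = 0
    for bio in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        try:
            rec = _record_from_header(bio.id, bio.description, str(bio.seq),
                                      partial_token=partial_token)
            if rec.id in seen:
                raise ValueError(f"record {rec.id!r}: duplicate id")
            seen.add(rec.id)
            records.append(rec)
        except ValueError as exc:
            if strict:
                raise FastaError(str(exc)) from exc
            errors.append(str(exc))
    if n_entries == 0:
        raise FastaError(f"{path}: no FASTA records found")
    if strict:
        return records
    return records, errors


def write_fasta(records, path, wrap: int = 60) -> None:
    """Write records to FASTA; a trailing '*' on the id marks partials."""
    bio_records = []
    for rec in records:
        header = rec.id + ("*" if rec.is_partial else "")
        bio_records.append(
            _BioSeqRecord(Seq(rec.residues), id=header, description=rec.description)
        )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap or None)
        writer.write_file(bio_records)


@dataclass
class GroupedAlignment:
    """Equal-length alignment rows with a group label per row."""

    ids: list[str]
    rows: list[str]
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise RaggedAlignmentError(
                f"ragged alignment: row lengths {sorted(lengths)}"
            )
        for rid, row in zip(self.ids, self.rows):
            for pos, ch in enumerate(row, start=1):
                if ch not in ALN_ALPHABET:
                    raise ValueError(
                        f"row {rid!r}: illegal character {ch!r} at column {pos}"
                    )
        missing = [rid for rid in self.ids if rid not in self.group_of]
        if missing:
            raise MissingGroupError(
                f"ids without group label: {', '.join(missing)}"
            )

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def groups(self) -> list[str]:
        return sorted({self.group_of[i] for i in self.ids})

    def members(self, group: str) -> list[int]:
        """Row indices belonging to *group*."""
        return [k for k, rid in enumerate(self.ids) if self.group_of[rid] == group]


def read_alignment(path, groups_path) -> GroupedAlignment:
    """Read an aligned FASTA plus an id→group TSV into a GroupedAlignment."""
    ids: list[str] = []
    rows: list[str] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        ids.append(bio.id)
        rows.append(str(bio.seq).upper())
    if not ids:
        raise FastaError(f"{path}: no alignment rows found")
    table = pd.read_csv(groups_path, sep="\t", dtype=str)
    for col in ("id", "group"):
        if col not in table.columns:
            raise ValueError(f"{groups_path}: missing required column {col!r}")
    group_of = dict(zip(table["id"], table["group"]))
    return GroupedAlignment(ids=ids, rows=rows, group_of=group_of)


@dataclass(frozen=True, order=True)
class DomainAnnotation:
    """One annotated domain on a sequence (1-based inclusive coordinates)."""

    seq_id: str
    start: int
    end: int
    domain: str
    known: bool = True

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise DomainTableError(
                f"{self.seq_id}/{self.domain}: bad coordinates "
                f"start={self.start} end={self.end}"
            )


def read_domains(path) -> dict[str, list[DomainAnnotation]]:
    """Read a domain TSV (seq_id, domain, start, end) into per-sequence lists.

    Lists are sorted by start coordinate.  Labels outside the controlled
    vocabulary are kept but flagged (``known=False``).
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("seq_id", "domain", "start", "end"):
        if col not in table.columns:
            raise DomainTableError(f"{path}: missing required column {col!r}")
    result: dict[str, list[DomainAnnotation]] = {}
    for row in table.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise DomainTableError(
                f"{row.seq_id}/{row.domain}: non-integer coordinate "
                f"({row.start!r}, {row.end!r})"
            ) from exc
        ann = DomainAnnotation(
            seq_id=str(row.seq_id),
            start=start,
            end=end,
            domain=str(row.domain),
            known=str(row.domain) in DOMAIN_VOCAB,
        )
        result.setdefault(ann.seq_id, []).append(ann)
    for anns in result.values():
        anns.sort(key=lambda a: (a.start, a.end, a.domain))
    return result
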