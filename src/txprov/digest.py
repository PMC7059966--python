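"""Checksum identity of a reference transcriptome.

A quantifier index is built from a FASTA file of reference cDNA sequences.
The identity of that sequence collection is captured by cryptographic
digests computed over the transcript sequences:

* ``sha256_hex`` / ``sha512_hex`` — SHA-256 / SHA-512 of all sequences
  concatenated in file order with the empty string as separator.  The
  SHA-256 value is the primary identifier used for registry lookup.
* ``order_invariant_sha256_hex`` — SHA-256 over the bytewise-sorted list of
  per-sequence SHA-256 hex digests (lowercase, concatenated with no
  separator).  This identifies the *set* of sequences regardless of their
  order in the file.
* ``name_sha256_hex`` — auxiliary digest over the sorted transcript
  identifiers (newline-joined).  Stored for diagnostics only; never used
  for registry matching.

Sequences are hashed exactly as read — no case folding, no alphabet
validation — because raw bytes are the only convention that is reproducible
without extra agreement between tools.  Pass ``uppercase=True`` to match
pipelines that fold case before hashing.
"""

from __future__ import annotations

import gzip
import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO

from .errors import FormatError, InputError

__all__ = [
    "SequenceEntry",
    "TranscriptomeDigest",
    "read_fasta",
    "compute_digests",
    "digest_fasta",
]


@dataclass
class SequenceEntry:
    """One FASTA record: identifier, header remainder, and its sequence.

    ``id`` is the first whitespace-delimited token of the header; ``seq``
    has all line breaks and internal whitespace removed.
    """

    id: str
    description: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("FASTA record with empty identifier")


@dataclass(frozen=True)
class TranscriptomeDigest:
    """The checksum identity of a set of reference transcript sequences."""

    sha256_hex: str
    sha512_hex: str
    order_invariant_sha256_hex: str
    name_sha256_hex: str
    n_transcripts: int

    def __post_init__(self) -> None:
        for attr, n in (
            ("sha256_hex", 64),
            ("sha512_hex", 128),
            ("order_invariant_sha256_hex", 64),
            ("name_sha256_hex", 64),
        ):
            value = getattr(self, attr)
            if len(value) != n or any(c not in "0123456789abcdef" for c in value):
                raise ValueError(f"{attr} must be {n} lowercase hex chars, got {value!r}")
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be non-negative")

    def to_dict(self) -> dict:
        return {
            "sha256": self.sha256_hex,
            "sha512": self.sha512_hex,
            "order_invariant_sha256": self.order_invariant_sha256_hex,
            "name_sha256": self.name_sha256_hex,
            "n_transcripts": self.n_transcripts,
        }


def _is_gzipped(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def read_fasta(
    path: Union[str, Path],
    gzipped: Union[bool, str] = "auto",
    uppercase: bool = False,
) -> List[SequenceEntry]:
    """Read a FASTA file (plain or gzip) into an ordered list of entries.

    File order is preserved; multi-line sequences are joined; CRLF line
    endings are tolerated; records with empty sequences are retained.
    Duplicate identifiers trigger a warning but both records are kept,
    since file order matters for the concatenation digest.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    if gzipped == "auto":
        gzipped = _is_gzipped(path)

    opener = gzip.open if gzipped else open
    entries: List[SequenceEntry] = []
    with opener(path, "rt") as fh:
        # require '>' as the first non-blank character
        pos = fh.tell()
        first = fh.read(1)
        while first and first in " \t\r\n":
            pos = fh.tell()
            first = fh.read(1)
        if first != ">":
            raise FormatError(f"not a FASTA file (first record lacks '>' header): {path}")
        fh.seek(pos)
        for record in SeqIO.parse(fh, "fasta"):
            # SeqIO's description repeats the id token; keep the remainder
            desc = record.description
            if desc.startswith(record.id):
                desc = desc[len(record.id):].lstrip()
            seq = str(record.seq)
            if uppercase:
                seq = seq.upper()
            entries.append(SequenceEntry(id=record.id, description=desc, seq=seq))

    seen: set = set()
    dups = []
    for e in entries:
        if e.id in seen:
            dups.append(e.id)
        seen.add(e.id)
    if dups:
        warnings.warn(
            f"duplicate FASTA identifiers kept in order: {sorted(set(dups))[:5]}",
            stacklevel=2,
        )
    return entries


def compute_digests(entries: Iterable[SequenceEntry]) -> TranscriptomeDigest:
    """Digest an ordered collection of sequences.

    Total function: the empty collection yields the standard digests of the
    empty byte string.
    """
    h256 = hashlib.sha256()
    h512 = hashlib.sha512()
    per_seq: List[str] = []
    names: List[str] = []
    n = 0
    for entry in entries:
        data = entry.seq.encode("utf-8")
        h256.update(data)
        h512.update(data)
        per_seq.append(hashlib.sha256(data).hexdigest())
        names.append(entry.id)
        n += 1
    order_invariant = hashlib.sha256("".join(sorted(per_seq)).encode("ascii")).hexdigest()
    name_digest = hashlib.sha256("\n".join(sorted(names)).encode("utf-8")).hexdigest()
    return TranscriptomeDigest(
        sha256_hex=h256.hexdigest(),
        sha512_hex=h512.hexdigest(),
        order_invariant_sha256_hex=order_invariant,
        name_sha256_hex=name_digest,
        n_transcripts=n,
    )


def digest_fasta(
    path: Union[str, Path],
    gzipped: Union[bool, str] = "auto",
    uppercase: bool = False,
) -> TranscriptomeDigest:
    """Digest a transcriptome FASTA file; equals ``compute_digests(read_fasta(path))``."""
    return compute_digests(read_fasta(path, gzipped=gzipped, uppercase=uppercase))
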