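"""Linked transcriptomes: shareable provenance for custom/de novo references.

When a transcriptome is not in the built-in hash table — a de novo
assembly, a reference augmented with fusion or pathogen transcripts, an
organism not yet covered — its checksum can be formally *linked* to
publicly available FASTA and GTF/GFF locations.  Creating the link does
two things: it adds a row to the local custom hash table, and it writes a
JSON document that any collaborator can load to teach their own machine
the same association.  After loading, import behaves exactly as if the
checksum had matched the built-in table.

JSON schema (normative here): a top-level array of objects with keys
``index``, ``source``, ``organism``, ``release``, ``genome``, ``sha256``,
``fasta`` (array of strings), ``gtf`` (one URI string).  An array allows
bundling several linked transcriptomes in one shareable file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

from .digest import digest_fasta
from .errors import FormatError, InputError, ProvenanceError, SchemaError
from .quantio import _META_PATHS, _HASH_KEYS
from .registry import FileCache, TranscriptomeRecord, append_custom_record

__all__ = ["LinkedTxome", "make_linked_txome", "load_linked_txome"]

_JSON_KEYS = ("index", "source", "organism", "release", "genome", "sha256", "fasta", "gtf")


@dataclass
class LinkedTxome(TranscriptomeRecord):
    """A registry record plus the index label and origin of the JSON link."""

    index_name: str = ""
    origin_json: Optional[str] = None

    def to_json_obj(self) -> dict:
        return {
            "index": self.index_name,
            "source": self.source,
            "organism": self.organism,
            "release": self.release,
            "genome": self.genome,
            "sha256": self.sha256_hex,
            "fasta": list(self.fasta_uris),
            "gtf": self.gtf_uri,
        }


def _digest_from_index_dir(index_dir: Path) -> str:
    """Read a stored checksum out of a quantifier index/sample directory."""
    for rel in ("info.json",) + _META_PATHS:
        candidate = index_dir / rel
        if candidate.exists():
            meta = json.loads(candidate.read_text())
            for key in _HASH_KEYS:
                if key in meta:
                    return str(meta[key]).strip().lower()
    raise InputError(
        f"could not find a stored index checksum under {index_dir}; "
        "point to the transcriptome FASTA instead"
    )


def make_linked_txome(
    fasta_or_index: Union[str, Path],
    source: str,
    organism: str,
    release: str,
    genome: str,
    fasta_uris: Sequence[str],
    gtf_uri: str,
    cache: Optional[FileCache] = None,
    json_out: Optional[Union[str, Path]] = None,
    write_json: bool = True,
) -> LinkedTxome:
    """Link a transcriptome digest to public FASTA/GTF locations.

    ``fasta_or_index`` is either the transcriptome FASTA (digested on the
    spot) or a quantifier index/sample directory whose metadata already
    stores the checksum.  The record is appended to the cache's custom
    hash table; when ``write_json`` a shareable JSON document is written
    to ``json_out``.
    """
    cache = cache or FileCache()
    path = Path(fasta_or_index)
    if path.is_dir():
        sha256 = _digest_from_index_dir(path)
    elif path.exists():
        sha256 = digest_fasta(path).sha256_hex
    else:
        raise InputError(f"no FASTA file or index directory at {path}")

    record = LinkedTxome(
        sha256_hex=sha256,
        source=source,
        organism=organism,
        release=release,
        genome=genome,
        fasta_uris=list(fasta_uris),
        gtf_uri=gtf_uri,
        index_name=path.name,
    )
    append_custom_record(cache.custom_registry_path, record)

    if write_json:
        if json_out is None:
            raise InputError("write_json=True requires json_out")
        Path(json_out).write_text(json.dumps([record.to_json_obj()], indent=1) + "\n")
    return record


def load_linked_txome(
    json_path: Union[str, Path],
    cache: Optional[FileCache] = None,
) -> List[LinkedTxome]:
    """Load a linked-transcriptome JSON and register its records locally.

    Accepts a single object or an array of objects.  After this call, an
    import of data quantified against any of the linked transcriptomes
    resolves provenance exactly as a built-in registry hit would.
    """
    cache = cache or FileCache()
    json_path = Path(json_path)
    if not json_path.exists():
        raise InputError(f"linked-transcriptome JSON not found: {json_path}")
    try:
        payload = json.loads(json_path.read_text())
    except json.JSONDecodeError as err:
        raise FormatError(f"{json_path} is not valid JSON: {err}") from err
    if isinstance(payload, dict):
        payload = [payload]
    if not isinstance(payload, list) or not payload:
        raise FormatError(f"{json_path}: expected a JSON object or non-empty array")

    records: List[LinkedTxome] = []
    for i, obj in enumerate(payload):
        missing = [k for k in _JSON_KEYS if k not in obj]
        if missing:
            raise FormatError(
                f"{json_path}[{i}]: missing required keys {missing}; "
                f"expected {list(_JSON_KEYS)}"
            )
        sha256 = str(obj["sha256"]).strip().lower()
        if len(sha256) != 64 or any(c not in "0123456789abcdef" for c in sha256):
            raise InputError(f"{json_path}[{i}]: malformed sha256 digest {obj['sha256']!r}")
        fasta = obj["fasta"]
        if isinstance(fasta, str):
            fasta = [fasta]
        try:
            record = LinkedTxome(
                sha256_hex=sha256,
                source=str(obj["source"]),
                organism=str(obj["organism"]),
                release=str(obj["release"]),
                genome=str(obj["genome"]),
                fasta_uris=[str(u) for u in fasta],
                gtf_uri=str(obj["gtf"]),
                index_name=str(obj["index"]),
                origin_json=str(json_path),
            )
        except SchemaError as err:
            raise FormatError(f"{json_path}[{i}]: {err}") from err
        append_custom_record(cache.custom_registry_path, record)
        records.append(record)
    return records
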