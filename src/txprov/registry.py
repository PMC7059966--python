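"""Checksum registry and local file cache.

The registry is the hash table mapping a transcriptome's SHA-256 digest to
its provenance record (source, organism, release, genome build, FASTA/GTF
locations).  Two tables exist: a built-in table shipped with the package
and a per-cache custom table populated by linked transcriptomes.  On a key
collision the custom entry wins.

The cache stores parsed annotation artifacts keyed by
``<sha256>.<kind>`` so that a transcriptome's annotation is downloaded and
parsed once, then reused — including by other users when the cache
directory is shared on a cluster.  Writes go to a temp file followed by an
atomic rename, so concurrent readers never observe a partial file.
"""

from __future__ import annotations

import json
import os
import tempfile
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Dict, List, Optional, Union

from . import __version__ as ARTIFACT_VERSION
from .errors import InputError, SchemaError

__all__ = [
    "TranscriptomeRecord",
    "CacheEntry",
    "FileCache",
    "Registry",
    "load_registry",
    "lookup",
    "builtin_registry_path",
    "default_cache_dir",
    "append_custom_record",
]

REGISTRY_COLUMNS = [
    "sha256_hex",
    "source",
    "organism",
    "release",
    "genome",
    "fasta_uris",
    "gtf_uri",
]

_URI_SCHEMES = ("http://", "https://", "ftp://", "file://")


@dataclass
class TranscriptomeRecord:
    """One registry row: digest → transcriptome provenance and source URIs."""

    sha256_hex: str
    source: str
    organism: str
    release: str
    genome: str
    fasta_uris: List[str]
    gtf_uri: str

    def __post_init__(self) -> None:
        self.sha256_hex = self.sha256_hex.strip().lower()
        if len(self.sha256_hex) != 64 or any(
            c not in "0123456789abcdef" for c in self.sha256_hex
        ):
            raise SchemaError(f"malformed sha256 key: {self.sha256_hex!r}")
        if not self.fasta_uris:
            raise SchemaError(f"record {self.sha256_hex[:12]}… has empty fasta_uris")
        for uri in list(self.fasta_uris) + [self.gtf_uri]:
            if not uri.startswith(_URI_SCHEMES):
                raise SchemaError(
                    f"URI must use http(s)/ftp/file scheme, got {uri!r}"
                )


def _record_to_tsv_row(rec: TranscriptomeRecord) -> str:
    return "\t".join(
        [
            rec.sha256_hex,
            rec.source,
            rec.organism,
            rec.release,
            rec.genome,
            ";".join(rec.fasta_uris),
            rec.gtf_uri,
        ]
    )


def _read_registry_tsv(path: Path) -> Dict[str, TranscriptomeRecord]:
    records: Dict[str, TranscriptomeRecord] = {}
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != REGISTRY_COLUMNS:
                    raise SchemaError(
                        f"{path}:{lineno}: bad registry header {header}; "
                        f"expected {REGISTRY_COLUMNS}"
                    )
                continue
            if len(fields) != len(REGISTRY_COLUMNS):
                raise SchemaError(
                    f"{path}:{lineno}: expected {len(REGISTRY_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(REGISTRY_COLUMNS, fields))
            try:
                rec = TranscriptomeRecord(
                    sha256_hex=row["sha256_hex"],
                    source=row["source"],
                    organism=row["organism"],
                    release=row["release"],
                    genome=row["genome"],
                    fasta_uris=[u for u in row["fasta_uris"].split(";") if u],
                    gtf_uri=row["gtf_uri"],
                )
            except SchemaError as err:
                raise SchemaError(f"{path}:{lineno}: {err}") from err
            records[rec.sha256_hex] = rec
    return records


@dataclass
class Registry:
    """Merged built-in + custom lookup table (custom wins on collisions)."""

    records: Dict[str, TranscriptomeRecord] = field(default_factory=dict)

    def get(self, sha256_hex: str) -> Optional[TranscriptomeRecord]:
        return lookup(self, sha256_hex)

    def __len__(self) -> int:
        return len(self.records)


def builtin_registry_path() -> Path:
    """Path of the registry table shipped with the package."""
    return Path(__file__).parent / "data" / "builtin_registry.tsv"


def load_registry(
    builtin: Optional[Union[str, Path]] = None,
    custom: Optional[Union[str, Path]] = None,
) -> Registry:
    """Load and merge the built-in and custom checksum tables.

    ``custom`` may point to a nonexistent file (treated as empty).  When
    the same digest appears in both tables, the custom record takes
    precedence and a warning is recorded.
    """
    builtin = Path(builtin) if builtin is not None else builtin_registry_path()
    merged = _read_registry_tsv(builtin) if builtin.exists() else {}
    if custom is not None and Path(custom).exists():
        custom_records = _read_registry_tsv(Path(custom))
        clashes = set(merged) & set(custom_records)
        if clashes:
            warnings.warn(
                f"custom registry overrides {len(clashes)} built-in digest(s): "
                f"{sorted(k[:12] for k in clashes)}",
                stacklevel=2,
            )
        merged.update(custom_records)
    return Registry(records=merged)


def lookup(table: Registry, sha256_hex: str) -> Optional[TranscriptomeRecord]:
    """Exact, case-insensitive lookup of a digest; ``None`` means not found."""
    key = str(sha256_hex).strip().lower()
    if len(key) != 64 or any(c not in "0123456789abcdef" for c in key):
        raise InputError(f"malformed sha256 lookup key: {sha256_hex!r}")
    return table.records.get(key)


def append_custom_record(custom_path: Union[str, Path], rec: TranscriptomeRecord) -> None:
    """Append (or replace, warning on conflict) a record in a custom table."""
    custom_path = Path(custom_path)
    existing: Dict[str, TranscriptomeRecord] = (
        _read_registry_tsv(custom_path) if custom_path.exists() else {}
    )
    if rec.sha256_hex in existing:
        old = existing[rec.sha256_hex]
        same = (old.fasta_uris, old.gtf_uri) == (rec.fasta_uris, rec.gtf_uri)
        what = "re-registering" if same else "replacing conflicting"
        warnings.warn(
            f"{what} registry entry for {rec.sha256_hex[:12]}…", stacklevel=2
        )
    existing[rec.sha256_hex] = rec
    custom_path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(REGISTRY_COLUMNS)]
    lines += [_record_to_tsv_row(r) for r in existing.values()]
    _atomic_write_text(custom_path, "\n".join(lines) + "\n")


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=".tmp-", suffix=path.suffix)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def default_cache_dir() -> Path:
    """Cache location: $TXPROV_CACHE, else $XDG_CACHE_HOME/txprov, else ~/.cache/txprov."""
    env = os.environ.get("TXPROV_CACHE")
    if env:
        return Path(env)
    xdg = os.environ.get("XDG_CACHE_HOME")
    base = Path(xdg) if xdg else Path.home() / ".cache"
    return base / "txprov"


@dataclass
class CacheEntry:
    key: str
    path: str
    created: float
    artifact_version: str


class FileCache:
    """Keyed local file cache with an atomically rewritten JSON index.

    Keys are opaque strings; annotation resources use ``<sha256>.<kind>``
    with kind in {txdb, ranges, tx2gene}.  ``put`` runs a producer callback
    against a temp path and renames the result into place, so a cache
    shared across processes never serves a partially written file.
    """

    INDEX_NAME = "cache_index.json"

    def __init__(self, directory: Optional[Union[str, Path]] = None):
        self.directory = Path(directory) if directory else default_cache_dir()
        self.directory.mkdir(parents=True, exist_ok=True)

    # -- custom registry lives inside the cache directory ----------------
    @property
    def custom_registry_path(self) -> Path:
        return self.directory / "custom_registry.tsv"

    @property
    def _index_path(self) -> Path:
        return self.directory / self.INDEX_NAME

    def _load_index(self) -> Dict[str, CacheEntry]:
        if not self._index_path.exists():
            return {}
        with open(self._index_path) as fh:
            raw = json.load(fh)
        return {k: CacheEntry(**v) for k, v in raw.items()}

    def _save_index(self, index: Dict[str, CacheEntry]) -> None:
        _atomic_write_text(
            self._index_path,
            json.dumps({k: asdict(v) for k, v in index.items()}, indent=1),
        )

    def entries(self) -> List[CacheEntry]:
        return list(self._load_index().values())

    def get(self, key: str) -> Optional[Path]:
        """Return the cached file path for ``key``, or None. Never mutates."""
        entry = self._load_index().get(key)
        if entry is None:
            return None
        path = Path(entry.path)
        return path if path.exists() else None

    def put(self, key: str, producer: Callable[[Path], None]) -> Path:
        """Produce a file for ``key`` and publish it atomically.

        ``producer`` writes to the temp path it is given; on success the
        file is renamed to its final location and the index updated.  On
        producer failure nothing is registered.
        """
        final = self.directory / key
        fd, tmp = tempfile.mkstemp(dir=str(self.directory), prefix=".tmp-")
        os.close(fd)
        tmp_path = Path(tmp)
        try:
            producer(tmp_path)
            os.replace(tmp_path, final)
        except BaseException:
            if tmp_path.exists():
                tmp_path.unlink()
            raise
        index = self._load_index()
        index[key] = CacheEntry(
            key=key,
            path=str(final),
            created=time.time(),
            artifact_version=ARTIFACT_VERSION,
        )
        self._save_index(index)
        return final

    def remove(self, key: str) -> bool:
        index = self._load_index()
        entry = index.pop(key, None)
        if entry is None:
            return False
        path = Path(entry.path)
        if path.exists():
            path.unlink()
        self._save_index(index)
        return True
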