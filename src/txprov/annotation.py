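"""GTF/GFF3 parsing into a lightweight annotation database.

The database holds what provenance-aware import needs and nothing more:
transcript ranges (1-based, fully closed intervals — the native GTF/GFF3
convention), gene spans, the transcript→gene mapping, per-chromosome
sequence info, and provenance of the parsed file.

One parser covers the common annotation dialects:

* ``gencode`` / ``generic-gtf`` — GTF attribute syntax ``key "value";``
  with explicit ``transcript`` feature lines.
* ``ensembl`` — GTF; transcript ids may carry a trailing ``.N`` version,
  so matching against quantified ids falls back to version-stripped ids.
* ``refseq`` / ``generic-gff3`` — GFF3 ``key=value`` attributes with
  ID/Parent chains; transcript-level features are ``transcript``/``mRNA``
  plus any feature referenced by an exon's ``Parent`` (this also covers de
  novo annotation pipelines whose transcript rows use nonstandard types).

Feature lines are tokenized by gffutils; the model assembly on top is
ours.  Persistence is a single JSON file round-tripped through the file
cache, version-stamped so format changes invalidate cleanly.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import gffutils

from . import __version__ as ARTIFACT_VERSION
from .errors import CacheInvalidError, FormatError, InputError
from .registry import FileCache

__all__ = [
    "TranscriptRange",
    "AnnotationDB",
    "parse_annotation",
    "normalize_tx_id",
    "save_db",
    "load_db",
]

DIALECTS = ("gencode", "ensembl", "refseq", "generic-gff3", "generic-gtf", "auto")

_DB_FORMAT_VERSION = 1


@dataclass
class TranscriptRange:
    """A transcript's genomic location plus identifying attributes.

    Coordinates are 1-based fully closed; strand is '+', '-' or '*'
    (unstranded).  ``gene_id`` is a string, or a list when the annotation
    assigns a transcript to several genes (multi-Parent GFF3).
    """

    seqname: str
    start: int
    end: int
    strand: str
    tx_id: str
    gene_id: Union[str, List[str]]
    extra: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"bad interval for {self.tx_id}: {self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "*"}:
            raise FormatError(f"bad strand {self.strand!r} for {self.tx_id}")

    @property
    def primary_gene_id(self) -> str:
        return self.gene_id[0] if isinstance(self.gene_id, list) else self.gene_id

    def overlaps(self, seqname: str, start: int, end: int) -> bool:
        """Closed-interval overlap (touching endpoints count)."""
        return self.seqname == seqname and self.start <= end and start <= self.end

    def to_dict(self) -> dict:
        return {
            "seqname": self.seqname,
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
            "tx_id": self.tx_id,
            "gene_id": self.gene_id,
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TranscriptRange":
        return cls(**d)


@dataclass
class AnnotationDB:
    """Parsed transcript/gene model with sequence info and provenance."""

    transcripts: List[TranscriptRange]
    genes: Dict[str, TranscriptRange]
    tx2gene: Dict[str, str]
    seqinfo: Dict[str, dict]
    exons_by_tx: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def transcript_index(self) -> Dict[str, TranscriptRange]:
        return {t.tx_id: t for t in self.transcripts}


def normalize_tx_id(raw_id: str, dialect: str = "generic-gtf") -> str:
    """Normalize a quantified transcript id for joining against annotation ids.

    GENCODE FASTA headers are pipe-delimited bundles
    (``ENST…|ENSG…|…``); the transcript id is the first field.  Other
    dialects pass through unchanged; Ensembl version suffixes are handled
    at match time by a version-stripped fallback, not here.
    """
    if not raw_id:
        raise InputError("empty transcript id")
    if dialect == "gencode":
        return raw_id.split("|")[0]
    return raw_id


def strip_version(tx_id: str) -> str:
    """Drop a trailing ``.N`` version suffix if present."""
    head, dot, tail = tx_id.rpartition(".")
    if dot and tail.isdigit():
        return head
    return tx_id


def _read_text(path: Path) -> str:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        with gzip.open(path, "rt") as fh:
            return fh.read()
    return path.read_text()


def _detect_dialect(text: str) -> str:
    for line in text.splitlines():
        if line.startswith("##gff-version"):
            return "generic-gff3"
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            continue
        attrs = fields[8]
        if '"' in attrs and not ("=" in attrs.split('"')[0]):
            return "generic-gtf"
        if "=" in attrs:
            return "generic-gff3"
    raise FormatError("could not detect annotation dialect (no feature lines found)")


def _norm_strand(s: str) -> str:
    return s if s in {"+", "-"} else "*"


def _parse_seqinfo(text: str, genome: Optional[str]) -> Dict[str, dict]:
    seqinfo: Dict[str, dict] = {}
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                seqinfo[parts[1]] = {
                    "length": int(parts[3]),
                    "genome": genome,
                    "circular": False,
                }
    return seqinfo


def parse_annotation(
    path: Union[str, Path],
    dialect: str = "auto",
    genome: Optional[str] = None,
    provenance: Optional[Dict[str, str]] = None,
) -> AnnotationDB:
    """Parse a GTF or GFF3 file (plain or gzip) into an :class:`AnnotationDB`.

    Gene ranges are the min-start/max-end span of each gene's transcripts
    on a shared seqname+strand.  ``seqinfo`` is populated from
    ``##sequence-region`` pragmas when present, otherwise lengths are
    unknown.  A transcript whose feature lines disagree about its gene is
    a format error; a transcript with several declared parents keeps them
    all as a list (summarization uses the first).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    if dialect not in DIALECTS:
        raise InputError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    text = _read_text(path)
    detected = _detect_dialect(text)
    if dialect == "auto":
        dialect = detected
    # attribute syntax is decided by content, not by the declared dialect
    # (refseq ships both GTF and GFF3; the dialect only steers id handling)
    is_gff3 = detected == "generic-gff3"

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    if is_gff3:
        transcripts, tx2gene, exons_by_tx = _assemble_gff3(db)
    else:
        transcripts, tx2gene, exons_by_tx = _assemble_gtf(db)

    if not transcripts:
        raise FormatError(f"no transcript-level features derivable from {path}")

    genes = _gene_spans(transcripts)
    seqinfo = _parse_seqinfo(text, genome)
    for t in transcripts:
        if t.seqname not in seqinfo:
            seqinfo[t.seqname] = {"length": None, "genome": genome, "circular": False}

    prov = {"path": str(path), "dialect": dialect}
    if provenance:
        prov.update(provenance)
    return AnnotationDB(
        transcripts=transcripts,
        genes=genes,
        tx2gene=tx2gene,
        seqinfo=seqinfo,
        exons_by_tx=exons_by_tx,
        provenance=prov,
    )


def _first(attrs, key) -> Optional[str]:
    vals = attrs.get(key)
    if not vals:
        return None
    return vals[0] if isinstance(vals, list) else vals


_BIOTYPE_KEYS = ("transcript_biotype", "gene_biotype", "transcript_type", "gene_type")


def _extra_from(attrs) -> Dict[str, str]:
    extra = {}
    for key in _BIOTYPE_KEYS:
        val = _first(attrs, key)
        if val is not None:
            extra[key] = val
    return extra


def _assemble_gtf(db) -> Tuple[List[TranscriptRange], Dict[str, str], Dict[str, List[Tuple[int, int]]]]:
    # cross-line gene consistency: every line carrying a transcript_id votes
    gene_votes: Dict[str, set] = {}
    for f in db.all_features():
        tx = _first(f.attributes, "transcript_id")
        g = _first(f.attributes, "gene_id")
        if tx and g:
            gene_votes.setdefault(tx, set()).add(g)
    conflicting = sorted(tx for tx, gs in gene_votes.items() if len(gs) > 1)
    if conflicting:
        raise FormatError(
            f"transcript(s) with conflicting gene assignments across lines: "
            f"{conflicting[:10]}"
        )

    transcripts: List[TranscriptRange] = []
    tx2gene: Dict[str, str] = {}
    for f in db.features_of_type("transcript", order_by=("seqid", "start")):
        tx_id = _first(f.attributes, "transcript_id")
        gene_id = _first(f.attributes, "gene_id")
        if tx_id is None or gene_id is None:
            raise FormatError(
                f"transcript feature at {f.seqid}:{f.start}-{f.end} lacks "
                "transcript_id/gene_id attributes"
            )
        transcripts.append(
            TranscriptRange(
                seqname=f.seqid,
                start=f.start,
                end=f.end,
                strand=_norm_strand(f.strand),
                tx_id=tx_id,
                gene_id=gene_id,
                extra=_extra_from(f.attributes),
            )
        )
        tx2gene[tx_id] = gene_id

    exons_by_tx: Dict[str, List[Tuple[int, int]]] = {}
    for f in db.features_of_type("exon", order_by=("seqid", "start")):
        tx = _first(f.attributes, "transcript_id")
        if tx:
            exons_by_tx.setdefault(tx, []).append((f.start, f.end))
    return transcripts, tx2gene, exons_by_tx


_GFF3_TX_TYPES = {"transcript", "mRNA"}


def _assemble_gff3(db) -> Tuple[List[TranscriptRange], Dict[str, str], Dict[str, List[Tuple[int, int]]]]:
    exon_parents: set = set()
    exons_by_parent: Dict[str, List[Tuple[int, int]]] = {}
    for f in db.features_of_type("exon", order_by=("seqid", "start")):
        for parent in f.attributes.get("Parent", []):
            exon_parents.add(parent)
            exons_by_parent.setdefault(parent, []).append((f.start, f.end))

    transcripts: List[TranscriptRange] = []
    tx2gene: Dict[str, str] = {}
    seen: set = set()
    for f in db.all_features(order_by=("seqid", "start")):
        fid = f.id
        is_tx = f.featuretype in _GFF3_TX_TYPES or fid in exon_parents
        if f.featuretype in {"gene", "exon", "CDS"} or not is_tx:
            continue
        if fid in seen:
            continue
        seen.add(fid)
        tx_id = _first(f.attributes, "transcript_id") or fid
        # gene resolution order: Parent chain, explicit gene_id, Note, self
        parents = list(f.attributes.get("Parent", []))
        if parents:
            gene_id: Union[str, List[str]] = parents if len(parents) > 1 else parents[0]
        else:
            explicit = _first(f.attributes, "gene_id")
            if explicit is not None:
                gene_id = explicit
            else:
                notes = list(f.attributes.get("Note", []))
                if notes:
                    gene_id = notes if len(notes) > 1 else notes[0]
                else:
                    gene_id = tx_id
        transcripts.append(
            TranscriptRange(
                seqname=f.seqid,
                start=f.start,
                end=f.end,
                strand=_norm_strand(f.strand),
                tx_id=tx_id,
                gene_id=gene_id,
                extra=_extra_from(f.attributes),
            )
        )
        primary = gene_id[0] if isinstance(gene_id, list) else gene_id
        tx2gene[tx_id] = primary

    exons_by_tx: Dict[str, List[Tuple[int, int]]] = {}
    for f in db.all_features():
        if f.id in exons_by_parent:
            tx_id = _first(f.attributes, "transcript_id") or f.id
            exons_by_tx[tx_id] = exons_by_parent[f.id]
    return transcripts, tx2gene, exons_by_tx


def _gene_spans(transcripts: List[TranscriptRange]) -> Dict[str, TranscriptRange]:
    by_gene: Dict[str, List[TranscriptRange]] = {}
    for t in transcripts:
        by_gene.setdefault(t.primary_gene_id, []).append(t)
    genes: Dict[str, TranscriptRange] = {}
    for gene_id, members in by_gene.items():
        anchor = (members[0].seqname, members[0].strand)
        group = [m for m in members if (m.seqname, m.strand) == anchor]
        if len(group) != len(members):
            warnings.warn(
                f"gene {gene_id} has transcripts on multiple seqname/strand "
                "combinations; span computed on the first",
                stacklevel=3,
            )
        genes[gene_id] = TranscriptRange(
            seqname=anchor[0],
            start=min(m.start for m in group),
            end=max(m.end for m in group),
            strand=anchor[1],
            tx_id=gene_id,
            gene_id=gene_id,
        )
    return genes


# ---------------------------------------------------------------------------
# cache persistence

def save_db(db: AnnotationDB, cache: FileCache, sha256_hex: str, kind: str = "txdb") -> str:
    """Serialize ``db`` into the cache under ``<sha256>.<kind>``; returns the key."""
    key = f"{sha256_hex}.{kind}"
    payload = {
        "format_version": _DB_FORMAT_VERSION,
        "artifact_version": ARTIFACT_VERSION,
        "transcripts": [t.to_dict() for t in db.transcripts],
        "genes": {g: r.to_dict() for g, r in db.genes.items()},
        "tx2gene": db.tx2gene,
        "seqinfo": db.seqinfo,
        "exons_by_tx": {k: [list(e) for e in v] for k, v in db.exons_by_tx.items()},
        "provenance": db.provenance,
    }
    cache.put(key, lambda tmp: tmp.write_text(json.dumps(payload)))
    return key


def load_db(key: str, cache: FileCache) -> Optional[AnnotationDB]:
    """Load a cached annotation database; None if absent.

    A file written by an incompatible format version, or one that cannot be
    parsed, raises :class:`CacheInvalidError` so the caller re-parses from
    source.
    """
    path = cache.get(key)
    if path is None:
        return None
    try:
        payload = json.loads(path.read_text())
        if payload.get("format_version") != _DB_FORMAT_VERSION:
            raise CacheInvalidError(
                f"cache entry {key} has format version "
                f"{payload.get('format_version')}, expected {_DB_FORMAT_VERSION}"
            )
        return AnnotationDB(
            transcripts=[TranscriptRange.from_dict(d) for d in payload["transcripts"]],
            genes={g: TranscriptRange.from_dict(d) for g, d in payload["genes"].items()},
            tx2gene=payload["tx2gene"],
            seqinfo=payload["seqinfo"],
            exons_by_tx={k: [tuple(e) for e in v] for k, v in payload["exons_by_tx"].items()},
            provenance=payload["provenance"],
        )
    except CacheInvalidError:
        raise
    except (json.JSONDecodeError, KeyError, TypeError) as err:
        raise CacheInvalidError(f"cache entry {key} is corrupted: {err}") from err
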