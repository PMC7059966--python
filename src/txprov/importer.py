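"""Provenance-verified import of quantification data.

``import_quants`` is the center of the package.  Given a sample table it:

1. parses every sample's quantification directory and verifies that the
   embedded index checksum — and therefore the reference transcriptome —
   is identical across all samples;
2. assembles three features × samples assay matrices (counts from
   NumReads, abundance from TPM, length from EffectiveLength), features
   ordered as in the first sample's quant.sf, samples ordered as in the
   table;
3. looks the checksum up in the registry: on a match, the annotation is
   loaded from the local cache (or parsed from the record's GTF/GFF URI on
   first use, then cached) and transcript ranges are attached together
   with the genome build; on no match a *non-ranged* container is returned
   — assays intact, ``metadata["txome"] == "unknown"`` — because the
   genomic context of the rows is simply not known;
4. records per-sample run metadata, source URIs and package version in
   the container metadata.

Ranged containers refuse genomic comparisons across genome builds or with
unknown chromosomes (``subset_by_overlaps``), which is precisely the class
of silent mistake checksum-based provenance exists to prevent.
"""

from __future__ import annotations

import datetime
import logging
import urllib.request
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__ as ARTIFACT_VERSION
from .annotation import (
    AnnotationDB,
    TranscriptRange,
    load_db,
    normalize_tx_id,
    parse_annotation,
    save_db,
    strip_version,
)
from .errors import (
    IncompatibilityError,
    InputError,
    ProvenanceError,
    CacheInvalidError,
)
from .quantio import SampleTable, read_quant_dir
from .registry import FileCache, Registry, TranscriptomeRecord, load_registry, lookup

logger = logging.getLogger("txprov")

__all__ = [
    "ExperimentContainer",
    "import_quants",
    "attach_ranges",
    "subset_by_overlaps",
    "save_container",
    "load_container",
]

ASSAY_NAMES = ("counts", "abundance", "length")


@dataclass
class ExperimentContainer:
    """Features × samples expression container with provenance metadata.

    ``assays`` maps name → DataFrame (index: feature ids, columns: sample
    names); all assays share dimensions and ordering.  ``row_ranges`` is a
    list of :class:`TranscriptRange` aligned 1:1 with the features, or
    ``None`` for a non-ranged container (unknown transcriptome).
    """

    assays: Dict[str, pd.DataFrame]
    column_data: pd.DataFrame
    metadata: Dict[str, object] = field(default_factory=dict)
    row_ranges: Optional[List[TranscriptRange]] = None
    level: str = "transcript"

    def __post_init__(self) -> None:
        shapes = {k: v.shape for k, v in self.assays.items()}
        if len(set(shapes.values())) > 1:
            raise InputError(f"assay dimensions disagree: {shapes}")
        first = next(iter(self.assays.values()))
        for name, a in self.assays.items():
            if not (a.index.equals(first.index) and a.columns.equals(first.columns)):
                raise InputError(f"assay {name} ordering differs from the others")
        if self.row_ranges is not None and len(self.row_ranges) != len(first.index):
            raise InputError(
                f"row_ranges length {len(self.row_ranges)} != "
                f"{len(first.index)} features"
            )

    @property
    def feature_ids(self) -> List[str]:
        return list(next(iter(self.assays.values())).index)

    @property
    def sample_names(self) -> List[str]:
        return list(next(iter(self.assays.values())).columns)

    @property
    def is_ranged(self) -> bool:
        return self.row_ranges is not None

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.assays.values())).shape

    def subset_features(self, keep: Sequence[bool]) -> "ExperimentContainer":
        keep = np.asarray(keep, dtype=bool)
        assays = {k: v.loc[keep] for k, v in self.assays.items()}
        ranges = (
            [r for r, k in zip(self.row_ranges, keep) if k]
            if self.row_ranges is not None
            else None
        )
        return ExperimentContainer(
            assays=assays,
            column_data=self.column_data,
            metadata=dict(self.metadata),
            row_ranges=ranges,
            level=self.level,
        )

    def to_anndata(self):
        """Adapter to an AnnData (samples × features) with assay layers."""
        import anndata as ad

        counts = self.assays["counts"]
        adata = ad.AnnData(
            X=counts.T.to_numpy(),
            obs=self.column_data.set_index(pd.Index(self.sample_names)),
            var=pd.DataFrame(index=pd.Index(self.feature_ids)),
            layers={
                "abundance": self.assays["abundance"].T.to_numpy(),
                "length": self.assays["length"].T.to_numpy(),
            },
        )
        if self.row_ranges is not None:
            adata.var["seqname"] = [r.seqname for r in self.row_ranges]
            adata.var["start"] = [r.start for r in self.row_ranges]
            adata.var["end"] = [r.end for r in self.row_ranges]
            adata.var["strand"] = [r.strand for r in self.row_ranges]
        adata.uns["txprov"] = {
            k: v for k, v in self.metadata.items() if isinstance(v, (str, int, float))
        }
        return adata


def _resolve_uri(uri: str) -> Path:
    """Resolve a URI to a local file path, fetching remote schemes if needed."""
    parsed = urllib.parse.urlparse(uri)
    if parsed.scheme == "file":
        return Path(urllib.parse.unquote(parsed.path))
    if parsed.scheme in {"http", "https", "ftp"}:
        local, _ = urllib.request.urlretrieve(uri)  # network-dependent path
        return Path(local)
    return Path(uri)  # plain path


def _annotation_for(
    record: TranscriptomeRecord,
    cache: FileCache,
    dialect: str,
) -> AnnotationDB:
    """Cache-first annotation retrieval: load if cached, else parse + cache."""
    key = f"{record.sha256_hex}.txdb"
    try:
        db = load_db(key, cache)
    except CacheInvalidError:
        logger.warning("cache entry %s invalid; re-parsing annotation", key)
        db = None
    if db is not None:
        logger.info("using cached annotation for %s…", record.sha256_hex[:12])
        return db
    try:
        local = _resolve_uri(record.gtf_uri)
        db = parse_annotation(
            local,
            dialect=dialect,
            genome=record.genome,
            provenance={
                "source": record.source,
                "organism": record.organism,
                "release": record.release,
                "gtf_uri": record.gtf_uri,
            },
        )
    except Exception as err:
        raise InputError(
            f"failed to fetch/parse annotation from {record.gtf_uri}: {err}"
        ) from err
    save_db(db, cache, record.sha256_hex)
    return db


def import_quants(
    table: SampleTable,
    registry: Optional[Registry] = None,
    cache: Optional[FileCache] = None,
    allow_missing_tx: bool = False,
    dialect: str = "auto",
) -> ExperimentContainer:
    """Import a sample table of quantification directories.

    Returns a ranged container when the common index checksum is found in
    the registry (built-in or custom), otherwise a non-ranged container
    with ``metadata["txome"] == "unknown"``.  Samples quantified against
    different indices cannot be combined and raise
    :class:`ProvenanceError`.
    """
    if len(table) == 0:
        raise InputError("empty sample table")
    cache = cache or FileCache()
    if registry is None:
        registry = load_registry(custom=cache.custom_registry_path)

    samples = [
        read_quant_dir(f, name=n) for n, f in zip(table.names, table.files)
    ]

    digests = {s.name: s.index_seq_hash for s in samples}
    if len(set(digests.values())) > 1:
        detail = "\n".join(f"  {n}: {d}" for n, d in digests.items())
        raise ProvenanceError(
            "samples were quantified against different reference "
            f"transcriptomes (index checksums differ):\n{detail}"
        )
    sha256 = samples[0].index_seq_hash

    feature_ids = samples[0].tx_ids
    ref_set = set(feature_ids)
    for s in samples[1:]:
        if set(s.tx_ids) != ref_set:
            raise ProvenanceError(
                f"sample {s.name} reports a different transcript set than "
                f"{samples[0].name} despite an identical index checksum"
            )

    idx = pd.Index(feature_ids, name="tx_id")
    cols = {"counts": "num_reads", "abundance": "tpm", "length": "effective_length"}
    assays = {
        name: pd.DataFrame(
            {
                s.name: s.table.set_index("tx_id")[col].reindex(idx)
                for s in samples
            },
            index=idx,
        )
        for name, col in cols.items()
    }

    column_data = table.covariates.set_index(
        pd.Index(table.names, name="names"), drop=False
    ).drop(columns=["names"])
    column_data["run_metadata"] = [s.run_metadata for s in samples]

    metadata: Dict[str, object] = {
        "digest": sha256,
        "artifact_version": ARTIFACT_VERSION,
        "import_time": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "quant_paths": [str(s.path) for s in samples],
    }

    record = lookup(registry, sha256)
    container = ExperimentContainer(
        assays=assays, column_data=column_data, metadata=metadata
    )
    if record is None:
        logger.info(
            "index checksum %s… not found in any hash table; "
            "returning a non-ranged container",
            sha256[:12],
        )
        metadata["txome"] = "unknown"
        return container

    logger.info(
        "found matching transcriptome: %s %s release %s",
        record.source,
        record.organism,
        record.release,
    )
    metadata["txome"] = record
    db = _annotation_for(record, cache, dialect=dialect)
    return attach_ranges(container, db, allow_missing_tx=allow_missing_tx)


def attach_ranges(
    container: ExperimentContainer,
    db: AnnotationDB,
    allow_missing_tx: bool = False,
) -> ExperimentContainer:
    """Attach transcript ranges (and genome/seqinfo metadata) to a container.

    Feature ids are matched against the annotation after dialect
    normalization, with a version-stripped fallback for Ensembl-style
    ``.N`` suffixes.  Features absent from the annotation are an error by
    default — silent dropping would hide exactly the annotation/quant
    mismatch this package exists to catch — unless ``allow_missing_tx``,
    in which case the offending rows are removed from every assay and the
    count recorded in metadata.
    """
    if container.level != "transcript":
        raise InputError("ranges can only be attached at the transcript level")
    tx_index = db.transcript_index()
    # version-stripped fallback is only safe where the stripped id is
    # unambiguous in the annotation
    counts: Dict[str, int] = {}
    for tid in tx_index:
        s = strip_version(tid)
        counts[s] = counts.get(s, 0) + 1
    stripped_index = {
        strip_version(tid): rng
        for tid, rng in tx_index.items()
        if counts[strip_version(tid)] == 1
    }
    dialect = db.provenance.get("dialect", "generic-gtf")
    rec = container.metadata.get("txome")
    if isinstance(rec, TranscriptomeRecord) and rec.source.lower() == "gencode":
        dialect = "gencode"

    ranges: List[Optional[TranscriptRange]] = []
    missing: List[str] = []
    for fid in container.feature_ids:
        norm = normalize_tx_id(fid, dialect)
        rng = tx_index.get(norm)
        if rng is None:
            rng = stripped_index.get(strip_version(norm))
        if rng is None:
            missing.append(fid)
        ranges.append(rng)

    if missing:
        if not allow_missing_tx:
            shown = ", ".join(missing[:10])
            more = f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""
            raise InputError(
                f"{len(missing)} quantified transcript(s) absent from the "
                f"annotation: {shown}{more}; pass allow_missing_tx=True to drop them"
            )
        keep = [r is not None for r in ranges]
        container = container.subset_features(keep)
        ranges = [r for r in ranges if r is not None]
        container.metadata["n_dropped_missing_tx"] = len(missing)

    container.row_ranges = ranges
    container.metadata["seqinfo"] = db.seqinfo
    genomes = {v.get("genome") for v in db.seqinfo.values()}
    container.metadata["genome"] = next(iter(genomes)) if len(genomes) == 1 else None
    container.metadata["annotation_provenance"] = db.provenance
    return container


def subset_by_overlaps(
    container: ExperimentContainer,
    query_ranges: Sequence[Union[TranscriptRange, Tuple[str, int, int]]],
    query_genome: Optional[str] = None,
    ignore_strand: bool = True,
) -> ExperimentContainer:
    """Keep features whose range overlaps any query range (closed intervals).

    Before any coordinate is compared, the genome builds must match and
    every query chromosome must be known to the container with a
    consistent length; mixing builds is an error, never a silent empty
    result.
    """
    if not container.is_ranged:
        raise InputError("container is non-ranged; overlaps are undefined")
    genome = container.metadata.get("genome")
    if query_genome is not None and genome is not None and query_genome != genome:
        raise IncompatibilityError(
            f"genome builds differ: container is {genome!r}, query is {query_genome!r}"
        )
    seqinfo = container.metadata.get("seqinfo", {})

    queries: List[TranscriptRange] = []
    for q in query_ranges:
        if isinstance(q, TranscriptRange):
            queries.append(q)
        else:
            seqname, start, end = q[0], q[1], q[2]
            strand = q[3] if len(q) > 3 else "*"
            queries.append(
                TranscriptRange(
                    seqname=seqname, start=start, end=end, strand=strand,
                    tx_id="query", gene_id="query",
                )
            )
    for q in queries:
        if q.seqname not in seqinfo:
            raise IncompatibilityError(
                f"query chromosome {q.seqname!r} is absent from the container's "
                f"sequence info ({sorted(seqinfo)})"
            )

    def hits(r: TranscriptRange) -> bool:
        for q in queries:
            if r.overlaps(q.seqname, q.start, q.end):
                if ignore_strand or "*" in (r.strand, q.strand) or r.strand == q.strand:
                    return True
        return False

    keep = [hits(r) for r in container.row_ranges]
    return container.subset_features(keep)


# ---------------------------------------------------------------------------
# on-disk container serialization (directory layout)

def save_container(container: ExperimentContainer, out_dir: Union[str, Path]) -> Path:
    """Serialize a container to a directory of TSV + JSON files."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in container.assays.items():
        df.to_csv(out_dir / f"assay_{name}.tsv", sep="\t")
    coldata = container.column_data.copy()
    if "run_metadata" in coldata.columns:
        coldata["run_metadata"] = coldata["run_metadata"].map(json.dumps)
    coldata.to_csv(out_dir / "column_data.tsv", sep="\t")
    if container.row_ranges is not None:
        pd.DataFrame([r.to_dict() for r in container.row_ranges]).to_csv(
            out_dir / "row_ranges.tsv", sep="\t", index=False
        )
    meta = dict(container.metadata)
    txome = meta.get("txome")
    if isinstance(txome, TranscriptomeRecord):
        meta["txome"] = {
            "sha256_hex": txome.sha256_hex,
            "source": txome.source,
            "organism": txome.organism,
            "release": txome.release,
            "genome": txome.genome,
            "fasta_uris": txome.fasta_uris,
            "gtf_uri": txome.gtf_uri,
        }
    meta["level"] = container.level
    (out_dir / "metadata.json").write_text(json.dumps(meta, indent=1, default=str))
    return out_dir


def load_container(in_dir: Union[str, Path]) -> ExperimentContainer:
    """Inverse of :func:`save_container`."""
    import ast
    import json

    in_dir = Path(in_dir)
    if not (in_dir / "metadata.json").exists():
        raise InputError(f"not a container directory: {in_dir}")
    assays = {}
    for name in ASSAY_NAMES:
        path = in_dir / f"assay_{name}.tsv"
        assays[name] = pd.read_csv(
            path, sep="\t", index_col=0, float_precision="round_trip"
        )
        assays[name].index = assays[name].index.astype(str)
    coldata = pd.read_csv(in_dir / "column_data.tsv", sep="\t", index_col=0)
    if "run_metadata" in coldata.columns:
        coldata["run_metadata"] = coldata["run_metadata"].map(json.loads)
    meta = json.loads((in_dir / "metadata.json").read_text())
    level = meta.pop("level", "transcript")
    txome = meta.get("txome")
    if isinstance(txome, dict):
        meta["txome"] = TranscriptomeRecord(**txome)
    ranges = None
    ranges_path = in_dir / "row_ranges.tsv"
    if ranges_path.exists():
        rdf = pd.read_csv(ranges_path, sep="\t")
        ranges = []
        for row in rdf.itertuples(index=False):
            gene_id = row.gene_id
            if isinstance(gene_id, str) and gene_id.startswith("["):
                gene_id = ast.literal_eval(gene_id)
            extra = row.extra
            if isinstance(extra, str):
                extra = ast.literal_eval(extra)
            elif not isinstance(extra, dict):
                extra = {}
            ranges.append(
                TranscriptRange(
                    seqname=str(row.seqname),
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    tx_id=str(row.tx_id),
                    gene_id=gene_id,
                    extra=extra,
                )
            )
    return ExperimentContainer(
        assays=assays,
        column_data=coldata,
        metadata=meta,
        row_ranges=ranges,
        level=level,
    )
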