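"""Gene-level summarization and identifier conversion.

Transcript-level estimates are combined per gene and sample as:

* counts:  ``counts_g = Σ_t counts_t``
* TPM:     ``tpm_g = Σ_t tpm_t``
* length:  the abundance-weighted mean effective length,
  ``length_g = Σ_t (tpm_t / tpm_g) · length_t`` when ``tpm_g > 0``, else
  the unweighted mean of the member lengths.

The weights use each sample's own TPM, so a gene's effective length can
differ between samples when isoform usage shifts — that is the point of
the weighting.  Totals are conserved: per sample, summed counts and
summed TPM are identical before and after (when no feature is dropped).
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .annotation import AnnotationDB, TranscriptRange, normalize_tx_id, strip_version
from .errors import InputError
from .importer import ExperimentContainer

__all__ = ["summarize_to_gene", "convert_ids"]


def _map_features_to_genes(
    container: ExperimentContainer, db: AnnotationDB, allow_missing_tx: bool
):
    dialect = db.provenance.get("dialect", "generic-gtf")
    # version-stripped fallback: safe whenever every annotation id sharing
    # the stripped form maps to the same gene
    candidates: Dict[str, set] = {}
    for tid, gid in db.tx2gene.items():
        candidates.setdefault(strip_version(tid), set()).add(gid)
    stripped = {s: next(iter(g)) for s, g in candidates.items() if len(g) == 1}

    gene_of: Dict[str, Optional[str]] = {}
    missing = []
    for fid in container.feature_ids:
        norm = normalize_tx_id(fid, dialect)
        gid = db.tx2gene.get(norm)
        if gid is None:
            gid = stripped.get(strip_version(norm))
        if gid is None:
            missing.append(fid)
        gene_of[fid] = gid
    return gene_of, missing


def summarize_to_gene(
    container: ExperimentContainer,
    db: AnnotationDB,
    allow_missing_tx: bool = False,
) -> ExperimentContainer:
    """Summarize a transcript-level container to the gene level.

    Transcripts with list-valued gene assignments contribute to their
    first parent (a warning reports how many).  Transcripts with no gene
    mapping are an error unless ``allow_missing_tx``, in which case they
    are dropped before aggregation.
    """
    if container.level != "transcript":
        raise InputError("container is already at the gene level")
    gene_of, missing = _map_features_to_genes(container, db, allow_missing_tx)
    if missing:
        if not allow_missing_tx:
            shown = ", ".join(missing[:10])
            raise InputError(
                f"{len(missing)} transcript(s) have no gene mapping: {shown}"
            )
        keep = [gene_of[f] is not None for f in container.feature_ids]
        container = container.subset_features(keep)

    multi = sum(
        1
        for t in db.transcripts
        if isinstance(t.gene_id, list) and t.tx_id in gene_of
    )
    if multi:
        warnings.warn(
            f"{multi} transcript(s) assigned to multiple genes; "
            "using the first parent",
            stacklevel=2,
        )

    genes = pd.Index(
        [gene_of[f] for f in container.feature_ids], name="gene_id"
    )
    counts = container.assays["counts"].set_axis(genes)
    tpm = container.assays["abundance"].set_axis(genes)
    length = container.assays["length"].set_axis(genes)

    counts_g = counts.groupby(level=0, sort=False).sum()
    tpm_g = tpm.groupby(level=0, sort=False).sum()
    # abundance-weighted mean length, with unweighted-mean fallback at tpm 0
    weighted = (tpm * length).groupby(level=0, sort=False).sum()
    mean_len = length.groupby(level=0, sort=False).mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        length_g = weighted / tpm_g
    length_g = length_g.where(tpm_g > 0, mean_len)

    order = counts_g.index
    assays = {
        "counts": counts_g,
        "abundance": tpm_g.loc[order],
        "length": length_g.loc[order],
    }

    row_ranges = None
    if container.is_ranged:
        row_ranges = []
        for gid in order:
            rng = db.genes.get(gid)
            if rng is None:
                members = [
                    r
                    for f, r in zip(container.feature_ids, container.row_ranges)
                    if gene_of[f] == gid
                ]
                rng = TranscriptRange(
                    seqname=members[0].seqname,
                    start=min(m.start for m in members),
                    end=max(m.end for m in members),
                    strand=members[0].strand,
                    tx_id=gid,
                    gene_id=gid,
                )
            row_ranges.append(rng)

    metadata = dict(container.metadata)
    metadata["level"] = "gene"
    member_tx: Dict[str, list] = {}
    for f in container.feature_ids:
        member_tx.setdefault(gene_of[f], []).append(f)
    metadata["n_genes"] = len(order)

    return ExperimentContainer(
        assays=assays,
        column_data=container.column_data,
        metadata=metadata,
        row_ranges=row_ranges,
        level="gene",
    )


def convert_ids(
    container: ExperimentContainer,
    mapping: Dict[str, str],
    on_collision: str = "error",
) -> ExperimentContainer:
    """Rewrite feature identifiers through ``mapping``.

    ``on_collision`` decides what happens when several features map to the
    same new id: ``error`` (default), ``keep-first``, or ``aggregate-sum``
    (assay rows are summed; any ranges are dropped because a summed row no
    longer has a single location).
    """
    if on_collision not in {"error", "keep-first", "aggregate-sum"}:
        raise InputError(f"unknown collision policy {on_collision!r}")
    uncovered = [f for f in container.feature_ids if f not in mapping]
    if uncovered:
        raise InputError(
            f"{len(uncovered)} feature id(s) not covered by the mapping: "
            f"{uncovered[:10]}"
        )
    new_ids = [mapping[f] for f in container.feature_ids]
    dup_mask = pd.Index(new_ids).duplicated(keep=False)
    if dup_mask.any():
        if on_collision == "error":
            dups = sorted(set(pd.Index(new_ids)[dup_mask]))
            raise InputError(
                f"mapping collapses multiple features onto: {dups[:10]}; "
                "choose a collision policy"
            )
        if on_collision == "keep-first":
            keep = ~pd.Index(new_ids).duplicated(keep="first")
            container = container.subset_features(keep.tolist())
            new_ids = [mapping[f] for f in container.feature_ids]
        else:  # aggregate-sum
            idx = pd.Index(new_ids, name="feature_id")
            assays = {
                name: df.set_axis(idx).groupby(level=0, sort=False).sum()
                for name, df in container.assays.items()
            }
            return ExperimentContainer(
                assays=assays,
                column_data=container.column_data,
                metadata=dict(container.metadata),
                row_ranges=None,
                level=container.level,
            )
    idx = pd.Index(new_ids, name="feature_id")
    assays = {name: df.set_axis(idx) for name, df in container.assays.items()}
    return ExperimentContainer(
        assays=assays,
        column_data=container.column_data,
        metadata=dict(container.metadata),
        row_ranges=list(container.row_ranges) if container.row_ranges else None,
        level=container.level,
    )
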