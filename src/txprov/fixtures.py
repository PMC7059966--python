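"""Self-contained synthetic inputs: toy transcriptomes and quantifications.

Everything the import pipeline consumes — a transcriptome FASTA, matching
GTF and GFF3 renderings of the same gene model, a registry record with
``file://`` URIs, and Salmon-layout quantification directories whose
metadata embeds the FASTA digest — can be generated here from a seed, so
every pathway is exercisable with no network access and byte-identical
across runs.

The quantification model is deliberately minimal: counts are drawn from a
negative-binomial-like gamma–Poisson mix, effective length is a fixed
offset truncation ``max(length − 100, 1)`` (a stand-in for fragment-length
correction, not a model of it), and TPM follows from the standard
identity ``tpm_i ∝ (counts_i / efflen_i)`` scaled to sum to 1e6.  These
fixtures validate plumbing and provenance logic, not biological realism.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .annotation import AnnotationDB, parse_annotation
from .digest import digest_fasta, read_fasta
from .quantio import write_quant_dir
from .registry import TranscriptomeRecord

__all__ = ["make_toy_txome", "simulate_quant"]

_BASES = np.array(list("ACGT"))


def make_toy_txome(
    out_dir: Union[str, Path],
    n_genes: int = 20,
    tx_per_gene: int = 3,
    seq_len_range: Tuple[int, int] = (100, 500),
    seed: int = 42,
    genome: str = "toyGenome1",
    source: str = "toysource",
    organism: str = "Synthetica exempli",
    release: str = "1",
) -> Dict[str, object]:
    """Write a synthetic transcriptome bundle and return its pieces.

    Produces ``txome.fa`` (random nucleotide sequences), consistent
    ``annotation.gtf`` and ``annotation.gff3`` renderings of one gene
    model (single-exon transcripts nested inside their gene's span), and
    a :class:`TranscriptomeRecord` whose digest is that of the FASTA and
    whose URIs point at the local files.  Seed-fixed calls are
    byte-identical.
    """
    if n_genes < 1 or tx_per_gene < 1:
        raise ValueError("n_genes and tx_per_gene must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chroms = [f"chr{c + 1}" for c in range(min(3, n_genes))]
    gene_gap = 1000

    fasta_lines: List[str] = []
    gtf_lines: List[str] = []
    gff3_lines: List[str] = ["##gff-version 3"]
    tx_ids: List[str] = []
    cursor = {c: 1 for c in chroms}

    body_gtf: List[str] = []
    body_gff3: List[str] = []
    for g in range(1, n_genes + 1):
        chrom = chroms[(g - 1) % len(chroms)]
        strand = "+" if rng.integers(2) == 0 else "-"
        gene_id = f"GENE{g:03d}"
        gene_start = cursor[chrom]
        tx_entries = []
        offset = 0
        for t in range(1, tx_per_gene + 1):
            tx_id = f"TX{g:03d}.{t}"
            tx_ids.append(tx_id)
            length = int(rng.integers(seq_len_range[0], seq_len_range[1] + 1))
            start = gene_start + offset
            end = start + length - 1
            offset += int(rng.integers(10, 200))
            seq = "".join(rng.choice(_BASES, size=length))
            fasta_lines.append(f">{tx_id} gene={gene_id}")
            for i in range(0, length, 70):
                fasta_lines.append(seq[i : i + 70])
            tx_entries.append((tx_id, start, end, length))
        gene_end = max(e for _, _, e, _ in tx_entries)
        cursor[chrom] = gene_end + gene_gap

        body_gtf.append(
            f'{chrom}\ttoy\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t'
            f'gene_id "{gene_id}";'
        )
        body_gff3.append(
            f"{chrom}\ttoy\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t"
            f"ID={gene_id}"
        )
        for tx_id, start, end, length in tx_entries:
            gtf_attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
            body_gtf.append(
                f"{chrom}\ttoy\ttranscript\t{start}\t{end}\t.\t{strand}\t.\t{gtf_attrs}"
            )
            body_gtf.append(
                f"{chrom}\ttoy\texon\t{start}\t{end}\t.\t{strand}\t.\t"
                f'{gtf_attrs} exon_number "1";'
            )
            body_gff3.append(
                f"{chrom}\ttoy\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={tx_id};Parent={gene_id}"
            )
            body_gff3.append(
                f"{chrom}\ttoy\texon\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={tx_id}.exon1;Parent={tx_id}"
            )

    for chrom in chroms:
        pragma_len = cursor[chrom] + gene_gap
        gff3_lines.append(f"##sequence-region {chrom} 1 {pragma_len}")
    gff3_lines += body_gff3
    gtf_lines += body_gtf

    fasta_path = out_dir / "txome.fa"
    gtf_path = out_dir / "annotation.gtf"
    gff3_path = out_dir / "annotation.gff3"
    fasta_path.write_text("\n".join(fasta_lines) + "\n")
    gtf_path.write_text("\n".join(gtf_lines) + "\n")
    gff3_path.write_text("\n".join(gff3_lines) + "\n")

    digest = digest_fasta(fasta_path)
    record = TranscriptomeRecord(
        sha256_hex=digest.sha256_hex,
        source=source,
        organism=organism,
        release=release,
        genome=genome,
        fasta_uris=[fasta_path.resolve().as_uri()],
        gtf_uri=gtf_path.resolve().as_uri(),
    )
    db = parse_annotation(gtf_path, dialect="generic-gtf", genome=genome)
    return {
        "fasta": fasta_path,
        "gtf": gtf_path,
        "gff3": gff3_path,
        "db": db,
        "record": record,
        "digest": digest,
        "tx_ids": tx_ids,
    }


def simulate_quant(
    fasta: Union[str, Path],
    out_root: Union[str, Path],
    n_samples: int = 4,
    lib_size_range: Tuple[int, int] = (50_000, 100_000),
    seed: int = 42,
    sample_names: Optional[List[str]] = None,
    index_seq_hash: Optional[str] = None,
) -> List[Path]:
    """Write Salmon-layout quantification directories for a FASTA.

    Each sample gets random non-negative estimated counts (gamma–Poisson,
    so dispersion exceeds Poisson), ``effective_length = max(length − 100,
    1)``, and TPM from the normalization identity; the metadata JSON
    embeds the FASTA's digest (or an explicit ``index_seq_hash``, used by
    tests to fabricate provenance conflicts) plus synthetic run metadata.
    """
    fasta = Path(fasta)
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    entries = read_fasta(fasta)
    lengths = np.array([len(e.seq) for e in entries], dtype=int)
    efflens = np.maximum(lengths - 100, 1).astype(float)
    tx_ids = [e.id for e in entries]
    if index_seq_hash is None:
        index_seq_hash = digest_fasta(fasta).sha256_hex

    if sample_names is None:
        sample_names = [f"sample{i + 1}" for i in range(n_samples)]
    if len(sample_names) != n_samples:
        raise ValueError("sample_names length must equal n_samples")

    paths: List[Path] = []
    for name in sample_names:
        lib_size = int(rng.integers(lib_size_range[0], lib_size_range[1] + 1))
        rates = rng.gamma(shape=0.7, scale=1.0, size=len(entries))
        probs = rates / rates.sum()
        counts = rng.poisson(lib_size * probs).astype(float)
        rate = counts / efflens
        denom = rate.sum()
        tpm = (rate / denom) * 1e6 if denom > 0 else np.zeros_like(rate)

        rows = [
            (tx_ids[i], int(lengths[i]), float(efflens[i]), float(tpm[i]), float(counts[i]))
            for i in range(len(entries))
        ]
        table = pd.DataFrame(
            rows, columns=["tx_id", "length", "effective_length", "tpm", "num_reads"]
        )
        run_metadata = {
            "library_type": "ISR",
            "percent_mapped": round(float(rng.uniform(80, 99)), 2),
            "num_processed": lib_size,
            "quantifier": "synthetic-quant",
            "quantifier_version": "0.0",
        }
        sample_dir = out_root / name
        write_quant_dir(sample_dir, table, index_seq_hash, run_metadata)
        paths.append(sample_dir)
    return paths
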