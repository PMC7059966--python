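# Methods

## Checksum identity of a sequence collection

The identity of a reference transcriptome is computed from its cDNA
sequences alone — never from headers, file names, or user declarations.
Two digests are primary:

- `sha256_hex` / `sha512_hex`: the hash of all sequences concatenated in
  file order with the empty string as separator. Concatenation makes the
  digest *split-insensitive* (`["ACGT"]` and `["AC","GT"]` collide by
  construction) but order-sensitive; it is the identifier the quantifier
  ecosystem embeds in sample output, so it is what registry lookup keys
  on.
- `order_invariant_sha256_hex`: the SHA-256 of the per-sequence SHA-256
  hex digests, lowercase, sorted bytewise-lexicographically and
  concatenated with no separator. This fixes an encoding for the
  "sorted set of checksums" idea precisely, and is stored for future
  interoperability with sequence-collection identifier standards; it is
  not used for lookup.

Normative byte-level choices, since any ambiguity destroys
reproducibility across implementations:

- sequences are hashed exactly as read — **no case folding** and no
  alphabet validation. Raw bytes are the only convention requiring no
  extra agreement between tools; a `uppercase=True` option exists for
  pipelines that fold case. Alphabet linting is deliberately not a hash
  precondition.
- sequences are encoded as UTF-8 (ASCII in practice) before hashing.
- an auxiliary `name_sha256_hex` over the sorted, newline-joined
  transcript identifiers is computed because real quantifier outputs
  carry a name hash next to the sequence hash; it is diagnostic only and
  never participates in matching.

Empty input is legal and yields the standard empty-string digests.
Duplicate FASTA identifiers are kept (with a warning) because file order,
not identifier uniqueness, determines the concatenation digest.

## Quantification directories

A sample is its whole output directory, not just `quant.sf`: the
provenance lives in `aux_info/meta_info.json` (fallback:
`meta_info.json`), under the key `index_seq_hash` (fallback: `seq_hash`).
A directory without a readable checksum is a *provenance* error, distinct
from format errors, because the data may be fine and yet unusable for
verified import. `quant.sf` columns are matched by header name, not
position. Floats are written with `repr` (shortest round-trippable
decimal) and read back with round-trip parsing, so the fixture writer and
the reader are exact inverses — assay fidelity downstream is then
testable as bit-for-bit equality rather than tolerance comparison.

## Registry and cache

The registry maps SHA-256 → (source, organism, release, genome, FASTA
URIs, GTF/GFF URI). The shipped built-in table is a scaffold; digests for
real public releases are a data-maintenance task against the live
mirrors, out of scope for an offline build. Custom entries (linked
transcriptomes) live in a per-cache TSV and win over built-in rows on
collision, with a warning. Lookup is exact and case-insensitive on hex;
"not found" is a value, not an error, because the non-ranged fallback is
a legitimate outcome.

The file cache is a directory with a JSON index, designed for the
cluster-sharing use case: every write (payloads and the index itself)
goes to a temp file in the same directory followed by `os.replace`, so
concurrent readers never observe a partial file and the last writer wins.
Keys are `<sha256>.<kind>`; entries are stamped with the package version
so a format change invalidates cleanly (`CacheInvalidError` → re-parse).

## Annotation parsing

One parser handles GTF and GFF3; the attribute syntax is detected from
content, while the declared dialect steers identifier handling only.
Feature-line tokenization is delegated to `gffutils` (in-memory database,
duplicate-tolerant); model assembly on top is this package's:

- GTF: transcripts come from explicit `transcript` features; every line
  carrying a `transcript_id` votes on the gene assignment, and
  conflicting votes are a format error naming the transcript —
  inconsistent annotations should fail loudly before ranges are attached
  to expression data.
- GFF3: transcript-level features are `transcript`/`mRNA` plus any
  feature whose ID is referenced by an exon's `Parent` — this covers de
  novo annotation pipelines whose transcript rows use other types. Gene
  resolution order: `Parent` attribute(s), explicit `gene_id`, free-text
  `Note` (seen in de novo annotation output, where the "gene" column is
  an ORF description), finally the transcript's own id. Multiple parents
  are kept as a list; summarization uses the first and warns.

Coordinates are 1-based fully closed throughout (the GTF/GFF3 native
convention). Strand `.`/`?` maps to `*`. Gene ranges are the
min-start/max-end span of the gene's transcripts on one seqname+strand
(first group wins, with a warning, if members disagree). `seqinfo` is
populated from `##sequence-region` pragmas where present, else lengths
are unknown; the genome build label comes from the registry record, not
the annotation file. Ensembl-style biotype attributes
(`transcript_biotype`/`gene_biotype`/`*_type`) are kept in `extra` when
present; CDS coordinates are not modeled.

Persistence is a single version-stamped JSON file per transcriptome in
the cache. A relational store would add nothing here: the access pattern
is load-everything, and round-trip fidelity is the only requirement.

## Import semantics

- The checksum must be identical across all samples of one import; the
  error lists every sample's digest. Samples sharing a checksum but
  reporting different transcript sets (impossible unless files were
  edited) also error.
- Features are ordered as in the first sample's `quant.sf`; samples as in
  the sample table. counts ← NumReads, abundance ← TPM, length ←
  EffectiveLength, verbatim.
- Id matching at range attachment: dialect normalization first (GENCODE
  pipe-bundled FASTA ids reduce to their first field), then exact match,
  then a version-stripped (`.N` suffix) fallback — applied only where the
  stripped id is unambiguous in the annotation, since guessing among
  ambiguous candidates could attach a wrong range silently.
- Missing transcripts are an **error by default**, not a drop: silent row
  dropping hides exactly the annotation/quantification mismatch this
  package exists to catch. `allow_missing_tx=True` drops the rows from
  every assay and records the count in metadata.
- Overlap subsetting is closed-interval (touching endpoints overlap) and
  strand-blind by default (`ignore_strand=False` requires strand match,
  with `*` matching anything). Genome builds must match and query
  chromosomes must be known to the container before any coordinate is
  compared; mismatches raise rather than returning an empty result.

## Summarization

Per gene and sample: counts and TPM are sums over member transcripts; the
effective length is the TPM-weighted mean of member lengths, falling back
to the unweighted mean when the gene's TPM is zero (the weighted form is
0/0 there; the unweighted mean is the natural limit and keeps the value
finite for downstream offset use). Weights are each sample's own TPM, so
gene length varies across samples with isoform usage — the
abundance-weighted-mean convention of the transcript-import framework
this follows. No counts-from-abundance rescaling modes are offered.
Identifier conversion supports bijective renames and three collision
policies (error / keep-first / aggregate-sum); aggregate-sum drops ranges
because a summed row no longer has a single location.

## Synthetic data

`make_toy_txome` emits one gene model rendered consistently as FASTA, GTF
and GFF3: a configurable number of genes (default 20) with a configurable
number of single-exon transcripts each (default 3), random sequences of
100–500 nt, laid out head-to-tail on up to three chromosomes, with a
registry record carrying the FASTA digest and `file://` URIs.
`simulate_quant` (default 4 samples) draws library sizes of 50–100k
reads, gamma–Poisson counts (overdispersed relative to Poisson, as real
count data are), sets `effective_length = max(length − 100, 1)` — a fixed
offset truncation standing in for fragment-length correction, not a model
of it — and computes TPM by the normalization identity
`tpm_i ∝ counts_i / efflen_i`, scaled to 1e6 (all-zero samples get
all-zero TPM). Defaults were chosen once as small-but-realistic for a toy
pipeline and are not tuned.

What passing tests on these fixtures show: the plumbing — hashing,
parsing, verification, assembly, caching, aggregation — is exact. What
they do not show: robustness to real annotation irregularities
(multi-exon structures beyond what range attachment needs, malformed
attribute escapes, scaffold-heavy assemblies) or statistical realism of
the expression values; none of the package's claims depend on the
latter.

## Problem sizes

The test suite and the acceptance script run on transcriptomes of 3–20
genes × 1–3 transcripts, 1–4 samples, 100 random digest sets, and 20
random summarization fixtures of up to ~50 genes — sizes at which every
check is exact and the full run takes seconds. All operations are linear
(or n log n) in transcripts × samples, and the import path has been kept
free of per-row Python loops in the assay assembly, so the same code
serves full-size transcriptomes (~10⁵ transcripts).

## Known limitations

- The built-in registry ships empty; real-release digests must be added
  by the data-maintenance route or via linked-transcriptome JSONs.
- Remote URI fetching (`http(s)`/`ftp`) exists but is best-effort and
  untested offline; all tested paths use `file://` URIs.
- Inferential replicates, single-cell binary formats, equivalence-class
  files, and exon-level assays are out of scope; exon ranges are exposed
  only as `AnnotationDB.exons_by_tx`.
- The linked-transcriptome JSON stores only the SHA-256 (the registry
  key), not the SHA-512.
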