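# Built-in checksum -> transcriptome hash table.
# One row per reference transcriptome release: the SHA-256 digest of the
# concatenated cDNA sequences is the primary key; fasta_uris are
# ';'-separated. Populating digests for real GENCODE/Ensembl/RefSeq
# releases is a data-maintenance task performed against the live mirrors;
# this shipped table is the scaffold, and custom/linked entries take
# precedence on collision.
sha256_hex	source	organism	release	genome	fasta_uris	gtf_uri
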