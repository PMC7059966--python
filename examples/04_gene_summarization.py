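"""Transcript-to-gene summarization with abundance-weighted lengths.

Shows the aggregation rules on a hand-checkable two-isoform gene, then on
a full synthetic pipeline where totals are conserved.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from txprov import import_quants, summarize_to_gene, SampleTable
from txprov.annotation import AnnotationDB, TranscriptRange
from txprov.importer import ExperimentContainer
from txprov.fixtures import make_toy_txome, simulate_quant
from txprov.registry import FileCache, append_custom_record

# --- hand-checkable case: isoforms (tpm 3, len 100) and (tpm 1, len 200) ---
idx = pd.Index(["t1", "t2"], name="tx_id")
mk = lambda v: pd.DataFrame({"s1": v}, index=idx, dtype=float)
se = ExperimentContainer(
    assays={"counts": mk([30, 10]), "abundance": mk([3, 1]), "length": mk([100, 200])},
    column_data=pd.DataFrame(index=pd.Index(["s1"], name="names")),
    metadata={},
)
tx = [TranscriptRange("chr1", 1, 100, "+", t, "G") for t in ("t1", "t2")]
db = AnnotationDB(transcripts=tx, genes={"G": tx[0]},
                  tx2gene={"t1": "G", "t2": "G"},
                  seqinfo={"chr1": {"length": None, "genome": None, "circular": False}})
gene = summarize_to_gene(se, db)
print("gene counts:", float(gene.assays["counts"].loc["G", "s1"]))      # 40.0
print("gene tpm:   ", float(gene.assays["abundance"].loc["G", "s1"]))   # 4.0
print("gene length:", float(gene.assays["length"].loc["G", "s1"]))      # 125.0
# length = (3/4)*100 + (1/4)*200: the dominant isoform dominates the
# gene's effective length.

# --- full pipeline: totals are conserved through summarization ---
with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    bundle = make_toy_txome(tmp / "txome", n_genes=6, tx_per_gene=3, seed=42)
    quants = simulate_quant(bundle["fasta"], tmp / "quants", n_samples=2, seed=42)
    cache = FileCache(tmp / "cache")
    append_custom_record(cache.custom_registry_path, bundle["record"])
    coldata = SampleTable(pd.DataFrame({
        "names": [q.name for q in quants],
        "files": [str(q / "quant.sf") for q in quants],
    }))
    se = import_quants(coldata, cache=cache)
    gl = summarize_to_gene(se, bundle["db"])
    print("\ntranscript container:", se.shape, "-> gene container:", gl.shape)
    print("counts conserved:",
          np.allclose(se.assays["counts"].sum(), gl.assays["counts"].sum()))
    print("TPM conserved:   ",
          np.allclose(se.assays["abundance"].sum(), gl.assays["abundance"].sum()))
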