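"""Share provenance for a de novo transcriptome via a linked-txome JSON.

Machine A links a custom transcriptome's digest to its public FASTA/GFF3
locations and writes a JSON document.  Machine B (a fresh cache) loads the
JSON; importing then attaches ranges exactly as a built-in registry hit
would.
"""

import tempfile
from pathlib import Path

import pandas as pd

from txprov import import_quants, make_linked_txome, load_linked_txome, SampleTable
from txprov.fixtures import make_toy_txome, simulate_quant
from txprov.registry import FileCache

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    bundle = make_toy_txome(tmp / "txome", n_genes=4, tx_per_gene=2, seed=42)
    quants = simulate_quant(bundle["fasta"], tmp / "quants", n_samples=2, seed=42)
    rec = bundle["record"]

    # machine A: create the link (side effects: custom table row + JSON file)
    machine_a = FileCache(tmp / "cache_a")
    link_json = tmp / "linked_txome.json"
    made = make_linked_txome(
        bundle["fasta"], source="dammit", organism="Fundulus rathbuni",
        release="0", genome="none", fasta_uris=rec.fasta_uris,
        gtf_uri=rec.gtf_uri, cache=machine_a, json_out=link_json,
    )
    print("linked digest:", made.sha256_hex[:16], "…  JSON:", link_json.name)

    # machine B: load the shared JSON into a brand-new cache, then import
    machine_b = FileCache(tmp / "cache_b")
    load_linked_txome(link_json, cache=machine_b)
    coldata = SampleTable(pd.DataFrame({
        "names": ["sample1", "sample2"],
        "files": [str(q / "quant.sf") for q in quants],
    }))
    se = import_quants(coldata, cache=machine_b)
    print("machine B import ranged:", se.is_ranged,
          "| organism:", se.metadata["txome"].organism)

# The JSON is the only thing that traveled between machines; the checksum
# inside it is what reconnects the quantifications to their annotation.
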