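"""Reading and writing per-sample quantification directories.

A quantification directory (Salmon layout) holds ``quant.sf`` — a TSV with
one row per transcript and columns Name, Length, EffectiveLength, TPM,
NumReads — next to an ``aux_info/meta_info.json`` metadata file that embeds
the checksum of the index the sample was quantified against.  The whole
directory, not just quant.sf, is the quantifier's output: the metadata file
is what makes provenance identification possible.

The writer here mirrors the reader so synthetic fixtures round-trip
bit-for-bit; floats are serialized with ``repr`` (shortest round-trippable
decimal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .errors import InputError, FormatError, ProvenanceError, SchemaError

__all__ = [
    "QuantRow",
    "QuantSample",
    "SampleTable",
    "QUANT_COLUMNS",
    "read_quant_dir",
    "read_sample_table",
    "write_quant_dir",
]

#: canonical quant.sf column order
QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]

#: metadata JSON keys probed for the index sequence checksum, in order
_HASH_KEYS = ("index_seq_hash", "seq_hash")

#: locations probed for the metadata JSON, relative to the sample directory
_META_PATHS = ("aux_info/meta_info.json", "meta_info.json")


@dataclass
class QuantRow:
    """One transcript's quantification estimates in one sample."""

    tx_id: str
    length: int
    effective_length: float
    tpm: float
    num_reads: float


@dataclass
class QuantSample:
    """One sample's parsed quantification directory.

    ``table`` is a DataFrame with columns tx_id, length, effective_length,
    tpm, num_reads in quant.sf row order.
    """

    name: str
    path: Path
    table: pd.DataFrame
    index_seq_hash: str
    run_metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def rows(self) -> List[QuantRow]:
        return [QuantRow(*t) for t in self.table.itertuples(index=False)]

    @property
    def tx_ids(self) -> List[str]:
        return self.table["tx_id"].tolist()


@dataclass
class SampleTable:
    """The sample sheet: unique sample names, quant.sf paths, covariates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("names", "files"):
            if col not in self.data.columns:
                raise SchemaError(f"sample table lacks required column '{col}'")
        if self.data["names"].duplicated().any():
            dup = self.data.loc[self.data["names"].duplicated(), "names"].tolist()
            raise SchemaError(f"duplicate sample names: {dup}")

    @property
    def names(self) -> List[str]:
        return self.data["names"].tolist()

    @property
    def files(self) -> List[str]:
        return self.data["files"].tolist()

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["files"])

    def __len__(self) -> int:
        return len(self.data)


def _check_hex(value: str, where: str) -> str:
    value = str(value).strip().lower()
    if not value or any(c not in "0123456789abcdef" for c in value):
        raise ProvenanceError(f"malformed index checksum in {where}: {value!r}")
    return value


def read_quant_dir(quant_sf_path: Union[str, Path], name: Optional[str] = None) -> QuantSample:
    """Parse one quantification directory given the path of its quant.sf.

    The metadata JSON is searched at ``aux_info/meta_info.json`` then
    ``meta_info.json`` inside the sample directory; its index checksum key
    is required.  quant.sf columns are matched by header name, not
    position.
    """
    quant_sf_path = Path(quant_sf_path)
    if not quant_sf_path.exists():
        raise InputError(f"quant.sf not found: {quant_sf_path}")
    sample_dir = quant_sf_path.parent

    meta_path = None
    for rel in _META_PATHS:
        candidate = sample_dir / rel
        if candidate.exists():
            meta_path = candidate
            break
    if meta_path is None:
        raise ProvenanceError(
            f"no metadata JSON found for {sample_dir} "
            f"(expected one of: {', '.join(_META_PATHS)}); the whole "
            "quantification directory, not just quant.sf, is the quantifier output"
        )
    with open(meta_path) as fh:
        meta = json.load(fh)
    index_seq_hash = None
    for key in _HASH_KEYS:
        if key in meta:
            index_seq_hash = _check_hex(meta[key], str(meta_path))
            break
    if index_seq_hash is None:
        raise ProvenanceError(
            f"metadata JSON {meta_path} lacks an index checksum key "
            f"(expected one of: {', '.join(_HASH_KEYS)})"
        )
    run_metadata = {k: v for k, v in meta.items() if k not in _HASH_KEYS}

    # round_trip parsing so written repr-floats come back bit-identical
    df = pd.read_csv(quant_sf_path, sep="\t", float_precision="round_trip")
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"malformed quant.sf header in {quant_sf_path}: missing columns "
            f"{missing}; expected {QUANT_COLUMNS}"
        )
    table = pd.DataFrame(
        {
            "tx_id": df["Name"].astype(str),
            "length": df["Length"].astype(int),
            "effective_length": df["EffectiveLength"].astype(float),
            "tpm": df["TPM"].astype(float),
            "num_reads": df["NumReads"].astype(float),
        }
    )
    if table["tx_id"].duplicated().any():
        dup = table.loc[table["tx_id"].duplicated(), "tx_id"].tolist()[:5]
        raise FormatError(f"duplicate transcript ids in {quant_sf_path}: {dup}")
    return QuantSample(
        name=name or sample_dir.name,
        path=sample_dir,
        table=table,
        index_seq_hash=index_seq_hash,
        run_metadata=run_metadata,
    )


def read_sample_table(
    csv_path: Union[str, Path],
    quant_root: Optional[Union[str, Path]] = None,
) -> SampleTable:
    """Read the sample sheet CSV.

    A ``names`` column is required.  If no ``files`` column is present,
    ``quant_root`` must be given and paths are synthesized as
    ``quant_root/<name>/quant.sf``.  File existence is checked eagerly so a
    typo'd path fails before any parsing starts.
    """
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise InputError(f"sample table not found: {csv_path}")
    df = pd.read_csv(csv_path)
    if "names" not in df.columns:
        raise SchemaError(f"sample table {csv_path} lacks required column 'names'")
    if "files" not in df.columns:
        if quant_root is None:
            raise SchemaError(
                f"sample table {csv_path} has no 'files' column and no quant_root was given"
            )
        root = Path(quant_root)
        df = df.copy()
        df["files"] = [str(root / str(n) / "quant.sf") for n in df["names"]]
    missing = [f for f in df["files"] if not Path(f).exists()]
    if missing:
        raise InputError("missing quantification files:\n" + "\n".join(str(m) for m in missing))
    return SampleTable(df)


def _fmt(x: float) -> str:
    # repr gives the shortest decimal that round-trips the double exactly
    return repr(float(x))


def write_quant_dir(
    out_dir: Union[str, Path],
    rows: Union[pd.DataFrame, Sequence[QuantRow]],
    index_seq_hash: str,
    run_metadata: Optional[Dict[str, object]] = None,
) -> Path:
    """Write a quantification directory that ``read_quant_dir`` inverts exactly."""
    out_dir = Path(out_dir)
    (out_dir / "aux_info").mkdir(parents=True, exist_ok=True)

    if isinstance(rows, pd.DataFrame):
        records = list(rows.itertuples(index=False))
    else:
        records = [(r.tx_id, r.length, r.effective_length, r.tpm, r.num_reads) for r in rows]

    lines = ["\t".join(QUANT_COLUMNS)]
    for tx_id, length, efflen, tpm, reads in records:
        lines.append(f"{tx_id}\t{int(length)}\t{_fmt(efflen)}\t{_fmt(tpm)}\t{_fmt(reads)}")
    (out_dir / "quant.sf").write_text("\n".join(lines) + "\n")

    meta = dict(run_metadata or {})
    meta["index_seq_hash"] = index_seq_hash
    with open(out_dir / "aux_info" / "meta_info.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return out_dir
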