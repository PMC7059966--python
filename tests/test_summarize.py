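"""Gene-level summarization against a naive per-gene oracle, plus id conversion."""

import numpy as np
import pandas as pd
import pytest

from txprov.errors import InputError
from txprov.importer import ExperimentContainer
from txprov.annotation import AnnotationDB, TranscriptRange
from txprov.summarize import convert_ids, summarize_to_gene


def build_container(tx_ids, counts, tpm, length, samples=("s1",)):
    idx = pd.Index(tx_ids, name="tx_id")
    mk = lambda m: pd.DataFrame(np.asarray(m, dtype=float), index=idx, columns=samples)
    return ExperimentContainer(
        assays={"counts": mk(counts), "abundance": mk(tpm), "length": mk(length)},
        column_data=pd.DataFrame(index=pd.Index(samples, name="names")),
        metadata={},
    )


def db_for(tx2gene):
    transcripts = [
        TranscriptRange(seqname="chr1", start=1, end=100, strand="+",
                        tx_id=t, gene_id=g)
        for t, g in tx2gene.items()
    ]
    genes = {}
    for t in transcripts:
        g = genes.setdefault(
            t.primary_gene_id,
            TranscriptRange(seqname="chr1", start=t.start, end=t.end, strand="+",
                            tx_id=t.primary_gene_id, gene_id=t.primary_gene_id),
        )
    return AnnotationDB(
        transcripts=transcripts, genes=genes, tx2gene=dict(tx2gene),
        seqinfo={"chr1": {"length": None, "genome": None, "circular": False}},
        provenance={"dialect": "generic-gtf"},
    )


def naive_summarize(container, tx2gene):
    """Reference loop implementing the stated formulas directly."""
    out = {}
    for sample in container.sample_names:
        per_gene = {}
        for tx in container.feature_ids:
            g = tx2gene[tx]
            per_gene.setdefault(g, []).append(
                (
                    container.assays["counts"].loc[tx, sample],
                    container.assays["abundance"].loc[tx, sample],
                    container.assays["length"].loc[tx, sample],
                )
            )
        for g, members in per_gene.items():
            counts = sum(c for c, _, _ in members)
            tpm = sum(t for _, t, _ in members)
            if tpm > 0:
                length = sum((t / tpm) * l for _, t, l in members)
            else:
                length = sum(l for _, _, l in members) / len(members)
            out[(g, sample)] = (counts, tpm, length)
    return out


class TestSummarizeToGene:
    def test_worked_example_abundance_weighted_length(self):
        # two isoforms: (tpm 3, len 100, counts 30) and (tpm 1, len 200, counts 10)
        # -> counts 40, tpm 4, length (3/4)*100 + (1/4)*200 = 125
        se = build_container(["t1", "t2"], [[30], [10]], [[3], [1]], [[100], [200]])
        gene = summarize_to_gene(se, db_for({"t1": "G", "t2": "G"}))
        assert gene.assays["counts"].loc["G", "s1"] == 40
        assert gene.assays["abundance"].loc["G", "s1"] == 4
        assert gene.assays["length"].loc["G", "s1"] == 125

    def test_single_transcript_gene_is_identity(self):
        se = build_container(["t1"], [[7.5]], [[12.0]], [[88.0]])
        gene = summarize_to_gene(se, db_for({"t1": "G"}))
        assert gene.assays["counts"].loc["G", "s1"] == 7.5
        assert gene.assays["abundance"].loc["G", "s1"] == 12.0
        assert gene.assays["length"].loc["G", "s1"] == 88.0

    def test_zero_tpm_gene_falls_back_to_unweighted_mean(self):
        se = build_container(["t1", "t2"], [[0], [0]], [[0], [0]], [[100], [300]])
        gene = summarize_to_gene(se, db_for({"t1": "G", "t2": "G"}))
        assert gene.assays["length"].loc["G", "s1"] == 200
        assert gene.assays["counts"].loc["G", "s1"] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(2, 50))
        tx2gene = {}
        tx_ids = []
        for g in range(n_genes):
            for t in range(int(rng.integers(1, 4))):
                tx = f"t{g}_{t}"
                tx_ids.append(tx)
                tx2gene[tx] = f"G{g}"
        n = len(tx_ids)
        samples = ("s1", "s2")
        counts = rng.integers(0, 500, size=(n, 2)).astype(float)
        tpm = rng.gamma(1.0, 10.0, size=(n, 2))
        tpm[rng.random(size=(n, 2)) < 0.2] = 0.0  # exercise the fallback
        length = rng.integers(50, 2000, size=(n, 2)).astype(float)
        se = build_container(tx_ids, counts, tpm, length, samples)
        gene = summarize_to_gene(se, db_for(tx2gene))
        oracle = naive_summarize(se, tx2gene)
        for (g, sample), (c, t, l) in oracle.items():
            assert gene.assays["counts"].loc[g, sample] == pytest.approx(c)
            assert gene.assays["abundance"].loc[g, sample] == pytest.approx(t)
            assert gene.assays["length"].loc[g, sample] == pytest.approx(l)

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_and_tpm_conserved(self, seed):
        rng = np.random.default_rng(100 + seed)
        tx_ids = [f"t{i}" for i in range(30)]
        tx2gene = {t: f"G{i % 7}" for i, t in enumerate(tx_ids)}
        counts = rng.integers(0, 100, size=(30, 2)).astype(float)
        tpm = rng.gamma(1.0, 5.0, size=(30, 2))
        length = rng.integers(100, 900, size=(30, 2)).astype(float)
        se = build_container(tx_ids, counts, tpm, length, ("s1", "s2"))
        gene = summarize_to_gene(se, db_for(tx2gene))
        assert np.allclose(
            gene.assays["counts"].sum(), se.assays["counts"].sum()
        )
        assert np.allclose(
            gene.assays["abundance"].sum(), se.assays["abundance"].sum()
        )

    def test_unmapped_transcript_policy(self):
        se = build_container(["t1", "tX"], [[1], [2]], [[1], [2]], [[10], [20]])
        db = db_for({"t1": "G"})
        with pytest.raises(InputError, match="tX"):
            summarize_to_gene(se, db)
        gene = summarize_to_gene(se, db, allow_missing_tx=True)
        assert list(gene.assays["counts"].index) == ["G"]

    def test_gene_ranges_span_members(self, sample_table, registered_cache,
                                      toy_bundle):
        from txprov.importer import import_quants

        se = import_quants(sample_table, cache=registered_cache)
        gene = summarize_to_gene(se, toy_bundle["db"])
        assert gene.is_ranged
        tx_by_gene = {}
        for t in toy_bundle["db"].transcripts:
            tx_by_gene.setdefault(t.primary_gene_id, []).append(t)
        for rng_g in gene.row_ranges:
            members = tx_by_gene[rng_g.tx_id]
            assert rng_g.start == min(m.start for m in members)
            assert rng_g.end == max(m.end for m in members)
        assert gene.level == "gene"

    def test_gene_level_container_cannot_be_resummarized(self):
        se = build_container(["t1"], [[1]], [[1]], [[10]])
        gene = summarize_to_gene(se, db_for({"t1": "G"}))
        with pytest.raises(InputError):
            summarize_to_gene(gene, db_for({"t1": "G"}))


class TestConvertIds:
    def test_bijective_rename_keeps_matrices(self):
        se = build_container(["t1", "t2"], [[1], [2]], [[1], [2]], [[10], [20]])
        out = convert_ids(se, {"t1": "a", "t2": "b"})
        assert out.feature_ids == ["a", "b"]
        assert (out.assays["counts"].to_numpy() == se.assays["counts"].to_numpy()).all()

    def test_collision_default_errors(self):
        se = build_container(["t1", "t2"], [[1], [2]], [[1], [2]], [[10], [20]])
        with pytest.raises(InputError, match="collision|collapses"):
            convert_ids(se, {"t1": "x", "t2": "x"})

    def test_collision_aggregate_sum(self):
        se = build_container(["t1", "t2"], [[1], [2]], [[3], [4]], [[10], [20]])
        out = convert_ids(se, {"t1": "x", "t2": "x"}, on_collision="aggregate-sum")
        assert out.assays["counts"].loc["x", "s1"] == 3
        assert out.assays["abundance"].loc["x", "s1"] == 7

    def test_collision_keep_first(self):
        se = build_container(["t1", "t2"], [[1], [2]], [[3], [4]], [[10], [20]])
        out = convert_ids(se, {"t1": "x", "t2": "x"}, on_collision="keep-first")
        assert out.assays["counts"].loc["x", "s1"] == 1

    def test_uncovered_id_errors(self):
        se = build_container(["t1", "t2"], [[1], [2]], [[1], [2]], [[10], [20]])
        with pytest.raises(InputError, match="not covered"):
            convert_ids(se, {"t1": "a"})
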