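"""Shared fixtures: small FASTA/SAM builders and the session-scoped pipeline run."""

from __future__ import annotations

from types import SimpleNamespace

import pysam
import pytest

from hicbin.contacts import PairStats, build_contact_map, stream_pairs
from hicbin.contigs import scan_contigs, write_fasta
from hicbin.cluster import cluster_graph, filter_bins, to_graph
from hicbin.normalize import normalize_map
from hicbin.simulate import SimulationConfig, simulate_dataset
from hicbin.validate import SoftTruth


@pytest.fixture
def fasta_writer(tmp_path):
    def write(records: list[tuple[str, str]], name: str = "test.fasta"):
        path = tmp_path / name
        write_fasta(records, path)
        return path

    return write


@pytest.fixture
def sam_writer(tmp_path):
    """Write a SAM from (qname, flag, ref, pos, mapq) alignment tuples."""

    def write(contigs: dict[str, int], alignments, name: str = "test.sam", sort_order="queryname"):
        path = tmp_path / name
        header = {
            "HD": {"VN": "1.6", "SO": sort_order},
            "SQ": [{"SN": c, "LN": ln} for c, ln in contigs.items()],
        }
        tid = {c: k for k, c in enumerate(contigs)}
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for qname, flag, ref, pos, mapq in alignments:
                aln = pysam.AlignedSegment(fh.header)
                aln.query_name = qname
                aln.flag = flag
                if ref is not None:
                    aln.reference_id = tid[ref]
                    aln.reference_start = pos
                    aln.cigarstring = "50M"
                aln.mapping_quality = mapq
                fh.write(aln)
        return path

    return write


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Default synthetic fixture pushed through the whole pipeline once.

    Exercises the real ingestion path (FASTA scan + SAM streaming), then
    normalization, clustering and the extent filter, and returns every
    intermediate for the end-to-end checks.
    """
    outdir = tmp_path_factory.mktemp("community")
    cfg = SimulationConfig()
    comm = simulate_dataset(cfg, outdir)
    table = scan_contigs(outdir / "contigs.fasta", list(cfg.enzymes))
    stats = PairStats()
    pairs = stream_pairs(outdir / "pairs.sam", min_mapq=60, stats=stats)
    cmap = build_contact_map(pairs, table, min_len=1000, min_signal=5)
    bal = normalize_map(cmap)
    graph = to_graph(bal)
    solution = filter_bins(cluster_graph(graph, trials=10, seed=cfg.seed), cmap.contigs, 50_000)
    truth = SoftTruth.load(outdir / "truth.tsv")
    return SimpleNamespace(
        cfg=cfg,
        comm=comm,
        outdir=outdir,
        table=table,
        pair_stats=stats,
        cmap=cmap,
        bal=bal,
        graph=graph,
        solution=solution,
        truth=truth,
    )
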