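"""Whole-contig Hi-C contact map accumulation from filtered read-pair alignments.

Read pairs are streamed from a name-sorted BAM/SAM; a pair is usable when
both mates are mapped, primary, non-supplementary, and at or above the
mapping-quality threshold (the same contract as a samtools ``-F 0x904``
exclusion plus a MAPQ cut).  Counts accumulate between whole contigs; the
map then drops contigs shorter than ``min_len`` and, iteratively, contigs
with fewer than ``min_signal`` non-self observations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam
import scipy.sparse as sp

from hicbin.contigs import ContigRecord

logger = logging.getLogger(__name__)

_FLAG_EXCLUDE = 0x904  # unmapped | secondary | supplementary


@dataclass(frozen=True)
class PairObservation:
    """One usable Hi-C read pair: the two contigs hit and where."""

    contig_a: str
    contig_b: str
    mapq_a: int = 60
    mapq_b: int = 60
    pos_a: int = 0
    pos_b: int = 0


@dataclass
class PairStats:
    """Accounting for the streaming filter, so pair conservation can be audited."""

    pairs_total: int = 0
    pairs_filtered: int = 0  # failed flags, pairing, or MAPQ
    pairs_yielded: int = 0


@dataclass
class MapStats:
    """Accounting for contact-map construction."""

    pairs_in: int = 0
    pairs_filtered_dup: int = 0
    pairs_length_excluded: int = 0
    pairs_signal_excluded: int = 0
    pairs_retained: int = 0
    contigs_in: int = 0
    contigs_length_excluded: int = 0
    contigs_signal_excluded: int = 0
    contigs_retained: int = 0


@dataclass
class ContactMap:
    """Sparse symmetric whole-contig raw contact counts ``c_ij`` over accepted contigs.

    The diagonal holds self-pair counts ``c_ii`` (both mates on one contig);
    these are kept but never count towards the non-self signal criterion.
    """

    contigs: list[ContigRecord]
    counts: sp.csr_matrix
    min_len: int
    min_mapq: int
    min_signal: int
    stats: MapStats = field(default_factory=MapStats)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.contigs]

    def save(self, outdir: str | Path) -> None:
        """Persist as a portable archive: contig table TSV + sparse triplet TSV + params."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        enzymes = sorted({e for c in self.contigs for e in c.sites})
        with open(outdir / "contigs.tsv", "w") as fh:
            cols = ["id", "length", "gc", "depth"] + [f"sites_{e}" for e in enzymes]
            fh.write("\t".join(cols) + "\n")
            for c in self.contigs:
                row = [c.id, str(c.length), f"{c.gc:.6f}", "" if c.depth is None else repr(c.depth)]
                row += [str(c.sites.get(e, 0)) for e in enzymes]
                fh.write("\t".join(row) + "\n")
        coo = sp.triu(self.counts).tocoo()
        with open(outdir / "contacts.tsv", "w") as fh:
            fh.write("i\tj\tcount\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i}\t{j}\t{int(v)}\n")
        with open(outdir / "params.json", "w") as fh:
            json.dump(
                {
                    "min_len": self.min_len,
                    "min_mapq": self.min_mapq,
                    "min_signal": self.min_signal,
                    "enzymes": enzymes,
                    "stats": self.stats.__dict__,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, indir: str | Path) -> "ContactMap":
        indir = Path(indir)
        with open(indir / "params.json") as fh:
            params = json.load(fh)
        contigs: list[ContigRecord] = []
        with open(indir / "contigs.tsv") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            site_cols = [(k, h[len("sites_") :]) for k, h in enumerate(header) if h.startswith("sites_")]
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                contigs.append(
                    ContigRecord(
                        id=parts[0],
                        length=int(parts[1]),
                        gc=float(parts[2]),
                        depth=float(parts[3]) if parts[3] else None,
                        sites={name: int(parts[k]) for k, name in site_cols},
                    )
                )
        n = len(contigs)
        ii, jj, vv = [], [], []
        with open(indir / "contacts.tsv") as fh:
            fh.readline()
            for line in fh:
                i, j, v = line.split("\t")
                ii.append(int(i))
                jj.append(int(j))
                vv.append(int(v))
        upper = sp.coo_matrix((vv, (ii, jj)), shape=(n, n))
        counts = (upper + sp.triu(upper, k=1).T).tocsr()
        stats = MapStats(**params.get("stats", {}))
        return cls(
            contigs=contigs,
            counts=counts,
            min_len=params["min_len"],
            min_mapq=params["min_mapq"],
            min_signal=params["min_signal"],
            stats=stats,
        )


def _usable(aln: pysam.AlignedSegment, min_mapq: int) -> bool:
    return (aln.flag & _FLAG_EXCLUDE) == 0 and aln.mapping_quality >= min_mapq


def stream_pairs(
    bam: str | Path,
    min_mapq: int = 60,
    stats: PairStats | None = None,
) -> Iterator[PairObservation]:
    """Yield usable Hi-C pairs from a name-sorted (or name-grouped) BAM/SAM.

    Mates are matched by adjacency of query names, which requires name
    grouping; a coordinate-sorted header raises with an instruction to
    name-sort.  A pair is yielded only when exactly two primary, mapped,
    non-supplementary mates are present and both reach ``min_mapq``.
    """
    if stats is None:
        stats = PairStats()
    with pysam.AlignmentFile(str(bam), check_sq=False) as fh:
        so = (fh.header.get("HD") or {}).get("SO")
        if so == "coordinate":
            raise ValueError(
                f"{bam} is coordinate-sorted; mates cannot be paired in one pass. "
                "Name-sort it first (samtools sort -n)."
            )
        group: list[pysam.AlignedSegment] = []
        name: str | None = None

        def flush(group: list[pysam.AlignedSegment]) -> PairObservation | None:
            stats.pairs_total += 1
            usable = [a for a in group if _usable(a, min_mapq)]
            # keep at most one record per mate (primary records only survive 0x904)
            if len(usable) != 2:
                stats.pairs_filtered += 1
                return None
            a, b = usable
            stats.pairs_yielded += 1
            return PairObservation(
                contig_a=a.reference_name,
                contig_b=b.reference_name,
                mapq_a=a.mapping_quality,
                mapq_b=b.mapping_quality,
                pos_a=a.reference_start,
                pos_b=b.reference_start,
            )

        for aln in fh.fetch(until_eof=True):
            if aln.query_name != name:
                if group:
                    obs = flush(group)
                    if obs is not None:
                        yield obs
                group = []
                name = aln.query_name
            group.append(aln)
        if group:
            obs = flush(group)
            if obs is not None:
                yield obs


def build_contact_map(
    pairs: Iterable[PairObservation],
    table: list[ContigRecord],
    min_len: int = 1000,
    min_signal: int = 5,
    min_mapq: int = 60,
    dedup: bool = False,
) -> ContactMap:
    """Accumulate the whole-contig contact map and apply the acceptance filters.

    Phase 1 accumulates ``c_ij`` over pairs whose two contigs both have
    length >= ``min_len`` (self pairs go to the diagonal).  Phase 2
    iteratively removes contigs whose non-self signal is below
    ``min_signal``, re-checking after each sweep until a fixed point, since
    removing one contig can drop a neighbour below threshold.

    ``dedup`` drops coordinate-identical duplicate pairs (off by default:
    duplicates are counted as independent observations).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if min_signal < 0:
        raise ValueError("min_signal must be >= 0")
    index = {c.id: k for k, c in enumerate(table)}
    if len(index) != len(table):
        raise ValueError("duplicate contig IDs in table")
    long_enough = np.array([c.length >= min_len for c in table], dtype=bool)

    stats = MapStats(contigs_in=len(table))
    acc: dict[tuple[int, int], int] = {}
    seen: set[tuple[int, int, int, int]] = set()
    for p in pairs:
        stats.pairs_in += 1
        try:
            i, j = index[p.contig_a], index[p.contig_b]
        except KeyError as exc:
            raise KeyError(f"pair references unknown contig id {exc.args[0]!r}") from None
        if dedup:
            coord = (i, p.pos_a, j, p.pos_b) if (i, p.pos_a) <= (j, p.pos_b) else (j, p.pos_b, i, p.pos_a)
            if coord in seen:
                stats.pairs_filtered_dup += 1
                continue
            seen.add(coord)
        if not (long_enough[i] and long_enough[j]):
            stats.pairs_length_excluded += 1
            continue
        key = (i, j) if i <= j else (j, i)
        acc[key] = acc.get(key, 0) + 1

    keep_len = np.flatnonzero(long_enough)
    stats.contigs_length_excluded = len(table) - len(keep_len)
    remap = -np.ones(len(table), dtype=np.int64)
    remap[keep_len] = np.arange(len(keep_len))
    n = len(keep_len)
    if acc:
        keys = np.array(list(acc.keys()), dtype=np.int64)
        vals = np.array(list(acc.values()), dtype=np.int64)
        ii, jj = remap[keys[:, 0]], remap[keys[:, 1]]
        upper = sp.coo_matrix((vals, (ii, jj)), shape=(n, n)).tocsr()
    else:
        upper = sp.csr_matrix((n, n), dtype=np.int64)
    full = upper + sp.triu(upper, k=1).T
    pairs_after_len = int(upper.sum())

    # phase 2: iterate the non-self signal criterion to a fixed point
    mask = np.ones(n, dtype=bool)
    while True:
        sub = full[mask][:, mask]
        nonself = np.asarray(sub.sum(axis=1)).ravel() - sub.diagonal()
        weak = nonself < min_signal
        if not weak.any():
            break
        idx = np.flatnonzero(mask)
        mask[idx[weak]] = False
        if not mask.any():
            break

    final = full[mask][:, mask].tocsr()
    final.eliminate_zeros()
    stats.pairs_retained = int(sp.triu(final).sum())
    stats.pairs_signal_excluded = pairs_after_len - stats.pairs_retained
    kept_orig = keep_len[np.flatnonzero(mask)]
    stats.contigs_retained = len(kept_orig)
    stats.contigs_signal_excluded = n - stats.contigs_retained
    for k, c in enumerate(table):
        c.accepted = False
    contigs = []
    for k in kept_orig:
        table[k].accepted = True
        contigs.append(table[k])
    logger.info(
        "contact map: %d/%d contigs retained (%d short, %d weak signal); "
        "%d/%d pairs retained",
        stats.contigs_retained,
        stats.contigs_in,
        stats.contigs_length_excluded,
        stats.contigs_signal_excluded,
        stats.pairs_retained,
        stats.pairs_in,
    )
    return ContactMap(
        contigs=contigs,
        counts=final,
        min_len=min_len,
        min_mapq=min_mapq,
        min_signal=min_signal,
        stats=stats,
    )
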