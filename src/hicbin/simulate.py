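"""Synthetic community and Hi-C pair generation for desk-scale pipeline tests.

The generator emulates the study conditions the pipeline targets: a
multi-genome community with a long-tailed generalized-Pareto abundance
profile and a wide GC range; restriction-site-conditioned Hi-C pairs in
which intra-genome (intra-cellular) contacts dominate inter-genome noise
by roughly an order of magnitude; and a fragmented "assembly" of the
genomes into contigs with known contig -> genome truth.  Pairs can be
emitted as an idealized name-grouped SAM so the real ingestion path is
exercised end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.stats import genpareto

from hicbin.contigs import DEFAULT_ENZYMES, EnzymeSpec, site_positions, write_fasta
from hicbin.validate import SoftTruth

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    The abundance profile is a generalized Pareto draw; the default shape
    (xi = -2, scale 31) yields the long-tailed, roughly 50:1
    most-to-least spread characteristic of gut-community profiles.
    ``noise_frac`` is the probability a pair is inter-cellular noise
    (default 0.1: intra-cell contacts an order of magnitude more frequent).
    ``decay_mean`` is the mean genomic separation of proximity contacts;
    ``bg_frac`` is the fraction of intra-genome pairs drawn uniformly
    across the genome, emulating the cell-wide crosslinking background
    that makes a whole genome one flow module.
    """

    n_genomes: int = 10
    genome_len: tuple[int, int] = (500_000, 1_000_000)
    gc: tuple[float, float] = (0.3, 0.7)
    gpd_shape: float = -2.0
    gpd_scale: float = 31.0
    gpd_location: float = 0.0
    enzymes: tuple[EnzymeSpec, ...] = tuple(EnzymeSpec(n, s) for n, s in DEFAULT_ENZYMES.items())
    n_pairs: int = 200_000
    noise_frac: float = 0.1
    decay_mean: float = 20_000.0
    bg_frac: float = 0.5
    frag_mean: int = 10_000
    seed: int = 9878132

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not 0 <= self.noise_frac <= 1:
            raise ValueError("noise_frac must be in [0, 1]")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.genome_len[0] > self.genome_len[1] or self.genome_len[0] < 1:
            raise ValueError("invalid genome_len range")
        if not 0 < self.gc[0] <= self.gc[1] < 1:
            raise ValueError("invalid gc range")


@dataclass
class SyntheticCommunity:
    """Genomes (circular), their abundances, and the fragmented contig truth."""

    genomes: dict[str, str]
    abundance: dict[str, float]
    contig_seqs: dict[str, str]
    contig_genome: dict[str, str]
    breakpoints: dict[str, np.ndarray]  # per genome: contig start offsets (sorted, starts at 0)
    contig_ids: dict[str, list[str]]  # per genome: contig ids in genomic order
    truth: SoftTruth = field(default=None)  # type: ignore[assignment]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(sorted(self.contig_seqs.items()), outdir / "contigs.fasta")
        write_fasta(sorted(self.genomes.items()), outdir / "genomes.fasta")
        self.truth.save(outdir / "truth.tsv")
        with open(outdir / "abundance.tsv", "w") as fh:
            for g in sorted(self.abundance):
                fh.write(f"{g}\t{self.abundance[g]:.6g}\n")


def sample_abundances(
    n: int,
    shape: float = -2.0,
    scale: float = 31.0,
    location: float = 0.0,
    seed: int | np.random.Generator | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Draw ``n`` i.i.d. generalized-Pareto relative abundances.

    ``shape`` is the standard xi parameter (negative = bounded tail).
    ``normalize`` rescales the draw to sum to 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = genpareto.rvs(shape, loc=location, scale=scale, size=n, random_state=rng)
    draws = np.maximum(draws, np.finfo(float).tiny)
    if normalize:
        draws = draws / draws.sum()
    return draws


def generate_genome(length: int, gc: float, seed: int | np.random.Generator | None = None) -> str:
    """I.i.d. circular genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def expected_site_spacing(gc: float, site: str) -> float:
    """Expected spacing (bp) between recognition-site starts in i.i.d. sequence.

    Returns ``1/p`` with ``p`` the product over site bases of ``gc/2`` for
    G/C and ``(1-gc)/2`` for A/T.  At GC 0.5 any four-cutter gives the
    naive 1-in-256 bp.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    site = site.upper()
    if set(site) - set("ACGT"):
        raise ValueError(f"ambiguous bases in site {site!r}")
    p = 1.0
    for base in site:
        p *= gc / 2 if base in "GC" else (1 - gc) / 2
    return 1.0 / p


def fragment_genome(
    length: int, frag_mean: int, rng: np.random.Generator, min_len: int = 500
) -> np.ndarray:
    """Start offsets (first always 0) of the fragments of one circular genome.

    The genome is cut at ``k-1`` uniform internal breakpoints with
    ``k = max(1, round(length/frag_mean))``; fragments shorter than
    ``min_len`` are merged into their right neighbour.  Fragment lengths
    always sum to ``length`` exactly.
    """
    if frag_mean < 1000:
        raise ValueError("frag_mean must be >= 1000")
    k = max(1, int(np.floor(length / frag_mean + 0.5)))
    internal = np.sort(rng.choice(np.arange(1, length), size=min(k - 1, length - 1), replace=False))
    bps = np.concatenate([[0], internal])
    while len(bps) > 1:
        seg_len = np.diff(np.append(bps, length))
        short = np.flatnonzero(seg_len < min_len)
        if not len(short):
            break
        # merge the first short fragment into its right neighbour
        drop = short[0] + 1 if short[0] + 1 < len(bps) else short[0]
        bps = np.delete(bps, drop)
    return bps


def fragment_genomes(
    genomes: dict[str, str], frag_mean: int, seed: int | np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, str], dict[str, np.ndarray], dict[str, list[str]], SoftTruth]:
    """Fragment every circular genome into truth-labelled contigs.

    Returns contig sequences, contig -> genome labels, per-genome start
    offsets, per-genome ordered contig ids, and the hard :class:`SoftTruth`
    (weight = contig length).  Concatenating a genome's contigs reproduces
    the genome exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    contig_seqs: dict[str, str] = {}
    contig_genome: dict[str, str] = {}
    breakpoints: dict[str, np.ndarray] = {}
    contig_ids: dict[str, list[str]] = {}
    for gid in sorted(genomes):
        seq = genomes[gid]
        bps = fragment_genome(len(seq), frag_mean, rng)
        ends = np.append(bps[1:], len(seq))
        ids = []
        for k, (s, e) in enumerate(zip(bps, ends), start=1):
            cid = f"{gid}.c{k:04d}"
            contig_seqs[cid] = seq[s:e]
            contig_genome[cid] = gid
            ids.append(cid)
        breakpoints[gid] = bps
        contig_ids[gid] = ids
    truth = SoftTruth(
        labels={c: frozenset([g]) for c, g in contig_genome.items()},
        weight={c: float(len(s)) for c, s in contig_seqs.items()},
    )
    return contig_seqs, contig_genome, breakpoints, contig_ids, truth


def generate_community(cfg: SimulationConfig) -> SyntheticCommunity:
    """Generate genomes, abundances and the fragmented contig set.

    All randomness flows from ``cfg.seed`` through a spawned seed sequence
    (one child stream per stage), so communities are reproducible.  GC
    contents are evenly spaced across the configured range so every draw
    covers the extremes.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_len, rng_gen, rng_frag, rng_ab = (np.random.default_rng(s) for s in children)
    gcs = (
        np.linspace(cfg.gc[0], cfg.gc[1], cfg.n_genomes)
        if cfg.n_genomes > 1
        else np.array([np.mean(cfg.gc)])
    )
    lengths = rng_len.integers(cfg.genome_len[0], cfg.genome_len[1] + 1, size=cfg.n_genomes)
    genomes = {
        f"g{k:02d}": generate_genome(int(lengths[k]), float(gcs[k]), rng_gen)
        for k in range(cfg.n_genomes)
    }
    ab = sample_abundances(
        cfg.n_genomes, cfg.gpd_shape, cfg.gpd_scale, cfg.gpd_location, seed=rng_ab, normalize=True
    )
    abundance = {gid: float(ab[k]) for k, gid in enumerate(sorted(genomes))}
    contig_seqs, contig_genome, breakpoints, contig_ids, truth = fragment_genomes(
        genomes, cfg.frag_mean, rng_frag
    )
    logger.info(
        "community: %d genomes (%d-%d bp), %d contigs, abundance spread %.1f:1",
        cfg.n_genomes,
        lengths.min(),
        lengths.max(),
        len(contig_seqs),
        ab.max() / ab.min(),
    )
    return SyntheticCommunity(
        genomes=genomes,
        abundance=abundance,
        contig_seqs=contig_seqs,
        contig_genome=contig_genome,
        breakpoints=breakpoints,
        contig_ids=contig_ids,
        truth=truth,
    )


def _snap_to_sites(targets: np.ndarray, sites: np.ndarray, length: int) -> np.ndarray:
    """Nearest cut site to each target position, with circular wrap-around."""
    idx = np.searchsorted(sites, targets % length)
    right = sites[idx % len(sites)]
    left = sites[(idx - 1) % len(sites)]
    d_right = (right - targets) % length
    d_left = (targets - left) % length
    return np.where(d_right <= d_left, right, left)


def simulate_hic_pairs(
    comm: SyntheticCommunity, cfg: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw restriction-site-conditioned Hi-C pairs over the community.

    Each pair picks a genome in proportion to abundance.  With probability
    ``1 - noise_frac`` the pair is intra-genome: one end uniform over the
    genome's pooled cut sites and the partner at a circular exponential
    separation (mean ``decay_mean``) snapped to the nearest cut site, or —
    with probability ``bg_frac`` within the intra draw — uniform over the
    genome's sites (cell-wide background).  With probability ``noise_frac``
    the partner is a uniform cut site of a second, abundance-weighted
    genome (inter-cellular noise).  Genomes without any cut site are
    skipped with a warning.

    Returns a frame (contig_a, pos_a, contig_b, pos_b, genome_a, genome_b)
    with positions 0-based on the fragmented contigs.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    gids = sorted(comm.genomes)
    sites = {}
    for gid in gids:
        pos = [site_positions(comm.genomes[gid], e.site) for e in cfg.enzymes]
        pooled = np.unique(np.concatenate(pos)) if pos else np.array([], dtype=np.int64)
        if len(pooled) == 0:
            logger.warning("genome %s has no cut sites for any enzyme; skipped", gid)
            continue
        sites[gid] = pooled
    active = [g for g in gids if g in sites]
    if not active:
        raise ValueError("no genome has a cut site; cannot simulate pairs")
    ab = np.array([comm.abundance[g] for g in active])
    ab = ab / ab.sum()
    if cfg.n_pairs == 0:
        return pd.DataFrame(
            columns=["contig_a", "pos_a", "contig_b", "pos_b", "genome_a", "genome_b"]
        )

    g_a = rng.choice(len(active), size=cfg.n_pairs, p=ab)
    is_noise = rng.random(cfg.n_pairs) < cfg.noise_frac
    g_b = np.where(is_noise, rng.choice(len(active), size=cfg.n_pairs, p=ab), g_a)
    is_bg = ~is_noise & (rng.random(cfg.n_pairs) < cfg.bg_frac)

    pos_a = np.empty(cfg.n_pairs, dtype=np.int64)
    pos_b = np.empty(cfg.n_pairs, dtype=np.int64)
    for k, gid in enumerate(active):
        st = sites[gid]
        L = len(comm.genomes[gid])
        sel_a = np.flatnonzero(g_a == k)
        pos_a[sel_a] = st[rng.integers(0, len(st), size=len(sel_a))]
        # proximity partners: exponential separation around the first site
        sel_prox = sel_a[~is_noise[sel_a] & ~is_bg[sel_a]]
        if len(sel_prox):
            d = rng.exponential(cfg.decay_mean, size=len(sel_prox))
            sign = rng.choice([-1, 1], size=len(sel_prox))
            pos_b[sel_prox] = _snap_to_sites(pos_a[sel_prox] + sign * d.astype(np.int64), st, L)
        # background partners: uniform site in the same genome
        sel_bg = sel_a[is_bg[sel_a]]
        if len(sel_bg):
            pos_b[sel_bg] = st[rng.integers(0, len(st), size=len(sel_bg))]
        # noise partners landing in this genome: uniform site
        sel_b = np.flatnonzero(is_noise & (g_b == k))
        if len(sel_b):
            pos_b[sel_b] = st[rng.integers(0, len(st), size=len(sel_b))]

    rows = {
        "contig_a": np.empty(cfg.n_pairs, dtype=object),
        "pos_a": np.empty(cfg.n_pairs, dtype=np.int64),
        "contig_b": np.empty(cfg.n_pairs, dtype=object),
        "pos_b": np.empty(cfg.n_pairs, dtype=np.int64),
        "genome_a": np.array([active[k] for k in g_a], dtype=object),
        "genome_b": np.array([active[k] for k in g_b], dtype=object),
    }
    for side, gvec, pvec in (("a", g_a, pos_a), ("b", g_b, pos_b)):
        for k, gid in enumerate(active):
            sel = np.flatnonzero(gvec == k)
            if not len(sel):
                continue
            bps = comm.breakpoints[gid]
            cidx = np.searchsorted(bps, pvec[sel], side="right") - 1
            ids = comm.contig_ids[gid]
            rows[f"contig_{side}"][sel] = [ids[c] for c in cidx]
            rows[f"pos_{side}"][sel] = pvec[sel] - bps[cidx]
    return pd.DataFrame(rows)


def write_pairs_sam(pairs: pd.DataFrame, contig_seqs: dict[str, str], path: str | Path) -> None:
    """Emit pairs as an idealized name-grouped SAM (primary, mapped, MAPQ 60).

    Alignments are error-free 75 bp (clipped at contig ends); sequences are
    omitted, which keeps the file a pure alignment-coordinate fixture.
    """
    names = sorted(contig_seqs)
    lengths = {c: len(contig_seqs[c]) for c in names}
    tid = {c: k for k, c in enumerate(names)}
    header = {
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": c, "LN": lengths[c]} for c in names],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for k, row in enumerate(pairs.itertuples(index=False)):
            qname = f"SIM{k:09d}"
            for mate_flag, contig, pos, ocontig, opos in (
                (0x1 | 0x40, row.contig_a, row.pos_a, row.contig_b, row.pos_b),
                (0x1 | 0x80, row.contig_b, row.pos_b, row.contig_a, row.pos_a),
            ):
                aln = pysam.AlignedSegment(fh.header)
                aln.query_name = qname
                aln.flag = mate_flag
                aln.reference_id = tid[contig]
                read_len = min(75, lengths[contig] - int(pos))
                aln.reference_start = int(pos)
                aln.mapping_quality = 60
                aln.cigarstring = f"{max(read_len, 1)}M"
                aln.next_reference_id = tid[ocontig]
                aln.next_reference_start = int(opos)
                fh.write(aln)


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> SyntheticCommunity:
    """Full fixture: community files, pair table and SAM under ``outdir``."""
    outdir = Path(outdir)
    comm = generate_community(cfg)
    comm.write(outdir)
    pairs = simulate_hic_pairs(comm, cfg)
    pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    write_pairs_sam(pairs, comm.contig_seqs, outdir / "pairs.sam")
    return comm
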