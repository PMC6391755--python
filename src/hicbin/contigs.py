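"""Per-contig metadata from assembly FASTA: lengths, GC, restriction-site counts.

Restriction-site counts (``n_i``) feed the first stage of contact-map bias
removal; GC and depth feed the per-bin report.  A helper uniformly splits
long contigs into near-equal pieces, which limits the damage a chimeric
misassembly can do to downstream binning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

_UNAMBIGUOUS = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The two four-cutter enzymes used by default (NEB names).  Sau3AI cuts the
#: GC-balanced site GATC; MluCI cuts the AT-rich site AATT.
DEFAULT_ENZYMES = {"Sau3AI": "GATC", "MluCI": "AATT"}

_SPADES_COV = re.compile(r"(?:^|_)cov_([0-9]+(?:\.[0-9]+)?)")


def revcomp(seq: str) -> str:
    """Reverse complement of an unambiguous uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: a name and its unambiguous recognition sequence."""

    name: str
    site: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", self.site.upper())
        if len(self.site) < 1:
            raise ValueError("recognition site must be non-empty")
        bad = set(self.site) - _UNAMBIGUOUS
        if bad:
            raise ValueError(f"ambiguous bases in recognition site {self.site!r}: {sorted(bad)}")

    @classmethod
    def from_string(cls, text: str) -> "EnzymeSpec":
        """Build from an enzyme name (``Sau3AI``/``MluCI``), a raw recognition
        sequence (``GATC``), or an explicit ``Name=SEQ`` pair."""
        if "=" in text:
            name, site = text.split("=", 1)
            return cls(name, site)
        for name, site in DEFAULT_ENZYMES.items():
            if text.lower() == name.lower():
                return cls(name, site)
        return cls(text.upper(), text)


@dataclass
class ContigRecord:
    """Metadata for one assembly contig.

    ``sites`` maps enzyme name to the tally of recognition-site occurrences
    (the :math:`n_i` of the site-product normalization).  ``gc`` is computed
    over unambiguous bases only and is 0.0 for all-N sequences.  ``depth``
    is the mean shotgun coverage when known (SPAdes-style ``cov_`` header
    token, or an external depth table), never inferred from Hi-C.
    """

    id: str
    length: int
    gc: float
    sites: dict[str, int] = field(default_factory=dict)
    depth: float | None = None
    accepted: bool = True

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id}: length must be >= 1")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"contig {self.id}: gc must be in [0, 1]")
        if any(v < 0 for v in self.sites.values()):
            raise ValueError(f"contig {self.id}: negative site count")

    def total_sites(self, enzymes: Sequence[str] | None = None) -> int:
        """Summed site count over the named enzymes (all tallied enzymes when None)."""
        if enzymes is None:
            return sum(self.sites.values())
        return sum(self.sites[e] for e in enzymes)


def _count_overlapping(seq: str, pat: str) -> int:
    n = 0
    i = seq.find(pat)
    while i != -1:
        n += 1
        i = seq.find(pat, i + 1)
    return n


def count_sites(seq: str, site: str) -> int:
    """Count occurrences of ``site`` or its reverse complement in ``seq``.

    Occurrences are counted at distinct start positions and may overlap.
    For palindromic sites (GATC, AATT) this equals the plain forward count.
    Ambiguous bases in ``seq`` (N) never match; ambiguous bases in ``site``
    raise ``ValueError``.
    """
    if not seq or not site:
        raise ValueError("seq and site must be non-empty")
    site = site.upper()
    if set(site) - _UNAMBIGUOUS:
        raise ValueError(f"ambiguous bases in site {site!r}")
    seq = seq.upper()
    rc = revcomp(site)
    n = _count_overlapping(seq, site)
    if rc != site:
        # distinct patterns of equal length can never share a start position
        n += _count_overlapping(seq, rc)
    return n


def site_positions(seq: str, site: str) -> np.ndarray:
    """Sorted start positions of ``site`` or its reverse complement in ``seq``."""
    site = site.upper()
    if set(site) - _UNAMBIGUOUS:
        raise ValueError(f"ambiguous bases in site {site!r}")
    seq = seq.upper()
    pats = {site, revcomp(site)}
    pos: list[int] = []
    for pat in pats:
        pos.extend(m.start() for m in re.finditer(f"(?={re.escape(pat)})", seq))
    return np.unique(np.asarray(pos, dtype=np.int64))


def _gc_fraction(seq: str) -> float:
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    return gc / denom if denom else 0.0


def parse_depth(header: str) -> float | None:
    """Mean coverage from a SPAdes-style header token ``cov_<float>``, else None."""
    m = _SPADES_COV.search(header)
    return float(m.group(1)) if m else None


def scan_contigs(
    fasta: str | Path,
    enzymes: Sequence[EnzymeSpec],
    depth_table: Mapping[str, float] | None = None,
) -> list[ContigRecord]:
    """Scan an assembly FASTA into one :class:`ContigRecord` per sequence.

    Duplicate sequence IDs raise ``ValueError``.  Depths come from the
    header when present, else from ``depth_table`` when supplied.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence ID in {fasta}: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        depth = parse_depth(rec.description)
        if depth is None and depth_table is not None:
            depth = depth_table.get(rec.id)
        records.append(
            ContigRecord(
                id=rec.id,
                length=len(seq),
                gc=_gc_fraction(seq),
                sites={e.name: count_sites(seq, e.site) for e in enzymes},
                depth=depth,
            )
        )
    return records


def read_depth_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV (contig id, mean depth) to a dict."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, value = line.split("\t")[:2]
            out[name] = float(value)
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write (id, sequence) pairs as FASTA with ``width``-column wrapping."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def split_sequence(seq: str, target_len: int) -> list[str]:
    """Split ``seq`` into ``max(1, round(len/target))`` near-equal pieces.

    Piece lengths differ by at most 1 bp and concatenate back to ``seq``.
    """
    if target_len <= 0:
        raise ValueError("target_len must be >= 1")
    L = len(seq)
    k = max(1, int(np.floor(L / target_len + 0.5)))
    base, rem = divmod(L, k)
    pieces = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        pieces.append(seq[start : start + size])
        start += size
    return pieces


def split_contigs(fasta: str | Path, target_len: int, out_fasta: str | Path) -> int:
    """Uniformly split every sequence of a FASTA into near-equal pieces.

    Piece IDs are suffixed ``.<index>`` (1-based).  Returns the number of
    pieces written.
    """

    def gen() -> Iterator[tuple[str, str]]:
        for rec in SeqIO.parse(str(fasta), "fasta"):
            for i, piece in enumerate(split_sequence(str(rec.seq), target_len), start=1):
                yield f"{rec.id}.{i}", piece

    n = 0
    with open(out_fasta, "w") as fh:
        for name, seq in gen():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
            n += 1
    return n
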