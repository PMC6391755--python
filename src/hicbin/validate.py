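"""Ground-truth construction and extrinsic scoring of genome-binning solutions.

Truth comes from contig-vs-reference alignments: a reference becomes a
source label for a contig when the union of its alignments covers at least
``min_cov_frac`` of the contig.  Assignments are kept soft (a contig may
belong to several sources where genomes co-assemble), with contig length as
the item weight.  Scoring offers adjusted mutual information (a hard
measure — multi-source items are resolved by a seeded coin toss) and the
extended, length-weighted B-cubed precision/recall/F, which handles
overlapping truth directly.  MAG quality-rank classifiers convert
externally supplied completeness/contamination estimates into the two
community reporting standards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score

from hicbin.contigs import ContigRecord


@dataclass
class SoftTruth:
    """Overlapping contig -> source assignment with per-item weights.

    ``labels[c]`` is the non-empty set of source genomes for contig ``c``;
    ``weight[c]`` is its value in weighted metrics (contig length in bp).
    """

    labels: dict[str, frozenset[str]]
    weight: dict[str, float]
    covered_fraction: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        for c, labs in self.labels.items():
            if not labs:
                raise ValueError(f"item {c} has no source label")
            if self.weight.get(c, 0) <= 0:
                raise ValueError(f"item {c} has non-positive weight")

    @property
    def items(self) -> list[str]:
        return list(self.labels)

    def harden(self, seed: int = 0) -> dict[str, str]:
        """One label per item; multi-source items resolved by a seeded uniform draw."""
        rng = np.random.default_rng(seed)
        out = {}
        for c in sorted(self.labels):
            labs = sorted(self.labels[c])
            out[c] = labs[0] if len(labs) == 1 else labs[rng.integers(len(labs))]
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig_id\tsource_id\tweight\tcovered_fraction\n")
            for c in sorted(self.labels):
                for s in sorted(self.labels[c]):
                    cov = (self.covered_fraction or {}).get(c, {}).get(s, 1.0)
                    fh.write(f"{c}\t{s}\t{self.weight[c]:g}\t{cov:.4f}\n")

    @classmethod
    def load(cls, path: str | Path) -> "SoftTruth":
        labels: dict[str, set[str]] = {}
        weight: dict[str, float] = {}
        cov: dict[str, dict[str, float]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("contig_id"):
                raise ValueError(f"{path} is not a truth TSV")
            for line in fh:
                c, s, w, f = line.rstrip("\n").split("\t")
                labels.setdefault(c, set()).add(s)
                weight[c] = float(w)
                cov.setdefault(c, {})[s] = float(f)
        return cls(
            labels={c: frozenset(v) for c, v in labels.items()},
            weight=weight,
            covered_fraction=cov,
        )


def read_alignments(path: str | Path, dialect: str = "tabular") -> pd.DataFrame:
    """Read contig-vs-reference alignments into (query, reference, qstart, qend, identity).

    Dialects: ``tabular`` (those five columns, 0-based half-open),
    ``blast6`` (BLAST/LAST outfmt-6 style: qseqid sseqid pident length
    mismatch gapopen qstart qend ... with 1-based inclusive query coords),
    and ``maf`` (alignment blocks; the second ``s`` line of each block is
    taken as the query).
    """
    if dialect == "tabular":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            names=["query", "reference", "qstart", "qend", "identity"],
        )
    elif dialect == "blast6":
        raw = pd.read_csv(path, sep="\t", comment="#", header=None)
        df = pd.DataFrame(
            {
                "query": raw[0],
                "reference": raw[1],
                "qstart": raw[6] - 1,
                "qend": raw[7],
                "identity": raw[2] / 100.0,
            }
        )
    elif dialect == "maf":
        rows = []
        block: list[list[str]] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("a"):
                    block = []
                elif line.startswith("s"):
                    block.append(line.split())
                    if len(block) == 2:
                        ref, qry = block
                        start, size = int(qry[2]), int(qry[3])
                        if qry[4] == "-":  # MAF stores minus-strand coords from the end
                            start = int(qry[5]) - start - size
                        rows.append((qry[1], ref[1], start, start + size, np.nan))
        df = pd.DataFrame(rows, columns=["query", "reference", "qstart", "qend", "identity"])
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    return df


def _union_length(intervals: np.ndarray) -> int:
    order = np.argsort(intervals[:, 0])
    total = 0
    cur_s, cur_e = intervals[order[0]]
    for s, e in intervals[order[1:]]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return int(total + cur_e - cur_s)


def truth_from_alignments(
    aln: pd.DataFrame,
    table: Sequence[ContigRecord],
    min_cov_frac: float = 0.5,
) -> tuple[SoftTruth, list[str]]:
    """Soft truth from alignments: label = reference covering >= ``min_cov_frac``.

    Coverage is the union of the query's aligned intervals on each
    reference divided by contig length.  Returns the truth plus the list
    of contigs with no qualifying reference (excluded from scoring).
    """
    lengths = {r.id: r.length for r in table}
    unknown = set(aln["query"]) - set(lengths)
    if unknown:
        raise KeyError(f"alignment queries absent from contig table: {sorted(unknown)[:5]}")
    if (aln["qend"] <= aln["qstart"]).any():
        raise ValueError("malformed alignment interval: qend <= qstart")
    labels: dict[str, set[str]] = {}
    cov_frac: dict[str, dict[str, float]] = {}
    for (query, reference), grp in aln.groupby(["query", "reference"], sort=False):
        covered = _union_length(grp[["qstart", "qend"]].to_numpy())
        frac = covered / lengths[query]
        if frac >= min_cov_frac:
            labels.setdefault(query, set()).add(reference)
            cov_frac.setdefault(query, {})[reference] = frac
    excluded = sorted(set(aln["query"]) - set(labels))
    truth = SoftTruth(
        labels={c: frozenset(v) for c, v in labels.items()},
        weight={c: float(lengths[c]) for c in labels},
        covered_fraction=cov_frac,
    )
    return truth, excluded


def ami(
    truth: Mapping[str, object] | Sequence[object],
    pred: Mapping[str, object] | Sequence[object],
    average_method: str = "max",
) -> float:
    """Adjusted mutual information between two hard labellings.

    ``AMI = (MI - E[MI]) / (norm(H_t, H_p) - E[MI])`` with the expectation
    under the permutation model.  The normalizer defaults to
    ``max(H_t, H_p)``, reproducing the historical scikit-learn behaviour
    this metric is calibrated against; other normalizers can be selected
    via ``average_method``.  Mappings are aligned on their shared keys.
    """
    if isinstance(truth, Mapping) and isinstance(pred, Mapping):
        keys = sorted(set(truth) & set(pred))
        if not keys:
            raise ValueError("truth and pred share no items")
        t = [truth[k] for k in keys]
        p = [pred[k] for k in keys]
    else:
        t, p = list(truth), list(pred)
        if len(t) != len(p):
            raise ValueError("truth and pred must cover the same items")
    if len(t) == 1:
        return 1.0
    return float(adjusted_mutual_info_score(t, p, average_method=average_method))


@dataclass(frozen=True)
class B3Score:
    precision: float
    recall: float
    f: float


def weighted_b3(
    truth: SoftTruth,
    pred: Mapping[str, int],
    all_truth_items: bool = False,
) -> B3Score:
    """Extended (overlap-aware) B-cubed precision, recall and F, item-weighted.

    For items e, e' let C and T be their predicted-bin and truth-label
    sets.  Pair precision is ``min(|C∩C'|, |T∩T'|) / |C∩C'|`` averaged
    (weights w) over e' sharing a predicted bin with e, the self pair
    included; recall swaps the roles of C and T.  Per-item averages are
    then averaged over items with the same weights.  Predictions here are
    hard (one bin per item), truth may overlap; with unit weights and hard
    truth this reduces to classical B-cubed.

    With ``all_truth_items`` every truth item enters the recall average,
    so unclustered items (dropped by the contact-map filters) count as
    zero-recall mass; otherwise only predicted items are scored.
    """
    if not pred:
        raise ValueError("empty prediction")
    missing = set(pred) - set(truth.labels)
    if missing:
        raise KeyError(f"predicted items absent from truth: {sorted(missing)[:5]}")
    items = sorted(truth.labels) if all_truth_items else sorted(pred)
    w = truth.weight
    labels = truth.labels

    # precision: group by predicted bin
    by_bin: dict[int, list[str]] = {}
    for c in items:
        if c in pred:
            by_bin.setdefault(pred[c], []).append(c)
    prec_num = prec_den = 0.0
    for members in by_bin.values():
        wt = np.array([w[c] for c in members])
        total_w = wt.sum()
        for k, c in enumerate(members):
            # |C∩C'| = 1 within a bin; pair precision = 1 iff truth overlaps
            share = np.array([1.0 if labels[c] & labels[o] else 0.0 for o in members])
            prec_num += w[c] * float(share @ wt) / total_w
            prec_den += w[c]

    # recall: for each item, pairs sharing >= 1 truth label
    by_label: dict[str, list[str]] = {}
    for c in items:
        for lab in labels[c]:
            by_label.setdefault(lab, []).append(c)
    rec_num = rec_den = 0.0
    for c in items:
        shared: dict[str, int] = {}
        for lab in labels[c]:
            for o in by_label[lab]:
                shared[o] = shared.get(o, 0) + 1
        den = num = 0.0
        c_bin = pred.get(c)
        for o, t_olap in shared.items():
            den += w[o]
            if c_bin is not None and pred.get(o) == c_bin:
                num += w[o] * min(1, t_olap) / t_olap
        rec_num += w[c] * num / den
        rec_den += w[c]

    precision = prec_num / prec_den if prec_den else 0.0
    recall = rec_num / rec_den if rec_den else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return B3Score(precision=precision, recall=recall, f=f)


_COMPLETENESS_RANKS = [(90.0, "near"), (70.0, "substantial"), (50.0, "moderate")]
_CONTAMINATION_RANKS = [(5.0, "low"), (10.0, "medium"), (15.0, "high")]


@dataclass(frozen=True)
class QualityRank:
    completeness: float
    contamination: float
    completeness_rank: str  # near / substantial / moderate / partial
    contamination_rank: str  # low / medium / high / very_high
    mimag_rank: str  # high / medium / low

    @property
    def simple_rank(self) -> tuple[str, str]:
        return (self.completeness_rank, self.contamination_rank)


def rank_mag(
    completeness: float, contamination: float, rrna_trna: bool | None = None
) -> QualityRank:
    """Classify a MAG by completeness/contamination under both rank standards.

    The simple standard ranks the two axes independently (completeness:
    near >=90, substantial >=70, moderate >=50, else partial;
    contamination: low <=5, medium <=10, high <=15, else very_high).  The
    MIMAG draft ranks are high (>90 complete, <5 contaminated, rRNA+tRNA
    present), medium (>=50, <10), else low.  ``rrna_trna`` unknown (None)
    caps the MIMAG rank at medium.
    """
    if not 0.0 <= completeness <= 100.0:
        raise ValueError("completeness must be a percentage in [0, 100]")
    if contamination < 0.0:
        raise ValueError("contamination must be >= 0")
    comp_rank = "partial"
    for thresh, name in _COMPLETENESS_RANKS:
        if completeness >= thresh:
            comp_rank = name
            break
    cont_rank = "very_high"
    for thresh, name in _CONTAMINATION_RANKS:
        if contamination <= thresh:
            cont_rank = name
            break
    if completeness > 90.0 and contamination < 5.0 and rrna_trna is True:
        mimag = "high"
    elif completeness >= 50.0 and contamination < 10.0:
        mimag = "medium"
    else:
        mimag = "low"
    return QualityRank(
        completeness=completeness,
        contamination=contamination,
        completeness_rank=comp_rank,
        contamination_rank=cont_rank,
        mimag_rank=mimag,
    )
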