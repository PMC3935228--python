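"""Pairwise substitution counting, Kimura 2-parameter distances and
barcode-gap species delimitation.

The K2P model corrects the observed proportion of differing sites for
multiple hits, treating transitions (A<->G, C<->T) and transversions at
different rates:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

where P and Q are the transition and transversion proportions over the
compared columns.  Columns containing a gap or any ambiguity code in either
sequence are excluded (pairwise deletion).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import SequenceRecord, SequenceSet

UNAMBIGUOUS = frozenset("ACGT")
_PURINES = frozenset("AG")


class SaturationError(ValueError):
    """Observed divergence too high for the K2P correction (log argument <= 0)."""


@dataclass(frozen=True)
class DistanceResult:
    """Substitution summary for one sequence pair (pairwise deletion)."""

    n_sites: int
    transitions: int
    transversions: int

    @property
    def n_diff(self) -> int:
        return self.transitions + self.transversions

    @property
    def p(self) -> float:
        """Observed proportion of differing sites."""
        return self.n_diff / self.n_sites

    @property
    def P(self) -> float:
        return self.transitions / self.n_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.n_sites

    @property
    def d_k2p(self) -> float:
        return k2p(self)


def round_percent(value: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching how percent differences are
    conventionally printed (e.g. 3.45 -> 3.5 rather than banker's 3.4)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pairwise_counts(
    s1: SequenceRecord,
    s2: SequenceRecord,
    interval: tuple[int, int] | None = None,
) -> DistanceResult:
    """Count compared sites, transitions and transversions between two
    equal-length sequences; ``interval`` is a 1-based closed range for
    segment comparisons (e.g. a 435-bp C-terminal piece).
    """
    if len(s1) != len(s2):
        raise ValueError(
            f"unequal lengths: {s1.id!r} has {len(s1)}, {s2.id!r} has {len(s2)}"
        )
    a, b = s1.residues, s2.residues
    if interval is not None:
        start, end = interval
        if not (1 <= start <= end <= len(a)):
            raise ValueError(f"interval {interval} out of bounds for length {len(a)}")
        a, b = a[start - 1 : end], b[start - 1 : end]
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in UNAMBIGUOUS or y not in UNAMBIGUOUS:
            continue
        n += 1
        if x != y:
            if (x in _PURINES) == (y in _PURINES):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError(f"no comparable sites between {s1.id!r} and {s2.id!r}")
    return DistanceResult(n_sites=n, transitions=ts, transversions=tv)


def k2p(dr: DistanceResult) -> float:
    """Kimura 2-parameter distance in substitutions/site.

    Raises SaturationError when the correction is undefined rather than
    returning infinity, so pipelines fail loudly on garbage input.
    """
    P, Q = dr.P, dr.Q
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        raise SaturationError(
            f"K2P undefined at P={P:.4f}, Q={Q:.4f} (saturated divergence)"
        )
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix with per-cell substitution summaries.

    ``distances`` holds substitutions/site (K2P) or proportions (p) per the
    metric used to build it; ``counts`` keeps the raw DistanceResult per
    unordered pair so both percent values and difference counts stay
    retrievable.
    """

    labels: list[str]
    distances: np.ndarray
    metric: str = "k2p"
    counts: dict[frozenset[str], DistanceResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance grid shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        self.distances = d

    def get(self, i: str, j: str) -> float:
        return float(
            self.distances[self.labels.index(i), self.labels.index(j)]
        )

    def percent(self, i: str, j: str, ndigits: int = 1) -> float:
        return round_percent(100.0 * self.get(i, j), ndigits)

    def n_diff(self, i: str, j: str) -> int:
        if i == j:
            return 0
        return self.counts[frozenset((i, j))].n_diff

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(f"{v:.8f}" for v in self.distances[i])
                fh.write(f"{lab}\t{row}\n")
        return path

    def to_phylip(self, path: str | Path) -> Path:
        """PHYLIP square distance format."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = "  ".join(f"{v:.8f}" for v in self.distances[i])
                fh.write(f"{lab:<10s}  {row}\n")
        return path


def build_matrix(seqs: SequenceSet, metric: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix over an aligned set (metric 'k2p' or 'p')."""
    if metric not in ("k2p", "p"):
        raise ValueError(f"unknown metric {metric!r}")
    seqs.require_aligned()
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    labels = seqs.ids
    n = len(labels)
    d = np.zeros((n, n), dtype=float)
    counts: dict[frozenset[str], DistanceResult] = {}
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dr = pairwise_counts(seqs.records[i], seqs.records[j])
                val = k2p(dr) if metric == "k2p" else dr.p
            except (ValueError, SaturationError) as exc:
                raise type(exc)(
                    f"pair ({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from exc
            d[i, j] = d[j, i] = val
            counts[frozenset((labels[i], labels[j]))] = dr
    return DistanceMatrix(labels=labels, distances=d, metric=metric, counts=counts)


@dataclass
class GroupStats:
    """Summary over a set of pairwise percent distances."""

    n_pairs: int
    minimum: float
    mean: float
    sd: float | None  # sample SD; None when only one pair
    maximum: float


@dataclass
class GroupDivergenceReport:
    """Within-group and between-group percent-distance summaries.

    Within-group statistics are absent (None) for singleton groups: they
    are averages over real pairs only.
    """

    within: dict[str, GroupStats | None]
    between: dict[tuple[str, str], GroupStats]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "within": {
                g: (None if s is None else vars(s)) for g, s in self.within.items()
            },
            "between": {
                f"{a}|{b}": vars(s) for (a, b), s in self.between.items()
            },
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def _stats(values: Sequence[float]) -> GroupStats:
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
    return GroupStats(
        n_pairs=int(arr.size),
        minimum=float(arr.min()),
        mean=float(arr.mean()),
        sd=sd,
        maximum=float(arr.max()),
    )


def group_divergence(
    m: DistanceMatrix, labels: Mapping[str, str]
) -> GroupDivergenceReport:
    """Percent divergence statistics within and between labeled groups."""
    unknown = [lab for lab in m.labels if lab not in labels]
    if unknown:
        raise ValueError(f"matrix labels without a group assignment: {unknown}")
    groups: dict[str, list[str]] = {}
    for lab in m.labels:
        groups.setdefault(labels[lab], []).append(lab)
    within: dict[str, GroupStats | None] = {}
    for g, members in groups.items():
        pairs = [
            100.0 * m.get(a, b)
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        ]
        within[g] = _stats(pairs) if pairs else None
    between: dict[tuple[str, str], GroupStats] = {}
    names = sorted(groups)
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            pairs = [
                100.0 * m.get(a, b) for a in groups[ga] for b in groups[gb]
            ]
            between[(ga, gb)] = _stats(pairs)
    return GroupDivergenceReport(within=within, between=between)


@dataclass(frozen=True)
class GapVerdict:
    """Barcode-gap decision for one group pair."""

    pair: tuple[str, str]
    gap_present: bool
    max_within: float | None  # max within-distance over both groups, percent
    min_between: float


def barcode_gap(
    report: GroupDivergenceReport, threshold: float = 2.0
) -> dict[tuple[str, str], GapVerdict]:
    """Decide, per group pair, whether a barcode gap (hiatus) exists at the
    given percent threshold: every within-group distance of both groups must
    fall strictly below it and every between-group distance at or above it.

    Singleton groups contribute no within-group distances and cannot break
    the gap on their side.
    """
    verdicts: dict[tuple[str, str], GapVerdict] = {}
    for (ga, gb), bet in report.between.items():
        maxw_vals = [
            s.maximum for s in (report.within[ga], report.within[gb]) if s is not None
        ]
        max_within = max(maxw_vals) if maxw_vals else None
        ok = (max_within is None or max_within < threshold) and threshold <= bet.minimum
        verdicts[(ga, gb)] = GapVerdict(
            pair=(ga, gb),
            gap_present=ok,
            max_within=max_within,
            min_between=bet.minimum,
        )
    return verdicts


def delimit_clusters(m: DistanceMatrix, threshold: float) -> dict[str, int]:
    """Single-linkage clusters: join every pair with percent distance
    strictly below ``threshold``.  Clusters are numbered 1, 2, ... in order
    of their lexicographically smallest member label.
    """
    parent = {lab: lab for lab in m.labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(m.labels):
        for b in m.labels[i + 1 :]:
            if 100.0 * m.get(a, b) < threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    clusters: dict[str, list[str]] = {}
    for lab in m.labels:
        clusters.setdefault(find(lab), []).append(lab)
    ordered = sorted(clusters.values(), key=lambda mem: min(mem))
    assignment: dict[str, int] = {}
    for k, members in enumerate(ordered, start=1):
        for lab in members:
            assignment[lab] = k
    return assignment
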