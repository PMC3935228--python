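"""Genitalic morphometric discriminant for cryptic-species pairs.

Six lengths are taken off the male genitalia: uncus widths at the apex (a)
and at the basal "neck" (b), distances from the uncus apex to the widest (c)
and narrowest (d) cross-sections, and the valval dorsal-window length (l)
and height (h).  Two dimensionless scores summarize them:

    u = a/b + w * c/d        (uncus shape; weight w defaults to 0.5)
    v = h/l                  (valva proportions)

Because only ratios enter, the scores are invariant to the measurement unit
and to specimen size.  The separability test asks the exact geometric
question the scatter plot answers: does a straight line classify every
specimen correctly?
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog


@dataclass(frozen=True)
class GenitaliaMeasurements:
    """Six genitalic lengths of one specimen, in a shared arbitrary unit."""

    specimen_id: str
    a: float
    b: float
    c: float
    d: float
    l: float
    h: float
    species: str | None = None

    def __post_init__(self) -> None:
        for name in "abcdlh":
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"specimen {self.specimen_id!r}: measurement {name} must be > 0"
                )


@dataclass(frozen=True)
class MorphoScore:
    """The two discriminant coordinates (both dimensionless, positive)."""

    u: float
    v: float


def morpho_score(m: GenitaliaMeasurements, weight: float = 0.5) -> MorphoScore:
    """u = a/b + weight * c/d and v = h/l, computed exactly as written."""
    return MorphoScore(u=m.a / m.b + weight * (m.c / m.d), v=m.h / m.l)


def read_measurements(path: str | Path) -> list[GenitaliaMeasurements]:
    """TSV with columns id, species, a, b, c, d, l, h."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "a", "b", "c", "d", "l", "h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return [
        GenitaliaMeasurements(
            specimen_id=str(row["id"]),
            a=row["a"], b=row["b"], c=row["c"], d=row["d"],
            l=row["l"], h=row["h"],
            species=str(row["species"]) if "species" in df.columns else None,
        )
        for _, row in df.iterrows()
    ]


def write_scores(
    measurements: Sequence[GenitaliaMeasurements],
    path: str | Path,
    weight: float = 0.5,
) -> Path:
    path = Path(path)
    rows = []
    for m in measurements:
        s = morpho_score(m, weight=weight)
        rows.append(
            {"id": m.specimen_id, "species": m.species,
             "a": m.a, "b": m.b, "c": m.c, "d": m.d, "l": m.l, "h": m.h,
             "u": s.u, "v": s.v}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


@dataclass
class SeparabilityVerdict:
    """Outcome of the exact linear-separability test.

    When separable, ``boundary`` is one witness line (w1, w2, b) with
    w1*u + w2*v + b > 0 for the second class and < 0 for the first.
    Otherwise ``min_overlap`` is the smallest number of points any straight
    line must misclassify.
    """

    separable: bool
    boundary: tuple[float, float, float] | None = None
    min_overlap: int | None = None


def _strict_witness(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float, float] | None:
    """LP feasibility for strict separation with unit margin."""
    n0, n1 = len(x0), len(x1)
    # variables: w1, w2, b ; constraints  w.x + b <= -1 (class 0), >= 1 (class 1)
    A = np.vstack(
        [np.hstack([x0, np.ones((n0, 1))]), -np.hstack([x1, np.ones((n1, 1))])]
    )
    bvec = -np.ones(n0 + n1)
    res = linprog(
        c=np.zeros(3), A_ub=A, b_ub=bvec,
        bounds=[(None, None)] * 3, method="highs",
    )
    if res.status == 0:
        return tuple(float(v) for v in res.x)  # type: ignore[return-value]
    return None


def _min_errors_by_sweep(pts: np.ndarray, y: np.ndarray) -> int:
    """Minimum misclassification over all lines: try every direction normal
    to a point-pair difference (plus axes), sweep the projection threshold."""
    n = len(pts)
    dirs = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
    for i in range(n):
        for j in range(i + 1, n):
            dvec = pts[j] - pts[i]
            if np.allclose(dvec, 0):
                continue
            dirs.append(np.array([-dvec[1], dvec[0]]))  # perpendicular
            dirs.append(dvec)
    best = n
    for w in dirs:
        proj = pts @ w
        order = np.argsort(proj, kind="stable")
        sorted_proj = proj[order]
        sorted_y = y[order]
        # threshold between consecutive projections; class-0 below/above
        ones_prefix = np.concatenate([[0], np.cumsum(sorted_y == 1)])
        zeros_prefix = np.concatenate([[0], np.cumsum(sorted_y == 0)])
        total1, total0 = ones_prefix[-1], zeros_prefix[-1]
        for k in range(n + 1):
            # a threshold can only fall between distinct projection values
            if 0 < k < n and sorted_proj[k - 1] == sorted_proj[k]:
                continue
            # class 1 on the high side
            err = ones_prefix[k] + (total0 - zeros_prefix[k])
            best = min(best, int(err))
            # class 0 on the high side
            err = zeros_prefix[k] + (total1 - ones_prefix[k])
            best = min(best, int(err))
    return best


def separability(
    points: Sequence[tuple[float, float]], labels: Sequence[int | str]
) -> SeparabilityVerdict:
    """Decide whether a straight line separates the two labeled classes of
    (u, v) points exactly; if not, report the minimum overlap."""
    pts = np.asarray(points, dtype=float)
    labs = np.asarray(labels)
    classes = sorted({str(l) for l in labs})
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y = np.array([0 if str(l) == classes[0] else 1 for l in labs])
    if (y == 0).sum() == 0 or (y == 1).sum() == 0:
        raise ValueError("one class is empty")
    witness = _strict_witness(pts[y == 0], pts[y == 1])
    if witness is not None:
        return SeparabilityVerdict(separable=True, boundary=witness)
    return SeparabilityVerdict(
        separable=False, min_overlap=_min_errors_by_sweep(pts, y)
    )
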