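"""Synthetic barcode and morphometric data with the statistical structure
barcode-gap delimitation assumes.

The sequence simulator draws an ancestral COI-like sequence, derives one
consensus per species by placing substitutions at globally distinct sites
(infinite-sites style between species, so fixed diagnostic differences
exist by construction), and then scatters a few further substitutions per
individual haplotype (these may hit any site, which realistically makes
some inter-species differences non-diagnostic).  Substitution counts
between consensuses are chosen so that the realized K2P distances hit the
requested targets; substitution types are transition-biased with
probability kappa/(kappa+1).

Defaults emulate a three-species study design: between-species K2P targets
of 2.0%, 3.4% and 4.5%, haplotypes within 1-3 substitutions of their
consensus (under 0.5% divergence), 658 aligned columns, AT-rich base
composition typical of insect mitochondrial DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .distances import k2p, pairwise_counts
from .morphometrics import GenitaliaMeasurements
from .seqio import SequenceRecord, SequenceSet

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": "CT", "G": "CT", "C": "AG", "T": "AG",
}

DEFAULT_DIVERGENCE = ((0.0, 0.020, 0.034), (0.020, 0.0, 0.045), (0.034, 0.045, 0.0))
DEFAULT_BASE_COMPOSITION = (0.31, 0.15, 0.15, 0.39)  # AT-rich, COI-like


@dataclass
class SimulationConfig:
    """Parameters of the species-set simulator; defaults are the standing
    study conditions used throughout the test-suite."""

    n_species: int = 3
    target_divergence: Sequence[Sequence[float]] = DEFAULT_DIVERGENCE
    kappa: float = 4.0  # transition/transversion rate ratio
    base_composition: Sequence[float] = DEFAULT_BASE_COMPOSITION
    seq_length: int = 658
    n_per_species: int = 20
    intra_max_diffs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_per_species < 1 or self.seq_length < 1:
            raise ValueError("counts must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        grid = np.asarray(self.target_divergence, dtype=float)
        if grid.shape != (self.n_species, self.n_species):
            raise ValueError("divergence grid shape must be n_species x n_species")
        if not np.allclose(grid, grid.T) or not np.allclose(np.diag(grid), 0.0):
            raise ValueError("divergence grid must be symmetric with zero diagonal")
        if self.intra_max_diffs < 0:
            raise ValueError("intra_max_diffs must be >= 0")


@dataclass
class TruthTable:
    """Ground truth emitted alongside a simulated sequence set."""

    species_of: dict[str, str]
    haplotype_of: dict[str, int]
    mutated_positions: dict[str, list[int]]  # 1-based, vs species consensus
    consensus: dict[str, str]
    consensus_diff_counts: dict[frozenset[str], int]
    consensus_k2p: dict[frozenset[str], float]


def _k2p_of_p(p: float, transition_fraction: float) -> float:
    P, Q = transition_fraction * p, (1.0 - transition_fraction) * p
    arg1, arg2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        return math.inf
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


def _invert_k2p(d_target: float, transition_fraction: float) -> float:
    """Observed-difference proportion p whose K2P correction equals the
    target, found by bisection (monotone on the valid range)."""
    if d_target == 0.0:
        return 0.0
    lo, hi = 0.0, 0.75
    while _k2p_of_p(hi, transition_fraction) is math.inf or _k2p_of_p(
        hi, transition_fraction
    ) < d_target:
        hi *= 0.95
        if hi < 1e-6:
            raise ValueError(f"divergence target {d_target} unattainable")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _k2p_of_p(mid, transition_fraction) < d_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _substitute(base: str, kappa: float, rng: np.random.Generator) -> str:
    if rng.random() < kappa / (kappa + 1.0):
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][rng.integers(0, 2)]


def _per_species_counts(cfg: SimulationConfig) -> list[int]:
    """Solve n_i + n_j = L * p_ij for per-species substitution counts from
    the shared ancestor (least squares for >3 species, exact for <=3)."""
    t = cfg.kappa / (cfg.kappa + 1.0)
    k = cfg.n_species
    grid = np.asarray(cfg.target_divergence, dtype=float)
    if k == 1:
        return [0]
    targets: list[tuple[int, int, float]] = []
    for i in range(k):
        for j in range(i + 1, k):
            p = _invert_k2p(grid[i, j], t)
            targets.append((i, j, cfg.seq_length * p))
    if k == 2:
        c = targets[0][2]
        n1 = int(round(c / 2.0))
        return [n1, int(round(c)) - n1]
    A = np.zeros((len(targets), k))
    b = np.zeros(len(targets))
    for row, (i, j, c) in enumerate(targets):
        A[row, i] = A[row, j] = 1.0
        b[row] = c
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(sol < -0.5):
        raise ValueError(
            "divergence grid violates the triangle structure "
            f"(negative implied substitution count: {sol})"
        )
    counts = [max(0, int(round(v))) for v in sol]
    if sum(counts) > cfg.seq_length:
        raise ValueError("divergence targets require more substitutions than sites")
    return counts


def simulate_species_set(cfg: SimulationConfig) -> tuple[SequenceSet, TruthTable]:
    """Generate labeled haplotypes for every species plus ground truth.

    Fully reproducible from ``cfg.seed``.  Realized consensus K2P distances
    are recomputed with the distance module and stored in the truth table.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = np.asarray(cfg.base_composition, dtype=float)
    ancestral = "".join(rng.choice(list(BASES), size=cfg.seq_length, p=freqs))
    counts = _per_species_counts(cfg)
    total = sum(counts)
    positions = rng.choice(cfg.seq_length, size=total, replace=False) if total else []
    consensus: dict[str, str] = {}
    species_names = [f"species{i + 1}" for i in range(cfg.n_species)]
    cursor = 0
    for sp, n_sub in zip(species_names, counts):
        seq = list(ancestral)
        for pos in positions[cursor : cursor + n_sub]:
            seq[pos] = _substitute(seq[pos], cfg.kappa, rng)
        cursor += n_sub
        consensus[sp] = "".join(seq)

    records: list[SequenceRecord] = []
    species_of: dict[str, str] = {}
    haplotype_of: dict[str, int] = {}
    mutated: dict[str, list[int]] = {}
    for si, sp in enumerate(species_names):
        for ind in range(cfg.n_per_species):
            ident = f"sp{si + 1}_{ind + 1:02d}"
            seq = list(consensus[sp])
            if ind == 0 or cfg.intra_max_diffs == 0:
                n_extra = 0  # keep the consensus haplotype in the sample
            else:
                n_extra = int(rng.integers(0, cfg.intra_max_diffs + 1))
            pos_extra = sorted(
                int(p) for p in rng.choice(cfg.seq_length, size=n_extra, replace=False)
            ) if n_extra else []
            for pos in pos_extra:
                seq[pos] = _substitute(seq[pos], cfg.kappa, rng)
            records.append(
                SequenceRecord(id=ident, residues="".join(seq), species=sp)
            )
            species_of[ident] = sp
            haplotype_of[ident] = ind
            mutated[ident] = [p + 1 for p in pos_extra]

    diff_counts: dict[frozenset[str], int] = {}
    k2p_real: dict[frozenset[str], float] = {}
    for i, sa in enumerate(species_names):
        for sb in species_names[i + 1 :]:
            ra = SequenceRecord(id=sa, residues=consensus[sa])
            rb = SequenceRecord(id=sb, residues=consensus[sb])
            dr = pairwise_counts(ra, rb)
            key = frozenset((sa, sb))
            diff_counts[key] = dr.n_diff
            k2p_real[key] = k2p(dr)

    truth = TruthTable(
        species_of=species_of,
        haplotype_of=haplotype_of,
        mutated_positions=mutated,
        consensus=consensus,
        consensus_diff_counts=diff_counts,
        consensus_k2p=k2p_real,
    )
    return SequenceSet(records), truth


@dataclass(frozen=True)
class Fragment:
    """A degraded-template piece with its true position on the alignment."""

    id: str
    source_id: str
    offset: int  # 1-based alignment position of the first residue
    residues: str

    def as_record(self, species: str | None = None) -> SequenceRecord:
        return SequenceRecord(id=self.id, residues=self.residues, species=species)


def degrade_fragments(
    seqs: SequenceSet,
    mean_fragment_len: int,
    min_len: int = 20,
    seed: int = 0,
) -> list[Fragment]:
    """Cut each template at random breakpoints into pieces with the
    requested mean length (geometric spacing), never shorter than
    ``min_len``; fragments carry their true 1-based offsets and reassemble
    to the template exactly."""
    if min_len < 1 or mean_fragment_len < min_len:
        raise ValueError("need mean_fragment_len >= min_len >= 1")
    rng = np.random.default_rng(seed)
    out: list[Fragment] = []
    for rec in seqs:
        L = len(rec.residues)
        cuts: list[int] = [0]
        while cuts[-1] < L:
            if mean_fragment_len >= L:
                step = L
            else:
                step = max(min_len, int(rng.geometric(1.0 / mean_fragment_len)))
            cuts.append(min(L, cuts[-1] + step))
        if len(cuts) > 2 and cuts[-1] - cuts[-2] < min_len:
            del cuts[-2]  # merge a short tail into the previous fragment
        for k, (s, e) in enumerate(zip(cuts, cuts[1:]), start=1):
            out.append(
                Fragment(
                    id=f"{rec.id}_frag{k}",
                    source_id=rec.id,
                    offset=s + 1,
                    residues=rec.residues[s:e],
                )
            )
    return out


def simulate_morphometrics(
    n_per_group: Sequence[int],
    group_means: Sequence[Sequence[float]],
    dispersion: float | Sequence[float],
    seed: int = 0,
    floor: float = 1e-3,
) -> list[GenitaliaMeasurements]:
    """Gaussian scatter (truncated at a small positive floor) around each
    group's mean in six-measurement (a, b, c, d, l, h) space."""
    if len(n_per_group) != len(group_means):
        raise ValueError("n_per_group and group_means lengths differ")
    means = [np.asarray(m, dtype=float) for m in group_means]
    for m in means:
        if m.shape != (6,) or np.any(m <= 0):
            raise ValueError("each group mean must be 6 positive values")
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (6,))
    if np.any(disp < 0):
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    out: list[GenitaliaMeasurements] = []
    for gi, (n, mu) in enumerate(zip(n_per_group, means), start=1):
        if n < 1:
            raise ValueError("each group needs at least one specimen")
        for k in range(n):
            vals = np.maximum(floor, mu + rng.normal(0.0, disp))
            out.append(
                GenitaliaMeasurements(
                    specimen_id=f"g{gi}_{k + 1:02d}",
                    a=vals[0], b=vals[1], c=vals[2], d=vals[3],
                    l=vals[4], h=vals[5],
                    species=f"group{gi}",
                )
            )
    return out
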