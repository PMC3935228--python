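"""Diagnostic-site discovery, ID-tag (mini-barcode) window selection,
degenerate-primer virtual PCR, and fragment-based species calling.

A diagnostic site is an alignment column at which every member of a species
sample carries the same unambiguous nucleotide, yet the species differ.
Dense runs of such sites make short "ID tag" amplicons (~100 bp) that can
still be amplified from fragmented, decades-old museum DNA and suffice to
assign a specimen to species.  All coordinates are 1-based closed intervals
on the plus strand of the reference alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqio import IUPAC_CODES, SequenceRecord, SequenceSet

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

UNAMBIGUOUS = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


def iupac_match(a: str, b: str) -> bool:
    """Two IUPAC codes are compatible iff their base sets intersect."""
    if a == "-" or b == "-":
        return False
    return bool(IUPAC_CODES[a] & IUPAC_CODES[b])


@dataclass(frozen=True)
class DiagnosticSite:
    """One fixed inter-group difference: 1-based column and the invariant
    residue of each group there."""

    position: int
    states: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based")
        bad = {s for s in self.states.values() if s not in UNAMBIGUOUS}
        if bad:
            raise ValueError(f"diagnostic states must be unambiguous, got {bad}")
        if len(set(self.states.values())) < 2:
            raise ValueError("a diagnostic site needs >= 2 distinct group states")


def find_diagnostic_sites(
    seqs: SequenceSet,
    labels: Mapping[str, str],
    groups: Sequence[str] | None = None,
) -> list[DiagnosticSite]:
    """All columns where each chosen group is invariant and unambiguous and
    at least two groups differ, in ascending position order."""
    seqs.require_aligned()
    members: dict[str, list[SequenceRecord]] = {}
    for rec in seqs:
        g = labels.get(rec.id, rec.species)
        if g is not None:
            members.setdefault(g, []).append(rec)
    if groups is None:
        groups = sorted(members)
    unknown = [g for g in groups if g not in members]
    if unknown:
        raise ValueError(f"no sequences labeled with group(s) {unknown}")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sites: list[DiagnosticSite] = []
    L = seqs.alignment_length
    for col in range(L):
        states: dict[str, str] = {}
        ok = True
        for g in groups:
            observed = {rec.residues[col] for rec in members[g]}
            if len(observed) != 1 or not observed <= UNAMBIGUOUS:
                ok = False
                break
            states[g] = next(iter(observed))
        if ok and len(set(states.values())) > 1:
            sites.append(DiagnosticSite(position=col + 1, states=states))
    return sites


@dataclass(frozen=True)
class TagWindow:
    """A candidate mini-barcode interval scored by its diagnostic content.

    ``pair_min`` is the weakest per-pair discrimination inside the window:
    the minimum, over group pairs, of the number of contained sites at
    which that pair differs.
    """

    start: int
    end: int
    site_count: int
    pair_min: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _pair_min(sites_in: Sequence[DiagnosticSite], groups: Sequence[str]) -> int:
    if len(groups) < 2:
        return 0
    best = None
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            c = sum(1 for s in sites_in if s.states[ga] != s.states[gb])
            best = c if best is None else min(best, c)
    return best or 0


def select_tag_windows(
    sites: Sequence[DiagnosticSite],
    groups: Sequence[str],
    window_len: int,
    alignment_length: int,
    top_k: int = 5,
) -> list[TagWindow]:
    """Slide a fixed-length window over the alignment and rank windows by
    (pair_min, site_count) lexicographically, descending; ties break toward
    the smaller start, and windows containing an identical site set collapse
    to the leftmost."""
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if window_len > alignment_length:
        raise ValueError("window_len exceeds alignment length")
    if not sites:
        return []
    windows: list[TagWindow] = []
    seen_site_sets: set[tuple[int, ...]] = set()
    for start in range(1, alignment_length - window_len + 2):
        end = start + window_len - 1
        inside = [s for s in sites if start <= s.position <= end]
        key = tuple(s.position for s in inside)
        if key in seen_site_sets:
            continue
        seen_site_sets.add(key)
        windows.append(
            TagWindow(
                start=start,
                end=end,
                site_count=len(inside),
                pair_min=_pair_min(inside, groups),
            )
        )
    windows.sort(key=lambda w: (-w.pair_min, -w.site_count, w.start))
    return windows[:top_k]


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide over the IUPAC alphabet, written 5'->3'."""

    name: str
    residues: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("primer sequence must be non-empty")
        canon = self.residues.upper()
        bad = set(canon) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"primer {self.name!r}: non-IUPAC characters {bad}")
        object.__setattr__(self, "residues", canon)
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")

    def __len__(self) -> int:
        return len(self.residues)


def match_primer(template: SequenceRecord, primer: Primer) -> list[tuple[int, int]]:
    """All 1-based closed binding intervals of a primer on the template's
    plus strand.  Forward primers match as written; reverse primers match
    through their reverse complement.  Degenerate positions match whenever
    the IUPAC base sets intersect; no mismatches are tolerated."""
    probe = (
        primer.residues
        if primer.orientation == "forward"
        else reverse_complement(primer.residues)
    )
    tmpl = template.residues
    hits: list[tuple[int, int]] = []
    for i in range(len(tmpl) - len(probe) + 1):
        if all(iupac_match(p, t) for p, t in zip(probe, tmpl[i : i + len(probe)])):
            hits.append((i + 1, i + len(probe)))
    return hits


class AmplificationError(ValueError):
    """Virtual PCR failure: missing, multiple or mis-ordered primer sites."""


@dataclass(frozen=True)
class AmpliconResult:
    """A successful in-silico amplification on one template."""

    template_id: str
    forward_interval: tuple[int, int]
    reverse_interval: tuple[int, int]
    insert: str

    @property
    def insert_len(self) -> int:
        return len(self.insert)

    @property
    def product_len(self) -> int:
        f0, f1 = self.forward_interval
        r0, r1 = self.reverse_interval
        return self.insert_len + (f1 - f0 + 1) + (r1 - r0 + 1)

    @property
    def insert_interval(self) -> tuple[int, int]:
        return (self.forward_interval[1] + 1, self.reverse_interval[0] - 1)


def virtual_pcr(
    template: SequenceRecord, fwd: Primer, rev: Primer
) -> AmpliconResult:
    """Amplify in silico: both primers must bind exactly once, with the
    forward site strictly upstream of the reverse site.  Multiple binding
    sites abort (mirroring non-specific amplification)."""
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise AmplificationError(
            f"primer orientations wrong: {fwd.name} is {fwd.orientation}, "
            f"{rev.name} is {rev.orientation}"
        )
    fhits = match_primer(template, fwd)
    rhits = match_primer(template, rev)
    for name, hits in ((fwd.name, fhits), (rev.name, rhits)):
        if len(hits) == 0:
            raise AmplificationError(f"primer {name!r} does not bind {template.id!r}")
        if len(hits) > 1:
            raise AmplificationError(
                f"primer {name!r} binds {template.id!r} at {len(hits)} sites"
            )
    (f0, f1), (r0, r1) = fhits[0], rhits[0]
    if not f1 < r0:
        raise AmplificationError(
            f"reverse site {r0}-{r1} not downstream of forward site {f0}-{f1}"
        )
    insert = template.residues[f1 : r0 - 1]
    return AmpliconResult(
        template_id=template.id,
        forward_interval=(f0, f1),
        reverse_interval=(r0, r1),
        insert=insert,
    )


@dataclass
class SiteEvidence:
    """What one diagnostic site says about a fragment."""

    position: int
    observed: str
    matching_groups: list[str]


@dataclass
class SpeciesCall:
    """Verdict for one fragment: a group label, 'ambiguous', 'contaminated'
    or 'no-match', with per-site evidence."""

    verdict: str
    evidence: list[SiteEvidence] = field(default_factory=list)


def call_species(
    fragment: SequenceRecord,
    profile: Sequence[DiagnosticSite],
    offset: int = 1,
) -> SpeciesCall:
    """Assign a (possibly short, degraded) fragment to a species using the
    diagnostic profile.  ``offset`` is the 1-based alignment position of the
    fragment's first residue; profile sites outside the fragment are ignored.

    A group label is returned only when every scorable site matches exactly
    that group.  Two or more sites backing different groups — or ambiguity
    codes at diagnostic sites — flag contamination.
    """
    if offset < 1:
        raise ValueError("offset is 1-based and must be >= 1")
    frag_start, frag_end = offset, offset + len(fragment.residues) - 1
    evidence: list[SiteEvidence] = []
    ambiguous_hits = 0
    supported: list[set[str]] = []
    for site in profile:
        if not (frag_start <= site.position <= frag_end):
            continue
        obs = fragment.residues[site.position - frag_start]
        if obs not in UNAMBIGUOUS:
            ambiguous_hits += 1
            evidence.append(SiteEvidence(site.position, obs, []))
            continue
        matches = sorted(g for g, st in site.states.items() if st == obs)
        evidence.append(SiteEvidence(site.position, obs, matches))
        supported.append(set(matches))
    if not evidence:
        return SpeciesCall(verdict="no-match", evidence=[])
    # Groups consistent with every scorable site
    consistent: set[str] | None = None
    for s in supported:
        consistent = s if consistent is None else consistent & s
    distinct_backings = {frozenset(s) for s in supported if s}
    conflicting = (
        sum(1 for s in supported if s) >= 2
        and consistent is not None
        and not consistent
        and len(distinct_backings) >= 2
    )
    if conflicting or ambiguous_hits >= 2:
        return SpeciesCall(verdict="contaminated", evidence=evidence)
    if consistent is None or not consistent:
        return SpeciesCall(verdict="no-match", evidence=evidence)
    if len(consistent) > 1 or ambiguous_hits:
        return SpeciesCall(verdict="ambiguous", evidence=evidence)
    return SpeciesCall(verdict=next(iter(consistent)), evidence=evidence)


def tag_difference_counts(
    seqs: SequenceSet, window: TagWindow | tuple[int, int]
) -> dict[frozenset[str], int]:
    """Per unordered pair of sequences, the count of differing unambiguous
    columns inside the window interval."""
    seqs.require_aligned()
    start, end = (
        (window.start, window.end) if isinstance(window, TagWindow) else window
    )
    L = seqs.alignment_length
    if not (1 <= start <= end <= L):
        raise ValueError(f"window {start}-{end} out of range for length {L}")
    out: dict[frozenset[str], int] = {}
    recs = list(seqs)
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            c = sum(
                1
                for col in range(start - 1, end)
                if a.residues[col] in UNAMBIGUOUS
                and b.residues[col] in UNAMBIGUOUS
                and a.residues[col] != b.residues[col]
            )
            out[frozenset((a.id, b.id))] = c
    return out
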