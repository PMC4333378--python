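"""Mutation calling against a reporter reference.

Aligns sequenced mutant inserts to the reference target globally, left-normalizes
indel placement so that slippage events in repeats are reported at a single
canonical position, calls substitution/insertion/deletion events, and groups
nearby events into complex event groups using the >10-nt separation rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

DNA = frozenset("ACGT")
DNA_N = frozenset("ACGTN")
GAP = "-"


class InputError(ValueError):
    """Raised for malformed user inputs (bad alphabet, bad coordinates, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """A labelled 1-based inclusive interval on the reference."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InputError(
                f"region {self.label!r}: invalid interval [{self.start}, {self.end}]"
            )

    def contains(self, coord: float) -> bool:
        return self.start <= coord <= self.end


@dataclass(frozen=True)
class ReferenceTarget:
    """Reporter target sequence with annotated regions and a detectable-site model.

    ``detectable_sites`` is either a set of 1-based positions (when the positions
    are known) or a scalar count D (when only the aggregate number of detectable
    changes is known, as for the 147 detectable changes of the lacZ-alpha gap).
    """

    id: str
    sequence: str
    regions: tuple[Region, ...] = ()
    detectable_sites: frozenset[int] | int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise InputError(f"reference {self.id!r}: empty sequence")
        bad = set(seq) - DNA
        if bad:
            raise InputError(
                f"reference {self.id!r}: non-ACGT characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)
        labels = [r.label for r in self.regions]
        if len(labels) != len(set(labels)):
            raise InputError(f"reference {self.id!r}: duplicate region labels")
        for r in self.regions:
            if r.end > len(seq):
                raise InputError(
                    f"region {r.label!r} [{r.start}, {r.end}] exceeds reference "
                    f"length {len(seq)}"
                )
        if isinstance(self.detectable_sites, (set, frozenset)):
            sites = frozenset(self.detectable_sites)
            if sites and (min(sites) < 1 or max(sites) > len(seq)):
                raise InputError("detectable sites outside [1, length]")
            object.__setattr__(self, "detectable_sites", sites)
        elif self.detectable_sites is not None:
            if int(self.detectable_sites) < 1:
                raise InputError("detectable-site count D must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def detectable_count(self) -> int | None:
        """D: the number of detectable sites/changes, however specified."""
        if self.detectable_sites is None:
            return None
        if isinstance(self.detectable_sites, frozenset):
            return len(self.detectable_sites)
        return int(self.detectable_sites)

    def region_of(self, coord: float) -> Region | None:
        for r in self.regions:
            if r.contains(coord):
                return r
        return None


@dataclass(frozen=True)
class MutantRead:
    """One sequenced mutant insert. ``events`` is simulator ground truth when set."""

    id: str
    sequence: str
    source_reaction: str = ""
    events: tuple["MutationEvent", ...] | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise InputError(f"read {self.id!r}: empty sequence")
        bad = set(seq) - DNA_N
        if bad:
            raise InputError(f"read {self.id!r}: non-ACGTN characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class ScoringParams:
    """Global-alignment scoring. A gap of length L costs open + (L-1) * extend."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise InputError("scoring: match must exceed mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise InputError("scoring: gap penalties must be negative")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Gapped global alignment of reference (row 0) vs read (row 1)."""

    ref_row: str
    read_row: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.read_row):
            raise InputError("alignment rows differ in length")
        for a, b in zip(self.ref_row, self.read_row):
            if a == GAP and b == GAP:
                raise InputError("alignment column with gaps in both rows")

    @property
    def reference(self) -> str:
        return self.ref_row.replace(GAP, "")

    @property
    def read(self) -> str:
        return self.read_row.replace(GAP, "")


@dataclass(frozen=True)
class MutationEvent:
    """A called substitution, insertion or deletion in reference coordinates.

    Insertions are anchored to the reference base immediately to their left
    (position 0 means an insertion before position 1). Ref/alt alleles follow
    the usual convention: insertions have an empty ref_allele, deletions an
    empty alt_allele.
    """

    kind: str  # substitution | insertion | deletion
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        k = self.kind
        if k == "substitution":
            if len(self.ref_allele) != len(self.alt_allele) or not self.ref_allele:
                raise InputError("substitution alleles must be equal, non-empty")
            if self.ref_allele == self.alt_allele:
                raise InputError("substitution with identical alleles")
            if self.position < 1:
                raise InputError("substitution position must be >= 1")
        elif k == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise InputError("insertion must have empty ref, non-empty alt")
            if self.position < 0:
                raise InputError("insertion anchor must be >= 0")
        elif k == "deletion":
            if self.alt_allele or not self.ref_allele:
                raise InputError("deletion must have empty alt, non-empty ref")
            if self.position < 1:
                raise InputError("deletion position must be >= 1")
        else:
            raise InputError(f"unknown event kind {k!r}")

    @property
    def length(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele))

    @property
    def start(self) -> int:
        return self.position

    @property
    def end(self) -> int:
        """Last reference coordinate touched (anchor + 1 for insertions)."""
        if self.kind == "insertion":
            return self.position + 1
        return self.position + len(self.ref_allele) - 1

    @property
    def net_length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass(frozen=True)
class EventGroup:
    """Events from one mutant clustered by the <=10-nt single-linkage rule."""

    events: tuple[MutationEvent, ...]
    span: tuple[int, int]
    is_complex: bool

    @property
    def midpoint(self) -> float:
        return (self.span[0] + self.span[1]) / 2.0

    @property
    def net_length_change(self) -> int:
        return sum(e.net_length_change for e in self.events)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _build_aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    # N scores 0 against everything so ambiguous read bases are alignment-neutral
    letters = "ACGTN"
    mat = substitution_matrices.Array(alphabet=letters, dims=2)
    for a in letters:
        for b in letters:
            if "N" in (a, b):
                mat[a, b] = 0.0
            elif a == b:
                mat[a, b] = scoring.match
            else:
                mat[a, b] = scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_to_reference(
    reference: ReferenceTarget,
    read: MutantRead,
    scoring: ScoringParams = ScoringParams(),
) -> PairwiseAlignment:
    """Globally align ``read`` to ``reference`` under ``scoring``.

    Among co-optimal alignments the aligner's first traceback is taken; the
    canonical event representation is obtained afterwards via
    :func:`normalize_indels`, which makes the final event list independent of
    which co-optimal placement was emitted.
    """
    aligner = _build_aligner(scoring)
    aln = aligner.align(reference.sequence, read.sequence)[0]
    return PairwiseAlignment(ref_row=str(aln[0]), read_row=str(aln[1]), score=aln.score)


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal gap runs as half-open column intervals [i, j)."""
    runs = []
    i = 0
    n = len(row)
    while i < n:
        if row[i] == GAP:
            j = i
            while j < n and row[j] == GAP:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def normalize_indels(alignment: PairwiseAlignment) -> PairwiseAlignment:
    """Shift every gap run as far left as score-equivalence allows.

    A run of gaps in one row can move one column left when the column to its
    left has no gap in either row and the facing base there equals the facing
    base at the run's right edge (a rotation of the indel allele). The result
    is the unique left-most canonical form; the operation is idempotent and
    preserves both ungapped sequences and the alignment score.
    """
    ref = list(alignment.ref_row)
    read = list(alignment.read_row)

    changed = True
    while changed:
        changed = False
        for gap_row, base_row in ((read, ref), (ref, read)):
            for i, j in _gap_runs("".join(gap_row)):
                while (
                    i > 0
                    and gap_row[i - 1] != GAP
                    and base_row[i - 1] != GAP
                    and base_row[i - 1] == base_row[j - 1]
                ):
                    # move the facing base from the left edge to the right edge
                    gap_row[j - 1] = gap_row[i - 1]
                    gap_row[i - 1] = GAP
                    i -= 1
                    j -= 1
                    changed = True
    return PairwiseAlignment("".join(ref), "".join(read), alignment.score)


def call_events(alignment: PairwiseAlignment) -> list[MutationEvent]:
    """Convert a (normalized) alignment into mutation events.

    Maximal gap runs become one insertion/deletion each; every mismatch column
    becomes its own length-1 substitution. Columns whose read base is N are
    masked and never produce events (N bases inside insertion alleles are
    dropped). Applying the returned events to the reference reconstructs the
    read exactly whenever the read is N-free.
    """
    events: list[MutationEvent] = []
    ref_pos = 0  # 1-based position of last consumed reference base
    cols = list(zip(alignment.ref_row, alignment.read_row))
    i = 0
    n = len(cols)
    while i < n:
        a, b = cols[i]
        if a == GAP:  # insertion run
            j = i
            ins = []
            while j < n and cols[j][0] == GAP:
                ins.append(cols[j][1])
                j += 1
            alt = "".join(c for c in ins if c != "N")
            if alt:
                events.append(MutationEvent("insertion", ref_pos, "", alt))
            elif ins:
                logger.debug("masked N-only insertion after position %d", ref_pos)
            i = j
        elif b == GAP:  # deletion run
            j = i
            dele = []
            while j < n and cols[j][1] == GAP:
                dele.append(cols[j][0])
                j += 1
            events.append(
                MutationEvent("deletion", ref_pos + 1, "".join(dele), "")
            )
            ref_pos += len(dele)
            i = j
        else:
            ref_pos += 1
            if a != b:
                if b == "N":
                    logger.debug("masked N at reference position %d", ref_pos)
                else:
                    events.append(MutationEvent("substitution", ref_pos, a, b))
            i += 1
    return events


def apply_events(reference: str, events: Sequence[MutationEvent]) -> str:
    """Apply non-overlapping events (any order) to a reference sequence."""
    order = {"deletion": 0, "substitution": 0, "insertion": 1}
    evs = sorted(events, key=lambda e: (e.position, order[e.kind]))
    out: list[str] = []
    pos = 1  # next reference base to copy (1-based)
    for e in evs:
        if e.kind == "insertion":
            take = e.position  # copy through the anchor base
        else:
            take = e.position - 1
        if take < pos - 1:
            raise InputError(f"overlapping events at position {e.position}")
        out.append(reference[pos - 1 : take])
        pos = take + 1
        if e.kind == "substitution":
            if reference[pos - 1 : pos - 1 + len(e.ref_allele)] != e.ref_allele:
                raise InputError(f"ref allele mismatch at position {e.position}")
            out.append(e.alt_allele)
            pos += len(e.ref_allele)
        elif e.kind == "deletion":
            if reference[pos - 1 : pos - 1 + len(e.ref_allele)] != e.ref_allele:
                raise InputError(f"ref allele mismatch at position {e.position}")
            pos += len(e.ref_allele)
        else:  # insertion
            out.append(e.alt_allele)
    out.append(reference[pos - 1 :])
    return "".join(out)


def call_read(
    reference: ReferenceTarget,
    read: MutantRead,
    scoring: ScoringParams = ScoringParams(),
) -> list[MutationEvent]:
    """align -> normalize -> call, the standard per-read pipeline."""
    return call_events(normalize_indels(align_to_reference(reference, read, scoring)))


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def group_events(
    events: Sequence[MutationEvent], grouping_distance: int = 10
) -> list[EventGroup]:
    """Single-linkage clustering of one mutant's events.

    Two events join the same group iff their nearest reference coordinates are
    <= ``grouping_distance`` apart; errors strictly more than the distance
    apart count as independent (the group count is the n of the multiple-error
    correction, capped at 3 downstream).
    """
    if grouping_distance < 0:
        raise InputError("grouping_distance must be >= 0")
    evs = sorted(events, key=lambda e: (e.start, e.end))
    groups: list[EventGroup] = []
    current: list[MutationEvent] = []
    for e in evs:
        if current and e.start - max(x.end for x in current) > grouping_distance:
            groups.append(_finish_group(current))
            current = []
        current.append(e)
    if current:
        groups.append(_finish_group(current))
    return groups


def _finish_group(events: list[MutationEvent]) -> EventGroup:
    span = (min(e.position for e in events), max(e.position for e in events))
    return EventGroup(tuple(events), span, is_complex=len(events) > 1)


def multiplicity_of(groups_per_mutant: Iterable[Sequence[EventGroup]], cap: int = 3) -> dict[int, int]:
    """Per-mutant detectable-error-group counts, folded at ``cap`` (default 3)."""
    counts: dict[int, int] = {}
    for groups in groups_per_mutant:
        n = len(list(groups))
        if n == 0:
            continue
        if n > cap:
            logger.warning("mutant with %d error groups folded into n=%d", n, cap)
            n = cap
        counts[n] = counts.get(n, 0) + 1
    return counts
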