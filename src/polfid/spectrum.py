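"""Error-spectrum tabulation: strand-collapsed substitution classes, indel and
complex counts, region partitions and positional hotspot scanning."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .calling import DNA, EventGroup, InputError, MutationEvent, ReferenceTarget

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: The six strand-collapsed substitution classes, in display order.
SUBSTITUTION_CLASSES = (
    "A→T/T→A",
    "A→C/T→G",
    "A→G/T→C",
    "G→A/C→T",
    "G→C/C→G",
    "G→T/C→A",
)

TRANSITION_CLASSES = ("A→G/T→C", "G→A/C→T")
GC_TEMPLATED_CLASSES = tuple(c for c in SUBSTITUTION_CLASSES if c.startswith("G"))
AT_TEMPLATED_CLASSES = tuple(c for c in SUBSTITUTION_CLASSES if c.startswith("A"))


def collapse_substitution(ref_base: str, alt_base: str) -> str:
    """Map an ordered (templating, product) base pair onto its collapsed class.

    Complement-symmetric: (x, y) and (complement x, complement y) collapse to
    the same class, so each class pools the two strand readings.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in DNA or alt_base not in DNA:
        raise InputError(f"non-ACGT substitution bases ({ref_base!r}, {alt_base!r})")
    if ref_base == alt_base:
        raise InputError("substitution with identical bases")
    if ref_base in "CT":  # collapse onto the purine-templated reading
        ref_base, alt_base = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    label = f"{ref_base}→{alt_base}/{COMPLEMENT[ref_base]}→{COMPLEMENT[alt_base]}"
    assert label in SUBSTITUTION_CLASSES
    return label


@dataclass(frozen=True)
class ErrorSpectrum:
    """Class-count table (lacZ-alpha Table-2 shape).

    ``complex`` is zero in the per-event view; in the per-group view every
    multi-event group is tallied once under ``complex`` instead of its member
    events. ``percentages`` is None when no events were observed (explicitly
    undefined rather than 0/0).
    """

    substitution_counts: dict[str, int]
    insertions: int
    deletions: int
    complex: int
    total_events: int
    percentages: dict[str, float] | None
    transitions: int
    transversions: int
    gc_templated: int
    at_templated: int

    def count(self, label: str) -> int:
        if label == "Insertions":
            return self.insertions
        if label == "Deletions":
            return self.deletions
        if label == "Complex":
            return self.complex
        return self.substitution_counts[label]


def _iter_events(groups_per_mutant: Iterable[Sequence[EventGroup]]):
    for groups in groups_per_mutant:
        for g in groups:
            yield g


def tabulate_spectrum(
    groups_per_mutant: Iterable[Sequence[EventGroup]],
    view: str = "events",
) -> ErrorSpectrum:
    """Tabulate the mutation-class spectrum.

    view="events": every event counts in its own category (how the lacZ-alpha
    table is laid out, with no complex row). view="groups": each multi-event
    group counts once as complex; singleton groups count under their event's
    category (the STR/coding summary convention).
    """
    if view not in ("events", "groups"):
        raise InputError(f"unknown spectrum view {view!r}")
    sub = {c: 0 for c in SUBSTITUTION_CLASSES}
    ins = dele = cplx = 0
    for group in _iter_events(groups_per_mutant):
        if view == "groups" and group.is_complex:
            cplx += 1
            continue
        for e in group.events:
            if e.kind == "substitution":
                sub[collapse_substitution(e.ref_allele, e.alt_allele)] += 1
            elif e.kind == "insertion":
                ins += 1
            else:
                dele += 1
    total = sum(sub.values()) + ins + dele + cplx
    transitions = sum(sub[c] for c in TRANSITION_CLASSES)
    transversions = sum(sub.values()) - transitions
    gc = sum(sub[c] for c in GC_TEMPLATED_CLASSES)
    at = sum(sub[c] for c in AT_TEMPLATED_CLASSES)

    percentages: dict[str, float] | None
    if total == 0:
        percentages = None
    else:
        percentages = {}
        for label in SUBSTITUTION_CLASSES:
            percentages[label] = round(100.0 * sub[label] / total, 1)
        percentages["Insertions"] = round(100.0 * ins / total, 1)
        percentages["Deletions"] = round(100.0 * dele / total, 1)
        if view == "groups":
            percentages["Complex"] = round(100.0 * cplx / total, 1)
        percentages["Transitions"] = round(100.0 * transitions / total, 1)
        percentages["Transversions"] = round(100.0 * transversions / total, 1)
        percentages["A→N/T→N"] = round(100.0 * at / total, 1)
        percentages["G→N/C→N"] = round(100.0 * gc / total, 1)

    return ErrorSpectrum(
        substitution_counts=sub,
        insertions=ins,
        deletions=dele,
        complex=cplx,
        total_events=total,
        percentages=percentages,
        transitions=transitions,
        transversions=transversions,
        gc_templated=gc,
        at_templated=at,
    )


@dataclass(frozen=True)
class RegionTally:
    """Per-region (group count, event count) plus the unassigned remainder."""

    regions: dict[str, tuple[int, int]]
    unassigned: tuple[int, int]

    @property
    def total_groups(self) -> int:
        return sum(g for g, _ in self.regions.values()) + self.unassigned[0]

    @property
    def total_events(self) -> int:
        return sum(e for _, e in self.regions.values()) + self.unassigned[1]


def partition_by_region(
    groups_per_mutant: Iterable[Sequence[EventGroup]],
    reference: ReferenceTarget,
) -> RegionTally:
    """Assign each event group to the region containing its span midpoint.

    The midpoint rule makes boundary-straddling groups deterministic. Groups
    whose midpoint falls in no annotated region are tallied as unassigned.
    """
    tally = {r.label: [0, 0] for r in reference.regions}
    unassigned = [0, 0]
    for group in _iter_events(groups_per_mutant):
        if group.span[1] > len(reference) or group.span[0] < 0:
            raise InputError(f"group span {group.span} outside reference")
        region = reference.region_of(group.midpoint)
        bucket = tally[region.label] if region is not None else unassigned
        bucket[0] += 1
        bucket[1] += len(group.events)
    return RegionTally(
        regions={k: (v[0], v[1]) for k, v in tally.items()},
        unassigned=(unassigned[0], unassigned[1]),
    )


@dataclass(frozen=True)
class HotspotResult:
    position: int
    event_count: int
    expected_count: float
    p_value: float
    q_value: float


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def hotspot_scan(
    events: Sequence[MutationEvent],
    n_mutants: int,
    reference: ReferenceTarget,
    alpha: float = 0.05,
) -> list[HotspotResult]:
    """Exploratory hotspot scan against a uniform-across-positions null.

    Each position's event count (events anchored by their start coordinate) is
    tested against Binomial(total events, 1/L) with a one-sided upper tail,
    followed by Benjamini-Hochberg correction across positions. Positions with
    q <= alpha are returned sorted by descending count. The underlying study
    located its hotspot by inspection; this statistic is a reproducible stand-in
    and is labelled exploratory in all outputs.
    """
    if not (0 < alpha <= 1):
        raise InputError("alpha must be in (0, 1]")
    if n_mutants < 1:
        raise InputError("n_mutants must be >= 1")
    if not events:
        return []
    L = len(reference)
    counts = np.zeros(L, dtype=int)
    for e in events:
        counts[max(e.start, 1) - 1] += 1
    total = int(counts.sum())
    expected = total / L
    p = stats.binom.sf(counts - 1, total, 1.0 / L)
    q = _benjamini_hochberg(p)
    hits = [
        HotspotResult(i + 1, int(counts[i]), expected, float(p[i]), float(q[i]))
        for i in range(L)
        if q[i] <= alpha and counts[i] > 0
    ]
    hits.sort(key=lambda h: (-h.event_count, h.position))
    return hits
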