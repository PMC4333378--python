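"""Error-prone polymerase simulator.

Simulates gap-filling synthesis across a reporter target with per-templating-base
substitution biases, slippage indels that grow with homopolymer run length,
hairpin "scrunching" complex events, and the colony-screening readout — so the
calling/spectrum/fidelity stages can be exercised end-to-end against known truth.

Randomness contract: each public operation takes a seed and drives a single
numpy Generator in a documented order (per chunk: the per-site uniform matrix,
then the per-hairpin uniform matrix, then secondary draws per flagged molecule
in row order and per event in column order). Fixed inputs and seed give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calling import (
    InputError,
    MutantRead,
    MutationEvent,
    ReferenceTarget,
    Region,
    apply_events,
)
from .fidelity import ColonyCounts, GapAssayParams, corrected_mutation_frequency, error_rate_gap_assay

logger = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass(frozen=True)
class PolymeraseErrorModel:
    """Per-site stochastic error model for one synthesis pass.

    substitution_rates: templating base -> {product base: per-site probability}.
    indel_rate: per-site single-base indel probability outside repeats.
    slippage_base: per-site indel probability inside a length-2 homopolymer;
    grows by ``slippage_growth`` per extra repeat unit (rate at run length L is
    slippage_base * slippage_growth**(L-2)).
    insertion_fraction: fraction of indel events that are insertions.
    scrunch_rate: per-molecule probability, for each annotated hairpin region,
    of a complex event that expands the loop template (>=2 sub-events within
    10 nt, so downstream grouping labels it complex).
    hairpin_regions: (loop Region, expansion template string) pairs.
    """

    substitution_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    indel_rate: float = 0.0
    slippage_base: float = 0.0
    slippage_growth: float = 1.0
    insertion_fraction: float = 0.5
    scrunch_rate: float = 0.0
    hairpin_regions: tuple[tuple[Region, str], ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        for b, alts in self.substitution_rates.items():
            if b not in BASES:
                raise InputError(f"bad templating base {b!r}")
            for a, r in alts.items():
                if a not in BASES or a == b:
                    raise InputError(f"bad product base {a!r} for template {b!r}")
                if not (0 <= r <= 1):
                    raise InputError("substitution rates must lie in [0, 1]")
        for name in ("indel_rate", "slippage_base", "insertion_fraction", "scrunch_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InputError(f"{name} must lie in [0, 1]")
        if self.slippage_growth < 1:
            raise InputError("slippage_growth must be >= 1")

    def sub_rate_total(self, base: str) -> float:
        return sum(self.substitution_rates.get(base, {}).values())


@dataclass(frozen=True)
class AssaySimConfig:
    n_molecules: int
    expression_p: float
    background_mf: float = 0.0
    detectability: frozenset[int] | None = None  # None = every site detectable
    n_sequenced: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise InputError("n_molecules must be >= 1")
        if not (0 < self.expression_p <= 1):
            raise InputError("expression_p must lie in (0, 1]")
        if not (0 <= self.background_mf < 1):
            raise InputError("background_mf must lie in [0, 1)")
        if self.detectability is not None:
            object.__setattr__(self, "detectability", frozenset(self.detectability))


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------


def homopolymer_run_lengths(sequence: str) -> np.ndarray:
    """Length of the homopolymer run containing each position (1 if unique)."""
    L = len(sequence)
    out = np.ones(L, dtype=int)
    i = 0
    while i < L:
        j = i
        while j < L and sequence[j] == sequence[i]:
            j += 1
        out[i:j] = j - i
        i = j
    return out


def _per_site_probs(model: PolymeraseErrorModel, reference: ReferenceTarget):
    seq = reference.sequence
    L = len(seq)
    p_sub = np.array([model.sub_rate_total(b) for b in seq])
    runs = homopolymer_run_lengths(seq)
    p_indel = np.where(
        runs >= 2,
        model.slippage_base * model.slippage_growth ** (runs - 2.0),
        model.indel_rate,
    )
    p_tot = p_sub + p_indel
    if np.any(p_tot >= 1):
        raise InputError("per-site total event probability must be < 1")
    return p_sub, p_indel, p_tot


def _sample_substitution(rng: np.random.Generator, model, base: str) -> str:
    alts = model.substitution_rates.get(base, {})
    labels = sorted(alts)
    weights = np.array([alts[a] for a in labels])
    total = weights.sum()
    u = rng.random() * total
    acc = 0.0
    for lab, w in zip(labels, weights):
        acc += w
        if u < acc:
            return lab
    return labels[-1]


def _scrunch_events(
    rng: np.random.Generator, reference: ReferenceTarget, region: Region, template: str
) -> list[MutationEvent]:
    """A complex loop-expansion: duplicate the expansion template inside the
    loop plus one nearby companion sub-event, all within 10 nt."""
    seq = reference.sequence
    anchor = region.start  # insertion after the first loop base
    events = [MutationEvent("insertion", anchor, "", template)]
    companion_pos = min(anchor + 2 + int(rng.integers(0, 3)), len(seq))
    if companion_pos == anchor:  # degenerate tiny reference
        companion_pos = min(anchor + 1, len(seq))
    if rng.random() < 0.5:
        events.append(
            MutationEvent("deletion", companion_pos, seq[companion_pos - 1], "")
        )
    else:
        ref_base = seq[companion_pos - 1]
        alt = BASES[(BASES.index(ref_base) + 1) % 4]
        events.append(MutationEvent("substitution", companion_pos, ref_base, alt))
    return events


def simulate_synthesis(
    model: PolymeraseErrorModel,
    reference: ReferenceTarget,
    n: int,
    seed: int,
    chunk_size: int = 65536,
) -> list[MutantRead]:
    """Simulate ``n`` synthesis products (at most one event per site per
    molecule). Each returned read carries its ground-truth events."""
    if n < 1:
        raise InputError("n must be >= 1")
    seq = reference.sequence
    L = len(seq)
    p_sub, p_indel, p_tot = _per_site_probs(model, reference)
    runs = homopolymer_run_lengths(seq)
    rng = np.random.default_rng(seed)
    n_hp = len(model.hairpin_regions)

    reads: list[MutantRead] = []
    clean = None  # shared object fields for unmutated molecules
    idx = 0
    while idx < n:
        c = min(chunk_size, n - idx)
        U = rng.random((c, L))
        hits = U < p_tot[None, :]
        if n_hp and model.scrunch_rate > 0:
            scrunch = rng.random((c, n_hp)) < model.scrunch_rate
        else:
            scrunch = None
        flagged = np.flatnonzero(
            hits.any(axis=1) | (scrunch.any(axis=1) if scrunch is not None else False)
        )
        flag_set = set(int(x) for x in flagged)
        for m in range(c):
            mol_id = f"sim_{idx + m}"
            if m not in flag_set:
                reads.append(MutantRead(mol_id, seq, "sim", ()))
                continue
            events: list[MutationEvent] = []
            used: set[int] = set()
            if scrunch is not None:
                for h, (region, template) in enumerate(model.hairpin_regions):
                    if scrunch[m, h]:
                        for e in _scrunch_events(rng, reference, region, template):
                            events.append(e)
                            used.update(range(e.start, e.end + 1))
            for j in np.flatnonzero(hits[m]):
                pos = int(j) + 1
                if pos in used:
                    continue  # scrunch takes precedence at collision sites
                w = rng.random()
                if w < p_sub[j] / p_tot[j]:
                    alt = _sample_substitution(rng, model, seq[j])
                    events.append(MutationEvent("substitution", pos, seq[j], alt))
                else:
                    if rng.random() < model.insertion_fraction:
                        # stutter: duplicate the templating base, anchored at it
                        events.append(MutationEvent("insertion", pos, "", seq[j]))
                    else:
                        events.append(MutationEvent("deletion", pos, seq[j], ""))
                used.add(pos)
            events.sort(key=lambda e: (e.position, e.kind != "insertion"))
            product = apply_events(seq, events)
            reads.append(MutantRead(mol_id, product, "sim", tuple(events)))
        idx += c
    return reads


# ---------------------------------------------------------------------------
# colony screening
# ---------------------------------------------------------------------------


def _event_detectable(e: MutationEvent, detectable: frozenset[int] | None) -> bool:
    if detectable is None:
        return True
    return any(p in detectable for p in range(e.start, e.end + 1))


def simulate_colony_assay(
    products: list[MutantRead],
    reference: ReferenceTarget,
    config: AssaySimConfig,
) -> tuple[ColonyCounts, list[MutantRead]]:
    """Score products as colonies and sample mutants for sequencing.

    A product scores mutant iff it carries >=1 event overlapping a detectable
    site AND an independent expression draw (probability expression_p)
    succeeds. Background mutants are added as a binomial draw at background_mf
    over the non-mutant products. Returns counts plus a uniform
    without-replacement sample of n_sequenced mutant products.
    """
    rng = np.random.default_rng(config.seed)
    detectable = config.detectability
    candidates = [
        i
        for i, r in enumerate(products)
        if r.events and any(_event_detectable(e, detectable) for e in r.events)
    ]
    expressed = rng.random(len(candidates)) < config.expression_p
    mutant_idx = [i for i, ok in zip(candidates, expressed) if ok]
    n_background = int(
        rng.binomial(len(products) - len(mutant_idx), config.background_mf)
    )
    counts = ColonyCounts(
        total_colonies=len(products),
        mutant_colonies=len(mutant_idx) + n_background,
        background_mf=config.background_mf,
    )
    k = config.n_sequenced
    if k >= len(mutant_idx):
        if k > len(mutant_idx):
            logger.warning(
                "requested %d sequenced mutants but only %d available; returning all",
                k,
                len(mutant_idx),
            )
        sampled_idx = mutant_idx
    else:
        sampled_idx = sorted(rng.choice(mutant_idx, size=k, replace=False).tolist())
    return counts, [products[i] for i in sampled_idx]


def recover_error_rate(counts: ColonyCounts, params: GapAssayParams) -> float:
    """Close the loop: colony counts -> corrected MF -> errors per base."""
    return error_rate_gap_assay(corrected_mutation_frequency(counts), params)


# ---------------------------------------------------------------------------
# calibration preset
# ---------------------------------------------------------------------------

#: 64-nt reference used by the calibration preset; near-balanced composition
#: with a CG-rich stretch and short T runs but no long STR. Class weights are
#: normalized per templating-base count, so preset class proportions are exact
#: for any composition.
PRESET_REFERENCE_SEQUENCE = (
    "ATGCCGCGTTACGCATCAGGCTAGTTGACGCAGATCCGTAACTGGATTCCATGAGTCTAGCTAC"
)

#: lacZ-alpha class-count calibration (substitution classes, insertions,
#: deletions) used to weight the preset's error channels.
PRESET_CLASS_COUNTS = {
    "A→T/T→A": 1,
    "A→C/T→G": 2,
    "A→G/T→C": 0,
    "G→A/C→T": 24,
    "G→C/C→G": 4,
    "G→T/C→A": 2,
}
PRESET_INSERTIONS = 20
PRESET_DELETIONS = 42

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def model_from_dict(payload: dict) -> PolymeraseErrorModel:
    """Build a model from a parsed JSON/YAML mapping.

    hairpin_regions entries are [[start, end], template] with 1-based
    inclusive loop coordinates.
    """
    if not isinstance(payload, dict):
        raise InputError("model config must be a mapping")
    known = {
        "substitution_rates", "indel_rate", "slippage_base", "slippage_growth",
        "insertion_fraction", "scrunch_rate", "hairpin_regions", "seed",
    }
    unknown = set(payload) - known
    if unknown:
        raise InputError(f"unknown model config keys: {sorted(unknown)}")
    kwargs = dict(payload)
    if "hairpin_regions" in kwargs:
        regions = []
        for i, entry in enumerate(kwargs["hairpin_regions"]):
            try:
                (start, end), template = entry
                regions.append((Region(f"hairpin_{i}", int(start), int(end)),
                                str(template).upper()))
            except (TypeError, ValueError) as exc:
                raise InputError(
                    f"hairpin_regions[{i}]: expected [[start, end], template]"
                ) from exc
        kwargs["hairpin_regions"] = tuple(regions)
    return PolymeraseErrorModel(**kwargs)


def primpol_lacz_model(
    error_rate: float = 1.0e-4,
    reference_sequence: str = PRESET_REFERENCE_SEQUENCE,
) -> tuple[PolymeraseErrorModel, ReferenceTarget]:
    """Calibration preset: per-site rates scaled so the mean per-base event
    probability equals ``error_rate`` and event-class proportions match the
    lacZ-alpha gap spectrum (substitutions 33/95 split per class, insertions
    20/95, deletions 42/95). A calibration target, not a mechanistic claim.
    """
    reference = ReferenceTarget(id="preset_target", sequence=reference_sequence)
    seq = reference.sequence
    L = len(seq)
    base_counts = {b: seq.count(b) for b in BASES}

    # per-class per-site weight so summed class intensity tracks class counts
    sub_rates: dict[str, dict[str, float]] = {b: {} for b in BASES}
    for label, count in PRESET_CLASS_COUNTS.items():
        if count == 0:
            continue
        ref_b, alt_b = label[0], label[2]  # purine-templated reading
        n_sites = base_counts[ref_b] + base_counts[COMPLEMENT[ref_b]]
        w = count / n_sites  # intensity per site of this class
        sub_rates[ref_b][alt_b] = sub_rates[ref_b].get(alt_b, 0.0) + w
        sub_rates[COMPLEMENT[ref_b]][COMPLEMENT[alt_b]] = (
            sub_rates[COMPLEMENT[ref_b]].get(COMPLEMENT[alt_b], 0.0) + w
        )
    # substitution weights sum (over sites) to the total substitution count (33)
    indel_weight = (PRESET_INSERTIONS + PRESET_DELETIONS) / L  # per site

    total_weight = (
        sum(
            sum(sub_rates[b].values()) * base_counts[b] for b in BASES
        )
        + indel_weight * L
    )
    scale = error_rate * L / total_weight
    sub_rates = {
        b: {a: r * scale for a, r in alts.items()} for b, alts in sub_rates.items()
    }
    model = PolymeraseErrorModel(
        substitution_rates=sub_rates,
        indel_rate=indel_weight * scale,
        slippage_base=indel_weight * scale,  # runs behave like ordinary sites
        slippage_growth=1.0,
        insertion_fraction=PRESET_INSERTIONS / (PRESET_INSERTIONS + PRESET_DELETIONS),
    )
    return model, reference
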