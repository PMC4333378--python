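"""Fidelity statistics for forward-mutation reporter assays.

Corrected mutant frequency and gap-assay error rate (lacZ-alpha style),
observed-frequency background subtraction, the multiple-error correction
Pol EF_est, class-partitioned error frequencies with zero-count upper bounds,
and fold comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .calling import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColonyCounts:
    total_colonies: int
    mutant_colonies: int
    background_mf: float

    def __post_init__(self) -> None:
        if self.total_colonies < 0 or self.mutant_colonies < 0:
            raise InputError("colony counts must be non-negative")
        if self.mutant_colonies > self.total_colonies:
            raise InputError("mutant colonies exceed total colonies")
        if not (0 <= self.background_mf < 1):
            raise InputError("background frequency must lie in [0, 1)")


@dataclass(frozen=True)
class GapAssayParams:
    """Error-rate conversion parameters: detectable sites D, expression
    frequency P, and the synthesis-opportunity ratio Ni/N (default 1)."""

    D: int
    P: float
    NiN: float = 1.0

    def __post_init__(self) -> None:
        if self.D < 1:
            raise InputError("D must be >= 1")
        if not (0 < self.P <= 1):
            raise InputError("P must lie in (0, 1]")
        if not self.NiN > 0:
            raise InputError("Ni/N must be > 0")


@dataclass(frozen=True)
class ErrorMultiplicity:
    """How many mutants carried n = 1, 2, 3 independent detectable error
    groups (groups beyond 3 are folded into n = 3 on construction)."""

    counts: dict[int, int]
    total_mutants: int

    def __post_init__(self) -> None:
        folded: dict[int, int] = {}
        for n, c in self.counts.items():
            if n < 1 or c < 0:
                raise InputError("multiplicity counts must map n>=1 to counts>=0")
            key = min(n, 3)
            if n > 3:
                logger.warning("folding %d mutants with n=%d errors into n=3", c, n)
            folded[key] = folded.get(key, 0) + c
        object.__setattr__(self, "counts", folded)
        if sum(folded.values()) != self.total_mutants:
            raise InputError("multiplicity counts do not sum to total_mutants")

    @classmethod
    def from_counts(cls, counts: dict[int, int]) -> "ErrorMultiplicity":
        return cls(dict(counts), sum(counts.values()))


@dataclass(frozen=True)
class FidelityResult:
    corrected_mf: float | None = None
    error_rate: float | None = None
    pol_ef: float | None = None
    pol_ef_est: float | None = None
    class_frequencies: dict[str, tuple[float, bool]] | None = None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def corrected_mutation_frequency(counts: ColonyCounts) -> float:
    """(mutant / total) - background, clamped at zero."""
    if counts.total_colonies == 0:
        raise InputError("total_colonies must be >= 1")
    raw = counts.mutant_colonies / counts.total_colonies - counts.background_mf
    if raw < 0:
        logger.warning("corrected frequency negative (%.3g); clamped to 0", raw)
        return 0.0
    return raw


def error_rate_gap_assay(corrected_mf: float, params: GapAssayParams) -> float:
    """Errors per base incorporated: corrected MF / (D * P * Ni/N)."""
    divisor = params.D * params.P * params.NiN
    if divisor <= 0:
        raise InputError("non-positive D*P*NiN divisor")
    return corrected_mf / divisor


def pol_error_frequency(observed_mf: float, ssdna_background: float) -> float:
    """Observed reporter frequency minus the ssDNA background, clamped at 0."""
    if observed_mf < 0 or ssdna_background < 0:
        raise InputError("frequencies must be non-negative")
    return max(0.0, observed_mf - ssdna_background)


def multiplicity_denominator(multiplicity: ErrorMultiplicity) -> float:
    """sum over n = 1..3 of (1/n) * (mutants with n errors / total mutants)."""
    if multiplicity.total_mutants < 1:
        raise InputError("total_mutants must be >= 1")
    if not any(c > 0 for c in multiplicity.counts.values()):
        raise InputError("at least one multiplicity count must be positive")
    return sum(
        (1.0 / n) * (multiplicity.counts.get(n, 0) / multiplicity.total_mutants)
        for n in (1, 2, 3)
    )


def pol_ef_est(pol_ef: float, multiplicity: ErrorMultiplicity) -> float:
    """Multiple-error-corrected polymerase error frequency.

    Divides the background-subtracted error frequency by the mean reciprocal
    error count, so mutants carrying several independent errors (>10 nt apart)
    are not under-counted. The denominator lies in (0, 1], hence
    pol_ef_est >= pol_ef always.
    """
    return pol_ef / multiplicity_denominator(multiplicity)


def class_error_frequency(
    parent_ef: float, class_count: int, total_count: int
) -> tuple[float, bool]:
    """Apportion a parent error frequency to one mutation class.

    With observed events the frequency is parent * class/total; with zero
    observations the one-event upper bound parent * 1/total is returned and
    flagged (matching how zero-count class rows are printed as '<' bounds).
    """
    if total_count < 1:
        raise InputError("total_count must be >= 1")
    if not (0 <= class_count <= total_count):
        raise InputError("class_count must lie in [0, total_count]")
    if class_count == 0:
        return parent_ef / total_count, True
    return parent_ef * class_count / total_count, False


def fold_change(a: float, b: float) -> float:
    """a / b; returns inf (with a warning) when b == 0 and a > 0."""
    if b == 0:
        if a == 0:
            return 0.0
        logger.warning("fold change with zero denominator reported as infinite")
        return math.inf
    return a / b


# ---------------------------------------------------------------------------
# rendering helpers (printed-precision arithmetic)
# ---------------------------------------------------------------------------


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def round_at_exponent(x: float, exponent: int, decimals: int = 1) -> float:
    """Round the mantissa of x at a fixed power of ten.

    round_at_exponent(6.68e-4, -3) == 0.7e-3 — the rendering used by the
    published frequency tables, which fix one exponent per column.
    """
    scale = 10.0**exponent
    return round(x / scale, decimals) * scale


def format_scientific(x: float, sig: int = 2) -> str:
    """Human-table rendering, e.g. '1.6 × 10^-3'."""
    if x == 0:
        return "0"
    if math.isinf(x):
        return "inf"
    exp = int(math.floor(math.log10(abs(x))))
    mant = x / 10.0**exp
    mant = round(mant, sig - 1)
    if abs(mant) >= 10:  # rounding overflow, e.g. 9.97 -> 10.0
        mant /= 10
        exp += 1
    return f"{mant:.{sig - 1}f} × 10^{exp}"


def gap_assay_table(
    rows: dict[str, ColonyCounts],
    params: GapAssayParams,
    mf_exponent: int = -3,
) -> dict[str, FidelityResult]:
    """Reproduce the printed gap-assay workflow for a table of samples.

    The corrected mutation frequency is computed at full precision, then
    rounded at the table's fixed exponent (one decimal at 10^-3 by default)
    *before* conversion to an error rate — matching how the published error
    rates were derived from the printed corrected frequencies.
    """
    out: dict[str, FidelityResult] = {}
    for sample, counts in rows.items():
        mf = corrected_mutation_frequency(counts)
        mf_printed = round_at_exponent(mf, mf_exponent)
        out[sample] = FidelityResult(
            corrected_mf=mf,
            error_rate=error_rate_gap_assay(mf_printed, params),
        )
    return out
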