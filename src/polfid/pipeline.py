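"""End-to-end pipeline orchestration: call -> spectrum -> fidelity."""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .calling import (
    InputError,
    MutantRead,
    ReferenceTarget,
    call_read,
    group_events,
    multiplicity_of,
)
from .fidelity import (
    ErrorMultiplicity,
    GapAssayParams,
    corrected_mutation_frequency,
    error_rate_gap_assay,
    format_scientific,
    pol_ef_est,
    pol_error_frequency,
)
from .io import (
    read_bed_regions,
    read_counts_tsv,
    read_mutants_fasta,
    read_reference_fasta,
    write_event_table,
    write_hotspots_tsv,
    write_json,
    write_region_tally_tsv,
    write_spectrum_tsv,
)
from .spectrum import hotspot_scan, partition_by_region, tabulate_spectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    reference_path: str
    mutants_path: str
    counts_path: str | None = None
    regions_path: str | None = None
    D: int | None = None
    P: float = 0.3
    NiN: float = 1.0
    grouping_distance: int = 10
    hotspot_alpha: float = 0.05
    outdir: str = "polfid_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grouping_distance < 0:
            raise InputError("grouping distance must be >= 0")


@dataclass
class RunReport:
    versions: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        if stage in self.stages:
            raise RuntimeError(f"stage {stage!r} recorded twice")
        self.stages[stage] = counts


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute calling, spectrum and fidelity stages and write all tables.

    All results are computed before any file is written, so an input failure
    leaves no partial output tree behind.
    """
    from dataclasses import asdict

    report = RunReport(
        versions={"polfid": __version__, "python": platform.python_version()},
        config=asdict(config),
    )

    # ---- load inputs ----
    reference = read_reference_fasta(config.reference_path)
    if config.regions_path:
        regions = read_bed_regions(config.regions_path, reference)
        reference = ReferenceTarget(
            id=reference.id, sequence=reference.sequence, regions=tuple(regions),
            detectable_sites=config.D,
        )
    elif config.D is not None:
        reference = ReferenceTarget(
            id=reference.id, sequence=reference.sequence,
            detectable_sites=config.D,
        )
    mutants = read_mutants_fasta(config.mutants_path)
    report.record("load", references=1, mutants=len(mutants),
                  regions=len(reference.regions))

    # ---- calling ----
    per_mutant: dict[str, list] = {}
    for read in mutants:
        events = call_read(reference, read)
        per_mutant[read.id] = group_events(events, config.grouping_distance)
    all_groups = list(per_mutant.values())
    all_events = [e for groups in all_groups for g in groups for e in g.events]
    report.record("call", events=len(all_events),
                  groups=sum(len(g) for g in all_groups))

    # ---- spectrum ----
    spectrum_events = tabulate_spectrum(all_groups, view="events")
    spectrum_groups = tabulate_spectrum(all_groups, view="groups")
    tally = partition_by_region(all_groups, reference)
    hotspots = hotspot_scan(all_events, max(len(mutants), 1), reference,
                            config.hotspot_alpha)
    report.record("spectrum", total_events=spectrum_events.total_events,
                  hotspots=len(hotspots))

    # ---- fidelity ----
    fidelity_payload: dict = {}
    if config.counts_path:
        counts_rows = read_counts_tsv(config.counts_path)
        D = config.D or reference.detectable_count
        params = GapAssayParams(D=D, P=config.P, NiN=config.NiN) if D else None
        multiplicity = multiplicity_of(all_groups)
        for sample, counts in counts_rows.items():
            mf = corrected_mutation_frequency(counts)
            entry: dict = {
                "corrected_mf": mf,
                "corrected_mf_printed": format_scientific(mf),
            }
            if params is not None:
                rate = error_rate_gap_assay(mf, params)
                entry["error_rate"] = rate
                entry["error_rate_printed"] = format_scientific(rate)
            observed = counts.mutant_colonies / counts.total_colonies
            ef = pol_error_frequency(observed, counts.background_mf)
            entry["pol_ef"] = ef
            if multiplicity:
                entry["pol_ef_est"] = pol_ef_est(
                    ef, ErrorMultiplicity.from_counts(multiplicity)
                )
            fidelity_payload[sample] = entry
        report.record("fidelity", samples=len(counts_rows))

    # ---- write outputs ----
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_event_table(outdir / "events.tsv", per_mutant)
    write_spectrum_tsv(outdir / "spectrum_events.tsv", spectrum_events)
    write_spectrum_tsv(outdir / "spectrum_groups.tsv", spectrum_groups)
    write_region_tally_tsv(outdir / "region_tally.tsv", tally)
    write_hotspots_tsv(outdir / "hotspots.tsv", hotspots)
    if fidelity_payload:
        write_json(outdir / "fidelity.json", fidelity_payload)
    write_json(
        outdir / "run_report.json",
        {
            "versions": report.versions,
            "config": report.config,
            "stages": report.stages,
            "warnings": report.warnings,
        },
    )
    return report
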