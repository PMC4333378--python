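"""Readers and writers: FASTA, BED regions, colony-count TSV, result tables.

All tables are tab-delimited with a header row and "." for missing values;
machine outputs use plain e-notation, human summaries use 'm.m × 10^k'.
BED input is 0-based half-open and converted to the 1-based inclusive internal
convention on read (the conversion is logged).
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .calling import (
    EventGroup,
    InputError,
    MutantRead,
    MutationEvent,
    ReferenceTarget,
    Region,
)
from .fidelity import ColonyCounts
from .spectrum import (
    SUBSTITUTION_CLASSES,
    ErrorSpectrum,
    HotspotResult,
    RegionTally,
)

logger = logging.getLogger(__name__)

MISSING = "."


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    ids = [i for i, _ in records]
    if len(ids) != len(set(ids)):
        raise InputError(f"duplicate record ids in {path}")
    return records


def read_reference_fasta(
    path: str | Path,
    regions: Sequence[Region] = (),
    detectable_sites: frozenset[int] | int | None = None,
) -> ReferenceTarget:
    records = read_fasta(path)
    if len(records) > 1:
        logger.warning("%s has %d records; using the first", path, len(records))
    rid, seq = records[0]
    return ReferenceTarget(
        id=rid, sequence=seq, regions=tuple(regions), detectable_sites=detectable_sites
    )


def read_mutants_fasta(path: str | Path) -> list[MutantRead]:
    return [MutantRead(id=rid, sequence=seq) for rid, seq in read_fasta(path)]


def read_bed_regions(path: str | Path, reference: ReferenceTarget) -> list[Region]:
    """BED (chrom, start, end, name), 0-based half-open -> 1-based inclusive."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"BED file not found: {path}")
    regions: list[Region] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise InputError(f"{path}:{lineno}: expected 4 BED columns, got {len(fields)}")
        chrom, start_s, end_s, name = fields[:4]
        if chrom != reference.id:
            raise InputError(
                f"{path}:{lineno}: chrom {chrom!r} does not match reference id "
                f"{reference.id!r}"
            )
        try:
            start0, end0 = int(start_s), int(end_s)
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: non-integer coordinates") from exc
        if not (0 <= start0 < end0 <= len(reference)):
            raise InputError(
                f"{path}:{lineno}: interval [{start0}, {end0}) outside reference "
                f"of length {len(reference)}"
            )
        logger.info(
            "BED %s [%d, %d) -> 1-based inclusive [%d, %d]",
            name, start0, end0, start0 + 1, end0,
        )
        regions.append(Region(label=name, start=start0 + 1, end=end0))
    return regions


def read_counts_tsv(path: str | Path) -> dict[str, ColonyCounts]:
    """TSV with header: sample, total, mutants, background."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"counts file not found: {path}")
    rows: dict[str, ColonyCounts] = {}
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample", "total", "mutants", "background"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(
                f"{path}: expected columns {sorted(required)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            sample = row["sample"]
            if sample in rows:
                raise InputError(f"{path}:{lineno}: duplicate sample {sample!r}")
            try:
                rows[sample] = ColonyCounts(
                    total_colonies=int(row["total"]),
                    mutant_colonies=int(row["mutants"]),
                    background_mf=float(row["background"]),
                )
            except (ValueError, InputError) as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise InputError(f"{path}: no count rows")
    return rows


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_fasta(path: str | Path, reads: Sequence[MutantRead]) -> None:
    with Path(path).open("w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")


def write_counts_tsv(path: str | Path, rows: dict[str, ColonyCounts]) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\ttotal\tmutants\tbackground\n")
        for sample, c in rows.items():
            fh.write(
                f"{sample}\t{c.total_colonies}\t{c.mutant_colonies}\t{c.background_mf:g}\n"
            )


def write_event_table(
    path: str | Path, per_mutant: dict[str, list[EventGroup]]
) -> None:
    """TSV: mutant_id, kind, position, ref_allele, alt_allele, length,
    group_id, is_complex."""
    with Path(path).open("w") as fh:
        fh.write(
            "mutant_id\tkind\tposition\tref_allele\talt_allele\tlength\t"
            "group_id\tis_complex\n"
        )
        for mutant_id, groups in per_mutant.items():
            for gi, group in enumerate(groups):
                for e in group.events:
                    fh.write(
                        f"{mutant_id}\t{e.kind}\t{e.position}\t"
                        f"{e.ref_allele or MISSING}\t{e.alt_allele or MISSING}\t"
                        f"{e.length}\t{gi}\t{str(group.is_complex).lower()}\n"
                    )


def write_spectrum_tsv(path: str | Path, spectrum: ErrorSpectrum) -> None:
    """Mutation Type / Number / Frequency (%) table plus derived rows."""
    pct = spectrum.percentages

    def fmt(label: str) -> str:
        return MISSING if pct is None else f"{pct[label]:.1f}"

    with Path(path).open("w") as fh:
        fh.write("Mutation Type\tNumber\tFrequency (%)\n")
        for label in SUBSTITUTION_CLASSES:
            fh.write(f"{label}\t{spectrum.substitution_counts[label]}\t{fmt(label)}\n")
        fh.write(f"Insertions\t{spectrum.insertions}\t{fmt('Insertions')}\n")
        fh.write(f"Deletions\t{spectrum.deletions}\t{fmt('Deletions')}\n")
        if spectrum.complex:
            fh.write(f"Complex\t{spectrum.complex}\t{fmt('Complex')}\n")
        total_pct = MISSING if pct is None else "100.0"
        fh.write(f"Total\t{spectrum.total_events}\t{total_pct}\n")
        fh.write(f"A→N/T→N\t{spectrum.at_templated}\t{fmt('A→N/T→N')}\n")
        fh.write(f"G→N/C→N\t{spectrum.gc_templated}\t{fmt('G→N/C→N')}\n")
        fh.write(f"Transitions\t{spectrum.transitions}\t{fmt('Transitions')}\n")
        fh.write(f"Transversions\t{spectrum.transversions}\t{fmt('Transversions')}\n")


def write_region_tally_tsv(path: str | Path, tally: RegionTally) -> None:
    with Path(path).open("w") as fh:
        fh.write("region\tgroup_count\tevent_count\n")
        for label, (g, e) in tally.regions.items():
            fh.write(f"{label}\t{g}\t{e}\n")
        fh.write(f"unassigned\t{tally.unassigned[0]}\t{tally.unassigned[1]}\n")


def write_hotspots_tsv(path: str | Path, hits: Sequence[HotspotResult]) -> None:
    with Path(path).open("w") as fh:
        fh.write("# exploratory scan: binomial test vs uniform null, BH-corrected\n")
        fh.write("position\tevent_count\texpected_count\tp_value\tq_value\n")
        for h in hits:
            fh.write(
                f"{h.position}\t{h.event_count}\t{h.expected_count:.4g}\t"
                f"{h.p_value:.4g}\t{h.q_value:.4g}\n"
            )


def read_model_config(path: str | Path):
    """Load a simulator model from a YAML or JSON file (YAML parses both)."""
    import yaml

    from .simulate import model_from_dict

    path = Path(path)
    if not path.exists():
        raise InputError(f"model config not found: {path}")
    try:
        payload = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise InputError(f"{path}: malformed YAML/JSON ({exc})") from exc
    return model_from_dict(payload)


def write_json(path: str | Path, payload: dict) -> None:
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2, ensure_ascii=False, sort_keys=True)
        fh.write("\n")
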