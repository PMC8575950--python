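"""Genome annotation and mobility-table I/O.

Reads circular genome annotations (GenBank or GFF3+FASTA) into a uniform
0-based, wrap-aware representation; classifies ORFs into accessory vs core
cargo with explicit, reproducible rules (the printed tables' accessory calls
were manual, so rule sets carry id lists and/or product-keyword patterns);
counts ORFs inside headful windows with half-weighting of boundary
straddlers; and round-trips the mobility-record CSV / ledger TSV+JSON
formats.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .geometry import AttBSite, CircularInterval, GenomicLocus
from .metrics import (
    CargoAnnotation,
    LedgerRow,
    MobilityRecord,
    TransferFrequency,
    ValidationError,
)
from .render import ND, as_fraction, count_string, rate_string


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Orf:
    orf_id: str
    span: CircularInterval
    strand: int
    product: str = ""
    orf_class: str = "unassigned"  # accessory | core | unassigned


@dataclass
class AnnotatedGenome:
    genome_id: str
    length: int
    circular: bool
    orfs: list[Orf] = field(default_factory=list)
    attb_sites: list[AttBSite] = field(default_factory=list)
    loci: list[GenomicLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [o.orf_id for o in self.orfs]
        if len(ids) != len(set(ids)):
            raise AnnotationError(f"{self.genome_id}: duplicate ORF ids")
        for orf in self.orfs:
            if orf.span.genome_length != self.length:
                raise AnnotationError(
                    f"{self.genome_id}: ORF {orf.orf_id} on wrong genome length"
                )


@dataclass(frozen=True)
class AccessoryRuleSet:
    """Reproducible accessory-ORF classification rules.

    Precedence: exclude_ids > include_ids > keyword match on the product
    text (case-insensitive substring/regex).
    """

    keyword_patterns: tuple[str, ...] = ()
    include_ids: frozenset[str] = frozenset()
    exclude_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "keyword_patterns", tuple(self.keyword_patterns))
        object.__setattr__(self, "include_ids", frozenset(self.include_ids))
        object.__setattr__(self, "exclude_ids", frozenset(self.exclude_ids))
        if self.include_ids & self.exclude_ids:
            raise ValidationError("include_ids and exclude_ids must be disjoint")

    def matches(self, orf: Orf) -> bool:
        if orf.orf_id in self.exclude_ids:
            return False
        if orf.orf_id in self.include_ids:
            return True
        return any(
            re.search(pat, orf.product, flags=re.IGNORECASE)
            for pat in self.keyword_patterns
        )


#: Product keywords typical of host-utilisable cargo (virulence factors,
#: AMR genes and the like); used by default for synthetic annotations.
DEFAULT_ACCESSORY_KEYWORDS: tuple[str, ...] = (
    "toxin",
    "enterotoxin",
    "leukotoxin",
    "resistance",
    "virulence",
    "adhesin",
    "lipoprotein",
)

DEFAULT_RULES = AccessoryRuleSet(keyword_patterns=DEFAULT_ACCESSORY_KEYWORDS)


# ---------------------------------------------------------------------------
# genome annotation readers


def _orf_class_from_notes(notes: Sequence[str]) -> str:
    for note in notes:
        m = re.search(r"orf_class:(\w+)", note)
        if m:
            return m.group(1)
    return "unassigned"


def _read_genbank(path: Path) -> AnnotatedGenome:
    record = SeqIO.read(str(path), "genbank")
    length = len(record.seq)
    if length == 0:
        raise AnnotationError(f"{path}: record has no sequence length")
    circular = record.annotations.get("topology", "") == "circular"
    orfs: list[Orf] = []
    for i, feature in enumerate(record.features):
        if feature.type != "CDS":
            continue
        loc = feature.location
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 2 and int(parts[1].end) == length and int(parts[0].start) == 0:
            # origin-spanning CDS: tail piece at the end, head piece at 0
            start = int(parts[1].start)
            span_len = (length - start) + int(parts[0].end)
        elif len(parts) == 1:
            start = int(loc.start)
            span_len = int(loc.end) - int(loc.start)
        else:
            raise AnnotationError(f"{path}: unsupported compound CDS location {loc}")
        quals = feature.qualifiers
        orf_id = (
            quals.get("locus_tag", [None])[0]
            or quals.get("protein_id", [None])[0]
            or f"cds{i:04d}"
        )
        orfs.append(
            Orf(
                orf_id=orf_id,
                span=CircularInterval(start, span_len, length),
                strand=int(loc.strand or 1),
                product=quals.get("product", [""])[0],
                orf_class=_orf_class_from_notes(quals.get("note", [])),
            )
        )
    return AnnotatedGenome(record.id or path.stem, length, circular, orfs)


def _read_gff3(path: Path, fasta: Path) -> AnnotatedGenome:
    import gffutils

    seq_record = SeqIO.read(str(fasta), "fasta")
    length = len(seq_record.seq)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    circular = False
    for region in db.features_of_type("region"):
        if region.attributes.get("Is_circular", ["false"])[0].lower() == "true":
            circular = True
    # group CDS segments by their declared ID: an origin-spanning ORF is two
    # lines sharing one ID, the first ending at L and the second starting at 1
    segments: dict[str, list] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS"):
        fid = feat.attributes["ID"][0]
        if fid not in segments:
            segments[fid] = []
            order.append(fid)
        segments[fid].append(feat)
    orfs: list[Orf] = []
    for fid in order:
        feats = segments[fid]
        first = feats[0]
        strand = -1 if first.strand == "-" else 1
        if len(feats) == 1:
            start = first.start - 1
            span_len = first.end - first.start + 1
        elif len(feats) == 2:
            tail = next((f for f in feats if f.end == length), None)
            head = next((f for f in feats if f.start == 1), None)
            if tail is None or head is None:
                raise AnnotationError(
                    f"{path}: CDS {fid} split but not across the origin"
                )
            start = tail.start - 1
            span_len = (length - start) + head.end
        else:
            raise AnnotationError(f"{path}: CDS {fid} has >2 segments")
        orfs.append(
            Orf(
                orf_id=fid,
                span=CircularInterval(start, span_len, length),
                strand=strand,
                product=first.attributes.get("product", [""])[0],
                orf_class=_orf_class_from_notes(first.attributes.get("note", [])),
            )
        )
    return AnnotatedGenome(seq_record.id or path.stem, length, circular, orfs)


def read_genome_annotation(
    path: str | Path,
    format: str = "genbank",
    fasta: str | Path | None = None,
) -> AnnotatedGenome:
    """Read a circular genome annotation into the uniform representation.

    ``format`` is "genbank" or "gff3"; GFF3 requires the companion FASTA for
    the sequence length.  Coordinates are converted to 0-based half-open and
    origin-spanning CDS features become single wrapped intervals.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"no such file: {path}")
    if format == "genbank":
        return _read_genbank(path)
    if format in ("gff3", "gff3+fasta"):
        if fasta is None:
            raise AnnotationError("gff3 format needs the companion fasta=")
        return _read_gff3(path, Path(fasta))
    raise AnnotationError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# cargo classification and window counting


def classify_orfs(genome: AnnotatedGenome, rules: AccessoryRuleSet) -> CargoAnnotation:
    """Count accessory vs total ORFs under an explicit rule set."""
    if not genome.orfs:
        raise AnnotationError(f"{genome.genome_id}: no ORFs to classify")
    accessory = sum(1 for orf in genome.orfs if rules.matches(orf))
    return CargoAnnotation(Fraction(accessory), Fraction(len(genome.orfs)))


def orfs_in_window(
    genome: AnnotatedGenome,
    window: CircularInterval,
    partial_weight: Fraction | float = Fraction(1, 2),
    orf_class: Optional[str] = None,
) -> Fraction:
    """Weighted ORF count in a headful window.

    ORFs fully inside count 1; ORFs straddling a window edge count
    ``partial_weight`` (default 0.5, matching the tables' half-ORF
    convention).  ``orf_class`` optionally restricts to one class.
    """
    weight = as_fraction(partial_weight)
    if not 0 <= weight <= 1:
        raise ValidationError("partial_weight must be in [0, 1]")
    total = Fraction(0)
    for orf in genome.orfs:
        if orf_class is not None and orf.orf_class != orf_class:
            continue
        if window.contains_interval(orf.span):
            total += 1
        elif window.overlaps(orf.span):
            total += weight
    return total


def window_cargo(
    genome: AnnotatedGenome,
    window: CircularInterval,
    rules: AccessoryRuleSet = DEFAULT_RULES,
    partial_weight: Fraction | float = Fraction(1, 2),
) -> CargoAnnotation:
    """Accessory/total cargo annotation of one headful window."""
    weight = as_fraction(partial_weight)
    accessory = Fraction(0)
    total = Fraction(0)
    for orf in genome.orfs:
        if window.contains_interval(orf.span):
            w = Fraction(1)
        elif window.overlaps(orf.span):
            w = weight
        else:
            continue
        total += w
        if rules.matches(orf):
            accessory += w
    if total == 0:
        raise AnnotationError("window contains no ORFs")
    return CargoAnnotation(accessory, total)


# ---------------------------------------------------------------------------
# registries (attB sites, loci)


def read_attb_registry(path: str | Path, genome_length: int) -> list[AttBSite]:
    """CSV (site_id, position, direction {+,-}, phage_id) → attB sites."""
    sites = []
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for idx, row in frame.iterrows():
        direction = {"+": 1, "-": -1, "+1": 1, "-1": -1}.get(row["direction"].strip())
        if direction is None:
            raise AnnotationError(f"{path} row {idx + 2}: bad direction {row['direction']!r}")
        position = int(row["position"])
        if not 0 <= position < genome_length:
            raise AnnotationError(f"{path} row {idx + 2}: position out of range")
        sites.append(
            AttBSite(
                site_id=row["site_id"],
                position=position,
                direction=direction,
                occupied_by=row.get("phage_id", "") or None,
            )
        )
    return sites


def read_loci(path: str | Path, genome_length: int) -> list[GenomicLocus]:
    """CSV (locus_id, start, length, locus_class) → genomic loci."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        GenomicLocus(
            locus_id=row["locus_id"],
            span=CircularInterval(int(row["start"]), int(row["length"]), genome_length),
            locus_class=row.get("locus_class", "") or "locus",
        )
        for _, row in frame.iterrows()
    ]


# ---------------------------------------------------------------------------
# mobility record tables and ledgers

RECORD_COLUMNS = [
    "element_id",
    "accession",
    "category",
    "mechanism",
    "organism",
    "freq_lo",
    "freq_hi",
    "titre_tru_per_ml",
    "accessory_orfs",
    "total_orfs",
    "source",
]


def _fraction_or_none(cell: str) -> Optional[Fraction]:
    cell = cell.strip()
    if cell in ("", ND):
        return None
    return as_fraction(cell)


def read_mobility_records(path: str | Path) -> list[MobilityRecord]:
    """Read the mobility-record CSV schema; empty cells mean ND.

    Extra columns (printed values, discrepancy flags in the packaged
    fixtures) are ignored.  Schema violations are reported with their row
    number.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records: list[MobilityRecord] = []
    for idx, row in frame.iterrows():
        rownum = idx + 2  # 1-based incl. header
        try:
            freq_lo = _fraction_or_none(row["freq_lo"])
            freq_hi = _fraction_or_none(row["freq_hi"])
            titre = _fraction_or_none(row["titre_tru_per_ml"])
            if freq_lo is not None:
                frequency = TransferFrequency.range(
                    freq_lo, freq_hi if freq_hi is not None else freq_lo
                )
            else:
                frequency = None
            acc = _fraction_or_none(row["accessory_orfs"])
            tot = _fraction_or_none(row["total_orfs"])
            cargo = CargoAnnotation(acc, tot) if acc is not None and tot is not None else None
            records.append(
                MobilityRecord(
                    element_id=row["element_id"],
                    accession=row["accession"],
                    category=row["category"],
                    mechanism=row["mechanism"],
                    organism=row["organism"],
                    frequency=frequency,
                    titre=titre,
                    cargo=cargo,
                    source=row["source"],
                )
            )
        except (ValidationError, ValueError, ArithmeticError) as exc:
            raise ValidationError(f"{path} row {rownum}: {exc}") from exc
    return records


def _fraction_cell(value: Optional[Fraction]) -> str:
    if value is None:
        return ""
    f = as_fraction(value)
    # exact decimal when the denominator is 2^a·5^b, else num/den
    den = f.denominator
    while den % 2 == 0:
        den //= 2
    while den % 5 == 0:
        den //= 5
    if den == 1:
        from decimal import Decimal

        return str(Decimal(f.numerator) / Decimal(f.denominator))
    return f"{f.numerator}/{f.denominator}"


def write_mobility_records(records: Sequence[MobilityRecord], path: str | Path) -> None:
    """Write records back to the CSV schema (lossless round-trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.element_id,
                    r.accession,
                    r.category,
                    r.mechanism,
                    r.organism,
                    _fraction_cell(r.frequency.lo if r.frequency else None),
                    _fraction_cell(
                        r.frequency.hi
                        if r.frequency and r.frequency.is_range
                        else None
                    ),
                    _fraction_cell(r.titre),
                    _fraction_cell(r.cargo.accessory_orfs if r.cargo else None),
                    _fraction_cell(r.cargo.total_orfs if r.cargo else None),
                    r.source,
                ]
            )


def write_ledger(
    rows: Sequence[LedgerRow],
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write a ledger as table-styled TSV and (optionally) full-precision JSON."""
    from .metrics import render_cargo_cell

    header = [
        "element_id",
        "accession",
        "category",
        "mechanism",
        "organism",
        "transfer_frequency",
        "cargo_capacity_rate",
        "relative_mobility",
        "rank_by_frequency",
        "rank_by_mobility",
        "source",
    ]
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(header)
        for row in rows:
            writer.writerow(
                [
                    row.record.element_id,
                    row.record.accession,
                    row.record.category,
                    row.record.mechanism,
                    row.record.organism,
                    row.frequency.render(),
                    render_cargo_cell(row),
                    row.relative_mobility.render() if row.relative_mobility else ND,
                    row.rank_by_frequency,
                    row.rank_by_mobility,
                    row.record.source,
                ]
            )
    if json_path is not None:
        payload = []
        for row in rows:
            rm = row.relative_mobility
            payload.append(
                {
                    "element_id": row.record.element_id,
                    "accession": row.record.accession,
                    "category": row.record.category,
                    "mechanism": row.record.mechanism,
                    "organism": row.record.organism,
                    "frequency_lo": float(row.frequency.lo),
                    "frequency_hi": float(row.frequency.hi),
                    "cargo_rate": float(row.cargo_rate) if row.cargo_rate is not None else None,
                    "accessory_orfs": count_string(row.record.cargo.accessory_orfs)
                    if row.record.cargo
                    else None,
                    "total_orfs": count_string(row.record.cargo.total_orfs)
                    if row.record.cargo
                    else None,
                    "cargo_rate_2dp": rate_string(row.cargo_rate)
                    if row.cargo_rate is not None
                    else None,
                    "relative_mobility_lo": float(rm.lo) if rm else None,
                    "relative_mobility_hi": float(rm.hi) if rm else None,
                    "rank_by_frequency": row.rank_by_frequency,
                    "rank_by_mobility": row.rank_by_mobility,
                    "source": row.record.source,
                }
            )
        Path(json_path).write_text(json.dumps(payload, indent=2))
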