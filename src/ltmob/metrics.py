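"""Comparative horizontal-gene-transfer mobility statistics.

Three statistics put phage-, island-, plasmid- and transposon-mediated
transfer on one scale:

* **Transfer frequency (TE/donor)** — transductant/lysogen titres (TrU/ml)
  divided by the donor population density (CFU/ml) at induction, so that
  transduction and conjugation rates become comparable.
* **Cargo capacity rate** — accessory ORFs utilisable by the recipient
  divided by total ORFs in the transferred sequence, kept as an exact
  fraction (half-ORF counts arise when a headful boundary cuts an ORF).
* **Relative frequency of genetic mobility** — transfer frequency × cargo
  capacity rate, the composite statistic ranking how much useful DNA each
  element actually moves per donor cell.

All arithmetic is exact-rational; rendering to the tables' 3-significant-
figure / 2-decimal style is a separate step (see :mod:`ltmob.render`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from .render import as_fraction, rate_string, round_sig, sci_notation


class ValidationError(ValueError):
    pass


CATEGORIES = ("plasmid", "phage", "PICI", "ICE", "chromosomal_marker")

#: category → mechanisms seen in the comparative tables
CATEGORY_MECHANISMS: dict[str, frozenset[str]] = {
    "plasmid": frozenset({"conjugation", "mobilisation", "GT"}),
    "phage": frozenset({"lysogenisation"}),
    "PICI": frozenset({"PICI_transfer"}),
    "ICE": frozenset({"conjugation"}),
    "chromosomal_marker": frozenset({"GT", "LT"}),
}


@dataclass(frozen=True)
class DonorCalibration:
    """Optical-density landmark → donor CFU/ml conversion for titre normalisation."""

    organism_label: str
    od_landmark: float
    donor_cfu_per_ml: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "donor_cfu_per_ml", as_fraction(self.donor_cfu_per_ml))
        if self.donor_cfu_per_ml <= 0:
            raise ValidationError("donor_cfu_per_ml must be positive")


# S. aureus lysogens induced at OD540 0.15 (6.5e7 CFU/ml); Salmonella at
# OD600 0.20 (1.0e8 CFU/ml).
S_AUREUS_CALIBRATION = DonorCalibration("s_aureus", 0.15, Fraction(65_000_000))
SALMONELLA_CALIBRATION = DonorCalibration("salmonella", 0.20, Fraction(100_000_000))

DEFAULT_CALIBRATIONS: dict[str, DonorCalibration] = {
    "s_aureus": S_AUREUS_CALIBRATION,
    "salmonella": SALMONELLA_CALIBRATION,
}


@dataclass(frozen=True)
class TransferFrequency:
    """A transfer frequency in TE/donor: a point value or a closed range."""

    lo: Fraction
    hi: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", as_fraction(self.lo))
        object.__setattr__(self, "hi", as_fraction(self.hi))
        if self.lo < 0:
            raise ValidationError("transfer frequency must be non-negative")
        if self.hi < self.lo:
            raise ValidationError("stored as lo <= hi")

    @classmethod
    def point(cls, value) -> "TransferFrequency":
        f = as_fraction(value)
        return cls(f, f)

    @classmethod
    def range(cls, a, b) -> "TransferFrequency":
        fa, fb = as_fraction(a), as_fraction(b)
        return cls(min(fa, fb), max(fa, fb))

    @property
    def is_range(self) -> bool:
        return self.lo != self.hi

    def scale(self, factor: Fraction) -> "TransferFrequency":
        factor = as_fraction(factor)
        if factor < 0:
            raise ValidationError("scale factor must be non-negative")
        return TransferFrequency(self.lo * factor, self.hi * factor)

    def render(self, sig: int = 3, hi_first: bool = True) -> str:
        """Table-style string, ranges printed high-to-low by default."""
        if not self.is_range:
            return sci_notation(self.lo, sig)
        first, second = (self.hi, self.lo) if hi_first else (self.lo, self.hi)
        return f"{sci_notation(first, sig)} to {sci_notation(second, sig)}"


@dataclass(frozen=True)
class CargoAnnotation:
    """Accessory / total ORF counts of a transferred sequence (0.5 granularity)."""

    accessory_orfs: Fraction
    total_orfs: Fraction

    def __post_init__(self) -> None:
        acc = as_fraction(self.accessory_orfs)
        tot = as_fraction(self.total_orfs)
        object.__setattr__(self, "accessory_orfs", acc)
        object.__setattr__(self, "total_orfs", tot)
        if tot <= 0:
            raise ValidationError("total_orfs must be positive")
        if not 0 <= acc <= tot:
            raise ValidationError("need 0 <= accessory_orfs <= total_orfs")
        for value, name in ((acc, "accessory_orfs"), (tot, "total_orfs")):
            if (value * 2).denominator != 1:
                raise ValidationError(f"{name} must be a multiple of 0.5, got {value}")


@dataclass(frozen=True)
class MobilityRecord:
    """One genetic element or chromosomal marker in the comparative ledger.

    Exactly one of ``frequency`` (TE/donor, possibly a range) or ``titre``
    (TrU/ml, to be normalised with the organism's donor calibration) must be
    given.  ``cargo`` is None when the paper reports ND.
    """

    element_id: str
    accession: str
    category: str
    mechanism: str
    organism: str
    frequency: Optional[TransferFrequency]
    titre: Optional[Fraction]
    cargo: Optional[CargoAnnotation]
    source: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_MECHANISMS:
            raise ValidationError(
                f"{self.element_id}: unknown category {self.category!r}"
            )
        if self.mechanism not in CATEGORY_MECHANISMS[self.category]:
            raise ValidationError(
                f"{self.element_id}: mechanism {self.mechanism!r} not valid "
                f"for category {self.category!r}"
            )
        if (self.frequency is None) == (self.titre is None):
            raise ValidationError(
                f"{self.element_id}: exactly one of frequency or titre required"
            )
        if self.titre is not None:
            object.__setattr__(self, "titre", as_fraction(self.titre))
            if self.titre < 0:
                raise ValidationError(f"{self.element_id}: titre must be non-negative")


@dataclass(frozen=True)
class LedgerRow:
    record: MobilityRecord
    frequency: TransferFrequency  # resolved table value (TE/donor)
    cargo_rate: Optional[Fraction]
    relative_mobility: Optional[TransferFrequency]
    rank_by_frequency: int
    rank_by_mobility: int


def normalize_transfer_frequency(titre, calibration: DonorCalibration) -> Fraction:
    """TrU/ml → TE per donor cell at full precision (titre / donor CFU/ml)."""
    t = as_fraction(titre)
    if t < 0:
        raise ValidationError("titre must be non-negative")
    if calibration.donor_cfu_per_ml <= 0:
        raise ValidationError("calibration must have positive CFU/ml")
    return t / calibration.donor_cfu_per_ml


def summarize_replicates(titres: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n−1) of replicate titres."""
    values = [float(t) for t in titres]
    if not values:
        raise ValidationError("need at least one replicate")
    if any(v < 0 for v in values):
        raise ValidationError("titres must be non-negative")
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    ss = sum((v - mean) ** 2 for v in values)
    return mean, math.sqrt(ss / (n - 1))


def cargo_capacity_rate(cargo: CargoAnnotation) -> Fraction:
    """Exact accessory/total ORF fraction in (0, 1]."""
    return cargo.accessory_orfs / cargo.total_orfs


def relative_mobility(
    frequency: TransferFrequency, cargo: Optional[CargoAnnotation]
) -> Optional[TransferFrequency]:
    """Transfer frequency × exact cargo fraction; ND cargo propagates ND (None)."""
    if cargo is None:
        return None
    return frequency.scale(cargo_capacity_rate(cargo))


def _table_frequency(
    record: MobilityRecord, calibrations: Mapping[str, DonorCalibration]
) -> TransferFrequency:
    """The TE/donor value as the comparative tables carry it.

    Literature rows are taken as printed; titre-based rows are normalised
    and then rounded to 3 significant figures, because the table column (and
    every derived cell downstream of it) holds the rounded value.
    """
    if record.frequency is not None:
        return record.frequency
    try:
        cal = calibrations[record.organism]
    except KeyError:
        raise ValidationError(
            f"{record.element_id}: no donor calibration for organism "
            f"{record.organism!r}"
        ) from None
    full = normalize_transfer_frequency(record.titre, cal)
    return TransferFrequency.point(Fraction(round_sig(full, 3)))


def _dense_ranks(keys: Sequence[Optional[Fraction]]) -> list[int]:
    """Dense ranks, descending; None keys all share the last rank."""
    present = sorted({k for k in keys if k is not None}, reverse=True)
    rank_of = {k: i + 1 for i, k in enumerate(present)}
    nd_rank = len(present) + 1
    return [rank_of[k] if k is not None else nd_rank for k in keys]


def build_mobility_ledger(
    records: Sequence[MobilityRecord],
    calibrations: Mapping[str, DonorCalibration] | None = None,
) -> list[LedgerRow]:
    """Assemble the comparative ledger: frequencies, cargo rates, relative
    mobilities and dense ranks.

    Rows are returned in canonical order (descending upper frequency
    endpoint, ties broken by element id), so the result is invariant to the
    input permutation.  Ranks are dense on the upper endpoint; rows with ND
    mobility rank last.
    """
    if calibrations is None:
        calibrations = DEFAULT_CALIBRATIONS
    resolved: list[tuple[MobilityRecord, TransferFrequency, Optional[Fraction], Optional[TransferFrequency]]] = []
    for record in records:
        freq = _table_frequency(record, calibrations)
        rate = cargo_capacity_rate(record.cargo) if record.cargo is not None else None
        rm = relative_mobility(freq, record.cargo)
        resolved.append((record, freq, rate, rm))
    resolved.sort(key=lambda item: (-item[1].hi, item[0].element_id))
    freq_ranks = _dense_ranks([freq.hi for _, freq, _, _ in resolved])
    mob_ranks = _dense_ranks(
        [rm.hi if rm is not None else None for _, _, _, rm in resolved]
    )
    return [
        LedgerRow(record, freq, rate, rm, fr, mr)
        for (record, freq, rate, rm), fr, mr in zip(resolved, freq_ranks, mob_ranks)
    ]


def render_cargo_cell(row: LedgerRow) -> str:
    """Table-style cargo cell, e.g. "0.15 (4/26)" or "ND"."""
    from .render import ND, count_string

    cargo = row.record.cargo
    if cargo is None:
        return ND
    return (
        f"{rate_string(row.cargo_rate)} "
        f"({count_string(cargo.accessory_orfs)}/{count_string(cargo.total_orfs)})"
    )
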