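"""Synthetic inputs with known ground truth.

Emulates the structures the analysis assumes — circular bacterial
chromosomes (the real systems are the ~2.8 Mb S. aureus and ~4.9 Mb
S. Typhimurium chromosomes) carrying annotated ORFs split into accessory and
core classes, attB sites with packaging directions, and selectable markers
placed at chosen headful distances — plus element panels with known transfer
frequencies and cargo fractions.  Sequence content is random A/C/G/T: the
geometry and the counts are what the consuming analyses use, not motifs.

Everything is deterministic for a seed, down to byte-identical output files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .annotations import AnnotatedGenome, Orf
from .geometry import (
    AttBSite,
    CircularInterval,
    GenomicLocus,
    ProphageModel,
    headful_windows,
)

ACCESSORY_PRODUCTS = (
    "staphylococcal enterotoxin homolog",
    "cadmium resistance transporter",
    "leukotoxin family cytolysin",
    "fibronectin-binding adhesin",
    "virulence regulator protein",
    "membrane lipoprotein Lpl",
    "tetracycline resistance protein",
    "pore-forming toxin subunit",
)

CORE_PRODUCTS = (
    "DNA polymerase III subunit",
    "30S ribosomal protein S4",
    "DNA gyrase subunit A",
    "cell division protein FtsZ",
    "elongation factor Tu",
    "ATP synthase F1 subunit",
    "glycolytic enzyme enolase",
    "tRNA ligase",
)


class SynthesisError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerPlacement:
    """A selectable marker at a known headful distance from an attB site."""

    site_id: str
    headful: int  # 1-based headful index the marker must land in
    offset: int  # bp into the window (marker fully inside the window)
    length: int = 800


@dataclass
class GenomeSpec:
    length: int = 1_000_000
    n_orfs: int = 200
    accessory_fraction: float = 0.25
    attb_layout: list[tuple[float, int]] = field(
        default_factory=lambda: [(0.10, +1), (0.55, -1)]
    )
    markers: list[MarkerPlacement] = field(default_factory=list)
    prophage: ProphageModel = field(
        default_factory=lambda: ProphageModel("synthetic_phage", 45_000, 7)
    )
    seed: int = 0
    genome_id: str = "toygenome"

    def __post_init__(self) -> None:
        if not 0.0 <= self.accessory_fraction <= 1.0:
            raise SynthesisError("accessory_fraction must be in [0, 1]")
        if self.length < 1000:
            raise SynthesisError("genome too short to annotate")
        for frac, direction in self.attb_layout:
            if not 0.0 <= frac < 1.0 or direction not in (+1, -1):
                raise SynthesisError("attb_layout entries are (fraction in [0,1), ±1)")
        for m in self.markers:
            if m.headful < 1:
                raise SynthesisError("marker headful indices are 1-based")


def _attb_sites(spec: GenomeSpec) -> list[AttBSite]:
    return [
        AttBSite(f"attB{i + 1}", int(frac * spec.length) % spec.length, direction)
        for i, (frac, direction) in enumerate(spec.attb_layout)
    ]


def _place_markers(spec: GenomeSpec, sites: list[AttBSite]) -> list[GenomicLocus]:
    by_id = {s.site_id: s for s in sites}
    loci = []
    model = spec.prophage
    for m in spec.markers:
        site = by_id.get(m.site_id)
        if site is None:
            raise SynthesisError(f"marker references unknown site {m.site_id!r}")
        if m.headful > model.n_max:
            raise SynthesisError(
                f"marker at HF{m.headful} beyond the prophage reach (n_max={model.n_max})"
            )
        windows = headful_windows(site, model, spec.length)
        if m.headful > len(windows):
            raise SynthesisError(
                f"marker at HF{m.headful} beyond the genome (only {len(windows)} windows)"
            )
        window = windows[m.headful - 1]
        if m.offset + m.length > window.length:
            raise SynthesisError(
                f"marker offset {m.offset}+{m.length} exceeds window length {window.length}"
            )
        start = (window.start + m.offset) % spec.length
        loci.append(
            GenomicLocus(
                f"{m.site_id}_hf{m.headful}",
                CircularInterval(start, m.length, spec.length),
                "marker",
            )
        )
    return loci


def _generate_orfs(spec: GenomeSpec, rng: np.random.Generator) -> list[Orf]:
    L, n = spec.length, spec.n_orfs
    slot = L // n
    if slot < 150:
        raise SynthesisError("too many ORFs for this genome length")
    rotation = int(rng.integers(L))  # lets slots (hence ORFs) wrap the origin
    orfs = []
    for i in range(n):
        max_len = min(1500, slot - 60)
        length = int(rng.integers(90, max_len + 1)) // 3 * 3
        offset = int(rng.integers(0, slot - length + 1))
        start = (i * slot + offset + rotation) % L
        accessory = bool(rng.random() < spec.accessory_fraction)
        pool = ACCESSORY_PRODUCTS if accessory else CORE_PRODUCTS
        product = pool[int(rng.integers(len(pool)))]
        orfs.append(
            Orf(
                orf_id=f"orf{i:04d}",
                span=CircularInterval(start, length, L),
                strand=int(rng.choice([1, -1])),
                product=product,
                orf_class="accessory" if accessory else "core",
            )
        )
    return orfs


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_toy_genome(
    spec: GenomeSpec, outdir: str | Path | None = None
) -> tuple[AnnotatedGenome, dict[str, Path]]:
    """Build a toy circular genome; optionally write GenBank, GFF3+FASTA and
    registry CSVs.

    Markers are placed strictly inside their requested headful window, so
    ``headful_index`` recovers the requested index exactly; ORF class labels
    are recorded in the annotations as ground truth.  Output files are
    byte-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    sequence = _random_sequence(spec.length, rng)
    orfs = _generate_orfs(spec, rng)
    sites = _attb_sites(spec)
    loci = _place_markers(spec, sites)
    genome = AnnotatedGenome(
        genome_id=spec.genome_id,
        length=spec.length,
        circular=True,
        orfs=orfs,
        attb_sites=sites,
        loci=loci,
    )
    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths["genbank"] = outdir / f"{spec.genome_id}.gb"
        paths["gff3"] = outdir / f"{spec.genome_id}.gff3"
        paths["fasta"] = outdir / f"{spec.genome_id}.fasta"
        paths["attb"] = outdir / f"{spec.genome_id}.attb.csv"
        paths["loci"] = outdir / f"{spec.genome_id}.loci.csv"
        write_genbank(genome, sequence, paths["genbank"])
        write_gff3(genome, paths["gff3"])
        write_fasta(genome, sequence, paths["fasta"])
        write_attb_csv(sites, paths["attb"])
        write_loci_csv(loci, paths["loci"])
    return genome, paths


def _orf_location(orf: Orf, genome_length: int):
    if orf.span.wraps:
        tail_len = genome_length - orf.span.start
        return CompoundLocation(
            [
                SimpleLocation(orf.span.start, genome_length, strand=orf.strand),
                SimpleLocation(0, orf.span.length - tail_len, strand=orf.strand),
            ]
        )
    return SimpleLocation(orf.span.start, orf.span.end, strand=orf.strand)


def write_genbank(genome: AnnotatedGenome, sequence: str, path: Path) -> None:
    record = SeqRecord(
        Seq(sequence),
        id=genome.genome_id,
        name=genome.genome_id[:16],
        description="synthetic circular chromosome",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    record.annotations["date"] = "01-JAN-2000"  # fixed: byte-identical output
    for orf in genome.orfs:
        record.features.append(
            SeqFeature(
                _orf_location(orf, genome.length),
                type="CDS",
                qualifiers={
                    "locus_tag": [orf.orf_id],
                    "product": [orf.product],
                    "note": [f"orf_class:{orf.orf_class}"],
                },
            )
        )
    SeqIO.write([record], str(path), "genbank")


def write_fasta(genome: AnnotatedGenome, sequence: str, path: Path) -> None:
    record = SeqRecord(Seq(sequence), id=genome.genome_id, description="")
    SeqIO.write([record], str(path), "fasta")


def write_gff3(genome: AnnotatedGenome, path: Path) -> None:
    """Emit a minimal standard GFF3 (1-based inclusive coordinates;
    origin-spanning ORFs as two CDS lines sharing an ID)."""
    lines = ["##gff-version 3", f"##sequence-region {genome.genome_id} 1 {genome.length}"]
    circ = "true" if genome.circular else "false"
    lines.append(
        f"{genome.genome_id}\tltmob\tregion\t1\t{genome.length}\t.\t+\t.\t"
        f"ID=region0;Is_circular={circ}"
    )
    for orf in genome.orfs:
        strand = "+" if orf.strand == 1 else "-"
        attrs = f"ID={orf.orf_id};product={orf.product};note=orf_class:{orf.orf_class}"
        for seg_start, seg_end in orf.span.segments():
            lines.append(
                f"{genome.genome_id}\tltmob\tCDS\t{seg_start + 1}\t{seg_end}\t.\t"
                f"{strand}\t0\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_attb_csv(sites: Sequence[AttBSite], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["site_id", "position", "direction", "phage_id"])
        for s in sites:
            writer.writerow(
                [s.site_id, s.position, "+" if s.direction == 1 else "-", s.occupied_by or ""]
            )


def write_loci_csv(loci: Sequence[GenomicLocus], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["locus_id", "start", "length", "locus_class"])
        for locus in loci:
            writer.writerow(
                [locus.locus_id, locus.span.start, locus.span.length, locus.locus_class]
            )


# ---------------------------------------------------------------------------
# element panels


MECHANISM_OF = {
    "plasmid": "conjugation",
    "phage": "lysogenisation",
    "PICI": "PICI_transfer",
    "ICE": "conjugation",
}


def generate_element_panel(
    n_elements: int, seed: int = 0, nd_fraction: float = 0.15, range_fraction: float = 0.3
):
    """Random element panel with stored ground-truth relative mobilities.

    Transfer frequencies are log-uniform over [1e-9, 1] (the span the
    comparative tables cover, conjugative transposons up to PICIs); cargo
    fractions have half-ORF granularity; a share of rows carries ND cargo.
    Returns a DataFrame in the mobility-record CSV schema plus truth columns
    (truth_rm_lo/truth_rm_hi), computed by direct multiplication.
    """
    import pandas as pd

    from .render import as_fraction

    rng = np.random.default_rng(seed)
    rows = []
    categories = list(MECHANISM_OF)
    for i in range(n_elements):
        category = categories[int(rng.integers(len(categories)))]
        lo = 10.0 ** rng.uniform(-9, 0)
        lo_str = f"{lo:.3e}"
        if rng.random() < range_fraction:
            hi = 10.0 ** rng.uniform(np.log10(lo), 0)
            hi_str = f"{hi:.3e}"
        else:
            hi_str = ""
        if rng.random() < nd_fraction:
            acc_str = tot_str = ""
            rm_lo = rm_hi = None
        else:
            total = Fraction(int(rng.integers(4, 241)), 2)  # 2.0 .. 120.0 by halves
            acc = Fraction(int(rng.integers(0, total.numerator + 1)), 2)
            acc_str, tot_str = str(float(acc)), str(float(total))
            flo = as_fraction(lo_str)
            fhi = as_fraction(hi_str) if hi_str else flo
            rm_lo = float(flo * acc / total)
            rm_hi = float(fhi * acc / total)
        rows.append(
            {
                "element_id": f"element{i:03d}",
                "accession": "",
                "category": category,
                "mechanism": MECHANISM_OF[category],
                "organism": "synthetic",
                "freq_lo": lo_str,
                "freq_hi": hi_str,
                "titre_tru_per_ml": "",
                "accessory_orfs": acc_str,
                "total_orfs": tot_str,
                "source": "synthetic panel",
                "truth_rm_lo": rm_lo,
                "truth_rm_hi": rm_hi,
            }
        )
    return pd.DataFrame(rows)
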