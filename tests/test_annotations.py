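"""Annotation parsing, accessory classification, window counting, record I/O."""

from fractions import Fraction

import pytest

from ltmob import (
    AccessoryRuleSet,
    AnnotatedGenome,
    CircularInterval,
    GenomeSpec,
    MarkerPlacement,
    Orf,
    ProphageModel,
    classify_orfs,
    generate_element_panel,
    generate_toy_genome,
    orfs_in_window,
    read_attb_registry,
    read_genome_annotation,
    read_loci,
    read_mobility_records,
    write_ledger,
    write_mobility_records,
)
from ltmob.annotations import AnnotationError, window_cargo
from ltmob.metrics import ValidationError, build_mobility_ledger
from ltmob.render import rate_string


@pytest.fixture(scope="module")
def written_genome(tmp_path_factory):
    spec = GenomeSpec(
        length=50_000,
        n_orfs=10,
        accessory_fraction=0.4,
        attb_layout=[(0.1, +1)],
        markers=[MarkerPlacement("attB1", headful=2, offset=100)],
        prophage=ProphageModel("p", 6000, 4),
        seed=11,
        genome_id="mini50k",
    )
    outdir = tmp_path_factory.mktemp("genomes")
    genome, paths = generate_toy_genome(spec, outdir)
    return genome, paths


class TestGenomeReaders:
    def test_genbank_round_trip(self, written_genome):
        genome, paths = written_genome
        parsed = read_genome_annotation(paths["genbank"], format="genbank")
        assert parsed.length == 50_000
        assert parsed.circular
        assert len(parsed.orfs) == 10
        assert [o.orf_id for o in parsed.orfs] == [o.orf_id for o in genome.orfs]
        assert [o.span for o in parsed.orfs] == [o.span for o in genome.orfs]
        assert [o.orf_class for o in parsed.orfs] == [o.orf_class for o in genome.orfs]

    def test_gff3_equals_genbank(self, written_genome):
        _, paths = written_genome
        from_gb = read_genome_annotation(paths["genbank"], format="genbank")
        from_gff = read_genome_annotation(paths["gff3"], format="gff3", fasta=paths["fasta"])
        assert from_gff.length == from_gb.length
        assert from_gff.circular == from_gb.circular
        assert sorted(from_gff.orfs, key=lambda o: o.orf_id) == sorted(
            from_gb.orfs, key=lambda o: o.orf_id
        )

    def test_origin_spanning_cds_reads_as_single_wrapped_interval(self, tmp_path):
        from ltmob.synth import write_fasta, write_genbank, write_gff3

        L = 9_000
        wrapped = Orf("wrap1", CircularInterval(8_500, 900, L), 1, "pore-forming toxin subunit", "accessory")
        plain = Orf("mid1", CircularInterval(3_000, 600, L), -1, "elongation factor Tu", "core")
        genome = AnnotatedGenome("wrapg", L, True, [wrapped, plain])
        seq = "ACGT" * (L // 4)
        write_genbank(genome, seq, tmp_path / "w.gb")
        write_gff3(genome, tmp_path / "w.gff3")
        write_fasta(genome, seq, tmp_path / "w.fasta")
        for parsed in (
            read_genome_annotation(tmp_path / "w.gb", format="genbank"),
            read_genome_annotation(tmp_path / "w.gff3", format="gff3", fasta=tmp_path / "w.fasta"),
        ):
            orf = next(o for o in parsed.orfs if o.orf_id == "wrap1")
            assert orf.span == CircularInterval(8_500, 900, L)
            assert orf.span.wraps

    def test_missing_file_errors(self):
        with pytest.raises(AnnotationError):
            read_genome_annotation("does_not_exist.gb")


def _toy_element(n_orfs=26, accessory_ids=()):
    L = 30_000
    orfs = [
        Orf(
            f"g{i}",
            CircularInterval(i * 1000, 800, L),
            1,
            "hypothetical protein",
            "unassigned",
        )
        for i in range(n_orfs)
    ]
    return AnnotatedGenome("element", L, True, orfs), accessory_ids


class TestClassification:
    def test_empty_rules_zero_accessory(self):
        genome, _ = _toy_element()
        cargo = classify_orfs(genome, AccessoryRuleSet())
        assert (cargo.accessory_orfs, cargo.total_orfs) == (0, 26)

    def test_include_list_gives_table_style_fraction(self):
        genome, _ = _toy_element(26)
        rules = AccessoryRuleSet(include_ids=frozenset({"g0", "g5", "g9", "g20"}))
        cargo = classify_orfs(genome, rules)
        assert (cargo.accessory_orfs, cargo.total_orfs) == (4, 26)
        assert rate_string(cargo.accessory_orfs / cargo.total_orfs) == "0.15"

    def test_match_all_keyword_saturates(self):
        genome, _ = _toy_element(12)
        cargo = classify_orfs(genome, AccessoryRuleSet(keyword_patterns=("protein",)))
        assert cargo.accessory_orfs == cargo.total_orfs == 12

    def test_exclude_overrides_include(self):
        genome, _ = _toy_element(5)
        rules = AccessoryRuleSet(
            include_ids=frozenset({"g1"}),
            exclude_ids=frozenset({"g2"}),
            keyword_patterns=("hypothetical",),
        )
        cargo = classify_orfs(genome, rules)
        assert cargo.accessory_orfs == 4  # all but the excluded one

    def test_adding_keywords_is_monotone(self, toy_genome):
        keywords = ["toxin", "resistance", "adhesin", "lipoprotein"]
        counts = []
        for k in range(len(keywords) + 1):
            cargo = classify_orfs(toy_genome, AccessoryRuleSet(keyword_patterns=tuple(keywords[:k])))
            counts.append(cargo.accessory_orfs)
        assert counts == sorted(counts)

    def test_disjointness_enforced(self):
        with pytest.raises(ValidationError):
            AccessoryRuleSet(include_ids=frozenset("a"), exclude_ids=frozenset("a"))


class TestWindowCounts:
    def _genome(self):
        L = 10_000
        orfs = [Orf(f"o{i}", CircularInterval(i * 400, 300, L), 1, "x", "core") for i in range(5)]
        # one ORF straddling position 2000
        orfs.append(Orf("straddle", CircularInterval(1_900, 300, L), 1, "x", "core"))
        return AnnotatedGenome("wg", L, True, orfs)

    def test_full_and_straddling_counts(self):
        genome = self._genome()
        window = CircularInterval(0, 2_000, 10_000)
        assert orfs_in_window(genome, window) == Fraction(11, 2)  # 5 full + 0.5
        assert orfs_in_window(genome, window, partial_weight=0) == 5
        assert orfs_in_window(genome, window, partial_weight=1) == 6

    def test_weights_bracket_half(self):
        genome = self._genome()
        window = CircularInterval(0, 2_000, 10_000)
        lo = orfs_in_window(genome, window, partial_weight=0)
        mid = orfs_in_window(genome, window)
        hi = orfs_in_window(genome, window, partial_weight=1)
        assert lo <= mid <= hi

    def test_partition_sums_to_total(self, toy_genome):
        # half-weighted counts over a partition of the circle: each straddler
        # contributes 0.5 + 0.5
        L = toy_genome.length
        edges = [0, 13_000, 27_000, 44_000]
        windows = [
            CircularInterval(edges[i], (edges[(i + 1) % 4] - edges[i]) % L, L)
            for i in range(4)
        ]
        total = sum(orfs_in_window(toy_genome, w) for w in windows)
        assert total == len(toy_genome.orfs)

    def test_window_cargo_uses_ground_truth_keywords(self, toy_genome):
        window = CircularInterval(0, toy_genome.length, toy_genome.length)
        cargo = window_cargo(toy_genome, window)
        truth = sum(1 for o in toy_genome.orfs if o.orf_class == "accessory")
        assert cargo.accessory_orfs == truth
        assert cargo.total_orfs == len(toy_genome.orfs)


class TestRecordIO:
    def test_fixture_row_counts(self, fixture_tables):
        assert len(fixture_tables.records_table1) == 20
        assert len(fixture_tables.records_table3) == 22

    def test_empty_csv(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "element_id,accession,category,mechanism,organism,freq_lo,freq_hi,"
            "titre_tru_per_ml,accessory_orfs,total_orfs,source\n"
        )
        assert read_mobility_records(path) == []

    def test_schema_violation_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "element_id,accession,category,mechanism,organism,freq_lo,freq_hi,"
            "titre_tru_per_ml,accessory_orfs,total_orfs,source\n"
            "ok,,plasmid,conjugation,x,1e-5,,,,,\n"
            "bad,,plasmid,lysogenisation,x,1e-5,,,,,\n"
        )
        with pytest.raises(ValidationError, match="row 3"):
            read_mobility_records(path)

    def test_write_read_round_trip(self, tmp_path, fixture_tables):
        path = tmp_path / "rt.csv"
        write_mobility_records(fixture_tables.records_table1, path)
        assert read_mobility_records(path) == fixture_tables.records_table1

    def test_panel_round_trip(self, tmp_path):
        panel = generate_element_panel(12, seed=5)
        path = tmp_path / "panel.csv"
        panel.drop(columns=["truth_rm_lo", "truth_rm_hi"]).to_csv(path, index=False)
        records = read_mobility_records(path)
        back = tmp_path / "panel_back.csv"
        write_mobility_records(records, back)
        assert read_mobility_records(back) == records

    def test_ledger_tsv_and_json(self, tmp_path, fixture_tables):
        rows = build_mobility_ledger(
            fixture_tables.records_table1, fixture_tables.calibrations
        )
        write_ledger(rows, tmp_path / "l.tsv", tmp_path / "l.json")
        import json

        lines = (tmp_path / "l.tsv").read_text().splitlines()
        assert len(lines) == 1 + len(rows)
        sapi1 = next(l for l in lines if l.startswith("SaPI1"))
        assert "3.78 × 10^−1" in sapi1 and "0.15 (4/26)" in sapi1
        payload = json.loads((tmp_path / "l.json").read_text())
        assert len(payload) == len(rows)
        sapi1_js = next(e for e in payload if e["element_id"] == "SaPI1")
        assert sapi1_js["relative_mobility_hi"] == pytest.approx(2.46 * 4 / 26)


class TestRegistries:
    def test_attb_and_loci_csvs(self, written_genome):
        genome, paths = written_genome
        sites = read_attb_registry(paths["attb"], genome.length)
        assert [s.site_id for s in sites] == [s.site_id for s in genome.attb_sites]
        assert [(s.position, s.direction) for s in sites] == [
            (s.position, s.direction) for s in genome.attb_sites
        ]
        loci = read_loci(paths["loci"], genome.length)
        assert [(l.locus_id, l.span) for l in loci] == [
            (l.locus_id, l.span) for l in genome.loci
        ]

    def test_bad_direction_reported(self, tmp_path):
        path = tmp_path / "attb.csv"
        path.write_text("site_id,position,direction,phage_id\ns1,10,north,\n")
        with pytest.raises(AnnotationError, match="row 2"):
            read_attb_registry(path, 1000)
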