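"""GFF3 ingest, neighborhood extraction/categorization, operon detection,
and synteny comparison."""

import pytest

from soxyprof.errors import (InvalidAnnotationError, InvalidInputError,
                             InvalidParameterError)
from soxyprof.neighborhood import (GeneModel, categorize, compare_synteny,
                                   detect_operon, extract_neighborhood,
                                   map_hits_to_genes, read_gff3, sox_labels,
                                   write_gff3, SOX_OPERON_GENES)
from soxyprof.synthetic import (GenomeSpec, PlantedCopy, generate_genome)

from .test_search import make_hit


def gm(gid, start, end, strand="+", product="hypothetical protein",
       contig="c1"):
    return GeneModel(gene_id=gid, contig=contig, start=start, end=end,
                     strand=strand, product=product)


def run_of_genes(gaps, strand="+", products=None):
    """Consecutive genes with the given intergenic gaps."""
    genes = []
    pos = 100
    for i, gap in enumerate([0] + list(gaps)):
        pos += gap
        g = gm(f"g{i}", pos, pos + 300, strand,
               products[i] if products else "hypothetical protein")
        genes.append(g)
        pos += 300
    return genes


class TestGFF3:
    def test_coordinate_round_trip(self, tmp_path):
        spec = GenomeSpec(genome_id="R1",
                          planted=[PlantedCopy("S1a", False, "soxyz_pair")])
        genome, _ = generate_genome(spec, seed=6)
        path = tmp_path / "x.gff3"
        write_gff3(genome.genes, path, genome.contig_lengths)
        back = read_gff3(path)
        assert len(back) == len(genome.genes)
        for a, b in zip(genome.genes, back):
            assert (a.gene_id, a.start, a.end, a.strand, a.product) == \
                (b.gene_id, b.start, b.end, b.strand, b.product)

    def test_on_disk_coordinates_are_one_based_inclusive(self, tmp_path):
        g = gm("only", 9, 21)  # 0-based half-open
        path = tmp_path / "one.gff3"
        write_gff3([g], path)
        line = [l for l in path.read_text().splitlines()
                if not l.startswith("#")][0]
        fields = line.split("\t")
        assert (fields[3], fields[4]) == ("10", "21")


class TestMapHits:
    def test_planted_loci_mapped(self):
        spec = GenomeSpec(genome_id="M1", planted=[
            PlantedCopy("S1a", False, "sedimenticola_operon")])
        genome, truth = generate_genome(spec, seed=7)
        hits = [make_hit(truth.gene_id.iloc[0], "A" * 150, genome="M1")]
        loci, unmatched = map_hits_to_genes(hits, genome.genes)
        assert len(loci) == 1 and not unmatched
        assert loci[0][1].gene_id == truth.gene_id.iloc[0]

    def test_unknown_id_reported_not_fatal(self):
        loci, unmatched = map_hits_to_genes(
            [make_hit("nope", "A" * 150)], [gm("g1", 0, 300)])
        assert loci == [] and unmatched == ["nope"]

    def test_duplicate_gene_ids_fatal(self):
        with pytest.raises(InvalidAnnotationError):
            map_hits_to_genes([], [gm("g1", 0, 300), gm("g1", 400, 700)])


class TestExtractNeighborhood:
    def test_mid_contig_window(self):
        genes = run_of_genes([50] * 14)
        nmap = extract_neighborhood(genes[7], genes, k=5)
        assert len(nmap.genes) == 11
        assert not nmap.truncated_upstream and not nmap.truncated_downstream
        assert [g.gene.start for g in nmap.genes] == sorted(
            g.gene.start for g in nmap.genes)

    def test_contig_edge_truncation(self):
        genes = run_of_genes([50] * 5)
        nmap = extract_neighborhood(genes[0], genes, k=3)
        assert nmap.truncated_upstream and not nmap.truncated_downstream
        assert len(nmap.genes) == 4

    def test_other_contigs_excluded(self):
        genes = run_of_genes([50] * 3)
        genes += [gm("far", 0, 300, contig="c2")]
        nmap = extract_neighborhood(genes[1], genes, k=5)
        assert all(g.gene.contig == "c1" for g in nmap.genes)

    def test_k_precondition(self):
        genes = run_of_genes([50])
        with pytest.raises(InvalidParameterError):
            extract_neighborhood(genes[0], genes, k=0)

    def test_missing_locus(self):
        with pytest.raises(InvalidInputError):
            extract_neighborhood("ghost", run_of_genes([50]), k=2)


class TestCategorize:
    @pytest.mark.parametrize("product,expected", [
        ("dimethyl sulfoxide reductase subunit DmsA", "sulfur"),
        ("LuxR family transcriptional regulator", "regulatory"),
        ("signal transduction histidine kinase", "regulatory"),
        ("RNA polymerase sigma-54 factor RpoN", "regulatory"),
        ("hypothetical protein", "hypothetical"),
        ("rhodanese-like domain sulfurtransferase", "other"),
        ("XoxF-type methanol dehydrogenase", "carbon"),
        ("formate dehydrogenase subunit alpha FdhA", "carbon"),
        ("sulfur oxidation protein SoxB", "sulfur"),
        ("octaheme tetrathionate reductase Otr", "sulfur"),
        ("completely novel widget", "hypothetical"),
    ])
    def test_keyword_rules(self, product, expected):
        genes = run_of_genes([50, 50], products=["x", product, "y"])
        nmap = categorize(extract_neighborhood(genes[1], genes, k=1))
        assert nmap.genes[1].category == expected

    def test_empty_map_rejected(self):
        genes = run_of_genes([50])
        with pytest.raises(InvalidInputError):
            categorize(extract_neighborhood(genes[0], genes, k=1),
                       category_map=())


class TestSoxLabels:
    def test_fused_symbol_expands(self):
        assert sox_labels("sulfur oxidation protein SoxYZ") == {"soxY", "soxZ"}
        assert sox_labels("cytochrome SoxAX complex") == {"soxA", "soxX"}
        assert sox_labels("sulfur oxidation protein SoxB") == {"soxB"}
        assert sox_labels("hypothetical protein") == set()


class TestDetectOperon:
    def _genome_with_layout(self, layout_name, seed=9):
        spec = GenomeSpec(genome_id="OP1",
                          planted=[PlantedCopy("S1a", False, layout_name)])
        genome, truth = generate_genome(spec, seed=seed)
        return genome, truth.gene_id.iloc[0]

    def test_operon_layout_verdict_true(self):
        genome, focal = self._genome_with_layout("sedimenticola_operon")
        op = detect_operon(genome.genes, focal)
        assert op.verdict
        assert op.max_internal_gap <= 200

    def test_dispersed_layout_verdict_false(self):
        genome, focal = self._genome_with_layout("thiodiazotropha_dispersed")
        op = detect_operon(genome.genes, focal)
        assert not op.verdict

    def test_gap_boundary_splits_run(self):
        products = ["sulfur oxidation c-type cytochrome SoxA",
                    "sulfur oxidation protein SoxB",
                    "sulfur oxidation c-type cytochrome SoxX",
                    "sulfur oxidation protein SoxY",
                    "sulfur oxidation protein SoxZ"]
        at_gap = run_of_genes([200, 100, 100, 100], products=products)
        assert detect_operon(at_gap, "g3", SOX_OPERON_GENES, 200).verdict
        over_gap = run_of_genes([201, 100, 100, 100], products=products)
        op = detect_operon(over_gap, "g3", SOX_OPERON_GENES, 200)
        assert not op.verdict
        assert "g0" not in op.member_ids

    def test_strand_switch_splits_run(self):
        products = ["sulfur oxidation c-type cytochrome SoxA",
                    "sulfur oxidation protein SoxB",
                    "sulfur oxidation c-type cytochrome SoxX",
                    "sulfur oxidation protein SoxY",
                    "sulfur oxidation protein SoxZ"]
        genes = run_of_genes([50, 50, 50, 50], products=products)
        genes[0] = gm("g0", genes[0].start, genes[0].end, "-", products[0])
        assert not detect_operon(genes, "g3", SOX_OPERON_GENES, 200).verdict

    def test_reverse_complement_symmetry(self):
        """Flipping the genome (mirror coordinates, flip strands) must not
        change the verdict."""
        genome, focal = self._genome_with_layout("sedimenticola_operon")
        total = max(g.end for g in genome.genes) + 100
        flipped = [GeneModel(gene_id=g.gene_id, contig=g.contig,
                             start=total - g.end, end=total - g.start,
                             strand="-" if g.strand == "+" else "+",
                             product=g.product)
                   for g in genome.genes]
        a = detect_operon(genome.genes, focal)
        b = detect_operon(flipped, focal)
        assert a.verdict == b.verdict
        assert set(a.member_ids) == set(b.member_ids)

    def test_max_gap_precondition(self):
        genes = run_of_genes([50])
        with pytest.raises(InvalidParameterError):
            detect_operon(genes, "g0", max_gap=0)


class TestCompareSynteny:
    def _categorized(self, layout, seed):
        spec = GenomeSpec(genome_id=f"SY{seed}",
                          planted=[PlantedCopy("S4", True, layout)])
        genome, truth = generate_genome(spec, seed=seed)
        focal = truth.gene_id.iloc[0]
        return categorize(extract_neighborhood(focal, genome.genes, k=3))

    def test_identical_maps_score_one(self):
        nmap = self._categorized("s4_c1", 3)
        assert compare_synteny(nmap, nmap) == pytest.approx(1.0)

    def test_shared_layout_high_conservation(self):
        a = self._categorized("s4_c1", 3)
        b = self._categorized("s4_c1", 4)
        assert compare_synteny(a, b) >= 0.8

    def test_uncategorized_rejected(self):
        genes = run_of_genes([50, 50])
        nmap = extract_neighborhood(genes[1], genes, k=1)
        with pytest.raises(InvalidInputError):
            compare_synteny(nmap, nmap)

    def test_score_bounded(self):
        a = self._categorized("s4_c1", 5)
        b = self._categorized("s1c_dms", 6)
        assert 0 <= compare_synteny(a, b) <= 1
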