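"""Tests of the synthetic-cohort generator and its planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soxyprof.errors import (InfeasibleTargetError, InvalidModelError,
                             InvalidParameterError)
from soxyprof.signatures import global_identity
from soxyprof.synthetic import (CYS_POSITION_1BASED, DEFAULT_ECOLOGY_MODEL,
                                DIVERGENT_SIGNATURES, GenomeSpec, PlantedCopy,
                                build_reference_set, cohort_specs,
                                generate_cohort, generate_genome,
                                perturb_sequence, plant_signature,
                                shuffle_sequence, write_cohort)


class TestReferenceSet:
    def test_canonical_arm_and_cysteine(self, refs):
        arm_start = CYS_POSITION_1BASED - 6
        assert refs.canonical_soxy[arm_start:CYS_POSITION_1BASED] == "VTIGGC"
        assert refs.canonical_soxy[CYS_POSITION_1BASED - 1] == "C"
        # exactly one GGC trimer, inside the arm window
        assert refs.canonical_soxy.count("GGC") == 1
        assert refs.canonical_soxy.index("GGC") == CYS_POSITION_1BASED - 3

    def test_deterministic(self):
        a = build_reference_set(6, seed=1)
        b = build_reference_set(6, seed=1)
        assert a.canonical_soxy == b.canonical_soxy
        assert a.seed_alignment == b.seed_alignment
        assert a.signature_exemplars == b.signature_exemplars

    def test_narrow_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_reference_set(5, seed=1)

    def test_signature_motif_structure(self, refs):
        motifs = {e.name: e.arm_motif for e in refs.signatures}
        s1a = motifs["S1a"]
        assert s1a == "VTIGGC"
        for name in ("S1b", "S1c"):
            diff = sum(1 for a, b in zip(s1a, motifs[name]) if a != b)
            assert diff == 1, f"{name} must differ from S1a at exactly one site"
        for name in ("S2", "S3", "S4"):
            diff = sum(1 for a, b in zip(s1a, motifs[name]) if a != b)
            assert diff >= 3, f"{name} must be multiply diverged"
        assert all("GGC" in m for m in motifs.values())

    def test_exemplar_identity_in_published_range(self, refs):
        for entry in refs.signatures:
            lo, hi = entry.target_identity_range
            ident = global_identity(refs.signature_exemplars[entry.name],
                                    refs.canonical_soxy).identity
            assert lo - 3 <= ident <= hi + 3

    def test_exemplar_arms_exact(self, refs):
        for entry in refs.signatures:
            ex = refs.signature_exemplars[entry.name]
            assert ex[CYS_POSITION_1BASED - 6:CYS_POSITION_1BASED] == entry.arm_motif


class TestPlantSignature:
    @pytest.mark.parametrize("target", [30, 60, 85, 100])
    def test_identity_by_hand_count(self, refs, target):
        """Substitution-only planting: identity verified by directly counting
        mismatched positions (the sequences stay equal length)."""
        sig = next(e for e in refs.signatures if e.name == "S2")
        out = plant_signature(refs.canonical_soxy, sig, target, seed=5)
        assert len(out) == len(refs.canonical_soxy)
        mism = sum(1 for a, b in zip(out, refs.canonical_soxy) if a != b)
        ident = 100 * (len(out) - mism) / len(out)
        if target == 100:
            # only the arm rewrite may differ
            arm = slice(CYS_POSITION_1BASED - 6, CYS_POSITION_1BASED)
            assert out[arm] == sig.arm_motif
            assert out[:arm.start] == refs.canonical_soxy[:arm.start]
            assert out[arm.stop:] == refs.canonical_soxy[arm.stop:]
        else:
            assert abs(ident - target) <= 3

    def test_arm_written_exactly_and_protected(self, refs):
        for entry in refs.signatures:
            out = plant_signature(refs.canonical_soxy, entry, 55, seed=9)
            assert out[CYS_POSITION_1BASED - 6:CYS_POSITION_1BASED] == entry.arm_motif
            assert "GGC" in out

    def test_global_identity_agrees(self, refs):
        sig = next(e for e in refs.signatures if e.name == "S1a")
        out = plant_signature(refs.canonical_soxy, sig, 60, seed=2)
        assert global_identity(out, refs.canonical_soxy).identity == pytest.approx(60, abs=3)

    def test_precondition(self, refs):
        sig = refs.signatures.entries[0]
        with pytest.raises(InvalidParameterError):
            plant_signature(refs.canonical_soxy, sig, 19, seed=1)

    def test_infeasible_target(self):
        with pytest.raises(InfeasibleTargetError):
            perturb_sequence("ACDEFGHIKL", identity=1.0, seed=0, protected=(0, 8))


class TestShuffle:
    def test_composition_invariant(self):
        assert shuffle_sequence("AAAA", 3) == "AAAA"
        seq = "ACDEFGHIKLMNPQRSTVWY" * 10
        out = shuffle_sequence(seq, 3)
        assert sorted(out) == sorted(seq)
        assert len(out) == len(seq)

    def test_positional_uniformity(self):
        """Over many shuffles each residue should be uniform over positions."""
        seq = "ACDEFGHIKL"
        counts = np.zeros(len(seq))
        n = 1000
        for s in range(n):
            counts[shuffle_sequence(seq, s).index("A")] += 1
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 1e-3


class TestGenerateGenome:
    def test_five_copies_truth_marked(self, refs):
        spec = GenomeSpec(genome_id="T0001", planted=[
            PlantedCopy("S1a", False, "sedimenticola_operon"),
            PlantedCopy("S1a", False, "soxyz_pair"),
            PlantedCopy("S2", True, "s2_adh"),
            PlantedCopy("S3", False, "s3_otr"),
            PlantedCopy("S4", True, "s4_c1"),
        ])
        genome, truth = generate_genome(spec, seed=4)
        assert len(truth) == 5
        gene_ids = {g.gene_id for g in genome.genes}
        prot_ids = {p.protein_id for p in genome.proteins}
        assert set(truth.gene_id) <= gene_ids
        assert set(truth.gene_id) <= prot_ids

    def test_zero_copies(self):
        genome, truth = generate_genome(GenomeSpec(genome_id="T0", planted=[]),
                                        seed=4)
        assert truth.empty
        assert len(genome.proteins) > 0  # decoys only

    def test_fused_copy_length(self, refs):
        spec = GenomeSpec(genome_id="T1",
                          planted=[PlantedCopy("S2", True, "s2_adh")])
        genome, truth = generate_genome(spec, seed=4)
        seq = next(p.seq for p in genome.proteins
                   if p.protein_id == truth.gene_id.iloc[0])
        expected = len(refs.canonical_soxy) + len(refs.canonical_soxz)
        assert len(seq) == expected

    def test_coordinates_consistent_with_protein_lengths(self):
        spec = GenomeSpec(genome_id="T2",
                          planted=[PlantedCopy("S1a", False, "soxyz_pair")])
        genome, _ = generate_genome(spec, seed=4)
        by_id = {p.protein_id: p for p in genome.proteins}
        for gm in genome.genes:
            assert gm.end - gm.start == len(by_id[gm.gene_id].seq) * 3 + 3
        starts = [g.start for g in genome.genes]
        assert starts == sorted(starts)

    def test_planted_sequences_pass_quality_filters(self):
        spec = GenomeSpec(genome_id="T3", planted=[
            PlantedCopy(s, s in ("S2", "S4"), lay) for s, lay in
            [("S1a", "soxyz_pair"), ("S1c", "s1c_dms"), ("S2", "s2_adh")]])
        genome, truth = generate_genome(spec, seed=8)
        by_id = {p.protein_id: p.seq for p in genome.proteins}
        for gid in truth.gene_id:
            assert len(by_id[gid]) >= 140
            assert "GGC" in by_id[gid]

    def test_too_many_copies_rejected(self):
        with pytest.raises(InvalidParameterError):
            GenomeSpec(genome_id="T4", planted=[
                PlantedCopy("S1a", False, "soxyz_pair")] * 6)


class TestCohort:
    def test_deterministic_files(self, tmp_path):
        outputs = []
        for d in ("a", "b"):
            genomes, meta, truth = generate_cohort(5, seed=3)
            m = write_cohort(genomes, meta, truth, tmp_path / d, seed=3)
            outputs.append(m["checksums"])
        assert outputs[0] == outputs[1]

    def test_truth_retrievable_from_files(self, tmp_path):
        genomes, meta, truth = generate_cohort(6, seed=5)
        write_cohort(genomes, meta, truth, tmp_path, seed=5)
        from Bio import SeqIO
        faa = {r.id: str(r.seq) for r in SeqIO.parse(str(tmp_path / "proteins.faa"),
                                                     "fasta")}
        from soxyprof.neighborhood import read_gff3
        gms = {g.gene_id: g for g in read_gff3(tmp_path / "genes.gff3")}
        t = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        for _, row in t.iterrows():
            assert row.gene_id in faa
            gm = gms[row.gene_id]
            assert gm.start + 1 == row.start and gm.end == row.end
            assert gm.strand == row.strand

    def test_specialists_never_divergent(self):
        specs = cohort_specs(100, seed=7)
        for spec in specs:
            if spec.label == "specialist":
                sigs = {c.signature for c in spec.planted}
                assert not (sigs & DIVERGENT_SIGNATURES)

    def test_divergent_generalists_have_multiple_copies(self):
        genomes, meta, truth = generate_cohort(50, seed=9)
        meta = meta.set_index("genome_id")
        per_genome = truth.groupby("genome_id")
        for gid, grp in per_genome:
            if set(grp.signature) & DIVERGENT_SIGNATURES:
                assert meta.loc[gid, "ecology_label"] == "generalist"
                assert len(grp) >= 2

    def test_degenerate_model_single_genome(self):
        model = {"specialist": {"weight": 1.0, "kind": "specialist",
                                "environments": ["specialized"],
                                "repertoires": [(("S1a",), 1.0)]}}
        genomes, meta, truth = generate_cohort(1, model, seed=2)
        assert len(genomes) == 1
        assert list(truth.signature) == ["S1a"]

    def test_label_frequencies_match_model(self):
        """Empirical label and divergence frequencies at n=200 stay within
        5 points of the model (binomial sampling check)."""
        specs = cohort_specs(200, seed=13)
        frac_spec = np.mean([s.label == "specialist" for s in specs])
        assert abs(frac_spec - 0.5) <= 0.05
        gen = [s for s in specs if s.label == "generalist"]
        frac_div = np.mean([
            bool({c.signature for c in s.planted} & DIVERGENT_SIGNATURES)
            for s in gen])
        assert abs(frac_div - 0.9) <= 0.05

    def test_invalid_models_rejected(self):
        bad_weight = {"specialist": {**DEFAULT_ECOLOGY_MODEL["specialist"],
                                     "weight": 0.4}}
        with pytest.raises(InvalidModelError):
            cohort_specs(5, bad_weight, seed=1)
        bad_sig = {"generalist": {"weight": 1.0, "kind": "generalist",
                                  "environments": ["seagrass"],
                                  "repertoires": [(("S9",), 1.0)]}}
        with pytest.raises(InvalidModelError):
            cohort_specs(5, bad_sig, seed=1)
        bad_kind = {"x": {"weight": 1.0, "kind": "other", "environments": ["e"],
                          "repertoires": [(("S1a",), 1.0)]}}
        with pytest.raises(InvalidModelError):
            cohort_specs(5, bad_kind, seed=1)
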