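"""Generator contracts: determinism, planted structures, site planting."""

import hashlib
from pathlib import Path

import pytest

from mirwood import structure as st
from mirwood import targets as tg
from mirwood import validation
from mirwood._seq import revcomp_dna, transcribe
from mirwood.simulate import (GroundTruth, SimulationConfig, plant_target_site,
                              simulate_dataset)

MICRO = dict(seed=42, genome_length=160_000, n_genes=50, n_novel_hairpins=3,
             n_known_mirnas=10, library_depth=3_000, n_de_mirnas=4,
             mrna_library_depth=200_000, n_extra_degs=10)


def sha_dir(d):
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(Path(d).iterdir()) if p.is_file()}


class TestConfig:
    def test_proportions_must_sum_to_one(self):
        cfg = SimulationConfig(mirna_proportion=0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_negcorr_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(negcorr_fraction=1.5).validate()

    def test_library_ids(self):
        assert SimulationConfig().libraries == [
            "PS1", "PS2", "PS3", "TS1", "TS2", "TS3", "SS1", "SS2", "SS3"]


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        simulate_dataset(SimulationConfig(**MICRO), tmp_path / "a")
        simulate_dataset(SimulationConfig(**MICRO), tmp_path / "b")
        assert sha_dir(tmp_path / "a") == sha_dir(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        simulate_dataset(SimulationConfig(**MICRO), tmp_path / "a")
        other = dict(MICRO, seed=43)
        simulate_dataset(SimulationConfig(**other), tmp_path / "c")
        a, c = sha_dir(tmp_path / "a"), sha_dir(tmp_path / "c")
        assert a["genome.fa"] != c["genome.fa"]


class TestPlantedStructures:
    def test_ground_truth_counts(self, small_bundle, small_config):
        _, _, truth = small_bundle
        assert len(truth.planted_hairpins) == small_config.n_novel_hairpins
        assert len(truth.planted_de_mirnas) == small_config.n_de_mirnas

    def test_planted_hairpins_refold_as_stemloops(self, small_bundle):
        _, _, truth = small_bundle
        for hp in truth.planted_hairpins:
            fr = st.fold(hp["precursor"])
            ok, arm = st.is_stemloop(fr, hp["mature"])
            assert ok and arm == hp["arm"]
            assert fr.mfe <= -18.0

    def test_mature_on_exactly_one_arm_of_precursor(self, small_bundle):
        _, _, truth = small_bundle
        for hp in truth.planted_hairpins:
            assert hp["precursor"].count(hp["mature"]) == 1

    def test_planted_loci_match_genome(self, small_bundle):
        from Bio import SeqIO

        bundle_dir, _, truth = small_bundle
        genome = {r.id: str(r.seq) for r in SeqIO.parse(
            str(Path(bundle_dir) / "genome.fa"), "fasta")}
        for hp in truth.planted_hairpins:
            chrom, s, e, strand = hp["locus"]
            seg = genome[chrom][s - 1:e]
            assert transcribe(seg) == hp["precursor"]

    def test_planted_sites_obey_rules_by_construction(self, small_bundle):
        _, _, truth = small_bundle
        for mat, sites in truth.planted_targets.items():
            for _gid, _pos, w in sites:
                assert 0 <= w <= 4
        assert truth.planted_negative_pairs  # something to integrate

    def test_truth_round_trips_through_json(self, small_bundle, tmp_path):
        _, _, truth = small_bundle
        truth.to_json(tmp_path / "t.json")
        back = GroundTruth.from_json(tmp_path / "t.json")
        assert back == truth


class TestPlantTargetSite:
    GENE = "ACGT" * 40
    MIRNA = "UGGAGCUCCCUUCAUUCCAAU"

    def test_zero_mismatch_site_is_reverse_complement(self):
        out = plant_target_site(self.MIRNA, self.GENE, 0.0, 10)
        site = out[10:10 + 21]
        assert site == revcomp_dna(self.MIRNA.replace("U", "T"))

    def test_half_unit_is_single_wobble(self):
        out = plant_target_site(self.MIRNA, self.GENE, 0.5, 10)
        hit = tg.score_duplex(self.MIRNA, out[10:31])
        assert hit.total_weighted == 0.5

    @pytest.mark.parametrize("w", [1.0, 1.5, 2.0, 3.0, 4.0])
    def test_requested_weight_is_realised_exactly(self, w):
        out = plant_target_site(self.MIRNA, self.GENE, w, 20)
        hit = tg.score_duplex(self.MIRNA, out[20:41])
        assert hit.total_weighted == w and hit.passes_rules
        ref = validation.check_target_rules(self.MIRNA, out[20:41])
        assert ref["passes_rules"]

    def test_above_cap_rejected(self):
        with pytest.raises(ValueError):
            plant_target_site(self.MIRNA, self.GENE, 4.5, 10)

    def test_infeasible_wobble_rejected(self):
        mirna = "GCC" + "A" * 18  # no G/U at positions 13+
        with pytest.raises(ValueError, match="infeasible"):
            plant_target_site(mirna, self.GENE, 0.5, 10)

    def test_site_must_fit(self):
        with pytest.raises(ValueError):
            plant_target_site(self.MIRNA, "ACGT", 0.0, 0)


class TestLibraryComposition:
    def test_category_mix_recovered_within_sampling_error(self, small_run,
                                                          small_config):
        result, _, _ = small_run
        from mirwood.annotate import category_distribution

        dist = category_distribution(result.annotations)
        mix = small_config.contaminant_mix
        for lib in [l for l in result.qc_reports][:3]:
            frac = dist[(lib, "count")] / dist[(lib, "count")].sum()
            # classes removed before annotation (polyA, short) excluded; the
            # remaining proportions are renormalised
            keep = {k: v for k, v in mix.items()
                    if k not in ("polyA", "short", "degradation")}
            keep["miRNA"] = small_config.mirna_proportion
            keep_total = sum(keep.values()) + mix["degradation"]
            for cls in ("rRNA", "tRNA", "miRNA"):
                expected = keep[cls] / keep_total
                observed = frac[cls] if cls != "miRNA" else (
                    frac["miRNA"] + frac["unannotated"])
                assert observed == pytest.approx(expected, abs=0.05)
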