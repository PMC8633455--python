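"""Known-miRNA naming, novel hairpin prediction and candidate validation."""

import numpy as np
import pytest

from mirwood import discovery as disc
from mirwood import validation
from mirwood.annotate import CleanTag
from mirwood._seq import back_transcribe, transcribe
from mirwood.simulate import SimulationConfig, _build_hairpin


def tag(seq_dna, n=5, lib="PS1"):
    return CleanTag(seq=seq_dna, counts={lib: n})


@pytest.fixture(scope="module")
def catalogue():
    entries_focal = [
        disc.CatalogueEntry(name="ptc-miR1001-5p",
                            mature="UGGAGCUCCCUUCAUUCCAAU", arm="5p"),
    ]
    entries_other = [
        disc.CatalogueEntry(name="ath-miR2002",
                            mature="UUGGACUGAAGGGAGCUCCCU", arm="3p"),
        disc.CatalogueEntry(name="osa-miR2003",
                            mature="CAGCCAAGGAUGACUUGCCGG", arm="5p"),
    ]
    return disc.Catalogue(entries_focal, entries_other)


class TestAssignKnown:
    def test_focal_match_is_existing_with_arm_suffix(self, catalogue):
        recs = disc.assign_known(
            [tag(back_transcribe("UGGAGCUCCCUUCAUUCCAAU"))], catalogue)
        assert len(recs) == 1
        r = recs[0]
        assert r.status == "existing" and r.name == "ptc-miR1001-5p"
        assert r.arm_label == "5p"

    def test_other_species_3p_arm_renamed_y(self, catalogue):
        recs = disc.assign_known(
            [tag(back_transcribe("UUGGACUGAAGGGAGCUCCCU"))], catalogue)
        r = recs[0]
        assert r.status == "conserved" and r.name == "miR2002-y"
        assert r.arm_label == "y"

    def test_other_species_5p_arm_renamed_x(self, catalogue):
        recs = disc.assign_known(
            [tag(back_transcribe("CAGCCAAGGAUGACUUGCCGG"))], catalogue)
        assert recs[0].name == "miR2003-x" and recs[0].arm_label == "x"

    def test_unmatched_tag_excluded(self, catalogue):
        assert disc.assign_known([tag("ACGT" * 5 + "A")], catalogue) == []

    def test_counts_carried_through(self, catalogue):
        t = tag(back_transcribe("UGGAGCUCCCUUCAUUCCAAU"), n=9, lib="TS2")
        recs = disc.assign_known([t], catalogue)
        assert recs[0].counts == {"TS2": 9}

    def test_empty_catalogue_rejected(self):
        with pytest.raises(ValueError):
            disc.Catalogue([], [])


class TestPredictNovel:
    def embed(self, rng, hairpins, n_copies=1):
        """A toy genome embedding the given precursors (DNA)."""
        parts = []
        for pre in hairpins:
            for _ in range(n_copies):
                parts.append("".join(rng.choice(list("ACGT"), 300)))
                parts.append(back_transcribe(pre))
        parts.append("".join(rng.choice(list("ACGT"), 300)))
        return {"chr1": "".join(parts)}

    def test_planted_hairpin_recovered(self, rng):
        cfg = SimulationConfig()
        mature = transcribe("".join(rng.choice(list("ACGT"), 21)))
        pre, star = _build_hairpin(mature, "5p", rng, [])
        genome = self.embed(rng, [pre])
        cands = disc.predict_novel([tag(back_transcribe(mature))], genome)
        assert len(cands) == 1
        c = cands[0]
        assert c.passed and c.mature_tag.seq == back_transcribe(mature)
        assert c.criteria["spacing_min"][1] and c.criteria["max_bulge"][1]

    def test_3p_arm_hairpin_recovered(self, rng):
        mature = transcribe("".join(rng.choice(list("ACGT"), 21)))
        pre, _ = _build_hairpin(mature, "3p", rng, [])
        genome = self.embed(rng, [pre])
        cands = disc.predict_novel([tag(back_transcribe(mature))], genome)
        assert len(cands) == 1 and cands[0].passed

    def test_copy_number_cap(self, rng):
        mature = transcribe("".join(rng.choice(list("ACGT"), 21)))
        pre, _ = _build_hairpin(mature, "5p", rng, [])
        genome = self.embed(rng, [pre], n_copies=13)  # 13 loci x 2 strands > 20
        cands = disc.predict_novel([tag(back_transcribe(mature))], genome)
        assert cands == []

    def test_tag_without_genome_hit_ignored(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 2000))}
        cands = disc.predict_novel([tag("GGTTCCGGAACCTTAGGCCTA")], genome)
        assert cands == []

    def test_length_bounds_respected(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 2000))}
        too_long = tag("".join(rng.choice(list("ACGT"), 26)))
        assert disc.predict_novel([too_long], genome) == []

    def test_candidates_revalidate_independently(self, small_run):
        result, _, _ = small_run
        assert result.candidates
        for c in result.candidates:
            res = validation.revalidate_hairpin(
                c.precursor_seq, c.mature_tag.seq, c.fold.structure,
                c.copies_on_reference)
            assert res["all"], res


class TestDedupe:
    def make(self, rng, mature, total, locus_start):
        pre, _ = _build_hairpin(transcribe(mature), "5p", rng, [])
        from mirwood import structure as st

        fr = st.fold(pre)
        cand = disc.evaluate_candidate(
            CleanTag(seq=mature, counts={"PS1": total}), fr, 20,
            ("chr1", locus_start, locus_start + len(pre) - 1, "+"), 1,
            disc.DEFAULT_DISCOVERY, "5p")
        assert cand is not None
        return cand

    def test_same_mature_collapses_with_copy_count(self, rng):
        mature = back_transcribe(transcribe("".join(rng.choice(list("ACGT"), 21))))
        c1 = self.make(rng, mature, 10, 100)
        c2 = self.make(rng, mature, 10, 900)
        recs = disc.dedupe_candidates([c1, c2])
        assert len(recs) == 1 and recs[0].copies_on_reference == 2

    def test_highest_count_gets_lowest_index(self, rng):
        m1 = back_transcribe(transcribe("".join(rng.choice(list("ACGT"), 21))))
        m2 = back_transcribe(transcribe("".join(rng.choice(list("ACGT"), 21))))
        c_low = self.make(rng, m1, 3, 100)
        c_high = self.make(rng, m2, 30, 900)
        recs = disc.dedupe_candidates([c_low, c_high])
        assert recs[0].name.startswith("novel-m0001")
        assert recs[0].mature_seq == transcribe(m2)

    def test_naming_stable_across_input_order(self, rng):
        m1 = back_transcribe(transcribe("".join(rng.choice(list("ACGT"), 21))))
        m2 = back_transcribe(transcribe("".join(rng.choice(list("ACGT"), 21))))
        c1 = self.make(rng, m1, 3, 100)
        c2 = self.make(rng, m2, 30, 900)
        names_a = [r.name + r.mature_seq for r in disc.dedupe_candidates([c1, c2])]
        names_b = [r.name + r.mature_seq for r in disc.dedupe_candidates([c2, c1])]
        assert names_a == names_b

    def test_no_tag_is_both_known_and_novel(self, small_run):
        result, _, _ = small_run
        known_seqs = {r.mature_seq for r in result.known_records}
        novel_seqs = {r.mature_seq for r in result.novel_records}
        assert not (known_seqs & novel_seqs)
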