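"""Duplex rule scoring against the independent checker, and transcriptome scans."""

import numpy as np
import pytest

from mirwood import targets as tg
from mirwood import validation
from mirwood._seq import revcomp_rna

MIRNA = "UGGAGCUCCCUUCAUUCCAAU"  # 21 nt


def site_for(mirna, changes=()):
    """Perfect-complement site with per-miRNA-position overrides.

    ``changes`` maps 1-based miRNA position -> kind ("gu" or "mm").
    """
    L = len(mirna)
    site = list(revcomp_rna(mirna))
    for pos, kind in dict(changes).items() if isinstance(changes, dict) else changes:
        m = mirna[pos - 1]
        if kind == "gu":
            assert m in "GU"
            site[L - pos] = "U" if m == "G" else "G"
        else:
            site[L - pos] = {"A": "C", "C": "A", "G": "A", "U": "C"}[m]
    return "".join(site)


class TestScoreDuplex:
    def test_perfect_complement_passes_everything(self):
        hit = tg.score_duplex(MIRNA, site_for(MIRNA))
        assert hit.total_weighted == 0.0 and hit.passes_rules

    def test_gu_weighs_half(self):
        hit = tg.score_duplex(MIRNA, site_for(MIRNA, {15: "gu"}))
        assert hit.total_weighted == 0.5
        assert hit.mismatch_vector[14] == 0.5

    def test_gu_at_cleavage_site_strict_vs_tolerant(self):
        assert MIRNA[10] == "U"  # position 11 supports a wobble
        site = site_for(MIRNA, {11: "gu"})
        strict = tg.score_duplex(MIRNA, site)
        assert not strict.rule_pass["rule4_cleavage"]
        tolerant = tg.score_duplex(MIRNA, site,
                                   tg.RuleConfig(rule4_strict_gu=False))
        assert tolerant.rule_pass["rule4_cleavage"]

    def test_five_full_mismatches_fail_total(self):
        site = site_for(MIRNA, {p: "mm" for p in (13, 15, 17, 19, 21)})
        hit = tg.score_duplex(MIRNA, site)
        assert hit.total_weighted == 5.0 and not hit.rule_pass["rule1_total"]

    def test_eight_wobbles_weigh_four_and_pass_total(self):
        gu_positions = [p for p in range(13, 22) if MIRNA[p - 1] in "GU"]
        # supplement with 5'-side G/U positions away from the seed rules
        extra = [p for p in range(1, 13) if MIRNA[p - 1] in "GU"]
        chosen = (gu_positions + extra)
        chosen = [p for i, p in enumerate(chosen) if p not in chosen[:i]][:8]
        assert len(chosen) == 8
        site = site_for(MIRNA, {p: "gu" for p in chosen})
        hit = tg.score_duplex(MIRNA, site)
        assert hit.total_weighted == 4.0 and hit.rule_pass["rule1_total"]

    def test_adjacent_run_of_three_fails(self):
        site = site_for(MIRNA, {p: "mm" for p in (14, 15, 16)})
        hit = tg.score_duplex(MIRNA, site)
        assert not hit.rule_pass["rule2_adjacent"]

    def test_adjacent_full_mismatches_in_seed_fail(self):
        site = site_for(MIRNA, {4: "mm", 5: "mm"})
        hit = tg.score_duplex(MIRNA, site)
        assert not hit.rule_pass["rule3_seed_adjacent"]

    def test_seed_total_cap(self):
        site = site_for(MIRNA, {p: "mm" for p in (2, 4, 6)})
        hit = tg.score_duplex(MIRNA, site)
        assert hit.rule_pass["rule5_seed_total"] is False or \
            sum(hit.mismatch_vector[:12]) <= 2.5
        assert sum(hit.mismatch_vector[:12]) == 3.0
        assert not hit.rule_pass["rule5_seed_total"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tg.score_duplex(MIRNA, "ACGU")

    def test_agrees_with_independent_checker(self, rng):
        bases = np.array(list("ACGU"))
        for _ in range(1500):
            L = int(rng.integers(18, 26))
            mirna = "".join(rng.choice(bases, L))
            if rng.random() < 0.5:
                site = "".join(rng.choice(bases, L))
            else:
                site = list(revcomp_rna(mirna))
                for _k in range(int(rng.integers(0, 6))):
                    site[int(rng.integers(0, L))] = str(rng.choice(bases))
                site = "".join(site)
            hit = tg.score_duplex(mirna, site)
            ref = validation.check_target_rules(mirna, site)
            for rule in hit.rule_pass:
                assert hit.rule_pass[rule] == ref[rule], (mirna, site, rule)
            assert hit.total_weighted == pytest.approx(
                sum(validation.position_weights(mirna, site)))

    def test_wobble_to_watson_crick_never_breaks_a_pass(self, rng):
        bases = np.array(list("ACGU"))
        for _ in range(300):
            mirna = "".join(rng.choice(bases, 21))
            site = list(revcomp_rna(mirna))
            for _k in range(int(rng.integers(0, 5))):
                p = int(rng.integers(1, 22))
                if mirna[p - 1] in "GU":
                    site[21 - p] = "U" if mirna[p - 1] == "G" else "G"
            site = "".join(site)
            hit = tg.score_duplex(mirna, site)
            if not hit.passes_rules:
                continue
            gu_pos = [i for i, w in enumerate(hit.mismatch_vector) if w == 0.5]
            if not gu_pos:
                continue
            p = gu_pos[0] + 1
            fixed = list(site)
            fixed[21 - p] = revcomp_rna(mirna[p - 1])
            assert tg.score_duplex(mirna, "".join(fixed)).passes_rules


class TestMFERatio:
    def test_perfect_site_has_ratio_one(self):
        hit = tg.score_duplex(MIRNA, site_for(MIRNA))
        hit = tg.mfe_ratio_filter(hit, MIRNA)
        assert hit.mfe_ratio == pytest.approx(1.0)
        assert hit.passes_mfe

    def test_heavily_mismatched_site_fails(self):
        site = site_for(MIRNA, {p: "mm" for p in (3, 6, 9, 13, 16)})
        hit = tg.score_duplex(MIRNA, site)
        hit = tg.mfe_ratio_filter(hit, MIRNA)
        assert hit.mfe_ratio < 0.74 and not hit.passes_mfe

    def test_unpairable_mirna_rejected_with_zero_perfect_energy(self):
        mirna = "A" * 21
        hit = tg.score_duplex(mirna, "U" * 21)
        hit = tg.mfe_ratio_filter(hit, mirna, mfe_perfect=0.0)
        assert not hit.passes_mfe


class TestScan:
    def transcripts(self):
        rng = np.random.default_rng(8)
        t = "".join(rng.choice(list("ACGT"), 400))
        site = site_for(MIRNA).replace("U", "T")
        planted = t[:150] + site + t[150 + len(site):]
        return {"G1": planted, "G2": t[::-1]}

    def test_planted_site_found_at_position(self):
        hits = tg.scan_transcriptome({"m1": MIRNA}, self.transcripts())
        by_t = {(h.mirna, h.transcript) for h in hits}
        assert ("m1", "G1") in by_t
        g1 = next(h for h in hits if h.transcript == "G1")
        assert g1.site_start == 150 + len(MIRNA)
        assert g1.total_weighted == 0.0

    def test_no_complementary_transcript_no_hits(self):
        hits = tg.scan_transcriptome({"m1": "ACGU" * 5 + "A"},
                                     {"G1": "A" * 200})
        assert hits == []

    def test_result_independent_of_transcript_order(self):
        tx = self.transcripts()
        rev = dict(reversed(list(tx.items())))
        h1 = tg.scan_transcriptome({"m1": MIRNA}, tx)
        h2 = tg.scan_transcriptome({"m1": MIRNA}, rev)
        assert [(h.mirna, h.transcript, h.site_start) for h in h1] == \
            [(h.mirna, h.transcript, h.site_start) for h in h2]

    def test_scanner_preselection_matches_full_scoring(self, rng):
        # every window the vectorised mask accepts must pass score_duplex too
        bases = np.array(list("ACGT"))
        tseq = "".join(rng.choice(bases, 300))
        site = site_for(MIRNA).replace("U", "T")
        tseq = tseq[:40] + site + tseq[40 + len(site):]
        idx = tg._scan_one(MIRNA, tseq, tg.DEFAULT_RULES)
        assert 40 in idx
        for w0 in idx:
            window = tseq[w0:w0 + len(MIRNA)]
            assert tg.score_duplex(MIRNA, window).passes_rules
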