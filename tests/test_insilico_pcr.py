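from __future__ import annotations

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mxprime import (
    MismatchPolicy,
    Primer,
    SequenceRecord,
    amplify,
    find_binding_sites,
    multiplex_amplify,
    specificity_matrix,
    synthesize_templates,
)
from mxprime._iupac import reverse_complement

from ._oracles import naive_binding_sites

BRO385 = Primer(name="Bro385", sequence="GGGGCCATTAACTTTATC")
FISHR1 = Primer(name="FishR1", sequence="TAGACTTCTGGGTGGCCAAAGAATCA", role="universal_reverse")


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestFindBindingSites:
    def test_embedded_forward_site_on_plus_strand(self):
        template = "AAA" + BRO385.sequence + "TTT"
        (site,) = find_binding_sites(template, BRO385)
        assert (site.strand, site.start, site.end, site.mismatches) == ("+", 4, 21, 0)

    def test_reverse_complement_site_on_minus_strand(self):
        template = "AC" + reverse_complement(FISHR1.sequence) + "GT"
        (site,) = find_binding_sites(template, FISHR1)
        assert site.strand == "-"
        assert (site.start, site.end) == (3, 2 + len(FISHR1.sequence))

    def test_mutation_at_3prime_terminus_blocks_annealing(self):
        seq = BRO385.sequence[:-1] + ("A" if BRO385.sequence[-1] != "A" else "G")
        template = "AAA" + seq + "TTT"
        assert find_binding_sites(template, BRO385) == []

    def test_mismatches_outside_protected_window_are_tolerated(self):
        mutated = "TT" + BRO385.sequence[2:]  # 2 mismatches at the 5' end
        (site,) = find_binding_sites("G" + mutated + "C", BRO385)
        assert site.mismatches == 2
        assert all(off >= 3 for off in site.mismatch_offsets)

    def test_gapped_template_rejected(self):
        with pytest.raises(ValueError, match="gapped"):
            find_binding_sites("ACGT-ACGT", BRO385)

    @pytest.mark.parametrize("seed", range(4))
    def test_relaxing_the_policy_never_removes_sites(self, seed):
        rng = random.Random(seed)
        template = _random_dna(rng, 400)
        primer = Primer(name="p", sequence=_random_dna(rng, 12))
        strict = find_binding_sites(template, primer, MismatchPolicy(1, 3))
        relaxed = find_binding_sites(template, primer, MismatchPolicy(3, 1))
        keys = lambda sites: {(s.strand, s.start) for s in sites}
        assert keys(strict) <= keys(relaxed)

    def test_matches_naive_scanner_on_many_random_cases(self):
        """Vectorized scanner vs an independent per-position rescan, 1000 cases."""
        rng = random.Random(20240901)
        iupac_extra = "RYSWKMN"
        for case in range(1000):
            tlen = rng.randint(60, 2000)
            template = list(_random_dna(rng, tlen))
            plen = rng.randint(15, 30)
            primer_seq = list(_random_dna(rng, plen))
            # plant a near-copy so hits actually occur
            if tlen > plen + 2:
                pos = rng.randrange(tlen - plen)
                planted = primer_seq.copy()
                for _ in range(rng.randint(0, 3)):
                    planted[rng.randrange(plen)] = rng.choice("ACGT")
                template[pos : pos + plen] = planted
            if case % 3 == 0:  # sprinkle ambiguity codes
                for _ in range(rng.randint(1, 4)):
                    template[rng.randrange(tlen)] = rng.choice(iupac_extra)
            template = "".join(template)
            policy = MismatchPolicy(
                max_mismatches=rng.randint(0, 3),
                protected_window=rng.randint(0, 4),
                iupac=rng.random() < 0.8,
            )
            got = [
                (s.strand, s.start, s.end, s.mismatches)
                for s in find_binding_sites(
                    template, Primer(name="p", sequence="".join(primer_seq)), policy
                )
            ]
            want = naive_binding_sites(
                template,
                "".join(primer_seq),
                max_mismatches=policy.max_mismatches,
                protected_window=policy.protected_window,
                iupac=policy.iupac,
            )
            assert sorted(got) == sorted(want), f"case {case}"


class TestAmplify:
    def test_constructed_254bp_product(self):
        rng = random.Random(0)
        template = BRO385.sequence + _random_dna(rng, 210) + reverse_complement(FISHR1.sequence)
        (amp,) = amplify(template, BRO385, FISHR1)
        assert amp.length == 254
        assert amp.length == amp.reverse_site.end - amp.forward_site.start + 1

    def test_no_forward_site_means_no_product(self):
        rng = random.Random(1)
        template = _random_dna(rng, 100) + reverse_complement(FISHR1.sequence)
        assert amplify(template, BRO385, FISHR1) == []

    def test_two_forward_sites_give_two_products_100bp_apart(self):
        rng = random.Random(2)
        template = (
            BRO385.sequence
            + _random_dna(rng, 100 - len(BRO385.sequence))
            + BRO385.sequence
            + _random_dna(rng, 60)
            + reverse_complement(FISHR1.sequence)
        )
        amps = amplify(template, BRO385, FISHR1)
        lengths = sorted(a.length for a in amps)
        assert len(lengths) == 2 and lengths[1] - lengths[0] == 100

    def test_product_lengths_invariant_under_template_reverse_complement(self):
        rng = random.Random(3)
        template = BRO385.sequence + _random_dna(rng, 150) + reverse_complement(FISHR1.sequence)
        fwd = sorted(a.length for a in amplify(template, BRO385, FISHR1))
        rev = sorted(
            a.length for a in amplify(reverse_complement(template), BRO385, FISHR1)
        )
        assert fwd == rev == [194]

    def test_overlapping_primer_pair_rejected_as_artifact(self):
        # product would be shorter than the two primers combined
        template = BRO385.sequence[:10] + reverse_complement(FISHR1.sequence)
        assert amplify(template, BRO385, FISHR1) == []


class TestMultiplexAndSpecificity:
    def test_target_template_yields_species_and_control_bands(self, coi_panel):
        templates, _ = synthesize_templates(coi_panel, ["B. rousseauxii"], seed=5)
        (_, rec), = templates
        bs = multiplex_amplify(rec, coi_panel)
        assert bs.bands == (254, 650)
        assert bs.provenance[254] == (("Bro385", "FishR1"),)
        assert bs.provenance[650] == (("16SL1987", "16SH2609"),)

    def test_control_only_template(self, coi_panel):
        templates, _ = synthesize_templates(coi_panel, ["Z. zungaro"], seed=6)
        (_, rec), = templates
        assert multiplex_amplify(rec, coi_panel).bands == (650,)

    def test_empty_template_rejected(self, coi_panel):
        with pytest.raises(ValueError, match="empty"):
            multiplex_amplify("", coi_panel)

    def test_specificity_matrix_verdicts(self, coi_panel, nontarget_species):
        targets = list(coi_panel.forwards)
        templates, _ = synthesize_templates(
            coi_panel, targets + nontarget_species, seed=9
        )
        lanes = list(templates) + [("water", None)]
        matrix = specificity_matrix(coi_panel, lanes)
        verdicts = [r.verdict for r in matrix.rows]
        assert verdicts == ["target-confirmed"] * 3 + ["non-target"] * 5 + ["assay-failure"]

    def test_template_with_two_species_sites_is_ambiguous(self, coi_panel):
        rng = random.Random(4)
        bro = coi_panel.forwards["B. rousseauxii"]
        bva = coi_panel.forwards["B. vaillantii"]
        rev = coi_panel.universal_reverse
        cf, cr = coi_panel.control_pair
        template = (
            cf.sequence
            + _random_dna(rng, 650 - len(cf.sequence) - len(cr.sequence))
            + reverse_complement(cr.sequence)
            + bro.sequence
            + _random_dna(rng, 30)
            + bva.sequence
            + _random_dna(rng, 300)
            + reverse_complement(rev.sequence)
        )
        rec = SequenceRecord("dual", template)
        matrix = specificity_matrix(coi_panel, [("B. rousseauxii", rec)])
        assert matrix.rows[0].verdict == "ambiguous"

    def test_unlabeled_template_rejected(self, coi_panel):
        with pytest.raises(ValueError, match="unlabeled"):
            specificity_matrix(coi_panel, [(None, None)])
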