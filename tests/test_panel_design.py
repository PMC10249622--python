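from __future__ import annotations

import random

import pytest

from mxprime import (
    Primer,
    PrimerCandidate,
    assemble_panel,
    consensus,
    enumerate_candidates,
    panel_report,
    simulate_species_alignment,
)
from mxprime._iupac import reverse_complement
from mxprime.panel_design import InfeasiblePanelError, MultiplexPanel

from ._oracles import brute_force_panel_choice

PERMISSIVE = dict(tm_window=(0.0, 200.0))


def _lenient_dimers():
    from mxprime.primer_eval import DimerPolicy

    return DimerPolicy(flag_run=99, flag_3prime_run=99)


def _shared_primers(aln):
    """Universal reverse + control pair cut from conserved consensus regions."""
    cons = consensus(aln, aln.species[0]).ungapped
    rev = Primer(name="UnivR", sequence=reverse_complement(cons[-26:-6]), role="universal_reverse")
    cf = Primer(name="CtlF", sequence=cons[5:27], role="control_forward")
    cr = Primer(name="CtlR", sequence=reverse_complement(cons[80:102]), role="control_reverse")
    return rev, (cf, cr)


class TestEnumerateCandidates:
    def test_every_candidate_ends_on_a_planted_diagnostic_column(self):
        aln, truth = simulate_species_alignment(3, 5, 600, 0.0, 0.0, 2, seed=3)
        rev, _ = _shared_primers(aln)
        for sp in truth.species:
            planted_cols = {col for col, _ in truth.planted_diagnostics[sp]}
            cands = enumerate_candidates(aln, sp, rev)
            assert cands, sp
            for c in cands:
                # gapless simulation: alignment columns == ungapped positions
                assert c.footprint_columns[1] in planted_cols
                assert c.three_prime_on_diagnostic
                assert c.diagnostic_count >= 1
                assert len(c.primer.sequence) == (
                    c.footprint_columns[1] - c.footprint_columns[0] + 1
                )

    def test_geometric_impossibility_yields_empty_list(self, toy_aln):
        # B's only diagnostic column (3) cannot host an 18..22-mer 3' end
        rev = Primer(
            name="R10",
            sequence=reverse_complement("ACCTACGTAC"),
            role="universal_reverse",
        )
        assert enumerate_candidates(toy_aln, "B", rev, length_range=(6, 8)) == []

    def test_target_without_diagnostic_sites_yields_empty_list(self, toy_aln):
        rev = Primer(
            name="R10",
            sequence=reverse_complement("ACGTACGTAC"),
            role="universal_reverse",
        )
        assert enumerate_candidates(toy_aln, "A", rev) == []

    def test_sorted_by_coverage_then_product_length(self):
        aln, _ = simulate_species_alignment(3, 5, 600, 0.0, 0.0, 3, seed=5)
        rev, _ = _shared_primers(aln)
        cands = enumerate_candidates(aln, "sp01", rev)
        keys = [(-c.diagnostic_count, -c.amplicon_length, c.start_ungapped) for c in cands]
        assert keys == sorted(keys)


def _fixed(name, band, seq=None):
    rng = random.Random(hash(name) & 0xFFFF)
    seq = seq or "".join(rng.choice("ACGT") for _ in range(20))
    return PrimerCandidate.fixed(Primer(name=name, sequence=seq), band)


class TestAssemblePanel:
    def _shared(self, coi_panel):
        return coi_panel.universal_reverse, coi_panel.control_pair

    def test_published_coi_band_set_is_feasible_with_gap_61(self, coi_panel):
        cands = {
            sp: [PrimerCandidate.fixed(p, coi_panel.expected_bands[sp])]
            for sp, p in coi_panel.forwards.items()
        }
        panel = assemble_panel(
            cands, *self._shared(coi_panel), coi_panel.control_band,
            min_band_separation=30, name="coi", marker="COI",
        )
        assert panel.all_bands() == [254, 405, 466, 650]
        assert panel.min_band_gap() == 61

    def test_published_cr_band_set_is_feasible_with_gap_129(self, cr_panel):
        cands = {
            sp: [PrimerCandidate.fixed(p, cr_panel.expected_bands[sp])]
            for sp, p in cr_panel.forwards.items()
        }
        panel = assemble_panel(
            cands, cr_panel.universal_reverse, cr_panel.control_pair,
            cr_panel.control_band, min_band_separation=30, name="cr", marker="CR",
        )
        assert panel.all_bands() == [160, 290, 451, 580]
        assert panel.min_band_gap() == 129

    def test_too_close_bands_are_infeasible(self):
        cands = {
            "X": [_fixed("x1", 300)],
            "Y": [_fixed("y1", 310)],
        }
        rev = Primer(name="R", sequence="ACGTACGTACGTACGTACGT", role="universal_reverse")
        ctl = (
            Primer(name="CF", sequence="TTGACCTTGACCGTTAGGCC", role="control_forward"),
            Primer(name="CR", sequence="GGCATTGGCATTACCTTGCA", role="control_reverse"),
        )
        with pytest.raises(InfeasiblePanelError, match="min separation"):
            assemble_panel(
                cands, rev, ctl, 650, min_band_separation=30,
                dimer_policy=_lenient_dimers(), **PERMISSIVE,
            )

    def test_selection_invariant_under_candidate_permutation(self):
        rng = random.Random(17)
        cands = {
            sp: [_fixed(f"{sp}{i}", rng.randrange(100, 900)) for i in range(5)]
            for sp in ("X", "Y", "Z")
        }
        rev = Primer(name="R", sequence="ACGTACGTACGTACGTACGT", role="universal_reverse")
        ctl = (
            Primer(name="CF", sequence="TTGACCTTGACCGTTAGGCC", role="control_forward"),
            Primer(name="CR", sequence="GGCATTGGCATTACCTTGCA", role="control_reverse"),
        )
        kwargs = dict(
            min_band_separation=30, dimer_policy=_lenient_dimers(), **PERMISSIVE
        )
        baseline = assemble_panel(cands, rev, ctl, 975, **kwargs)
        for seed in range(5):
            shuffled = {
                sp: random.Random(seed).sample(pool, len(pool))
                for sp, pool in cands.items()
            }
            again = assemble_panel(shuffled, rev, ctl, 975, **kwargs)
            assert again.expected_bands == baseline.expected_bands
            assert {p.name for p in again.forwards.values()} == {
                p.name for p in baseline.forwards.values()
            }

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search_oracle(self, seed):
        """On <=4 species x <=6 candidates, selection achieves the brute-force
        optimum of the max-min-band-gap objective."""
        rng = random.Random(seed)
        n_species = rng.randint(2, 4)
        bands_by_species = {
            f"s{i}": sorted(
                rng.sample(range(100, 1000, 7), rng.randint(1, 6))
            )
            for i in range(n_species)
        }
        control_band = rng.randrange(100, 1000)
        min_sep = rng.choice([20, 30, 50])
        cands = {
            sp: [_fixed(f"{sp}c{j}", b) for j, b in enumerate(bands)]
            for sp, bands in bands_by_species.items()
        }
        rev = Primer(name="R", sequence="ACGTACGTACGTACGTACGT", role="universal_reverse")
        ctl = (
            Primer(name="CF", sequence="TTGACCTTGACCGTTAGGCC", role="control_forward"),
            Primer(name="CR", sequence="GGCATTGGCATTACCTTGCA", role="control_reverse"),
        )
        oracle = brute_force_panel_choice(bands_by_species, control_band, min_sep)
        try:
            panel = assemble_panel(
                cands, rev, ctl, control_band, min_band_separation=min_sep,
                dimer_policy=_lenient_dimers(), **PERMISSIVE,
            )
        except InfeasiblePanelError:
            assert oracle is None
            return
        assert oracle is not None
        oracle_bands = sorted(oracle.values()) + [control_band]
        got_bands = panel.all_bands()

        def min_gap(bands):
            bands = sorted(bands)
            return min(b - a for a, b in zip(bands, bands[1:]))

        assert min_gap(got_bands) == min_gap(sorted(oracle_bands))

    def test_assembled_forwards_cover_planted_diagnostics(self):
        aln, truth = simulate_species_alignment(3, 5, 600, 0.0, 0.0, 2, seed=8)
        rev, ctl = _shared_primers(aln)
        cands = {sp: enumerate_candidates(aln, sp, rev) for sp in truth.species}
        panel = assemble_panel(
            cands, rev, ctl, 700, min_band_separation=20,
            dimer_policy=_lenient_dimers(), name="synth",
        )
        for sp, primer in panel.forwards.items():
            planted = {col for col, _ in truth.planted_diagnostics[sp]}
            chosen = next(
                c for c in cands[sp] if c.primer.name == primer.name
            )
            covered = set(
                range(chosen.footprint_columns[0], chosen.footprint_columns[1] + 1)
            )
            assert covered & planted


class TestPanelReport:
    def test_coi_report_lists_primers_dimers_and_ladder(self, coi_panel):
        report = panel_report(coi_panel)
        assert len(report.qc) == 6
        assert len(report.dimers) == 15
        assert [bp for _, bp in report.band_order] == [254, 405, 466, 650]

    def test_cr_band_order(self, cr_panel):
        report = panel_report(cr_panel)
        assert [bp for _, bp in report.band_order] == [160, 290, 451, 580]

    def test_duplicate_expected_bands_rejected_before_reporting(self, coi_panel):
        with pytest.raises(ValueError, match="distinct"):
            MultiplexPanel(
                name="dup",
                marker="COI",
                forwards=dict(coi_panel.forwards),
                universal_reverse=coi_panel.universal_reverse,
                control_pair=coi_panel.control_pair,
                expected_bands={sp: 254 for sp in coi_panel.forwards},
                control_band=650,
            )

    def test_report_includes_footprint_specificity_with_alignment(self):
        aln, truth = simulate_species_alignment(3, 5, 600, 0.0, 0.0, 2, seed=12)
        rev, ctl = _shared_primers(aln)
        cands = {sp: enumerate_candidates(aln, sp, rev) for sp in truth.species}
        panel = assemble_panel(
            cands, rev, ctl, 700, min_band_separation=20,
            dimer_policy=_lenient_dimers(), name="synth",
        )
        report = panel_report(panel, aln)
        assert set(report.footprint_specificity) == {
            p.name for p in panel.forwards.values()
        }
        for rows in report.footprint_specificity.values():
            assert rows and all(r.mismatches >= 1 for r in rows)
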