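"""Linkage: pedigree validation, marker QC, exact LOD enumeration, intervals."""

import math

import numpy as np
import pandas as pd
import pytest

from famseq.examples import chr12_lod_track
from famseq.linkage import (AFFECTED, EXCLUDED, UNAFFECTED, UNKNOWN,
                            CandidateInterval, DiseaseModel,
                            EnumerationBoundError, Individual, MarkerPanel,
                            Pedigree, PedigreeError, extract_interval,
                            informative_meioses, lod_score, lod_track,
                            marker_qc, max_attainable_lod, obligate_carriers,
                            pedigree_likelihood, restrict_founders_affected)
from conftest import nuclear
from oracles import brute_force_likelihood

LOG2 = math.log10(2.0)


# --------------------------------------------------------------------------
# Pedigree structure
# --------------------------------------------------------------------------

class TestPedigreeValidation:
    def test_single_parent_rejected(self):
        with pytest.raises(PedigreeError):
            Individual("X", father="F", mother=None)

    def test_missing_parent_rejected(self):
        with pytest.raises(PedigreeError):
            Pedigree([Individual("C", "F", "M")])

    def test_cycle_rejected(self):
        inds = [Individual("A", "B", "C"), Individual("B", "A", "C"),
                Individual("C")]
        with pytest.raises(PedigreeError):
            Pedigree(inds)

    def test_duplicate_id_rejected(self):
        with pytest.raises(PedigreeError):
            Pedigree([Individual("A"), Individual("A")])

    def test_ped_round_trip(self, family_a, tmp_path):
        path = tmp_path / "fam.ped"
        family_a.to_ped(path)
        back = Pedigree.from_ped(path)
        assert set(back.members) == set(family_a.members)
        for iid in family_a.members:
            a, b = family_a[iid], back[iid]
            assert (a.father, a.mother, a.affection) == (b.father, b.mother, b.affection)


# --------------------------------------------------------------------------
# Marker QC
# --------------------------------------------------------------------------

def _panel(geno_rows, samples):
    info = pd.DataFrame({
        "marker": [f"m{i}" for i in range(len(geno_rows))],
        "cm": np.arange(len(geno_rows), dtype=float),
        "bp": 1000 * (np.arange(len(geno_rows)) + 1),
        "freq": 0.5,
    })
    geno = pd.DataFrame(geno_rows, columns=samples,
                        index=info["marker"], dtype=float)
    return MarkerPanel(info.set_index("marker", drop=False), geno)


class TestMarkerQC:
    def test_qc_rules(self):
        ped, _ = nuclear(2, 1)
        samples = ["F", "M", "C0", "C1"]
        panel = _panel([
            [1, 0, 1, 0],           # complete, polymorphic, consistent: retained
            [1, 0, np.nan, 0],      # missing in 1 of 4 samples: removed
            [0, 0, 0, 0],           # monomorphic: removed
            [0, 0, 2, 0],           # Mendelian-impossible child: blanked -> removed
        ], samples)
        kept, report = marker_qc(panel, ped)
        assert list(kept.info["marker"]) == ["m0"]
        assert bool(report.loc["m3", "n_blanked"] == 1)
        assert not bool(report.loc["m1", "complete"])

    def test_empty_result_is_not_failure(self):
        ped, _ = nuclear(1, 1)
        panel = _panel([[0, 0, 0]], ["F", "M", "C0"])
        kept, _ = marker_qc(panel, ped)
        assert len(kept) == 0

    def test_unexamined_connectors_do_not_count_against_call_rate(self, family_a_sub):
        # II-5 is an untyped obligate carrier; a marker typed in everyone else passes
        samples = [i for i in family_a_sub.topological_order]
        row = [1 if family_a_sub[s].affection == AFFECTED else 0 for s in samples]
        panel = _panel([row], samples)
        panel.genotypes.loc[:, "II-5"] = np.nan
        kept, _ = marker_qc(panel, family_a_sub)
        assert len(kept) == 1


# --------------------------------------------------------------------------
# Restriction to founders + affecteds
# --------------------------------------------------------------------------

class TestRestriction:
    def test_all_affected_is_identity(self):
        inds = [Individual("F", affection=AFFECTED),
                Individual("M", affection=AFFECTED),
                Individual("C", "F", "M", affection=AFFECTED)]
        ped = Pedigree(inds)
        sub = restrict_founders_affected(ped)
        assert set(sub.members) == {"F", "M", "C"}
        assert all(sub[i].affection == AFFECTED for i in sub.members)

    def test_nuclear_keeps_founders_plus_affected_child(self):
        ped, _ = nuclear(3, 1)
        sub = restrict_founders_affected(ped)
        assert set(sub.members) == {"F", "M", "C0"}

    def test_unaffected_nonfounders_dropped_connectors_marked(self):
        inds = [
            Individual("G1", affection=AFFECTED), Individual("G2", affection=UNAFFECTED),
            Individual("P", "G1", "G2", affection=UNAFFECTED),   # connector
            Individual("S", affection=UNAFFECTED),
            Individual("U", "G1", "G2", affection=UNAFFECTED),   # droppable sib
            Individual("C", "P", "S", affection=AFFECTED),
        ]
        sub = restrict_founders_affected(Pedigree(inds))
        assert "U" not in sub
        assert sub["P"].affection == UNKNOWN
        assert obligate_carriers(sub) == {"P"}

    def test_no_affected_raises(self):
        ped = Pedigree([Individual("F", affection=UNAFFECTED),
                        Individual("M", affection=UNAFFECTED)])
        with pytest.raises(PedigreeError):
            restrict_founders_affected(ped)


# --------------------------------------------------------------------------
# Exact likelihood vs the unfactorized brute-force oracle
# --------------------------------------------------------------------------

def _three_gen(extra_sib=False):
    inds = [
        Individual("A0", affection=AFFECTED), Individual("B0", affection=UNAFFECTED),
        Individual("P", "A0", "B0", affection=AFFECTED),
        Individual("S", affection=UNAFFECTED),
        Individual("C1", "P", "S", affection=AFFECTED),
        Individual("C2", "P", "S", affection=AFFECTED),
        Individual("C3", "P", "S", affection=UNAFFECTED),
    ]
    geno = {"A0": 1, "B0": 0, "P": 1, "S": 0, "C1": 1, "C2": 1, "C3": 0}
    if extra_sib:
        inds.append(Individual("P2", "A0", "B0", affection=AFFECTED))
        geno["P2"] = 1
    return Pedigree(inds), geno


def _oracle_cases():
    cases = []
    for n, a in [(2, 2), (3, 2), (4, 3)]:
        cases.append((f"nuclear_{n}_{a}",) + nuclear(n, a))
    cases.append(("three_gen_7",) + _three_gen())
    cases.append(("three_gen_8",) + _three_gen(extra_sib=True))
    ped, geno = nuclear(3, 3)
    geno = dict(geno)
    geno["C1"] = None          # one untyped member
    cases.append(("missing_genotype", ped, geno))
    ped, geno = nuclear(3, 3)
    geno = dict(geno)
    geno["C2"] = 0             # apparent recombinant
    cases.append(("recombinant", ped, geno))
    return cases


class TestLikelihoodAgainstOracle:
    @pytest.mark.parametrize("name,ped,geno",
                             _oracle_cases(), ids=lambda c: c if isinstance(c, str) else "")
    @pytest.mark.parametrize("linked", [True, False])
    def test_matches_brute_force(self, name, ped, geno, linked, model):
        assert len(ped) <= 8
        impl = pedigree_likelihood(ped, geno, model, linked=linked)
        oracle = brute_force_likelihood(ped, geno, model, linked=linked)
        assert impl == pytest.approx(oracle, abs=1e-9)

    def test_unaffected_only_pedigree_finite(self, model):
        ped = Pedigree([Individual("F", affection=UNAFFECTED),
                        Individual("M", affection=UNAFFECTED),
                        Individual("C", "F", "M", affection=UNAFFECTED)])
        ll = pedigree_likelihood(ped, {"F": 1, "M": 0, "C": 0}, model, linked=False)
        assert math.isfinite(ll)

    def test_meiosis_bound_refused(self, model):
        ped, geno = nuclear(12, 6)
        assert ped.n_meioses == 24
        with pytest.raises(EnumerationBoundError, match="22"):
            pedigree_likelihood(ped, geno, model, linked=True)


class TestLodScore:
    @pytest.mark.parametrize("n_children,expected_m", [(3, 2), (4, 3)])
    def test_cosegregating_ratio_is_2_to_m(self, n_children, expected_m, model):
        """Fully informative co-segregation: L(linked)/L(unlinked) = 2^m."""
        ped, geno = nuclear(n_children, n_children)
        assert informative_meioses(ped) == expected_m
        lod = lod_score(ped, geno, model)
        assert 10 ** lod == pytest.approx(2 ** expected_m, rel=1e-5)

    def test_uninformative_marker_lod_zero(self, model):
        ped, _ = nuclear(3, 3)
        assert lod_score(ped, {}, model) == pytest.approx(0.0, abs=1e-12)

    def test_phase_forced_recombinant_is_excluded(self, model):
        """A recombinant from a phase-known carrier has zero linked likelihood."""
        inds = [
            Individual("A0", affection=AFFECTED), Individual("B0", affection=UNAFFECTED),
            Individual("P", "A0", "B0", affection=AFFECTED),
            Individual("S", affection=UNAFFECTED),
            Individual("C", "P", "S", affection=AFFECTED),
        ]
        ped = Pedigree(inds)
        geno = {"A0": 2, "B0": 0, "P": 1, "S": 0, "C": 0}
        assert lod_score(ped, geno, model) is EXCLUDED

    def test_additivity_over_independent_pedigrees(self, model):
        ped1, geno1 = nuclear(3, 3)
        inds2 = [Individual("F2", affection=AFFECTED),
                 Individual("M2", affection=UNAFFECTED),
                 Individual("K0", "F2", "M2", affection=AFFECTED),
                 Individual("K1", "F2", "M2", affection=AFFECTED)]
        geno2 = {"F2": 1, "M2": 0, "K0": 1, "K1": 1}
        union = Pedigree(list(ped1.members.values()) + inds2)
        lod_union = lod_score(union, {**geno1, **geno2}, model)
        expected = lod_score(ped1, geno1, model) + lod_score(Pedigree(inds2), geno2, model)
        assert lod_union == pytest.approx(expected, abs=1e-9)

    def test_lod_bounded_by_max_attainable(self, model):
        ped, geno = nuclear(4, 4)
        bound = max_attainable_lod(ped)
        for flip in range(4):
            g = dict(geno)
            if flip:
                g[f"C{flip - 1}"] = None
            lod = lod_score(ped, g, model)
            if lod is not EXCLUDED:
                assert lod <= bound + 1e-9


class TestMaxAttainable:
    def test_no_informative_meioses(self):
        ped, _ = nuclear(1, 1)
        assert informative_meioses(ped) == 0
        assert max_attainable_lod(ped) == 0.0

    def test_nine_meioses_display_2_7(self):
        assert round(9 * LOG2, 1) == 2.7

    def test_family_a_bound_and_enumeration_agree(self, family_a_sub,
                                                  family_a_marker, model):
        assert informative_meioses(family_a_sub) == 9
        bound = max_attainable_lod(family_a_sub)
        assert round(bound, 1) == 2.7
        lod = lod_score(family_a_sub, family_a_marker, model)
        assert lod == pytest.approx(bound, abs=1e-5)


# --------------------------------------------------------------------------
# Interval extraction
# --------------------------------------------------------------------------

class TestExtractInterval:
    def test_published_flank_geometry(self):
        track = chr12_lod_track()
        (iv,) = extract_interval(track)
        assert iv.flank_left_bp == 107_595_567
        assert iv.flank_right_bp == 116_187_660
        assert iv.max_length_bp == 8_592_092
        assert iv.min_start_bp == 107_603_157
        assert iv.min_end_bp == 116_182_525

    def test_single_marker_plateau_one_bp_max_interval(self):
        track = pd.DataFrame({
            "marker": ["a", "b", "c"], "cm": [1.0, 1.1, 1.2],
            "bp": [999, 1000, 1001], "lod": [0.0, 1.0, 0.0]})
        (iv,) = extract_interval(track)
        assert iv.max_length_bp == 1
        assert iv.min_length_bp == 1

    def test_two_plateaus_ranked_longer_first(self):
        track = pd.DataFrame({
            "marker": list("abcdefg"), "cm": np.arange(7, dtype=float),
            "bp": [100, 200, 300, 400, 500, 520, 540],
            "lod": [0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0]})
        ivs = extract_interval(track)
        assert len(ivs) == 2
        assert ivs[0].max_length_bp >= ivs[1].max_length_bp
        assert ivs[0].min_start_bp == 200

    def test_excluded_markers_rank_below_everything(self):
        track = pd.DataFrame({
            "marker": ["a", "b", "c"], "cm": [0.0, 1.0, 2.0],
            "bp": [100, 200, 300], "lod": [EXCLUDED, 0.5, EXCLUDED]})
        (iv,) = extract_interval(track)
        assert iv.min_start_bp == 200
        assert iv.max_length_bp == 300 - 100 - 1

    def test_min_cm_report_filter(self):
        track = pd.DataFrame({
            "marker": list("abcde"), "cm": [0.0, 0.1, 0.2, 5.0, 9.0],
            "bp": [100, 200, 300, 40_000, 90_000],
            "lod": [0.0, 1.0, 0.0, 1.0, 1.0]})
        ivs = extract_interval(track, min_cm=1.0)
        assert len(ivs) == 1 and ivs[0].min_start_bp == 40_000

    def test_empty_track_raises(self):
        with pytest.raises(ValueError):
            extract_interval(pd.DataFrame({"marker": [], "cm": [], "bp": [],
                                           "lod": []}))


class TestCausalLocusRecovery:
    def test_causal_locus_inside_maximum_interval(self, model):
        """With informative flanking markers and full penetrance, the true
        locus falls inside the extracted maximum interval in >= 99% of seeds."""
        from famseq.syndata import (PedigreeSpec, TraitModel,
                                    simulate_marker_panel, simulate_pedigree,
                                    substream)

        recovered = attempted = 0
        for seed in range(100):
            ped, carriers = simulate_pedigree(
                PedigreeSpec(3, 3), TraitModel(), substream(seed, "rec-ped"))
            try:
                sub = restrict_founders_affected(ped)
            except PedigreeError:
                continue
            if sub.n_meioses > 22 or len(sub.affected) < 2:
                continue
            panel, causal_bp = simulate_marker_panel(
                sub, carriers, substream(seed, "rec-mk"))
            panel, _ = marker_qc(panel, sub)
            if len(panel) == 0:
                continue
            track = lod_track(sub, panel, model)
            iv = extract_interval(track)[0]
            lo = iv.flank_left_bp if iv.flank_left_bp is not None else 0
            hi = iv.flank_right_bp if iv.flank_right_bp is not None else 10 ** 12
            attempted += 1
            recovered += int(lo < causal_bp < hi)
        assert attempted >= 50
        assert recovered / attempted >= 0.99
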