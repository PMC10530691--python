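"""Scar classification, the rearrangement bonus, chromothripsis, aggregation.

The grid test checks the classifier against a literal, independently
hand-written rule table over state x size x placement x matched-translocation
count, on a mask-free toy chromosome.
"""

import itertools

import pytest

from hrdscar import (
    SCAR_CLASSES,
    ScoreConfig,
    classify_geometry,
    classify_scar,
    classify_sv_scar,
    compute_hrd,
    detect_chromothripsis,
    match_rearrangement_breakpoints,
    score_segment,
)
from hrdscar.variant_io import AneuploidyCall

from conftest import make_cnv, make_sv

MB = 1_000_000


class TestWeightTable:
    def test_nine_classes_and_weights(self):
        expected = {"TAI-0": 1, "TAI-1": 2, "TAI-LOH-1": 3,
                    "LOH-0": 1, "LOH-1": 2, "LOH-2": 3,
                    "LST-1": 1, "LST-2": 2, "LST-3": 3}
        assert {n: c.weight for n, c in SCAR_CLASSES.items()} == expected
        assert SCAR_CLASSES["TAI-LOH-1"].signature == "TAI"
        assert all(SCAR_CLASSES[n].signature == n.split("-")[0]
                   for n in expected if not n.startswith("TAI-LOH"))


class TestClassifySegment:
    @pytest.mark.parametrize("start,length,state,expected", [
        # terminal p placements (start=1)
        (1, 5 * MB, "loss", "TAI-0"),
        (1, 12 * MB, "gain", "TAI-1"),
        (1, 20 * MB, "loss", "TAI-LOH-1"),
        (1, 20 * MB, "gain", "TAI-1"),
        (1, 10 * MB, "gain", None),            # exactly 10 Mb: strict comparisons
        (1, 3 * MB, "loss", None),             # exactly 3 Mb: below TAI floor
        # interstitial placements (both ends break)
        (110 * MB, 16 * MB, "loss", "LOH-2"),
        (110 * MB, 16 * MB, "aoh", "LOH-2"),
        (110 * MB, 11 * MB, "gain", "LST-2"),
        (110 * MB, int(2.5 * MB), "loss", None),
        # centromere-anchored (start in cen: one break)
        (97 * MB, 16 * MB, "aoh", "LOH-1"),
        (97 * MB, 11 * MB, "gain", "LST-1"),
    ])
    def test_decision_table(self, toy_genome, start, length, state, expected):
        seg = make_cnv(start=start, length=length, state=state)
        geom = classify_geometry(seg, toy_genome)
        cls = classify_scar(seg, geom)
        assert (cls.name if cls else None) == expected

    def test_whole_chromosome_never_scores(self, toy_genome):
        seg = make_cnv(start=1, length=200_000_000)
        geom = classify_geometry(seg, toy_genome)
        assert classify_scar(seg, geom) is None

    def test_loh_0_on_wide_effective_centromere(self):
        # masks widen the effective centromeric region; with a permissive
        # stitch both ends of a >15 Mb AOH can sit inside it
        from hrdscar import ChromAnnotation, GenomeBuild
        wide = GenomeBuild("wide", (ChromAnnotation(
            "W", 200_000_000, (90_000_000, 110_000_000),
            masked_regions=((72_000_000, 89_900_000), (110_100_000, 120_000_000)),
        ),))
        seg = make_cnv(chrom="W", start=75_000_000, length=41 * MB, state="aoh")
        geom = classify_geometry(seg, wide)
        assert geom.cn_breakpoints == 0 and not geom.terminal
        assert classify_scar(seg, geom).name == "LOH-0"


class TestSVScars:
    def test_large_inversion_is_lst2(self):
        inv = make_sv(sv_type="inversion", chrom_a="T", pos_a=110 * MB,
                      chrom_b="T", pos_b=121 * MB, size=11 * MB)
        assert classify_sv_scar(inv).name == "LST-2"

    def test_small_inversion_scores_nothing(self):
        inv = make_sv(sv_type="inversion", chrom_a="T", pos_a=110 * MB,
                      chrom_b="T", pos_b=118 * MB, size=8 * MB)
        assert classify_sv_scar(inv) is None

    def test_large_insertion_is_lst3(self):
        ins = make_sv(sv_type="insertion", chrom_a="T", pos_a=110 * MB,
                      chrom_b="T", pos_b=110 * MB, size=11 * MB)
        assert classify_sv_scar(ins).name == "LST-3"

    def test_unmatched_interchromosomal_translocation_scores_one(self):
        cls = classify_sv_scar(make_sv())
        assert cls.name == "LST-1" and cls.weight == 1

    def test_translocation_rule_is_switchable(self):
        cfg = ScoreConfig(score_unmatched_translocations=False)
        assert classify_sv_scar(make_sv(), cfg) is None


class TestBreakpointMatching:
    def test_both_ends_matched(self, toy_genome):
        seg = make_cnv(start=110 * MB, length=16 * MB)
        svs = [make_sv(id="a", pos_a=seg.start + 100_000),
               make_sv(id="b", pos_a=seg.end - 200_000, pos_b=61 * MB)]
        assert match_rearrangement_breakpoints(seg, svs) == 2

    def test_one_sv_supports_at_most_one_end(self):
        seg = make_cnv(start=110 * MB, length=400_000)  # both ends within tol of one SV
        svs = [make_sv(id="a", pos_a=seg.start + 200_000)]
        assert match_rearrangement_breakpoints(seg, svs) == 1

    def test_tolerance_boundary(self):
        seg = make_cnv(start=110 * MB, length=16 * MB)
        near = [make_sv(pos_a=seg.start - 500_000)]
        far = [make_sv(pos_a=seg.start - 500_001)]
        assert match_rearrangement_breakpoints(seg, near) == 1
        assert match_rearrangement_breakpoints(seg, far) == 0

    def test_no_svs(self):
        assert match_rearrangement_breakpoints(make_cnv(), []) == 0


class TestScoreSegmentWorkedExamples:
    def test_subthreshold_deletion_with_two_translocation_ends(self, toy_genome):
        """5.3 Mb interstitial deletion flanked by translocations: 2 vs 0."""
        seg = make_cnv(start=110 * MB, length=5_300_000)
        geom = classify_geometry(seg, toy_genome)
        svs = [make_sv(id="a", pos_a=seg.start),
               make_sv(id="b", pos_a=seg.end, pos_b=61 * MB)]
        ogm = score_segment(seg, geom, svs, mode="ogm")
        assert ogm.total_points == 2 and ogm.base_points == 0
        assert ogm.scar_class.name == "LST-2"
        assert score_segment(seg, geom, svs, mode="cna") is None

    def test_large_deletion_with_one_translocation_end(self, toy_genome):
        """>15 Mb interstitial deletion, one end from a translocation: 4 vs 3."""
        seg = make_cnv(start=110 * MB, length=16 * MB)
        geom = classify_geometry(seg, toy_genome)
        svs = [make_sv(id="a", pos_a=seg.start)]
        ogm = score_segment(seg, geom, svs, mode="ogm")
        assert (ogm.base_points, ogm.bonus_points, ogm.total_points) == (3, 1, 4)
        cna = score_segment(seg, geom, svs, mode="cna")
        assert cna.total_points == 3 and cna.scar_class.name == "LOH-2"


class TestChromothripsis:
    @pytest.mark.parametrize("n,flagged", [(15, False), (16, True)])
    def test_fusion_count_boundary(self, n, flagged):
        svs = [make_sv(id=f"f{i}", chrom_a="T", pos_a=(i + 1) * MB,
                       chrom_b="T", pos_b=(i + 2) * MB) for i in range(n)]
        counts, flags = detect_chromothripsis(svs)
        assert counts == {"T": n}
        assert (("T" in flags) is flagged)

    def test_interchromosomal_translocations_do_not_count(self):
        svs = [make_sv(id=f"f{i}") for i in range(16)]  # all T->U
        counts, flags = detect_chromothripsis(svs)
        assert counts == {} and not flags

    def test_exclusion_zeroes_flagged_chromosome(self, toy_genome):
        svs = [make_sv(id=f"f{i}", chrom_a="T", pos_a=(i + 1) * MB,
                       chrom_b="T", pos_b=int((i + 1.2) * MB)) for i in range(16)]
        cnvs = [make_cnv(chrom="T", start=110 * MB, length=16 * MB),
                make_cnv(chrom="U", start=60 * MB, length=16 * MB)]
        keep = compute_hrd(svs, cnvs, [], toy_genome, mode="ogm")
        drop = compute_hrd(svs, cnvs, [], toy_genome,
                           score_config=ScoreConfig(exclude_chromothripsis=True),
                           mode="ogm")
        assert keep.chromothripsis_chroms == frozenset({"T"})
        assert keep.excluded_chroms == frozenset()
        assert drop.excluded_chroms == frozenset({"T"})
        assert drop.per_chromosome["T"] == 0
        assert drop.total == keep.per_chromosome["U"]


def _oracle_base_points(state: str, size_mb: int, placement: str) -> int:
    """Hand-derived rule table, written independently of the classifier."""
    loss_like = state in ("loss", "aoh")
    if placement == "terminal":
        if size_mb <= 3:
            return 0
        if loss_like and size_mb > 15:
            return 3                       # TAI-LOH-1
        if size_mb > 10:
            return 2                       # TAI-1
        return 1                           # TAI-0 (3 < size < 10)
    if placement == "interstitial":        # two break ends
        if loss_like and size_mb > 15:
            return 3                       # LOH-2
        if size_mb > 10:
            return 2                       # LST-2
        return 0
    if placement == "cen":                 # start inside the centromere
        if loss_like and size_mb > 15:
            return 2                       # LOH-1
        if size_mb > 10:
            return 1                       # LST-1
        return 0
    raise AssertionError(placement)


class TestOracleGrid:
    """Classifier vs brute-force table over the enumerated segment grid."""

    PLACEMENT_START = {"terminal": 1, "interstitial": 110 * MB, "cen": 96 * MB}

    @pytest.mark.parametrize("state,size_mb,placement,n_matched", list(
        itertools.product(["gain", "loss", "aoh"], [2, 4, 8, 11, 16, 20],
                          ["terminal", "interstitial", "cen"], [0, 1, 2])))
    def test_total_matches_oracle(self, toy_genome, state, size_mb, placement,
                                  n_matched):
        start = self.PLACEMENT_START[placement]
        seg = make_cnv(start=start, length=size_mb * MB, state=state)
        svs = [make_sv(id=f"m{i}", pos_a=seg.end if i == 0 else seg.start,
                       pos_b=(60 + i) * MB) for i in range(n_matched)]
        base = _oracle_base_points(state, size_mb, placement)
        # every retained interchromosomal translocation adds exactly one point,
        # whether consumed as an end bonus or scored as an unmatched event
        ogm = compute_hrd(svs, [seg], [], toy_genome, mode="ogm")
        cna = compute_hrd(svs, [seg], [], toy_genome, mode="cna")
        assert ogm.total == base + n_matched
        assert cna.total == base
        assert ogm.total >= cna.total


class TestAggregation:
    def test_empty_inputs_total_zero(self, toy_genome):
        result = compute_hrd([], [], [], toy_genome)
        assert result.total == 0 and result.scars == ()

    def test_additivity_and_signature_partition(self, toy_genome):
        svs = [make_sv(id="inv", sv_type="inversion", chrom_a="U", chrom_b="U",
                       pos_a=60 * MB, pos_b=72 * MB, size=12 * MB)]
        cnvs = [make_cnv(chrom="T", start=1, length=20 * MB),           # TAI-LOH-1
                make_cnv(chrom="T", start=110 * MB, length=16 * MB),    # LOH-2
                make_cnv(chrom="U", start=50 * MB, length=11 * MB,
                         state="gain")]                                 # LST-2
        result = compute_hrd(svs, cnvs, [], toy_genome, mode="ogm")
        assert result.total == sum(s.total_points for s in result.scars)
        assert result.total == sum(result.per_chromosome.values())
        assert result.total == sum(result.signature_totals.values())
        assert result.signature_totals == {"TAI": 3, "LOH": 3, "LST": 4}

    def test_aneuploidies_contribute_zero_in_every_mode(self, grch38):
        an = [AneuploidyCall("13", "gain"), AneuploidyCall("21", "gain"),
              AneuploidyCall("X", "whole_chrom_aoh")]
        for mode in ("ogm", "cna"):
            assert compute_hrd([], [], an, grch38, mode=mode).total == 0

    def test_adding_a_scar_never_decreases_total(self, toy_genome):
        base_cnvs = [make_cnv(chrom="T", start=110 * MB, length=16 * MB)]
        extra = make_cnv(chrom="U", start=60 * MB, length=16 * MB, id="x")
        t0 = compute_hrd([], base_cnvs, [], toy_genome).total
        t1 = compute_hrd([], base_cnvs + [extra], [], toy_genome).total
        assert t1 >= t0

    def test_deterministic_json(self, toy_genome):
        svs = [make_sv(id="a", pos_a=110 * MB), make_sv(id="b", pos_a=112 * MB)]
        cnvs = [make_cnv(), make_cnv(chrom="U", start=50 * MB, length=12 * MB,
                                     state="gain", id="g")]
        j1 = compute_hrd(svs, cnvs, [], toy_genome).to_json()
        j2 = compute_hrd(list(reversed(svs)), list(reversed(cnvs)), [],
                         toy_genome).to_json()
        assert j1 == j2
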