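"""GI->KO->EC/pathway mapping and MEGAN-like assignment rules."""

import io
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sapkit.artificial_blast import TabularHit, make_artificial_record
from sapkit.errors import SapkitError, UnknownKoError
from sapkit.functional_mapping import (
    AssignmentParams,
    TargetGroup,
    assign_read,
    assign_subjects,
    load_function_map,
)

from conftest import make_record

KO_TABLE = (
    "K02588\tnifH\tNitrogenase iron protein NifH\t1.18.6.1\tko00910\n"
    "K00368\tnirS\tNitrite reductase (NO-forming)\t1.7.2.1\tko00910\n"
    "K00001\tadh\tAlcohol dehydrogenase\t1.1.1.1\tko00010;ko00071\n"
    "K99999\torphan\tNo EC at all\t\t\n"
)


def _map(gi2ko_rows):
    mapping = "".join(f"{gi}\t{ko}\n" for gi, ko in gi2ko_rows)
    return load_function_map(io.StringIO(mapping), io.StringIO(KO_TABLE))


def _hit(read_id, gi, bit, ev=1e-20):
    return TabularHit(read_id, f"gi|{gi}|ref|P_{gi}.1", 90.0, 30, 3, 0, 1, 90, 1, 30, ev, bit)


NITROGEN = TargetGroup(name="nitrogen", pathway_ids={"ko00910"})


class TestLoadFunctionMap:
    def test_ko_row_fields(self):
        fmap = _map([(10, "K02588")])
        rec = fmap.ko_records["K02588"]
        assert rec.symbol == "nifH"
        assert rec.definition == "Nitrogenase iron protein NifH"
        assert rec.ec_numbers == {"1.18.6.1"}
        assert rec.pathway_ids == {"ko00910"}

    def test_empty_streams_give_empty_map(self):
        fmap = load_function_map(io.StringIO(""), io.StringIO(""))
        assert fmap.gi_to_kos == {} and fmap.ko_records == {}

    def test_duplicate_gi_rows_union_kos(self):
        fmap = _map([(10, "K02588"), (10, "K00368")])
        assert fmap.gi_to_kos[10] == {"K02588", "K00368"}

    def test_unknown_ko_rejected(self):
        with pytest.raises(UnknownKoError, match="K12345"):
            _map([(10, "K12345")])

    def test_reverse_indices_match_brute_force_inversion(self):
        rng = random.Random(3)
        kos = ["K02588", "K00368", "K00001", "K99999"]
        rows = [(gi, rng.choice(kos)) for gi in range(1, 201)]
        fmap = _map(rows)
        ec_brute = {}
        pw_brute = {}
        for gi, ko_set in fmap.gi_to_kos.items():
            for ko in ko_set:
                for ec in fmap.ko_records[ko].ec_numbers:
                    ec_brute.setdefault(ec, set()).add(gi)
                for pw in fmap.ko_records[ko].pathway_ids:
                    pw_brute.setdefault(pw, set()).add(gi)
        assert fmap.ec_to_gis == ec_brute
        assert fmap.pathway_to_gis == pw_brute


class TestAssignSubjects:
    def test_census_counts_all_mapped_subjects(self):
        """247 subjects all mapped to one KO appear as one census row of 247."""
        gis = list(range(1, 248))
        fmap = _map([(gi, "K02588") for gi in gis])
        hits = [make_artificial_record(make_record(gi, "M" * 50)) for gi in gis]
        result = assign_subjects(hits, fmap)
        row = result.census[result.census["ec"] == "1.18.6.1"].iloc[0]
        assert row["subject_count"] == 247
        assert row["ko"] == "K02588" and row["symbol"] == "nifH"

    def test_below_threshold_subject_excluded(self):
        fmap = _map([(1, "K02588")])
        hit = make_artificial_record(make_record(1, "M" * 50))
        hit.bit_score = 30.0
        result = assign_subjects([hit], fmap)
        assert result.gi_bins == {} and len(result.census) == 0

    def test_unmapped_gi_lands_in_not_assigned(self):
        fmap = _map([(1, "K02588")])
        hits = [
            make_artificial_record(make_record(1, "M" * 50)),
            make_artificial_record(make_record(2, "M" * 50)),
        ]
        result = assign_subjects(hits, fmap)
        assert result.not_assigned == {2}
        assert set(result.gi_bins) == {1}

    def test_census_equals_brute_force_over_random_map(self):
        rng = random.Random(9)
        kos = ["K02588", "K00368", "K00001"]
        rows = [(gi, rng.choice(kos)) for gi in range(1, 101) if rng.random() < 0.7]
        fmap = _map(rows)
        hits = [make_artificial_record(make_record(gi, "M" * 40)) for gi in range(1, 101)]
        result = assign_subjects(hits, fmap)
        for ko in kos:
            brute = sum(1 for gi, k in fmap.gi_to_kos.items() if ko in k)
            census_rows = result.census[result.census["ko"] == ko]
            if brute:
                assert (census_rows["subject_count"] == brute).all()
            else:
                assert census_rows.empty


class TestAssignRead:
    def test_single_mapped_hit(self):
        fmap = _map([(10, "K02588")])
        a = assign_read([_hit("r1", 10, 80.0)], fmap, target=NITROGEN)
        assert a.ko_ids == {"K02588"}
        assert a.in_target

    def test_unmapped_best_falls_through_to_mapped_co_optimal(self):
        """Best hit unmapped at 100 bits; mapped 95-bit hit within top 10% wins."""
        fmap = _map([(20, "K00368")])
        hits = [_hit("r1", 99, 100.0), _hit("r1", 20, 95.0)]
        a = assign_read(hits, fmap, target=NITROGEN)
        assert a.ko_ids == {"K00368"}
        assert a.best_hit.bit_score == 95.0

    def test_mapped_hit_outside_top_percent_ignored(self):
        fmap = _map([(20, "K00368")])
        hits = [_hit("r1", 99, 100.0), _hit("r1", 20, 85.0)]  # 85 < 90 = top-10% floor
        a = assign_read(hits, fmap, target=NITROGEN)
        assert a.ko_ids == set()

    def test_all_hits_below_min_bit_score_unassigned(self):
        fmap = _map([(10, "K02588")])
        a = assign_read([_hit("r1", 10, 34.9)], fmap, target=NITROGEN)
        assert a.ko_ids == set() and not a.in_target

    def test_tie_broken_by_evalue_then_gi(self):
        fmap = _map([(5, "K02588"), (3, "K00368"), (7, "K00001")])
        hits = [
            _hit("r1", 5, 80.0, ev=1e-18),
            _hit("r1", 3, 80.0, ev=1e-20),
            _hit("r1", 7, 80.0, ev=1e-20),
        ]
        a = assign_read(hits, fmap)
        assert a.ko_ids == {"K00368"}  # same E-value as gi 7 but smaller GI

    def test_off_target_assignment_not_in_target(self):
        fmap = _map([(7, "K00001")])
        a = assign_read([_hit("r1", 7, 80.0)], fmap, target=NITROGEN)
        assert a.ko_ids == {"K00001"} and not a.in_target

    def test_mixed_read_ids_rejected(self):
        fmap = _map([(10, "K02588")])
        with pytest.raises(SapkitError, match="multiple reads"):
            assign_read([_hit("r1", 10, 80.0), _hit("r2", 10, 80.0)], fmap)

    @given(st.randoms(use_true_random=False))
    def test_permutation_invariance(self, rnd):
        fmap = _map([(5, "K02588"), (3, "K00368"), (7, "K00001")])
        hits = [
            _hit("r1", 5, 82.0, ev=1e-19),
            _hit("r1", 3, 80.0, ev=1e-20),
            _hit("r1", 7, 79.0, ev=1e-18),
            _hit("r1", 99, 81.0, ev=1e-17),
        ]
        baseline = assign_read(hits, fmap, target=NITROGEN)
        shuffled = hits[:]
        rnd.shuffle(shuffled)
        again = assign_read(shuffled, fmap, target=NITROGEN)
        assert again.ko_ids == baseline.ko_ids
        assert again.in_target == baseline.in_target

    @given(st.floats(min_value=0, max_value=120, allow_nan=False))
    def test_raising_min_bit_score_is_monotone(self, threshold):
        """A stricter bit-score floor never adds assignments."""
        fmap = _map([(5, "K02588"), (3, "K00368")])
        hits = [_hit("r1", 5, 82.0), _hit("r1", 3, 50.0)]
        lenient = assign_read(hits, fmap, AssignmentParams(min_bit_score=35.0))
        strict = assign_read(hits, fmap, AssignmentParams(min_bit_score=35.0 + threshold))
        assert strict.ko_ids <= lenient.ko_ids or strict.ko_ids == set()

    def test_self_hit_assignment_matches_subject_binning(self):
        """A subject's own artificial record assigns the read as assign_subjects binned it."""
        fmap = _map([(42, "K02588")])
        rec = make_record(42, "M" * 60)
        art = make_artificial_record(rec)
        subjects = assign_subjects([art], fmap)
        read_view = assign_read([art], fmap)
        assert read_view.ko_ids == {ko for ko, _, _ in subjects.gi_bins[42]}


def test_target_group_requires_a_selector():
    with pytest.raises(SapkitError):
        TargetGroup(name="empty")
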