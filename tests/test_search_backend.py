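"""Six-frame translation, Karlin-Altschul statistics and the builtin aligner.

The independent alignment oracle is biotite's full (unbanded, unseeded)
optimal local alignment with the same BLOSUM62 matrix.  biotite charges a
length-g gap ``open + (g-1)*extend``, so the builtin convention
(``open + g*extend``) is reproduced by passing ``(-(open+extend), -extend)``.
"""

import math

import numpy as np
import pytest
import biotite.sequence as bioseq
import biotite.sequence.align as bioalign

from sapkit.errors import SapkitError
from sapkit.search_backend import (
    ScoringParams,
    evalue,
    search_translated,
    translate_six_frames,
)
from sapkit.synth_fixtures import _random_protein, _read_from_protein

from conftest import make_record

_ORACLE_MATRIX = bioalign.SubstitutionMatrix.std_protein_matrix()


def oracle_raw_score(dna_read: str, subject_aa: str) -> int:
    """Full Smith-Waterman score over all six frames (biotite, unbanded)."""
    subj = bioseq.ProteinSequence(subject_aa)
    best = 0
    for _frame, peptide in translate_six_frames(dna_read):
        if not peptide:
            continue
        aln = bioalign.align_optimal(
            bioseq.ProteinSequence(peptide), subj, _ORACLE_MATRIX,
            gap_penalty=(-12, -1), local=True, max_number=1,
        )[0]
        best = max(best, aln.score)
    return best


def raw_from_bits(bits: float, params: ScoringParams) -> int:
    return round((bits * math.log(2) + math.log(params.k_const)) / params.lam)


class TestTranslateSixFrames:
    def test_plus_one_frame(self):
        frames = dict(translate_six_frames("ATGGCC"))
        assert frames[1] == "MA"

    def test_minus_one_frame_is_reverse_complement_translation(self):
        frames = dict(translate_six_frames("ATGGCC"))
        assert frames[-1] == "GH"  # translate(GGCCAT)

    def test_stop_codon_emitted_as_star(self):
        assert dict(translate_six_frames("TAA"))[1] == "*"

    def test_n_containing_codon_is_x(self):
        assert dict(translate_six_frames("ATNGCC"))[1] == "XA"

    def test_trailing_partial_codons_dropped(self):
        frames = dict(translate_six_frames("ATGGCCA"))
        assert frames[1] == "MA"
        assert frames[2] == "WP"

    def test_short_read_gives_six_empty_peptides(self):
        frames = translate_six_frames("AT")
        assert len(frames) == 6
        assert all(pep == "" for _, pep in frames)


class TestEvalue:
    def test_worked_arithmetic(self):
        assert evalue(50, 33, 10**6) == pytest.approx(2.93e-8, rel=1e-3)

    def test_halving_db_halves_evalue(self):
        assert evalue(50, 33, 5 * 10**5) == pytest.approx(evalue(50, 33, 10**6) / 2)

    def test_one_extra_bit_halves_evalue(self):
        assert evalue(51, 33, 10**6) == pytest.approx(evalue(50, 33, 10**6) / 2)

    def test_monotone_in_database_size(self):
        """The filter theorem's engine: E against a sub-database never exceeds
        E against the full database at fixed score."""
        for bits in (30.0, 50.0, 120.0):
            assert evalue(bits, 33, 10**4) <= evalue(bits, 33, 10**7)


def _random_db(rng, n, lo=150, hi=300):
    return [
        make_record(i + 1, _random_protein(rng, int(rng.integers(lo, hi)))) for i in range(n)
    ]


class TestSearchTranslated:
    def test_exact_fragment_hits_source_at_full_identity(self):
        rng = np.random.default_rng(1)
        db = _random_db(rng, 10)
        read = _read_from_protein(rng, db[3].sequence, 120, 0.0)
        hits = search_translated([("r1", read)], db, ScoringParams())
        assert hits, "perfect 40-residue fragment must be found"
        best = hits[0]
        assert best.subject_id == db[3].canonical_id
        assert best.percent_identity == 100.0
        assert best.mismatches == 0

    def test_random_read_has_no_hits_at_default_cutoff(self):
        rng = np.random.default_rng(2)
        db = _random_db(rng, 10)
        read = "".join(rng.choice(list("ACGT"), size=100))
        assert search_translated([("r1", read)], db, ScoringParams()) == []

    def test_lowering_cutoff_never_adds_hits(self):
        rng = np.random.default_rng(3)
        db = _random_db(rng, 15)
        reads = [
            (f"r{i}", _read_from_protein(rng, db[i].sequence, 100, 0.10)) for i in range(10)
        ]
        loose = search_translated(reads, db, ScoringParams(evalue_cutoff=1e-5))
        strict = search_translated(reads, db, ScoringParams(evalue_cutoff=1e-10))
        loose_keys = {(h.query_id, h.subject_id) for h in loose}
        strict_keys = {(h.query_id, h.subject_id) for h in strict}
        assert strict_keys <= loose_keys
        assert all(h.evalue <= 1e-10 for h in strict)

    def test_at_most_one_hit_per_read_subject_pair(self):
        rng = np.random.default_rng(4)
        db = _random_db(rng, 5)
        reads = [(f"r{i}", _read_from_protein(rng, db[0].sequence, 100, 0.02)) for i in range(5)]
        hits = search_translated(reads, db, ScoringParams())
        keys = [(h.query_id, h.subject_id) for h in hits]
        assert len(keys) == len(set(keys))

    def test_db_residue_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        db = _random_db(rng, 3)
        with pytest.raises(SapkitError, match="db_residues"):
            search_translated([("r1", "ACG" * 30)], db, ScoringParams(db_residues=1))

    def test_minus_strand_hit_serialised_start_greater_than_end(self):
        rng = np.random.default_rng(6)
        db = _random_db(rng, 4)
        peptide_fragment = db[1].sequence[10:44]
        from sapkit.synth_fixtures import _reverse_translate, _COMPLEMENT

        dna = _reverse_translate(rng, peptide_fragment)
        rc = dna.translate(_COMPLEMENT)[::-1]
        hits = search_translated([("r1", rc)], db, ScoringParams())
        best = next(h for h in hits if h.subject_id == db[1].canonical_id)
        assert best.query_start > best.query_end
        assert best.subject_start <= best.subject_end

    def test_effective_search_space_override_scales_evalue(self):
        rng = np.random.default_rng(7)
        db = _random_db(rng, 6)
        read = _read_from_protein(rng, db[2].sequence, 100, 0.0)
        base = search_translated([("r1", read)], db, ScoringParams())
        total = sum(r.length for r in db)
        locked = search_translated(
            [("r1", read)], db, ScoringParams(effective_db_residues=total * 10)
        )
        b = next(h for h in base if h.subject_id == db[2].canonical_id)
        l = next(h for h in locked if h.subject_id == db[2].canonical_id)
        assert l.evalue == pytest.approx(b.evalue * 10)
        assert l.bit_score == b.bit_score


class TestAlignerAgainstFullSmithWaterman:
    def test_seeded_banded_score_equals_full_sw_on_derived_pairs(self):
        """On 24 random (read, subject) pairs where the read derives from the
        subject, the builtin banded score equals the unbanded optimum."""
        rng = np.random.default_rng(42)
        params = ScoringParams(evalue_cutoff=1e3)
        checked = 0
        for trial in range(24):
            subject = _random_protein(rng, int(rng.integers(60, 400)))
            read = _read_from_protein(rng, subject, int(rng.integers(60, 121)), 0.05)
            rec = make_record(trial + 1, subject)
            hits = search_translated([("r", read)], [rec], params)
            assert hits, "a read derived from the subject must produce a hit"
            builtin_raw = raw_from_bits(hits[0].bit_score, params)
            assert builtin_raw == oracle_raw_score(read, subject)
            checked += 1
        assert checked >= 20

    def test_banded_score_never_exceeds_full_sw_on_random_pairs(self):
        rng = np.random.default_rng(43)
        params = ScoringParams(evalue_cutoff=1e30)  # report everything found
        for trial in range(10):
            subject = _random_protein(rng, 120)
            read = "".join(rng.choice(list("ACGT"), size=90))
            hits = search_translated([("r", read)], [make_record(trial + 1, subject)], params)
            if hits:
                builtin_raw = raw_from_bits(hits[0].bit_score, params)
                assert builtin_raw <= oracle_raw_score(read, subject)
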