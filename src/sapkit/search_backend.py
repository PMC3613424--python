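"""Translated (DNA-vs-protein) similarity search with Karlin-Altschul statistics.

The built-in backend is a desk-scale seed-and-extend aligner: each read is
translated in all six frames, exact ``seed_word_length``-mer matches against
the protein database trigger a banded gapped Smith-Waterman extension around
the seed diagonals, and alignments are reported when their E-value clears the
cutoff.  Raw scores are converted to bits with fixed gapped BLOSUM62 constants
(lambda = 0.267, K = 0.041) and the E-value is the plain Karlin-Altschul
product E = m * n * 2**(-S_bits) over the raw search space — no length
corrections — so E is exactly linear in the database residue count n.  That
linearity is what makes a sub-database filter pass lossless: for a fixed
alignment, shrinking the database can only shrink E, never grow it.

An adapter contract for external tabular-output search tools (e.g. blastx)
is provided for production-scale runs; its statistics are the tool's own.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from sapkit._align import banded_local_align
from sapkit.artificial_blast import TabularHit, parse_tabular
from sapkit.errors import BackendError, BackendUnavailableError, SapkitError
from sapkit.refdb_io import ReferenceRecord

FRAME_LABELS = (1, 2, 3, -1, -2, -3)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = "".join(_BLOSUM62.alphabet)
_SUB_MATRIX = np.array(_BLOSUM62, dtype=np.int32)
_X_INDEX = _ALPHABET.index("X")

_ENCODE = np.full(256, _X_INDEX, dtype=np.int8)
for _i, _aa in enumerate(_ALPHABET):
    _ENCODE[ord(_aa)] = _i
_ENCODE[ord("U")] = _ALPHABET.index("C")  # selenocysteine scored as cysteine
_ENCODE[ord("J")] = _ALPHABET.index("L")

_N_STANDARD = 20  # indices 0..19 are the standard residues in the BLOSUM62 alphabet


@dataclass
class ScoringParams:
    """Alignment scoring and statistics parameters for the built-in backend.

    ``db_residues`` must equal the residue count of the searched database (it
    is filled in automatically when left unset); ``effective_db_residues``,
    when set, replaces n in the E-value only — the hook that lets a pipeline
    evaluate first-pass hits against the full database's search space.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k_const: float = 0.041
    evalue_cutoff: float = 1e-5
    seed_word_length: int = 3
    band_width: int = 15
    db_residues: Optional[int] = None
    effective_db_residues: Optional[int] = None

    def __post_init__(self) -> None:
        if self.matrix != "BLOSUM62":
            raise SapkitError("only the BLOSUM62 matrix is built in")
        for name in ("gap_open", "gap_extend", "lam", "k_const", "evalue_cutoff", "seed_word_length"):
            if getattr(self, name) <= 0:
                raise SapkitError(f"{name} must be positive")

    def bit_score(self, raw_score: float) -> float:
        """Karlin-Altschul normalised score: S = (lambda*S_raw - ln K) / ln 2."""
        return (self.lam * raw_score - math.log(self.k_const)) / math.log(2.0)

    def with_cutoff(self, cutoff: float) -> "ScoringParams":
        return replace(self, evalue_cutoff=cutoff)


def evalue(bit_score: float, query_residues: int, db_residues: int) -> float:
    """E = m * n * 2**(-S): expected chance alignments at score >= S.

    Strictly decreasing in S and exactly linear in the database size n, so at
    fixed S one extra bit halves E and halving n halves E.
    """
    return query_residues * db_residues * 2.0 ** (-bit_score)


def translate_six_frames(read: str) -> List[Tuple[int, str]]:
    """Translate a DNA read in all six frames with the standard genetic code.

    Returns ``[(frame, peptide), ...]`` for frames +1, +2, +3, -1, -2, -3.
    Trailing partial codons are dropped; stop codons appear as ``*`` and
    codons containing N as ``X``.  Reads shorter than 3 nt give six empty
    peptides.
    """
    seq = Seq(read.upper())
    rc = seq.reverse_complement()
    out: List[Tuple[int, str]] = []
    for frame in FRAME_LABELS:
        src = seq if frame > 0 else rc
        offset = abs(frame) - 1
        sub = src[offset : offset + 3 * ((len(src) - offset) // 3)]
        out.append((frame, str(sub.translate())))
    return out


def _encode(peptide: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(peptide.encode("ascii"), dtype=np.uint8)]


class SeedIndex:
    """Exact k-mer index over the encoded protein database.

    Only words made of the 20 standard residues are indexed; every such word
    has a positive BLOSUM62 self-score, so an exact match is always a valid
    seed.
    """

    def __init__(self, db: Sequence[ReferenceRecord], word_length: int = 3):
        self.word_length = word_length
        self.encoded: List[np.ndarray] = [_encode(rec.sequence) for rec in db]
        self.index: Dict[int, List[Tuple[int, int]]] = {}
        k = word_length
        for subj_idx, enc in enumerate(self.encoded):
            for pos in range(len(enc) - k + 1):
                word = enc[pos : pos + k]
                if (word >= _N_STANDARD).any():
                    continue
                code = 0
                for c in word:
                    code = code * _N_STANDARD + int(c)
                self.index.setdefault(code, []).append((subj_idx, pos))

    def seeds(self, query_enc: np.ndarray) -> Dict[int, List[int]]:
        """Map subject index -> list of seed diagonals (subject_pos - query_pos)."""
        k = self.word_length
        hits: Dict[int, List[int]] = {}
        for qpos in range(len(query_enc) - k + 1):
            word = query_enc[qpos : qpos + k]
            if (word >= _N_STANDARD).any():
                continue
            code = 0
            for c in word:
                code = code * _N_STANDARD + int(c)
            for subj_idx, spos in self.index.get(code, ()):
                hits.setdefault(subj_idx, []).append(spos - qpos)
        return hits


@dataclass
class _FrameHit:
    frame: int
    raw_score: int
    q_start: int  # peptide coords, 1-based
    q_end: int
    s_start: int
    s_end: int
    matches: int
    mismatches: int
    gap_opens: int
    align_len: int
    query_residues: int


def _peptide_to_read_coords(frame: int, read_len: int, p_start: int, p_end: int) -> Tuple[int, int]:
    """Map 1-based peptide alignment coords to nucleotide coords on the read.

    Plus frames give start <= end; minus frames are serialised with
    start > end, the usual tabular convention for reverse-strand hits.
    """
    offset = abs(frame) - 1
    if frame > 0:
        return offset + 3 * (p_start - 1) + 1, offset + 3 * p_end
    return read_len - offset - 3 * (p_start - 1), read_len - offset - 3 * p_end + 1


def _check_db_residues(db: Sequence[ReferenceRecord], params: ScoringParams) -> ScoringParams:
    total = sum(rec.length for rec in db)
    if params.db_residues is None:
        return replace(params, db_residues=total)
    if params.db_residues != total:
        raise SapkitError(
            f"params.db_residues ({params.db_residues}) != database residue count ({total})"
        )
    return params


def search_translated(
    reads: Iterable[Tuple[str, str]],
    db: Sequence[ReferenceRecord],
    params: Optional[ScoringParams] = None,
    seed_index: Optional[SeedIndex] = None,
) -> List[TabularHit]:
    """Six-frame seed-and-extend search of DNA reads against a protein database.

    For every read, exact seed-word matches trigger a banded gapped local
    alignment (band ``band_width`` diagonals around the seed diagonals) of
    each frame's peptide against the seeded subjects.  At most the single
    best alignment per (read, subject) pair is reported, provided its E-value
    clears ``params.evalue_cutoff``; output is ordered by read (input order)
    then ascending E-value.
    """
    db = list(db)
    if not db:
        raise SapkitError("search_translated requires a non-empty database")
    params = _check_db_residues(db, params or ScoringParams())
    n_stat = params.effective_db_residues or params.db_residues
    if seed_index is None:
        seed_index = SeedIndex(db, params.seed_word_length)
    half_band = (params.band_width - 1) // 2

    hits: List[TabularHit] = []
    for read_id, dna in reads:
        per_subject: Dict[int, _FrameHit] = {}
        for frame, peptide in translate_six_frames(dna):
            if len(peptide) < params.seed_word_length:
                continue
            enc = _encode(peptide)
            for subj_idx, diags in seed_index.seeds(enc).items():
                dlo = min(diags) - half_band
                dhi = max(diags) + half_band
                (score, qs, qe, ss, se, match, mism, gaps, alen) = banded_local_align(
                    enc,
                    seed_index.encoded[subj_idx],
                    _SUB_MATRIX,
                    params.gap_open,
                    params.gap_extend,
                    dlo,
                    dhi,
                )
                if score <= 0:
                    continue
                prev = per_subject.get(subj_idx)
                if prev is None or score > prev.raw_score:
                    per_subject[subj_idx] = _FrameHit(
                        frame, score, qs, qe, ss, se, match, mism, gaps, alen, len(peptide)
                    )
        read_hits: List[TabularHit] = []
        for subj_idx, fh in per_subject.items():
            bits = params.bit_score(fh.raw_score)
            e = evalue(bits, fh.query_residues, n_stat)
            if e > params.evalue_cutoff:
                continue
            q_start, q_end = _peptide_to_read_coords(fh.frame, len(dna), fh.q_start, fh.q_end)
            read_hits.append(
                TabularHit(
                    query_id=read_id,
                    subject_id=db[subj_idx].canonical_id,
                    percent_identity=round(100.0 * fh.matches / fh.align_len, 2),
                    alignment_length=fh.align_len,
                    mismatches=fh.mismatches,
                    gap_opens=fh.gap_opens,
                    query_start=q_start,
                    query_end=q_end,
                    subject_start=fh.s_start,
                    subject_end=fh.s_end,
                    evalue=e,
                    bit_score=round(bits, 1),
                )
            )
        read_hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.subject_id))
        hits.extend(read_hits)
    return hits


def align_pair_raw_score(dna_read: str, subject: ReferenceRecord) -> int:
    """Best raw local alignment score of a read (all six frames) vs one subject.

    Unbanded and unseeded — the full Smith-Waterman optimum over frames, used
    as a reference point for the banded search.
    """
    senc = _encode(subject.sequence)
    n = len(senc)
    best = 0
    for _frame, peptide in translate_six_frames(dna_read):
        if not peptide:
            continue
        enc = _encode(peptide)
        m = len(enc)
        score = banded_local_align(
            enc, senc, _SUB_MATRIX, 11, 1, -(m + 1), n + 1
        )[0]
        best = max(best, score)
    return best


@dataclass
class ExternalTool:
    """Configuration of an external translated-search executable.

    ``arg_template`` is formatted with ``query``, ``db``, ``evalue`` and
    ``out`` placeholders and must request 12-column tabular output.
    """

    executable: str = "blastx"
    arg_template: str = "-query {query} -db {db} -evalue {evalue} -outfmt 6 -out {out}"


def external_search_adapter(
    reads_path: "str | Path",
    db_path: "str | Path",
    params: ScoringParams,
    tool: Optional[ExternalTool] = None,
) -> List[TabularHit]:
    """Run an external tabular-output search tool and parse its hits.

    Contract-equivalent to :func:`search_translated` from the pipeline's view:
    hits above the E-value cutoff are dropped after parsing.  A missing
    executable raises :class:`BackendUnavailableError` (the built-in backend
    needs no external tools); a non-zero exit or unparseable output raises
    :class:`BackendError` carrying the tool's message.
    """
    tool = tool or ExternalTool()
    if shutil.which(tool.executable) is None:
        raise BackendUnavailableError(
            f"{tool.executable!r} not found on PATH; use the builtin backend instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        out_path = Path(tmp) / "hits.tsv"
        args = tool.arg_template.format(
            query=str(reads_path), db=str(db_path), evalue=params.evalue_cutoff, out=str(out_path)
        )
        proc = subprocess.run(
            [tool.executable] + args.split(),
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise BackendError(
                f"{tool.executable} exited with {proc.returncode}: {proc.stderr.strip()}"
            )
        try:
            with open(out_path) as fh:
                hits = list(parse_tabular(fh))
        except OSError as exc:
            raise BackendError(f"{tool.executable} produced no parseable output: {exc}") from exc
    return [h for h in hits if h.evalue <= params.evalue_cutoff]


def make_external_searcher(
    tool: Optional[ExternalTool] = None,
    formatdb_template: str = "makeblastdb -in {db} -dbtype prot",
):
    """Build a pipeline-compatible searcher around an external tool.

    The returned callable has the built-in searcher's signature
    ``(reads, db_records, params) -> hits``: it writes reads and database to
    temporary FASTA files, formats the database (``formatdb_template``, empty
    to skip) and delegates to :func:`external_search_adapter`.
    """
    from sapkit.refdb_io import write_fasta, write_reads_fasta  # local import: avoid cycle

    tool = tool or ExternalTool()

    def searcher(reads, db, params):
        if shutil.which(tool.executable) is None:
            raise BackendUnavailableError(
                f"{tool.executable!r} not found on PATH; use the builtin backend instead"
            )
        with tempfile.TemporaryDirectory() as tmp:
            reads_path = Path(tmp) / "reads.fasta"
            db_path = Path(tmp) / "db.fasta"
            with open(reads_path, "w") as fh:
                write_reads_fasta(reads, fh)
            with open(db_path, "w") as fh:
                write_fasta(db, fh)
            if formatdb_template:
                cmd = formatdb_template.format(db=str(db_path)).split()
                if shutil.which(cmd[0]) is None:
                    raise BackendUnavailableError(f"{cmd[0]!r} not found on PATH")
                proc = subprocess.run(cmd, capture_output=True, text=True)
                if proc.returncode != 0:
                    raise BackendError(f"{cmd[0]} failed: {proc.stderr.strip()}")
            return external_search_adapter(reads_path, db_path, params, tool)

    return searcher
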