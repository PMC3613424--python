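"""MEGAN-like functional binning of subjects and reads via GI→KO→EC/pathway maps.

The assigner mirrors the functional half of MEGAN's behaviour on tabular
alignment input: a hit below the minimum bit score (default 35) is ignored;
among the survivors of one read, hits within ``top_percent`` (default 10%) of
the best bit score are co-optimal, and the read inherits the KO set of the
highest-scoring co-optimal hit whose GI is functionally mapped.  Ties on bit
score are broken by smaller E-value, then smaller GI, so assignment is
deterministic and independent of hit order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from sapkit.artificial_blast import TabularHit
from sapkit.errors import SapkitError, UnknownKoError

logger = logging.getLogger(__name__)

_GI_IN_ID_RE = re.compile(r"gi\|(\d+)\|?")

NOT_ASSIGNED = "not assigned"


def gi_from_subject_id(subject_id: str) -> Optional[int]:
    """Extract the leading GI number from an id like ``gi|22536352|ref|NP_687203.1``."""
    m = _GI_IN_ID_RE.match(subject_id)
    return int(m.group(1)) if m else None


@dataclass
class KoRecord:
    """One KEGG-orthology group: gene symbol, definition, EC numbers, pathways.

    Partial EC codes such as ``1.13.12.-`` are opaque labels, not wildcards.
    """

    ko_id: str
    symbol: str = ""
    definition: str = ""
    ec_numbers: Set[str] = field(default_factory=set)
    pathway_ids: Set[str] = field(default_factory=set)


@dataclass
class FunctionMap:
    """GI→KO and KO→EC/pathway lookup with reverse indices built on load."""

    gi_to_kos: Dict[int, Set[str]] = field(default_factory=dict)
    ko_records: Dict[str, KoRecord] = field(default_factory=dict)
    ec_to_gis: Dict[str, Set[int]] = field(default_factory=dict)
    pathway_to_gis: Dict[str, Set[int]] = field(default_factory=dict)
    ko_to_gis: Dict[str, Set[int]] = field(default_factory=dict)

    def rebuild_reverse_indices(self) -> None:
        self.ec_to_gis = {}
        self.pathway_to_gis = {}
        self.ko_to_gis = {}
        for gi, kos in self.gi_to_kos.items():
            for ko in kos:
                self.ko_to_gis.setdefault(ko, set()).add(gi)
                rec = self.ko_records[ko]
                for ec in rec.ec_numbers:
                    self.ec_to_gis.setdefault(ec, set()).add(gi)
                for pw in rec.pathway_ids:
                    self.pathway_to_gis.setdefault(pw, set()).add(gi)

    def kos_for_gi(self, gi: Optional[int]) -> Set[str]:
        if gi is None:
            return set()
        return self.gi_to_kos.get(gi, set())


@dataclass
class TargetGroup:
    """The user's selection of a sub-database: any union of ECs, KOs and pathways."""

    name: str
    ec_numbers: Set[str] = field(default_factory=set)
    ko_ids: Set[str] = field(default_factory=set)
    pathway_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.ec_numbers or self.ko_ids or self.pathway_ids):
            raise SapkitError(f"target group {self.name!r} has no selectors")

    def contains_ko(self, ko: KoRecord) -> bool:
        return (
            ko.ko_id in self.ko_ids
            or bool(ko.ec_numbers & self.ec_numbers)
            or bool(ko.pathway_ids & self.pathway_ids)
        )


@dataclass
class AssignmentParams:
    """Assigner thresholds: minimum bit score and the co-optimal top-percent band."""

    min_bit_score: float = 35.0
    top_percent: float = 10.0

    def __post_init__(self) -> None:
        if self.min_bit_score < 0:
            raise SapkitError("min_bit_score must be >= 0")
        if not 0 <= self.top_percent <= 100:
            raise SapkitError("top_percent must be in [0, 100]")


@dataclass
class Assignment:
    """The functional assignment of one read: its KO set and whether it is on-target."""

    read_id: str
    ko_ids: Set[str] = field(default_factory=set)
    best_hit: Optional[TabularHit] = None
    in_target: bool = False


def load_function_map(mapping_stream: IO[str], ko_stream: IO[str]) -> FunctionMap:
    """Load GI→KO rows and KO description rows into a :class:`FunctionMap`.

    ``mapping_stream`` rows: ``gi<TAB>ko_id``; duplicate GI rows union their KOs.
    ``ko_stream`` rows: ``ko_id<TAB>symbol<TAB>definition<TAB>ec;ec<TAB>pw;pw``
    (the EC and pathway fields may be empty).  A GI row naming a KO absent from
    the KO table raises :class:`UnknownKoError`.
    """
    fmap = FunctionMap()
    for line in ko_stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        parts += [""] * (5 - len(parts))
        ko_id, symbol, definition, ecs, pathways = parts[:5]
        fmap.ko_records[ko_id] = KoRecord(
            ko_id=ko_id,
            symbol=symbol,
            definition=definition,
            ec_numbers={e for e in ecs.split(";") if e},
            pathway_ids={p for p in pathways.split(";") if p},
        )
    for line_no, line in enumerate(mapping_stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        gi_text, ko_id = line.split("\t")[:2]
        if ko_id not in fmap.ko_records:
            raise UnknownKoError(f"line {line_no}: GI {gi_text} maps to unknown KO {ko_id!r}")
        fmap.gi_to_kos.setdefault(int(gi_text), set()).add(ko_id)
    fmap.rebuild_reverse_indices()
    return fmap


@dataclass
class SubjectAssignments:
    """Result of binning reference subjects from artificial self-hits."""

    gi_bins: Dict[int, Set[Tuple[str, str, str]]]  # gi -> {(ko, ec, pathway)}
    not_assigned: Set[int]
    census: pd.DataFrame  # columns: ec, ko, symbol, definition, subject_count


def assign_subjects(
    artificial_hits: Iterable[TabularHit],
    fmap: FunctionMap,
    params: Optional[AssignmentParams] = None,
) -> SubjectAssignments:
    """Bin every reference subject from its artificial self-hit record.

    A subject whose hit clears ``min_bit_score`` is binned to every
    (KO, EC, pathway) combination its GI maps to; unmapped GIs land in the
    "not assigned" bucket.  The census counts subjects per (EC, KO) pair, the
    shape of a per-enzyme sub-database report.
    """
    params = params or AssignmentParams()
    gi_bins: Dict[int, Set[Tuple[str, str, str]]] = {}
    not_assigned: Set[int] = set()
    per_ko_subjects: Dict[str, Set[int]] = {}
    for hit in artificial_hits:
        if hit.query_id != hit.subject_id:
            logger.warning(
                "non-self-hit artificial record (query %s != subject %s); using subject id",
                hit.query_id,
                hit.subject_id,
            )
        gi = gi_from_subject_id(hit.subject_id)
        if gi is None:
            continue
        if hit.bit_score < params.min_bit_score:
            continue
        kos = fmap.kos_for_gi(gi)
        if not kos:
            not_assigned.add(gi)
            continue
        bins = gi_bins.setdefault(gi, set())
        for ko in kos:
            per_ko_subjects.setdefault(ko, set()).add(gi)
            rec = fmap.ko_records[ko]
            ecs = rec.ec_numbers or {""}
            pws = rec.pathway_ids or {""}
            for ec in ecs:
                for pw in pws:
                    bins.add((ko, ec, pw))
    rows = []
    for ko, gis in per_ko_subjects.items():
        rec = fmap.ko_records[ko]
        for ec in sorted(rec.ec_numbers) or [""]:
            rows.append(
                {
                    "ec": ec,
                    "ko": ko,
                    "symbol": rec.symbol,
                    "definition": rec.definition,
                    "subject_count": len(gis),
                }
            )
    census = pd.DataFrame(rows, columns=["ec", "ko", "symbol", "definition", "subject_count"])
    census = census.sort_values(["ec", "ko"]).reset_index(drop=True)
    return SubjectAssignments(gi_bins=gi_bins, not_assigned=not_assigned, census=census)


def assign_read(
    hits_for_one_read: Sequence[TabularHit],
    fmap: FunctionMap,
    params: Optional[AssignmentParams] = None,
    target: Optional[TargetGroup] = None,
) -> Assignment:
    """Assign one read from its alignment hits.

    Hits below ``min_bit_score`` are discarded; of the survivors only hits
    within ``top_percent`` of the best bit score are kept; the read receives
    the KO set of the highest-scoring kept hit whose GI has a KO mapping
    (ties: smaller E-value, then smaller GI).  The KO set is empty when no
    kept hit is mapped.
    """
    params = params or AssignmentParams()
    hits = list(hits_for_one_read)
    if not hits:
        raise SapkitError("assign_read called with no hits")
    read_ids = {h.query_id for h in hits}
    if len(read_ids) != 1:
        raise SapkitError(f"assign_read received hits for multiple reads: {sorted(read_ids)}")
    read_id = hits[0].query_id

    survivors = [h for h in hits if h.bit_score >= params.min_bit_score]
    assignment = Assignment(read_id=read_id)
    if not survivors:
        return assignment
    best_bit = max(h.bit_score for h in survivors)
    floor = (1.0 - params.top_percent / 100.0) * best_bit
    kept = [h for h in survivors if h.bit_score >= floor]

    def rank(h: TabularHit):
        gi = gi_from_subject_id(h.subject_id)
        return (-h.bit_score, h.evalue, gi if gi is not None else float("inf"))

    for hit in sorted(kept, key=rank):
        kos = fmap.kos_for_gi(gi_from_subject_id(hit.subject_id))
        if kos:
            assignment.ko_ids = set(kos)
            assignment.best_hit = hit
            break
    if target is not None and assignment.ko_ids:
        assignment.in_target = any(
            target.contains_ko(fmap.ko_records[ko]) for ko in assignment.ko_ids
        )
    return assignment


def group_hits_by_read(hits: Iterable[TabularHit]) -> Dict[str, List[TabularHit]]:
    """Group a hit stream by query id, preserving first-seen read order."""
    grouped: Dict[str, List[TabularHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    return grouped
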