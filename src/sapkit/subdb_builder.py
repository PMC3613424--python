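"""Turning a target group into a GI list and a sub-database FASTA.

The sub-database is the subset of the full reference database whose subjects
the functional assigner bins into the target group.  Records keep their full
original deflines so downstream annotation of sub-database hits and of
full-database hits is identical.  Extraction is a single streaming pass, so a
database far larger than RAM can be subset on a desktop machine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Set, Union

from sapkit.errors import SapkitError
from sapkit.functional_mapping import FunctionMap, TargetGroup
from sapkit.refdb_io import ReferenceRecord, extract_by_gi, write_fasta

logger = logging.getLogger(__name__)


def select_target_gis(fmap: FunctionMap, target: TargetGroup) -> Set[int]:
    """Union of GIs reachable from the target's EC, KO and pathway selectors.

    Selectors naming an EC/KO/pathway absent from the map are warned about
    (listed once) but do not fail the selection.
    """
    gis: Set[int] = set()
    unmatched = []
    for ec in sorted(target.ec_numbers):
        found = fmap.ec_to_gis.get(ec)
        if found:
            gis |= found
        else:
            unmatched.append(f"EC:{ec}")
    for ko in sorted(target.ko_ids):
        found = fmap.ko_to_gis.get(ko)
        if found:
            gis |= found
        else:
            unmatched.append(f"KO:{ko}")
    for pw in sorted(target.pathway_ids):
        found = fmap.pathway_to_gis.get(pw)
        if found:
            gis |= found
        else:
            unmatched.append(f"pathway:{pw}")
    if unmatched:
        logger.warning(
            "target group %r: %d selector(s) matched no GI: %s",
            target.name,
            len(unmatched),
            ", ".join(unmatched),
        )
    return gis


@dataclass
class SubdbStats:
    """What came out of a sub-database build."""

    records_written: int
    residues_written: int
    gis_unmatched: int

    def to_tsv(self) -> str:
        return (
            "records_written\tresidues_written\tgis_unmatched\n"
            f"{self.records_written}\t{self.residues_written}\t{self.gis_unmatched}\n"
        )


def build_subdb(
    refdb: Union[IO[str], Iterable[ReferenceRecord]],
    gi_set: Set[int],
    out_stream: IO[str],
) -> SubdbStats:
    """Stream-extract the GI set from the full database into a sub-database FASTA."""
    unmatched: Set[int] = set()
    records = 0
    residues = 0

    def counted():
        nonlocal records, residues
        for rec in extract_by_gi(refdb, gi_set, unmatched_out=unmatched):
            records += 1
            residues += rec.length
            yield rec

    write_fasta(counted(), out_stream)
    stats = SubdbStats(
        records_written=records,
        residues_written=residues,
        gis_unmatched=len(unmatched),
    )
    logger.info(
        "sub-database: %d records, %d residues, %d GI(s) unmatched",
        stats.records_written,
        stats.residues_written,
        stats.gis_unmatched,
    )
    return stats


def build_subdb_records(
    refdb: Union[IO[str], Iterable[ReferenceRecord]],
    fmap: FunctionMap,
    target: TargetGroup,
) -> list:
    """In-memory convenience: select target GIs and materialise their records."""
    gi_set = select_target_gis(fmap, target)
    if not gi_set:
        raise SapkitError(f"target group {target.name!r} selected no GIs from the map")
    return list(extract_by_gi(refdb, gi_set))
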