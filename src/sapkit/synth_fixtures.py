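"""Synthetic reference databases, function maps and simulated reads.

The generator emulates the structure a pathway-targeted annotation run sees in
the wild: a reference database in which a few orthologous families (each tied
to one KO with a distinct EC under one pathway) sit among unrelated background
proteins, and a read set in which a fraction of 100 nt DNA reads derive from
those families.  Optional "trap" constructs exercise the pipeline's
verification pass: a target-family protein T has a closely related OFF-target
paralog P, and reads derived from P align to T above the cutoff but to P
strictly better — the filter pass admits them, the verification pass must
discard them.

Family members are point-substituted copies of a family ancestor; reads are
reverse-translated protein fragments (uniform synonymous codons, random
strand) with DNA substitutions.  All randomness flows from the scenario seed
through per-stage generators; identical spec and seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from sapkit.errors import SapkitError
from sapkit.functional_mapping import FunctionMap, KoRecord, TargetGroup
from sapkit.refdb_io import ReferenceRecord

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
DNA = "ACGT"

# Standard-code codons per residue (stop codons excluded).
_CODONS: Dict[str, List[str]] = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"],
    "D": ["GAT", "GAC"],
    "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Nitrogen-cycle orthologous groups used for target families (one distinct EC
# each, all under the nitrogen-metabolism pathway map).
TARGET_KO_POOL = [
    ("K02588", "nifH", "Nitrogenase iron protein NifH", "1.18.6.1"),
    ("K00368", "nirS", "Nitrite reductase (NO-forming)", "1.7.2.1"),
    ("K00376", "nosZ", "Nitrous-oxide reductase", "1.7.99.6"),
    ("K00362", "nirB", "Nitrite reductase (NAD(P)H) large subunit", "1.7.1.4"),
    ("K03385", "nrfA", "Cytochrome c-552", "1.7.2.2"),
    ("K00366", "nirA", "Ferredoxin-nitrite reductase", "1.7.7.1"),
    ("K10535", "hao", "Hydroxylamine oxidase", "1.7.3.4"),
    ("K00360", "nasB", "Nitrate reductase (NADH)", "1.7.1.1"),
]
TARGET_PATHWAY = "ko00910"

# Off-target groups (fatty-acid metabolism flavoured) for background proteins
# and trap paralogs.
OFFTARGET_KO_POOL = [
    ("K00001", "adh", "Alcohol dehydrogenase", "1.1.1.1"),
    ("K00128", "aldH", "Aldehyde dehydrogenase (NAD+)", "1.2.1.3"),
    ("K00022", "fadB", "3-hydroxyacyl-CoA dehydrogenase", "1.1.1.35"),
    ("K01897", "fadD", "Long-chain acyl-CoA synthetase", "6.2.1.3"),
]
OFFTARGET_PATHWAY = "ko00071"

GI_BASE = 1_000_001


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic annotation scenario.

    Defaults are scenario S1, the package's standard verification scenario:
    3 target families of 5 members, 2 trap constructs, 40 background
    proteins, and 500 reads of 100 nt at 2% DNA substitution, seed 42.
    """

    n_target_families: int = 3
    members_per_family: int = 5
    n_background_proteins: int = 40
    protein_length_range: Tuple[int, int] = (120, 240)
    n_reads: int = 500
    read_length: int = 100
    substitution_rate: float = 0.02
    fraction_target_reads: float = 0.3
    trap_families: int = 2
    trap_reads_per_family: int = 10
    member_divergence: float = 0.05
    trap_divergence: float = 0.12
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "n_target_families",
            "members_per_family",
            "n_background_proteins",
            "n_reads",
            "read_length",
            "trap_families",
            "trap_reads_per_family",
        ):
            if getattr(self, name) < 0:
                raise SapkitError(f"{name} must be >= 0")
        for name in ("substitution_rate", "fraction_target_reads", "member_divergence", "trap_divergence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SapkitError(f"{name} must be in [0, 1]")


@dataclass
class ReferenceSetBundle:
    """In-memory product of :func:`generate_reference_set`."""

    records: List[ReferenceRecord]
    fmap: FunctionMap
    target: Optional[TargetGroup]
    truth_subjects: pd.DataFrame  # gi, kind, family, ko, ec
    gi2ko_rows: List[Tuple[int, str]]
    ko_rows: List[Tuple[str, str, str, str, str]]  # ko, symbol, definition, ecs, pathways

    @property
    def target_family_gis(self) -> Set[int]:
        mask = self.truth_subjects["kind"].isin(["target_member", "trap_target"])
        return set(self.truth_subjects.loc[mask, "gi"])


@dataclass
class Scenario:
    """A complete scenario: reference bundle plus simulated reads with truth."""

    spec: ScenarioSpec
    bundle: ReferenceSetBundle
    reads: List[Tuple[str, str]]
    truth_reads: pd.DataFrame  # read_id, source, source_gi, ko, must_exclude


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _make_record(gi: int, acc: str, description: str, sequence: str) -> ReferenceRecord:
    header = f"gi|{gi}|ref|{acc}| {description}"
    return ReferenceRecord(
        primary_gi=gi,
        canonical_id=f"gi|{gi}|ref|{acc}",
        all_headers=[header],
        sequence=sequence,
    )


def _ko_catalog(spec: ScenarioSpec) -> Tuple[list, list]:
    """Target-family and off-target KO descriptors, extended synthetically if needed."""
    needed_target = spec.n_target_families + spec.trap_families
    targets = list(TARGET_KO_POOL)
    i = 1
    while len(targets) < needed_target:
        targets.append((f"K9{i:04d}", f"syn{i}", f"Synthetic target family {i}", f"3.5.1.{i}"))
        i += 1
    needed_off = spec.trap_families + 2
    offs = list(OFFTARGET_KO_POOL)
    i = 1
    while len(offs) < needed_off:
        offs.append((f"K8{i:04d}", f"off{i}", f"Synthetic off-target family {i}", f"2.7.7.{i}"))
        i += 1
    return targets[:needed_target], offs[:needed_off]


def generate_reference_set(spec: ScenarioSpec) -> ReferenceSetBundle:
    """Build the synthetic reference database, function map, target and truth.

    Target families are mutated copies of a family ancestor so within-family
    identity is far above background; each family is tied to one KO with a
    distinct EC under the target pathway.  Trap constructs add, per trap, one
    target-mapped protein T and one off-target paralog P close to T.
    Background proteins are random sequences, a quarter of them mapped to
    off-target KOs and the rest unmapped.
    """
    rng = np.random.default_rng([spec.seed, 0])
    lo, hi = spec.protein_length_range
    target_kos, off_kos = _ko_catalog(spec)

    records: List[ReferenceRecord] = []
    gi2ko: List[Tuple[int, str]] = []
    truth_rows: List[dict] = []
    used_kos: Set[str] = set()
    gi = GI_BASE

    def add(kind: str, family: str, ko: Optional[str], ec: str, desc: str, seq: str) -> int:
        nonlocal gi
        this_gi = gi
        gi += 1
        acc = f"SP_{this_gi % 1_000_000:06d}.1"
        records.append(_make_record(this_gi, acc, desc, seq))
        if ko is not None:
            gi2ko.append((this_gi, ko))
            used_kos.add(ko)
        truth_rows.append(
            {"gi": this_gi, "kind": kind, "family": family, "ko": ko or "", "ec": ec}
        )
        return this_gi

    # Ordinary target families.
    for f in range(spec.n_target_families):
        ko, symbol, definition, ec = target_kos[f]
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_protein(rng, length)
        for m in range(spec.members_per_family):
            seq = _mutate_protein(rng, ancestor, spec.member_divergence)
            add("target_member", symbol, ko, ec, f"{definition} [{symbol} member {m+1}]", seq)

    # Trap constructs: target protein T plus off-target paralog P close to T.
    for t in range(spec.trap_families):
        ko_t, sym_t, def_t, ec_t = target_kos[spec.n_target_families + t]
        ko_p, sym_p, def_p, ec_p = off_kos[t]
        length = int(rng.integers(lo, hi + 1))
        paralog = _random_protein(rng, length)  # P is the read source
        target_protein = _mutate_protein(rng, paralog, spec.trap_divergence)
        add("trap_target", sym_t, ko_t, ec_t, f"{def_t} [trap target]", target_protein)
        add("trap_paralog", sym_t, ko_p, ec_p, f"{def_p} [trap paralog]", paralog)

    # Background proteins: ~1/4 mapped off-target, the rest unmapped.
    for b in range(spec.n_background_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_protein(rng, length)
        if b % 4 == 0 and off_kos:
            ko_b, sym_b, def_b, ec_b = off_kos[(spec.trap_families + b) % len(off_kos)]
            add("background_mapped", "", ko_b, ec_b, f"{def_b} [background]", seq)
        else:
            add("background", "", None, "", "hypothetical protein", seq)

    ko_rows: List[Tuple[str, str, str, str, str]] = []
    for ko, symbol, definition, ec in target_kos:
        ko_rows.append((ko, symbol, definition, ec, TARGET_PATHWAY))
    for ko, symbol, definition, ec in off_kos:
        ko_rows.append((ko, symbol, definition, ec, OFFTARGET_PATHWAY))

    fmap = FunctionMap()
    for ko, symbol, definition, ecs, pathways in ko_rows:
        fmap.ko_records[ko] = KoRecord(
            ko_id=ko,
            symbol=symbol,
            definition=definition,
            ec_numbers={e for e in ecs.split(";") if e},
            pathway_ids={p for p in pathways.split(";") if p},
        )
    for g, ko in gi2ko:
        fmap.gi_to_kos.setdefault(g, set()).add(ko)
    fmap.rebuild_reverse_indices()

    target = None
    if spec.n_target_families + spec.trap_families > 0:
        target = TargetGroup(name="nitrogen", pathway_ids={TARGET_PATHWAY})

    truth = pd.DataFrame(truth_rows, columns=["gi", "kind", "family", "ko", "ec"])
    return ReferenceSetBundle(
        records=records,
        fmap=fmap,
        target=target,
        truth_subjects=truth,
        gi2ko_rows=gi2ko,
        ko_rows=ko_rows,
    )


def _reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in peptide)


def _mutate_dna(rng: np.random.Generator, dna: str, rate: float) -> str:
    out = list(dna)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [b for b in DNA if b != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _read_from_protein(
    rng: np.random.Generator, seq: str, read_length: int, substitution_rate: float
) -> str:
    n_aa = -(-read_length // 3)  # ceil: enough residues to cover the read
    start = int(rng.integers(0, len(seq) - n_aa + 1))
    dna = _reverse_translate(rng, seq[start : start + n_aa])[:read_length]
    dna = _mutate_dna(rng, dna, substitution_rate)
    if rng.random() < 0.5:
        dna = dna.translate(_COMPLEMENT)[::-1]
    return dna


def simulate_reads(
    bundle: ReferenceSetBundle, spec: ScenarioSpec
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Simulate the read set of a scenario with per-read ground-truth labels.

    Composition: ``fraction_target_reads`` of the reads are fragments of
    target-family members; ``trap_reads_per_family`` reads per trap derive
    from the off-target paralog (labelled must-exclude); the remainder splits
    evenly between background-protein fragments and uniform random DNA.
    """
    rng = np.random.default_rng([spec.seed, 1])
    by_gi = {rec.primary_gi: rec for rec in bundle.records}
    truth = bundle.truth_subjects
    min_len = min((rec.length for rec in bundle.records), default=0)
    if bundle.records and spec.read_length > 3 * min_len:
        raise SapkitError(
            f"read_length {spec.read_length} exceeds 3x the shortest protein ({min_len} aa)"
        )

    target_gis = list(truth.loc[truth["kind"] == "target_member", "gi"])
    paralog_gis = list(truth.loc[truth["kind"] == "trap_paralog", "gi"])
    background_gis = list(truth.loc[truth["kind"].str.startswith("background"), "gi"])
    ko_of = dict(zip(truth["gi"], truth["ko"]))

    n_target = round(spec.fraction_target_reads * spec.n_reads) if target_gis else 0
    n_trap = min(len(paralog_gis) * spec.trap_reads_per_family, spec.n_reads - n_target)
    n_rest = spec.n_reads - n_target - n_trap
    n_bg = n_rest // 2 if background_gis else 0
    n_random = n_rest - n_bg

    reads: List[Tuple[str, str]] = []
    rows: List[dict] = []

    def emit(source: str, source_gi: Optional[int], dna: str, must_exclude: bool) -> None:
        read_id = f"read_{len(reads)+1:05d}"
        reads.append((read_id, dna))
        rows.append(
            {
                "read_id": read_id,
                "source": source,
                "source_gi": source_gi if source_gi is not None else "",
                "ko": ko_of.get(source_gi, "") if source_gi is not None else "",
                "must_exclude": must_exclude,
            }
        )

    for _ in range(n_target):
        src = target_gis[int(rng.integers(len(target_gis)))]
        emit(
            "target",
            src,
            _read_from_protein(rng, by_gi[src].sequence, spec.read_length, spec.substitution_rate),
            False,
        )
    for p_gi in paralog_gis:
        for _ in range(spec.trap_reads_per_family):
            if len(reads) >= n_target + n_trap:
                break
            emit(
                "trap",
                p_gi,
                _read_from_protein(
                    rng, by_gi[p_gi].sequence, spec.read_length, spec.substitution_rate
                ),
                True,
            )
    for _ in range(n_bg):
        src = background_gis[int(rng.integers(len(background_gis)))]
        emit(
            "background",
            src,
            _read_from_protein(rng, by_gi[src].sequence, spec.read_length, spec.substitution_rate),
            False,
        )
    for _ in range(n_random):
        emit("random", None, "".join(rng.choice(list(DNA), size=spec.read_length)), False)

    truth_reads = pd.DataFrame(
        rows, columns=["read_id", "source", "source_gi", "ko", "must_exclude"]
    )
    return reads, truth_reads


def generate_scenario(spec: Optional[ScenarioSpec] = None) -> Scenario:
    """Generate a complete scenario (reference set + reads) from one spec."""
    spec = spec or ScenarioSpec()
    bundle = generate_reference_set(spec)
    reads, truth_reads = simulate_reads(bundle, spec)
    return Scenario(spec=spec, bundle=bundle, reads=reads, truth_reads=truth_reads)


def generate_trap_case(spec: Optional[ScenarioSpec] = None) -> Scenario:
    """Generate a scenario guaranteed to contain filter-pass traps.

    Requires ``trap_families >= 1``: each trap contributes reads that hit the
    sub-database above the cutoff but whose best full-database hit is the
    off-target paralog, so the verification pass must exclude them.
    """
    spec = spec or ScenarioSpec()
    if spec.trap_families < 1:
        raise SapkitError("generate_trap_case requires trap_families >= 1")
    return generate_scenario(spec)
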