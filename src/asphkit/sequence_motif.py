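"""Consensus-motif scanning for AspH-catalyzed EGF-like-domain hydroxylation.

AspH (aspartate/asparagine-beta-hydroxylase) hydroxylates Asp/Asn residues
inside disulfide-bridged macrocycles of EGF-like domains (EGFDs).  Two
sequence-level substrate rules are implemented:

* the *legacy* consensus ``C-X-[DN]-X-X-X-X-[FY]-X-C-X-C`` (12 residues,
  requiring a C5 cysteine one residue downstream of the ring-closing C4), and
* the *revised* rule: a 10-residue cysteine-bridged macrocycle whose third
  residue is D or N (the hydroxylation acceptor) and whose eighth residue is
  F or Y, with no constraint beyond the closing cysteine.

Every legacy match is by construction also a revised match at the same
acceptor position; the converse does not hold, and the revised-only class is
exactly the set of candidate sites the legacy consensus misses (fibulin-type
EGFDs with long C4-C5 inserts, and non-EGFD contexts).

Coordinates are 1-based inclusive throughout, matching UniProt residue
numbering.  The scanner is purely sequence-level: it does not check that a
disulfide physically bridges the two ring cysteines.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

ACCEPTOR_RESIDUES = frozenset("DN")
AROMATIC_RESIDUES = frozenset("FY")

#: ring length of the revised macrocycle (residues, inclusive of both Cys)
RING_LENGTH = 10
#: ring position (1-based) of the D/N hydroxylation acceptor
SITE_OFFSET = 3
#: ring position (1-based) of the required aromatic residue
AROMATIC_OFFSET = 8
#: window length of the legacy consensus (ring + X + C5)
LEGACY_LENGTH = 12


class FastaParseError(ValueError):
    """Raised when a FASTA entry is malformed or contains non-canonical residues."""


class DomainRangeError(ValueError):
    """Raised when a domain annotation lies outside its parent sequence."""


class InapplicableDomainError(ValueError):
    """Raised when an operation needs more cysteines than the domain has."""


class MotifConsistencyError(AssertionError):
    """Raised on a legacy hit without a matching revised hit (impossible by
    construction; indicates an internal defect)."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaParseError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise FastaParseError(
                f"{self.accession}: non-canonical residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class DomainAnnotation:
    accession: str
    domain_label: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DomainRangeError(
                f"{self.accession}/{self.domain_label}: bad span {self.start}-{self.end}"
            )

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclasses.dataclass(frozen=True)
class CysteineIndex:
    """Ordinal numbering (C1..Ck, N- to C-terminal) of the cysteines of a domain."""

    domain: DomainAnnotation
    positions: tuple[int, ...]  # absolute 1-based, strictly increasing

    @property
    def ordinals(self) -> dict[int, int]:
        return {pos: i + 1 for i, pos in enumerate(self.positions)}

    def __len__(self) -> int:
        return len(self.positions)


@dataclasses.dataclass(frozen=True)
class MotifRule:
    name: str  # "legacy" | "revised"
    pattern_length: int
    site_offset: int = SITE_OFFSET
    aromatic_offset: int = AROMATIC_OFFSET


LEGACY_RULE = MotifRule("legacy", LEGACY_LENGTH)
REVISED_RULE = MotifRule("revised", RING_LENGTH)


@dataclasses.dataclass(frozen=True)
class MotifHit:
    """A candidate hydroxylation site.

    ``ring_start``/``ring_end`` are the absolute positions of the two
    macrocycle cysteines (C3/C4 in EGFD numbering); for both rules the ring is
    exactly 10 residues, so ``ring_end - ring_start == 9`` and the acceptor is
    ``ring_start + 2``.
    """

    accession: str
    rule: str
    ring_start: int
    ring_end: int
    site_position: int
    site_residue: str
    aromatic_residue: str
    domain_label: str = "none"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into validated :class:`ProteinRecord` objects.

    Sequences are upper-cased; ordering is preserved.  A record with an empty
    sequence or a non-canonical residue raises :class:`FastaParseError` naming
    the offending entry.
    """
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not entry.id:
            raise FastaParseError(f"entry #{len(records) + 1}: missing header")
        records.append(ProteinRecord(entry.id, seq, entry.description))
    return records


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    """Read a domain-annotation TSV with header accession/domain_label/start/end."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "domain_label": str})
    required = {"accession", "domain_label", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        DomainAnnotation(r.accession, r.domain_label, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def index_cysteines(record: ProteinRecord, domain: DomainAnnotation) -> CysteineIndex:
    """Number the cysteines inside a domain span from the N terminus (C1..Ck)."""
    if domain.end > len(record):
        raise DomainRangeError(
            f"{domain.accession}/{domain.domain_label}: span {domain.start}-{domain.end}"
            f" exceeds sequence length {len(record)}"
        )
    positions = tuple(
        pos
        for pos in range(domain.start, domain.end + 1)
        if record.sequence[pos - 1] == "C"
    )
    return CysteineIndex(domain, positions)


def c4_c5_spacing(index: CysteineIndex) -> int:
    """Residues strictly between the 4th and 5th cysteines of a domain.

    0 means C4 and C5 are adjacent; 1 is the legacy C4-X-C5 arrangement.
    """
    if len(index) < 5:
        raise InapplicableDomainError(
            f"{index.domain.accession}/{index.domain.domain_label}: "
            f"{len(index)} cysteine(s), need >= 5"
        )
    return index.positions[4] - index.positions[3] - 1


def _window_is_ring(seq: str, i: int) -> bool:
    """True if the 10-mer starting at 0-based ``i`` is a revised-rule ring."""
    return (
        seq[i] == "C"
        and seq[i + RING_LENGTH - 1] == "C"
        and seq[i + SITE_OFFSET - 1] in ACCEPTOR_RESIDUES
        and seq[i + AROMATIC_OFFSET - 1] in AROMATIC_RESIDUES
    )


def scan_revised(record: ProteinRecord) -> list[MotifHit]:
    """All 10-residue C-bridged macrocycle candidates (revised rule).

    Overlapping and nested windows are all reported.  The wildcard positions
    admit any canonical residue, including further cysteines.
    """
    seq = record.sequence
    hits = []
    for i in range(len(seq) - RING_LENGTH + 1):
        if _window_is_ring(seq, i):
            hits.append(
                MotifHit(
                    accession=record.accession,
                    rule="revised",
                    ring_start=i + 1,
                    ring_end=i + RING_LENGTH,
                    site_position=i + SITE_OFFSET,
                    site_residue=seq[i + SITE_OFFSET - 1],
                    aromatic_residue=seq[i + AROMATIC_OFFSET - 1],
                )
            )
    return hits


def scan_legacy(record: ProteinRecord) -> list[MotifHit]:
    """Legacy consensus hits: a revised ring followed by X-C (the C5 cysteine)."""
    seq = record.sequence
    hits = []
    for i in range(len(seq) - LEGACY_LENGTH + 1):
        if _window_is_ring(seq, i) and seq[i + LEGACY_LENGTH - 1] == "C":
            hits.append(
                MotifHit(
                    accession=record.accession,
                    rule="legacy",
                    ring_start=i + 1,
                    ring_end=i + RING_LENGTH,
                    site_position=i + SITE_OFFSET,
                    site_residue=seq[i + SITE_OFFSET - 1],
                    aromatic_residue=seq[i + AROMATIC_OFFSET - 1],
                )
            )
    return hits


def classify_sites(
    legacy_hits: Iterable[MotifHit], revised_hits: Iterable[MotifHit]
) -> pd.DataFrame:
    """Per-site table flagging each candidate as ``both`` or ``revised_only``.

    Sites are keyed by (accession, site_position).  A legacy hit without a
    matching revised hit cannot arise from the scanners and raises
    :class:`MotifConsistencyError`.
    """
    revised = {(h.accession, h.site_position): h for h in revised_hits}
    legacy_keys = set()
    for h in legacy_hits:
        key = (h.accession, h.site_position)
        if key not in revised:
            raise MotifConsistencyError(
                f"legacy hit at {key} has no revised counterpart"
            )
        legacy_keys.add(key)
    rows = [
        {
            "accession": acc,
            "site_position": pos,
            "site_residue": hit.site_residue,
            "ring_start": hit.ring_start,
            "ring_end": hit.ring_end,
            "flag": "both" if (acc, pos) in legacy_keys else "revised_only",
        }
        for (acc, pos), hit in sorted(revised.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["accession", "site_position", "site_residue", "ring_start",
                 "ring_end", "flag"],
    )


def _enclosing_domain(
    hit: MotifHit, domains: Sequence[DomainAnnotation]
) -> DomainAnnotation | None:
    for dom in domains:
        if dom.accession == hit.accession and dom.contains(hit.site_position):
            return dom
    return None


def scan_proteome(
    records: Sequence[ProteinRecord],
    domains: Sequence[DomainAnnotation] = (),
) -> pd.DataFrame:
    """Scan whole sequences under both rules and assemble the hit report.

    Scanning is not restricted to annotated domains (revised-rule matches occur
    in non-EGFD contexts); when annotations are supplied, each hit inside a
    domain is labeled with it and, where the domain has >= 5 cysteines, with
    its C4-C5 spacing.  Deduplication is by (accession, rule, ring_start).
    """
    record_by_acc = {r.accession: r for r in records}
    rows = []
    seen: set[tuple[str, str, int]] = set()
    for record in records:
        legacy = scan_legacy(record)
        revised = scan_revised(record)
        flags = classify_sites(legacy, revised)
        flag_by_site = dict(zip(flags["site_position"], flags["flag"]))
        for hit in legacy + revised:
            key = (hit.accession, hit.rule, hit.ring_start)
            if key in seen:
                continue
            seen.add(key)
            dom = _enclosing_domain(hit, domains)
            spacing: int | None = None
            label = "none"
            if dom is not None:
                label = dom.domain_label
                idx = index_cysteines(record_by_acc[hit.accession], dom)
                if len(idx) >= 5:
                    spacing = c4_c5_spacing(idx)
            rows.append(
                {
                    "accession": hit.accession,
                    "rule": hit.rule,
                    "ring_start": hit.ring_start,
                    "ring_end": hit.ring_end,
                    "site_position": hit.site_position,
                    "site_residue": hit.site_residue,
                    "aromatic_residue": hit.aromatic_residue,
                    "domain_label": label,
                    "c4_c5_spacing": spacing,
                    "flag": flag_by_site[hit.site_position],
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["accession", "rule", "ring_start", "ring_end", "site_position",
                 "site_residue", "aromatic_residue", "domain_label",
                 "c4_c5_spacing", "flag"],
    )
    return df.sort_values(
        ["accession", "site_position", "rule"], ignore_index=True
    )


def write_hit_report(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["c4_c5_spacing"] = out["c4_c5_spacing"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out.to_csv(path, sep="\t", index=False)
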