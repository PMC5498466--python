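"""Reference toxin/antitoxin protein sets: loading, validation, clustering.

Reference records are proteins with a family label (relE, relB, mazF, ...)
and a role (toxin or antitoxin). They are grouped into single-linkage
clusters using local alignment, and each cluster contributes one
representative sequence to the downstream homology search.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_ALPHABET = AMINO_ACIDS | {"X"}
ROLES = ("toxin", "antitoxin")
MIN_SEQ_LEN = 20
MAX_SEQ_LEN = 400


class ReferenceParseError(ValueError):
    """Raised when a reference FASTA header or sequence cannot be parsed."""


class ReferenceValidationError(ValueError):
    """Raised when parsed records violate the reference-set invariants."""


@dataclass(frozen=True)
class TAFamilyRecord:
    """One reference toxin or antitoxin protein."""

    record_id: str
    family: str
    role: str
    sequence: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ReferenceValidationError(
                f"record {self.record_id!r}: role must be one of {ROLES}, got {self.role!r}"
            )
        if not (MIN_SEQ_LEN <= len(self.sequence) <= MAX_SEQ_LEN):
            raise ReferenceValidationError(
                f"record {self.record_id!r}: sequence length {len(self.sequence)} "
                f"outside [{MIN_SEQ_LEN}, {MAX_SEQ_LEN}]"
            )
        bad = set(self.sequence) - EXTENDED_ALPHABET
        if bad:
            raise ReferenceValidationError(
                f"record {self.record_id!r}: invalid residues {sorted(bad)}"
            )


@dataclass
class ReferenceCluster:
    """A single-linkage cluster of same-role reference records."""

    cluster_id: str
    members: list[str]
    representative: str
    family: str
    role: str
    representative_seq: str = field(repr=False, default="")

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ReferenceValidationError(
                f"cluster {self.cluster_id}: representative not among members"
            )


def bundled_reference_path() -> Path:
    """Path to the small curated demo reference set shipped with the package."""
    return Path(
        importlib.resources.files("tascreen").joinpath("data/reference_ta.faa")
    )


def load_reference_fasta(path: str | Path, delimiter: str = "|") -> list[TAFamilyRecord]:
    """Load a reference FASTA whose headers follow ``id<delim>family<delim>role``.

    Records are returned in file order. Raises :class:`ReferenceParseError`
    for malformed headers and :class:`ReferenceValidationError` for duplicate
    ids, invalid sequences, or inconsistent family/role combinations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference FASTA not found: {path}")
    records: list[TAFamilyRecord] = []
    seen_ids: set[str] = set()
    family_roles: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(delimiter)
        if len(parts) != 3:
            raise ReferenceParseError(
                f"malformed header {rec.description!r}: expected "
                f"id{delimiter}family{delimiter}role"
            )
        record_id, family, role = (p.strip() for p in parts)
        if not record_id or not family:
            raise ReferenceParseError(
                f"malformed header {rec.description!r}: empty id or family"
            )
        if record_id in seen_ids:
            raise ReferenceValidationError(f"duplicate record id {record_id!r}")
        seen_ids.add(record_id)
        record = TAFamilyRecord(record_id, family, role, str(rec.seq).upper())
        prior = family_roles.setdefault(family, role)
        if prior != role:
            raise ReferenceValidationError(
                f"family {family!r} has inconsistent roles ({prior} vs {role})"
            )
        records.append(record)
    if not records:
        raise ReferenceParseError(f"no records parsed from {path}")
    return records


def _pair_links(
    a: TAFamilyRecord,
    b: TAFamilyRecord,
    length_coverage: float,
    score_density: float,
) -> bool:
    """BLASTCLUST-style linkage: coverage on the shorter sequence and
    bit-score density (bits per aligned column) must both clear threshold."""
    from .homology_search import align_local

    shorter, longer = (a, b) if len(a.sequence) <= len(b.sequence) else (b, a)
    hit = align_local(shorter.sequence, longer.sequence)
    if hit.aln_length == 0:
        return False
    if hit.coverage_query < length_coverage:
        return False
    return hit.bit_score / hit.aln_length >= score_density


def cluster_references(
    records: Sequence[TAFamilyRecord],
    length_coverage: float = 0.75,
    score_density: float = 1.0,
) -> list[ReferenceCluster]:
    """Single-linkage clustering of reference records.

    Two records link iff a local alignment covers at least ``length_coverage``
    of the shorter sequence and scores at least ``score_density`` bits per
    aligned column. Records of different roles never link: role is
    authoritative metadata, not inferred. The representative is the longest
    member (ties: lexicographically smallest id). Output is independent of
    input order.
    """
    if not records:
        raise ReferenceValidationError("cannot cluster an empty reference set")
    if not (0 < length_coverage <= 1):
        raise ValueError(f"length_coverage must be in (0, 1], got {length_coverage}")
    ordered = sorted(records, key=lambda r: r.record_id)
    parent = {r.record_id: r.record_id for r in ordered}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if a.role != b.role:
                continue
            if _pair_links(a, b, length_coverage, score_density):
                union(a.record_id, b.record_id)

    by_root: dict[str, list[TAFamilyRecord]] = {}
    for r in ordered:
        by_root.setdefault(find(r.record_id), []).append(r)

    clusters: list[ReferenceCluster] = []
    for members in by_root.values():
        rep = min(members, key=lambda r: (-len(r.sequence), r.record_id))
        clusters.append(
            ReferenceCluster(
                cluster_id="",
                members=sorted(r.record_id for r in members),
                representative=rep.record_id,
                family=rep.family,
                role=rep.role,
                representative_seq=rep.sequence,
            )
        )
    clusters.sort(key=lambda c: c.representative)
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"C{i:03d}"
    return clusters


def write_clusters_tsv(
    clusters: Iterable[ReferenceCluster],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Emit clusters as TSV: cluster_id, member_id, family, role, is_representative."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("cluster_id\tmember_id\tfamily\trole\tis_representative\n")
        for c in clusters:
            for m in c.members:
                fh.write(
                    f"{c.cluster_id}\t{m}\t{c.family}\t{c.role}\t"
                    f"{str(m == c.representative).lower()}\n"
                )
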