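"""Local protein alignment, E-value calibration, and family assignment.

This replaces an external BLAST step with an in-process Smith-Waterman
search (optimal local alignment with affine gaps) scored against cluster
representatives, plus Karlin-Altschul E-values. A gap of length ``k`` costs
``gap_open + k * gap_extend`` (the BLAST convention). The gapped BLOSUM62
constants K and lambda are configuration, not computed from the scoring
system; the finite-size edge correction is omitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

from Bio import Align
from Bio.Align import substitution_matrices

from .reference_db import EXTENDED_ALPHABET, ReferenceCluster

if TYPE_CHECKING:  # pragma: no cover
    from .pairing import GeneFeature

#: default gapped Karlin-Altschul parameters for BLOSUM62, gap 11/1
DEFAULT_K = 0.041
DEFAULT_LAMBDA = 0.267
DEFAULT_E_CUTOFF = 0.01


class AlignmentInputError(ValueError):
    """Raised for empty sequences or residues outside the accepted alphabet."""


@dataclass(frozen=True)
class AlignmentHit:
    """A scored optimal local alignment between two protein sequences.

    ``identity`` is the fraction of aligned columns (gap columns included)
    with identical residues; ``coverage_query`` is the fraction of the query
    spanned by the local alignment.
    """

    query_id: str
    target_id: str
    raw_score: int
    bit_score: float
    e_value: float
    identity: float
    coverage_query: float
    aln_length: int


@dataclass(frozen=True)
class FamilyAssignment:
    gene_id: str
    family: str | None
    role: str  # toxin | antitoxin | unassigned
    best_hit: AlignmentHit | None


@lru_cache(maxsize=8)
def _matrix(name: str):
    """Substitution matrix with every X pairing forced to zero."""
    mat = substitution_matrices.load(name)
    if "X" in mat.alphabet:
        xi = mat.alphabet.index("X")
        mat[xi, :] = 0.0
        mat[:, xi] = 0.0
    return mat


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _matrix(matrix)
    # PairwiseAligner charges open_gap_score for the first gapped position,
    # so open + extend reproduces cost(k) = gap_open + k*gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise AlignmentInputError(f"{label} sequence is empty")
    bad = set(seq) - EXTENDED_ALPHABET
    if bad:
        raise AlignmentInputError(f"{label} sequence has unknown residues {sorted(bad)}")


def bit_score(raw_score: int, K: float = DEFAULT_K, lam: float = DEFAULT_LAMBDA) -> float:
    """Normalized score in bits: (lambda*S - ln K) / ln 2."""
    return (lam * raw_score - math.log(K)) / math.log(2)


def evalue(
    raw_score: float,
    m: int,
    n: int,
    K: float = DEFAULT_K,
    lam: float = DEFAULT_LAMBDA,
) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S).

    ``m`` is the query length and ``n`` the total residue count of the
    searched database.
    """
    if m <= 0 or n <= 0:
        raise ValueError(f"sequence/database sizes must be positive, got m={m}, n={n}")
    return K * m * n * math.exp(-lam * raw_score)


def align_local(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    target_id: str = "target",
    K: float = DEFAULT_K,
    lam: float = DEFAULT_LAMBDA,
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment of ``a`` (query) against ``b``.

    X matches everything with score 0; any other non-standard residue is an
    error. The returned hit's E-value uses m=len(a), n=len(b); callers
    searching a database should recompute it with :func:`evalue`.
    """
    _check_sequence(a, "query")
    _check_sequence(b, "target")
    aligner = _aligner(matrix, gap_open, gap_extend)
    raw = int(round(aligner.score(a, b)))
    if raw <= 0:
        return AlignmentHit(query_id, target_id, 0, bit_score(0, K, lam),
                            evalue(0, len(a), len(b), K, lam), 0.0, 0.0, 0)
    alignment = next(iter(aligner.align(a, b)))
    qblocks, tblocks = alignment.aligned
    matches = 0
    aligned_cols = 0
    prev_qe = prev_te = None
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        if prev_qe is not None:
            aligned_cols += (qs - prev_qe) + (ts - prev_te)  # gap columns
        aligned_cols += qe - qs
        matches += sum(1 for x, y in zip(a[qs:qe], b[ts:te]) if x == y)
        prev_qe, prev_te = qe, te
    span_q = qblocks[-1][1] - qblocks[0][0]
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        raw_score=raw,
        bit_score=bit_score(raw, K, lam),
        e_value=evalue(raw, len(a), len(b), K, lam),
        identity=matches / aligned_cols if aligned_cols else 0.0,
        coverage_query=span_q / len(a),
        aln_length=aligned_cols,
    )


def database_size(clusters: Sequence[ReferenceCluster]) -> int:
    """Total residue count across cluster representatives (the n of E = Kmn·e^{-λS})."""
    return sum(len(c.representative_seq) for c in clusters)


def assign_family(
    gene: "GeneFeature",
    clusters: Sequence[ReferenceCluster],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    K: float = DEFAULT_K,
    lam: float = DEFAULT_LAMBDA,
) -> FamilyAssignment:
    """Assign a gene's protein to the TA family of its best-scoring hit.

    The protein is aligned against every cluster representative; hits with
    E-value above ``e_cutoff`` are discarded. Among qualifying hits the
    highest bit score wins; ties break by lower E-value, then higher
    identity, then lexicographically smallest representative id. With no
    qualifying hit the gene is unassigned.
    """
    if not clusters:
        raise ValueError("cluster set is empty")
    n_db = database_size(clusters)
    m = len(gene.protein)
    best: tuple | None = None
    for cluster in sorted(clusters, key=lambda c: c.representative):
        hit = align_local(
            gene.protein,
            cluster.representative_seq,
            matrix=matrix,
            gap_open=gap_open,
            gap_extend=gap_extend,
            query_id=gene.gene_id,
            target_id=cluster.representative,
            K=K,
            lam=lam,
        )
        e = evalue(hit.raw_score, m, n_db, K, lam)
        if e > e_cutoff:
            continue
        hit = AlignmentHit(
            hit.query_id, hit.target_id, hit.raw_score, hit.bit_score,
            e, hit.identity, hit.coverage_query, hit.aln_length,
        )
        key = (-hit.bit_score, hit.e_value, -hit.identity, cluster.representative)
        if best is None or key < best[0]:
            best = (key, hit, cluster)
    if best is None:
        return FamilyAssignment(gene.gene_id, None, "unassigned", None)
    _, hit, cluster = best
    return FamilyAssignment(gene.gene_id, cluster.family, cluster.role, hit)


def assign_all(
    features: Iterable["GeneFeature"],
    clusters: Sequence[ReferenceCluster],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    **align_kwargs,
) -> list[FamilyAssignment]:
    return [assign_family(g, clusters, e_cutoff, **align_kwargs) for g in features]


def read_external_hits(path: str | Path) -> list[AlignmentHit]:
    """Import a 12-column tab-separated hit table from an external search tool.

    Columns: query, target, pident, length, mismatches, gapopens, qstart,
    qend, tstart, tend, evalue, bitscore. Raw scores are not recoverable
    from this format and are stored as 0.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            q, t = cols[0], cols[1]
            pident = float(cols[2]) / 100.0
            length = int(cols[3])
            qstart, qend = int(cols[6]), int(cols[7])
            hits.append(
                AlignmentHit(
                    query_id=q,
                    target_id=t,
                    raw_score=0,
                    bit_score=float(cols[11]),
                    e_value=float(cols[10]),
                    identity=pident,
                    coverage_query=0.0 if qend < qstart else (qend - qstart + 1) / max(qend, 1),
                    aln_length=length,
                )
            )
    return hits


def write_assignments_tsv(
    assignments: Iterable[FamilyAssignment],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tfamily\trole\tbit_score\te_value\tidentity\n")
        for a in assignments:
            if a.best_hit is None:
                fh.write(f"{a.gene_id}\t.\tunassigned\t.\t.\t.\n")
            else:
                h = a.best_hit
                fh.write(
                    f"{a.gene_id}\t{a.family}\t{a.role}\t{h.bit_score:.2f}\t"
                    f"{h.e_value:.3g}\t{h.identity:.4f}\n"
                )
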