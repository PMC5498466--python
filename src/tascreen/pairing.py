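"""Turn family assignments plus genome coordinates into TA operon pair calls.

Coordinates are GFF3-style 1-based inclusive throughout. A pair is two
co-directed neighbors on the same contig, one assigned toxin and one
assigned antitoxin of different families, within a configurable intergenic
distance; overlaps of 1-3 nt are flagged as transcriptionally coupled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .homology_search import FamilyAssignment

DEFAULT_MAX_INTERGENIC_NT = 150
COUPLED_RANGE = (-3, -1)  # inclusive overlap lengths 1..3 nt


@dataclass(frozen=True)
class GeneFeature:
    """An annotated protein-coding gene (1-based inclusive coordinates)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    protein: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")


@dataclass
class TAPairCandidate:
    """A predicted TA operon: a toxin gene plus its cognate antitoxin."""

    toxin: str
    antitoxin: str
    toxin_family: str
    antitoxin_family: str
    contig: str
    strand: str
    intergenic_nt: int
    antitoxin_upstream: bool
    coupled: bool
    toxin_start: int
    toxin_end: int
    antitoxin_start: int
    antitoxin_end: int
    in_island: bool | None = None
    pair_rank: int = 0

    def __post_init__(self) -> None:
        if self.toxin == self.antitoxin:
            raise ValueError("toxin and antitoxin cannot be the same gene")
        if self.toxin_family == self.antitoxin_family:
            raise ValueError("toxin and antitoxin families must differ")


def intergenic_distance(a: GeneFeature, b: GeneFeature) -> int:
    """Nucleotides between two features ordered by start; negative = overlap.

    With 1-based inclusive coordinates this is ``b.start - a.end - 1``:
    abutting genes give 0, a 3-nt overlap gives -3.
    """
    if a.contig != b.contig:
        raise ValueError(f"features on different contigs: {a.contig} vs {b.contig}")
    if a.start > b.start:
        raise ValueError("caller must order features by start (a.start <= b.start)")
    return b.start - a.end - 1


def find_ta_pairs(
    features: Sequence[GeneFeature],
    assignments: Sequence[FamilyAssignment],
    max_intergenic_nt: int = DEFAULT_MAX_INTERGENIC_NT,
    require_no_intervening: bool = True,
) -> list[TAPairCandidate]:
    """Call TA pairs from assigned features by the co-directed adjacency rule.

    Candidates are pairs of co-directed genes on one contig, one assigned
    toxin and one assigned antitoxin of different families, with intergenic
    distance <= ``max_intergenic_nt``. With ``require_no_intervening`` only
    consecutive annotated genes qualify. Each gene joins at most one pair:
    conflicts resolve greedily by ascending intergenic distance, then
    leftmost start. Output is sorted by (contig, start of the upstream gene
    in transcription direction) and ranked 1..N.
    """
    amap: dict[str, FamilyAssignment] = {a.gene_id: a for a in assignments}
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in sorted(features, key=lambda f: (f.contig, f.start, f.end, f.gene_id)):
        by_contig.setdefault(f.contig, []).append(f)

    candidates: list[tuple[int, str, int, GeneFeature, GeneFeature]] = []
    for contig, genes in by_contig.items():
        for i, g1 in enumerate(genes):
            js = [i + 1] if require_no_intervening else range(i + 1, len(genes))
            for j in js:
                if j >= len(genes):
                    break
                g2 = genes[j]
                d = intergenic_distance(g1, g2)
                if d > max_intergenic_nt:
                    break  # genes are start-sorted; later partners only farther
                if g1.strand != g2.strand:
                    continue
                a1, a2 = amap.get(g1.gene_id), amap.get(g2.gene_id)
                if a1 is None or a2 is None:
                    continue
                roles = {a1.role, a2.role}
                if roles != {"toxin", "antitoxin"}:
                    continue
                if a1.family == a2.family:
                    continue
                candidates.append((d, contig, g1.start, g1, g2))

    used: set[str] = set()
    pairs: list[TAPairCandidate] = []
    for d, contig, _, g1, g2 in sorted(candidates, key=lambda c: (c[0], c[1], c[2])):
        if g1.gene_id in used or g2.gene_id in used:
            continue
        used.update((g1.gene_id, g2.gene_id))
        a1, a2 = amap[g1.gene_id], amap[g2.gene_id]
        toxin_gene, anti_gene = (g1, g2) if a1.role == "toxin" else (g2, g1)
        toxin_asn, anti_asn = (a1, a2) if a1.role == "toxin" else (a2, a1)
        upstream_gene = g1 if g1.strand == "+" else g2
        pairs.append(
            TAPairCandidate(
                toxin=toxin_gene.gene_id,
                antitoxin=anti_gene.gene_id,
                toxin_family=toxin_asn.family,
                antitoxin_family=anti_asn.family,
                contig=contig,
                strand=g1.strand,
                intergenic_nt=d,
                antitoxin_upstream=(upstream_gene.gene_id == anti_gene.gene_id),
                coupled=COUPLED_RANGE[0] <= d <= COUPLED_RANGE[1],
                toxin_start=toxin_gene.start,
                toxin_end=toxin_gene.end,
                antitoxin_start=anti_gene.start,
                antitoxin_end=anti_gene.end,
            )
        )

    def upstream_start(p: TAPairCandidate) -> int:
        first = min(p.toxin_start, p.antitoxin_start)
        last = max(p.toxin_start, p.antitoxin_start)
        return first if p.strand == "+" else last

    pairs.sort(key=lambda p: (p.contig, upstream_start(p)))
    return [replace(p, pair_rank=i) for i, p in enumerate(pairs, start=1)]


REPORT_COLUMNS = [
    "pair_rank", "contig", "strand", "toxin", "toxin_family", "antitoxin",
    "antitoxin_family", "toxin_start", "toxin_end", "antitoxin_start",
    "antitoxin_end", "intergenic_nt", "coupled", "antitoxin_upstream",
    "toxin_len_aa", "antitoxin_len_aa", "toxin_mw_da", "antitoxin_mw_da",
    "toxin_pi", "antitoxin_pi", "pi_asymmetry", "in_island",
]


def operon_report(
    pairs: Sequence[TAPairCandidate],
    physchem: Mapping[str, "PhyschemSummary"],  # noqa: F821
) -> pd.DataFrame:
    """One row per predicted operon merging architecture with physicochemistry."""
    from .physchem import pi_asymmetry

    rows = []
    for p in pairs:
        for gid in (p.toxin, p.antitoxin):
            if gid not in physchem:
                raise KeyError(f"missing physchem summary for gene {gid!r}")
        tox, anti = physchem[p.toxin], physchem[p.antitoxin]
        rows.append({
            "pair_rank": p.pair_rank,
            "contig": p.contig,
            "strand": p.strand,
            "toxin": p.toxin,
            "toxin_family": p.toxin_family,
            "antitoxin": p.antitoxin,
            "antitoxin_family": p.antitoxin_family,
            "toxin_start": p.toxin_start,
            "toxin_end": p.toxin_end,
            "antitoxin_start": p.antitoxin_start,
            "antitoxin_end": p.antitoxin_end,
            "intergenic_nt": p.intergenic_nt,
            "coupled": p.coupled,
            "antitoxin_upstream": p.antitoxin_upstream,
            "toxin_len_aa": tox.length_aa,
            "antitoxin_len_aa": anti.length_aa,
            "toxin_mw_da": round(tox.mw_da, 2),
            "antitoxin_mw_da": round(anti.mw_da, 2),
            "toxin_pi": round(tox.pi, 2),
            "antitoxin_pi": round(anti.pi, 2),
            "pi_asymmetry": pi_asymmetry(tox, anti),
            "in_island": p.in_island,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


# ---------------------------------------------------------------------------
# genome annotation I/O


def load_genome(
    gff3_path: str | Path,
    fasta_path: str | Path | None = None,
    feature_types: Sequence[str] = ("CDS", "gene"),
) -> list[GeneFeature]:
    """Read gene coordinates from GFF3 and protein sequences from FASTA.

    Features are matched to proteins by their GFF3 ``ID`` attribute. When
    both a gene and its CDS carry the same ID, the first encountered wins.
    With no FASTA the features carry empty protein sequences.
    """
    proteins: dict[str, str] = {}
    if fasta_path is not None:
        proteins = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", merge_strategy="create_unique", force=True
    )
    features: list[GeneFeature] = []
    seen: set[str] = set()
    for ftype in feature_types:
        for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
            fid = feat.attributes.get("ID", [feat.id])[0]
            if fid in seen:
                continue
            seen.add(fid)
            features.append(
                GeneFeature(
                    gene_id=fid,
                    contig=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    protein=proteins.get(fid, ""),
                )
            )
    features.sort(key=lambda f: (f.contig, f.start, f.end, f.gene_id))
    return features


def load_genome_tsv(tsv_path: str | Path, fasta_path: str | Path) -> list[GeneFeature]:
    """Read a simple annotation table: gene_id, contig, start, end, strand."""
    proteins = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    required = {"gene_id", "contig", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    return [
        GeneFeature(
            gene_id=str(r.gene_id),
            contig=str(r.contig),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            protein=proteins.get(str(r.gene_id), ""),
        )
        for r in df.itertuples()
    ]


def write_genome_gff3(
    features: Iterable[GeneFeature],
    path: str | Path,
    source: str = "tascreen",
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        for f in sorted(features, key=lambda f: (f.contig, f.start, f.end, f.gene_id)):
            fh.write(
                f"{f.contig}\t{source}\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t"
                f"ID={f.gene_id}\n"
            )


def write_pairs_tsv(
    pairs: Sequence[TAPairCandidate],
    physchem: Mapping[str, "PhyschemSummary"],  # noqa: F821
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    report = operon_report(pairs, physchem)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        report.to_csv(fh, sep="\t", index=False)


def write_pairs_gff3(
    pairs: Sequence[TAPairCandidate],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Predicted operons as a GFF3 track (one feature spanning both genes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        for p in pairs:
            start = min(p.toxin_start, p.antitoxin_start)
            end = max(p.toxin_end, p.antitoxin_end)
            fh.write(
                f"{p.contig}\ttascreen\toperon\t{start}\t{end}\t.\t{p.strand}\t.\t"
                f"ID=ta_pair_{p.pair_rank};toxin={p.toxin};antitoxin={p.antitoxin};"
                f"toxin_family={p.toxin_family};antitoxin_family={p.antitoxin_family};"
                f"coupled={str(p.coupled).lower()}\n"
            )
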