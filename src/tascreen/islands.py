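"""Genomic-island context flags for TA pairs.

A genomic island is operationalized as a maximal run of consecutive
non-core genes whose genomic span strictly exceeds a length threshold
(default 8 kb). Core-gene designation is user input (e.g., from an
orthology tool); no sequence-composition calling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .pairing import GeneFeature, TAPairCandidate

DEFAULT_MIN_ISLAND_LENGTH = 8000


@dataclass(frozen=True)
class IslandInterval:
    contig: str
    start: int  # 1-based inclusive
    end: int
    length_nt: int

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


def call_islands(
    features: Sequence[GeneFeature],
    core_gene_ids: set[str],
    min_island_length: int = DEFAULT_MIN_ISLAND_LENGTH,
) -> list[IslandInterval]:
    """Maximal runs of consecutive non-core genes spanning > ``min_island_length`` nt.

    The span is measured from the first gene's start to the last gene's end;
    the threshold is strict (a run spanning exactly 8000 nt is not an island).
    """
    ids = {f.gene_id for f in features}
    unknown = core_gene_ids - ids
    if unknown:
        raise ValueError(f"core gene ids absent from annotation: {sorted(unknown)[:5]}")
    islands: list[IslandInterval] = []
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in sorted(features, key=lambda f: (f.contig, f.start, f.end, f.gene_id)):
        by_contig.setdefault(f.contig, []).append(f)
    for contig, genes in by_contig.items():
        run: list[GeneFeature] = []
        for g in genes + [None]:  # sentinel flushes the last run
            if g is not None and g.gene_id not in core_gene_ids:
                run.append(g)
                continue
            if run:
                start = run[0].start
                end = max(x.end for x in run)
                span = end - start + 1
                if span > min_island_length:
                    islands.append(IslandInterval(contig, start, end, span))
                run = []
    islands.sort(key=lambda i: (i.contig, i.start))
    return islands


def annotate_pairs_with_islands(
    pairs: Sequence[TAPairCandidate],
    islands: Sequence[IslandInterval],
) -> list[TAPairCandidate]:
    """Set ``in_island`` true iff both genes of a pair lie fully within one island."""
    out: list[TAPairCandidate] = []
    for p in pairs:
        hit = any(
            isl.contig == p.contig
            and isl.contains(p.toxin_start, p.toxin_end)
            and isl.contains(p.antitoxin_start, p.antitoxin_end)
            for isl in islands
        )
        out.append(replace(p, in_island=hit))
    return out


def read_core_ids(path: str | Path) -> set[str]:
    """Core-gene list: one id per line; blank lines and # comments ignored."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return ids


def write_islands_bed(
    islands: Iterable[IslandInterval],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Emit islands as BED: 0-based half-open, so start-1 and end unchanged."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for isl in islands:
            fh.write(f"{isl.contig}\t{isl.start - 1}\t{isl.end}\tisland\n")
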