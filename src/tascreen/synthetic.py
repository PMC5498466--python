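"""Synthetic genomes, annotations, and expression tables with known truth.

Planted TA operons are divergence-controlled copies of reference family
exemplars laid out as co-directed antitoxin-toxin units among decoy genes,
including adversarial decoys that exercise every negative branch of the
pairing rule (wrong strand, same role, excessive distance, lone homolog).
Mutation is substitution-only so planted identity stays interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pairing import GeneFeature
from .reference_db import TAFamilyRecord
from .stress_expression import ExpressionTable

#: canonical antitoxin partner for each toxin family
TOXIN_PARTNERS = {"relE": "relB", "mazF": "mazE", "yoeB": "yefM",
                  "vapC": "vapB", "doc": "phd"}

#: Robinson-Robinson style background amino-acid frequencies
BACKGROUND_FREQS = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.065,
}
_BG_RESIDUES = np.array(list(BACKGROUND_FREQS))
_BG_P = np.array(list(BACKGROUND_FREQS.values()))
_BG_P = _BG_P / _BG_P.sum()

DECOY_KINDS = ("random", "wrong_strand_pair", "same_role_pair",
               "distant_pair", "lone_homolog")


@dataclass(frozen=True)
class PlantedPair:
    toxin_id: str
    antitoxin_id: str
    toxin_family: str
    antitoxin_family: str
    intergenic_nt: int
    contig: str
    strand: str


@dataclass(frozen=True)
class DecoyGene:
    gene_id: str
    kind: str


@dataclass
class TruthTable:
    pairs: list[PlantedPair] = field(default_factory=list)
    decoys: list[DecoyGene] = field(default_factory=list)
    seed: int = 0

    def all_gene_ids(self) -> list[str]:
        ids: list[str] = []
        for p in self.pairs:
            ids.extend((p.toxin_id, p.antitoxin_id))
        ids.extend(d.gene_id for d in self.decoys)
        return ids

    def pair_id_set(self) -> set[frozenset[str]]:
        return {frozenset((p.toxin_id, p.antitoxin_id)) for p in self.pairs}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# seed=%d\n" % self.seed)
            fh.write("kind\tgene_a\tgene_b\tfamily_a\tfamily_b\tintergenic_nt\t"
                     "contig\tstrand\n")
            for p in self.pairs:
                fh.write(f"planted_pair\t{p.toxin_id}\t{p.antitoxin_id}\t"
                         f"{p.toxin_family}\t{p.antitoxin_family}\t"
                         f"{p.intergenic_nt}\t{p.contig}\t{p.strand}\n")
            for d in self.decoys:
                fh.write(f"decoy:{d.kind}\t{d.gene_id}\t.\t.\t.\t.\t.\t.\n")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def mutate_protein(seq: str, divergence: float, seed) -> str:
    """Substitute exactly round(divergence*len) positions, never to the same residue.

    Replacement residues are drawn from a background frequency table
    renormalized to exclude the original residue. ``seed`` may be an int or
    a numpy Generator; the output is deterministic per seed.
    """
    if not (0 <= divergence < 1):
        raise ValueError(f"divergence must be in [0, 1), got {divergence}")
    rng = _rng(seed)
    n_mut = round(divergence * len(seq))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for pos in sorted(positions):
        current = out[pos]
        mask = _BG_RESIDUES != current
        p = _BG_P[mask]
        out[pos] = str(rng.choice(_BG_RESIDUES[mask], p=p / p.sum()))
    return "".join(out)


def random_protein(length: int, seed) -> str:
    rng = _rng(seed)
    return "".join(rng.choice(_BG_RESIDUES, size=length, p=_BG_P))


def _family_pair_templates(
    references: Sequence[TAFamilyRecord],
) -> list[tuple[TAFamilyRecord, TAFamilyRecord]]:
    by_family: dict[str, TAFamilyRecord] = {}
    for r in references:
        by_family.setdefault(r.family, r)  # first exemplar per family
    templates = []
    for tox_fam, anti_fam in TOXIN_PARTNERS.items():
        if tox_fam in by_family and anti_fam in by_family:
            templates.append((by_family[tox_fam], by_family[anti_fam]))
    if not templates:
        raise ValueError("references contain no known toxin/antitoxin family pair")
    return templates


def generate_genome(
    references: Sequence[TAFamilyRecord],
    n_pairs: int,
    n_decoys: int,
    divergence: float = 0.0,
    overlap_choices: Sequence[int] = (-1, -2, -3, 0, 10, 50),
    seed: int = 0,
    contig: str = "synthetic_1",
    spacer_range: tuple[int, int] = (200, 800),
) -> tuple[dict[str, str], list[GeneFeature], TruthTable]:
    """Plant co-directed antitoxin-toxin operons among decoy genes.

    Returns (proteins keyed by gene id, 1-based inclusive features, truth).
    Intergenic distances inside planted operons are sampled from
    ``overlap_choices``; inter-unit spacers from ``spacer_range`` keep
    unrelated neighbors beyond any sane pairing distance. Adversarial
    decoys (wrong-strand pair, same-role pair, distant pair, lone homolog)
    are included whenever the decoy budget allows; remaining decoys are
    random background proteins. Same seed reproduces output bit-identically.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    if n_decoys < 0:
        raise ValueError("n_decoys must be non-negative")
    rng = np.random.default_rng(seed)
    templates = _family_pair_templates(references)

    # a unit is a list of (protein, strand, gap_before_next_gene, tag)
    units: list[tuple[str, list]] = []
    for k in range(n_pairs):
        tox_rec, anti_rec = templates[k % len(templates)]
        d = int(rng.choice(np.asarray(overlap_choices)))
        strand = "+" if rng.random() < 0.5 else "-"
        tox = mutate_protein(tox_rec.sequence, divergence, rng)
        anti = mutate_protein(anti_rec.sequence, divergence, rng)
        # antitoxin upstream in transcription direction
        if strand == "+":
            genes = [(anti, strand, d, ("pair_anti", anti_rec.family)),
                     (tox, strand, 0, ("pair_tox", tox_rec.family))]
        else:
            genes = [(tox, strand, d, ("pair_tox", tox_rec.family)),
                     (anti, strand, 0, ("pair_anti", anti_rec.family))]
        units.append((f"pair:{d}:{strand}:{tox_rec.family}:{anti_rec.family}", genes))

    remaining = n_decoys
    tox_rec, anti_rec = templates[0]
    alt_tox = templates[1 % len(templates)][0]
    adversarial = [
        ("wrong_strand_pair", [
            (mutate_protein(anti_rec.sequence, divergence, rng), "+", 5, None),
            (mutate_protein(tox_rec.sequence, divergence, rng), "-", 0, None)]),
        ("same_role_pair", [
            (mutate_protein(tox_rec.sequence, divergence, rng), "+", 5, None),
            (mutate_protein(alt_tox.sequence, divergence, rng), "+", 0, None)]),
        ("distant_pair", [
            (mutate_protein(anti_rec.sequence, divergence, rng), "+", 1000, None),
            (mutate_protein(tox_rec.sequence, divergence, rng), "+", 0, None)]),
        ("lone_homolog", [
            (mutate_protein(tox_rec.sequence, divergence, rng), "+", 0, None)]),
    ]
    for kind, genes in adversarial:
        if remaining >= len(genes):
            units.append((f"decoy:{kind}", [
                (prot, strand, gap, ("decoy", kind)) for prot, strand, gap, _ in genes
            ]))
            remaining -= len(genes)
    while remaining > 0:
        length = int(rng.integers(50, 201))
        strand = "+" if rng.random() < 0.5 else "-"
        units.append(("decoy:random",
                      [(random_protein(length, rng), strand, 0, ("decoy", "random"))]))
        remaining -= 1

    order = rng.permutation(len(units))
    proteins: dict[str, str] = {}
    features: list[GeneFeature] = []
    truth = TruthTable(seed=seed)
    cursor = 1 + int(rng.integers(*spacer_range))
    counter = 0
    for ui in order:
        _, genes = units[ui]
        placed: list[tuple[str, GeneFeature, tuple]] = []
        for prot, strand, gap, tag in genes:
            counter += 1
            gid = f"g{counter:05d}"
            nt_len = 3 * (len(prot) + 1)
            feat = GeneFeature(gid, contig, cursor, cursor + nt_len - 1, strand, prot)
            proteins[gid] = prot
            features.append(feat)
            placed.append((gid, feat, tag))
            cursor = feat.end + 1 + gap
        cursor += int(rng.integers(*spacer_range))
        tags = [t for _, _, t in placed]
        if tags and tags[0] is not None and tags[0][0].startswith("pair_"):
            by_role = {t[0]: (gid, t[1]) for gid, _, t in placed}
            tox_id, tox_fam = by_role["pair_tox"]
            anti_id, anti_fam = by_role["pair_anti"]
            f1, f2 = placed[0][1], placed[1][1]
            truth.pairs.append(PlantedPair(
                toxin_id=tox_id, antitoxin_id=anti_id,
                toxin_family=tox_fam, antitoxin_family=anti_fam,
                intergenic_nt=f2.start - f1.end - 1,
                contig=contig, strand=f1.strand,
            ))
        else:
            for gid, _, tag in placed:
                truth.decoys.append(DecoyGene(gid, tag[1]))
    features.sort(key=lambda f: (f.contig, f.start, f.gene_id))
    return proteins, features, truth


def write_protein_fasta(proteins: Mapping[str, str], path: str | Path,
                        width: int = 60) -> None:
    with open(path, "w") as fh:
        for gid in sorted(proteins):
            fh.write(f">{gid}\n")
            seq = proteins[gid]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


#: condition -> (toxin fold change, antitoxin fold change); values are the
#: stress-response effects used as the default simulation scenario
DEFAULT_SCENARIO: dict[str, tuple[float, float]] = {
    "N-": (2.3, 1 / 2.5),
    "P-": (3.1, 1.0),
    "Zn": (10.6, 1.0),
}


def generate_expression(
    truth: TruthTable,
    scenario: Mapping[str, tuple[float, float]] | None = None,
    dispersion: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    baseline_range: tuple[float, float] = (500.0, 5000.0),
    control: str = "control",
) -> ExpressionTable:
    """Negative-binomial count table with planted fold changes.

    Counts use the NB1 parameterization, variance = mu*(1+dispersion), so
    the relative noise shrinks with the baseline and the planted effects
    stay recoverable at small replicate counts; dispersion 0 degenerates to
    Poisson. Toxin and antitoxin genes of every planted pair are scaled by
    the scenario fold changes per condition; decoys keep baseline means.
    """
    if scenario is None:
        scenario = DEFAULT_SCENARIO
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    for cond, (ft, fa) in scenario.items():
        if ft <= 0 or fa <= 0:
            raise ValueError(f"scenario effects must be positive ({cond}: {ft}, {fa})")
    rng = np.random.default_rng(seed)
    genes = truth.all_gene_ids()
    toxins = {p.toxin_id for p in truth.pairs}
    antitoxins = {p.antitoxin_id for p in truth.pairs}
    baselines = {g: float(rng.uniform(*baseline_range)) for g in genes}

    conditions = [control] + list(scenario)
    sample_rows = []
    data: dict[str, np.ndarray] = {}
    for cond in conditions:
        ft, fa = (1.0, 1.0) if cond == control else scenario[cond]
        for rep in range(1, n_reps + 1):
            sample = f"{cond}_r{rep}"
            mus = np.array([
                baselines[g] * (ft if g in toxins else fa if g in antitoxins else 1.0)
                for g in genes
            ])
            if dispersion == 0:
                counts = rng.poisson(mus)
            else:
                r = mus / dispersion
                p = 1.0 / (1.0 + dispersion)
                counts = rng.negative_binomial(r, p)
            data[sample] = counts.astype(float)
            sample_rows.append({"sample": sample, "condition": cond, "replicate": rep})
    values = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(sample_rows).set_index("sample")
    return ExpressionTable(values, samples, control=control)


def write_scenario_tsv(scenario: Mapping[str, tuple[float, float]],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("condition\ttoxin_fc\tantitoxin_fc\n")
        for cond, (ft, fa) in scenario.items():
            fh.write(f"{cond}\t{ft}\t{fa}\n")
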