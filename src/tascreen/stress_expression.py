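"""Expression-side readouts: growth rate, fold changes, activation calls.

The differential-expression test here is a deliberate re-specification: a
two-sided permutation test on the absolute log2 fold change, exhaustive
when the number of label arrangements is small. When the replicate
structure cannot attain the requested significance level at all (e.g. the
minimum exhaustive p with 3 vs 3 replicates is 2/20 = 0.1), classification
falls back to fold-change-only rather than silently never calling anything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pairing import TAPairCandidate

DEFAULT_PSEUDOCOUNT = 0.5
STATUS_VALUES = ("toxin-up", "antitoxin-down", "both", "none")


class InsufficientReplication(ValueError):
    """Permutation testing refused: fewer than 4 replicates in total."""


@dataclass
class ExpressionTable:
    """Genes x samples expression values with a condition/replicate map.

    ``values`` is indexed by gene id with one column per sample;
    ``samples`` maps each sample name to its condition label and replicate
    number. A designated control condition must exist.
    """

    values: pd.DataFrame
    samples: pd.DataFrame  # index: sample; columns: condition, replicate
    control: str = "control"

    def __post_init__(self) -> None:
        if not set(self.values.columns) <= set(self.samples.index):
            missing = set(self.values.columns) - set(self.samples.index)
            raise ValueError(f"samples without condition mapping: {sorted(missing)[:5]}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.control not in set(self.samples["condition"]):
            raise ValueError(f"control condition {self.control!r} absent from table")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        hits = [s for s in self.values.columns
                if self.samples.loc[s, "condition"] == condition]
        if not hits:
            raise KeyError(f"condition {condition!r} not in table")
        return hits

    def replicate_values(self, gene: str, condition: str) -> np.ndarray:
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} not in table")
        return self.values.loc[gene, self.samples_for(condition)].to_numpy(dtype=float)

    def normalized(self) -> "ExpressionTable":
        """Library-size scaling: each sample rescaled to the mean column total."""
        totals = self.values.sum(axis=0)
        target = totals.mean()
        scaled = self.values / totals.replace(0, np.nan) * target
        return ExpressionTable(scaled.fillna(0.0), self.samples.copy(), self.control)

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        condition_map_path: str | Path,
        control: str = "control",
    ) -> "ExpressionTable":
        values = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
        samples = pd.read_csv(condition_map_path, sep="\t", index_col=0, comment="#")
        if "condition" not in samples.columns:
            raise ValueError("condition map needs a 'condition' column")
        if "replicate" not in samples.columns:
            samples["replicate"] = samples.groupby("condition").cumcount() + 1
        return cls(values, samples, control)

    def to_tsv(self, counts_path: str | Path, condition_map_path: str | Path,
               header_lines: Sequence[str] = ()) -> None:
        for path, frame, label in (
            (counts_path, self.values, "gene_id"),
            (condition_map_path, self.samples, "sample"),
        ):
            with open(path, "w") as fh:
                for line in header_lines:
                    fh.write(f"# {line}\n")
                frame.to_csv(fh, sep="\t", index_label=label)


@dataclass
class PairActivationCall:
    """Per-condition activation readout for one TA pair."""

    pair_rank: int
    toxin: str
    antitoxin: str
    toxin_log2fc: dict[str, float] = field(default_factory=dict)
    antitoxin_log2fc: dict[str, float] = field(default_factory=dict)
    ta_ratio: dict[str, float] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    p_values: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    significant: bool = False


def growth_rate(x1: float, x2: float, t1: float, t2: float) -> float:
    """Specific growth rate mu = (ln x2 - ln x1) / (t2 - t1), per hour."""
    if x1 <= 0 or x2 <= 0:
        raise ValueError("cell densities must be positive")
    if t2 <= t1:
        raise ValueError("t2 must be greater than t1")
    return (math.log(x2) - math.log(x1)) / (t2 - t1)


def growth_rates_from_series(densities: pd.DataFrame) -> pd.DataFrame:
    """Interval growth rates from a (time_h, cells_per_ml) series."""
    required = {"time_h", "cells_per_ml"}
    if not required <= set(densities.columns):
        raise ValueError(f"density table needs columns {sorted(required)}")
    d = densities.sort_values("time_h").reset_index(drop=True)
    rows = []
    for i in range(1, len(d)):
        rows.append({
            "t1_h": d.time_h[i - 1],
            "t2_h": d.time_h[i],
            "mu_per_h": growth_rate(
                d.cells_per_ml[i - 1], d.cells_per_ml[i], d.time_h[i - 1], d.time_h[i]
            ),
        })
    return pd.DataFrame(rows, columns=["t1_h", "t2_h", "mu_per_h"])


def _log2fc(stress: np.ndarray, control: np.ndarray, pseudocount: float) -> float:
    return math.log2(
        (float(np.mean(stress)) + pseudocount) / (float(np.mean(control)) + pseudocount)
    )


def log2_fold_change(
    table: ExpressionTable,
    gene: str,
    condition: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """log2 of the pseudocount-stabilized ratio of replicate means (stress/control)."""
    stress = table.replicate_values(gene, condition)
    control = table.replicate_values(gene, table.control)
    return _log2fc(stress, control, pseudocount)


def min_attainable_p(n_stress: int, n_control: int, n_perm: int = 10000) -> float:
    """Smallest p-value the permutation test can produce for this design.

    Exhaustive enumeration over C(n, k) arrangements bottoms out at 2/N
    (the observed split and its mirror always tie on |log2FC|).
    """
    total = math.comb(n_stress + n_control, n_stress)
    if total <= n_perm:
        return 2.0 / total
    return 1.0 / (1.0 + n_perm)


def permutation_significance(
    table: ExpressionTable,
    gene: str,
    condition: str,
    n_perm: int = 10000,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Two-sided permutation p-value for |log2FC| of stress vs control.

    Replicate labels are permuted between the two groups. When the number
    of distinct label arrangements is at most ``n_perm`` all of them are
    enumerated and p = #{arrangements with |log2FC| >= observed} / N
    (the observed arrangement is among them); otherwise ``n_perm`` random
    arrangements are drawn and p = (1 + #extreme) / (1 + n_perm).
    """
    stress = table.replicate_values(gene, condition)
    control = table.replicate_values(gene, table.control)
    ns, nc = len(stress), len(control)
    if ns + nc < 4:
        raise InsufficientReplication(
            f"{ns}+{nc} replicates: permutation test needs at least 4 in total"
        )
    observed = abs(_log2fc(stress, control, pseudocount))
    pooled = np.concatenate([stress, control])
    total = math.comb(ns + nc, ns)
    if total <= n_perm:
        count = 0
        idx = range(ns + nc)
        for chosen in combinations(idx, ns):
            mask = np.zeros(ns + nc, dtype=bool)
            mask[list(chosen)] = True
            stat = abs(_log2fc(pooled[mask], pooled[~mask], pseudocount))
            if stat >= observed - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ns + nc)
        stat = abs(_log2fc(pooled[perm[:ns]], pooled[perm[ns:]], pseudocount))
        if stat >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def classify_pairs(
    table: ExpressionTable,
    pairs: Sequence[TAPairCandidate],
    fc_threshold: float = 2.0,
    alpha: float = 0.01,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    n_perm: int = 10000,
    seed: int = 0,
) -> list[PairActivationCall]:
    """Per-condition activation status of each TA pair.

    toxin-up: toxin log2FC >= log2(fc_threshold); antitoxin-down: antitoxin
    log2FC <= -log2(fc_threshold); both/none accordingly. Significance at
    ``alpha`` is additionally required whenever the permutation test is
    attainable for the replicate design; otherwise (too few replicates, or
    a minimum attainable p above alpha) the call is fold-change-only.
    ``ta_ratio`` is the pseudocount-stabilized toxin/antitoxin mean ratio.
    """
    lfc_cut = math.log2(fc_threshold)
    calls: list[PairActivationCall] = []
    for p in pairs:
        call = PairActivationCall(pair_rank=p.pair_rank, toxin=p.toxin,
                                  antitoxin=p.antitoxin)
        for cond in table.conditions:
            tox_vals = table.replicate_values(p.toxin, cond)
            anti_vals = table.replicate_values(p.antitoxin, cond)
            call.ta_ratio[cond] = (float(np.mean(tox_vals)) + pseudocount) / (
                float(np.mean(anti_vals)) + pseudocount
            )
            if cond == table.control:
                continue
            tox_lfc = log2_fold_change(table, p.toxin, cond, pseudocount)
            anti_lfc = log2_fold_change(table, p.antitoxin, cond, pseudocount)
            call.toxin_log2fc[cond] = tox_lfc
            call.antitoxin_log2fc[cond] = anti_lfc

            ns = len(tox_vals)
            nc = len(table.replicate_values(p.toxin, table.control))
            testable = ns + nc >= 4 and min_attainable_p(ns, nc, n_perm) <= alpha
            if testable:
                tox_p = permutation_significance(
                    table, p.toxin, cond, n_perm, seed, pseudocount)
                anti_p = permutation_significance(
                    table, p.antitoxin, cond, n_perm, seed, pseudocount)
                tox_sig = tox_p <= alpha
                anti_sig = anti_p <= alpha
                call.p_values[cond] = (tox_p, anti_p)
            else:
                tox_sig = anti_sig = True  # fold-change-only fallback
                call.p_values[cond] = (None, None)

            toxin_up = tox_lfc >= lfc_cut and tox_sig
            anti_down = anti_lfc <= -lfc_cut and anti_sig
            if toxin_up and anti_down:
                call.status[cond] = "both"
            elif toxin_up:
                call.status[cond] = "toxin-up"
            elif anti_down:
                call.status[cond] = "antitoxin-down"
            else:
                call.status[cond] = "none"
            if testable and call.status[cond] != "none":
                call.significant = True
        calls.append(call)
    return calls


def write_activation_tsv(
    calls: Iterable[PairActivationCall],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("pair_rank\ttoxin\tantitoxin\tcondition\ttoxin_log2fc\t"
                 "antitoxin_log2fc\tta_ratio\tstatus\ttoxin_p\tantitoxin_p\n")
        for c in calls:
            for cond in c.status:
                tox_p, anti_p = c.p_values.get(cond, (None, None))
                fh.write(
                    f"{c.pair_rank}\t{c.toxin}\t{c.antitoxin}\t{cond}\t"
                    f"{c.toxin_log2fc[cond]:.4f}\t{c.antitoxin_log2fc[cond]:.4f}\t"
                    f"{c.ta_ratio[cond]:.4f}\t{c.status[cond]}\t"
                    f"{'.' if tox_p is None else f'{tox_p:.4g}'}\t"
                    f"{'.' if anti_p is None else f'{anti_p:.4g}'}\n"
                )
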