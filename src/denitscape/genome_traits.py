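"""Genome-level denitrifier typing and trait comparisons.

A genome is typed by its repertoire of denitrification genes: nitrite
reductase (nirK and/or nirS), nitric oxide reductase (nor, any
heme-copper oxidase subtype) and nitrous oxide reductase (nosZ, clade I
or II). Complete denitrifiers carry nir + nor + nosZ; initiators carry
nir but not nosZ; terminators carry nosZ but not nir;
initiator-terminators carry nir and nosZ but lack nor. Genomes with
neither nir nor nosZ — and anammox bacteria or archaeal nitrifiers
whose nitrite reductases are not respiratory denitrification enzymes —
are non-denitrifiers, as are nor-only genomes (detoxification rather
than respiration).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from denitscape.data_io import DataError


class DenitrifierType(str, enum.Enum):
    COMPLETE = "complete"
    INITIATOR = "initiator"
    TERMINATOR = "terminator"
    INITIATOR_TERMINATOR = "initiator_terminator"
    NON_DENITRIFIER = "non_denitrifier"


DENITRIFIER_TYPES = (
    DenitrifierType.COMPLETE,
    DenitrifierType.INITIATOR,
    DenitrifierType.TERMINATOR,
    DenitrifierType.INITIATOR_TERMINATOR,
)


@dataclass(frozen=True)
class GeneRepertoire:
    """Denitrification gene presence plus exclusion flags for one genome."""

    has_nirK: bool = False
    has_nirS: bool = False
    has_nor: bool = False
    has_nosZ: bool = False
    nosZ_clade: str = "none"  # one of: I, II, both, none
    is_anammox: bool = False
    is_archaeal_nitrifier: bool = False

    def __post_init__(self) -> None:
        if (self.nosZ_clade != "none") != self.has_nosZ:
            raise ValueError(
                f"nosZ_clade={self.nosZ_clade!r} inconsistent with "
                f"has_nosZ={self.has_nosZ}"
            )

    @property
    def has_nir(self) -> bool:
        return self.has_nirK or self.has_nirS


def classify_denitrifier(rep: GeneRepertoire) -> DenitrifierType:
    """Assign the five-way denitrifier type for one gene repertoire.

    Exclusion flags override everything: anammox genomes and archaeal
    nitrifiers are non-denitrifiers regardless of gene content, as are
    genomes with neither nir nor nosZ (including nor-only genomes).
    """
    if rep.is_anammox or rep.is_archaeal_nitrifier:
        return DenitrifierType.NON_DENITRIFIER
    if not rep.has_nir and not rep.has_nosZ:
        return DenitrifierType.NON_DENITRIFIER
    if rep.has_nir and rep.has_nosZ:
        if rep.has_nor:
            return DenitrifierType.COMPLETE
        return DenitrifierType.INITIATOR_TERMINATOR
    if rep.has_nir:
        return DenitrifierType.INITIATOR
    return DenitrifierType.TERMINATOR


def classify_table(table: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_denitrifier` over a genome table."""
    nir = table["has_nirK"].astype(bool) | table["has_nirS"].astype(bool)
    nosz = table["has_nosZ"].astype(bool)
    nor = table["has_nor"].astype(bool)
    excluded = table["is_anammox"].astype(bool) | table[
        "is_archaeal_nitrifier"
    ].astype(bool)
    out = pd.Series(DenitrifierType.NON_DENITRIFIER.value, index=table.index)
    out[nir & ~nosz] = DenitrifierType.INITIATOR.value
    out[~nir & nosz] = DenitrifierType.TERMINATOR.value
    out[nir & nosz & nor] = DenitrifierType.COMPLETE.value
    out[nir & nosz & ~nor] = DenitrifierType.INITIATOR_TERMINATOR.value
    out[excluded] = DenitrifierType.NON_DENITRIFIER.value
    return out


def apply_quality_filter(
    table: pd.DataFrame,
    min_completeness: float = 80.0,
    max_contamination: float = 5.0,
    require_gunc: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop low-quality genomes; exclusion is strict at the boundaries.

    Genomes *less than* ``min_completeness`` % complete or *more than*
    ``max_contamination`` % contaminated are removed, so completeness
    exactly 80 and contamination exactly 5 are retained; genomes failing
    GUNC taxonomic-consistency screening are removed when
    ``require_gunc``. Returns the filtered table and per-criterion
    removal counts (a genome may count against several criteria).
    """
    completeness = table["completeness"].astype(float)
    contamination = table["contamination"].astype(float)
    low_comp = completeness < min_completeness
    high_cont = contamination > max_contamination
    if require_gunc:
        gunc_fail = ~table["gunc_pass"].astype(bool)
    else:
        gunc_fail = pd.Series(False, index=table.index)
    removed = low_comp | high_cont | gunc_fail
    report = {
        "low_completeness": int(low_comp.sum()),
        "high_contamination": int(high_cont.sum()),
        "gunc_fail": int(gunc_fail.sum()),
        "removed_total": int(removed.sum()),
        "retained": int((~removed).sum()),
    }
    return table.loc[~removed].copy(), report


def summarize_types(
    table: pd.DataFrame, group_by: str | None = None
) -> pd.DataFrame:
    """Count denitrifier types and their proportions, overall or by group.

    Proportions of the four denitrifier types are computed over
    denitrifier genomes only; ``denitrifier_fraction`` is the share of
    denitrifiers among all genomes in the group. A genome whose nosZ
    clade is "both" is counted under clade I in clade-conditional
    summaries elsewhere; here only the type column matters.
    """
    if "denitrifier_type" not in table.columns:
        table = table.assign(denitrifier_type=classify_table(table))
    if group_by is not None and group_by not in table.columns:
        raise KeyError(f"unknown grouping column {group_by!r}")
    groups = (
        [("all", table)] if group_by is None else list(table.groupby(group_by))
    )
    rows = []
    for name, sub in groups:
        counts = sub["denitrifier_type"].value_counts()
        n_total = len(sub)
        n_denit = sum(
            int(counts.get(t.value, 0)) for t in DENITRIFIER_TYPES
        )
        row: dict[str, object] = {"group": name, "n_genomes": n_total}
        for t in DenitrifierType:
            row[f"n_{t.value}"] = int(counts.get(t.value, 0))
        for t in DENITRIFIER_TYPES:
            row[f"prop_{t.value}"] = (
                row[f"n_{t.value}"] / n_denit if n_denit else math.nan
            )
        row["denitrifier_fraction"] = n_denit / n_total if n_total else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def nosz_clade_cross_table(table: pd.DataFrame) -> pd.DataFrame:
    """Complete-pathway vs. nosZ-clade conditional proportions.

    Among nosZ-carrying genomes, reports both P(clade | complete) and
    P(complete | clade). Genomes with both clades are counted as clade I
    (conservative toward the clade I / complete-pathway association) and
    flagged in the output.
    """
    if "denitrifier_type" not in table.columns:
        table = table.assign(denitrifier_type=classify_table(table))
    carriers = table[table["has_nosZ"].astype(bool)].copy()
    clade = carriers["nosZ_clade"].astype(str).replace({"both": "I"})
    complete = carriers["denitrifier_type"] == DenitrifierType.COMPLETE.value
    rows = []
    for cl in ("I", "II"):
        in_clade = clade == cl
        n_clade = int(in_clade.sum())
        rows.append(
            {
                "clade": cl,
                "n_nosZ_genomes": n_clade,
                "p_complete_given_clade": (
                    float((complete & in_clade).sum() / n_clade)
                    if n_clade else math.nan
                ),
                "p_clade_given_complete": (
                    float((complete & in_clade).sum() / complete.sum())
                    if complete.sum() else math.nan
                ),
                "n_both_counted_as_I": int(
                    (carriers["nosZ_clade"] == "both").sum()
                ) if cl == "I" else 0,
            }
        )
    return pd.DataFrame(rows)


def trait_density(count: float, genome_size: float) -> float:
    """Genomic trait density: copies per Mbp of genome."""
    if genome_size <= 0:
        raise DataError(f"genome_size must be positive, got {genome_size}")
    return count * 1e6 / genome_size


def bin_growth_rate(rate: float, cutoff: float = 0.2) -> str:
    """Bin a predicted maximum growth rate (per hour) as fast or slow.

    Codon-usage-bias growth predictions saturate below ~0.2 h^-1, which
    motivates the cutoff; a rate exactly at the cutoff is binned fast.
    """
    if rate < 0:
        raise DataError(f"growth rate must be non-negative, got {rate}")
    return "fast" if rate >= cutoff else "slow"


# ---------------------------------------------------------------------------
# rank statistics


@dataclass
class RankComparison:
    """Kruskal-Wallis omnibus plus Dunn pairwise tests with BH correction."""

    statistic: float
    df: int
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adjusted
    letters: dict[str, str]
    medians: dict[str, float]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adjusted[i] = running
    return adjusted


def compact_letter_display(
    groups: Sequence[str], pairs: Mapping[tuple[str, str], float], alpha: float = 0.05
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different (adjusted
    p >= alpha). Groups are processed in the order given, so the
    assignment is deterministic.
    """
    def differ(a: str, b: str) -> bool:
        p = pairs.get((a, b), pairs.get((b, a), 1.0))
        return p < alpha

    groups = list(groups)
    columns: list[set[str]] = [set(groups)]
    for a, b in combinations(groups, 2):
        if not differ(a, b):
            continue
        for col in list(columns):
            if a in col and b in col:  # insert: split the violating column
                columns.remove(col)
                columns.append(col - {a})
                columns.append(col - {b})
        # absorb: drop columns contained in another
        columns = [
            col
            for i, col in enumerate(columns)
            if col
            and not any(
                col <= other and (col < other or j < i)
                for j, other in enumerate(columns)
                if j != i
            )
        ]
    letters = {g: "" for g in groups}
    for i, col in enumerate(sorted(columns, key=lambda c: min(groups.index(g) for g in c))):
        letter = chr(ord("a") + i)
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


def compare_groups_ranked(
    values: Sequence[float],
    groups: Sequence[str],
    tie_floor: float | None = None,
    alpha: float = 0.05,
) -> RankComparison:
    """Kruskal-Wallis test with Dunn pairwise z-tests and BH correction.

    When ``tie_floor`` is set, every value below the floor is replaced by
    the floor before ranking, so all sub-threshold values share one rank
    (used for growth rates, whose codon-bias predictions are not
    meaningful below 0.2 h^-1). Dunn z statistics use the tie-corrected
    standard error; BH adjustment spans all pairwise comparisons within
    this call. Letters come from the insert-and-absorb compact letter
    display at ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if not np.any(groups == lab):
            raise ValueError(f"group {lab!r} is empty")
    if tie_floor is not None:
        values = np.where(values < tie_floor, tie_floor, values)

    samples = [values[groups == lab] for lab in labels]
    if np.ptp(values) == 0:  # every value tied: no evidence of difference
        statistic, p_value = 0.0, 1.0
    else:
        statistic, p_value = stats.kruskal(*samples)

    # Dunn pairwise z tests on the pooled mid-ranks
    n = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {lab: ranks[groups == lab].mean() for lab in labels}
    sizes = {lab: int((groups == lab).sum()) for lab in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    rows = []
    for a, b in combinations(labels, 2):
        se2 = (n * (n + 1) / 12.0 - tie_term) * (1 / sizes[a] + 1 / sizes[b])
        if se2 <= 0:
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(se2)
        p_raw = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p_raw})
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    if len(pairwise):
        pairwise["p_adjusted"] = _bh_adjust(pairwise["p_raw"].to_numpy())
    else:
        pairwise["p_adjusted"] = []
    pair_p = {
        (r.group_a, r.group_b): r.p_adjusted for r in pairwise.itertuples()
    }
    letters = compact_letter_display(labels, pair_p, alpha=alpha)
    medians = {lab: float(np.median(values[groups == lab])) for lab in labels}
    return RankComparison(
        statistic=float(statistic),
        df=len(labels) - 1,
        p_value=float(p_value),
        pairwise=pairwise,
        letters=letters,
        medians=medians,
    )


def compare_counts_ks(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """One-sided two-sample Kolmogorov-Smirnov test.

    Tests whether ``values_b`` is stochastically smaller than
    ``values_a`` via the D^- statistic ``max(F_b - F_a)`` over the
    pooled support (the ECDF of b sits above that of a where b's values
    are smaller). The p-value uses the one-sided asymptotic formula
    ``exp(-2 m n D^2 / (m + n))``.
    """
    a = np.sort(np.asarray(values_a, dtype=float))
    b = np.sort(np.asarray(values_b, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least two values")
    support = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, support, side="right") / len(a)
    cdf_b = np.searchsorted(b, support, side="right") / len(b)
    d = float(max(np.max(cdf_b - cdf_a), 0.0))
    m, n = len(a), len(b)
    p = float(min(1.0, math.exp(-2 * m * n * d * d / (m + n))))
    return d, p
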