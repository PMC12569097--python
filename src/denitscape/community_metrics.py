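"""Community-level denitrification gene balance statistics.

Per-sample filtered counts of nirK, nirS and nosZ clade I/II read
placements are turned into two per-Gbp delta statistics:

    delta_nos_nir    = 1e9 * ((nosZI + nosZII) - (nirS + nirK)) / (L * reads)
    delta_nosZI_II   = 1e9 * (nosZI - nosZII) / (L * reads)

where ``L`` is the read length (150 nt by default — reads longer than
that are truncated upstream) and ``reads`` the sample's total read
count. Positive delta_nos_nir means the community's capacity to
terminate denitrification (reduce N2O) exceeds its capacity to initiate
it (reduce NO2-); positive delta_nosZI_II means clade I nosZ — enriched
in complete denitrifiers — dominates the N2O reducers. Deltas are
defined even when one or both gene groups are undetected, which is why
they are preferred over ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from denitscape.data_io import DataError
from denitscape.genome_traits import RankComparison, compare_groups_ranked

DEFAULT_READ_LENGTH = 150.0

# clade labels excluded from counting: non-denitrifying anammox NirS
# clade 1h, archaeal-nitrifier NirK clades 2 and 4, eukaryotic NirK
# clades 1b and 1e, and nosZ clade III (the reference-tree outgroup).
DEFAULT_EXCLUDED_CLADES = frozenset(
    {"NirS_1h", "NirK_2", "NirK_4", "NirK_1b", "NirK_1e", "nosZ_III"}
)

# map a counted clade label to the tally it contributes to
CLADE_TO_COUNT: dict[str, str] = {
    "nirK": "nirK",
    "NirK_1a": "nirK",
    "NirK_1c": "nirK",
    "NirK_1d": "nirK",
    "NirK_1f": "nirK",
    "NirK_1g": "nirK",
    "NirK_3": "nirK",
    "nirS": "nirS",
    "NirS_1a": "nirS",
    "NirS_1b": "nirS",
    "NirS_2": "nirS",
    "nosZ_I": "nosZI",
    "nosZ_II": "nosZII",
    "nosZI": "nosZI",
    "nosZII": "nosZII",
}

KNOWN_CLADES = (
    frozenset(CLADE_TO_COUNT) | DEFAULT_EXCLUDED_CLADES | {"outgroup"}
)


@dataclass(frozen=True)
class GeneCounts:
    """Filtered denitrification gene fragment counts for one sample."""

    sample_id: str
    nirK: int
    nirS: int
    nosZI: int
    nosZII: int
    reads: float
    read_length: float = DEFAULT_READ_LENGTH

    def __post_init__(self) -> None:
        for name in ("nirK", "nirS", "nosZI", "nosZII"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} count is negative")


@dataclass(frozen=True)
class DeltaResult:
    sample_id: str
    delta_nos_nir: float
    delta_nosZI_nosZII: float


def delta_nos_nir(counts: GeneCounts) -> float:
    """Per-Gbp excess of nosZ over nir gene fragments (termination
    minus initiation capacity)."""
    if counts.reads <= 0:
        raise DataError("total reads must be positive")
    if counts.read_length <= 0:
        raise DataError("read length must be positive")
    numerator = (counts.nosZI + counts.nosZII) - (counts.nirS + counts.nirK)
    return 1e9 * numerator / (counts.read_length * counts.reads)


def delta_nosZ_clades(counts: GeneCounts) -> float:
    """Per-Gbp excess of clade I over clade II nosZ fragments (proxy
    for complete-denitrifier dominance among N2O reducers)."""
    if counts.reads <= 0:
        raise DataError("total reads must be positive")
    if counts.read_length <= 0:
        raise DataError("read length must be positive")
    return 1e9 * (counts.nosZI - counts.nosZII) / (counts.read_length * counts.reads)


def compute_deltas(counts: GeneCounts) -> DeltaResult:
    return DeltaResult(
        sample_id=counts.sample_id,
        delta_nos_nir=delta_nos_nir(counts),
        delta_nosZI_nosZII=delta_nosZ_clades(counts),
    )


def filter_placed_reads(
    placements: pd.DataFrame,
    mass_threshold: float = 0.95,
    excluded_clades: Iterable[str] = DEFAULT_EXCLUDED_CLADES,
    clade_to_count: Mapping[str, str] = CLADE_TO_COUNT,
) -> dict[str, int]:
    """Tally reads surviving the placement filter into gene counts.

    A read is counted iff (a) at least ``mass_threshold`` of its
    placement mass accumulates on a single clade, (b) no mass at all
    lands on the outgroup, and (c) that clade is not excluded. Returns a
    dict with keys nirK, nirS, nosZI, nosZII.

    ``placements`` is a tidy frame with columns read_id, clade, mass
    (gene_family optional) as produced by
    :func:`denitscape.data_io.load_placements`.
    """
    excluded = set(excluded_clades)
    known = set(clade_to_count) | excluded | {"outgroup"}
    tallies = {"nirK": 0, "nirS": 0, "nosZI": 0, "nosZII": 0}
    if placements.empty:
        return tallies
    unknown = sorted(set(placements["clade"].astype(str)) - known)
    if unknown:
        raise DataError(
            f"unknown clade label(s) {unknown}; known labels: {sorted(known)}"
        )
    for _read, sub in placements.groupby("read_id", sort=False):
        masses = sub.groupby("clade")["mass"].sum()
        if masses.get("outgroup", 0.0) > 0:
            continue
        top_clade = masses.idxmax()
        if masses[top_clade] < mass_threshold:
            continue
        if top_clade in excluded:
            continue
        tallies[clade_to_count[top_clade]] += 1
    return tallies


def counts_from_placements(
    placements: pd.DataFrame,
    sample_id: str,
    reads: float,
    read_length: float = DEFAULT_READ_LENGTH,
    mass_threshold: float = 0.95,
    excluded_clades: Iterable[str] = DEFAULT_EXCLUDED_CLADES,
) -> GeneCounts:
    """Convenience: filter placements and wrap the tallies for a sample."""
    tallies = filter_placed_reads(
        placements, mass_threshold=mass_threshold, excluded_clades=excluded_clades
    )
    return GeneCounts(
        sample_id=sample_id, reads=reads, read_length=read_length, **tallies
    )


def deltas_table(counts_table: pd.DataFrame) -> pd.DataFrame:
    """Compute both deltas for each row of a gene-count table."""
    df = counts_table.copy()
    length = df.get("read_length")
    if length is None:
        length = pd.Series(DEFAULT_READ_LENGTH, index=df.index)
    length = length.astype(float).fillna(DEFAULT_READ_LENGTH)
    reads = df["reads"].astype(float)
    if (reads <= 0).any():
        raise DataError("total reads must be positive for every sample")
    bp = length * reads
    nos = df["nosZI"].astype(float) + df["nosZII"].astype(float)
    nir = df["nirS"].astype(float) + df["nirK"].astype(float)
    df["delta_nos_nir"] = 1e9 * (nos - nir) / bp
    df["delta_nosZI_nosZII"] = (
        1e9 * (df["nosZI"].astype(float) - df["nosZII"].astype(float)) / bp
    )
    return df


def assign_marine_zone(latitude: float) -> str:
    """Latitudinal marine biome zone from absolute latitude.

    polar above 60 degrees, westerlies from 30 to 60 inclusive, trades
    below 30. Hemisphere is ignored.
    """
    if math.isnan(latitude) or abs(latitude) > 90:
        raise DataError(f"latitude out of range: {latitude}")
    lat = abs(latitude)
    if lat > 60:
        return "polar"
    if lat >= 30:
        return "westerlies"
    return "trades"


def compare_biomes(
    deltas: Sequence[float] | pd.Series,
    biomes: Sequence[str] | pd.Series,
    alpha: float = 0.05,
) -> RankComparison:
    """Ranked comparison of a delta statistic across biomes.

    Kruskal-Wallis followed by BH-corrected Dunn pairwise tests; biomes
    sharing a compact-display letter have statistically similar median
    deltas. No tie floor is applied.
    """
    return compare_groups_ranked(deltas, biomes, tie_floor=None, alpha=alpha)
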