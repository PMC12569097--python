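"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the four data streams the analysis consumes:
genome annotation tables with a configurable denitrifier-type mixture,
per-sample metagenome gene counts with biome-specific delta offsets,
clade-structured reference sequences for placement validation, and MAG
abundance surveys with configurable linear responses to environmental
gradients. Every generator is a pure function of its configuration
(seed included): the same config yields byte-identical output.

Distributional choices are stand-ins — no generative model exists for
the real annotation and survey data — and are documented in the
methods note. Counts are Poisson at fixed sequencing depth; nucleotide
substitution is i.i.d. uniform over the three alternatives
(Jukes-Cantor-like); genome sizes are lognormal around a 4 Mbp median.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from denitscape.genome_traits import DenitrifierType

NUCLEOTIDES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """A simulation configuration violates an invariant."""


# Default type mixture over denitrifier genomes: complete 23%,
# initiators 49%, terminators 24%, initiator-terminators 4%; 18% of all
# genomes are denitrifiers.
DEFAULT_TYPE_MIXTURE: dict[str, float] = {
    "complete": 0.23,
    "initiator": 0.49,
    "terminator": 0.24,
    "initiator_terminator": 0.04,
}

DEFAULT_PHYLUM_WEIGHTS: dict[str, float] = {
    "Pseudomonadota": 0.40,
    "Actinomycetota": 0.18,
    "Bacteroidota": 0.16,
    "Planctomycetota": 0.06,
    "Chloroflexota": 0.06,
    "Gemmatimonadota": 0.04,
    "Other": 0.10,
}

# lognormal medians (h^-1) per type, matching the reported medians for
# predicted maximum growth rates
DEFAULT_GROWTH_MEDIANS: dict[str, float] = {
    "complete": 0.46,
    "initiator": 0.28,
    "terminator": 0.23,
    "initiator_terminator": 0.20,
    "non_denitrifier": 0.25,
}

# per-Gbp biome offsets (delta_nos_nir, delta_nosZI_nosZII); chosen so
# nir dominates nosZ and clade II dominates clade I nearly everywhere,
# with engineered (sewage-like) communities clade-I dominated
DEFAULT_BIOME_EFFECTS: dict[str, tuple[float, float]] = {
    "soil": (-120.0, -60.0),
    "aquatic": (-60.0, -30.0),
    "engineered": (-90.0, 25.0),
    "host_associated": (-40.0, -20.0),
}

# transporter / transcription-factor densities per Mbp and substrate
# count centres per type (complete denitrifiers are the flexible
# generalists: denser regulation and transport, broader substrate range)
TRAIT_CENTRES: dict[str, dict[str, float]] = {
    "complete": {"transporters": 68, "tfs": 30, "substrates": 20, "redox": 1.5},
    "initiator": {"transporters": 65, "tfs": 26, "substrates": 13, "redox": 0.7},
    "terminator": {"transporters": 40, "tfs": 18, "substrates": 11, "redox": 0.7},
    "initiator_terminator": {
        "transporters": 42, "tfs": 19, "substrates": 9, "redox": 0.6,
    },
    "non_denitrifier": {"transporters": 50, "tfs": 22, "substrates": 12, "redox": 0.5},
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the four generators, with study-scale defaults."""

    seed: int = 0
    # genomes
    n_genomes: int = 1000
    denitrifier_fraction: float = 0.18
    type_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIXTURE)
    )
    phylum_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_WEIGHTS)
    )
    quality_fail_fraction: float = 0.10
    growth_rate_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROWTH_MEDIANS)
    )
    growth_rate_sigma: float = 0.6
    genome_size_median: float = 4e6
    genome_size_sigma: float = 0.35
    nor_only_fraction: float = 0.06  # of non-denitrifiers: nor-only genomes
    anammox_fraction: float = 0.001  # of non-denitrifiers: anammox with nir
    clade_I_given_complete: float = 0.74
    clade_II_given_terminator: float = 0.80
    clade_II_given_init_term: float = 0.70
    # metagenome counts
    n_samples: int = 50
    depth: int = 1_000_000
    read_length: float = 150.0
    gene_rate_base: float = 400.0  # expected nir copies per Gbp
    nirK_fraction: float = 0.6  # of nir counts
    biome_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BIOME_EFFECTS)
    )
    # reference sequences
    clades: Sequence[str] = ("nosZ_I", "nosZ_II")
    n_refs_per_clade: int = 20
    seq_length: int = 900
    divergence_within: float = 0.05
    divergence_between: float = 0.40
    outgroup_divergence: float = 0.55
    n_outgroup: int = 20
    # MAG survey
    mags_per_type: Mapping[str, int] = field(
        default_factory=lambda: {
            "complete": 7,
            "initiator": 13,
            "terminator": 14,
            "initiator_terminator": 2,
        }
    )
    env_design: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"no3": (0.0, 1.0), "chlorophyll": (0.0, 1.0)}
    )
    type_slopes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "complete": {"no3": 0.5, "chlorophyll": 0.0},
            "initiator": {"no3": 0.0, "chlorophyll": 0.0},
            "terminator": {"no3": 0.0, "chlorophyll": 0.0},
            "initiator_terminator": {"no3": 0.0, "chlorophyll": 0.0},
        }
    )
    abundance_noise_sd: float = 0.05
    max_rel_abundance: float = 0.02

    def validate(self) -> None:
        mix = dict(self.type_mixture)
        if any(not 0 <= p <= 1 for p in mix.values()):
            raise ConfigError("type mixture proportions must lie in [0, 1]")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError(
                f"type mixture must sum to 1, got {sum(mix.values())!r}"
            )
        if self.n_genomes < 0:
            raise ConfigError("n_genomes must be non-negative")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if not 0 < self.divergence_within < 1 or not 0 < self.divergence_between < 1:
            raise ConfigError("divergences must lie in (0, 1)")
        if self.abundance_noise_sd < 0:
            raise ConfigError("abundance noise sd must be non-negative")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator (crc32 is stable
    # across processes, unlike the builtin hash)
    key = zlib.crc32(stream.encode()) % 2**31
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    )


def simulate_genomes(config: SimulationConfig) -> pd.DataFrame:
    """Draw a genome annotation table consistent with the type mixture.

    Each genome's gene presence columns are generated from its drawn
    type, so re-classifying the table recovers the mixture exactly up to
    multinomial sampling error. A ``quality_fail_fraction`` of genomes is
    given metrics that fail the standard quality filter. The truth type
    is included as column ``true_type``.
    """
    config.validate()
    rng = _rng(config, "genomes")
    n = config.n_genomes
    cols = {
        "genome_id": [f"G{i:06d}" for i in range(n)],
    }
    if n == 0:
        frame = pd.DataFrame(cols)
        for c in (
            "assembly_type completeness contamination gunc_pass phylum genome_size "
            "has_nirK has_nirS has_nor has_nosZ nosZ_clade is_anammox "
            "is_archaeal_nitrifier max_growth_rate n_ribosomal_proteins "
            "n_transporters n_transcription_factors n_substrates "
            "n_inorganic_donors n_inorganic_acceptors true_type"
        ).split():
            frame[c] = pd.Series(dtype=object)
        return frame

    # allocate counts by largest-remainder quota so the configured
    # mixture IS the realized ground truth (up to rounding), then
    # assign types to genomes in random order
    mix_total = sum(config.type_mixture.values())
    shares = {
        t: config.denitrifier_fraction * p / mix_total
        for t, p in config.type_mixture.items()
    }
    shares[DenitrifierType.NON_DENITRIFIER.value] = 1 - config.denitrifier_fraction
    floors = {t: int(n * s) for t, s in shares.items()}
    remainders = sorted(
        shares, key=lambda t: (n * shares[t]) - floors[t], reverse=True
    )
    short = n - sum(floors.values())
    for t in remainders[:short]:
        floors[t] += 1
    types = np.repeat(
        [str(t) for t in floors], [floors[t] for t in floors]
    ).astype(object)
    rng.shuffle(types)

    has_nirK = np.zeros(n, bool)
    has_nirS = np.zeros(n, bool)
    has_nor = np.zeros(n, bool)
    has_nosZ = np.zeros(n, bool)
    clade = np.full(n, "none", dtype=object)
    anammox = np.zeros(n, bool)

    u = rng.random((n, 4))
    for i, t in enumerate(types):
        if t in ("complete", "initiator", "initiator_terminator"):
            # which nitrite reductase: nirK-dominant, occasionally both
            if u[i, 0] < 0.55:
                has_nirK[i] = True
            elif u[i, 0] < 0.95:
                has_nirS[i] = True
            else:
                has_nirK[i] = has_nirS[i] = True
        if t == "complete":
            has_nor[i] = True
            has_nosZ[i] = True
            clade[i] = "I" if u[i, 1] < config.clade_I_given_complete else "II"
        elif t == "initiator":
            has_nor[i] = u[i, 1] < 0.5
        elif t == "terminator":
            has_nosZ[i] = True
            has_nor[i] = u[i, 1] < 0.3
            clade[i] = "II" if u[i, 2] < config.clade_II_given_terminator else "I"
        elif t == "initiator_terminator":
            has_nosZ[i] = True
            clade[i] = "II" if u[i, 2] < config.clade_II_given_init_term else "I"
        else:  # non-denitrifier: mostly empty, some nor-only, rare anammox
            if u[i, 1] < config.nor_only_fraction:
                has_nor[i] = True
            elif u[i, 1] < config.nor_only_fraction + config.anammox_fraction:
                anammox[i] = True
                has_nirS[i] = True

    fails = rng.random(n) < config.quality_fail_fraction
    completeness = np.where(
        fails & (rng.random(n) < 0.5),
        rng.uniform(50, 80, n),
        rng.uniform(80, 100, n),
    )
    contamination = np.where(
        fails & (completeness >= 80), rng.uniform(5, 15, n), rng.uniform(0, 5, n)
    )
    # among remaining failures, fail GUNC instead
    gunc_pass = ~(fails & (completeness >= 80) & (contamination <= 5))

    size = rng.lognormal(
        math.log(config.genome_size_median), config.genome_size_sigma, n
    )
    growth_mu = np.array(
        [math.log(config.growth_rate_medians[t]) for t in types]
    )
    growth = np.exp(rng.normal(growth_mu, config.growth_rate_sigma))
    # a small fraction of genomes has too few ribosomal proteins annotated
    n_ribo = rng.poisson(50, n)
    few = rng.random(n) < 0.03
    n_ribo[few] = rng.integers(0, 10, few.sum())

    mbp = size / 1e6
    centres = np.array(
        [
            [
                TRAIT_CENTRES[t]["transporters"],
                TRAIT_CENTRES[t]["tfs"],
                TRAIT_CENTRES[t]["substrates"],
                TRAIT_CENTRES[t]["redox"],
            ]
            for t in types
        ]
    )
    transporters = rng.poisson(centres[:, 0] * mbp)
    tfs = rng.poisson(centres[:, 1] * mbp)
    substrates = rng.poisson(centres[:, 2])
    donors = rng.poisson(centres[:, 3])
    acceptors = rng.poisson(centres[:, 3])

    phyla = list(config.phylum_weights)
    pw = np.array([config.phylum_weights[p] for p in phyla], float)
    frame = pd.DataFrame(
        {
            "genome_id": cols["genome_id"],
            "assembly_type": rng.choice(["isolate", "mag", "sag"], n, p=[0.49, 0.46, 0.05]),
            "completeness": np.round(completeness, 2),
            "contamination": np.round(contamination, 2),
            "gunc_pass": gunc_pass,
            "phylum": rng.choice(phyla, n, p=pw / pw.sum()),
            "genome_size": np.round(size).astype(int),
            "has_nirK": has_nirK,
            "has_nirS": has_nirS,
            "has_nor": has_nor,
            "has_nosZ": has_nosZ,
            "nosZ_clade": clade,
            "is_anammox": anammox,
            "is_archaeal_nitrifier": np.zeros(n, bool),
            "max_growth_rate": np.round(growth, 4),
            "n_ribosomal_proteins": n_ribo,
            "n_transporters": transporters,
            "n_transcription_factors": tfs,
            "n_substrates": substrates,
            "n_inorganic_donors": donors,
            "n_inorganic_acceptors": acceptors,
            "true_type": types,
        }
    )
    return frame


def expected_gene_rates(
    config: SimulationConfig, biome: str
) -> dict[str, float]:
    """Per-Gbp Poisson rates implied by a biome's configured deltas.

    The nir total is the base rate; the nosZ total is offset so the
    expected delta_nos_nir equals the configured biome effect, and the
    clade split so expected delta_nosZI_nosZII matches too.
    """
    d_nos_nir, d_clades = config.biome_effects[biome]
    nir_total = config.gene_rate_base
    nos_total = nir_total + d_nos_nir
    nosZI = (nos_total + d_clades) / 2
    nosZII = (nos_total - d_clades) / 2
    rates = {
        "nirK": nir_total * config.nirK_fraction,
        "nirS": nir_total * (1 - config.nirK_fraction),
        "nosZI": nosZI,
        "nosZII": nosZII,
    }
    if any(r < 0 for r in rates.values()):
        raise ConfigError(
            f"biome {biome!r}: configured effects imply a negative gene rate "
            f"({rates}); raise gene_rate_base or soften the effects"
        )
    return rates


def simulate_metagenome_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw (sample metadata, per-sample gene counts) across biomes.

    Counts are Poisson with per-gene rates chosen so the expected
    per-Gbp deltas equal the configured biome effects exactly. Each
    biome receives ``n_samples`` samples.
    """
    config.validate()
    rng = _rng(config, "metagenomes")
    meta_rows, count_rows = [], []
    habitat = {
        "soil": "soil",
        "aquatic": "aquatic",
        "engineered": "engineered",
        "host_associated": "host_associated",
    }
    gbp = config.depth * config.read_length / 1e9
    idx = 0
    for biome in config.biome_effects:
        rates = expected_gene_rates(config, biome)
        for _ in range(config.n_samples):
            sid = f"S{idx:05d}"
            idx += 1
            lat = float(rng.uniform(-80, 80)) if biome == "aquatic" else float("nan")
            meta_rows.append(
                {
                    "sample_id": sid,
                    "biome": biome,
                    "habitat_class": habitat.get(biome, "soil"),
                    "total_reads": config.depth,
                    "read_length": config.read_length,
                    "latitude": lat,
                }
            )
            count_rows.append(
                {
                    "sample_id": sid,
                    "nirK": int(rng.poisson(rates["nirK"] * gbp)),
                    "nirS": int(rng.poisson(rates["nirS"] * gbp)),
                    "nosZI": int(rng.poisson(rates["nosZI"] * gbp)),
                    "nosZII": int(rng.poisson(rates["nosZII"] * gbp)),
                    "reads": config.depth,
                    "read_length": config.read_length,
                }
            )
    return pd.DataFrame(meta_rows), pd.DataFrame(count_rows)


def _mutate(rng: np.random.Generator, seq: np.ndarray, divergence: float) -> np.ndarray:
    """i.i.d. substitution: each site mutates with prob ``divergence`` to
    one of the three alternative nucleotides, uniformly."""
    out = seq.copy()
    hit = rng.random(len(seq)) < divergence
    if hit.any():
        shift = rng.integers(1, 4, hit.sum())
        idx = np.searchsorted(NUCLEOTIDES, out[hit])
        out[hit] = NUCLEOTIDES[(idx + shift) % 4]
    return out


def simulate_reference_sequences(
    config: SimulationConfig,
) -> tuple[list, pd.DataFrame]:
    """Evolve clade-structured reference sequences from a common root.

    Each requested clade gets an ancestor derived from the root at the
    between-clade divergence, and ``n_refs_per_clade`` descendants at the
    within-clade divergence; an outgroup family is evolved at a higher
    divergence. Returns Biopython SeqRecords plus a truth table with
    columns seq_id / clade (clade "outgroup" for outgroup sequences).
    """
    config.validate()
    if len(config.clades) < 2:
        raise ConfigError("at least two clades are required")
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = _rng(config, "references")
    root = rng.choice(NUCLEOTIDES, config.seq_length)
    records, rows = [], []
    families = [(c, config.n_refs_per_clade) for c in config.clades]
    families.append(("outgroup", config.n_outgroup))
    for clade_name, n_seqs in families:
        div = (
            config.outgroup_divergence
            if clade_name == "outgroup"
            else config.divergence_between
        )
        ancestor = _mutate(rng, root, div)
        for j in range(n_seqs):
            seq = _mutate(rng, ancestor, config.divergence_within)
            seq_id = f"{clade_name}_ref{j:03d}"
            records.append(
                SeqRecord(Seq(seq.tobytes().decode()), id=seq_id, description="")
            )
            rows.append({"seq_id": seq_id, "clade": clade_name})
    return records, pd.DataFrame(rows)


def simulate_mag_survey(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw (abundance, environment, truth) tables for a MAG survey.

    Standardized abundances follow per-type linear responses to the
    environmental gradients plus Gaussian noise, then are rescaled so
    the maximum per MAG equals ``max_rel_abundance``. Because the
    standardized scale is defined relative to the observed maximum, the
    observation defining a responsive MAG's maximum is pinned at the
    noise-free optimum — noise on the scale-defining observation is
    indistinguishable from rescaled noise on all the others — and each
    gradient includes one sample at either extreme, with the remaining
    samples drawn from the central part of the range, so the optimum is
    attained at an isolated design point (see the methods note).

    Truth columns: mag_id, denitrifier_type and the true slope per
    predictor on the standardized-abundance scale.
    """
    config.validate()
    if config.n_samples < 10:
        raise ConfigError("MAG survey needs at least 10 samples")
    if len(config.env_design) < 2:
        raise ConfigError("env_design must cover at least two gradients")
    rng = _rng(config, "mag_survey")
    n = config.n_samples
    predictors = list(config.env_design)
    env = {}
    for pi, (name, (lo, hi)) in enumerate(config.env_design.items()):
        span = hi - lo
        col = rng.uniform(lo + 0.3 * span, hi - 0.3 * span, n)
        # pin one sample at each gradient extreme (distinct samples per
        # gradient) so a responsive MAG's optimum is isolated
        col[(2 * pi) % n] = hi
        col[(2 * pi + 1) % n] = lo
        env[name] = col
    env = pd.DataFrame(env, index=[f"S{i:04d}" for i in range(n)])

    abund_rows, truth_rows = [], []
    for t, n_mags in config.mags_per_type.items():
        slopes = {p: config.type_slopes.get(t, {}).get(p, 0.0) for p in predictors}
        for j in range(n_mags):
            mag_id = f"{t}_MAG{j:03d}"
            linear = np.zeros(n)
            for p in predictors:
                linear += slopes[p] * env[p].to_numpy()
            y = rng.normal(0.0, config.abundance_noise_sd, n)
            if np.ptp(linear) > 0:
                # shift the response so its noise-free peak is exactly 1
                # and pin the scale-defining observation there
                mean = linear + (1.0 - linear.max())
                y += mean
                y[int(np.argmax(mean))] = 1.0
            else:
                # unresponsive MAG: flat mid-range abundance; the noisy
                # maximum only rescales, leaving the zero slope unbiased
                y += 0.5
            y = np.clip(y, 0.0, 1.0)
            abund_rows.append(
                pd.Series(y * config.max_rel_abundance, index=env.index, name=mag_id)
            )
            truth_rows.append(
                {"mag_id": mag_id, "denitrifier_type": t, **{
                    f"slope_{p}": slopes[p] for p in predictors
                }}
            )
    abundance = pd.DataFrame(abund_rows)
    truth = pd.DataFrame(truth_rows)
    return abundance, env, truth
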