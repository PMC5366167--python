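"""Simulated F2 populations for genomic prediction experiments.

Two fully inbred lines fixed for opposite alleles (AA x aa) are crossed; the
uniformly heterozygous F1 is selfed, and each F2 individual is formed from
two independent F1 gametes.  Meiosis follows a no-interference (Haldane)
crossover model, so the recombination fraction between loci d centimorgans
apart is c(d) = (1 - exp(-0.02 d)) / 2 and chromosomes assort independently.

The default design is 10 chromosomes of 50 cM with one marker per cM
(p = 500) and one additive QTL per 10 cM window placed midway between
markers (50 QTL, unobserved by the marker panel).  QTL effects are i.i.d.
standard normal; Gaussian noise is scaled to a target narrow-sense
heritability of 0.5 on the realized genetic variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import GenotypeMatrix, InvalidConfigError, InvalidInputError


@dataclass(frozen=True)
class SimConfig:
    n_chromosomes: int = 10
    chr_length: float = 50.0        # genetic length per chromosome, cM
    marker_spacing: float = 1.0     # cM between adjacent markers
    qtl_spacing: float = 10.0       # one QTL per window of this size, cM
    n_individuals: int = 400
    heritability: float = 0.5
    seed: int = 0
    qtl_effect_dist: str = "standard-normal"

    def __post_init__(self):
        if not 0.0 < self.heritability <= 1.0:
            raise InvalidConfigError("heritability must be in (0, 1]")
        if self.qtl_effect_dist != "standard-normal":
            raise InvalidConfigError("unknown QTL effect distribution")


class Locus(NamedTuple):
    chromosome: int   # 1-based in reports; stored 1-based here too
    position_cm: float
    locus_id: str
    is_qtl: bool


@dataclass(frozen=True)
class GeneticMap:
    loci: tuple[Locus, ...]

    def __post_init__(self):
        chrom = self.chromosomes
        pos = self.positions_cm
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if not np.all(np.diff(p) > 0):
                raise InvalidInputError(f"positions not strictly increasing on chr {c}")

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([l.chromosome for l in self.loci])

    @property
    def positions_cm(self) -> np.ndarray:
        return np.array([l.position_cm for l in self.loci])

    @property
    def is_qtl(self) -> np.ndarray:
        return np.array([l.is_qtl for l in self.loci])

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class SimulatedPopulation:
    marker_genotypes: GenotypeMatrix
    qtl_genotypes: np.ndarray
    qtl_effects: np.ndarray
    genetic_values: np.ndarray
    phenotypes: np.ndarray
    realized_h2: float
    genetic_map: GeneticMap


def haldane_recombination_fraction(d_cm) -> np.ndarray | float:
    """c(d) = (1 - exp(-0.02 d)) / 2 for map distance d in centimorgans."""
    return 0.5 * (1.0 - np.exp(-0.02 * np.asarray(d_cm, dtype=np.float64)))


def build_map(config: SimConfig) -> GeneticMap:
    """Markers at 1, 2, ..., chr_length cM; one QTL per qtl_spacing window,
    placed half a marker interval past the window midpoint marker so it falls
    strictly between two adjacent markers (5.5, 15.5, ... for the defaults)."""
    if config.chr_length % config.marker_spacing != 0:
        raise InvalidConfigError("marker spacing must divide chromosome length")
    if config.chr_length % config.qtl_spacing != 0:
        raise InvalidConfigError("QTL spacing must divide chromosome length")
    n_mark = int(round(config.chr_length / config.marker_spacing))
    n_qtl = int(round(config.chr_length / config.qtl_spacing))
    loci: list[Locus] = []
    for c in range(1, config.n_chromosomes + 1):
        marker_pos = config.marker_spacing * np.arange(1, n_mark + 1)
        qtl_pos = config.qtl_spacing * (np.arange(1, n_qtl + 1) - 0.5) + 0.5
        entries = [(p, False) for p in marker_pos] + [(p, True) for p in qtl_pos]
        entries.sort()
        mi = qi = 0
        for pos, is_qtl in entries:
            if is_qtl:
                qi += 1
                lid = f"chr{c:02d}_qtl{qi:02d}"
            else:
                mi += 1
                lid = f"chr{c:02d}_m{mi:03d}"
            loci.append(Locus(c, float(pos), lid, is_qtl))
    return GeneticMap(tuple(loci))


def simulate_gametes(
    gmap: GeneticMap, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Parental-origin matrix (n_gametes x n_loci, values 0/1) for gametes of
    a fully heterozygous F1 parent.

    Within a chromosome the origin switches between adjacent loci with the
    Haldane probability for their map distance; the starting origin of each
    chromosome is uniform, so chromosomes assort independently.
    """
    chrom = gmap.chromosomes
    pos = gmap.positions_cm
    out = np.empty((n_gametes, gmap.n_loci), dtype=np.int8)
    for c in np.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        d = np.diff(pos[cols])
        cfrac = haldane_recombination_fraction(d)
        first = rng.random(n_gametes) < 0.5
        switches = rng.random((n_gametes, d.size)) < cfrac
        states = np.logical_xor.accumulate(
            np.concatenate([first[:, None], switches], axis=1), axis=1
        )
        out[:, cols] = states.astype(np.int8)
    return out


def simulate_gamete(
    parent_haplotypes: tuple[np.ndarray, np.ndarray],
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from an arbitrary pair of parental haplotypes."""
    hap0, hap1 = (np.asarray(h) for h in parent_haplotypes)
    if hap0.shape[0] != gmap.n_loci or hap1.shape[0] != gmap.n_loci:
        raise InvalidInputError("parent haplotypes must cover every locus")
    origin = simulate_gametes(gmap, 1, rng)[0]
    return np.where(origin == 0, hap0, hap1)


def assign_qtl_effects(
    gmap: GeneticMap, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. standard-normal additive allele-substitution effects, one per QTL."""
    q = int(gmap.is_qtl.sum())
    if q < 1:
        raise InvalidInputError("map contains no QTL")
    return rng.standard_normal(q)


def genetic_values_from_qtl(qtl_genotypes: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """Additive genetic value g_i = sum_q a_q (z_iq - 1), centered F2 coding."""
    Z = np.asarray(qtl_genotypes, dtype=np.float64)
    return (Z - 1.0) @ np.asarray(effects, dtype=np.float64)


def build_phenotype(
    genetic_values: np.ndarray, heritability: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Add Gaussian noise with variance var(g) (1 - h2) / h2 computed from the
    realized genetic variance; returns (phenotypes, realized h2)."""
    g = np.asarray(genetic_values, dtype=np.float64)
    if not 0.0 < heritability <= 1.0:
        raise InvalidInputError("heritability must be in (0, 1]")
    if heritability == 1.0:
        return g.copy(), 1.0
    var_g = float(np.var(g, ddof=1))
    if var_g <= 0:
        raise InvalidInputError("zero genetic variance with heritability < 1")
    var_noise = var_g * (1.0 - heritability) / heritability
    y = g + rng.normal(0.0, np.sqrt(var_noise), size=g.shape[0])
    realized = var_g / float(np.var(y, ddof=1))
    return y, realized


def simulate_f2_population(config: SimConfig | None = None) -> SimulatedPopulation:
    """Simulate a complete F2 panel: marker and QTL genotypes, additive QTL
    effects, genetic values and noisy phenotypes at the target heritability."""
    if config is None:
        config = SimConfig()
    gmap = build_map(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    # two independent F1 gametes per F2 individual; with AA x aa parents the
    # allele dosage at a locus is the parental-origin indicator itself
    dose = simulate_gametes(gmap, n, rng) + simulate_gametes(gmap, n, rng)
    is_qtl = gmap.is_qtl
    marker_vals = dose[:, ~is_qtl].astype(np.int8)
    qtl_vals = dose[:, is_qtl].astype(np.int8)
    marker_ids = tuple(l.locus_id for l in gmap.loci if not l.is_qtl)
    individual_ids = tuple(f"ind{i + 1:05d}" for i in range(n))
    effects = assign_qtl_effects(gmap, config, rng)
    g = genetic_values_from_qtl(qtl_vals, effects)
    y, realized = build_phenotype(g, config.heritability, rng)
    return SimulatedPopulation(
        marker_genotypes=GenotypeMatrix(marker_vals, marker_ids, individual_ids),
        qtl_genotypes=qtl_vals,
        qtl_effects=effects,
        genetic_values=g,
        phenotypes=y,
        realized_h2=realized,
        genetic_map=gmap,
    )


def maf_filter(genotypes: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Drop markers whose minor allele frequency is strictly below the
    threshold (allele frequency = mean dosage / 2, folded at 0.5); survivors
    keep their order, so the filter is idempotent."""
    freq = genotypes.values.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= threshold
    if not keep.any():
        raise InvalidInputError(
            f"MAF filter at {threshold} removed every marker"
        )
    return GenotypeMatrix(
        genotypes.values[:, keep],
        tuple(mid for mid, k in zip(genotypes.marker_ids, keep) if k),
        genotypes.individual_ids,
    )
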