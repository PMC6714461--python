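"""Synthetic populations with the statistical structure the analysis assumes.

Generates parental SNP sets, recombinant fully-homozygous segregants via a
Haldane-map meiosis model, backcross programs with phenotypic selection,
additive QTL phenotypes, logistic CO2 curves, and noisy tiling-array
prediction tables - everything needed to exercise the downstream stages
without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    FermentationCurve,
    GenomePosition,
    GenotypeMatrix,
    Marker,
    MarkerPanel,
    PhenotypeTable,
    SnpRecord,
    make_marker_id,
)

#: S. cerevisiae-like chromosome lengths (bp), roman-numeral names
DEFAULT_CHROMOSOMES: dict[str, int] = {
    "I": 230_000, "II": 813_000, "III": 316_000, "IV": 1_532_000,
    "V": 577_000, "VI": 270_000, "VII": 1_091_000, "VIII": 562_000,
    "IX": 440_000, "X": 746_000, "XI": 667_000, "XII": 1_078_000,
    "XIII": 924_000, "XIV": 784_000, "XV": 1_091_000, "XVI": 948_000,
}

DEFAULT_CM_PER_KB = 0.35
_BASES = np.array(list("ACGT"))


@dataclass
class QtlSpec:
    """One simulated additive QTL: marker, effect size, beneficial allele."""

    marker_id: str
    effect: float
    beneficial_allele: str = "B"

    def __post_init__(self) -> None:
        if not math.isfinite(self.effect):
            raise ValueError("QTL effect must be finite")
        if self.beneficial_allele not in ("B", "G"):
            raise ValueError("beneficial allele must be B or G")


@dataclass
class SimulationConfig:
    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOMES)
    )
    n_markers_per_chromosome: int = 3
    n_backcrosses: int = 4
    n_segregants: int = 77
    n_spores_per_round: int = 30
    qtls: list[QtlSpec] = field(default_factory=list)
    trait_mean: float = 25.0
    residual_sd: float = 5.0
    n_replicates: int = 2
    cm_per_kb: float = DEFAULT_CM_PER_KB
    selection_fraction: float = 1.0 / 30.0
    # parental SNP-set parameters
    n_snps: int = 17_000
    common_fraction: float = 0.8
    trait: str = "RS"
    #: redraw the backcross program until every QTL locus is still
    #: heterozygous in the final hybrid (the mapped lineage retained its
    #: donor blocks; a hybrid that lost them would never enter a scan)
    require_qtl_segregation: bool = True

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be > 0")
        if not 0 < self.selection_fraction <= 1:
            raise ValueError("selection_fraction must be in (0, 1]")


@dataclass
class KineticModelParams:
    """Logistic CO2 release model: ``co2_max / (1 + exp(-k (t - t_mid)))``."""

    co2_max: float = 110.0
    t_mid: float = 70.0
    k: float = 0.05
    noise_sd: float = 0.0
    times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 200.0, 4.0))

    def __post_init__(self) -> None:
        if self.co2_max <= 0:
            raise ValueError("co2_max must be > 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")


# ---------------------------------------------------------------------------
# parental SNP sets
# ---------------------------------------------------------------------------

def simulate_parental_snp_sets(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[SnpRecord], list[SnpRecord], MarkerPanel]:
    """Two parental SNP sets sharing ``common_fraction`` of their positions.

    Returns (B records, G records, panel) where the panel holds the
    symmetric-difference positions (the putative inter-parental markers),
    with the variant parent's alt allele on its side and the reference allele
    on the other.
    """
    if config.n_snps <= 0:
        raise ValueError("n_snps must be > 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chroms = list(config.chromosomes)
    weights = np.array([config.chromosomes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    b_records: list[SnpRecord] = []
    g_records: list[SnpRecord] = []
    markers: list[Marker] = []
    counts = rng.multinomial(config.n_snps, weights)
    for chrom, count in zip(chroms, counts):
        length = config.chromosomes[chrom]
        positions = np.sort(
            rng.choice(np.arange(1, length + 1), size=min(count, length), replace=False)
        )
        for pos in positions:
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            record = lambda: SnpRecord(  # noqa: E731 - fresh record per strain
                position=GenomePosition(chrom, int(pos)),
                ref_allele=str(ref),
                alt_allele=str(alt),
                quality=float(rng.uniform(30, 60)),
                genotype_quality=float(rng.uniform(20, 99)),
                zygosity="hom",
            )
            u = rng.random()
            if u < config.common_fraction:
                b_records.append(record())
                g_records.append(record())
            else:
                in_b = rng.random() < 0.5
                (b_records if in_b else g_records).append(record())
                markers.append(
                    Marker(
                        id=make_marker_id(chrom, int(pos)),
                        position=GenomePosition(chrom, int(pos)),
                        allele_b=str(alt) if in_b else str(ref),
                        allele_g=str(ref) if in_b else str(alt),
                    )
                )
    # kb-convention ids may collide within a kb window: disambiguate
    seen: dict[str, int] = {}
    unique: list[Marker] = []
    for m in markers:
        if m.id in seen:
            seen[m.id] += 1
            m = Marker(f"{m.id}.{seen[m.id]}", m.position, m.allele_b, m.allele_g)
        else:
            seen[m.id] = 0
        unique.append(m)
    return b_records, g_records, MarkerPanel(unique).sorted()


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def haldane_recombination_fraction(distance_bp: float, cm_per_kb: float) -> float:
    """Haldane map: d(cM) = cm_per_kb * kb; r = (1 - exp(-2 d / 100)) / 2."""
    d_cm = cm_per_kb * distance_bp / 1000.0
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def _interval_recomb(panel: MarkerPanel, cm_per_kb: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval recombination fractions; 0.5 across chromosome breaks."""
    markers = list(panel)
    r = np.empty(max(len(markers) - 1, 0))
    for i in range(len(markers) - 1):
        a, b = markers[i].position, markers[i + 1].position
        if a.chrom != b.chrom:
            r[i] = 0.5
        else:
            r[i] = haldane_recombination_fraction(b.pos - a.pos, cm_per_kb)
    start = np.full(1, 0.5)
    return start, r


def simulate_meioses(
    parent1: np.ndarray,
    parent2: np.ndarray,
    panel: MarkerPanel,
    n: int,
    cm_per_kb: float = DEFAULT_CM_PER_KB,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw ``n`` recombinant haploid genomes from two parental haplotypes.

    Each product is duplicated into a fully homozygous diploid downstream, so
    the haploid call vector *is* the segregant genotype. Crossovers follow a
    Markov walk with Haldane recombination fractions per marker interval
    (independent across chromosome breaks). Returns an (n, m) array of calls.
    """
    parent1 = np.asarray(parent1, dtype=object)
    parent2 = np.asarray(parent2, dtype=object)
    m = len(panel)
    if parent1.shape != (m,) or parent2.shape != (m,):
        raise ValueError("parent haplotypes must match the marker panel")
    rng = np.random.default_rng() if rng is None else rng
    _, r = _interval_recomb(panel, cm_per_kb)
    # state[i, j] in {0, 1}: which parental haplotype marker j comes from
    switches = np.empty((n, m), dtype=np.int8)
    switches[:, 0] = rng.random(n) < 0.5
    if m > 1:
        switches[:, 1:] = rng.random((n, m - 1)) < r
    state = np.cumsum(switches, axis=1) % 2
    out = np.where(state == 0, parent1[None, :], parent2[None, :])
    return out


def simulate_meiosis(
    parent1: np.ndarray,
    parent2: np.ndarray,
    panel: MarkerPanel,
    cm_per_kb: float = DEFAULT_CM_PER_KB,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """One meiotic product (see :func:`simulate_meioses`)."""
    return simulate_meioses(parent1, parent2, panel, 1, cm_per_kb, rng)[0]


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _genetic_values(
    frame_calls: np.ndarray,
    marker_ids: list[str],
    qtls: Sequence[QtlSpec],
    trait_mean: float,
    interactions: Optional[Sequence[tuple[str, str, float]]] = None,
) -> np.ndarray:
    g = np.full(frame_calls.shape[0], float(trait_mean))
    index = {mid: j for j, mid in enumerate(marker_ids)}
    for q in qtls:
        if q.marker_id not in index:
            raise KeyError(f"unknown QTL marker {q.marker_id!r}")
        carrier = frame_calls[:, index[q.marker_id]] == q.beneficial_allele
        g = g + q.effect * carrier
    for (ma, mb, eff) in interactions or ():
        both = (frame_calls[:, index[ma]] == "B") & (frame_calls[:, index[mb]] == "B")
        g = g + eff * both
    return g


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    qtls: Sequence[QtlSpec],
    trait_mean: float,
    residual_sd: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    n_replicates: int = 2,
    trait: str = "RS",
    interactions: Optional[Sequence[tuple[str, str, float]]] = None,
    inflate_class: Optional[tuple[str, str, float]] = None,
) -> PhenotypeTable:
    """Additive QTL phenotype model with Gaussian residuals.

    ``y = mu + sum_l a_l 1[g_l = beneficial] (+ interactions) + eps``;
    replicates share the genetic value and differ only in ``eps``.
    ``inflate_class = (marker, allele, factor)`` multiplies the residual sd
    for carriers of one genotype class (heteroscedasticity switch).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    calls = genotypes.frame.to_numpy(object)
    g = _genetic_values(calls, genotypes.marker_ids, qtls, trait_mean, interactions)
    sd = np.full(len(g), float(residual_sd))
    if inflate_class is not None:
        marker, allele, factor = inflate_class
        j = genotypes.marker_ids.index(marker)
        sd = np.where(calls[:, j] == allele, sd * factor, sd)
    rows = []
    for rep in range(1, n_replicates + 1):
        eps = rng.normal(0.0, 1.0, size=len(g)) * sd
        values = g + eps
        if trait == "RS":
            values = np.clip(values, 0.0, None)
        for seg, v in zip(genotypes.segregants, values):
            rows.append({"segregant": seg, "trait": trait, "replicate": rep, "value": v})
    return PhenotypeTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# backcross program
# ---------------------------------------------------------------------------

@dataclass
class BackcrossLog:
    rounds: list[dict] = field(default_factory=list)


def donor_fraction(haplotypes: tuple[np.ndarray, np.ndarray]) -> float:
    """Fraction of the diploid hybrid genome carrying the donor (B) allele."""
    a, b = haplotypes
    return float(((a == "B").mean() + (b == "B").mean()) / 2.0)


def simulate_backcross_program(
    config: SimulationConfig,
    panel: MarkerPanel,
    rng: Optional[np.random.Generator] = None,
    select: bool = True,
) -> tuple[tuple[np.ndarray, np.ndarray], BackcrossLog]:
    """Recurrent backcrossing of selected segregants to the recipient strain.

    Starts from the F1 (donor haplotype x recipient haplotype). Each round
    sporulates the current hybrid, phenotypes the spores under the configured
    QTL model (trait: lower is better, mimicking residual-sugar selection),
    keeps the best spore (or a random one when ``select`` is False), and
    crosses it back to the recipient. Returns the final hybrid's haplotype
    pair plus a per-round log of retained donor blocks.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = len(panel)
    donor = np.full(m, "B", dtype=object)
    recipient = np.full(m, "G", dtype=object)
    hybrid = (donor.copy(), recipient.copy())
    log_ = BackcrossLog()
    for rnd in range(config.n_backcrosses):
        n_spores = max(2, config.n_spores_per_round)
        spores = simulate_meioses(hybrid[0], hybrid[1], panel, n_spores,
                                  config.cm_per_kb, rng)
        if select and config.qtls:
            g = _genetic_values(spores, panel.ids, config.qtls, config.trait_mean)
            noise = rng.normal(0.0, config.residual_sd, size=n_spores)
            best = int(np.argmin(g + noise))  # smallest residual-sugar analogue
        elif select:
            # no QTLs defined: selection has nothing to act on
            best = int(rng.integers(n_spores))
        else:
            best = int(rng.integers(n_spores))
        chosen = spores[best]
        hybrid = (chosen.copy(), recipient.copy())
        blocks = _donor_blocks(chosen, panel)
        log_.rounds.append(
            {
                "round": rnd + 1,
                "donor_fraction": donor_fraction(hybrid),
                "retained_blocks": blocks,
            }
        )
    return hybrid, log_


def _donor_blocks(haplotype: np.ndarray, panel: MarkerPanel) -> list[tuple[str, int, int]]:
    blocks: list[tuple[str, int, int]] = []
    open_block: Optional[list] = None
    for call, marker in zip(haplotype, panel):
        if call == "B":
            if open_block is not None and open_block[0] == marker.position.chrom:
                open_block[2] = marker.position.pos
            else:
                if open_block is not None:
                    blocks.append(tuple(open_block))
                open_block = [marker.position.chrom, marker.position.pos, marker.position.pos]
        else:
            if open_block is not None:
                blocks.append(tuple(open_block))
                open_block = None
    if open_block is not None:
        blocks.append(tuple(open_block))
    return blocks


def simulate_segregant_matrix(
    hybrid: tuple[np.ndarray, np.ndarray],
    panel: MarkerPanel,
    n_segregants: int,
    cm_per_kb: float = DEFAULT_CM_PER_KB,
    rng: Optional[np.random.Generator] = None,
    id_prefix: str = "seg",
) -> GenotypeMatrix:
    """Fully homozygous diploid segregants of a hybrid, as a genotype matrix."""
    calls = simulate_meioses(hybrid[0], hybrid[1], panel, n_segregants, cm_per_kb, rng)
    frame = pd.DataFrame(
        calls,
        index=[f"{id_prefix}{i + 1:03d}" for i in range(n_segregants)],
        columns=panel.ids,
    )
    return GenotypeMatrix(frame)


def default_marker_panel(config: SimulationConfig) -> MarkerPanel:
    """Evenly spaced markers on every chromosome (deterministic layout)."""
    markers = []
    for chrom, length in config.chromosomes.items():
        k = config.n_markers_per_chromosome
        for i in range(k):
            pos = int((i + 1) * length / (k + 1))
            markers.append(
                Marker(
                    id=make_marker_id(chrom, pos),
                    position=GenomePosition(chrom, pos),
                    allele_b="A",
                    allele_g="C",
                )
            )
    return MarkerPanel(markers).sorted()


def simulate_population(
    config: SimulationConfig,
    panel: Optional[MarkerPanel] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[MarkerPanel, GenotypeMatrix, PhenotypeTable]:
    """End-to-end H4-style population: backcross, sporulate, phenotype.

    When ``config.require_qtl_segregation`` is set, backcross programs whose
    final hybrid lost a donor allele at a QTL locus are redrawn (bounded
    rejection sampling) so the causal loci actually segregate in the progeny.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    panel = default_marker_panel(config) if panel is None else panel
    qtl_idx = [panel.ids.index(q.marker_id) for q in config.qtls]
    for _ in range(200):
        hybrid, _ = simulate_backcross_program(config, panel, rng=rng)
        if not (config.require_qtl_segregation and qtl_idx):
            break
        if all(hybrid[0][j] != hybrid[1][j] for j in qtl_idx):
            break
    else:
        raise RuntimeError("backcross program never retained all QTL loci")
    matrix = simulate_segregant_matrix(
        hybrid, panel, config.n_segregants, config.cm_per_kb, rng
    )
    pheno = simulate_phenotypes(
        matrix,
        config.qtls,
        config.trait_mean,
        config.residual_sd,
        rng=rng,
        n_replicates=config.n_replicates,
        trait=config.trait,
    )
    return panel, matrix, pheno


# ---------------------------------------------------------------------------
# CO2 curves
# ---------------------------------------------------------------------------

def simulate_co2_curve(
    params: KineticModelParams,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    meta: Optional[dict] = None,
) -> FermentationCurve:
    """Logistic CO2 release sampled at ``params.times`` plus raw Gaussian noise.

    Noise is deliberately left unclipped and unrectified - the smoother is
    responsible for cleaning it up.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    t = params.times
    co2 = params.co2_max / (1.0 + np.exp(-params.k * (t - params.t_mid)))
    if params.noise_sd > 0:
        co2 = co2 + rng.normal(0.0, params.noise_sd, size=len(t))
    return FermentationCurve(times=t.copy(), co2=co2, meta=dict(meta or {}))


def logistic_crossing_time(params: KineticModelParams, fraction_of_max: float) -> float:
    """Closed-form time at which the noiseless logistic reaches
    ``fraction_of_max * co2_max``: ``t_mid + ln(x / (1 - x)) / k``."""
    x = fraction_of_max
    if not 0 < x < 1:
        raise ValueError("fraction must be in (0, 1)")
    return params.t_mid + math.log(x / (1.0 - x)) / params.k


# ---------------------------------------------------------------------------
# tiling-array prediction tables
# ---------------------------------------------------------------------------

def simulate_tiling_predictions(
    true_positions: Sequence[GenomePosition],
    chromosome_lengths: dict[str, int],
    jitter_sd: float = 0.0,
    false_positive_rate: float = 0.0,
    sensitivity: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Noisy array-style SNP predictions: (chrom, pos, z) rows.

    Each true position is emitted with probability ``sensitivity`` and
    rounded Gaussian positional jitter; spurious uniform positions are added
    so the expected fraction of unconfirmable predictions equals
    ``false_positive_rate``.
    """
    if not 0 <= false_positive_rate < 1 or not 0 <= sensitivity <= 1:
        raise ValueError("rates must be in [0, 1] (fp rate < 1)")
    rng = np.random.default_rng(seed) if rng is None else rng
    rows = []
    for pos in true_positions:
        if rng.random() >= sensitivity:
            continue
        jitter = int(round(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
        p = int(np.clip(pos.pos + jitter, 1, chromosome_lengths[pos.chrom]))
        rows.append({"chrom": pos.chrom, "pos": p, "z": float(3.0 + abs(rng.normal()))})
    n_true = len(rows)
    n_false = int(round(n_true * false_positive_rate / (1.0 - false_positive_rate)))
    chroms = list(chromosome_lengths)
    weights = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(n_false):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        rows.append(
            {
                "chrom": chrom,
                "pos": int(rng.integers(1, chromosome_lengths[chrom] + 1)),
                "z": float(3.0 + abs(rng.normal())),
            }
        )
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "z"])
    return frame.sort_values(["chrom", "pos"], ignore_index=True)
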