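"""Synthetic genotype datasets with controlled population structure.

Population allele frequencies follow the Balding-Nichols model: for a
locus with ancestral frequency p0 and drift parameter F, each population
draws its frequency from Beta(p0*(1-F)/F, (1-p0)*(1-F)/F). Genotypes are
sampled under Hardy-Weinberg equilibrium, admixed cohorts mix source
frequencies through Dirichlet ancestry fractions, and allele-depth tables
emulate NGS coverage with a log-normal depth model and binomial
heterozygote splits.

One global seed drives everything; each generator uses a deterministic
substream derived from it so components can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from aisnp.coverage_qc import AlleleDepthTable
from aisnp.genotype_io import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeMatrix,
    Locus,
    PopulationManifest,
)


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    super_label: str
    n_individuals: int
    drift: float  # Balding-Nichols F, in (0, 1)

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"{self.label}: n_individuals must be >= 1")
        if not 0 < self.drift < 1:
            raise ValueError(f"{self.label}: drift must be in (0, 1)")


@dataclass(frozen=True)
class AdmixedCohortSpec:
    label: str
    n_individuals: int
    alpha: tuple[float, ...]  # Dirichlet parameters over source populations

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"{self.label}: n_individuals must be >= 1")
        if any(a <= 0 for a in self.alpha):
            raise ValueError(f"{self.label}: Dirichlet alpha must be positive")


@dataclass
class SimulationConfig:
    """Everything needed to generate a full synthetic study dataset."""

    n_loci: int
    populations: list[PopulationSpec]
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    admixed_cohorts: list[AdmixedCohortSpec] = field(default_factory=list)
    depth_mean_range: tuple[float, float] = (500.0, 5000.0)
    depth_sigma: float = 0.5  # log-normal shape of per-call depth
    het_balance: float = 0.9  # expected minor/major ratio target b/(2-b)... see ACR
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral_freq_range must satisfy 0 < lo <= hi < 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for cohort in self.admixed_cohorts:
            if len(cohort.alpha) != len(self.populations):
                raise ValueError(
                    f"cohort {cohort.label}: alpha length must equal number "
                    f"of source populations"
                )

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic substream derived from the global seed."""
        import hashlib

        key = int.from_bytes(
            hashlib.sha256(stream.encode()).digest()[:4], "little"
        )
        seq = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(seq)


def _make_loci(n_loci: int) -> list[Locus]:
    return [Locus(f"sim{j + 1}", "1", 1000 * (j + 1), "A", "G") for j in range(n_loci)]


def simulate_frequencies(cfg: SimulationConfig) -> AlleleFrequencyTable:
    """True per-population alt frequencies under Balding-Nichols drift.

    n_chrom is set to 0 since these are parameters rather than estimates.
    """
    rng = cfg.rng("frequencies")
    lo, hi = cfg.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=cfg.n_loci)
    groups = [p.label for p in cfg.populations]
    freq = np.empty((len(groups), cfg.n_loci))
    for gi, pop in enumerate(cfg.populations):
        factor = (1.0 - pop.drift) / pop.drift
        freq[gi] = rng.beta(p0 * factor, (1.0 - p0) * factor)
    loci = _make_loci(cfg.n_loci)
    n_chrom = np.zeros_like(freq, dtype=np.int64)
    return AlleleFrequencyTable(groups, loci, freq, n_chrom)


def simulate_genotypes(
    freqs: AlleleFrequencyTable, cfg: SimulationConfig
) -> tuple[GenotypeMatrix, PopulationManifest]:
    """HWE genotypes for every configured population at the true frequencies."""
    rng = cfg.rng("genotypes")
    samples: list[str] = []
    s2p: dict[str, str] = {}
    p2s: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for pop in cfg.populations:
        gi = freqs.group_index(pop.label)
        p = freqs.alt_freq[gi]
        block = rng.binomial(2, p, size=(pop.n_individuals, len(p)))
        blocks.append(block)
        for i in range(pop.n_individuals):
            name = f"{pop.label}_{i + 1:04d}"
            samples.append(name)
            s2p[name] = pop.label
        p2s[pop.label] = pop.super_label
    codes = np.concatenate(blocks, axis=0).astype(np.int16)
    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = MISSING
    gm = GenotypeMatrix(samples, list(freqs.loci), codes)
    return gm, PopulationManifest(s2p, p2s)


def simulate_admixed_cohort(
    freqs: AlleleFrequencyTable,
    alpha: "tuple[float, ...] | np.ndarray",
    n: int,
    cfg: SimulationConfig,
    label: str = "ADMIX",
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Dirichlet-admixed genotypes plus the true Q matrix (n x K sources).

    Each individual's ancestry fractions q ~ Dirichlet(alpha); each
    genotype ~ Binomial(2, sum_k q_k f_kl).
    """
    rng = cfg.rng(f"admixed:{label}")
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (len(freqs.groups),):
        raise ValueError("alpha length must equal number of source groups")
    q = rng.dirichlet(alpha, size=n)
    p = q @ freqs.alt_freq  # (n, L) mixed frequencies
    codes = rng.binomial(2, np.clip(p, 0.0, 1.0)).astype(np.int16)
    samples = [f"{label}_{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(samples, list(freqs.loci), codes), q


def simulate_allele_depths(gm: GenotypeMatrix, cfg: SimulationConfig) -> AlleleDepthTable:
    """Allele-depth table for every (sample, locus) call in ``gm``.

    Total depth per call is log-normal around a per-locus mean drawn from
    ``depth_mean_range``; heterozygote alt depth ~ Binomial(depth, 0.5 *
    het_balance adjusted); homozygote calls put all reads on their allele.
    Missing genotypes get no record.
    """
    rng = cfg.rng("depths")
    lo, hi = cfg.depth_mean_range
    locus_mean = rng.uniform(lo, hi, size=gm.n_loci)
    # alt-read probability for hets such that E[min/max] trends to het_balance
    b = cfg.het_balance / (1.0 + cfg.het_balance)
    samples_out: list[str] = []
    rsids_out: list[str] = []
    ref_d: list[int] = []
    alt_d: list[int] = []
    mu = np.log(locus_mean) - 0.5 * cfg.depth_sigma**2
    for j, loc in enumerate(gm.loci):
        depth = rng.lognormal(mu[j], cfg.depth_sigma, size=gm.n_samples)
        depth = np.maximum(depth.round().astype(np.int64), 1)
        for i, sample in enumerate(gm.samples):
            g = int(gm.codes[i, j])
            if g == MISSING:
                continue
            d = int(depth[i])
            if g == 0:
                r, a = d, 0
            elif g == 2:
                r, a = 0, d
            else:
                a = int(rng.binomial(d, b))
                r = d - a
            samples_out.append(sample)
            rsids_out.append(loc.rsid)
            ref_d.append(r)
            alt_d.append(a)
    return AlleleDepthTable(
        samples=samples_out,
        rsids=rsids_out,
        ref_depth=np.array(ref_d, dtype=np.int64),
        alt_depth=np.array(alt_d, dtype=np.int64),
    )


def default_study_config(
    seed: int = 0,
    n_loci: int = 30,
    n_per_population: int = 100,
    drift: "tuple[float, ...] | None" = None,
) -> SimulationConfig:
    """A five-super-population setup echoing a continental reference panel.

    Four well-differentiated sources plus one Dirichlet-admixed cohort
    standing in for an admixed-continent sample set.
    """
    # tuned so overall per-locus Gst of the 5 groups spans roughly 0.0-0.9
    # with mean near 0.3, the regime of a strongly ascertained AISNP panel
    drift = drift or (0.7, 0.6, 0.65, 0.55)
    labels = [("AFRs", "AFR"), ("EASs", "EAS"), ("EURs", "EUR"), ("SASs", "SAS")]
    pops = [
        PopulationSpec(lab, sup, n_per_population, f)
        for (lab, sup), f in zip(labels, drift)
    ]
    cohorts = [
        AdmixedCohortSpec("AMRs", n_per_population, (0.2, 0.2, 1.2, 0.4))
    ]
    return SimulationConfig(
        n_loci=n_loci,
        populations=pops,
        admixed_cohorts=cohorts,
        seed=seed,
    )
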