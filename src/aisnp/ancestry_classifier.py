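"""Naive-Bayes ancestry assignment with HWE genotype likelihoods.

Training frequencies are Laplace-smoothed, f = (x + 1)/(2n + 2), so every
genotype likelihood is finite; priors are uniform unless overridden.
Leave-one-out cross-validation refits only the held-out individual's own
group (removing a non-member cannot change another group's frequencies)
and is fully deterministic: iteration order is input order and exact ties
resolve to the first group in the model's fixed group order, flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from aisnp.genotype_io import (
    MISSING,
    GenotypeMatrix,
    GroupLevel,
    PopulationManifest,
)


@dataclass
class TrainingModel:
    """Smoothed per-group allele frequencies plus priors."""

    groups: list[str]
    rsids: list[str]
    freqs: np.ndarray  # (K, L) smoothed alt frequencies, strictly inside (0,1)
    priors: np.ndarray  # (K,), sums to 1
    smoothing: str = "laplace_add_one"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if self.freqs.shape != (len(self.groups), len(self.rsids)):
            raise ValueError("frequency matrix dimensions inconsistent")
        if np.any(self.freqs <= 0) or np.any(self.freqs >= 1):
            raise ValueError("smoothed frequencies must be strictly inside (0,1)")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")


@dataclass
class ClassificationResult:
    sample: str
    log_likelihoods: np.ndarray  # per group, prior excluded
    posteriors: np.ndarray  # per group, sums to 1
    assigned: str
    n_loci_used: int
    tie: bool


@dataclass
class ConfusionMatrix:
    """Row-stochastic LOOCV assignment proportions, rows = true group."""

    groups: list[str]
    proportions: np.ndarray  # (K, K)
    row_counts: np.ndarray  # (K,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=self.groups, columns=self.groups
        )

    def diagonal(self) -> dict[str, float]:
        return {
            g: float(self.proportions[i, i]) for i, g in enumerate(self.groups)
        }


def smoothed_frequency(alt_count: "int | np.ndarray", n_chrom: "int | np.ndarray") -> "float | np.ndarray":
    """Laplace add-one on allele counts: (x + 1) / (2n + 2).

    With zero chromosomes this is the uninformative 1/2.
    """
    return (np.asarray(alt_count, dtype=float) + 1.0) / (
        np.asarray(n_chrom, dtype=float) + 2.0
    )


def _group_counts(
    gm: GenotypeMatrix, labels: np.ndarray, groups: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per (group, locus) alt-allele counts and chromosome counts."""
    alt = np.zeros((len(groups), gm.n_loci))
    chrom = np.zeros((len(groups), gm.n_loci))
    observed = gm.codes != MISSING
    for gi, g in enumerate(groups):
        rows = labels == g
        alt[gi] = np.where(observed[rows], gm.codes[rows], 0).sum(axis=0)
        chrom[gi] = 2 * observed[rows].sum(axis=0)
    return alt, chrom


def fit(
    gm: GenotypeMatrix,
    manifest: PopulationManifest,
    level: GroupLevel = "super",
    priors: "np.ndarray | None" = None,
) -> TrainingModel:
    """Fit smoothed training frequencies at the requested grouping level."""
    manifest.validate_against(gm)
    labels = np.array([manifest.group_of(s, level) for s in gm.samples])
    groups = sorted(set(labels))
    alt, chrom = _group_counts(gm, labels, groups)
    freqs = smoothed_frequency(alt, chrom)
    if priors is None:
        priors = np.full(len(groups), 1.0 / len(groups))
    return TrainingModel(groups, gm.rsids, freqs, priors)


def log_likelihood(
    genotypes: np.ndarray, model: TrainingModel, group: str
) -> float:
    """HWE genotype log-likelihood of a dosage vector under one group.

    ln P(g|p) summed over non-missing loci: p^2 for g=2, 2p(1-p) for g=1,
    (1-p)^2 for g=0; missing loci contribute 0.
    """
    gi = model.groups.index(group)
    return float(_loglik_rows(np.asarray(genotypes)[None, :], model.freqs)[0, gi])


def _loglik_rows(codes: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Log-likelihood of each row of ``codes`` under each frequency row.

    codes: (N, L) dosages with MISSING; freqs: (K, L). Returns (N, K).
    """
    log_p = np.log(freqs)  # (K, L)
    log_q = np.log1p(-freqs)
    obs = codes != MISSING
    # ln P = g ln p + (2-g) ln(1-p) + [g==1] ln 2, per non-missing locus
    w_alt = np.where(obs, codes, 0).astype(float)
    w_ref = np.where(obs, 2 - codes, 0).astype(float)
    n_het = ((codes == 1) & obs).sum(axis=1).astype(float)
    return w_alt @ log_p.T + w_ref @ log_q.T + n_het[:, None] * np.log(2.0)


def classify(
    genotypes: np.ndarray, model: TrainingModel, sample: str = "?"
) -> ClassificationResult:
    """Posterior ancestry assignment for one dosage vector."""
    codes = np.asarray(genotypes)
    ll = _loglik_rows(codes[None, :], model.freqs)[0]
    log_post = ll + np.log(model.priors)
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)
    post /= post.sum()
    best = int(np.argmax(post))
    tie = bool(np.sum(np.isclose(post, post[best], rtol=0, atol=1e-12)) > 1)
    if tie:  # ties resolve to the first group in fixed order
        best = int(np.flatnonzero(np.isclose(post, post[best], rtol=0, atol=1e-12))[0])
    return ClassificationResult(
        sample=sample,
        log_likelihoods=ll,
        posteriors=post,
        assigned=model.groups[best],
        n_loci_used=int(np.sum(codes != MISSING)),
        tie=tie,
    )


def loocv(
    gm: GenotypeMatrix,
    manifest: PopulationManifest,
    level: GroupLevel = "super",
    priors: "np.ndarray | None" = None,
) -> tuple[ConfusionMatrix, list[ClassificationResult]]:
    """Leave-one-out cross-validation over every individual.

    For each individual, its own group's smoothed frequencies are refitted
    without it; the other groups are untouched. Returns the confusion
    matrix and the per-individual verbose results.
    """
    manifest.validate_against(gm)
    labels = np.array([manifest.group_of(s, level) for s in gm.samples])
    groups = sorted(set(labels))
    sizes = {g: int(np.sum(labels == g)) for g in groups}
    singletons = [g for g, c in sizes.items() if c < 2]
    if singletons:
        raise ValueError(f"groups with fewer than 2 samples: {singletons}")

    alt, chrom = _group_counts(gm, labels, groups)
    if priors is None:
        priors = np.full(len(groups), 1.0 / len(groups))
    base_freqs = smoothed_frequency(alt, chrom)
    group_index = {g: i for i, g in enumerate(groups)}

    counts = np.zeros((len(groups), len(groups)), dtype=np.int64)
    results: list[ClassificationResult] = []
    for i, sample in enumerate(gm.samples):
        gi = group_index[labels[i]]
        codes = gm.codes[i]
        obs = codes != MISSING
        # remove this individual's contribution from its own group only
        alt_held = alt[gi] - np.where(obs, codes, 0)
        chrom_held = chrom[gi] - 2 * obs
        freqs = base_freqs.copy()
        freqs[gi] = smoothed_frequency(alt_held, chrom_held)
        model = TrainingModel(groups, gm.rsids, freqs, np.asarray(priors))
        res = classify(codes, model, sample=sample)
        results.append(res)
        counts[gi, group_index[res.assigned]] += 1

    row_counts = counts.sum(axis=1)
    proportions = counts / row_counts[:, None]
    return ConfusionMatrix(groups, proportions, row_counts), results


def classify_cohort(
    cohort: GenotypeMatrix, model: TrainingModel
) -> tuple[list[ClassificationResult], pd.DataFrame]:
    """Assign every cohort individual; return results + proportion summary."""
    model_idx = {r: j for j, r in enumerate(model.rsids)}
    shared = [r for r in cohort.rsids if r in model_idx]
    if cohort.n_samples > 0 and not shared:
        raise ValueError("cohort shares no loci with the model")
    cohort_cols = [cohort.rsids.index(r) for r in shared]
    model_cols = [model_idx[r] for r in shared]
    sub_model = TrainingModel(
        model.groups,
        shared,
        model.freqs[:, model_cols],
        model.priors,
        model.smoothing,
    )
    results = [
        classify(cohort.codes[i, cohort_cols], sub_model, sample=s)
        for i, s in enumerate(cohort.samples)
    ]
    tallies = {g: 0 for g in model.groups}
    for r in results:
        tallies[r.assigned] += 1
    n = max(len(results), 1)
    summary = pd.DataFrame(
        {
            "group": list(tallies),
            "n_assigned": list(tallies.values()),
            "proportion": [c / n if results else 0.0 for c in tallies.values()],
        }
    )
    if not results:
        summary = summary.iloc[0:0]
    return results, summary


def verbose_report(results: list[ClassificationResult], groups: list[str]) -> pd.DataFrame:
    """Per-individual table of log-likelihoods, posteriors and assignment."""
    rows = []
    for r in results:
        row: dict[str, object] = {"sample": r.sample, "assigned": r.assigned,
                                  "n_loci_used": r.n_loci_used, "tie": r.tie}
        for g, ll, post in zip(groups, r.log_likelihoods, r.posteriors):
            row[f"loglik_{g}"] = ll
            row[f"posterior_{g}"] = post
        rows.append(row)
    return pd.DataFrame(rows)
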