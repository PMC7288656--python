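"""Per-locus ancestry informativeness: delta, Fst (Nei Gst) and Rosenberg In.

The Fst estimator is Nei's Gst computed on unweighted group frequency
means: Ht = 2*pbar*(1-pbar), Hs = mean of 2p(1-p), Gst = (Ht - Hs)/Ht,
with a monomorphic locus (Ht = 0) defined as 0. A Weir-Cockerham theta
estimator is available behind ``fst_weir_cockerham`` for comparison; its
negative estimates are clamped to 0 with the raw value retained.

In is the informativeness-for-assignment statistic with natural
logarithms and the convention 0*ln(0) = 0, using the unweighted mean
frequency across groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from aisnp.genotype_io import (
    AlleleFrequencyTable,
    GenotypeMatrix,
    PopulationManifest,
    allele_frequencies,
    pool_groups,
)

DELTA_LARGE_CUTOFF = 0.40
DELTA_MODERATE_CUTOFF = 0.20
LOW_DIVERGENCE_CUTOFF = 0.10


def delta_one_vs_rest(
    aft: AlleleFrequencyTable, target: str, weighted: bool = True
) -> np.ndarray:
    """Per-locus |p_target - p_rest| with the rest pooled across groups."""
    p_t, p_r = pool_groups(aft, target, weighted=weighted)
    return np.abs(p_t - p_r)


def fst_nei(freqs: "np.ndarray | list[float]") -> float:
    """Nei's Gst for one biallelic locus from group alt frequencies."""
    p = np.asarray(freqs, dtype=float)
    if p.size < 2:
        raise ValueError("Gst requires >= 2 groups")
    if np.isnan(p).any():
        return float("nan")
    pbar = p.mean()
    ht = 2.0 * pbar * (1.0 - pbar)
    if ht == 0.0:
        return 0.0
    # Ht - Hs = 2*Var(p); the variance form avoids cancellation near
    # monomorphism and is exactly symmetric under allele relabelling
    return float(min(2.0 * np.var(p) / ht, 1.0))


def fst_weir_cockerham(
    n: "np.ndarray | list[float]",
    p: "np.ndarray | list[float]",
    h: "np.ndarray | list[float]",
) -> tuple[float, float]:
    """Weir-Cockerham theta for one biallelic locus.

    Arguments are per-group sample sizes (individuals), alt frequencies
    and observed heterozygote fractions. Returns (clamped, raw); raw can
    be negative, the clamped value is max(raw, 0).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.size
    if r < 2:
        raise ValueError("theta requires >= 2 groups")
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    raw = float(a / denom) if denom != 0 else 0.0
    return max(raw, 0.0), raw


def informativeness(freqs: "np.ndarray | list[float]") -> float:
    """Informativeness-for-assignment for one biallelic locus over K groups.

    In = sum over alleles j of [-pbar_j ln pbar_j + (1/K) sum_i p_ij ln p_ij]
    with 0*ln(0) := 0 and pbar the unweighted group mean.
    """
    p = np.asarray(freqs, dtype=float)
    if p.size < 2:
        raise ValueError("In requires >= 2 groups")
    if np.isnan(p).any():
        return float("nan")
    if np.all(p == p[0]):  # exactly-equal frequencies carry no information
        return 0.0

    def xlogx(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        nz = x > 0
        out[nz] = x[nz] * np.log(x[nz])
        return out

    total = 0.0
    for allele_freqs in (p, 1.0 - p):
        pbar = allele_freqs.mean()
        total += -float(xlogx(np.array([pbar]))[0]) + float(
            xlogx(allele_freqs).mean()
        )
    # numerical noise can leave a tiny negative residue at In = 0
    return max(total, 0.0)


@dataclass
class DivergenceTable:
    """All per-locus divergence metrics plus the threshold-count summary."""

    per_locus: pd.DataFrame  # rsid, delta_<G>..., fst_overall, in_overall
    pairwise_fst: pd.DataFrame  # rsid, fst_<A>|<B>...
    pairwise_in: pd.DataFrame
    counts: pd.DataFrame  # per target group: delta>0.40, delta>0.20, low fst/in


def divergence_report(
    aft: AlleleFrequencyTable,
    delta_large: float = DELTA_LARGE_CUTOFF,
    delta_moderate: float = DELTA_MODERATE_CUTOFF,
    low_divergence: float = LOW_DIVERGENCE_CUTOFF,
    weighted_pooling: bool = True,
) -> DivergenceTable:
    """Assemble delta / Fst / In across a super-population frequency table."""
    groups = aft.groups
    rsids = aft.rsids
    n_loci = len(rsids)

    per_locus = pd.DataFrame({"rsid": rsids})
    for g in groups:
        per_locus[f"delta_{g}"] = delta_one_vs_rest(
            aft, g, weighted=weighted_pooling
        )
    per_locus["fst_overall"] = [
        fst_nei(aft.alt_freq[:, j]) for j in range(n_loci)
    ]
    per_locus["in_overall"] = [
        informativeness(aft.alt_freq[:, j]) for j in range(n_loci)
    ]

    pairs = list(itertools.combinations(range(len(groups)), 2))
    pw_fst = pd.DataFrame({"rsid": rsids})
    pw_in = pd.DataFrame({"rsid": rsids})
    for i, k in pairs:
        col = f"{groups[i]}|{groups[k]}"
        sub = aft.alt_freq[[i, k]]
        pw_fst[col] = [fst_nei(sub[:, j]) for j in range(n_loci)]
        pw_in[col] = [informativeness(sub[:, j]) for j in range(n_loci)]

    count_rows = []
    for g in groups:
        # one-vs-rest In/Fst: target group against the pooled rest
        rest_cols = [f"{g}|{h}" if f"{g}|{h}" in pw_fst else f"{h}|{g}"
                     for h in groups if h != g]
        d = per_locus[f"delta_{g}"].to_numpy()
        p_t, p_r = pool_groups(aft, g, weighted=weighted_pooling)
        ovr_fst = np.array([fst_nei([a, b]) for a, b in zip(p_t, p_r)])
        ovr_in = np.array([informativeness([a, b]) for a, b in zip(p_t, p_r)])
        count_rows.append(
            {
                "target": g,
                f"n_delta_gt_{delta_large}": int(np.nansum(d > delta_large)),
                f"n_delta_gt_{delta_moderate}": int(np.nansum(d > delta_moderate)),
                f"n_fst_lt_{low_divergence}": int(np.nansum(ovr_fst < low_divergence)),
                f"n_in_lt_{low_divergence}": int(np.nansum(ovr_in < low_divergence)),
            }
        )
    counts = pd.DataFrame(count_rows)
    return DivergenceTable(per_locus, pw_fst, pw_in, counts)


def divergence_from_genotypes(
    gm: GenotypeMatrix, manifest: PopulationManifest, **kwargs
) -> DivergenceTable:
    """Convenience wrapper: super-population frequencies then the report."""
    aft = allele_frequencies(gm, manifest, level="super")
    return divergence_report(aft, **kwargs)
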