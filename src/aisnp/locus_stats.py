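"""Per-locus population-genetic and forensic statistics for a study group.

Conventions follow the desktop tools these statistics are usually quoted
from: expected heterozygosity is 2p(1-p) without the 2n/(2n-1) small-
sample correction (an ``unbiased`` flag switches it on); the matching
probability uses observed genotype frequencies; the power of exclusion is
the observed-heterozygosity formula h^2 * (1 - 2*h*H^2) with H = 1 - h.
The HWE p-value for a monomorphic locus is undefined (NaN), not 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from aisnp.genotype_io import MISSING, GenotypeMatrix


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test for a biallelic locus.

    Enumerates every heterozygote count compatible with the observed
    allele counts; the p-value is the sum of conditional probabilities of
    configurations no more probable than the observed one. Returns NaN
    for a monomorphic sample (the test is not conducted).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one individual required")
    n_a = 2 * n_aa + n_ab  # minor or major; symmetric below
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return float("nan")

    rare = min(n_a, n_b)
    # conditional P(n_het | n, n_a): n! / (nAA! nAB! nBB!) * 2^nAB * nA! nB! / (2n)!
    lg = math.lgamma
    log_const = lg(n + 1) + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1)

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            log_const
            + het * math.log(2.0)
            - lg(hom_rare + 1)
            - lg(het + 1)
            - lg(hom_common + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    log_probs = {h: log_prob(h) for h in hets}
    obs = log_probs[n_ab]
    # tolerate floating error when comparing equal-probability configurations
    p = sum(math.exp(lp) for lp in log_probs.values() if lp <= obs + 1e-9)
    return min(p, 1.0)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m for m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def genotype_counts(codes: np.ndarray) -> tuple[int, int, int]:
    """(n_ref_hom, n_het, n_alt_hom) over non-missing dosage codes."""
    codes = np.asarray(codes)
    obs = codes[codes != MISSING]
    return (
        int(np.sum(obs == 0)),
        int(np.sum(obs == 1)),
        int(np.sum(obs == 2)),
    )


def maf_ho_he(
    codes: np.ndarray, unbiased: bool = False
) -> tuple[float, float, float]:
    """Minor allele frequency, observed and expected heterozygosity.

    he = 2p(1-p), or with the 2n/(2n-1) correction when ``unbiased``.
    """
    n0, n1, n2 = genotype_counts(codes)
    n = n0 + n1 + n2
    if n == 0:
        return float("nan"), float("nan"), float("nan")
    p = (2 * n2 + n1) / (2 * n)
    maf = min(p, 1.0 - p)
    ho = n1 / n
    he = 2.0 * p * (1.0 - p)
    if unbiased and n > 0:
        he *= (2 * n) / (2 * n - 1)
    return maf, ho, he


def locus_summary(gm: GenotypeMatrix, unbiased_he: bool = False) -> pd.DataFrame:
    """Per-locus n / maf / ho / he / HWE p / monomorphic flag table."""
    rows = []
    for j, loc in enumerate(gm.loci):
        n0, n1, n2 = genotype_counts(gm.codes[:, j])
        n = n0 + n1 + n2
        maf, ho, he = maf_ho_he(gm.codes[:, j], unbiased=unbiased_he)
        hwe_p = hwe_exact_test(n0, n1, n2) if n > 0 else float("nan")
        rows.append(
            {
                "rsid": loc.rsid,
                "n": n,
                "maf": maf,
                "ho": ho,
                "he": he,
                "hwe_p": hwe_p,
                "monomorphic": bool(n > 0 and (n1 == 0 and (n0 == 0 or n2 == 0))),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-locus haplotype EM and LD r^2
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    """EM haplotype-frequency estimate for one locus pair.

    ``hap_freqs`` orders haplotypes (alt,alt), (alt,ref), (ref,alt),
    (ref,ref) with respect to the two loci.
    """

    hap_freqs: np.ndarray
    r2: float
    d: float
    em_iterations: int
    converged: bool
    loglik_trace: list[float]
    n_individuals: int


def em_haplotype_freqs(
    codes_a: np.ndarray,
    codes_b: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDResult:
    """EM over the double-heterozygote phase ambiguity for two loci.

    Starts from linkage-equilibrium product frequencies; individuals
    missing at either locus are excluded. Either locus monomorphic gives
    r^2 defined as 0.
    """
    codes_a = np.asarray(codes_a)
    codes_b = np.asarray(codes_b)
    if codes_a.shape != codes_b.shape:
        raise ValueError("dosage vectors differ in length")
    keep = (codes_a != MISSING) & (codes_b != MISSING)
    a = codes_a[keep].astype(np.int64)
    b = codes_b[keep].astype(np.int64)
    n = a.size
    if n < 2:
        raise ValueError("fewer than 2 usable individuals")

    # genotype-pair counts; index = 3*gA + gB
    pair_counts = np.bincount(3 * a + b, minlength=9).astype(float)

    # fixed haplotype contributions from unambiguous genotype pairs:
    # haplotype order: AB=alt/alt, Ab=alt/ref, aB=ref/alt, ab=ref/ref
    fixed = np.zeros(4)
    contrib = {
        (0, 0): (0, 0, 0, 2),
        (0, 1): (0, 0, 1, 1),
        (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1),
        (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0),
        (2, 1): (1, 1, 0, 0),
        (2, 2): (2, 0, 0, 0),
    }
    for (ga, gb), hap in contrib.items():
        fixed += pair_counts[3 * ga + gb] * np.asarray(hap, dtype=float)
    n_dh = pair_counts[3 * 1 + 1]  # double heterozygotes

    p_a = a.sum() / (2 * n)
    p_b = b.sum() / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        f = np.array(
            [p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)]
        )
        return LDResult(f, 0.0, 0.0, 0, True, [], n)

    f = np.array(
        [p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)]
    )
    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = fixed + n_dh * np.array([w, 1 - w, 1 - w, w])
        new_f = counts / (2 * n)
        trace.append(_hap_loglik(pair_counts, new_f))
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta < tol:
            converged = True
            break

    pa, pb = f[0] + f[1], f[0] + f[2]
    d = f[0] - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = float(d * d / denom) if denom > 0 else 0.0
    return LDResult(f, r2, float(d), iterations, converged, trace, n)


def _hap_loglik(pair_counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of genotype-pair counts given hap freqs."""
    f_ab, f_aB, f_Ab, f_AB = f[3], f[2], f[1], f[0]  # noqa: N806 readable below
    probs = np.empty(9)
    per_pair = {
        (0, 0): f_ab**2,
        (0, 1): 2 * f_ab * f_aB,
        (0, 2): f_aB**2,
        (1, 0): 2 * f_ab * f_Ab,
        (1, 1): 2 * (f_AB * f_ab + f_Ab * f_aB),
        (1, 2): 2 * f_AB * f_aB,
        (2, 0): f_Ab**2,
        (2, 1): 2 * f_AB * f_Ab,
        (2, 2): f_AB**2,
    }
    for (ga, gb), pr in per_pair.items():
        probs[3 * ga + gb] = pr
    ll = 0.0
    for c, pr in zip(pair_counts, probs):
        if c > 0:
            ll += c * math.log(max(pr, 1e-300))
    return ll


def ld_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise r^2 over all panel loci, as a square labelled frame."""
    rsids = gm.rsids
    m = len(rsids)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r2 = em_haplotype_freqs(gm.codes[:, i], gm.codes[:, j]).r2
            out[i, j] = out[j, i] = r2
    return pd.DataFrame(out, index=rsids, columns=rsids)


# ---------------------------------------------------------------------------
# Forensic identity statistics
# ---------------------------------------------------------------------------

def forensic_parameters(codes: np.ndarray) -> dict[str, float]:
    """Per-locus MP / PD / PIC / PE from dosage codes.

    mp = sum of squared observed genotype frequencies; pd = 1 - mp;
    pic = 1 - p^2 - q^2 - 2 p^2 q^2; pe = h^2 (1 - 2 h H^2), h = observed
    heterozygosity, H = 1 - h.
    """
    n0, n1, n2 = genotype_counts(codes)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("no calls at locus")
    freqs = np.array([n0, n1, n2]) / n
    mp = float(np.sum(freqs**2))
    pd_ = 1.0 - mp
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    pic = 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2
    h = n1 / n
    big_h = 1.0 - h
    pe = h**2 * (1.0 - 2.0 * h * big_h**2)
    return {"mp": mp, "pd": pd_, "pic": pic, "pe": pe}


def cumulative_panel_stats(per_locus: "pd.DataFrame | list[dict]") -> dict[str, float]:
    """Panel-level CPD/CPE and per-statistic means.

    cpd = 1 - prod(1 - pd_l); cpe = 1 - prod(1 - pe_l).
    """
    df = pd.DataFrame(per_locus)
    if df.empty:
        raise ValueError("at least one locus required")
    cpd = 1.0 - float(np.prod(1.0 - df["pd"].to_numpy()))
    cpe = 1.0 - float(np.prod(1.0 - df["pe"].to_numpy()))
    return {
        "cpd": cpd,
        "cpe": cpe,
        "mean_mp": float(df["mp"].mean()),
        "mean_pd": float(df["pd"].mean()),
        "mean_pic": float(df["pic"].mean()),
        "mean_pe": float(df["pe"].mean()),
    }


def forensic_report(gm: GenotypeMatrix) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-locus forensic table plus the panel summary."""
    rows = []
    for j, loc in enumerate(gm.loci):
        stats = forensic_parameters(gm.codes[:, j])
        stats["rsid"] = loc.rsid
        rows.append(stats)
    df = pd.DataFrame(rows)[["rsid", "mp", "pd", "pic", "pe"]]
    return df, cumulative_panel_stats(df)
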