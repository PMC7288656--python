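"""Unsupervised maximum-likelihood admixture decomposition.

Each individual's genome is modelled as a mixture over K ancestral
populations: genotype g_il ~ Binomial(2, pi_il) with pi_il = sum_k q_ik
f_kl. The likelihood is maximized by EM (expected ancestry counts), which
is guaranteed monotone in the log-likelihood; termination follows the
delta-log-likelihood < 1e-4 rule. F is clamped inside [1e-6, 1 - 1e-6]
after every update so no log ever diverges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from aisnp.genotype_io import MISSING, GenotypeMatrix

F_EPS = 1e-6
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 2000


@dataclass
class AdmixtureFit:
    k: int
    q: np.ndarray  # (N, K) row-stochastic ancestry fractions
    f: np.ndarray  # (K, L) ancestral alt frequencies in (0, 1)
    loglik_trace: np.ndarray
    converged: bool
    seed: int
    n_iterations: int

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _masked_arrays(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    obs = gm.codes != MISSING
    g = np.where(obs, gm.codes, 0).astype(float)
    return g, (2.0 - g) * obs, obs.astype(float)


def admixture_loglik(gm: GenotypeMatrix, q: np.ndarray, f: np.ndarray) -> float:
    """Binomial admixture log-likelihood (missing genotypes skipped).

    LL = sum_il [ g_il ln(pi_il) + (2 - g_il) ln(1 - pi_il) ]; the
    binomial coefficient is a data-only constant and is omitted.
    """
    q = np.asarray(q, dtype=float)
    f = np.asarray(f, dtype=float)
    if not np.allclose(q.sum(axis=1), 1.0):
        raise ValueError("Q rows must sum to 1")
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("F must lie strictly inside (0, 1)")
    g_alt, g_ref, _ = _masked_arrays(gm)
    pi = q @ f
    pi = np.clip(pi, F_EPS, 1.0 - F_EPS)
    return float(np.sum(g_alt * np.log(pi) + g_ref * np.log1p(-pi)))


def em_step(
    gm: GenotypeMatrix, q: np.ndarray, f: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One EM update of (Q, F); never decreases the log-likelihood.

    Responsibilities split each observed alt/ref allele across the K
    ancestries; Q rows renormalize expected ancestry counts over the 2L
    observed alleles, F entries are expected alt counts over expected
    totals.
    """
    g_alt, g_ref, obs = _masked_arrays(gm)
    pi = np.clip(q @ f, F_EPS, 1.0 - F_EPS)  # (N, L)

    # expected ancestry-k allele counts per individual/locus
    # alt: g * q_ik f_kl / pi ; ref: (2-g) * q_ik (1-f_kl) / (1-pi)
    alt_w = g_alt / pi  # (N, L)
    ref_w = g_ref / (1.0 - pi)
    # per (i, k): sum_l over loci
    a_ik = q * (alt_w @ f.T)  # expected alt alleles from ancestry k
    r_ik = q * (ref_w @ (1.0 - f).T)
    new_q = a_ik + r_ik
    denom = new_q.sum(axis=1, keepdims=True)
    new_q = np.where(denom > 0, new_q / denom, 1.0 / q.shape[1])

    # per (k, l): expected alt and total allele counts
    alt_kl = (q.T @ alt_w) * f  # broadcasting over l
    ref_kl = (q.T @ ref_w) * (1.0 - f)
    total = alt_kl + ref_kl
    with np.errstate(invalid="ignore", divide="ignore"):
        new_f = np.where(total > 0, alt_kl / total, f)
    new_f = np.clip(new_f, F_EPS, 1.0 - F_EPS)
    return new_q, new_f


def fit(
    gm: GenotypeMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> AdmixtureFit:
    """Fit the K-ancestry model from a random start under ``seed``.

    Q starts from Dirichlet(1, ..., 1) rows, F from Uniform(0.05, 0.95);
    EM iterates until the log-likelihood improves by less than ``tol``.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if gm.n_samples < k:
        raise ValueError(f"need at least K={k} individuals, have {gm.n_samples}")
    rng = np.random.default_rng(seed)
    q = rng.dirichlet(np.ones(k), size=gm.n_samples)
    f = rng.uniform(0.05, 0.95, size=(k, gm.n_loci))

    trace = [admixture_loglik(gm, q, f)]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        q, f = em_step(gm, q, f)
        ll = admixture_loglik(gm, q, f)
        trace.append(ll)
        if ll - trace[-2] < tol:
            converged = True
            break
    return AdmixtureFit(
        k=k,
        q=q,
        f=f,
        loglik_trace=np.asarray(trace),
        converged=converged,
        seed=seed,
        n_iterations=iterations,
    )


def run_k_range(
    gm: GenotypeMatrix,
    ks: "tuple[int, ...] | range" = (2, 3, 4, 5, 6),
    seeds: "tuple[int, ...]" = (0, 1, 2, 3, 4),
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> list[AdmixtureFit]:
    """Best-of-seeds fit for each K; one AdmixtureFit per K, in order."""
    fits = []
    for k in ks:
        best = None
        for seed in seeds:
            cand = fit(gm, k, seed=seed, max_iter=max_iter, tol=tol)
            if best is None or cand.loglik > best.loglik:
                best = cand
        fits.append(best)
    return fits


def align_to_truth(q: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Permute Q columns to best match a reference Q (label switching).

    Greedy assignment on column correlation; exact for small K.
    """
    from itertools import permutations

    k = q.shape[1]
    best_perm = tuple(range(k))
    best_err = np.inf
    for perm in permutations(range(k)):
        err = np.abs(q[:, list(perm)] - q_true).mean()
        if err < best_err:
            best_err = err
            best_perm = perm
    return q[:, list(best_perm)]


def write_q(fitres: AdmixtureFit, path: str) -> None:
    """Whitespace-delimited Q, one row per individual (.Q convention)."""
    np.savetxt(path, fitres.q, fmt="%.6f", delimiter=" ")


def write_p(fitres: AdmixtureFit, path: str) -> None:
    """Loci x K ancestral frequencies (.P convention)."""
    np.savetxt(path, fitres.f.T, fmt="%.6f", delimiter=" ")
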