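"""Maximum-likelihood admixture estimation from pooled allele counts.

Each colony is modelled as a three-way mixture of the A, M and C lineages.
At SNP j the expected reference-allele frequency is the classical admixture
mixture

    p_j = A * pA_j + M * pM_j + C * pC_j,

and the pooled count r_j out of n alleles (40 for 20 pooled workers) is
Binomial(n, p_j), independently across loci.  The estimate (A, M, C) is the
simplex point minimizing the negative log of the product of the binomial
probabilities over the non-missing loci.

The simplex constraint is handled by a softmax reparameterization over three
logits with one pinned to zero, optimized unconstrained (L-BFGS-B) from
multiple starts: the three simplex corners, the barycenter, and seeded random
points.  A brute-force lattice search (:func:`grid_oracle`) is provided as a
verification oracle for the optimizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .panel import ColonyObservation, LineagePanel

logger = logging.getLogger(__name__)

FREQ_CLAMP = 1e-6  # keeps log-likelihood finite at fixed panel loci
FLAT_TOL = 1e-6  # likelihood-spread tolerance for the non-identifiability flag


@dataclass
class AdmixtureEstimate:
    """Fitted (A, M, C) proportions with likelihood diagnostics."""

    colony_id: str
    A: float
    M: float
    C: float
    neg_log_likelihood: float
    converged: bool = True
    n_starts_used: int = 0
    flat_likelihood_flag: bool = False

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.A, self.M, self.C])


def mixture_freq(
    panel: LineagePanel,
    admixture: Sequence[float],
    snp_index: int | None = None,
) -> float | np.ndarray:
    """Expected reference-allele frequency under an admixture vector.

    Returns ``A*pA_j + M*pM_j + C*pC_j`` clamped to
    ``[FREQ_CLAMP, 1 - FREQ_CLAMP]``; the whole panel when ``snp_index`` is
    None.
    """
    w = np.asarray(admixture, float)
    p = w @ panel.freqs
    p = np.clip(p, FREQ_CLAMP, 1.0 - FREQ_CLAMP)
    return p if snp_index is None else float(p[snp_index])


def binomial_log_prob(r: int, n: int, p: float) -> float:
    """log of the binomial pmf C(n,r) p^r (1-p)^(n-r), computed in log space."""
    if not 0 <= r <= n:
        raise ValueError(f"r={r} outside [0, {n}]")
    log_comb = gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)
    return float(log_comb + r * np.log(p) + (n - r) * np.log1p(-p))


def _colony_arrays(colony: ColonyObservation, panel: LineagePanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(r, F, log_comb) restricted to the colony's non-missing SNPs."""
    keep = ~colony.missing
    if not keep.any():
        raise ValueError(f"colony {colony.colony_id!r} has zero non-missing SNPs")
    r = colony.counts[keep].astype(float)
    F = panel.freqs[:, keep]
    n = colony.n_alleles
    log_comb = gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)
    return r, F, log_comb


def _nll_from_arrays(w: np.ndarray, r: np.ndarray, F: np.ndarray, log_comb: np.ndarray, n: int) -> float:
    p = np.clip(w @ F, FREQ_CLAMP, 1.0 - FREQ_CLAMP)
    ll = log_comb + r * np.log(p) + (n - r) * np.log1p(-p)
    return float(-ll.sum())


def neg_log_likelihood(
    colony: ColonyObservation,
    panel: LineagePanel,
    admixture: Sequence[float],
) -> float:
    """Negative log-likelihood of an admixture vector for one colony.

    Sum over non-missing SNPs of the binomial log-probability of the observed
    count at the mixture frequency; missing SNPs contribute zero.
    """
    r, F, log_comb = _colony_arrays(colony, panel)
    return _nll_from_arrays(np.asarray(admixture, float), r, F, log_comb, colony.n_alleles)


def _softmax3(logits2: np.ndarray) -> np.ndarray:
    z = np.concatenate([logits2, [0.0]])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


_CORNERS = np.eye(3)


def estimate_admixture(
    colony: ColonyObservation,
    panel: LineagePanel,
    n_starts: int = 8,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> AdmixtureEstimate:
    """Maximum-likelihood (A, M, C) for one colony.

    Minimizes :func:`neg_log_likelihood` over the simplex via the softmax
    reparameterization, from ``n_starts`` starting points (3 corners,
    barycenter, seeded random logits).  The ``flat_likelihood_flag`` is set
    when the multi-start optima and the three simplex-corner likelihoods all
    agree within ``FLAT_TOL`` — the signature of a non-identifiable panel.
    """
    r, F, log_comb = _colony_arrays(colony, panel)
    n = colony.n_alleles

    def objective(logits2: np.ndarray) -> float:
        return _nll_from_arrays(_softmax3(logits2), r, F, log_comb, n)

    rng = np.random.default_rng(seed)
    starts = [np.array([10.0, 0.0]), np.array([0.0, 10.0]), np.array([-10.0, -10.0]), np.zeros(2)]
    while len(starts) < n_starts:
        starts.append(rng.normal(0.0, 2.0, size=2))

    best_val, worst_val = np.inf, -np.inf
    best_x = np.zeros(2)
    any_converged = False
    for x0 in starts[:n_starts]:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        any_converged = any_converged or bool(res.success)
        if res.fun < best_val:
            best_val, best_x = float(res.fun), res.x
        worst_val = max(worst_val, float(res.fun))

    w = _softmax3(best_x)
    corner_nll = [_nll_from_arrays(c, r, F, log_comb, n) for c in _CORNERS]
    flat = (worst_val - best_val < FLAT_TOL) and (max(corner_nll) - min(corner_nll) < FLAT_TOL)
    if flat:
        logger.debug("colony %s: flat likelihood surface", colony.colony_id)
    return AdmixtureEstimate(
        colony_id=colony.colony_id,
        A=float(w[0]),
        M=float(w[1]),
        C=float(w[2]),
        neg_log_likelihood=best_val,
        converged=any_converged,
        n_starts_used=n_starts,
        flat_likelihood_flag=bool(flat),
    )


def _simplex_lattice(step: float) -> np.ndarray:
    """All (A, M, C) with A, M multiples of ``step``, in lexicographic (A, M) order."""
    k = int(round(1.0 / step))
    pts = []
    for ia in range(k + 1):
        for im in range(k + 1 - ia):
            a, m = ia * step, im * step
            pts.append((a, m, max(1.0 - a - m, 0.0)))
    return np.asarray(pts)


def grid_oracle(
    colony: ColonyObservation,
    panel: LineagePanel,
    step: float = 0.01,
) -> tuple[tuple[float, float, float], float]:
    """Exhaustive lattice minimization of the negative log-likelihood.

    Evaluates every simplex lattice point with coordinates that are multiples
    of ``step``; ties resolve to the lexicographically smallest (A, M).
    A verification oracle for :func:`estimate_admixture`, not a production
    estimator.
    """
    if not 0.0 < step <= 0.1 + 1e-12:
        raise ValueError(f"step must be in (0, 0.1], got {step}")
    r, F, log_comb = _colony_arrays(colony, panel)
    n = colony.n_alleles
    W = _simplex_lattice(step)
    P = np.clip(W @ F, FREQ_CLAMP, 1.0 - FREQ_CLAMP)
    nll = -(log_comb + r * np.log(P) + (n - r) * np.log1p(-P)).sum(axis=1)
    best = int(np.argmin(nll))  # first minimum = lexicographic tie-break
    w = W[best]
    return (float(w[0]), float(w[1]), float(w[2])), float(nll[best])


def estimate_batch(
    colonies: Sequence[ColonyObservation],
    panel: LineagePanel,
    n_starts: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate every colony; failures are recorded and the batch continues.

    Returns a table with columns ``colony_id, A, M, C, nll, converged,
    flat_flag, error``.
    """
    rows = []
    for i, colony in enumerate(colonies):
        try:
            est = estimate_admixture(colony, panel, n_starts=n_starts, seed=seed + i)
            rows.append(
                {
                    "colony_id": est.colony_id,
                    "A": est.A,
                    "M": est.M,
                    "C": est.C,
                    "nll": est.neg_log_likelihood,
                    "converged": est.converged,
                    "flat_flag": est.flat_likelihood_flag,
                    "error": "",
                }
            )
        except Exception as exc:  # keep the batch alive on a bad colony
            logger.warning("colony %s failed: %s", colony.colony_id, exc)
            rows.append(
                {
                    "colony_id": colony.colony_id,
                    "A": np.nan,
                    "M": np.nan,
                    "C": np.nan,
                    "nll": np.nan,
                    "converged": False,
                    "flat_flag": False,
                    "error": str(exc),
                }
            )
        if (i + 1) % 100 == 0:
            logger.info("estimated %d/%d colonies", i + 1, len(colonies))
    return pd.DataFrame(rows)
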