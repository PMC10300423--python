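"""Permutation nulls, z-scores, empirical p-values, BH FDR, proportions.

Every permutation test in the package funnels through
:func:`permutation_enrichment`: a statistic is evaluated on the
observed input and on ``n_perm`` resampled inputs produced by a
caller-supplied null generator.  Per-permutation RNGs are derived
deterministically from the master seed by counter, so results are
reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .core import derive_rng


@dataclass
class EnrichmentResult:
    """Outcome of one permutation test.

    ``z`` is ``(observed - null_mean) / null_sd`` and is ``None`` when
    the null has zero spread around a different value.  ``p`` is the
    headline p-value: the two-sided normal p when ``z`` is defined,
    otherwise the empirical upper-tail p
    ``(#{null >= observed} + 1) / (n_perm + 1)``.
    """

    observed: float
    null_draws: np.ndarray = field(repr=False)
    null_mean: float
    null_sd: float
    z: float | None
    p: float
    p_normal: float | None
    p_empirical: float
    n_perm: int
    seed: int
    fdr: float | None = None

    def to_row(self) -> dict:
        return {
            "observed": self.observed, "null_mean": self.null_mean,
            "null_sd": self.null_sd, "z": self.z, "p_normal": self.p_normal,
            "p_empirical": self.p_empirical, "fdr": self.fdr,
            "n_perm": self.n_perm, "seed": self.seed,
        }


def results_to_frame(results: dict) -> pd.DataFrame:
    """Serialise a {label: EnrichmentResult} mapping as a tidy frame."""
    return pd.DataFrame({k: v.to_row() for k, v in results.items()}).T


def summarize_null(observed: float, null_draws, n_perm: int, seed: int,
                   alternative: str = "two-sided") -> EnrichmentResult:
    """Build an EnrichmentResult from an observed value and null draws."""
    draws = np.asarray(null_draws, dtype=float)
    mean = float(draws.mean())
    sd = float(draws.std(ddof=1)) if len(draws) > 1 else 0.0
    p_emp = float((np.sum(draws >= observed) + 1) / (len(draws) + 1))
    # a spread at float-rounding scale is a degenerate null
    tol = 1e-9 * max(1.0, abs(mean))
    if sd <= tol:
        sd = 0.0
        if abs(observed - mean) <= tol:
            observed = mean
    if sd > 0:
        z = (observed - mean) / sd
        if alternative == "two-sided":
            p_norm = float(2 * sps.norm.sf(abs(z)))
        elif alternative == "greater":
            p_norm = float(sps.norm.sf(z))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        p = min(max(p_norm, np.finfo(float).tiny), 1.0)
        return EnrichmentResult(observed, draws, mean, sd, float(z), p,
                                p_norm, p_emp, n_perm, seed)
    if observed == mean:
        return EnrichmentResult(observed, draws, mean, sd, 0.0, 1.0,
                                1.0, p_emp, n_perm, seed)
    # degenerate null with a different observed value: z undefined
    return EnrichmentResult(observed, draws, mean, sd, None, p_emp,
                            None, p_emp, n_perm, seed)


def permutation_enrichment(statistic: Callable, null_generator: Callable,
                           observed_input, n_perm: int, seed: int,
                           alternative: str = "two-sided"
                           ) -> EnrichmentResult:
    """Generic permutation test.

    ``null_generator(rng)`` returns one resampled input; ``statistic``
    maps an input to a float.  Each permutation gets its own RNG derived
    from ``seed`` by counter.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = float(statistic(observed_input))
    draws = np.empty(n_perm)
    for i in range(n_perm):
        draws[i] = statistic(null_generator(derive_rng(seed, i)))
    return summarize_null(observed, draws, n_perm, seed, alternative)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: dict, on: str = "empirical") -> dict:
    """BH-correct a family of permutation results.

    ``on="empirical"`` (default for the family-corrected tests) uses the
    exact empirical permutation p-values — guaranteed sub-uniform under
    the null even for small discrete statistics, where the normal
    approximation over-rejects — and makes them the headline ``p``.
    ``on="normal"`` corrects the normal-approximation p-values instead.
    """
    labels = list(results)
    if on == "empirical":
        ps = [results[k].p_empirical for k in labels]
        q = bh_fdr(ps)
        return {k: replace(results[k], p=float(p), fdr=float(qi))
                for k, p, qi in zip(labels, ps, q)}
    if on != "normal":
        raise ValueError(f"unknown correction basis {on!r}")
    q = bh_fdr([results[k].p for k in labels])
    return {k: replace(results[k], fdr=float(qi))
            for k, qi in zip(labels, q)}


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int
                         ) -> tuple[float, float]:
    """Pooled two-proportion z-test (two-sided normal p).

    Degenerate pooled proportions (0 or 1) carry no variance and return
    ``(0.0, 1.0)``.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n and n >= 1")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(z), float(p)
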