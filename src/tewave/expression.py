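"""Count normalization and LINE-1 group-expression testing.

Between-sample normalization uses TMM (trimmed mean of M-values): for
each sample against a reference library, gene-wise log2 ratios (M) are
doubly trimmed — by M (30%) and by average log2 abundance (5%) — and the
surviving ratios averaged with inverse-variance precision weights.  The
resulting factors are rescaled to geometric mean 1.  Counts of LINE-1
fragments merged during defragmentation are summed per joined locus
before analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import derive_rng
from .stats import EnrichmentResult, attach_fdr, summarize_null

logger = logging.getLogger("tewave")


@dataclass
class CountsMatrix:
    """Features x samples raw counts with per-sample stage labels."""

    counts: pd.DataFrame  # features x samples, non-negative
    stages: pd.Series  # sample -> stage label
    norm_factors: pd.Series | None = None

    def __post_init__(self):
        if not self.counts.columns.equals(self.stages.index):
            self.stages = self.stages.reindex(self.counts.columns)
            if self.stages.isna().any():
                raise ValueError("every sample needs a stage label")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def normalized(self) -> pd.DataFrame:
        """Counts per million on factor-adjusted library sizes."""
        factors = self.norm_factors
        if factors is None:
            factors = tmm_norm_factors(self.counts)
            self.norm_factors = factors
        eff = self.lib_sizes * factors
        return self.counts / eff * 1e6


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.30, sum_trim: float = 0.05) -> float:
    """log2 TMM factor of one library against the reference."""
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / n_obs) / (ref / n_ref))
        a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    keep = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a = m[keep], a[keep]
    obs_k, ref_k = obs[keep], ref[keep]
    if len(m) == 0 or np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = len(m)
    lo_l = int(np.floor(n * logratio_trim)) + 1
    hi_l = n + 1 - lo_l
    lo_s = int(np.floor(n * sum_trim)) + 1
    hi_s = n + 1 - lo_s
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_l) & (rank_m <= hi_l) \
        & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep2.any():
        return 0.0
    # asymptotic (delta-method) variance of M as precision weight
    v = (n_obs - obs_k) / (n_obs * obs_k) + (n_ref - ref_k) / (n_ref * ref_k)
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1 / v[keep2])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_norm_factors(counts: pd.DataFrame, logratio_trim: float = 0.30,
                     sum_trim: float = 0.05) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th count percentile
    (library-size scaled) is closest to the mean of those percentiles.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero library")
    q75 = np.array([np.quantile(x[:, j] / lib[j], 0.75)
                    for j in range(x.shape[1])])
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    logf = np.array([
        _tmm_pair(x[:, j], x[:, ref_j], lib[j], lib[ref_j],
                  logratio_trim, sum_trim)
        for j in range(x.shape[1])
    ])
    factors = 2.0 ** logf
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def tmm_normalize(matrix: CountsMatrix) -> pd.DataFrame:
    """Attach TMM factors and return normalized (CPM-scale) values."""
    matrix.norm_factors = tmm_norm_factors(matrix.counts)
    return matrix.normalized()


def aggregate_joined(matrix: CountsMatrix, join_map: dict[str, str]
                     ) -> CountsMatrix:
    """Sum fragment counts into their joined locus ids.

    ``join_map`` maps original feature ids to joined ids; features not
    in the map pass through unchanged.  Ids in the map but absent from
    the matrix contribute 0 (with a warning).
    """
    missing = [k for k in join_map if k not in matrix.counts.index]
    if missing:
        logger.warning("%d join_map ids absent from counts; treated as 0",
                       len(missing))
    groups = {fid: join_map.get(fid, fid) for fid in matrix.counts.index}
    summed = matrix.counts.groupby(groups, sort=False).sum()
    # keep first-appearance order of the joined ids
    seen: dict[str, None] = {}
    for fid in matrix.counts.index:
        seen.setdefault(groups[fid], None)
    summed = summed.reindex(list(seen))
    return CountsMatrix(summed, matrix.stages.copy(),
                        None if matrix.norm_factors is None
                        else matrix.norm_factors.copy())


def group_vs_random_expression(group_ids: Sequence[str],
                               universe_ids: Sequence[str],
                               normalized: pd.DataFrame,
                               stages: pd.Series, n_perm: int = 1000,
                               seed: int = 0
                               ) -> dict[str, EnrichmentResult]:
    """Compare a feature group's mean expression to random equal-size draws.

    Per stage, the observed statistic is the mean normalized expression
    over the group's features and the stage's replicates; the null draws
    equal-size feature sets from the universe without replacement.  FDR
    is corrected across stages.
    """
    group = list(dict.fromkeys(group_ids))
    universe = list(dict.fromkeys(universe_ids))
    if not set(group) <= set(universe):
        raise ValueError("group must be a subset of the universe")
    if len(group) > len(universe):
        raise ValueError("group larger than universe")
    stage_order = list(dict.fromkeys(stages))
    # per-feature per-stage means (replicates averaged first)
    stage_means = pd.DataFrame({
        st: normalized.loc[:, stages[stages == st].index].mean(axis=1)
        for st in stage_order
    })
    uni = stage_means.loc[universe].to_numpy()
    gidx = np.sort([universe.index(g) for g in group])
    observed = uni[gidx].mean(axis=0)
    k = len(group)
    draws = np.empty((n_perm, len(stage_order)))
    for i in range(n_perm):
        rng = derive_rng(seed, i)
        sample = np.sort(rng.choice(len(universe), size=k, replace=False))
        draws[i] = uni[sample].mean(axis=0)
    results = {
        st: summarize_null(float(observed[j]), draws[:, j], n_perm, seed)
        for j, st in enumerate(stage_order)
    }
    return attach_fdr(results)
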