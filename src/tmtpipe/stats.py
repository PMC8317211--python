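"""s0-moderated pairwise testing with permutation-based FDR.

The test statistic is the SAM form: d = (mean_a - mean_b) / (se + s0), where
se is the pooled two-sample standard error and s0 a constant on the log2
scale. s0 = 0 recovers the classic pooled-variance t statistic; s0 > 0 makes
small-variance proteins require a minimum fold change before they can reach
significance.

The FDR is estimated by permuting group labels (group sizes preserved): for
a threshold t, FDR(t) = pi0 * [mean over permutations of the number of
permuted |d| >= t] / [number of observed |d| >= t], with pi0 fixed at 1
(conservative). A protein's q-value is the minimum estimated FDR over the
rejection thresholds that would call it (t <= its |d|), which makes q
monotone non-increasing in |d|. When the number
of distinct label assignments is no larger than the requested permutation
count, the permutations are enumerated exhaustively (the identity assignment
excluded); otherwise distinct assignments are sampled uniformly without
replacement from a seeded generator.

An optional one-way ANOVA prefilter across the four sex x treatment groups
(Benjamini-Hochberg across proteins) restricts the universe entering the
pairwise tests, as used for the lower-coverage datasets.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import ComparisonResult, IntensityMatrix
from .errors import ConfigError, InputError, InsufficientDataError

log = logging.getLogger(__name__)

#: the three pairwise contrasts, (test group, reference group)
DEFAULT_COMPARISONS = (("MC", "FC"), ("FN", "FC"), ("MN", "MC"))


@dataclass
class TestConfig:
    """Parameters of the differential-testing stage."""

    s0: float = 0.5
    fdr: float = 0.05
    n_permutations: int = 250
    anova_fdr: float = 0.05
    anova_enabled: bool = True
    seed: int = 0
    pi0: float = 1.0
    aggregate: str = "mean"   # mean | median false-positive count over permutations
    welch: bool = False

    def __post_init__(self):
        if not 0.0 < self.fdr < 1.0:
            raise ConfigError("fdr must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.s0 < 0:
            raise ConfigError("s0 must be >= 0")
        if self.aggregate not in ("mean", "median"):
            raise ConfigError("aggregate must be 'mean' or 'median'")


TestConfig.__test__ = False  # keep pytest from collecting the config class


# ---------------------------------------------------------------------------
# ANOVA prefilter
# ---------------------------------------------------------------------------

def anova_prefilter(matrix: IntensityMatrix, config: TestConfig):
    """One-way fixed-effects F-test across the experimental groups.

    Proteins constant across all samples are dropped (F undefined). Returns
    ``(filtered matrix, table)`` where the table carries F, p, q (BH) and the
    keep flag for every tested protein; the filtered matrix retains proteins
    with q < ``config.anova_fdr``.
    """
    if matrix.scale != "log2":
        raise InputError("anova_prefilter expects a log2 matrix")
    labels = matrix.group_labels()
    groups = [g for g in dict.fromkeys(labels) if g != "POOL"]
    if len(groups) < 2:
        raise InputError("need at least 2 experimental groups")
    blocks = [matrix.values[labels.index[labels == g]].to_numpy() for g in groups]
    sizes = np.array([b.shape[1] for b in blocks])
    if (sizes < 2).any():
        raise InsufficientDataError("every group needs >= 2 replicates for ANOVA")
    n_total = sizes.sum()
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if df_within <= 0:
        raise ConfigError("zero residual degrees of freedom")

    means = np.column_stack([b.mean(axis=1) for b in blocks])
    grand = np.column_stack(blocks).mean(axis=1)
    ss_between = (sizes * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.zeros_like(grand)
    for b, m in zip(blocks, means.T):
        ss_within += ((b - m[:, None]) ** 2).sum(axis=1)

    constant = (ss_between + ss_within) <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_between) / (ss_within / df_within)
    p = sps.f.sf(F, df_between, df_within)
    tested = ~constant
    q = np.full_like(p, np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    table = pd.DataFrame({"F": F, "p_value": p, "q_value": q},
                         index=matrix.values.index)
    table.loc[constant, ["F", "p_value", "q_value"]] = np.nan
    table["keep"] = tested & (q < config.anova_fdr)
    kept = table.index[table["keep"]]
    out = matrix.subset_rows(kept)
    out.meta["n_dropped_anova"] = int(len(table) - len(kept))
    out.meta["n_dropped_constant"] = int(constant.sum())
    return out, table


# ---------------------------------------------------------------------------
# d statistic
# ---------------------------------------------------------------------------

def d_statistic(values_a, values_b, s0: float, welch: bool = False):
    """Moderated statistic d = (mean_a - mean_b) / (se + s0).

    Accepts 1-D arrays (one protein) or 2-D proteins x replicates arrays;
    returns ``(diff, d)``. With ``welch`` the unpooled (Welch) standard error
    replaces the pooled one.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    diff = a.mean(axis=1) - b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    if welch:
        se = np.sqrt(va / na + vb / nb)
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / denom,
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    if np.ndim(values_a) == 1:
        return float(diff[0]), float(d[0])
    return diff, d


# ---------------------------------------------------------------------------
# permutations
# ---------------------------------------------------------------------------

def _assignments(n: int, na: int, n_permutations: int, rng) -> list:
    """Index tuples (positions of group A) excluding the identity.

    Exhaustive when the number of distinct assignments (minus identity) fits
    within ``n_permutations``; otherwise a uniform sample of distinct
    assignments without replacement.
    """
    identity = tuple(range(na))
    total = comb(n, na)
    if total - 1 < 2:
        raise InsufficientDataError("fewer than 2 distinct permutations")
    if total - 1 <= n_permutations:
        return [c for c in combinations(range(n), na) if c != identity]
    seen = {identity}
    out = []
    while len(out) < n_permutations:
        c = tuple(sorted(rng.choice(n, size=na, replace=False).tolist()))
        if c in seen:
            continue
        seen.add(c)
        out.append(c)
    return out


def permutation_fdr(matrix: IntensityMatrix, test_group: str,
                    reference_group: str, config: TestConfig,
                    label: str | None = None) -> ComparisonResult:
    """SAM-style permutation FDR for one two-group contrast.

    The log2 fold change is test minus reference group mean. Significance is
    q < ``config.fdr``; direction follows the sign of the fold change.
    """
    if matrix.scale != "log2":
        raise InputError("permutation_fdr expects a log2 matrix")
    cols_a = matrix.group_samples(test_group)
    cols_b = matrix.group_samples(reference_group)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise InsufficientDataError(
            f"groups {test_group}/{reference_group} need >= 2 replicates")
    label = label or f"{test_group}_vs_{reference_group}"

    used = matrix.values[cols_a + cols_b].dropna()
    X = used.to_numpy()
    na = len(cols_a)
    n = X.shape[1]
    diff, d = d_statistic(X[:, :na], X[:, na:], config.s0, welch=config.welch)
    abs_d = np.abs(d)

    rng = np.random.default_rng(config.seed)
    assignments = _assignments(n, na, config.n_permutations, rng)
    all_idx = np.arange(n)
    perm_abs = np.empty((len(assignments), X.shape[0]))
    for i, idx_a in enumerate(assignments):
        idx_a = np.asarray(idx_a)
        idx_b = np.setdiff1d(all_idx, idx_a, assume_unique=True)
        _, dp = d_statistic(X[:, idx_a], X[:, idx_b], config.s0,
                            welch=config.welch)
        perm_abs[i] = np.abs(dp)

    # exceedance counts at each observed |d| threshold
    order = np.argsort(-abs_d, kind="stable")        # descending |d|
    thresholds = abs_d[order]
    n_obs_ge = np.arange(1, len(thresholds) + 1, dtype=float)
    # ties: every tied protein counts all its ties as called
    for i in range(len(thresholds) - 2, -1, -1):
        if thresholds[i] == thresholds[i + 1]:
            n_obs_ge[i] = n_obs_ge[i + 1]

    if config.aggregate == "mean":
        flat = np.sort(perm_abs.ravel())
        n_perm_ge = (len(flat) - np.searchsorted(flat, thresholds, side="left")
                     ) / perm_abs.shape[0]
    else:
        counts = np.empty((perm_abs.shape[0], len(thresholds)))
        for i in range(perm_abs.shape[0]):
            row = np.sort(perm_abs[i])
            counts[i] = len(row) - np.searchsorted(row, thresholds, side="left")
        n_perm_ge = np.median(counts, axis=0)

    fdr_at = np.minimum(config.pi0 * n_perm_ge / n_obs_ge, 1.0)
    # q_i = min over rejection thresholds that include protein i (t <= |d_i|)
    # of the estimated FDR; this makes q monotone non-increasing in |d|
    q_sorted = np.minimum.accumulate(fdr_at[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    direction = np.where(diff < 0, "down", "up")
    table = pd.DataFrame({
        "gene_name": matrix.records.loc[used.index, "gene_name"].to_numpy(),
        "log2_fc": diff,
        "d": d,
        "q_value": q,
        "significant": q < config.fdr,
        "direction": direction,
    }, index=used.index)
    return ComparisonResult(label=label, test_group=test_group,
                            reference_group=reference_group, table=table,
                            s0=config.s0, fdr=config.fdr,
                            n_permutations=len(assignments))


# ---------------------------------------------------------------------------
# suite
# ---------------------------------------------------------------------------

def _subseed(seed: int, label: str) -> int:
    return (int(seed) * 1000003 + zlib.crc32(label.encode())) % (2 ** 31)


def run_pairwise_suite(matrix: IntensityMatrix, config: TestConfig,
                       comparisons=DEFAULT_COMPARISONS):
    """ANOVA prefilter (optional) then the three pairwise permutation tests.

    Returns ``(results dict keyed by label, anova table or None)``. Each
    comparison draws its permutations from a seed derived from the config
    seed and the comparison label, so results are reproducible and
    independent of execution order.
    """
    anova_table = None
    if config.anova_enabled:
        matrix, anova_table = anova_prefilter(matrix, config)
    results = {}
    for test, ref in comparisons:
        label = f"{test}_vs_{ref}"
        sub = replace(config, seed=_subseed(config.seed, label))
        results[label] = permutation_fdr(matrix, test, ref, sub, label=label)
    return results, anova_table


def volcano_table(result: ComparisonResult) -> pd.DataFrame:
    """Volcano-ready table: log2 FC and -log10 q (q floored to avoid inf)."""
    eps = 1.0 / (result.n_permutations * max(len(result.table), 1) + 1)
    t = result.table.copy()
    t["neg_log10_q"] = -np.log10(np.maximum(t["q_value"], eps))
    return t


def summary_counts(results: dict) -> pd.DataFrame:
    """Per-comparison significant/up/down counts (Fig.3A-style summary)."""
    rows = []
    for label, res in results.items():
        rows.append({"comparison": label, **res.counts()})
    return pd.DataFrame(rows).set_index("comparison")
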