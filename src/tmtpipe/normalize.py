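"""Three-stage normalization of multi-plex TMT reporter intensities, plus QC.

Stage order is fixed as sample-loading (SL) -> trimmed mean of M-values
(TMM) -> batch correction. SL equalizes per-channel total intensity within
each plex (pipetting/labeling differences); TMM aligns the centers of the
per-channel intensity distributions within each plex; the batch step aligns
plexes either by internal reference scaling (IRS: per-protein factors that
make the pooled-reference measurements identical across plexes, applied on
the intensity scale) or by least-squares removal of additive plex offsets on
the log2 scale.

SL and TMM are positive per-channel scalings and IRS a positive per-protein
per-plex scaling, so every stage preserves within-channel ranks. Factors are
estimated on proteins quantified in all channels involved; missing cells are
scaled but never imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (POOL_GROUP, IntensityMatrix, NormalizationFactors,
                         QCReport)
from .errors import (ConfoundingError, DegenerateDataError, DesignError,
                     InputError, InsufficientDataError)

log = logging.getLogger(__name__)


def _require_intensity_scale(matrix: IntensityMatrix, op: str) -> None:
    if matrix.scale == "log2":
        raise InputError(f"{op} expects an intensity-scale matrix, got log2")


# ---------------------------------------------------------------------------
# sample loading
# ---------------------------------------------------------------------------

def sample_loading_normalize(matrix: IntensityMatrix):
    """Equalize per-channel total intensity within each plex.

    factor_j = (mean over the plex's channels of total intensity) / (total of
    channel j), computed on proteins present in every channel of the plex.
    Returns ``(normalized matrix, sl_factors)``.
    """
    _require_intensity_scale(matrix, "sample_loading_normalize")
    values = matrix.values.copy()
    factors = pd.Series(1.0, index=matrix.channels.index, name="sl_factor")
    for plex in matrix.plexes:
        cols = matrix.plex_samples(plex)
        block = values[cols]
        complete = block.dropna()
        totals = complete.sum(axis=0)
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise DegenerateDataError(f"plex {plex!r}: zero-total channel(s) {bad}")
        f = totals.mean() / totals
        values[cols] = block * f
        factors[cols] = f
    out = matrix.with_values(values, scale="normalized")
    return out, factors


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _trim_keep(order_values: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping the central part after trimming ``trim`` from
    each tail (by rank)."""
    n = len(order_values)
    k = int(np.floor(n * trim))
    if 2 * k >= n:
        raise InsufficientDataError("trim fraction removes every observation")
    ranks = np.argsort(np.argsort(order_values, kind="stable"), kind="stable")
    return (ranks >= k) & (ranks < n - k)


def tmm_factors(matrix: IntensityMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05, min_proteins: int = 10,
                rescale: bool = True) -> pd.Series:
    """Per-channel TMM scaling factors, computed within each plex.

    The reference channel of a plex is the one whose upper quartile is
    closest to the plex-mean upper quartile. For every other channel,
    M = log2(x_j / x_ref) and A = (1/2) log2(x_j * x_ref) per protein; the
    top and bottom ``trim_m`` of M and ``trim_a`` of A are discarded and the
    factor is 2 to the precision-weighted mean of the surviving M (delta
    method weights 1 / (1/x_j + 1/x_ref)). With ``rescale`` the factors are
    anchored so they multiply to 1 across the plex; without it the reference
    channel's factor is exactly 1.
    """
    _require_intensity_scale(matrix, "tmm_factors")
    factors = pd.Series(1.0, index=matrix.channels.index, name="tmm_factor")
    for plex in matrix.plexes:
        cols = matrix.plex_samples(plex)
        if len(cols) == 1:
            continue
        block = matrix.values[cols].dropna()
        block = block[(block > 0).all(axis=1)]
        if len(block) < max(min_proteins, 1):
            raise InsufficientDataError(
                f"plex {plex!r}: only {len(block)} complete positive proteins")
        uq = block.quantile(0.75, axis=0)
        ref = (uq - uq.mean()).abs().idxmin()
        x_ref = block[ref].to_numpy()
        raw = {}
        for col in cols:
            if col == ref:
                raw[col] = 1.0
                continue
            x = block[col].to_numpy()
            m = np.log2(x / x_ref)
            a = 0.5 * np.log2(x * x_ref)
            keep = _trim_keep(m, trim_m) & _trim_keep(a, trim_a)
            if keep.sum() < max(min_proteins, 1):
                raise InsufficientDataError(
                    f"plex {plex!r}, channel {col!r}: "
                    f"{int(keep.sum())} proteins survive trimming")
            w = 1.0 / (1.0 / x[keep] + 1.0 / x_ref[keep])
            raw[col] = float(2.0 ** (np.average(m[keep], weights=w)))
        f = pd.Series(raw)[cols]
        if rescale:
            f = f / np.exp(np.mean(np.log(f)))
        factors[cols] = f
    return factors


def tmm_normalize(matrix: IntensityMatrix, **kwargs):
    """Apply TMM: divide each channel by its (anchored) factor."""
    factors = tmm_factors(matrix, **kwargs)
    values = matrix.values / factors
    return matrix.with_values(values, scale="normalized"), factors


# ---------------------------------------------------------------------------
# IRS
# ---------------------------------------------------------------------------

def irs_normalize(matrix: IntensityMatrix):
    """Internal reference scaling across plexes.

    Per protein i: ref_i(plex) is the geometric mean of the plex's pooled
    channels; the target is the geometric mean of ref_i over plexes; every
    channel of the plex is multiplied by target_i / ref_i(plex). After IRS
    the pooled references are identical across plexes. Proteins with a zero
    or missing pool value in any plex are dropped (count in ``meta``).
    Returns ``(matrix, irs_factors)`` with factors proteins x plexes.
    """
    _require_intensity_scale(matrix, "irs_normalize")
    plexes = matrix.plexes
    for plex in plexes:
        if not matrix.pooled_samples(plex):
            raise DesignError(f"plex {plex!r} has no pooled_reference channel")
    if len(plexes) == 1:
        factors = pd.DataFrame(1.0, index=matrix.values.index, columns=plexes)
        out = matrix.copy()
        out.meta["n_dropped_irs"] = 0
        return out, factors

    refs = {}
    for plex in plexes:
        pools = matrix.values[matrix.pooled_samples(plex)]
        with np.errstate(divide="ignore", invalid="ignore"):
            # a zero/missing pool value invalidates the protein's reference
            refs[plex] = np.exp2(np.log2(pools).mean(axis=1, skipna=False))
    refs = pd.DataFrame(refs)
    valid = np.isfinite(refs).all(axis=1) & (refs > 0).all(axis=1)
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.info("irs_normalize: dropping %d proteins with missing/zero pool values",
                 n_dropped)
    refs = refs[valid]
    target = np.exp2(np.log2(refs).mean(axis=1))
    factors = refs.rdiv(target, axis=0)

    values = matrix.values.loc[refs.index].copy()
    for plex in plexes:
        cols = matrix.plex_samples(plex)
        values[cols] = values[cols].mul(factors[plex], axis=0)
    out = matrix.subset_rows(refs.index).with_values(values, scale="normalized")
    out.meta["n_dropped_irs"] = n_dropped
    return out, factors


# ---------------------------------------------------------------------------
# log2 + linear batch correction
# ---------------------------------------------------------------------------

def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    _require_intensity_scale(matrix, "log2_transform")
    if ((matrix.values <= 0).any()).any():
        raise DegenerateDataError("non-positive intensities at log2 transform")
    return matrix.with_values(np.log2(matrix.values), scale="log2")


def linear_batch_correct(matrix: IntensityMatrix,
                         group_labels: pd.Series | None = None) -> IntensityMatrix:
    """Remove additive per-plex offsets from a log2 matrix by least squares.

    Per protein, fit value = group mean + batch offset with sum-to-zero batch
    coding and subtract the fitted batch offsets; group-mean differences are
    untouched. Pooled channels form their own group so they are preserved.
    Requires each group observed in more than one plex (otherwise batch is
    confounded with group).
    """
    if matrix.scale != "log2":
        raise InputError("linear_batch_correct expects a log2 matrix")
    if matrix.values.isna().any().any():
        raise DegenerateDataError("missing values present; filter rows first")
    plexes = matrix.plexes
    if len(plexes) == 1:
        return matrix.copy()
    if group_labels is None:
        group_labels = matrix.group_labels()
    group_labels = group_labels.loc[matrix.values.columns]
    for g in dict.fromkeys(group_labels):
        seen = set(matrix.channels.loc[group_labels.index[group_labels == g], "plex"])
        if len(seen) < 2:
            raise ConfoundingError(f"group {g!r} observed in a single plex; "
                                   "batch confounded with group")

    groups = list(dict.fromkeys(group_labels))
    plex_of = matrix.channels["plex"]
    n_s = matrix.n_channels
    X_group = np.zeros((n_s, len(groups)))
    for j, sid in enumerate(matrix.values.columns):
        X_group[j, groups.index(group_labels[sid])] = 1.0
    X_batch = np.zeros((n_s, len(plexes) - 1))
    for j, sid in enumerate(matrix.values.columns):
        p = plexes.index(plex_of[sid])
        if p < len(plexes) - 1:
            X_batch[j, p] = 1.0
        else:
            X_batch[j, :] = -1.0
    X = np.hstack([X_group, X_batch])
    pinv = np.linalg.pinv(X)
    Y = matrix.values.to_numpy()
    coef = Y @ pinv.T
    batch_part = coef[:, len(groups):] @ X_batch.T
    corrected = pd.DataFrame(Y - batch_part, index=matrix.values.index,
                             columns=matrix.values.columns)
    return matrix.with_values(corrected, scale="log2")


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def normalize_pipeline(matrix: IntensityMatrix, batch_method: str = "irs",
                       tmm_kwargs: dict | None = None):
    """SL -> TMM -> batch correction -> log2 matrix.

    ``batch_method='irs'`` applies internal reference scaling on the
    intensity scale and then log2-transforms; ``'linear_model'`` transforms
    to log2 first and removes additive plex offsets by least squares.
    Returns ``(log2 matrix, NormalizationFactors)``.
    """
    if batch_method not in ("irs", "linear_model", "none"):
        raise InputError(f"unknown batch_method {batch_method!r}")
    m, sl = sample_loading_normalize(matrix)
    m, tmm = tmm_normalize(m, **(tmm_kwargs or {}))
    irs_f = None
    if batch_method == "irs":
        m, irs_f = irs_normalize(m)
        m = log2_transform(m)
    elif batch_method == "linear_model":
        m = log2_transform(m)
        m = linear_batch_correct(m)
    else:
        m = log2_transform(m)
    factors = NormalizationFactors(sl_factors=sl, tmm_factors=tmm,
                                   irs_factors=irs_f, method_batch=batch_method)
    return m, factors


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_report(matrix: IntensityMatrix, n_components: int = 5) -> QCReport:
    """Fig.2-style QC of a log2 matrix.

    CVs are computed on the intensity (2**x) scale per group per protein as
    100 * sd / mean with the sample (n-1) standard deviation, then averaged
    per group; Pearson correlations on log2 values over shared proteins; PCA
    on protein-centered log2 sample profiles by SVD. Groups with a single
    replicate are skipped with a warning.
    """
    if matrix.scale != "log2":
        raise InputError("qc_report expects a log2 matrix")
    if matrix.n_channels < 2:
        raise InputError("qc_report needs at least 2 channels")

    quart = matrix.values.quantile([0.25, 0.5, 0.75]).T
    quart.columns = ["q25", "median", "q75"]

    labels = matrix.group_labels()
    intens = np.exp2(matrix.values)
    cv_cols = {}
    for g in dict.fromkeys(labels):
        cols = labels.index[labels == g]
        if len(cols) < 2:
            log.warning("qc_report: group %r has one replicate; CV skipped", g)
            continue
        block = intens[cols]
        cv_cols[g] = 100.0 * block.std(axis=1, ddof=1) / block.mean(axis=1)
    cv = pd.DataFrame(cv_cols)
    group_mean_cv = cv.mean(axis=0)

    complete = matrix.values.dropna()
    pearson = complete.corr(method="pearson")

    X = complete.to_numpy().T  # samples x proteins
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    scores = pd.DataFrame(u[:, :k] * s[:k], index=complete.columns,
                          columns=[f"PC{i + 1}" for i in range(k)])
    total = float((s ** 2).sum())
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return QCReport(channel_quartiles=quart, cv_per_protein=cv,
                    group_mean_cv=group_mean_cv, pearson=pearson,
                    pca_scores=scores, explained_variance=explained)
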