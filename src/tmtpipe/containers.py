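"""In-memory containers shared across the pipeline.

The central object is :class:`IntensityMatrix`: a proteins x channels table of
reporter-ion intensities together with per-protein flags and per-channel
metadata. Missing measurements are stored as NaN; on the ``raw`` and
``normalized`` scales all present values are positive, on the ``log2`` scale
they are finite reals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DesignError, InputError

#: order of the experimental groups: male/female x control/nicotine
GROUPS = ("MC", "FC", "MN", "FN")

RECORD_COLUMNS = ("gene_name", "is_reverse", "is_contaminant", "only_identified_by_site")
CHANNEL_COLUMNS = ("plex", "channel", "role", "sex", "treatment")

ROLE_EXPERIMENTAL = "experimental"
ROLE_POOLED = "pooled_reference"
POOL_GROUP = "POOL"


def group_label(sex: str, treatment: str) -> str:
    """Map (sex, treatment) to the two-letter group code (MC/FC/MN/FN)."""
    s = {"M": "M", "F": "F"}.get(str(sex))
    t = {"control": "C", "nicotine": "N"}.get(str(treatment))
    if s is None or t is None:
        raise DesignError(f"cannot derive group from sex={sex!r}, treatment={treatment!r}")
    return s + t


def validate_channels(channels: pd.DataFrame) -> None:
    missing = [c for c in CHANNEL_COLUMNS if c not in channels.columns]
    if missing:
        raise DesignError(f"design table missing columns: {missing}")
    if channels.index.duplicated().any():
        raise DesignError("duplicate sample ids in design table")
    bad_role = set(channels["role"]) - {ROLE_EXPERIMENTAL, ROLE_POOLED}
    if bad_role:
        raise DesignError(f"unknown channel roles: {sorted(bad_role)}")
    pooled = channels[channels["role"] == ROLE_POOLED]
    if not ((pooled["sex"] == "none") & (pooled["treatment"] == "none")).all():
        raise DesignError("pooled_reference channels must have sex=none and treatment=none")
    exp = channels[channels["role"] == ROLE_EXPERIMENTAL]
    if (exp["sex"] == "none").any() or (exp["treatment"] == "none").any():
        raise DesignError("experimental channels must carry both sex and treatment")


@dataclass
class IntensityMatrix:
    """Proteins x channels intensity table with metadata.

    Attributes
    ----------
    values
        DataFrame indexed by protein id, columns are sample ids, NaN marks
        a missing measurement.
    records
        Per-protein metadata aligned to ``values.index`` (gene_name and the
        reverse / contaminant / only-identified-by-site flags).
    channels
        Per-channel metadata aligned to ``values.columns`` (plex, channel
        index, role, sex, treatment).
    scale
        One of ``raw``, ``normalized``, ``log2``.
    meta
        Free-form provenance (filter counts, dropped-row logs, ...).
    """

    values: pd.DataFrame
    records: pd.DataFrame
    channels: pd.DataFrame
    scale: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.values.index.equals(self.records.index):
            raise InputError("values rows and records index differ")
        if not self.values.columns.equals(self.channels.index):
            raise InputError("values columns and channels index differ")
        if self.values.index.duplicated().any():
            raise InputError("protein ids must be unique")
        validate_channels(self.channels)

    # -- basic introspection -------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def plexes(self) -> list:
        return list(dict.fromkeys(self.channels["plex"]))

    def plex_samples(self, plex) -> list:
        return list(self.channels.index[self.channels["plex"] == plex])

    def pooled_samples(self, plex=None) -> list:
        sel = self.channels["role"] == ROLE_POOLED
        if plex is not None:
            sel &= self.channels["plex"] == plex
        return list(self.channels.index[sel])

    def experimental_samples(self, plex=None) -> list:
        sel = self.channels["role"] == ROLE_EXPERIMENTAL
        if plex is not None:
            sel &= self.channels["plex"] == plex
        return list(self.channels.index[sel])

    def group_labels(self) -> pd.Series:
        """Per-channel group code; pooled channels are labelled POOL."""
        out = []
        for sid, row in self.channels.iterrows():
            if row["role"] == ROLE_POOLED:
                out.append(POOL_GROUP)
            else:
                out.append(group_label(row["sex"], row["treatment"]))
        return pd.Series(out, index=self.channels.index, name="group")

    def group_samples(self, group: str) -> list:
        labels = self.group_labels()
        return list(labels.index[labels == group])

    # -- transforms ----------------------------------------------------------
    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.records.copy(), self.channels.copy(),
            self.scale, dict(self.meta),
        )

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "IntensityMatrix":
        return IntensityMatrix(
            values, self.records.loc[values.index].copy(), self.channels.copy(),
            scale or self.scale, dict(self.meta),
        )

    def subset_rows(self, ids: Iterable) -> "IntensityMatrix":
        ids = list(ids)
        return IntensityMatrix(
            self.values.loc[ids].copy(), self.records.loc[ids].copy(),
            self.channels.copy(), self.scale, dict(self.meta),
        )


@dataclass
class NormalizationFactors:
    """Factors recorded by the normalization chain."""

    sl_factors: pd.Series | None = None        # per channel
    tmm_factors: pd.Series | None = None       # per channel, anchored to product 1 per plex
    irs_factors: pd.DataFrame | None = None    # proteins x plexes
    method_batch: str = "none"                 # irs | linear_model | none


@dataclass
class QCReport:
    """Quality-control summaries of a log2 matrix."""

    channel_quartiles: pd.DataFrame        # per channel: q25, median, q75
    cv_per_protein: pd.DataFrame           # per protein x group, percent
    group_mean_cv: pd.Series               # percent, averaged over proteins
    pearson: pd.DataFrame                  # channel x channel correlation of log2 values
    pca_scores: pd.DataFrame               # channel x component
    explained_variance: np.ndarray         # fractions, non-increasing


@dataclass
class ComparisonResult:
    """Per-protein output of one pairwise moderated test.

    ``table`` is indexed by protein id with columns gene_name, log2_fc
    (test minus reference group mean), d (s0-moderated statistic), q_value,
    significant and direction ("up"/"down" by the sign of log2_fc).
    """

    label: str
    test_group: str
    reference_group: str
    table: pd.DataFrame
    s0: float
    fdr: float
    n_permutations: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def counts(self) -> dict:
        sig = self.significant
        return {
            "n_tested": len(self.table),
            "n_significant": len(sig),
            "n_up": int((sig["direction"] == "up").sum()),
            "n_down": int((sig["direction"] == "down").sum()),
        }


@dataclass
class GeneSetCollection:
    """Named gene sets with case-normalized (upper-cased) symbols."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        norm = {}
        for name, members in self.sets.items():
            members = frozenset(str(m).upper() for m in members)
            if not members:
                raise InputError(f"gene set {name!r} is empty")
            norm[name] = members
        self.sets = norm

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class EdgeTable:
    """Undirected scored edges; no self-loops, scores in [0, 1]."""

    frame: pd.DataFrame  # columns protein_a, protein_b, combined_score

    def __post_init__(self):
        f = self.frame
        req = ["protein_a", "protein_b", "combined_score"]
        if list(f.columns[:3]) != req:
            raise InputError(f"edge table must have columns {req}")
        if (f["protein_a"] == f["protein_b"]).any():
            raise InputError("edge table contains self-loops")
        s = f["combined_score"]
        if ((s < 0) | (s > 1)).any():
            raise InputError("combined scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)
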