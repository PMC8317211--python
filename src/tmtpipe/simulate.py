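"""Synthetic TMT 10-plex datasets with known ground truth.

The generator emulates the study design this pipeline targets: two TMT
10-plex runs, each carrying two biological replicates of the four sex x
treatment groups (MC, FC, MN, FN) on eight experimental channels plus two
pooled-reference channels mixing the eight experimental samples in equal
amounts. Protein abundances are log-normal; each channel has a multiplicative
loading factor; each plex adds a per-protein log2 batch shift (the artefact
internal reference scaling removes) plus a global plex loading shift (the
artefact sample-loading normalization removes); sparse sex and treatment
effects are injected with known sign and size; decoy and contaminant rows
and completely-at-random missing cells provide the nuisance structure the
row filters remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (GROUPS, POOL_GROUP, ROLE_EXPERIMENTAL, ROLE_POOLED,
                         EdgeTable, GeneSetCollection, IntensityMatrix)
from .errors import DesignError, InputError

_SEX = {"MC": "M", "MN": "M", "FC": "F", "FN": "F"}
_TRT = {"MC": "control", "FC": "control", "MN": "nicotine", "FN": "nicotine"}

#: contrast label -> ground-truth effect column
CONTRAST_EFFECTS = {
    "MC_vs_FC": "sex_effect",
    "FN_vs_FC": "trt_effect_f",
    "MN_vs_MC": "trt_effect_m",
}


@dataclass
class SyntheticDesign:
    """Parameters of one simulated TMT study.

    Defaults mirror the emulated design: 2 plexes, 2 replicates per group per
    plex (n = 4 per group), 2 pooled channels per plex. Effect sizes and
    nuisance rates are synthetic conventions, documented in the methods note.
    """

    n_proteins: int = 1000
    n_plexes: int = 2
    replicates_per_group_per_plex: int = 2
    n_pooled_per_plex: int = 2
    frac_sex_de: float = 0.1
    frac_trt_de_f: float = 0.1
    frac_trt_de_m: float = 0.1
    effect_size_log2: float = 1.0          # mean |log2 effect|
    effect_size_spread: float = 0.3        # sd of |log2 effect|
    sigma_within: float = 0.25             # within-group log2 sd
    base_mean_log2: float = 18.0           # log2 reporter-intensity location
    base_sd_log2: float = 2.0              # log2 dynamic-range spread
    loading_range: tuple = (0.7, 1.3)      # per-channel multiplicative loading
    plex_loading_range: tuple = (0.8, 1.25)  # global per-plex loading shift
    batch_shift_log2: float = 0.5          # per-protein, per-plex shift scale
    frac_decoy: float = 0.01
    frac_contaminant: float = 0.01
    frac_only_site: float = 0.005
    frac_missing: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_sex_de", "frac_trt_de_f", "frac_trt_de_m",
                     "frac_decoy", "frac_contaminant", "frac_only_site",
                     "frac_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignError(f"{name} must lie in [0, 1], got {v}")
        if self.n_proteins <= 0:
            raise DesignError("n_proteins must be positive")
        if self.n_plexes < 1:
            raise DesignError("n_plexes must be >= 1")
        if self.sigma_within < 0:
            raise DesignError("sigma_within must be >= 0")

    def null(self) -> "SyntheticDesign":
        """Copy with every true effect removed."""
        return replace(self, frac_sex_de=0.0, frac_trt_de_f=0.0, frac_trt_de_m=0.0)


@dataclass
class GroundTruth:
    """Per-protein simulated truth.

    ``table`` is indexed by protein id with columns base_log2, sex_effect
    (added to male groups), trt_effect_f (added to FN), trt_effect_m (added
    to MN); effects are exactly 0 for proteins not drawn as differential.
    Nuisance rows (decoys/contaminants) are absent from the table.
    """

    table: pd.DataFrame

    def effect(self, contrast: str) -> pd.Series:
        if contrast not in CONTRAST_EFFECTS:
            raise InputError(f"unknown contrast {contrast!r}; "
                             f"expected one of {sorted(CONTRAST_EFFECTS)}")
        return self.table[CONTRAST_EFFECTS[contrast]]


def _draw_effects(rng, n, frac, mean, spread):
    eff = np.zeros(n)
    k = int(round(frac * n))
    if k == 0:
        return eff
    idx = rng.choice(n, size=k, replace=False)
    mag = np.abs(rng.normal(mean, spread, size=k))
    mag = np.maximum(mag, 0.05)  # drawn-as-differential proteins get a real effect
    sign = rng.choice([-1.0, 1.0], size=k)
    eff[idx] = sign * mag
    return eff


def _make_channels(design: SyntheticDesign) -> pd.DataFrame:
    rows = []
    reps = design.replicates_per_group_per_plex
    for p in range(1, design.n_plexes + 1):
        plex = f"plex{p}"
        ch = 0
        for g in GROUPS:
            for r in range(reps):
                rows.append({
                    "sample_id": f"{g}{(p - 1) * reps + r + 1}_{plex}",
                    "plex": plex, "channel": ch, "role": ROLE_EXPERIMENTAL,
                    "sex": _SEX[g], "treatment": _TRT[g],
                })
                ch += 1
        for q in range(design.n_pooled_per_plex):
            rows.append({
                "sample_id": f"POOL{q + 1}_{plex}",
                "plex": plex, "channel": ch, "role": ROLE_POOLED,
                "sex": "none", "treatment": "none",
            })
            ch += 1
    return pd.DataFrame(rows).set_index("sample_id")


def generate_dataset(design: SyntheticDesign):
    """Simulate one study; returns ``(IntensityMatrix, GroundTruth)``.

    Per protein i and experimental channel j of plex p::

        log2 signal = base_i + group effects + batch_shift(i, p) + N(0, sigma_within)
        intensity   = plex_loading_p * loading_j * 2**signal

    Each pooled channel carries the arithmetic mean of its plex's eight
    experimental pre-loading intensities, times its own loading factor and
    measurement noise. Fully reproducible from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_proteins
    channels = _make_channels(design)

    base = rng.normal(design.base_mean_log2, design.base_sd_log2, size=n)
    sex_eff = _draw_effects(rng, n, design.frac_sex_de,
                            design.effect_size_log2, design.effect_size_spread)
    trt_f = _draw_effects(rng, n, design.frac_trt_de_f,
                          design.effect_size_log2, design.effect_size_spread)
    trt_m = _draw_effects(rng, n, design.frac_trt_de_m,
                          design.effect_size_log2, design.effect_size_spread)
    group_shift = {
        "MC": sex_eff, "FC": np.zeros(n), "MN": sex_eff + trt_m, "FN": trt_f,
    }
    if design.batch_shift_log2 > 0:
        batch = rng.normal(0.0, design.batch_shift_log2, size=(n, design.n_plexes))
    else:
        batch = np.zeros((n, design.n_plexes))

    ids = [f"P{i:06d}" for i in range(1, n + 1)]
    genes = [f"G{i:05d}" for i in range(1, n + 1)]
    lo, hi = design.loading_range
    plo, phi = design.plex_loading_range
    cols = {}
    for p in range(design.n_plexes):
        plex = f"plex{p + 1}"
        plex_loading = rng.uniform(plo, phi) if phi > plo else plo
        exp_ids = channels.index[(channels["plex"] == plex)
                                 & (channels["role"] == ROLE_EXPERIMENTAL)]
        pre_loading = {}
        for sid in exp_ids:
            row = channels.loc[sid]
            g = ("M" if row["sex"] == "M" else "F") + \
                ("C" if row["treatment"] == "control" else "N")
            noise = rng.normal(0.0, design.sigma_within, size=n) \
                if design.sigma_within > 0 else 0.0
            signal = base + group_shift[g] + batch[:, p] + noise
            pre_loading[sid] = np.exp2(signal)
        pool_base = np.mean(np.column_stack(list(pre_loading.values())), axis=1)
        for sid in exp_ids:
            loading = rng.uniform(lo, hi) if hi > lo else lo
            cols[sid] = plex_loading * loading * pre_loading[sid]
        pool_ids = channels.index[(channels["plex"] == plex)
                                  & (channels["role"] == ROLE_POOLED)]
        for sid in pool_ids:
            loading = rng.uniform(lo, hi) if hi > lo else lo
            noise = np.exp2(rng.normal(0.0, design.sigma_within, size=n)) \
                if design.sigma_within > 0 else 1.0
            cols[sid] = plex_loading * loading * pool_base * noise

    values = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))
    values = values[list(channels.index)]
    records = pd.DataFrame({
        "gene_name": genes,
        "is_reverse": False, "is_contaminant": False,
        "only_identified_by_site": False,
    }, index=values.index)

    # nuisance rows: decoys, contaminants, only-identified-by-site
    def _nuisance(count, prefix, flag):
        nonlocal values, records
        if count == 0:
            return
        nids = [f"{prefix}{i:04d}" for i in range(1, count + 1)]
        sig = rng.normal(design.base_mean_log2, design.base_sd_log2,
                         size=(count, values.shape[1]))
        vals = pd.DataFrame(np.exp2(sig), index=pd.Index(nids, name="protein_id"),
                            columns=values.columns)
        recs = pd.DataFrame({
            "gene_name": "", "is_reverse": False, "is_contaminant": False,
            "only_identified_by_site": False,
        }, index=vals.index)
        recs[flag] = True
        values = pd.concat([values, vals])
        records = pd.concat([records, recs])

    _nuisance(int(round(design.frac_decoy * n)), "REV__P", "is_reverse")
    _nuisance(int(round(design.frac_contaminant * n)), "CON__P", "is_contaminant")
    _nuisance(int(round(design.frac_only_site * n)), "SITE__P", "only_identified_by_site")

    if design.frac_missing > 0:
        mask = rng.random(values.shape) < design.frac_missing
        arr = values.to_numpy()
        arr[mask] = np.nan
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)

    matrix = IntensityMatrix(values, records, channels, scale="raw")
    truth = GroundTruth(pd.DataFrame({
        "base_log2": base, "sex_effect": sex_eff,
        "trt_effect_f": trt_f, "trt_effect_m": trt_m,
        "gene_name": genes,
    }, index=pd.Index(ids, name="protein_id")))
    return matrix, truth


def truth_confusion(truth: GroundTruth, result) -> dict:
    """Confusion counts of a ComparisonResult against the simulated truth.

    Positives are proteins with a nonzero true effect for the result's
    contrast. Returns TP/FP/TN/FN plus empirical FDR = FP / max(1, TP + FP)
    and sensitivity = TP / max(1, TP + FN), computed over the proteins the
    result actually tested (its universe must be a subset of the truth).
    """
    idx = result.table.index
    missing = idx.difference(truth.table.index)
    if len(missing):
        raise InputError(f"{len(missing)} result proteins absent from ground truth")
    true_pos = truth.effect(result.label).loc[idx] != 0.0
    called = result.table["significant"].to_numpy(dtype=bool)
    tp = int((called & true_pos).sum())
    fp = int((called & ~true_pos).sum())
    fn = int((~called & true_pos).sum())
    tn = int((~called & ~true_pos).sum())
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "fdr": fp / max(1, tp + fp),
        "sensitivity": tp / max(1, tp + fn),
    }


def generate_gene_sets(truth: GroundTruth, n_sets: int = 30,
                       set_size: tuple = (10, 40),
                       n_effect_sets: int = 6, seed: int = 0) -> GeneSetCollection:
    """Synthetic gene-set collection over the simulated gene universe.

    Most sets are random draws; ``n_effect_sets`` sets are seeded with genes
    carrying true effects so over-representation has signal to find.
    """
    rng = np.random.default_rng(seed)
    genes = truth.table["gene_name"].to_numpy()
    any_effect = ((truth.table[["sex_effect", "trt_effect_f", "trt_effect_m"]] != 0)
                  .any(axis=1).to_numpy())
    effect_genes = genes[any_effect]
    sets, desc = {}, {}
    for i in range(n_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        size = min(size, len(genes))
        if i < n_effect_sets and len(effect_genes) >= 3:
            k = min(max(3, size // 2), len(effect_genes))
            members = set(rng.choice(effect_genes, size=k, replace=False))
            rest = rng.choice(genes, size=size, replace=False)
            members |= set(rest[: size - len(members)])
        else:
            members = set(rng.choice(genes, size=size, replace=False))
        name = f"SET_{i + 1:03d}"
        sets[name] = members
        desc[name] = "synthetic pathway (planted)" if i < n_effect_sets \
            else "synthetic pathway (random)"
    return GeneSetCollection(sets, desc)


def generate_ppi_edges(truth: GroundTruth, n_complexes: int = 5,
                       complex_size: tuple = (5, 8),
                       n_random_edges: int = 300, seed: int = 0) -> EdgeTable:
    """Synthetic STRING-like edge table with planted dense complexes.

    Complexes are near-cliques of high-scoring edges drawn preferentially
    from genes with true effects; the background is random low-to-mid score
    edges over the whole gene universe.
    """
    rng = np.random.default_rng(seed)
    genes = truth.table["gene_name"].to_numpy()
    any_effect = ((truth.table[["sex_effect", "trt_effect_f", "trt_effect_m"]] != 0)
                  .any(axis=1).to_numpy())
    effect_genes = list(genes[any_effect])
    rows = []
    used = set()
    pool = effect_genes if len(effect_genes) >= complex_size[1] else list(genes)
    for _ in range(n_complexes):
        size = int(rng.integers(complex_size[0], complex_size[1] + 1))
        avail = [g for g in pool if g not in used]
        if len(avail) < size:
            break
        members = list(rng.choice(avail, size=size, replace=False))
        used.update(members)
        for i in range(size):
            for j in range(i + 1, size):
                if rng.random() < 0.9:  # near-clique
                    rows.append((members[i], members[j],
                                 float(rng.uniform(0.80, 0.999))))
    for _ in range(n_random_edges):
        a, b = rng.choice(genes, size=2, replace=False)
        rows.append((a, b, float(rng.uniform(0.15, 0.95))))
    frame = pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])
    frame = frame[frame["protein_a"] != frame["protein_b"]]
    swap = frame["protein_a"] > frame["protein_b"]
    lo = np.where(swap, frame["protein_b"], frame["protein_a"])
    hi = np.where(swap, frame["protein_a"], frame["protein_b"])
    frame = frame.assign(protein_a=lo, protein_b=hi)
    frame = (frame.groupby(["protein_a", "protein_b"], as_index=False)
             ["combined_score"].max())
    return EdgeTable(frame)


def write_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", float_format="%.10g")


def read_truth(path) -> GroundTruth:
    return GroundTruth(pd.read_csv(path, sep="\t", index_col="protein_id"))
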