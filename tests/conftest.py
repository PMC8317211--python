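import numpy as np
import pandas as pd
import pytest

from tmtpipe.containers import IntensityMatrix

GROUP_META = {
    "MC": ("M", "control"), "FC": ("F", "control"),
    "MN": ("M", "nicotine"), "FN": ("F", "nicotine"),
    "POOL": ("none", "none"),
}


def make_matrix(values, groups, plexes=None, scale="raw", ids=None, genes=None):
    """Build an IntensityMatrix from a 2-D array and per-column group codes.

    ``groups`` is a list like ["MC", "FC", "POOL", ...]; ``plexes`` defaults
    to a single plex. Channel indices are assigned in column order per plex.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if plexes is None:
        plexes = ["plex1"] * m
    ids = ids or [f"P{i:04d}" for i in range(1, n + 1)]
    genes = genes or [f"G{i:04d}" for i in range(1, n + 1)]
    counters = {}
    rows = []
    for j, (g, plex) in enumerate(zip(groups, plexes)):
        sex, trt = GROUP_META[g]
        ch = counters.get(plex, 0)
        counters[plex] = ch + 1
        rows.append({
            "sample_id": f"{g}{j + 1}_{plex}", "plex": plex, "channel": ch,
            "role": "pooled_reference" if g == "POOL" else "experimental",
            "sex": sex, "treatment": trt,
        })
    channels = pd.DataFrame(rows).set_index("sample_id")
    vals = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"),
                        columns=channels.index)
    records = pd.DataFrame({
        "gene_name": genes, "is_reverse": False, "is_contaminant": False,
        "only_identified_by_site": False,
    }, index=vals.index)
    return IntensityMatrix(vals, records, channels, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
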