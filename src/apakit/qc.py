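"""Run-level quality control: mapping-rate arithmetic and replicate PCA."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .diffexpr import size_factors

_CATEGORY_COLS = ("aligned_0", "aligned_1", "aligned_multi")


def mapping_summary(rows: pd.DataFrame | Sequence[Mapping]) -> pd.DataFrame:
    """Mapping rates from per-sample alignment category counts.

    Expects columns ``sample_id``, ``raw_reads``, ``low_quality``,
    ``aligned_0``, ``aligned_1``, ``aligned_multi``.  Mapped reads are
    those aligned at least once; the mapping rate (%) divides them by all
    reads that entered alignment (the sum of the three aligned categories)
    and is rounded to 2 decimals.
    """
    df = pd.DataFrame(rows).copy()
    for col in _CATEGORY_COLS:
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in {col}")
    denom = df[list(_CATEGORY_COLS)].sum(axis=1)
    if (denom <= 0).any():
        bad = df.loc[denom <= 0, "sample_id"].tolist()
        raise ValueError(f"zero aligned-category total for sample(s) {bad}")
    df["mapped_reads"] = df["aligned_1"] + df["aligned_multi"]
    df["mapping_rate_pct"] = (100.0 * df["mapped_reads"] / denom).round(2)
    return df


def replicate_pca(counts: pd.DataFrame, n_components: int = 2) -> dict:
    """PCA of samples on log2 size-factor-normalized counts (pseudocount 1).

    Returns ``coordinates`` (sample x PC frame) and ``variance_explained_pct``.
    Requires >= 3 samples; an all-constant matrix is an error.
    """
    if counts.shape[1] < 3:
        raise ValueError("replicate PCA needs >= 3 samples")
    sf = size_factors(counts)
    logn = np.log2(counts / sf + 1.0)
    mat = logn.to_numpy(dtype=float).T  # samples x features
    if np.allclose(mat, mat[0]):
        raise ValueError("constant count matrix; PCA undefined")
    n_components = min(n_components, counts.shape[1] - 1)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(mat - mat.mean(axis=0))
    return {
        "coordinates": pd.DataFrame(
            coords,
            index=counts.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        "variance_explained_pct": (100.0 * pca.explained_variance_ratio_).tolist(),
    }
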