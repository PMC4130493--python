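"""Gene-proximity covariates used for matched sentinel sets."""

from __future__ import annotations

import numpy as np
import pandas as pd


def gene_covariates(chroms, positions, genes: pd.DataFrame,
                    density_window_bp: int = 250_000) -> pd.DataFrame:
    """Distance to the nearest gene and gene count within a window.

    ``genes`` holds 1-based inclusive intervals (columns chrom/start/end).
    Distance is 0 for positions inside a gene; positions on a chromosome
    with no genes get distance +inf and count 0. The density count includes
    every gene whose span intersects [pos - w, pos + w].
    """
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    dist = np.full(len(positions), np.inf)
    count = np.zeros(len(positions), dtype=np.int64)
    for chrom, sub in genes.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        pos = positions[mask]
        starts = np.sort(sub["start"].to_numpy(np.int64))
        ends_sorted = np.sort(sub["end"].to_numpy(np.int64))
        # nearest distance: check each gene interval via candidate neighbours
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        order = np.argsort(s)
        s, e = s[order], e[order]
        # gap to gene = max(start - pos, pos - end, 0); take min over genes.
        # vectorised over genes per chromosome (gene lists are small here).
        if len(s):
            gap = np.maximum(s[None, :] - pos[:, None], pos[:, None] - e[None, :])
            d = np.maximum(gap, 0).min(axis=1)
        else:
            d = np.full(len(pos), np.inf)
        dist[mask] = d
        # count genes with start <= pos+w and end >= pos-w
        w = density_window_bp
        n_start_ok = np.searchsorted(starts, pos + w, side="right")
        n_end_lt = np.searchsorted(ends_sorted, pos - w, side="left")
        count[mask] = n_start_ok - n_end_lt
    return pd.DataFrame({"dist_nearest_gene": dist, "n_genes_250kb": count})
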