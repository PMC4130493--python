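"""Allele-frequency computation and frequency-class binning."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import FREQ_COLUMNS, MISSING, GenotypeMatrix, PopFreqTable

AF_CLASSES = ("rare", "low_frequency", "common")


def allele_frequencies(gm: GenotypeMatrix) -> PopFreqTable:
    """Per-population non-reference allele frequencies.

    af = alt_count / n_chrom with n_chrom = 2 x (non-missing samples at the
    site); missing genotypes never enter the denominator. A population with
    zero observed chromosomes at a site gets af = NaN (flagged, excluded
    downstream).
    """
    if gm.n_variants == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    frames = []
    meta = pd.DataFrame({
        "variant_id": [v.variant_id for v in gm.variants],
        "chrom": [v.chrom for v in gm.variants],
        "pos": [v.pos for v in gm.variants],
        "ref": [v.ref for v in gm.variants],
        "alt": [v.alt for v in gm.variants],
    })
    for pop in gm.populations:
        calls = gm.calls[gm.pop_mask(pop)]
        observed = calls != MISSING
        alt_count = np.where(observed, calls, 0).sum(axis=0)
        n_chrom = 2 * observed.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            af = np.where(n_chrom > 0, alt_count / np.maximum(n_chrom, 1), np.nan)
        sub = meta.copy()
        sub["pop"] = pop
        sub["alt_count"] = alt_count
        sub["n_chrom"] = n_chrom
        sub["af"] = af
        frames.append(sub)
    return PopFreqTable(pd.concat(frames, ignore_index=True)[FREQ_COLUMNS])


def classify_af(af: float, bounds: tuple[float, float] = (0.01, 0.05)) -> str:
    """Frequency class of one allele frequency.

    rare: af < bounds[0]; low_frequency: bounds[0] <= af < bounds[1];
    common: af >= bounds[1] (lower boundaries inclusive).
    """
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"allele frequency outside [0,1]: {af}")
    lo, hi = bounds
    if af < lo:
        return "rare"
    if af < hi:
        return "low_frequency"
    return "common"


def classify_af_array(af, bounds: tuple[float, float] = (0.01, 0.05)) -> np.ndarray:
    """Vectorised :func:`classify_af` over an array of frequencies."""
    af = np.asarray(af, dtype=float)
    if ((af < 0) | (af > 1)).any():
        raise ValueError("allele frequency outside [0,1]")
    lo, hi = bounds
    out = np.where(af < lo, "rare", np.where(af < hi, "low_frequency", "common"))
    return out.astype(object)
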