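"""Per-site Wright's F_ST between population pairs, summaries and
stratified-SNP selection.

Two estimators are provided. ``nei_gst`` is the parameter-level definition
(H_T - H_S)/H_T with H_T computed from the unweighted mean frequency of the
two populations. ``hudson`` applies the sample-size correction to the
numerator, (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1), over the
denominator p1(1-p2) + p2(1-p1); it is unbiased at the site level and is
the default for comparing a sequenced cohort against panel frequencies.

Negative per-site estimates are clipped to 0 in the ``fst`` column used for
selection and reporting; the unclipped value is retained in ``fst_raw``
because clipping inflates means near F = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .afreq import classify_af_array
from .types import PopFreqTable

ESTIMATORS = ("hudson", "nei_gst")


def fst_site(p1: float, n1: int, p2: float, n2: int,
             estimator: str = "hudson") -> float:
    """Unclipped per-site F_ST; NaN when both populations are monomorphic."""
    out = fst_components(np.array([p1]), np.array([n1]),
                         np.array([p2]), np.array([n2]), estimator)
    return float(out["fst_raw"][0])


def fst_components(p1, n1, p2, n2, estimator: str = "hudson") -> dict:
    """Vectorised per-site F_ST with audit components.

    Returns dict of arrays: fst (clipped to [0,1]), fst_raw, num, den,
    defined (False where both populations are monomorphic for the same
    allele, where the statistic is undefined).
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if estimator == "hudson":
        if (np.any(n1 < 2) or np.any(n2 < 2)):
            raise ValueError("hudson estimator needs >= 2 chromosomes per population")
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    else:
        pbar = (p1 + p2) / 2.0  # unweighted: panel sizes must not dominate H_T
        ht = 2.0 * pbar * (1.0 - pbar)
        hs = (2.0 * p1 * (1 - p1) + 2.0 * p2 * (1 - p2)) / 2.0
        num, den = ht - hs, ht
    defined = den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(defined, num / np.where(defined, den, 1.0), np.nan)
    return {
        "fst": np.clip(raw, 0.0, 1.0),
        "fst_raw": raw,
        "num": num,
        "den": den,
        "defined": defined,
    }


def fst_table(freqs: PopFreqTable, pop1: str, pop2: str,
              estimator: str = "hudson") -> pd.DataFrame:
    """Per-variant F_ST for one population pair.

    Joins the two populations on site identity; sites where either
    frequency is undefined (no observed chromosomes) are dropped, and
    ``present_both`` marks sites segregating (af > 0) in both populations.
    """
    pair = freqs.pair_frame(pop1, pop2)
    pair = pair[pair["af1"].notna() & pair["af2"].notna()].reset_index(drop=True)
    comp = fst_components(pair["af1"].to_numpy(), pair["n1"].to_numpy(),
                          pair["af2"].to_numpy(), pair["n2"].to_numpy(), estimator)
    out = pair[["variant_id", "chrom", "pos", "ref", "alt", "af1", "af2", "n1", "n2"]].copy()
    out["fst"] = comp["fst"]
    out["fst_raw"] = comp["fst_raw"]
    out["num"] = comp["num"]
    out["den"] = comp["den"]
    out["defined"] = comp["defined"]
    out["present_both"] = (pair["af1"] > 0) & (pair["af2"] > 0)
    out["estimator"] = estimator
    return out


def mean_fst(table: pd.DataFrame, restrict_present_both: bool = True) -> dict:
    """Multi-locus F_ST summaries over defined sites.

    Emits three conventions, because they differ near F = 0:

    * ``ratio_of_averages`` - sum of per-site numerators over sum of
      denominators; the standard combined Hudson estimator and the headline
      mean (unbiased under the drift model).
    * ``mean`` - arithmetic mean of unclipped per-site values.
    * ``mean_clipped`` - arithmetic mean after clipping negatives to 0.

    By default restricted to SNPs present (af > 0) in both populations.
    """
    sub = table[table["defined"]]
    if restrict_present_both:
        sub = sub[sub["present_both"]]
    if sub.empty:
        raise ValueError("no defined sites for this pair")
    return {
        "ratio_of_averages": float(sub["num"].sum() / sub["den"].sum()),
        "mean": float(sub["fst_raw"].mean()),
        "mean_clipped": float(sub["fst"].mean()),
        "n_sites": int(len(sub)),
    }


def select_stratified(table: pd.DataFrame, threshold: float = 0.10) -> pd.DataFrame:
    """Sites with clipped F_ST strictly greater than ``threshold``."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0,1]")
    return table[table["defined"] & (table["fst"] > threshold)].reset_index(drop=True)


def sharing_fraction(source: pd.DataFrame, panel: pd.DataFrame,
                     bounds: tuple[float, float] = (0.01, 0.05)) -> pd.DataFrame:
    """Fraction of source-population variants present in a panel, by AF class.

    ``source`` and ``panel`` are single-population frequency frames (columns
    chrom/pos/ref/alt/af). A source variant is shared when the panel holds
    the same site with af > 0; bins with no variants are reported with a
    NaN fraction.
    """
    present = set(map(tuple, panel.loc[panel["af"] > 0, ["chrom", "pos", "ref", "alt"]]
                      .itertuples(index=False, name=None)))
    src = source[source["af"].notna() & (source["af"] > 0)].copy()
    src["af_class"] = classify_af_array(src["af"].to_numpy(), bounds)
    src["shared"] = [
        key in present
        for key in src[["chrom", "pos", "ref", "alt"]].itertuples(index=False, name=None)
    ]
    rows = []
    for cls in ("rare", "low_frequency", "common"):
        sub = src[src["af_class"] == cls]
        frac = float(sub["shared"].mean()) if len(sub) else float("nan")
        rows.append((cls, len(sub), frac))
    return pd.DataFrame(rows, columns=["af_class", "n_variants", "fraction_shared"])
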