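"""Functional-class enrichment and the matched-sentinel permutation test.

``class_enrichment`` asks whether a stratum of variants (e.g. those with
F_ST above a threshold, or the novel variants in an AF bin) carries more of
a functional class than the background, via a 2x2 Pearson chi-square
(no continuity correction; a Monte-Carlo hypergeometric fallback guards the
small-count regime). ``permutation_enrichment`` compares the number of
stratified SNPs near real GWAS sentinels with a null distribution built
from random sentinel sets matched on allele frequency, gene proximity and
local gene density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .afreq import classify_af_array
from .types import SentinelCatalog


@dataclass
class ClassEnrichmentResult:
    stratum: str
    func_class: str
    n_stratum: int
    observed: int
    expected: float
    fold: float
    chi2: float
    p_value: float
    method: str  # "chi2" or "resampling"

    def __post_init__(self) -> None:
        if self.observed > self.n_stratum:
            raise ValueError("observed exceeds stratum size")


@dataclass
class EnrichmentResult:
    phenotype: str
    observed: int
    expected: float
    fold: float
    p_exact: float
    n_perm: int
    window_bp: int
    null_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_exact <= 1.0):
            raise ValueError("permutation p must lie in (0,1]")


def class_enrichment(class_labels, stratum_mask, func_class: str,
                     stratum_name: str = "stratum",
                     background: str = "all",
                     min_expected: float = 5.0,
                     n_resample: int = 100_000,
                     rng: np.random.Generator | None = None) -> ClassEnrichmentResult:
    """Enrichment of one functional class inside a stratum of variants.

    fold = (class fraction in the stratum) / (class fraction in the
    background), where the background is all analysed variants
    (``background="all"``) or the stratum's complement
    (``background="complement"``). The chi-square test is always on the 2x2
    in/out-stratum x in/out-class table; when any expected cell falls below
    ``min_expected`` the p-value comes from Monte-Carlo resampling of the
    stratum-class cell under fixed margins (hypergeometric null) instead.
    """
    labels = np.asarray(class_labels, dtype=object)
    mask = np.asarray(stratum_mask, dtype=bool)
    if labels.shape != mask.shape:
        raise ValueError("class labels and stratum mask must align")
    if not mask.any():
        raise ValueError("empty stratum")
    in_class = labels == func_class
    n_total = len(labels)
    n_stratum = int(mask.sum())
    n_class_total = int(in_class.sum())
    observed = int((mask & in_class).sum())

    if background == "all":
        bg_frac = n_class_total / n_total
    elif background == "complement":
        out = ~mask
        bg_frac = in_class[out].mean() if out.any() else np.nan
    else:
        raise ValueError("background must be 'all' or 'complement'")
    if bg_frac == 0 or np.isnan(bg_frac):
        fold = float("nan")  # flagged: no background members of the class
    else:
        fold = (observed / n_stratum) / bg_frac
    expected = n_stratum * (n_class_total / n_total)

    table = np.array([
        [observed, n_stratum - observed],
        [n_class_total - observed, (n_total - n_stratum) - (n_class_total - observed)],
    ], dtype=float)
    exp_cells = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if (exp_cells >= min_expected).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        method = "chi2"
    else:
        chi2 = _chi2_stat(table)
        rng = np.random.default_rng(0) if rng is None else rng
        draws = rng.hypergeometric(n_class_total, n_total - n_class_total,
                                   n_stratum, size=n_resample)
        null_stats = _chi2_cellwise(draws, n_stratum, n_class_total, n_total)
        p = (1 + int((null_stats >= chi2 - 1e-12).sum())) / (1 + n_resample)
        method = "resampling"
    return ClassEnrichmentResult(stratum=stratum_name, func_class=func_class,
                                 n_stratum=n_stratum, observed=observed,
                                 expected=float(expected), fold=float(fold),
                                 chi2=float(chi2), p_value=float(p), method=method)


def _chi2_stat(table: np.ndarray) -> float:
    exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (table - exp) ** 2 / exp, 0.0)
    return float(terms.sum())


def _chi2_cellwise(a, n_stratum, n_class, n_total):
    """Chi-square statistics of 2x2 tables parameterised by the (1,1) cell."""
    a = np.asarray(a, dtype=float)
    b = n_stratum - a
    c = n_class - a
    d = (n_total - n_stratum) - c
    n = float(n_total)
    # standard 2x2 identity: chi2 = n (ad-bc)^2 / (row/col margin product)
    margins = n_stratum * (n - n_stratum) * n_class * (n - n_class)
    return n * (a * d - b * c) ** 2 / margins


def af_class_depletion(afs, novel_mask, class_labels, func_class: str,
                       bounds: tuple[float, float] = (0.01, 0.05),
                       background: str = "all",
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-AF-bin enrichment of a class among novel (vs all) variants.

    Applies :func:`class_enrichment` within each allele-frequency class
    with the novel variants as the stratum; folds below 1 indicate
    depletion (selection against new functional alleles).
    """
    afs = np.asarray(afs, dtype=float)
    novel = np.asarray(novel_mask, dtype=bool)
    labels = np.asarray(class_labels, dtype=object)
    bins = classify_af_array(afs, bounds)
    rows = []
    for cls in ("rare", "low_frequency", "common"):
        sel = bins == cls
        if not sel.any() or not novel[sel].any():
            continue
        res = class_enrichment(labels[sel], novel[sel], func_class,
                               stratum_name=f"novel@{cls}",
                               background=background, rng=rng)
        rows.append({"af_class": cls, "func_class": func_class,
                     "n_bin": int(sel.sum()), "n_novel": int(novel[sel].sum()),
                     "observed": res.observed, "fold": res.fold,
                     "chi2": res.chi2, "p_value": res.p_value,
                     "method": res.method})
    return pd.DataFrame(rows)


def count_stratified_near_sentinels(stratified: pd.DataFrame,
                                    sentinels: pd.DataFrame,
                                    window_bp: int = 500_000) -> int:
    """Distinct stratified SNPs within the closed window [pos-w, pos+w] of
    any sentinel (union semantics: a SNP inside two windows counts once)."""
    if len(sentinels) == 0:
        raise ValueError("empty sentinel list")
    if len(stratified) == 0:
        return 0
    total = 0
    sent_by_chrom = {c: np.sort(g["pos"].to_numpy(np.int64))
                     for c, g in sentinels.groupby("chrom")}
    for chrom, sub in stratified.groupby("chrom"):
        spos = sent_by_chrom.get(chrom)
        if spos is None:
            continue
        pos = sub["pos"].to_numpy(np.int64)
        idx = np.searchsorted(spos, pos)
        left = np.where(idx > 0, pos - spos[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
        right = np.where(idx < len(spos), spos[np.minimum(idx, len(spos) - 1)] - pos,
                         np.iinfo(np.int64).max)
        total += int((np.minimum(left, right) <= window_bp).sum())
    return total


def matched_pool_indices(sentinels: SentinelCatalog, pool: pd.DataFrame,
                         af_tol: float = 0.02, gene_prox_tol_bp: int = 10_000,
                         gene_count_tol: int = 2) -> list[np.ndarray]:
    """Eligible pool indices per sentinel under the covariate tolerances.

    A pool variant matches a sentinel when |d af| <= af_tol,
    |d dist_nearest_gene| <= gene_prox_tol_bp and |d n_genes_250kb| <=
    gene_count_tol; a sentinel never matches its own pool entry.
    """
    af = pool["af"].to_numpy(float)
    dist = pool["dist_nearest_gene"].to_numpy(float)
    ngene = pool["n_genes_250kb"].to_numpy(float)
    ids = pool["variant_id"].to_numpy(object)
    out = []
    for row in sentinels.entries.itertuples(index=False):
        ok = (np.abs(af - row.af) <= af_tol)
        ok &= np.abs(dist - row.dist_nearest_gene) <= gene_prox_tol_bp
        ok &= np.abs(ngene - row.n_genes_250kb) <= gene_count_tol
        ok &= ids != row.variant_id
        out.append(np.flatnonzero(ok))
    return out


def draw_matched_set(sentinels: SentinelCatalog, pool: pd.DataFrame,
                     rng: np.random.Generator,
                     af_tol: float = 0.02, gene_prox_tol_bp: int = 10_000,
                     gene_count_tol: int = 2,
                     on_empty: str = "drop",
                     eligibility: list[np.ndarray] | None = None) -> pd.DataFrame:
    """One random sentinel set matched covariate-wise to the real sentinels.

    One pool SNP per sentinel, uniform among eligible, without replacement
    within the set. A sentinel with no eligible match is dropped
    (``on_empty="drop"``, logged via the returned frame's length) or raises
    (``on_empty="error"``).
    """
    elig = (matched_pool_indices(sentinels, pool, af_tol, gene_prox_tol_bp,
                                 gene_count_tol)
            if eligibility is None else eligibility)
    chosen = _draw_one(elig, rng, on_empty)
    return pool.iloc[chosen].reset_index(drop=True)


def _draw_one(elig: list[np.ndarray], rng: np.random.Generator,
              on_empty: str = "drop") -> list[int]:
    chosen: list[int] = []
    used: set[int] = set()
    for i, cand in enumerate(elig):
        if len(cand) == 0:
            if on_empty == "drop":
                continue
            raise ValueError(f"sentinel {i} has no eligible matched SNP")
        pick = int(cand[rng.integers(0, len(cand))])
        tries = 0
        while pick in used:
            avail = [c for c in cand if c not in used]
            if not avail:
                if on_empty == "drop":
                    pick = None
                    break
                raise ValueError(f"sentinel {i} exhausted its match pool within this set")
            pick = int(avail[rng.integers(0, len(avail))])
            tries += 1
        if pick is not None:
            used.add(pick)
            chosen.append(pick)
    return chosen


def permutation_enrichment(stratified: pd.DataFrame, sentinels: SentinelCatalog,
                           pool: pd.DataFrame, n_perm: int = 10_000,
                           window_bp: int = 500_000,
                           rng: np.random.Generator | None = None,
                           af_tol: float = 0.02, gene_prox_tol_bp: int = 10_000,
                           gene_count_tol: int = 2,
                           keep_null: bool = False) -> EnrichmentResult:
    """Matched-permutation test for enrichment of stratified SNPs at GWAS loci.

    observed = distinct stratified SNPs within ``window_bp`` of the real
    sentinels; the null distribution is the same count over ``n_perm``
    covariate-matched random sentinel sets; expected = null mean;
    fold = observed/expected (inf flagged when expected is 0 but observed
    > 0); p_exact = (1 + #{null >= observed}) / (1 + n_perm), the add-one
    permutation estimator, so p is always positive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    observed = count_stratified_near_sentinels(stratified, sentinels.entries, window_bp)
    elig = matched_pool_indices(sentinels, pool, af_tol, gene_prox_tol_bp,
                                gene_count_tol)
    dropped = sum(1 for e in elig if len(e) == 0)
    if dropped:
        # drop unmatched sentinels from the observed count too, so observed
        # and null are computed over the same sentinel structure
        keep = [i for i, e in enumerate(elig) if len(e) > 0]
        sub = SentinelCatalog(sentinels.phenotype,
                              sentinels.entries.iloc[keep].reset_index(drop=True))
        observed = count_stratified_near_sentinels(stratified, sub.entries, window_bp)
        elig = [elig[i] for i in keep]

    # membership matrix: pool variant x stratified SNP within window
    null_counts = _null_counts(stratified, pool, elig, n_perm, window_bp, rng)
    expected = float(null_counts.mean())
    if expected > 0:
        fold = observed / expected
    else:
        fold = float("inf") if observed > 0 else 0.0
    p = (1 + int((null_counts >= observed).sum())) / (1 + n_perm)
    return EnrichmentResult(phenotype=sentinels.phenotype, observed=int(observed),
                            expected=expected, fold=float(fold), p_exact=float(p),
                            n_perm=n_perm, window_bp=window_bp,
                            null_counts=null_counts if keep_null else None)


def _null_counts(stratified: pd.DataFrame, pool: pd.DataFrame,
                 elig: list[np.ndarray], n_perm: int, window_bp: int,
                 rng: np.random.Generator) -> np.ndarray:
    n_strat = len(stratified)
    mask = np.zeros((len(pool), max(n_strat, 1)), dtype=bool)
    if n_strat:
        strat_by_chrom = {c: np.sort(np.flatnonzero((stratified["chrom"] == c).to_numpy()))
                          for c in stratified["chrom"].unique()}
        spos = stratified["pos"].to_numpy(np.int64)
        pool_chrom = pool["chrom"].to_numpy(object)
        pool_pos = pool["pos"].to_numpy(np.int64)
        for chrom, sidx in strat_by_chrom.items():
            pmask = pool_chrom == chrom
            if not pmask.any():
                continue
            positions = np.sort(spos[sidx])
            order = np.argsort(spos[sidx])
            sidx_sorted = sidx[order]
            ppos = pool_pos[pmask]
            lo = np.searchsorted(positions, ppos - window_bp, side="left")
            hi = np.searchsorted(positions, ppos + window_bp, side="right")
            prow = np.flatnonzero(pmask)
            for r, l, h in zip(prow, lo, hi):
                if h > l:
                    mask[r, sidx_sorted[l:h]] = True
    counts = np.empty(n_perm, dtype=np.int64)
    for t in range(n_perm):
        sel = _draw_one(elig, rng, on_empty="drop")
        counts[t] = mask[sel].any(axis=0).sum() if sel else 0
    return counts
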