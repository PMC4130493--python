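"""Synthetic multi-population cohort generator.

Emulates the statistical structure that the downstream analyses assume,
without any real data:

* per-population allele frequencies diverged from a shared ancestral
  frequency under the Balding-Nichols drift model (beta with mean p and
  variance F.p(1-p));
* Hardy-Weinberg diploid genotypes within each population;
* a low-coverage genotype-error process that undercalls heterozygotes,
  depressing the observed Het/Hom ratio;
* functional-class labels with optional class-dependent constraint
  (coding classes drift less and are less often novel at high frequency);
* GWAS-style sentinel catalogues with allele-frequency and gene-proximity
  covariates, with an optional positive-control enrichment mode.

All draws flow from one ``numpy`` Generator seeded from the spec, so every
output is bit-reproducible under a fixed seed. Sites are independent: no
linkage disequilibrium, haplotype structure or admixture is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .afreq import classify_af_array
from .genes import gene_covariates
from .types import (
    MISSING,
    FUNC_CLASSES,
    CODING_CLASSES,
    GenotypeMatrix,
    PopFreqTable,
    SentinelCatalog,
    VariantRecord,
)

# genome-wide share of each functional class (order matches FUNC_CLASSES);
# coding classes are ~1-2% of sites, as in human resequencing catalogues
DEFAULT_CLASS_PROPORTIONS = {
    "nonsynonymous": 0.010,
    "synonymous": 0.008,
    "stop": 0.0004,
    "splice": 0.0016,
    "utr5": 0.005,
    "utr3": 0.015,
    "intronic": 0.340,
    "intergenic": 0.600,
    "other": 0.020,
}

# fraction of variants absent from the known-variant set, by frequency class:
# most novel discoveries are rare, few are common
DEFAULT_NOVELTY_RATE = {"rare": 0.50, "low_frequency": 0.15, "common": 0.02}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    drift_f is the per-population Balding-Nichols F (dimensionless, in
    (0,1)); het_undercall_rate m is the probability that a true heterozygote
    is rendered homozygous by the low-coverage caller. The default m = 1 -
    1.05/1.55 makes a cohort with true Het/Hom ~1.55 read out at ~1.05 under
    the ref-collapse mode. class_constraint multiplies F per class; values
    < 1 for coding classes emulate purifying constraint on divergence.
    """

    n_samples: tuple[int, ...] = (100, 100)
    n_variants: int = 20_000
    pop_names: tuple[str, ...] = ("SA", "EUR")
    drift_f: tuple[float, ...] = (0.010, 0.010)
    ancestral_beta: tuple[float, float] = (0.3, 0.3)
    ancestral_af_bounds: tuple[float, float] = (0.001, 0.999)
    het_undercall_rate: float = 1.0 - 1.05 / 1.55
    het_collapse: str = "ref"  # "ref" | "split"
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    class_constraint: dict = field(default_factory=dict)  # per-class multiplier on F
    novelty_rate: dict = field(default_factory=lambda: dict(DEFAULT_NOVELTY_RATE))
    chrom_lengths: dict = field(default_factory=lambda: {"1": 120_000_000, "2": 100_000_000})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_samples) != len(self.pop_names) or len(self.drift_f) != len(self.pop_names):
            raise ValueError("n_samples, drift_f and pop_names must have equal length")
        for f in self.drift_f:
            if not (0.0 < f < 1.0):
                raise ValueError(f"Balding-Nichols F must lie in (0,1), got {f}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - set(FUNC_CLASSES)
        if unknown:
            raise ValueError(f"unknown functional classes {sorted(unknown)}")
        if not (0.0 <= self.het_undercall_rate < 1.0):
            raise ValueError("het_undercall_rate must be in [0,1)")
        if self.het_collapse not in {"ref", "split"}:
            raise ValueError("het_collapse must be 'ref' or 'split'")
        for rate in self.novelty_rate.values():
            if not (0.0 <= rate <= 1.0):
                raise ValueError("novelty rates must be in [0,1]")

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class TruthSet:
    """Error-free genotypes plus the latent quantities that generated them."""

    spec: CohortSpec
    genotypes: GenotypeMatrix          # true calls, no error process
    ancestral_af: np.ndarray           # (n_variants,)
    pop_af: np.ndarray                 # (n_pops, n_variants), the latent BN draws
    effective_f: np.ndarray            # (n_pops, n_variants) after class constraint

    def __post_init__(self) -> None:
        if self.pop_af.shape != (self.spec.n_pops, self.spec.n_variants):
            raise ValueError("pop_af shape does not match spec")

    def true_freq_table(self) -> PopFreqTable:
        """Latent per-population frequencies as a PopFreqTable (n_chrom = 2N)."""
        frames = []
        for k, pop in enumerate(self.spec.pop_names):
            n_chrom = 2 * self.spec.n_samples[k]
            af = self.pop_af[k]
            frames.append(pd.DataFrame({
                "variant_id": [v.variant_id for v in self.genotypes.variants],
                "chrom": [v.chrom for v in self.genotypes.variants],
                "pos": [v.pos for v in self.genotypes.variants],
                "ref": [v.ref for v in self.genotypes.variants],
                "alt": [v.alt for v in self.genotypes.variants],
                "pop": pop,
                "alt_count": np.round(af * n_chrom).astype(int),
                "n_chrom": n_chrom,
                "af": af,
            }))
        return PopFreqTable(pd.concat(frames, ignore_index=True))


_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}


def _unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions on a chromosome, sorted."""
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while len(pos) < n:  # top up rare collisions
        extra = rng.integers(1, length + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n]


def _variant_records(spec: CohortSpec, rng: np.random.Generator,
                     classes: np.ndarray) -> list[VariantRecord]:
    """Place variants uniformly on the spec's chromosomes with random alleles.

    Transition alts are favoured 2:1 so synthetic call sets have a Ti/Tv
    above 1 (real catalogues sit near 2); positions are unique per
    chromosome.
    """
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=spec.n_variants, p=lengths / lengths.sum())
    records: list[VariantRecord] = []
    positions = np.empty(spec.n_variants, dtype=np.int64)
    for ci in range(len(chroms)):
        mask = chrom_idx == ci
        n = int(mask.sum())
        if n:
            positions[mask] = _unique_positions(rng, spec.chrom_lengths[chroms[ci]], n)
    refs = _BASES[rng.integers(0, 4, size=spec.n_variants)]
    u = rng.random(spec.n_variants)
    tv_pick = rng.integers(0, 2, size=spec.n_variants)
    for i in range(spec.n_variants):
        ref = refs[i]
        if u[i] < 2 / 3:
            alt = _TRANSITION[ref]
        else:
            alt = _TRANSVERSIONS[ref][tv_pick[i]]
        records.append(VariantRecord(chrom=chroms[chrom_idx[i]], pos=int(positions[i]),
                                     ref=str(ref), alt=str(alt),
                                     func_class=str(classes[i])))
    return records


def simulate_frequencies(spec: CohortSpec, rng: np.random.Generator | None = None):
    """Draw ancestral and per-population allele frequencies.

    Ancestral p ~ Beta(a, b) truncated to ``ancestral_af_bounds``; each
    population's frequency ~ Beta with mean p and variance F_eff.p(1-p)
    (Balding-Nichols), where F_eff = drift_f[pop] x class_constraint[class].

    Returns (classes, ancestral_af, pop_af, effective_f).
    """
    rng = spec.rng() if rng is None else rng
    a, b = spec.ancestral_beta
    lo, hi = spec.ancestral_af_bounds
    p = np.clip(rng.beta(a, b, size=spec.n_variants), lo, hi)

    labels = list(spec.class_proportions)
    probs = np.array([spec.class_proportions[c] for c in labels])
    classes = np.array(labels, dtype=object)[rng.choice(len(labels), size=spec.n_variants, p=probs)]
    constraint = np.array([spec.class_constraint.get(c, 1.0) for c in classes])

    pop_af = np.empty((spec.n_pops, spec.n_variants))
    eff_f = np.empty((spec.n_pops, spec.n_variants))
    for k in range(spec.n_pops):
        f = spec.drift_f[k] * constraint
        eff_f[k] = f
        # Beta(p(1-F)/F, (1-p)(1-F)/F): mean p, variance F p (1-p)
        with np.errstate(divide="ignore"):
            alpha = p * (1.0 - f) / f
            beta = (1.0 - p) * (1.0 - f) / f
        draw = rng.beta(np.maximum(alpha, 1e-12), np.maximum(beta, 1e-12))
        pop_af[k] = np.where(f < 1e-9, p, draw)
    return classes, p, pop_af, eff_f


def simulate_genotypes(spec: CohortSpec,
                       rng: np.random.Generator | None = None) -> TruthSet:
    """Full truth-set draw: frequencies, variant placement, HWE genotypes,
    novelty labels."""
    rng = spec.rng() if rng is None else rng
    classes, p, pop_af, eff_f = simulate_frequencies(spec, rng)
    records = _variant_records(spec, rng, classes)

    n_total = sum(spec.n_samples)
    calls = np.empty((n_total, spec.n_variants), dtype=np.int8)
    pops: list[str] = []
    sample_ids: list[str] = []
    row = 0
    for k, pop in enumerate(spec.pop_names):
        n = spec.n_samples[k]
        calls[row:row + n] = rng.binomial(2, pop_af[k], size=(n, spec.n_variants))
        pops.extend([pop] * n)
        sample_ids.extend(f"{pop}_{i:04d}" for i in range(n))
        row += n

    # novelty: rate depends on the cohort-level AF class; under constraint,
    # coding novel variants are additionally suppressed outside the rare bin
    # (purifying selection keeps new functional alleles from rising in AF)
    cohort_af = np.average(pop_af, axis=0, weights=np.array(spec.n_samples, dtype=float))
    af_class = classify_af_array(cohort_af)
    base = np.array([spec.novelty_rate.get(c, 0.0) for c in af_class])
    constraint = np.array([spec.class_constraint.get(c, 1.0) for c in classes])
    nonrare = af_class != "rare"
    rate = np.where(nonrare, base * constraint, base)
    novel = rng.random(spec.n_variants) < rate
    records = [
        VariantRecord(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                      func_class=v.func_class, is_novel=bool(novel[i]))
        for i, v in enumerate(records)
    ]

    gm = GenotypeMatrix(sample_ids=sample_ids, variants=records, calls=calls,
                        pop_labels=pops)
    return TruthSet(spec=spec, genotypes=gm, ancestral_af=p, pop_af=pop_af,
                    effective_f=eff_f)


def inject_lowcov_errors(truth: TruthSet, m: float | None = None,
                         mode: str | None = None,
                         rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Apply the heterozygote-undercall error process.

    Each true heterozygote is independently rendered homozygous with
    probability m. In ``"ref"`` mode (default) the miscall collapses to the
    reference homozygote - the dominant failure at ~4x coverage, where the
    alternate allele is simply never sampled - giving an observed Het/Hom
    ratio of (1-m) x the true ratio in expectation. ``"split"`` mode sends
    miscalled hets to 0 or 2 with equal probability.
    """
    spec = truth.spec
    m = spec.het_undercall_rate if m is None else m
    mode = spec.het_collapse if mode is None else mode
    if not (0.0 <= m < 1.0):
        raise ValueError("het undercall rate must be in [0,1)")
    if mode not in {"ref", "split"}:
        raise ValueError("mode must be 'ref' or 'split'")
    rng = np.random.default_rng(spec.rng_seed + 1) if rng is None else rng
    gm = truth.genotypes
    calls = gm.calls.copy()
    het = calls == 1
    miscall = het & (rng.random(calls.shape) < m)
    if mode == "ref":
        calls[miscall] = 0
    else:
        calls[miscall] = np.where(rng.random(int(miscall.sum())) < 0.5, 0, 2)
    return GenotypeMatrix(sample_ids=list(gm.sample_ids), variants=list(gm.variants),
                          calls=calls, pop_labels=list(gm.pop_labels))


def simulate_gene_bed(spec: CohortSpec, n_genes: int = 300,
                      mean_len: int = 60_000,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Random gene intervals (1-based inclusive) on the spec's chromosomes."""
    rng = np.random.default_rng(spec.rng_seed + 2) if rng is None else rng
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_genes, p=lengths / lengths.sum())
    rows = []
    for g in range(n_genes):
        c = chroms[chrom_idx[g]]
        glen = max(1000, int(rng.exponential(mean_len)))
        start = int(rng.integers(1, max(2, spec.chrom_lengths[c] - glen)))
        rows.append((c, start, start + glen - 1, f"gene{g:04d}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def variant_pool(truth: TruthSet, genes: pd.DataFrame,
                 af_pop: str | None = None) -> pd.DataFrame:
    """Annotate every simulated variant with the sentinel-matching covariates.

    Returns a frame with variant_id/chrom/pos/af/dist_nearest_gene/
    n_genes_250kb plus the per-variant absolute between-population AF
    divergence (|af_pop1 - af_pop2|) for positive-control placement.
    """
    spec = truth.spec
    variants = truth.genotypes.variants
    k = 0 if af_pop is None else list(spec.pop_names).index(af_pop)
    chroms = [v.chrom for v in variants]
    pos = [v.pos for v in variants]
    cov = gene_covariates(chroms, pos, genes)
    div = (np.abs(truth.pop_af[0] - truth.pop_af[1])
           if spec.n_pops >= 2 else np.zeros(spec.n_variants))
    return pd.DataFrame({
        "variant_id": [v.variant_id for v in variants],
        "chrom": chroms,
        "pos": pos,
        "af": truth.pop_af[k],
        "dist_nearest_gene": cov["dist_nearest_gene"].to_numpy(),
        "n_genes_250kb": cov["n_genes_250kb"].to_numpy(),
        "divergence": div,
    })


def simulate_sentinels(truth: TruthSet, genes: pd.DataFrame, n_sentinels: int,
                       phenotype: str = "phenotype",
                       enrichment_strength: float = 0.0,
                       rng: np.random.Generator | None = None) -> SentinelCatalog:
    """Sample sentinel SNPs from the simulated variants.

    With ``enrichment_strength == 0`` sentinels are uniform over the pool
    (null calibration). Positive strength weights selection by
    exp(strength x normalised between-population divergence), placing
    sentinels preferentially near stratified variation - a positive-control
    signal of configurable size.
    """
    rng = np.random.default_rng(truth.spec.rng_seed + 3) if rng is None else rng
    pool = variant_pool(truth, genes)
    if n_sentinels > len(pool):
        raise ValueError(f"n_sentinels={n_sentinels} exceeds pool of {len(pool)} variants")
    if enrichment_strength == 0.0:
        w = np.ones(len(pool))
    else:
        div = pool["divergence"].to_numpy()
        scale = div.max() if div.max() > 0 else 1.0
        w = np.exp(enrichment_strength * div / scale)
    idx = rng.choice(len(pool), size=n_sentinels, replace=False, p=w / w.sum())
    entries = pool.iloc[np.sort(idx)].drop(columns="divergence").reset_index(drop=True)
    return SentinelCatalog(phenotype=phenotype, entries=entries)
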