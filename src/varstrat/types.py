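"""Core domain containers for multi-population variant call-set analysis.

The objects here are deliberately thin: a variant site, a diploid genotype
matrix with population labels, a long-format per-population allele-frequency
table, and a GWAS sentinel catalogue carrying the covariates used for
matched-permutation null sets (allele frequency, distance to the nearest
gene, and gene density within 250 kb).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Missing-genotype sentinel in :class:`GenotypeMatrix.calls`.
MISSING = -1

#: Recognised functional-class labels (one label per variant).
FUNC_CLASSES = (
    "nonsynonymous",
    "synonymous",
    "stop",
    "splice",
    "utr5",
    "utr3",
    "intronic",
    "intergenic",
    "other",
)

#: Precedence applied when an annotation source lists several classes for one
#: variant: the most consequential label wins.
CLASS_PRECEDENCE = (
    "stop",
    "splice",
    "nonsynonymous",
    "synonymous",
    "utr5",
    "utr3",
    "intronic",
    "intergenic",
    "other",
)

#: Classes counted as "coding" in enrichment/depletion analyses.
CODING_CLASSES = ("nonsynonymous", "synonymous", "stop", "splice")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant site (1-based, inclusive coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    func_class: str = "other"
    is_novel: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown functional class {self.func_class!r}")

    @property
    def vtype(self) -> str:
        """``"SNP"`` iff both alleles are single bases, else ``"INDEL"``."""
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def indel_len(self) -> int:
        """Signed length change in bp (0 for SNPs)."""
        return len(self.alt) - len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site identity used for call-set matching: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def resolve_func_class(labels) -> str:
    """Collapse a multi-label annotation to a single class by precedence.

    ``stop > splice > nonsynonymous > synonymous > utr5 > utr3 > intronic >
    intergenic > other`` (most consequential transcript effect wins).
    """
    labels = list(labels)
    if not labels:
        return "other"
    for lab in labels:
        if lab not in FUNC_CLASSES:
            raise ValueError(f"unknown functional class {lab!r}")
    return min(labels, key=CLASS_PRECEDENCE.index)


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosage calls for samples x variants.

    ``calls[i, j]`` is the number of alternate alleles (0/1/2) carried by
    sample *i* at variant *j*, or :data:`MISSING` (-1) for a no-call.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray
    pop_labels: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(self.pop_labels) != len(self.sample_ids):
            raise ValueError("every sample needs exactly one population label")
        bad = (self.calls < MISSING) | (self.calls > 2)
        if bad.any():
            raise ValueError("genotype calls must be in {0,1,2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        return np.array([p == pop for p in self.pop_labels], dtype=bool)

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=self.variants,
            calls=self.calls[idx],
            pop_labels=[self.pop_labels[i] for i in idx],
        )

    def site_keys(self) -> list[tuple[str, int, str, str]]:
        return [v.key for v in self.variants]


FREQ_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "pop", "alt_count", "n_chrom", "af",
]


@dataclass
class PopFreqTable:
    """Long-format per-variant, per-population alt-allele frequencies.

    One row per (variant, population); ``af = alt_count / n_chrom`` over the
    chromosomes actually observed (missing genotypes excluded). A population
    with zero observed chromosomes at a site is flagged with ``af = NaN`` and
    excluded downstream.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FREQ_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"frequency table missing columns {missing}")
        t = self.table
        defined = t["n_chrom"] > 0
        if ((t.loc[defined, "alt_count"] < 0)
                | (t.loc[defined, "alt_count"] > t.loc[defined, "n_chrom"])).any():
            raise ValueError("alt_count must satisfy 0 <= alt_count <= n_chrom")

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.table["pop"]))

    def for_pop(self, pop: str) -> pd.DataFrame:
        sub = self.table[self.table["pop"] == pop]
        if sub.empty:
            raise KeyError(f"no rows for population {pop!r}")
        return sub.reset_index(drop=True)

    def pair_frame(self, pop1: str, pop2: str) -> pd.DataFrame:
        """Inner-join the two populations on site identity.

        Returns columns variant_id/chrom/pos/ref/alt plus af1/n1/af2/n2.
        """
        a = self.for_pop(pop1)[["variant_id", "chrom", "pos", "ref", "alt", "af", "n_chrom"]]
        b = self.for_pop(pop2)[["variant_id", "af", "n_chrom"]]
        merged = a.merge(b, on="variant_id", suffixes=("1", "2"))
        return merged.rename(columns={"af1": "af1", "n_chrom1": "n1",
                                      "af2": "af2", "n_chrom2": "n2"})


@dataclass
class SentinelCatalog:
    """GWAS sentinel SNPs for one phenotype, with matching covariates."""

    phenotype: str
    entries: pd.DataFrame  # variant_id chrom pos af dist_nearest_gene n_genes_250kb

    REQUIRED = ["variant_id", "chrom", "pos", "af", "dist_nearest_gene", "n_genes_250kb"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.entries.columns]
        if missing:
            raise ValueError(f"sentinel catalogue missing columns {missing}")
        if (self.entries["dist_nearest_gene"] < 0).any():
            raise ValueError("dist_nearest_gene must be >= 0")
        if (self.entries["n_genes_250kb"] < 0).any():
            raise ValueError("n_genes_250kb must be >= 0")

    def __len__(self) -> int:
        return len(self.entries)
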