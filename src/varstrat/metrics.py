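"""Call-set QC, concordance and discovery-power metrics.

Site identity throughout is the tuple (chrom, pos, ref, alt): two call sets
agree at a site only when they report the same alternate allele there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .afreq import classify_af
from .types import MISSING, GenotypeMatrix, VariantRecord

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def sensitivity(exp_sites, ref_sites) -> float:
    """Fraction of reference-polymorphic sites recovered by the experimental set."""
    ref = set(ref_sites)
    if not ref:
        raise ValueError("sensitivity undefined for an empty reference set")
    return len(set(exp_sites) & ref) / len(ref)


def ppv(exp_sites, ref_sites) -> float:
    """Fraction of experimentally called polymorphic sites confirmed in the reference."""
    exp = set(exp_sites)
    if not exp:
        raise ValueError("PPV undefined for an empty experimental set")
    return len(exp & set(ref_sites)) / len(exp)


def titv_ratio(variants) -> float:
    """Transition/transversion ratio over the SNPs in ``variants`` (indels ignored)."""
    ti = tv = 0
    for v in variants:
        if v.vtype != "SNP":
            continue
        if (v.ref, v.alt) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if ti + tv == 0:
        raise ValueError("no SNPs supplied")
    if tv == 0:
        raise ValueError(f"Ti/Tv undefined: {ti} transitions, 0 transversions")
    return ti / tv


def het_hom_ratio(sample_calls) -> float:
    """Het/Hom(alt) ratio for one sample's genotype vector."""
    calls = np.asarray(sample_calls)
    n_het = int((calls == 1).sum())
    n_hom = int((calls == 2).sum())
    if n_hom == 0:
        raise ValueError("Het/Hom undefined: no alternate homozygotes")
    return n_het / n_hom


def cohort_het_hom(gm: GenotypeMatrix) -> tuple[float, float, np.ndarray]:
    """Cohort Het/Hom: mean and SD of per-sample ratios (plus the ratios)."""
    ratios = np.array([het_hom_ratio(gm.calls[i]) for i in range(gm.n_samples)])
    return float(ratios.mean()), float(ratios.std(ddof=0)), ratios


def af_discordant_fraction(af_a, af_b, threshold: float = 0.01) -> float:
    """Fraction of shared sites with |dAF| strictly greater than ``threshold``."""
    a = np.asarray(af_a, dtype=float)
    b = np.asarray(af_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frequency vectors must be paired over shared sites")
    if a.size == 0:
        raise ValueError("no shared sites")
    return float((np.abs(a - b) > threshold).mean())


def annotate_novelty(variants, known_set) -> list[VariantRecord]:
    """Flag each variant novel iff its (chrom,pos,ref,alt) is absent from known_set."""
    known = {tuple(k) for k in known_set}
    return [
        VariantRecord(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                      func_class=v.func_class, is_novel=v.key not in known)
        for v in variants
    ]


def novelty_by_af_class(variants, afs, bounds=(0.01, 0.05)) -> pd.DataFrame:
    """Tabulate novel/known counts per allele-frequency class."""
    rows = []
    for v, af in zip(variants, afs):
        rows.append((classify_af(float(af), bounds), v.is_novel))
    df = pd.DataFrame(rows, columns=["af_class", "is_novel"])
    out = df.groupby("af_class")["is_novel"].agg(n_novel="sum", n_total="count").reset_index()
    out["n_known"] = out["n_total"] - out["n_novel"]
    return out


def indel_frame_class(indel_len: int) -> str:
    """``inframe`` iff the length change is a multiple of 3 bp, else ``frameshift``."""
    if indel_len == 0:
        raise ValueError("indel_len 0 is not an indel")
    return "inframe" if abs(indel_len) % 3 == 0 else "frameshift"


def discovery_power(f: float, cohorts) -> float:
    """Probability of discovering a variant of population frequency ``f``.

    Per-copy binomial model: the sequenced cohort of N diploids carries
    Binomial(2N, f) copies of the allele; each copy is detected
    independently with probability s (the observed per-copy sensitivity);
    the variant is discovered iff at least one copy is detected. For one
    cohort the power is 1 - (1 - f.s)^(2N); independent cohorts multiply
    their miss probabilities.

    ``cohorts`` is an iterable of (n_diploids, sensitivity) pairs.
    """
    if f >= 1.0:
        raise ValueError("allele frequency must be < 1")
    if f <= 0.0:
        return 0.0
    miss = 1.0
    for n, s in cohorts:
        if not (0.0 < s <= 1.0):
            raise ValueError(f"sensitivity must be in (0,1], got {s}")
        if n < 1:
            raise ValueError("cohort size must be >= 1")
        miss *= (1.0 - f * s) ** (2 * n)
    return 1.0 - miss


@dataclass
class ConcordanceReport:
    sensitivity: float
    ppv: float
    n_ref_polymorphic: int
    n_exp_polymorphic: int
    n_shared: int
    genotype_concordance: float
    af_discordant_fraction: float

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_ref_polymorphic, self.n_exp_polymorphic):
            raise ValueError("shared sites exceed a call set's polymorphic count")


def _polymorphic_sites(gm: GenotypeMatrix) -> dict[tuple, int]:
    """Map site key -> variant column index for sites with >= 1 alt allele called."""
    observed = gm.calls != MISSING
    alt_counts = np.where(observed, gm.calls, 0).sum(axis=0)
    return {v.key: j for j, v in enumerate(gm.variants) if alt_counts[j] > 0}


def concordance(exp: GenotypeMatrix, ref: GenotypeMatrix,
                af_threshold: float = 0.01) -> ConcordanceReport:
    """Site- and genotype-level concordance of an experimental call set
    against a reference call set over shared samples.

    Sensitivity/PPV are site-level over polymorphic sites; genotype
    concordance and the AF-discordance fraction are computed over sites
    polymorphic in both sets, on non-missing genotype pairs of the samples
    present in both call sets.
    """
    exp_sites = _polymorphic_sites(exp)
    ref_sites = _polymorphic_sites(ref)
    shared = sorted(set(exp_sites) & set(ref_sites))
    sens = sensitivity(exp_sites, ref_sites)
    prec = ppv(exp_sites, ref_sites)

    shared_samples = [s for s in exp.sample_ids if s in set(ref.sample_ids)]
    exp_rows = {s: i for i, s in enumerate(exp.sample_ids)}
    ref_rows = {s: i for i, s in enumerate(ref.sample_ids)}
    n_match = n_pairs = 0
    af_e, af_r = [], []
    for key in shared:
        je, jr = exp_sites[key], ref_sites[key]
        ce = exp.calls[[exp_rows[s] for s in shared_samples], je]
        cr = ref.calls[[ref_rows[s] for s in shared_samples], jr]
        ok = (ce != MISSING) & (cr != MISSING)
        n_pairs += int(ok.sum())
        n_match += int((ce[ok] == cr[ok]).sum())
        oe = exp.calls[:, je][exp.calls[:, je] != MISSING]
        orr = ref.calls[:, jr][ref.calls[:, jr] != MISSING]
        if len(oe) and len(orr):
            af_e.append(oe.sum() / (2 * len(oe)))
            af_r.append(orr.sum() / (2 * len(orr)))
    geno_conc = n_match / n_pairs if n_pairs else float("nan")
    af_disc = (af_discordant_fraction(af_e, af_r, af_threshold)
               if af_e else float("nan"))
    return ConcordanceReport(
        sensitivity=sens, ppv=prec,
        n_ref_polymorphic=len(ref_sites), n_exp_polymorphic=len(exp_sites),
        n_shared=len(shared), genotype_concordance=geno_conc,
        af_discordant_fraction=af_disc,
    )


def qc_summary(gm: GenotypeMatrix) -> dict:
    """Ti/Tv, Het/Hom (cohort mean +/- SD), per-sample variant counts and
    per-class site counts for one call set."""
    mean_hh, sd_hh, _ = cohort_het_hom(gm)
    per_sample = ((gm.calls == 1) | (gm.calls == 2)).sum(axis=1)
    class_counts: dict[str, int] = {}
    for v in gm.variants:
        class_counts[v.func_class] = class_counts.get(v.func_class, 0) + 1
    return {
        "titv": titv_ratio(gm.variants),
        "het_hom_mean": mean_hh,
        "het_hom_sd": sd_hh,
        "n_variants_per_sample_mean": float(per_sample.mean()),
        "class_counts": class_counts,
    }
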