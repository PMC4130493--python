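"""Pipeline configuration: thresholds, windows and matching tolerances."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml


@dataclass
class PipelineConfig:
    """Analysis-wide tunables.

    fst_threshold
        F_ST above which a SNP is called stratified (strict >).
    window_bp
        Half-width of the sentinel window used when counting stratified
        SNPs near GWAS loci (closed interval [pos-w, pos+w]).
    n_perm
        Number of matched null sentinel sets drawn for the permutation test.
    af_tol / gene_prox_tol_bp / gene_count_tol
        Matching tolerances for null sentinel sets: allele frequency
        (+/-0.02), distance to the nearest gene (+/-10 kb) and number of
        genes within 250 kb (+/-2).
    af_class_bounds
        (rare/low, low/common) allele-frequency boundaries; rare < 1%,
        1% <= low-frequency < 5%, common >= 5%.
    af_diff_threshold
        |dAF| above which two call sets are counted discordant at a site.
    """

    fst_threshold: float = 0.10
    window_bp: int = 500_000
    n_perm: int = 10_000
    af_tol: float = 0.02
    gene_prox_tol_bp: int = 10_000
    gene_count_tol: int = 2
    af_class_bounds: tuple[float, float] = (0.01, 0.05)
    af_diff_threshold: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positives = {
            "fst_threshold": self.fst_threshold,
            "window_bp": self.window_bp,
            "n_perm": self.n_perm,
            "af_tol": self.af_tol,
            "gene_prox_tol_bp": self.gene_prox_tol_bp,
            "gene_count_tol": self.gene_count_tol,
            "af_diff_threshold": self.af_diff_threshold,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        lo, hi = self.af_class_bounds
        if not (0 < lo < hi < 1):
            raise ValueError(f"af_class_bounds must satisfy 0 < lo < hi < 1, got {self.af_class_bounds}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "af_class_bounds" in raw:
            raw["af_class_bounds"] = tuple(raw["af_class_bounds"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["af_class_bounds"] = list(data["af_class_bounds"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
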