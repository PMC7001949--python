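"""SNPs from published summary statistics.

Independent SNPs enter the model through their published per-allele odds
ratio theta_k and population allele frequency f_k alone: each SNP k becomes
one design column holding the genotype dosage G_k in {0, 1, 2} with
coefficient log(theta_k), so that jointly they contribute the polygenic risk
score PRS = sum_k log(theta_k) G_k. No genotyped reference sample is needed:
reference genotypes are simulated under Hardy-Weinberg equilibrium,
optionally conditioned on a binary family-history indicator, and the family
history log odds ratio can be attenuated to account for the heritability the
SNPs explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SnpInfo",
    "build_prs",
    "attenuate_family_history",
    "genotype_distribution_given_fh",
    "simulate_reference_genotypes",
]


@dataclass(frozen=True)
class SnpInfo:
    """Per-SNP published summary statistics.

    ``odds_ratio`` is the per-allele disease odds ratio theta_k with respect
    to the referent allele; ``frequency`` is the population frequency f_k of
    the non-referent allele, strictly inside (0, 1). Names must be unique.
    """

    names: tuple[str, ...]
    odds_ratio: np.ndarray
    frequency: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        theta = np.asarray(self.odds_ratio, dtype=float)
        freq = np.asarray(self.frequency, dtype=float)
        if not (len(names) == theta.size == freq.size):
            raise ValueError("names, odds_ratio and frequency must be equal length")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate SNP names: {dupes}")
        for i, (t, f) in enumerate(zip(theta, freq)):
            if not (np.isfinite(t) and t > 0):
                raise ValueError(f"SNP {names[i]!r} (row {i + 1}): odds ratio {t} "
                                 "must be finite and > 0")
            if not (0.0 < f < 1.0):
                raise ValueError(f"SNP {names[i]!r} (row {i + 1}): allele frequency "
                                 f"{f} must be in (0, 1)")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "odds_ratio", theta)
        object.__setattr__(self, "frequency", freq)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def log_odds_ratio(self) -> np.ndarray:
        return np.log(self.odds_ratio)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SnpInfo":
        required = ["snp.name", "snp.odds.ratio", "snp.freq"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"SNP table missing columns: {missing}")
        return cls(
            names=tuple(df["snp.name"].astype(str)),
            odds_ratio=df["snp.odds.ratio"].to_numpy(dtype=float),
            frequency=df["snp.freq"].to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp.name": list(self.names),
                "snp.odds.ratio": self.odds_ratio,
                "snp.freq": self.frequency,
            }
        )


def _check_genotypes(g: np.ndarray, allow_missing: bool) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    finite = np.isfinite(g)
    if not allow_missing and not finite.all():
        raise ValueError("missing genotypes; route through the imputation machinery")
    bad = finite & ~np.isin(g, (0.0, 1.0, 2.0))
    if bad.any():
        raise ValueError(f"genotypes must be in {{0, 1, 2}}; found {np.unique(g[bad])}")
    return g


def build_prs(snps: SnpInfo, genotypes: np.ndarray) -> np.ndarray | float:
    """PRS = sum_k log(theta_k) * G_k for one profile or a matrix of profiles."""
    g = _check_genotypes(genotypes, allow_missing=False)
    if g.ndim == 1:
        if g.size != len(snps):
            raise ValueError("genotype vector length must match SNP count")
        return float(g @ snps.log_odds_ratio)
    if g.shape[1] != len(snps):
        raise ValueError("genotype matrix columns must match SNP count")
    return g @ snps.log_odds_ratio


def attenuate_family_history(beta_fh: float, snps: SnpInfo) -> float:
    """Attenuated family-history log odds ratio after adding the SNPs.

    beta_FH_adj = beta_FH - 0.5 * sum_k (log theta_k)^2 * 2 f_k (1 - f_k):
    with the SNPs in the model, family history carries proportionally less
    information, by the share of (narrow-sense) heritability they explain.
    Apply only when ``beta_fh`` is unadjusted for the SNPs.
    """
    if len(snps) == 0:
        return float(beta_fh)
    log_or = snps.log_odds_ratio
    f = snps.frequency
    return float(beta_fh - 0.5 * np.sum(log_or**2 * 2.0 * f * (1.0 - f)))


def genotype_distribution_given_fh(
    theta: float, freq: float, fh: int
) -> np.ndarray:
    """Probabilities of genotype g in {0, 1, 2} given family-history status.

    Without family history (rare disease) the genotype follows HWE:
    ((1-f)^2, 2f(1-f), f^2). Among subjects with an affected first-degree
    relative the distribution tilts by theta^(g/2) (Mendelian sharing of one
    allele on average), renormalized.
    """
    if not (theta > 0 and np.isfinite(theta)):
        raise ValueError("theta must be finite and > 0")
    if not (0.0 < freq < 1.0):
        raise ValueError("freq must be in (0, 1)")
    hwe = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2])
    if fh == 0:
        return hwe
    if fh == 1:
        tilt = theta ** (0.5 * np.arange(3))
        p = tilt * hwe
        return p / p.sum()
    raise ValueError("fh must be 0 or 1")


def simulate_reference_genotypes(
    snps: SnpInfo,
    n_subjects: int | None = None,
    fh_status: np.ndarray | None = None,
    n_imputations: int = 5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Multiply-imputed genotype matrices for a reference sample.

    Returns an array of shape ``(n_imputations, n_subjects, n_snps)``: each
    subject's genotypes are drawn independently per SNP from HWE, conditioned
    on the subject's family-history status when ``fh_status`` is given.
    SNPs are assumed mutually independent.
    """
    rng = np.random.default_rng(rng)
    if fh_status is not None:
        fh = np.asarray(fh_status)
        if not np.isin(fh, (0, 1)).all():
            raise ValueError("family-history status must be 0/1")
        fh = fh.astype(int)
        if n_subjects is None:
            n_subjects = fh.size
        elif n_subjects != fh.size:
            raise ValueError("n_subjects disagrees with fh_status length")
    elif n_subjects is None:
        raise ValueError("either n_subjects or fh_status is required")

    n_snps = len(snps)
    out = np.empty((n_imputations, n_subjects, n_snps), dtype=np.int8)
    for k in range(n_snps):
        p0 = genotype_distribution_given_fh(snps.odds_ratio[k], snps.frequency[k], 0)
        cdf = np.cumsum(p0)
        if fh_status is not None:
            p1 = genotype_distribution_given_fh(snps.odds_ratio[k], snps.frequency[k], 1)
            cdf = np.where(fh[None, :, None] == 1, np.cumsum(p1), cdf[None, None, :])
        u = rng.random((n_imputations, n_subjects, 1))
        out[:, :, k] = (u > cdf).sum(axis=-1)
    return out
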