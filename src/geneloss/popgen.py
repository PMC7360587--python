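"""Population-level loss-of-function statistics.

Covers allele and homozygote (HMA) frequencies, Hardy-Weinberg tests,
damaging-variant filtering (PolyPhen/SIFT score windows), loss-of-function
density per kb of coding sequence, the observed/expected constraint ratio
with its Poisson upper bound (LOEUF-style), windowed nucleotide diversity
and Tajima's D, and a Jeffreys-Zellner-Siow Bayes-factor one-sample test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import integrate, stats


@dataclass
class VariantRecord:
    """One population variant with frequencies and pathogenicity scores."""

    variant_id: str
    gene_id: str
    consequence: str              # missense | stop_gained | frameshift | other
    cdna_pos: int
    protein_change: str
    pop_freqs: dict[str, float] = field(default_factory=dict)
    polyphen: float | None = None
    sift: float | None = None
    genotype_counts: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        for pop, f in self.pop_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for {pop} outside [0,1]")
        if self.genotype_counts is not None:
            if any(c < 0 for c in self.genotype_counts):
                raise ValueError("genotype counts must be non-negative")


@dataclass
class PopSummary:
    population: str
    allele_freq: float
    hma_freq: float
    genotype_counts: tuple[int, int, int]
    hwe_p: float


@dataclass
class ConstraintSummary:
    gene_id: str
    observed_lof: int
    expected_lof: float
    oe: float
    loeuf: float
    lof_density_per_kb: float = float("nan")
    cds_len_bp: int = 0


@dataclass
class PopStatWindow:
    start: int
    end: int
    n_sequences: int
    S: int
    pi: float
    tajima_d: float | None


@dataclass
class BayesTestResult:
    n: int
    t: float
    bf10: float
    bf01: float
    h0_value: float


# --------------------------------------------------------------------------
# genotype frequencies and HWE
# --------------------------------------------------------------------------

def allele_and_hma_freqs(counts: tuple[int, int, int],
                         population: str = "") -> PopSummary:
    """Minor-allele and homozygous-minor (HMA) frequencies from genotype counts.

    ``counts`` are (n_AA, n_Aa, n_aa) with 'a' the minor (inactivating)
    allele; allele_freq = (n_Aa + 2 n_aa) / 2N and hma_freq = n_aa / N.
    """
    n_aa_maj, n_het, n_aa_min = counts
    n = n_aa_maj + n_het + n_aa_min
    if n == 0:
        raise ValueError("empty sample")
    q = (n_het + 2 * n_aa_min) / (2 * n)
    return PopSummary(population=population, allele_freq=q,
                      hma_freq=n_aa_min / n, genotype_counts=tuple(counts),
                      hwe_p=hwe_test(counts))


def hwe_test(counts: tuple[int, int, int], method: str = "chi2") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    ``chi2`` is the 1-df goodness-of-fit test against p^2/2pq/q^2
    expectations (``chi2_cc`` adds Yates' continuity correction); ``exact``
    is the conditional exact test summing probabilities of heterozygote
    counts no more likely than the observed one.
    """
    n_AA, n_Aa, n_aa = counts
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty sample")
    if min(counts) < 0:
        raise ValueError("negative genotype count")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if method in {"chi2", "chi2_cc"}:
        expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
        observed = np.array(counts, dtype=float)
        if np.any(expected == 0):
            return 1.0
        diff = np.abs(observed - expected)
        if method == "chi2_cc":
            diff = np.maximum(diff - 0.5, 0.0)
        chi2 = float((diff ** 2 / expected).sum())
        return float(stats.chi2.sf(chi2, 1))
    if method == "exact":
        return _hwe_exact(n_Aa, 2 * n_aa + n_Aa, n)
    raise ValueError(f"unknown method {method!r}")


def _hwe_exact(het_obs: int, n_minor: int, n: int) -> float:
    """Exact HWE test conditioned on allele counts."""
    n_major = 2 * n - n_minor

    def logprob(het: int) -> float:
        # unnormalized: constant-in-het factors drop out after normalization
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        return (het * math.log(2.0)
                - math.lgamma(hom_maj + 1) - math.lgamma(het + 1)
                - math.lgamma(hom_min + 1))

    hets = [h for h in range(n_minor % 2, min(n_minor, n_major) + 1, 2)]
    logs = np.array([logprob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hets.index(het_obs)]
    return float(probs[probs <= p_obs + 1e-12].sum())


def superpop_mean_freq(pop_freqs: Mapping[str, float]) -> float:
    """Unweighted mean allele frequency over member populations."""
    if not pop_freqs:
        raise ValueError("no populations given")
    return float(np.mean(list(pop_freqs.values())))


# --------------------------------------------------------------------------
# damaging-variant filtering and constraint
# --------------------------------------------------------------------------

def filter_damaging(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep ORF-disrupting variants plus predicted-damaging missense.

    Stop-gained and frameshift records pass regardless of scores. Missense
    records pass only with PolyPhen in [0.7, 1] and SIFT in [0, 0.3]
    (inclusive); missense with missing scores is dropped.
    """
    out = []
    for r in records:
        if r.consequence in {"stop_gained", "frameshift"}:
            out.append(r)
        elif r.consequence == "missense":
            if r.polyphen is None or r.sift is None:
                continue
            if 0.7 <= r.polyphen <= 1.0 and 0.0 <= r.sift <= 0.3:
                out.append(r)
    return out


def lof_density(n_variants: int, cds_len_bp: int) -> float:
    """Damaging variants per kb of coding sequence."""
    if cds_len_bp <= 0:
        raise ValueError("CDS length must be positive")
    if n_variants < 0:
        raise ValueError("variant count must be non-negative")
    return 1000.0 * n_variants / cds_len_bp


def oe_and_loeuf(observed: int, expected: float, ci: float = 0.90,
                 gene_id: str = "", cds_len_bp: int = 0,
                 n_damaging: int | None = None) -> ConstraintSummary:
    """Observed/expected LoF ratio and its Poisson upper bound (LOEUF-style).

    With observed ~ Poisson(lambda * expected), the bound is the upper end of
    the two-sided ``ci`` confidence interval for lambda, computed from the
    exact chi-square relation for Poisson rates.
    """
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if expected <= 0:
        raise ValueError("expected count must be positive")
    alpha = 1.0 - ci
    upper_mu = 0.5 * stats.chi2.ppf(1.0 - alpha / 2.0, 2 * observed + 2)
    density = float("nan")
    if cds_len_bp > 0:
        density = lof_density(
            observed if n_damaging is None else n_damaging, cds_len_bp)
    return ConstraintSummary(
        gene_id=gene_id, observed_lof=observed, expected_lof=expected,
        oe=observed / expected, loeuf=float(upper_mu / expected),
        lof_density_per_kb=density, cds_len_bp=cds_len_bp)


# --------------------------------------------------------------------------
# windowed diversity and Tajima's D
# --------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D for sample size n."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def diversity_scan(haplotypes: np.ndarray, positions: Sequence[int],
                   window_bp: int = 100_000,
                   region_bp: int | None = None) -> list[PopStatWindow]:
    """Sliding-window S, per-site pi and Tajima's D over a haplotype matrix.

    ``haplotypes`` is a (n_sequences, n_sites) 0/1 matrix of derived-allele
    states at the given base-pair ``positions``. Windows tile the region in
    non-overlapping ``window_bp`` steps; pi is the mean pairwise difference
    per base pair of window span. D is undefined (None) when S = 0.
    """
    hap = np.asarray(haplotypes)
    n = hap.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    positions = np.asarray(positions)
    if positions.shape[0] != hap.shape[1]:
        raise ValueError("positions length must match haplotype columns")
    if region_bp is None:
        region_bp = int(positions.max(initial=0)) + 1
    consts = tajima_constants(n)
    out = []
    for start in range(0, region_bp, window_bp):
        end = min(start + window_bp, region_bp)
        mask = (positions >= start) & (positions < end)
        sub = hap[:, mask]
        derived = sub.sum(axis=0)
        seg = (derived > 0) & (derived < n)
        s = int(seg.sum())
        k = derived[seg].astype(float)
        pi_total = float((k * (n - k)).sum() / (n * (n - 1) / 2.0))
        if s == 0:
            d = None
        else:
            var = consts["e1"] * s + consts["e2"] * s * (s - 1)
            d = (pi_total - s / consts["a1"]) / math.sqrt(var) if var > 0 else None
        out.append(PopStatWindow(start=start, end=end, n_sequences=n, S=s,
                                 pi=pi_total / (end - start), tajima_d=d))
    return out


# --------------------------------------------------------------------------
# JZS Bayes-factor one-sample test
# --------------------------------------------------------------------------

def jzs_one_sample_bf(values: Sequence[float], h0: float,
                      prior_scale: float = 0.707) -> BayesTestResult:
    """Jeffreys-Zellner-Siow Bayes factor for a one-sample location test.

    The alternative places a Cauchy(``prior_scale``) prior on the
    standardized effect size; BF10 is computed by numerical integration over
    the auxiliary scale g (inverse-gamma(1/2, r^2/2) mixture
    representation). BF01 = 1/BF10; BF01 > 1 favours the null.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(float(x.mean()))):
        raise ValueError("zero variance")
    t = (x.mean() - h0) / (sd / math.sqrt(n))
    nu = n - 1
    r = prior_scale

    def null_density(t_: float) -> float:
        return (1.0 + t_ ** 2 / nu) ** (-(nu + 1) / 2.0)

    def integrand(g: float) -> float:
        m = 1.0 + n * g
        marg = m ** -0.5 * (1.0 + t ** 2 / (m * nu)) ** (-(nu + 1) / 2.0)
        prior = ((r ** 2 / 2.0) ** 0.5 / math.gamma(0.5)
                 * g ** -1.5 * math.exp(-r ** 2 / (2.0 * g)))
        return marg * prior

    num, _err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    bf10 = num / null_density(t)
    return BayesTestResult(n=n, t=float(t), bf10=float(bf10),
                           bf01=float(1.0 / bf10), h0_value=float(h0))
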