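"""LOH detection from major-allele frequencies of germline-het SNPs.

Three estimators live here:

* a two-component Beta-Normal mixture over MAF in [0.5, 1]: a truncated
  normal for heterozygous SNPs outside LOH (mean drifts above 0.5 with
  allelic dropout) plus a rescaled beta for SNPs inside LOH (mean drifts
  below 1 with non-tumor contamination). The mixture weight of the beta
  component is the LOH fraction; tumor fraction and dropout rate are mapped
  from the component means.
* an exact binomial phase-concordance test between paired lesions: under no
  LOH in the second sample, the major allele there is a fair coin per SNP,
  so the count of concordant calls among n informative SNPs is
  Binomial(n, 1/2); the upper-tail probability from k to n is the P value.
* an artifact-LOH fraction: the share of LOH-called SNPs outside regions of
  true LOH, measuring false-negative/allelic-dropout burden.

Derived-quantity mappings (documented working assumptions, not reported
formulas): with copy-neutral LOH at purity rho the retained-allele MAF
expectation is (1 + rho) / 2, so ``tumor_fraction = 2 * beta_mean - 1``;
symmetrically ``dropout_rate = 2 * (normal_mean - 0.5)``.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .types import RegionSet, SnpObservation

MIN_FIT_OBSERVATIONS = 200
_EPS = 1e-9


@dataclass(frozen=True)
class MafObservation:
    """Major-allele frequency of one germline-het SNP in a tumor sample."""

    chrom: str
    pos: int
    maf: float
    major_allele: str  # ref | alt
    coverage: int

    def __post_init__(self) -> None:
        if not 0.5 <= self.maf <= 1.0:
            raise ValueError(f"MAF {self.maf} outside [0.5, 1]")
        if self.major_allele not in ("ref", "alt", "tie"):
            raise ValueError(f"major_allele must be ref/alt/tie, got {self.major_allele!r}")


def heterozygous_snps(
    observations: Sequence[SnpObservation],
    low: float = 0.2,
    high: float = 0.8,
    min_coverage: int = 10,
) -> List[SnpObservation]:
    """Heuristic germline heterozygous calls: balanced allele fractions."""
    out = []
    for o in observations:
        if o.coverage < min_coverage:
            continue
        frac = o.alt_count / o.coverage
        if low <= frac <= high:
            out.append(o)
    return out


def major_allele_frequencies(
    germline_het_snps: Sequence[SnpObservation],
    tumor: Sequence[SnpObservation],
    min_coverage: int = 10,
) -> List[MafObservation]:
    """Tumor MAFs at positions heterozygous in the germline.

    Positions with tumor coverage below ``min_coverage`` are dropped.
    """
    het_positions = {(o.chrom, o.pos) for o in germline_het_snps}
    out: List[MafObservation] = []
    n_low = 0
    for obs in tumor:
        if (obs.chrom, obs.pos) not in het_positions:
            continue
        cov = obs.coverage
        if cov < min_coverage:
            n_low += 1
            continue
        if obs.ref_count > obs.alt_count:
            major, top = "ref", obs.ref_count
        elif obs.alt_count > obs.ref_count:
            major, top = "alt", obs.alt_count
        else:
            major, top = "tie", obs.ref_count
        out.append(MafObservation(chrom=obs.chrom, pos=obs.pos,
                                  maf=top / cov, major_allele=major, coverage=cov))
    if not out:
        warnings.warn("no overlapping covered positions for MAF computation")
    return out


# ---------------------------------------------------------------------------
# Beta-Normal mixture


@dataclass(frozen=True)
class LohMixtureFit:
    pi_loh: float
    mu_het: float
    sigma_het: float
    beta_a: float
    beta_b: float
    loglik: float
    n_snps: int
    converged: bool
    degenerate: bool
    restart_diagnostics: Tuple[dict, ...] = ()

    @property
    def loh_fraction(self) -> float:
        return self.pi_loh

    @property
    def beta_mean_maf(self) -> float:
        """Beta-component mean mapped back onto the MAF scale."""
        return 0.5 + 0.5 * self.beta_a / (self.beta_a + self.beta_b)

    @property
    def tumor_fraction(self) -> float:
        return float(np.clip(2.0 * self.beta_mean_maf - 1.0, 0.0, 1.0))

    @property
    def dropout_rate(self) -> float:
        return float(np.clip(2.0 * (self.mu_het - 0.5), 0.0, 1.0))

    def density(self, x) -> np.ndarray:
        """Fitted mixture density on the MAF scale [0.5, 1]."""
        x = np.asarray(x, dtype=float)
        return np.exp(_mixture_logpdf(
            x, self.pi_loh, self.mu_het, self.sigma_het, self.beta_a, self.beta_b))

    def to_dict(self) -> dict:
        return {
            "pi_loh": self.pi_loh, "mu_het": self.mu_het, "sigma_het": self.sigma_het,
            "beta_a": self.beta_a, "beta_b": self.beta_b,
            "loh_fraction": self.loh_fraction, "tumor_fraction": self.tumor_fraction,
            "dropout_rate": self.dropout_rate, "loglik": self.loglik,
            "n_snps": self.n_snps, "converged": self.converged,
            "degenerate": self.degenerate,
            "restarts": list(self.restart_diagnostics),
        }


def _mixture_logpdf(x, pi_loh, mu, sigma, a, b):
    """Log density of the Beta-Normal mixture on MAF in [0.5, 1].

    Normal component truncated to [0.5, 1]; beta component lives on MAF
    linearly rescaled to [0, 1] (jacobian 2).
    """
    x = np.clip(x, 0.5 + _EPS, 1.0 - _EPS)
    alo, ahi = (0.5 - mu) / sigma, (1.0 - mu) / sigma
    log_norm = stats.truncnorm.logpdf(x, alo, ahi, loc=mu, scale=sigma)
    log_beta = stats.beta.logpdf((x - 0.5) * 2.0, a, b) + math.log(2.0)
    comps = np.stack([
        np.log(max(1.0 - pi_loh, _EPS)) + log_norm,
        np.log(max(pi_loh, _EPS)) + log_beta,
    ])
    from scipy.special import logsumexp

    return logsumexp(comps, axis=0)


def _unpack(theta) -> Tuple[float, float, float, float, float]:
    """Unconstrained optimizer vector -> (pi, mu, sigma, a, b)."""
    from scipy.special import expit

    pi_loh = float(expit(theta[0]))
    mu = 0.5 + 0.5 * float(expit(theta[1]))
    sigma = float(np.clip(np.exp(theta[2]), 1e-4, 0.5))
    m = float(expit(theta[3]))  # beta mean on [0, 1]
    c = float(np.clip(np.exp(theta[4]), 0.5, 5e3))  # concentration
    a = max(m * c, 1e-3)
    b = max((1.0 - m) * c, 1e-3)
    return pi_loh, mu, sigma, a, b


def _pack(pi_loh, mu, sigma, m, c) -> np.ndarray:
    from scipy.special import logit

    return np.array([
        logit(np.clip(pi_loh, 1e-4, 1 - 1e-4)),
        logit(np.clip((mu - 0.5) * 2.0, 1e-4, 1 - 1e-4)),
        math.log(sigma),
        logit(np.clip(m, 1e-4, 1 - 1e-4)),
        math.log(c),
    ])


def fit_loh_mixture(
    mafs: Sequence[MafObservation],
    n_restarts: int = 8,
    seed: int = 0,
) -> LohMixtureFit:
    """Maximum-likelihood Beta-Normal mixture fit over MAF observations.

    The best of ``n_restarts`` seeded local optimizations is kept. Fits on
    fewer than 200 observations are refused as under-determined.
    """
    x = np.array([m.maf for m in mafs], dtype=float)
    if len(x) < MIN_FIT_OBSERVATIONS:
        raise ValueError(
            f"mixture fit needs >= {MIN_FIT_OBSERVATIONS} observations, got {len(x)}"
        )

    def nll(theta):
        pi_loh, mu, sigma, a, b = _unpack(theta)
        return -float(np.sum(_mixture_logpdf(x, pi_loh, mu, sigma, a, b)))

    rng = np.random.default_rng(seed)
    base = dict(pi_loh=0.3, mu=0.52, sigma=0.05, m=0.8, c=20.0)
    best = None
    diagnostics: List[dict] = []
    for restart in range(n_restarts):
        if restart == 0:
            init = dict(base)
        else:
            init = dict(
                pi_loh=float(np.clip(base["pi_loh"] + rng.uniform(-0.25, 0.4), 0.01, 0.95)),
                mu=float(np.clip(base["mu"] + rng.uniform(-0.015, 0.1), 0.501, 0.75)),
                sigma=float(np.clip(base["sigma"] * rng.uniform(0.3, 3.0), 1e-3, 0.3)),
                m=float(np.clip(base["m"] + rng.uniform(-0.3, 0.18), 0.05, 0.98)),
                c=float(base["c"] * rng.uniform(0.2, 5.0)),
            )
        theta0 = _pack(**init)
        init_ll = -nll(theta0)
        res = optimize.minimize(nll, theta0, method="L-BFGS-B")
        final_ll = -float(res.fun)
        diagnostics.append({
            "restart": restart, "init_loglik": init_ll,
            "final_loglik": final_ll, "success": bool(res.success),
        })
        if np.isfinite(final_ll) and (best is None or final_ll > best[0]):
            best = (final_ll, res)
    loglik, res = best
    pi_loh, mu, sigma, a, b = _unpack(res.x)
    beta_mean_maf = 0.5 + 0.5 * a / (a + b)
    degenerate = beta_mean_maf < mu
    if degenerate:
        warnings.warn("degenerate mixture fit: beta mean below normal mean; "
                      "pi_loh is unreliable")
    return LohMixtureFit(
        pi_loh=pi_loh, mu_het=mu, sigma_het=sigma, beta_a=a, beta_b=b,
        loglik=loglik, n_snps=len(x),
        converged=any(d["success"] for d in diagnostics),
        degenerate=degenerate, restart_diagnostics=tuple(diagnostics),
    )


# ---------------------------------------------------------------------------
# Binomial phase concordance


@dataclass(frozen=True)
class ConcordanceTest:
    n: int
    k: int
    p_upper: float
    verdict: str  # concordant_loh | opposite_allele_loh | no_loh_evidence | not_evaluable
    chrom: str = ""
    start_pos: int = 0
    end_pos: int = 0
    flagged: bool = False


def binomial_upper_tail(k: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, 1/2), via integer arithmetic."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    total = sum(math.comb(n, i) for i in range(k, n + 1))
    return total / 2**n


def _verdict(p_upper: float, low: float = 0.01, high: float = 0.99) -> str:
    if p_upper < low:
        return "concordant_loh"
    if p_upper > high:
        return "opposite_allele_loh"
    return "no_loh_evidence"


def phase_concordance_test(
    region_a: Sequence[MafObservation],
    region_b: Sequence[MafObservation],
) -> ConcordanceTest:
    """Exact binomial test of shared LOH phase between two samples.

    SNPs are matched on position; ties (MAF exactly 0.5) in either sample
    are excluded from n. k counts positions whose major allele agrees.
    """
    a_by_pos = {(o.chrom, o.pos): o for o in region_a}
    b_by_pos = {(o.chrom, o.pos): o for o in region_b}
    common = sorted(set(a_by_pos) & set(b_by_pos))
    n = k = 0
    for key in common:
        oa, ob = a_by_pos[key], b_by_pos[key]
        if oa.major_allele == "tie" or ob.major_allele == "tie":
            continue
        n += 1
        if oa.major_allele == ob.major_allele:
            k += 1
    if n == 0:
        return ConcordanceTest(n=0, k=0, p_upper=1.0, verdict="not_evaluable")
    p_upper = binomial_upper_tail(k, n)
    return ConcordanceTest(n=n, k=k, p_upper=p_upper, verdict=_verdict(p_upper))


def windowed_concordance(
    sample_a: Sequence[MafObservation],
    sample_b: Sequence[MafObservation],
    window: int = 50,
) -> List[ConcordanceTest]:
    """Moving-window phase-concordance track across matched SNPs.

    One test per window start within each chromosome; a chromosome with
    fewer matched SNPs than the window yields a single flagged shorter
    window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    a_by_pos = {(o.chrom, o.pos): o for o in sample_a}
    b_by_pos = {(o.chrom, o.pos): o for o in sample_b}
    common = sorted(set(a_by_pos) & set(b_by_pos))
    by_chrom: Dict[str, List[tuple]] = {}
    for key in common:
        by_chrom.setdefault(key[0], []).append(key)
    tests: List[ConcordanceTest] = []
    for chrom in sorted(by_chrom):
        keys = by_chrom[chrom]
        if len(keys) < window:
            windows = [(0, len(keys), True)]
        else:
            windows = [(i, i + window, False) for i in range(len(keys) - window + 1)]
        for lo, hi, flagged in windows:
            sub = keys[lo:hi]
            base = phase_concordance_test(
                [a_by_pos[k] for k in sub], [b_by_pos[k] for k in sub])
            tests.append(ConcordanceTest(
                n=base.n, k=base.k, p_upper=base.p_upper, verdict=base.verdict,
                chrom=chrom, start_pos=sub[0][1], end_pos=sub[-1][1], flagged=flagged,
            ))
    return tests


# ---------------------------------------------------------------------------
# Artifact LOH (false-negative / dropout) fraction


def artifact_loh_fraction(
    loh_calls: Optional[RegionSet],
    true_loh: Optional[RegionSet],
    snps: Sequence[MafObservation],
    call_threshold: float = 0.9,
) -> float:
    """Fraction of LOH-called SNPs among SNPs outside true-LOH regions.

    A SNP counts as LOH-called when its MAF reaches ``call_threshold`` or
    it falls in an explicitly called region. Raises if no SNP lies outside
    ``true_loh`` (not evaluable).
    """
    if not 0.5 < call_threshold <= 1.0:
        raise ValueError("call_threshold must be in (0.5, 1]")
    outside = [
        o for o in snps
        if true_loh is None or not true_loh.contains(o.chrom, o.pos)
    ]
    if not outside:
        raise ValueError("no SNPs outside true-LOH regions: fraction not evaluable")
    called = [
        o for o in outside
        if o.maf >= call_threshold
        or (loh_calls is not None and loh_calls.contains(o.chrom, o.pos))
    ]
    return len(called) / len(outside)
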