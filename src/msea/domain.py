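"""The domain mutation-rate test (MSEA-domain).

The per-position mutation counts Y of a transcript are modelled as
negative-binomial (the data are sparse and zero-heavy, so NB replaces the
Poisson motivation) with a log link on a binary domain indicator X:

    h0:  E(Y|X) = exp(b0)            (uniform rate)
    h1:  E(Y|X) = exp(b0 + b1 * X)   (rate shift inside the region)

A likelihood-ratio test with one degree of freedom (b1) compares the two
fits; the dispersion is a per-model maximum-likelihood nuisance. Domains can
overlap, so three indicator constructions are tested: each domain alone (M1),
maximal merged runs of overlapping domains (M2), and the union of all domains
(M3). The transcript-level p-value is the minimum over all indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .io_model import TranscriptProfile

logger = logging.getLogger("msea")

__all__ = [
    "DomainIndicator",
    "DomainResult",
    "UntestableTranscriptError",
    "build_indicators",
    "merge_overlapping",
    "nb_loglik",
    "fit_nb",
    "fit_nb_lrt",
    "test_transcript",
    "summarize_transcript",
]

#: bounds on the log scale: effect size, and dispersion alpha in [1e-8, 1e4]
_BETA1_BOUND = 20.0
_LOG_ALPHA_BOUNDS = (np.log(1e-8), np.log(1e4))

_MODEL_ORDER = {"M1": 0, "M2": 1, "M3": 2}


class UntestableTranscriptError(ValueError):
    """No converged indicator fit is available for the transcript."""


@dataclass(slots=True)
class DomainIndicator:
    """A binary region-membership vector for one model.

    ``x[j-1]`` is 1 when position j lies inside the region. Indicators that
    are all-0 or all-1 are unidentifiable and never constructed.
    """

    model: str  # M1, M2 or M3
    region_label: str
    x: np.ndarray


@dataclass(slots=True)
class DomainResult:
    """Outcome of one NB likelihood-ratio test."""

    transcript_id: str
    gene: str
    model: str
    region_label: str
    beta0: float
    beta1: float
    dispersion: float
    ll_h0: float
    ll_h1: float
    lrt_stat: float
    p_value: float
    converged: bool
    n_in: int = 0
    n_out: int = 0


def merge_overlapping(
    intervals: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge intervals sharing at least one position; touching ones stay apart."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def build_indicators(profile: TranscriptProfile) -> list[DomainIndicator]:
    """Construct the M1 / M2 / M3 indicator vectors for a transcript.

    All-1 designs (a domain covering the whole protein) and, degenerately,
    all-0 designs are dropped with a logged reason.
    """
    L = profile.length_L
    out: list[DomainIndicator] = []

    def make(model: str, label: str, intervals: list[tuple[int, int]]) -> None:
        x = np.zeros(L, dtype=np.int8)
        for s, e in intervals:
            x[s - 1 : e] = 1
        n_in = int(x.sum())
        if n_in == 0 or n_in == L:
            logger.info(
                "transcript %s: %s indicator %s dropped (constant design)",
                profile.transcript_id, model, label,
            )
            return
        out.append(DomainIndicator(model=model, region_label=label, x=x))

    for d in profile.domains:
        make("M1", d.domain_id, [(d.aa_start, d.aa_end)])
    spans = [(d.aa_start, d.aa_end) for d in profile.domains]
    for s, e in merge_overlapping(spans):
        make("M2", f"{s}-{e}", [(s, e)])
    if spans:
        make("M3", "all_domains", merge_overlapping(spans))
    return out


# ---------------------------------------------------------------------------
# Negative-binomial likelihood
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood, stable across the whole dispersion range.

    Parametrization: Var(Y) = mu + alpha * mu^2, size r = 1/alpha. The
    log-gamma ratio lgamma(y+r) - lgamma(r) is computed as an exact sum of
    logs for small integer counts, which stays accurate as r -> inf (the
    Poisson limit) where the naive difference of lgammas loses all precision.
    """
    y = np.asarray(y, dtype=np.float64)
    mu = np.broadcast_to(np.asarray(mu, dtype=np.float64), y.shape)
    r = 1.0 / alpha
    ymax = int(y.max())
    if ymax <= 10_000 and np.allclose(y, np.round(y)):
        # lgamma(y+r) - lgamma(r) = sum_{k=0}^{y-1} log(r + k)
        logs = np.log(r + np.arange(ymax, dtype=np.float64))
        cum = np.concatenate(([0.0], np.cumsum(logs)))
        ratio = cum[y.astype(np.int64)]
    else:
        ratio = special.gammaln(y + r) - special.gammaln(r)
    log1p_mu_r = np.log1p(mu / r)
    ll = (
        ratio
        - special.gammaln(y + 1.0)
        - r * log1p_mu_r
        + y * (np.log(mu) - np.log(r) - log1p_mu_r)
    )
    return float(ll.sum())


def _neg_ll(theta: np.ndarray, y: np.ndarray, x: np.ndarray | None) -> float:
    if x is None:
        eta = np.full_like(y, theta[0], dtype=np.float64)
        log_alpha = theta[1]
    else:
        eta = theta[0] + theta[1] * x
        log_alpha = theta[2]
    mu = np.exp(eta)
    return -nb_loglik(y, mu, np.exp(log_alpha))


def fit_nb(
    y: np.ndarray, x: np.ndarray | None = None
) -> tuple[np.ndarray, float, bool]:
    """Bounded ML fit of an intercept-only (x=None) or intercept+slope NB model.

    Returns (params, log-likelihood, converged) where params is
    (beta0, log_alpha) or (beta0, beta1, log_alpha). Multiple starts guard
    against the flat region near the dispersion boundary; beta1 is capped at
    +/-20 on the log scale so complete separation stays finite.
    """
    y = np.asarray(y, dtype=np.float64)
    mean_y = max(y.mean(), 1e-10)
    b0 = float(np.log(mean_y))
    la_starts = (np.log(0.5), np.log(1e-6))
    if x is None:
        starts = [np.array([b0, la]) for la in la_starts]
        bounds = [(-30.0, 30.0), _LOG_ALPHA_BOUNDS]
    else:
        x = np.asarray(x, dtype=np.float64)
        m_in = max(y[x > 0].mean(), 1e-10)
        m_out = max(y[x == 0].mean(), 1e-10)
        b1 = float(np.clip(np.log(m_in / m_out), -_BETA1_BOUND, _BETA1_BOUND))
        b0_out = float(np.log(m_out))
        starts = [np.array([b0, 0.0, la]) for la in la_starts]
        starts += [np.array([b0_out, b1, la]) for la in la_starts]
        bounds = [(-30.0, 30.0), (-_BETA1_BOUND, _BETA1_BOUND), _LOG_ALPHA_BOUNDS]

    runs = [
        optimize.minimize(
            _neg_ll,
            theta0,
            args=(y, x),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        for theta0 in starts
    ]
    best_fun = min(r.fun for r in runs)
    # the dispersion direction is flat near its boundary, so some starts end
    # with a line-search failure at the shared optimum; a successful run that
    # reaches the same objective certifies convergence
    successful = [r for r in runs if r.success and r.fun <= best_fun + 1e-6]
    if not successful:
        # polish the flat ridge with a simplex search, which does not rely on
        # finite-difference gradients
        seed = min(runs, key=lambda r: r.fun)
        polish = optimize.minimize(
            _neg_ll,
            np.clip(seed.x, [b[0] for b in bounds], [b[1] for b in bounds]),
            args=(y, x),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if polish.success and polish.fun <= best_fun + 1e-6:
            successful = [polish]
    best = min(successful, key=lambda r: r.fun) if successful else min(
        runs, key=lambda r: r.fun
    )
    return best.x, -float(best.fun), bool(successful)


def fit_nb_lrt(
    counts_Y: np.ndarray,
    x: np.ndarray,
    transcript_id: str = "",
    gene: str = "",
    model: str = "",
    region_label: str = "",
) -> DomainResult:
    """NB likelihood-ratio test of rate elevation inside the indicated region.

    Dispersion is estimated by ML separately under h0 and h1; the LRT statistic
    2*(ll_h1 - ll_h0) is referred to chi-square with one degree of freedom.
    Non-convergence is reported (converged=False, p=1) rather than raising.
    """
    y = np.asarray(counts_Y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if y.shape != x.shape:
        raise ValueError("counts and indicator must have equal length")
    if x.min() == x.max():
        raise ValueError("indicator is constant: design unidentifiable")
    if y.sum() < 1:
        raise ValueError("no mutation records")

    params0, ll0, ok0 = fit_nb(y, None)
    params1, ll1, ok1 = fit_nb(y, x)
    converged = ok0 and ok1
    lrt = 2.0 * (ll1 - ll0)
    if lrt < -1e-6:
        converged = False
    lrt = max(lrt, 0.0)
    if converged:
        p = float(stats.chi2.sf(lrt, df=1))
    else:
        p = 1.0
        logger.warning(
            "transcript %s: NB fit did not converge for %s %s",
            transcript_id, model, region_label,
        )
    return DomainResult(
        transcript_id=transcript_id,
        gene=gene,
        model=model,
        region_label=region_label,
        beta0=float(params1[0]),
        beta1=float(params1[1]),
        dispersion=float(np.exp(params1[2])),
        ll_h0=ll0,
        ll_h1=ll1,
        lrt_stat=lrt,
        p_value=max(p, np.nextafter(0, 1)),
        converged=converged,
        n_in=int(x.sum()),
        n_out=int((x == 0).sum()),
    )


def test_transcript(
    profile: TranscriptProfile, dedupe: bool = True
) -> list[DomainResult]:
    """Run the LRT for every usable indicator of a transcript.

    Identical indicator vectors across models (common for single-domain
    proteins, where M1 = M2 = M3) are fitted once and the result replicated,
    keeping per-model provenance.
    """
    indicators = build_indicators(profile)
    results: list[DomainResult] = []
    cache: dict[bytes, DomainResult] = {}
    for ind in indicators:
        key = ind.x.tobytes()
        if dedupe and key in cache:
            base = cache[key]
            results.append(
                DomainResult(
                    transcript_id=base.transcript_id,
                    gene=base.gene,
                    model=ind.model,
                    region_label=ind.region_label,
                    beta0=base.beta0,
                    beta1=base.beta1,
                    dispersion=base.dispersion,
                    ll_h0=base.ll_h0,
                    ll_h1=base.ll_h1,
                    lrt_stat=base.lrt_stat,
                    p_value=base.p_value,
                    converged=base.converged,
                    n_in=base.n_in,
                    n_out=base.n_out,
                )
            )
            continue
        res = fit_nb_lrt(
            profile.counts_Y,
            ind.x,
            transcript_id=profile.transcript_id,
            gene=profile.gene,
            model=ind.model,
            region_label=ind.region_label,
        )
        cache[key] = res
        results.append(res)
    return results


def summarize_transcript(
    results: list[DomainResult],
) -> tuple[float, DomainResult]:
    """Transcript-level p: the minimum over all converged indicator tests.

    Ties break toward M1 < M2 < M3, then lexicographic region label.
    """
    usable = [r for r in results if r.converged]
    if not usable:
        raise UntestableTranscriptError("no converged indicator test")
    best = min(
        usable,
        key=lambda r: (r.p_value, _MODEL_ORDER.get(r.model, 9), r.region_label),
    )
    return best.p_value, best
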