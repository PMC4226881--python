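"""Empirical-null calibration, multiple testing, and gene-level summaries.

Per-transcript NES values are only comparable after pooling: the null
distribution f0 of NES is estimated from background (silent) mutation sets
across all transcripts, as a normal with mean and standard deviation fitted
by iterative maximum likelihood on the central window of the median-centered
background NES (the central fit resists contamination of the tails by
genuinely selected background sets). Working NES values, also median-centered,
are standardized against f0 into z-scores and one-sided upper-tail nominal
p-values, then Benjamini-Hochberg adjusted. Genes are represented by their
most significant transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io_model import MutationClass

logger = logging.getLogger("msea")

__all__ = [
    "EmpiricalNull",
    "CalibrationError",
    "fit_empirical_null",
    "nominal_p",
    "bh_adjust",
    "summarize_genes",
    "s_ns_ratio",
]


class CalibrationError(ValueError):
    """The background NES set is too small or degenerate for null fitting."""


@dataclass(slots=True)
class EmpiricalNull:
    """A fitted normal null f0 for NES values.

    ``mu0``/``sigma0`` refer to median-centered background NES; the two
    median offsets record the centering applied to each set.
    """

    mu0: float
    sigma0: float
    n_background: int
    median_offset_background: float
    median_offset_working: float | None = None
    window: float = 0.90
    n_iterations: int = 0


def _truncated_normal_ml(
    x: np.ndarray, lo: float, hi: float, mu0: float, sigma0: float
) -> tuple[float, float]:
    """ML estimate of (mu, sigma) from observations restricted to [lo, hi]."""
    xin = x[(x >= lo) & (x <= hi)]
    m = xin.size

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        z_lo = (lo - mu) / sigma
        z_hi = (hi - mu) / sigma
        mass = stats.norm.cdf(z_hi) - stats.norm.cdf(z_lo)
        if mass <= 0:
            return 1e300
        return float(
            0.5 * np.sum(((xin - mu) / sigma) ** 2)
            + m * log_sigma
            + m * np.log(mass)
        )

    res = optimize.minimize(
        nll,
        np.array([mu0, np.log(sigma0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
    )
    mu, log_sigma = res.x
    return float(mu), float(np.exp(log_sigma))


def fit_empirical_null(
    background_nes,
    window: float = 0.90,
    tol: float = 1e-6,
    max_iter: int = 100,
    min_n: int = 50,
) -> EmpiricalNull:
    """Fit the normal null f0 to median-centered background NES values.

    The window is fixed at the empirical central-``window`` quantiles of the
    median-centered sample; (mu0, sigma0) maximize the truncated-normal
    likelihood of the in-window observations, iterating the optimizer (warm
    restarts) until both parameters move less than ``tol``. Observations in
    the excluded tails — where genuinely selected background sets would sit —
    never enter the fit.
    """
    x = np.asarray(background_nes, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise CalibrationError(
            f"only {x.size} background NES values; need at least {min_n}"
        )
    med = float(np.median(x))
    xc = x - med
    if float(xc.std()) <= 0.0:
        raise CalibrationError("background NES values are constant")

    tail = (1.0 - window) / 2.0
    lo, hi = np.quantile(xc, [tail, 1.0 - tail])
    xin = xc[(xc >= lo) & (xc <= hi)]
    mu, sigma = float(xin.mean()), float(xin.std())
    if sigma <= 0.0:
        raise CalibrationError("central window of background NES is constant")
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu_new, sigma_new = _truncated_normal_ml(xc, lo, hi, mu, sigma)
        if not np.isfinite(sigma_new) or sigma_new <= 0:
            raise CalibrationError("null fit degenerated (sigma <= 0)")
        done = abs(mu_new - mu) < tol and abs(sigma_new - sigma) < tol
        mu, sigma = mu_new, sigma_new
        if done:
            break
    logger.info(
        "empirical null: mu0=%.4f sigma0=%.4f from %d background NES "
        "(window %.2f, %d iterations)",
        mu, sigma, x.size, window, n_iter,
    )
    return EmpiricalNull(
        mu0=mu,
        sigma0=sigma,
        n_background=int(x.size),
        median_offset_background=med,
        window=window,
        n_iterations=n_iter,
    )


def nominal_p(working_nes, null: EmpiricalNull) -> np.ndarray:
    """One-sided nominal p-values for working NES under the fitted null.

    Working NES are median-centered, standardized by (mu0, sigma0), and
    converted through the upper normal tail (large NES = clustering).
    """
    x = np.asarray(working_nes, dtype=np.float64)
    med = float(np.median(x))
    null.median_offset_working = med
    z = (x - med - null.mu0) / null.sigma0
    return stats.norm.sf(z)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def summarize_genes(
    transcript_results: pd.DataFrame,
    p_column: str = "p_adjusted",
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """One row per gene: its most significant transcript's statistics.

    Ties on the adjusted p break toward the lexicographically smallest
    transcript_id. Adds a ``significant`` flag at ``cutoff``; transcripts
    flagged by the silent-hotspot veto (column ``background_flagged``, if
    present) are never marked significant.
    """
    if transcript_results.empty:
        out = transcript_results.copy()
        out["significant"] = pd.Series(dtype=bool)
        return out
    df = transcript_results.sort_values(
        [p_column, "transcript_id"], kind="mergesort"
    )
    best = df.groupby("gene", sort=True).head(1).copy()
    significant = best[p_column] < cutoff
    if "background_flagged" in best.columns:
        significant &= ~best["background_flagged"].astype(bool)
    best["significant"] = significant
    return best.sort_values("gene").reset_index(drop=True)


def s_ns_ratio(records) -> float:
    """S/NS = (#silent SNVs) / (#non-silent SNVs).

    Defined on SNVs only: non-silent SNVs are missense plus nonsense; indels
    and splice records do not enter either count. Genes without synonymous
    SNVs get 0; with no non-silent SNVs the ratio is undefined (NaN).
    """
    n_silent = sum(1 for r in records if r.mutation_class is MutationClass.SILENT)
    n_ns = sum(
        1
        for r in records
        if r.mutation_class in (MutationClass.MISSENSE, MutationClass.NONSENSE)
    )
    if n_ns == 0:
        return float("nan")
    return n_silent / n_ns
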