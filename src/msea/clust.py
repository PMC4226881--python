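"""The running-sum mutation-clustering test (MSEA-clust).

A walker traverses the amino-acid sequence keeping a mutation accumulation
score (MAS): at a mutated position j the score rises by y_j * S_inc with
S_inc = 1/sum(Y); at each non-mutated position it falls by
S_dec = 1/(number of non-mutated positions). Total rise and fall are both 1,
so the MAS bridges between 0 at both ends. The mutation enrichment score
MES = max(MAS) - min(MAS) measures the strongest cluster; its significance
comes from a randomization null that redraws the same number of mutation
records uniformly (with replacement, so recurrent mutations are representable)
across the transcript. The normalized score NES = (MES - mean(MES_pi))/sd(MES_pi)
makes transcripts of different lengths and mutation loads comparable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .io_model import TranscriptProfile

logger = logging.getLogger("msea")

__all__ = [
    "MasCurve",
    "ClustResult",
    "DegenerateTranscriptError",
    "UnscorableTranscriptError",
    "compute_mas",
    "mas_from_counts",
    "compute_mes",
    "default_n_perm",
    "randomization_null",
    "score_transcript",
    "silent_hotspot_veto",
    "child_seed",
]

#: permutation-count floor for very short transcripts, keeping the null
#: moments behind NES stable
N_PERM_FLOOR = 1000


class DegenerateTranscriptError(ValueError):
    """Every position is mutated (or none is): the decrement unit is undefined."""


class UnscorableTranscriptError(ValueError):
    """The randomization null is degenerate (zero spread), NES is undefined."""


@dataclass(slots=True)
class MasCurve:
    """The running-sum curve for one transcript.

    ``values[i-1]`` is the score after position i; ``argmax_pos``/``argmin_pos``
    are 1-based positions of the first occurrence of the extrema.
    """

    values: np.ndarray
    s_inc: float
    s_dec: float
    argmax_pos: int
    argmin_pos: int


@dataclass(slots=True)
class ClustResult:
    """Per-transcript outcome of the clustering test."""

    transcript_id: str
    gene: str
    n_mutations: int
    length_L: int
    mes: float
    nes: float
    p_empirical: float
    null_mean: float
    null_sd: float
    hotspot_start: int
    hotspot_end: int
    n_perm: int
    background_flagged: bool = False
    p_nominal: float | None = None
    p_adjusted: float | None = None


def mas_from_counts(counts: np.ndarray) -> MasCurve:
    """Build the running-sum curve from a per-position count vector."""
    y = np.asarray(counts)
    total = int(y.sum())
    if total < 1:
        raise DegenerateTranscriptError("no mutation records on transcript")
    mutated = y > 0
    n_unmutated = int((~mutated).sum())
    if n_unmutated == 0:
        raise DegenerateTranscriptError(
            "all positions mutated: decrement unit undefined"
        )
    s_inc = 1.0 / total
    s_dec = 1.0 / n_unmutated
    steps = np.where(mutated, y * s_inc, -s_dec)
    values = np.cumsum(steps)
    return MasCurve(
        values=values,
        s_inc=s_inc,
        s_dec=s_dec,
        argmax_pos=int(np.argmax(values)) + 1,
        argmin_pos=int(np.argmin(values)) + 1,
    )


def compute_mas(profile: TranscriptProfile) -> MasCurve:
    return mas_from_counts(profile.counts_Y)


def compute_mes(curve: MasCurve) -> tuple[float, int, int]:
    """MES = max(MAS) - min(MAS), plus the hotspot interval.

    The hotspot is the stretch over which the curve climbs from its minimum
    to its maximum. When the minimum precedes the maximum the climb happens
    over (argmin, argmax], so the interval is [argmin+1, argmax]; otherwise
    [argmax, argmin]. Endpoints are clamped to [1, L].
    """
    vmax = float(curve.values[curve.argmax_pos - 1])
    vmin = float(curve.values[curve.argmin_pos - 1])
    mes = vmax - vmin
    L = len(curve.values)
    if curve.argmin_pos < curve.argmax_pos:
        start, end = curve.argmin_pos + 1, curve.argmax_pos
    else:
        start, end = curve.argmax_pos, curve.argmin_pos
    start = max(1, min(start, L))
    end = max(1, min(end, L))
    return mes, start, end


def default_n_perm(L: int) -> int:
    """10 * L randomizations, floored at N_PERM_FLOOR for short transcripts."""
    return max(10 * L, N_PERM_FLOOR)


def _null_mes(
    L: int, n_records: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized randomization null: MES of n_perm uniform redraws.

    Each replicate places ``n_records`` records uniformly with replacement on
    positions 1..L. Replicates covering every position (possible only when
    n_records >= L) are redrawn, as the walk is undefined there.
    """
    pos = rng.integers(0, L, size=(n_perm, n_records))
    offsets = np.arange(n_perm, dtype=np.int64)[:, None] * L
    counts = np.bincount((pos + offsets).ravel(), minlength=n_perm * L).reshape(
        n_perm, L
    )
    n_mutated = (counts > 0).sum(axis=1)
    n_redrawn = 0
    while True:
        bad = np.flatnonzero(n_mutated == L)
        if bad.size == 0:
            break
        n_redrawn += bad.size
        repl = rng.integers(0, L, size=(bad.size, n_records))
        off = np.arange(bad.size, dtype=np.int64)[:, None] * L
        counts[bad] = np.bincount(
            (repl + off).ravel(), minlength=bad.size * L
        ).reshape(bad.size, L)
        n_mutated[bad] = (counts[bad] > 0).sum(axis=1)
    if n_redrawn:
        logger.info("redrew %d degenerate randomizations (all positions covered)", n_redrawn)
    s_dec = 1.0 / (L - n_mutated)
    steps = np.where(counts > 0, counts / n_records, -s_dec[:, None])
    mas = np.cumsum(steps, axis=1)
    return mas.max(axis=1) - mas.min(axis=1)


def randomization_null(
    profile: TranscriptProfile,
    n_perm: int | None = None,
    rng_seed: int = 0,
) -> np.ndarray:
    """Null MES distribution for one transcript, reproducible from the seed."""
    L = profile.length_L
    total = profile.n_records
    if total < 1:
        raise DegenerateTranscriptError("no mutation records on transcript")
    if bool((profile.counts_Y > 0).all()):
        raise DegenerateTranscriptError("all positions mutated: decrement unit undefined")
    if n_perm is None:
        n_perm = default_n_perm(L)
    rng = np.random.default_rng(rng_seed)
    return _null_mes(L, total, n_perm, rng)


def score_transcript(
    profile: TranscriptProfile,
    rng_seed: int,
    n_perm: int | None = None,
    pseudo_count: bool = False,
) -> ClustResult:
    """Score one transcript: MES, NES, empirical p, hotspot interval.

    The empirical p-value is #{MES_pi >= MES}/(1 + n_perm), which with the
    default n_perm = 10*L is the literal randomization-test formula; it can be
    exactly 0 when the observed MES exceeds every redraw. ``pseudo_count=True``
    switches to the conventional (1 + #{>=})/(1 + n_perm) variant.
    """
    curve = compute_mas(profile)
    mes, start, end = compute_mes(curve)
    null = randomization_null(profile, n_perm=n_perm, rng_seed=rng_seed)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd <= 0.0 or not np.isfinite(null_sd):
        raise UnscorableTranscriptError(
            f"transcript {profile.transcript_id}: null MES has zero spread"
        )
    nes = (mes - null_mean) / null_sd
    n_ge = int((null >= mes).sum())
    if pseudo_count:
        p = (1 + n_ge) / (1 + null.size)
    else:
        p = n_ge / (1 + null.size)
    return ClustResult(
        transcript_id=profile.transcript_id,
        gene=profile.gene,
        n_mutations=profile.n_records,
        length_L=profile.length_L,
        mes=mes,
        nes=nes,
        p_empirical=p,
        null_mean=null_mean,
        null_sd=null_sd,
        hotspot_start=start,
        hotspot_end=end,
        n_perm=int(null.size),
    )


def silent_hotspot_veto(
    background_profile: TranscriptProfile | None,
    rng_seed: int,
    min_records: int = 4,
    alpha: float = 0.05,
    n_perm: int | None = None,
) -> bool:
    """True when the transcript's background (silent) mutations themselves
    form a hotspot at nominal significance, vetoing any working-set hotspot.

    Backgrounds with fewer than ``min_records`` records (the same bar as
    working-set eligibility) are untestable: no veto.
    """
    if background_profile is None or background_profile.n_records < min_records:
        return False
    try:
        result = score_transcript(background_profile, rng_seed=rng_seed, n_perm=n_perm)
    except (DegenerateTranscriptError, UnscorableTranscriptError):
        return False
    return result.p_empirical < alpha


def child_seed(master_seed: int, transcript_id: str) -> int:
    """Deterministic per-transcript seed, independent of processing order."""
    digest = hashlib.blake2b(
        f"{master_seed}:{transcript_id}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "little") % (2**31)
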