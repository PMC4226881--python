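"""Synthetic-data generation and the power / type-I-error harness.

The simulation design mirrors the study conditions under which both hotspot
tests were characterized: proteins of length 500 (close to the RefSeq average
of 559 and median of 429), mutation loads of 4 and 8 records (the eligibility
bar is 4), mutation spanning windows of 10/50/100/200/300 residues swept
across the sequence for the clustering test, and single domains of length
100/200/300/400 with mutations confined to domain quarters (Q1..Q4) or the
whole domain for the domain test. Each scenario cell runs 100 replicate
datasets and reports power as the fraction with p < 0.05.

Generated records are missense mutations with synthetic sample IDs and flow
through the same I/O, profile-building and eligibility path as real data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from . import clust, domain
from .io_model import (
    MutationClass,
    MutationRecord,
    TranscriptProfile,
    build_profiles,
)

logger = logging.getLogger("msea")

__all__ = [
    "ClustScenario",
    "DomainScenario",
    "gen_clust_dataset",
    "gen_domain_dataset",
    "estimate_power",
    "location_starts",
    "run_grid",
]

#: domain quarters plus whole-domain placement; "uniform_L" is the null mode
#: that scatters mutations over the whole protein for type-I evaluation
ZONES = ("Q1", "Q2", "Q3", "Q4", "whole", "uniform_L")


@dataclass(frozen=True)
class ClustScenario:
    """One cell of the clustering-test power grid."""

    L: int = 500
    span_W: int = 50
    span_start: int = 1
    n_mut: int = 8
    recurrent: bool = False
    n_reps: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.span_start + self.span_W - 1 > self.L:
            raise ValueError("mutation spanning window exceeds protein length")
        if not self.recurrent and self.n_mut > self.span_W:
            raise ValueError(
                "cannot place more distinct mutations than window positions"
            )


@dataclass(frozen=True)
class DomainScenario:
    """One cell of the domain-test power grid (single centered domain)."""

    L: int = 500
    domain_len: int = 100
    domain_start: int | None = None
    mutation_zone: str = "whole"
    n_mut: int = 8
    recurrent: bool = False
    n_reps: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutation_zone not in ZONES:
            raise ValueError(f"unknown mutation zone {self.mutation_zone!r}")
        start = self.start
        if start < 1 or start + self.domain_len - 1 > self.L:
            raise ValueError("domain exceeds protein bounds")
        lo, hi = self.zone_bounds()
        if not self.recurrent and self.n_mut > hi - lo + 1:
            raise ValueError(
                "cannot place more distinct mutations than zone positions"
            )

    @property
    def start(self) -> int:
        """Domain start; defaults to centering the domain in the protein."""
        if self.domain_start is not None:
            return self.domain_start
        return (self.L - self.domain_len) // 2 + 1

    def zone_bounds(self) -> tuple[int, int]:
        """1-based inclusive bounds of the mutation placement zone.

        Quarter boundaries are computed on the domain and rounded half-up.
        """
        if self.mutation_zone == "uniform_L":
            return 1, self.L
        start = self.start
        if self.mutation_zone == "whole":
            return start, start + self.domain_len - 1
        q = int(self.mutation_zone[1])
        rel_lo = _round_half_up((q - 1) * self.domain_len / 4.0) + 1
        rel_hi = _round_half_up(q * self.domain_len / 4.0)
        return start + rel_lo - 1, start + rel_hi - 1


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _rep_rng(seed: int, rep: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, rep, stream]))


def _draw_positions(
    rng: np.random.Generator, lo: int, hi: int, n: int, recurrent: bool
) -> np.ndarray:
    if recurrent:
        return rng.integers(lo, hi + 1, size=n)
    return rng.choice(np.arange(lo, hi + 1), size=n, replace=False)


def _records_from_positions(
    positions: np.ndarray, transcript_id: str = "simT1", gene: str = "SIMG1"
) -> list[MutationRecord]:
    return [
        MutationRecord(
            gene=gene,
            transcript_id=transcript_id,
            sample_id=f"sim_s{i + 1}",
            aa_position=int(p),
            mutation_class=MutationClass.MISSENSE,
        )
        for i, p in enumerate(positions)
    ]


def _transcript_table(L: int, transcript_id: str = "simT1", gene: str = "SIMG1"):
    return pd.DataFrame(
        {"transcript_id": [transcript_id], "gene": [gene], "aa_length": [L]}
    )


def gen_clust_dataset(s: ClustScenario, rep: int) -> TranscriptProfile:
    """One replicate dataset: n_mut records inside the spanning window.

    Positions are uniform over [span_start, span_start+span_W-1], with
    replacement iff recurrent, else distinct. Deterministic under (seed, rep).
    """
    rng = _rep_rng(s.seed, rep)
    lo, hi = s.span_start, s.span_start + s.span_W - 1
    positions = _draw_positions(rng, lo, hi, s.n_mut, s.recurrent)
    profiles = build_profiles(
        _records_from_positions(positions), _transcript_table(s.L)
    )
    return profiles[0]


def gen_domain_dataset(s: DomainScenario, rep: int) -> TranscriptProfile:
    """One replicate dataset with a single annotated domain.

    Mutations land uniformly in the selected domain zone (or over the whole
    protein in the "uniform_L" null mode).
    """
    rng = _rep_rng(s.seed, rep)
    lo, hi = s.zone_bounds()
    positions = _draw_positions(rng, lo, hi, s.n_mut, s.recurrent)
    start = s.start
    domains = pd.DataFrame(
        {
            "transcript_id": ["simT1"],
            "domain_id": ["simdom1"],
            "domain_name": ["simulated domain"],
            "aa_start": [start],
            "aa_end": [start + s.domain_len - 1],
        }
    )
    profiles = build_profiles(
        _records_from_positions(positions), _transcript_table(s.L), domains
    )
    return profiles[0]


def _clust_rep_p(s: ClustScenario, rep: int) -> float:
    profile = gen_clust_dataset(s, rep)
    result = clust.score_transcript(
        profile, rng_seed=int(_rep_rng(s.seed, rep, stream=1).integers(2**31))
    )
    return result.p_empirical


def _domain_rep_p(s: DomainScenario, rep: int) -> float:
    profile = gen_domain_dataset(s, rep)
    results = domain.test_transcript(profile)
    try:
        p, _ = domain.summarize_transcript(results)
    except domain.UntestableTranscriptError:
        return 1.0
    return p


def estimate_power(
    scenario: ClustScenario | DomainScenario, method: str
) -> tuple[float, float]:
    """Power (fraction of replicates with p < alpha) and its binomial SE.

    The clustering test uses the per-transcript empirical p; the domain test
    the min-over-models LRT p. No pooled calibration runs inside the power
    loop — each replicate is a single-transcript experiment.
    """
    if method == "clust":
        if not isinstance(scenario, ClustScenario):
            raise TypeError("clust power needs a ClustScenario")
        rep_p = _clust_rep_p
    elif method == "domain":
        if not isinstance(scenario, DomainScenario):
            raise TypeError("domain power needs a DomainScenario")
        rep_p = _domain_rep_p
    else:
        raise ValueError(f"unknown method {method!r}")
    n = scenario.n_reps
    hits = sum(rep_p(scenario, rep) < scenario.alpha for rep in range(n))
    power = hits / n
    se = float(np.sqrt(power * (1.0 - power) / n))
    return power, se


def location_starts(L: int, W: int, max_locations: int = 10) -> list[int]:
    """Evenly spaced window starts whose union covers the whole sequence."""
    n = min(int(np.ceil(L / W)), max_locations)
    if n == 1:
        return [1]
    return [
        1 + _round_half_up(i * (L - W) / (n - 1)) for i in range(n)
    ]


_CLUST_FIELDS = {f.name for f in fields(ClustScenario)}
_DOMAIN_FIELDS = {f.name for f in fields(DomainScenario)}


def run_grid(config: dict, method: str, seed: int | None = None) -> pd.DataFrame:
    """Run a power grid from a config mapping of scenario fields to lists.

    Scalar values are broadcast; ``span_start: "sweep"`` (clust only) expands
    into the covering location sweep for each window length. Returns a
    long-format table with one row per scenario cell plus power and SE.
    Reruns with the same master seed are identical.
    """
    allowed = _CLUST_FIELDS if method == "clust" else _DOMAIN_FIELDS
    cls = ClustScenario if method == "clust" else DomainScenario
    unknown = set(config) - allowed
    if unknown:
        raise ValueError(f"unknown grid keys: {sorted(unknown)}")
    grid = {
        k: (v if isinstance(v, (list, tuple)) else [v]) for k, v in config.items()
    }
    if seed is not None:
        grid["seed"] = [seed]
    keys = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        sweep = method == "clust" and params.get("span_start") == "sweep"
        if sweep:
            base = {k: v for k, v in params.items() if k != "span_start"}
            probe = cls(**base)
            starts = location_starts(probe.L, probe.span_W)
        else:
            starts = [params.get("span_start")]
        for start in starts:
            p = dict(params)
            if start is not None:
                p["span_start"] = start
            elif "span_start" in p and p["span_start"] is None:
                del p["span_start"]
            scenario = cls(**p)
            power, se = estimate_power(scenario, method)
            row = {f.name: getattr(scenario, f.name) for f in fields(cls)}
            row.update(power=power, se=se)
            rows.append(row)
    columns = [f.name for f in fields(cls)] + ["power", "se"]
    return pd.DataFrame(rows, columns=columns)
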