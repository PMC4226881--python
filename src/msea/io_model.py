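"""Domain types, mutation classification, scenario construction, and tabular I/O.

Mutation set enrichment analysis works on amino-acid-space mutation records:
one record is one mutation observed in one sample, positioned on a transcript's
protein sequence (1-based codon numbering, e.g. IDH1 codon 132). This module
defines the record/profile types shared by both hotspot tests, the working vs.
background mutation-set scenarios, and readers for the three tab-delimited
inputs (mutations, transcript lengths, domain annotations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("msea")

__all__ = [
    "MutationClass",
    "MutationRecord",
    "DomainAnnotation",
    "TranscriptProfile",
    "MutationSetScenario",
    "Dialect",
    "DEFAULT_DIALECT",
    "MAF_DIALECT",
    "CLUST_SCENARIOS",
    "DOMAIN_SCENARIOS",
    "ReadReport",
    "read_mutations",
    "write_mutations",
    "read_transcripts",
    "read_domains",
    "classify_and_split",
    "build_profiles",
    "eligibility_filter",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when an input file or column mapping is unusable."""


class MutationClass(str, Enum):
    """Functional class of a somatic mutation in protein space."""

    SILENT = "silent"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"


#: classes that are single-nucleotide variants (indels excluded)
SNV_CLASSES = frozenset(
    {MutationClass.SILENT, MutationClass.MISSENSE, MutationClass.NONSENSE}
)
INDEL_CLASSES = frozenset(
    {MutationClass.FRAMESHIFT_INDEL, MutationClass.INFRAME_INDEL}
)


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One observed mutation in one sample.

    ``aa_position`` is the 1-based amino-acid index of the affected residue;
    for indels it is the first affected residue (a p.125_128del counts at 125).
    ``deleterious`` carries an optional precomputed prediction (e.g. from
    SIFT / PolyPhen-2 / MutationAssessor); None means no prediction available
    and is treated as benign by deleteriousness-filtered scenarios.
    """

    gene: str
    transcript_id: str
    sample_id: str
    aa_position: int
    mutation_class: MutationClass
    deleterious: bool | None = None
    change: str = ""  # optional reference/alternate string, part of dedup key

    def dedup_key(self) -> tuple:
        return (
            self.transcript_id,
            self.aa_position,
            self.mutation_class,
            self.change,
            self.sample_id,
        )


@dataclass(frozen=True, slots=True)
class DomainAnnotation:
    """A protein domain interval on a transcript, 1-based inclusive."""

    domain_id: str
    domain_name: str
    aa_start: int
    aa_end: int


@dataclass(slots=True)
class TranscriptProfile:
    """Per-transcript working state for hotspot analysis.

    ``counts_Y`` is the length-L integer vector of mutation-record counts per
    amino-acid position (position j stored at index j-1).
    """

    transcript_id: str
    gene: str
    length_L: int
    counts_Y: np.ndarray
    domains: list[DomainAnnotation] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return int(self.counts_Y.sum())

    @property
    def mutated_positions(self) -> set[int]:
        """1-based positions carrying at least one mutation record."""
        return set((np.flatnonzero(self.counts_Y) + 1).tolist())


# ---------------------------------------------------------------------------
# Mutation-set scenarios
# ---------------------------------------------------------------------------

# A record is matched against a scenario through a tag that folds the
# deleteriousness flag into the missense class; all other classes keep their
# plain name.  A missing flag counts as benign.
_DEL_MISSENSE = "missense_deleterious"
_BENIGN_MISSENSE = "missense_benign"


def _record_tag(record: MutationRecord) -> str:
    if record.mutation_class is MutationClass.MISSENSE:
        return _DEL_MISSENSE if record.deleterious else _BENIGN_MISSENSE
    return record.mutation_class.value


@dataclass(frozen=True)
class MutationSetScenario:
    """A (working, background) partition of mutation classes.

    Working mutations drive hotspot detection; background mutations (silent
    SNVs, optionally plus benign missense SNVs for the "Splus" variants) form
    the null set used for the silent-hotspot veto and empirical-null
    estimation. The two tag sets are disjoint by construction.
    """

    name: str
    working_tags: frozenset[str]
    background_tags: frozenset[str]

    def __post_init__(self) -> None:
        if self.working_tags & self.background_tags:
            raise ConfigurationError(
                f"scenario {self.name!r}: working and background sets overlap"
            )

    @property
    def uses_deleteriousness(self) -> bool:
        return not (
            _DEL_MISSENSE in self.working_tags
            and _BENIGN_MISSENSE in self.working_tags
        ) and _DEL_MISSENSE in (self.working_tags | self.background_tags)


_NS = frozenset({_DEL_MISSENSE, _BENIGN_MISSENSE, "nonsense", "splice"})
_DEL_NS = frozenset({_DEL_MISSENSE, "nonsense", "splice"})
_INDELS = frozenset({"frameshift_indel", "inframe_indel"})
_S = frozenset({"silent"})
_SPLUS = frozenset({"silent", _BENIGN_MISSENSE})

#: the six working/background scenarios for the clustering test
CLUST_SCENARIOS: dict[str, MutationSetScenario] = {
    s.name: s
    for s in (
        MutationSetScenario("NS/S", _NS, _S),
        MutationSetScenario("(del NS)/S", _DEL_NS, _S),
        MutationSetScenario("(del NS)/Splus", _DEL_NS, _SPLUS),
        MutationSetScenario("(NS+I)/S", _NS | _INDELS, _S),
        MutationSetScenario("(del NS+I)/S", _DEL_NS | _INDELS, _S),
        MutationSetScenario("(del NS+I)/Splus", _DEL_NS | _INDELS, _SPLUS),
    )
}

#: the four working-set scenarios for the domain test (background kept for
#: symmetry; the domain test does not use pooled calibration)
DOMAIN_SCENARIOS: dict[str, MutationSetScenario] = {
    s.name: s
    for s in (
        MutationSetScenario("NS", _NS, _S),
        MutationSetScenario("del NS", _DEL_NS, _S),
        MutationSetScenario("NS+I", _NS | _INDELS, _S),
        MutationSetScenario("del NS+I", _DEL_NS | _INDELS, _S),
    )
}


def classify_and_split(
    records: Sequence[MutationRecord], scenario: MutationSetScenario
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Partition records into (working, background) per the scenario.

    Records matching neither set (e.g. benign missense under "(del NS)/S")
    fall out of both. If the scenario filters on deleteriousness but no record
    carries a flag, a warning is logged and all missense are treated as benign.
    """
    if scenario.uses_deleteriousness and not any(
        r.deleterious is not None
        for r in records
        if r.mutation_class is MutationClass.MISSENSE
    ):
        logger.warning(
            "scenario %s filters on deleteriousness but no record carries a "
            "prediction; all missense SNVs treated as benign",
            scenario.name,
        )
    working = [r for r in records if _record_tag(r) in scenario.working_tags]
    background = [r for r in records if _record_tag(r) in scenario.background_tags]
    return working, background


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dialect:
    """Column mapping for the mutation table plus class-name translation."""

    gene: str = "gene"
    transcript: str = "transcript"
    sample: str = "sample"
    aa_position: str = "aa_position"
    mutation_class: str = "class"
    deleterious: str | None = "deleterious"
    change: str | None = "change"
    class_map: Mapping[str, MutationClass] = field(
        default_factory=lambda: {c.value: c for c in MutationClass}
    )


DEFAULT_DIALECT = Dialect()

#: mapping for MAF-style files (Variant_Classification vocabulary)
MAF_DIALECT = Dialect(
    gene="Hugo_Symbol",
    transcript="Transcript_ID",
    sample="Tumor_Sample_Barcode",
    aa_position="Protein_position",
    mutation_class="Variant_Classification",
    deleterious=None,
    change="HGVSp_Short",
    class_map={
        "Silent": MutationClass.SILENT,
        "Missense_Mutation": MutationClass.MISSENSE,
        "Nonsense_Mutation": MutationClass.NONSENSE,
        "Frame_Shift_Del": MutationClass.FRAMESHIFT_INDEL,
        "Frame_Shift_Ins": MutationClass.FRAMESHIFT_INDEL,
        "In_Frame_Del": MutationClass.INFRAME_INDEL,
        "In_Frame_Ins": MutationClass.INFRAME_INDEL,
        "Splice_Site": MutationClass.SPLICE,
    },
)

_TRUE = {"true", "1", "t", "yes", "y"}
_FALSE = {"false", "0", "f", "no", "n"}


@dataclass
class ReadReport:
    """Filtering tallies for one mutation-file read."""

    n_rows: int = 0
    n_retained: int = 0
    n_duplicates: int = 0
    n_missing_position: int = 0
    n_unknown_class: int = 0


def read_mutations(
    path,
    dialect: Dialect = DEFAULT_DIALECT,
    return_report: bool = False,
) -> list[MutationRecord] | tuple[list[MutationRecord], ReadReport]:
    """Read a tab-delimited mutation table into deduplicated records.

    Records are unique on (transcript, position, class, change, sample); rows
    with an unparseable position or an unknown class are dropped and tallied.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (
        dialect.gene,
        dialect.transcript,
        dialect.sample,
        dialect.aa_position,
        dialect.mutation_class,
    ):
        if col not in df.columns:
            raise ConfigurationError(f"mutation table lacks required column {col!r}")

    report = ReadReport(n_rows=len(df))
    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    has_del = dialect.deleterious is not None and dialect.deleterious in df.columns
    has_change = dialect.change is not None and dialect.change in df.columns
    for row in df.to_dict("records"):
        raw_pos = str(row[dialect.aa_position]).strip()
        try:
            pos = int(float(raw_pos))
            if pos < 1:
                raise ValueError
        except ValueError:
            report.n_missing_position += 1
            continue
        raw_class = str(row[dialect.mutation_class]).strip()
        mclass = dialect.class_map.get(raw_class)
        if mclass is None:
            report.n_unknown_class += 1
            continue
        deleterious: bool | None = None
        if has_del:
            raw = str(row[dialect.deleterious]).strip().lower()
            if raw in _TRUE:
                deleterious = True
            elif raw in _FALSE:
                deleterious = False
        record = MutationRecord(
            gene=str(row[dialect.gene]).strip(),
            transcript_id=str(row[dialect.transcript]).strip(),
            sample_id=str(row[dialect.sample]).strip(),
            aa_position=pos,
            mutation_class=mclass,
            deleterious=deleterious,
            change=str(row[dialect.change]).strip() if has_change else "",
        )
        key = record.dedup_key()
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        records.append(record)
    report.n_retained = len(records)
    logger.info(
        "read %d rows from %s: retained %d, duplicates %d, "
        "missing/invalid position %d, unknown class %d",
        report.n_rows,
        path,
        report.n_retained,
        report.n_duplicates,
        report.n_missing_position,
        report.n_unknown_class,
    )
    if return_report:
        return records, report
    return records


def write_mutations(records: Iterable[MutationRecord], path) -> None:
    """Write records as a default-dialect TSV (round-trips with read_mutations)."""
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "transcript": [r.transcript_id for r in records],
            "sample": [r.sample_id for r in records],
            "aa_position": [r.aa_position for r in records],
            "class": [r.mutation_class.value for r in records],
            "deleterious": [
                "" if r.deleterious is None else str(r.deleterious).lower()
                for r in records
            ],
            "change": [r.change for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_transcripts(path) -> pd.DataFrame:
    """Read the transcript annotation table (transcript_id, gene, aa_length)."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene": str})
    for col in ("transcript_id", "gene", "aa_length"):
        if col not in df.columns:
            raise ConfigurationError(f"transcript table lacks column {col!r}")
    df["aa_length"] = df["aa_length"].astype(int)
    return df


def read_domains(path) -> pd.DataFrame:
    """Read the domain annotation table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("transcript_id", "domain_id", "domain_name", "aa_start", "aa_end"):
        if col not in df.columns:
            raise ConfigurationError(f"domain table lacks column {col!r}")
    df["aa_start"] = df["aa_start"].astype(int)
    df["aa_end"] = df["aa_end"].astype(int)
    return df


# ---------------------------------------------------------------------------
# Profiles and eligibility
# ---------------------------------------------------------------------------


def build_profiles(
    records: Sequence[MutationRecord],
    transcripts: pd.DataFrame,
    domains: pd.DataFrame | None = None,
) -> list[TranscriptProfile]:
    """Tally records into one TranscriptProfile per mutated transcript.

    Records whose transcript is absent from the annotation, or whose position
    exceeds the annotated amino-acid length (an annotation-version mismatch
    signal), are dropped with a warning. Domain rows with coordinates outside
    [1, L] are rejected with a warning.
    """
    lengths = dict(zip(transcripts["transcript_id"], transcripts["aa_length"]))
    genes = dict(zip(transcripts["transcript_id"], transcripts["gene"]))

    by_transcript: dict[str, list[MutationRecord]] = {}
    n_unknown = n_out_of_range = 0
    for r in records:
        L = lengths.get(r.transcript_id)
        if L is None:
            n_unknown += 1
            continue
        if r.aa_position > L:
            n_out_of_range += 1
            continue
        by_transcript.setdefault(r.transcript_id, []).append(r)
    if n_unknown:
        logger.warning("%d records on transcripts absent from annotation; dropped", n_unknown)
    if n_out_of_range:
        logger.warning(
            "%d records with aa_position beyond transcript length; dropped "
            "(possible annotation-version mismatch)",
            n_out_of_range,
        )

    domain_map: dict[str, list[DomainAnnotation]] = {}
    if domains is not None:
        n_bad_domains = 0
        for row in domains.itertuples(index=False):
            L = lengths.get(row.transcript_id)
            if L is None or not (1 <= row.aa_start <= row.aa_end <= L):
                n_bad_domains += 1
                continue
            domain_map.setdefault(row.transcript_id, []).append(
                DomainAnnotation(
                    domain_id=str(row.domain_id),
                    domain_name=str(row.domain_name),
                    aa_start=int(row.aa_start),
                    aa_end=int(row.aa_end),
                )
            )
        if n_bad_domains:
            logger.warning("%d domain rows with invalid coordinates; rejected", n_bad_domains)

    profiles = []
    for tid in sorted(by_transcript):
        recs = by_transcript[tid]
        L = int(lengths[tid])
        counts = np.zeros(L, dtype=np.int64)
        for r in recs:
            counts[r.aa_position - 1] += 1
        profiles.append(
            TranscriptProfile(
                transcript_id=tid,
                gene=str(genes[tid]),
                length_L=L,
                counts_Y=counts,
                domains=sorted(
                    domain_map.get(tid, []), key=lambda d: (d.aa_start, d.aa_end, d.domain_id)
                ),
            )
        )
    return profiles


def eligibility_filter(
    profiles: Sequence[TranscriptProfile],
    min_mutations: int = 4,
    require_domains: bool = False,
) -> list[TranscriptProfile]:
    """Keep transcripts with at least ``min_mutations`` working records.

    The domain test additionally requires at least one domain annotation
    (``require_domains=True``).
    """
    kept = []
    for p in profiles:
        if p.n_records < min_mutations:
            logger.info(
                "transcript %s ineligible: %d records < %d",
                p.transcript_id, p.n_records, min_mutations,
            )
            continue
        if require_domains and not p.domains:
            logger.info("transcript %s ineligible: no domain annotation", p.transcript_id)
            continue
        kept.append(p)
    return kept
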