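"""Filtering and mapping of enrichment-library reads.

The selection rules mirror the standard pipeline for 454-era enriched
libraries: keep reads strictly longer than 80 bp, keep those containing at
least four repeats of a perfect microsatellite of any 2-6 bp motif, map
against the source genome, and accept a read only when a hit aligns at
least 90% of the read length at e-value <= 1e-40.  Accepted reads carry an
oriented genomic interval whose midpoint feeds the four-way tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .repeatscan import PROBE_SETS, SSRLocus, find_ssrs, is_target_motif

__all__ = [
    "ReadRecord",
    "AnnotatedRead",
    "MappingHit",
    "ReadAssignment",
    "LibrarySummary",
    "filter_reads",
    "select_ssr_reads",
    "parse_blast_tabular",
    "filter_hits",
    "assign_reads",
    "summarize_library",
]


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotatedRead:
    """A selected read together with its SSR loci.

    ``has_target`` is True when at least one locus belongs to the probe set
    under which the library was built (a read kept only for a non-probe
    motif such as AT is flagged False).
    """

    read: ReadRecord
    loci: tuple[SSRLocus, ...]
    has_target: bool


@dataclass(frozen=True)
class MappingHit:
    """One row of 12-column BLAST tabular output (outfmt 6)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_openings: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float


@dataclass(frozen=True)
class ReadAssignment:
    """A read accepted by the hit filter, placed on the genome."""

    read_id: str
    chromosome: str
    start: int  # oriented: start <= end
    end: int
    read_length: int
    loci: tuple[SSRLocus, ...] = ()

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class LibrarySummary:
    """Per-library counts and the three derived percentages.

    ``pct_over_80`` = 100 * reads_over_80bp / total_reads,
    ``pct_with_ssr`` = 100 * reads_with_ssr / reads_over_80bp,
    ``pct_with_primer`` = 100 * primer_designed / reads_with_ssr,
    each rounded half-up to one decimal.  A percentage with a zero
    denominator (or absent primer count) is None.
    """

    total_reads: int
    reads_over_80bp: int
    reads_with_ssr: int
    primer_designed: int | None
    pct_over_80: float | None
    pct_with_ssr: float | None
    pct_with_primer: float | None


def filter_reads(reads: Iterable[ReadRecord], min_length: int = 80) -> list[ReadRecord]:
    """Keep reads strictly longer than *min_length* bp."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    return [r for r in reads if r.length > min_length]


def select_ssr_reads(
    reads: Iterable[ReadRecord],
    min_repeats: int = 4,
    motif_lengths: Sequence[int] = range(2, 7),
    probe_set: Iterable[str] = PROBE_SETS[8],
) -> list[AnnotatedRead]:
    """Keep reads with >= 1 perfect SSR of any 2-6 bp motif.

    Selection is motif-agnostic (a read with only an AT repeat is kept);
    each kept read is annotated with all its loci and a flag saying whether
    any locus matches the probe set.
    """
    probes = frozenset(probe_set)
    out: list[AnnotatedRead] = []
    for read in reads:
        loci = find_ssrs(read.sequence, min_repeats, motif_lengths, read.read_id)
        if loci:
            flag = any(is_target_motif(loc.motif, probes) for loc in loci)
            out.append(AnnotatedRead(read, tuple(loci), flag))
    return out


def parse_blast_tabular(source: Iterable[str] | str) -> list[MappingHit]:
    """Parse 12-column BLAST tabular text ('#' comment lines ignored).

    *source* may be a path or an iterable of lines.  A malformed row raises
    ``ValueError`` naming the 1-based line number.
    """
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    hits: list[MappingHit] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(parts) != 12:
            raise ValueError(f"line {lineno}: expected 12 columns, got {len(parts)}")
        try:
            hits.append(
                MappingHit(
                    parts[0],
                    parts[1],
                    float(parts[2]),
                    int(parts[3]),
                    int(parts[4]),
                    int(parts[5]),
                    int(parts[6]),
                    int(parts[7]),
                    int(parts[8]),
                    int(parts[9]),
                    float(parts[10]),
                    float(parts[11]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed hit row ({exc})") from None
    return hits


def filter_hits(
    hits: Iterable[MappingHit],
    read_lengths: Mapping[str, int],
    min_query_coverage: float = 0.90,
    max_evalue: float = 1e-40,
) -> dict[str, MappingHit]:
    """At most one accepted hit per read.

    A hit survives when its e-value is <= *max_evalue* and its alignment
    length covers at least *min_query_coverage* of the read length.  Among
    survivors the single best hit by bit score wins; an exact bit-score tie
    between different subject locations leaves the read unassigned (avoids
    double counting of repetitive placements).
    """
    best: dict[str, MappingHit] = {}
    tied: set[str] = set()
    for hit in hits:
        qid = hit.query_id
        if qid not in read_lengths:
            continue
        if hit.e_value > max_evalue:
            continue
        if hit.alignment_length < min_query_coverage * read_lengths[qid]:
            continue
        cur = best.get(qid)
        if cur is None or hit.bit_score > cur.bit_score:
            best[qid] = hit
            tied.discard(qid)
        elif hit.bit_score == cur.bit_score and (
            hit.subject_id != cur.subject_id
            or {hit.subject_start, hit.subject_end}
            != {cur.subject_start, cur.subject_end}
        ):
            tied.add(qid)
    for qid in tied:
        del best[qid]
    return best


def assign_reads(
    accepted: Mapping[str, MappingHit],
    annotated: Mapping[str, AnnotatedRead],
    chromosome_lengths: Mapping[str, int],
) -> list[ReadAssignment]:
    """Place accepted reads on the genome with oriented intervals.

    The subject interval is oriented so start <= end (minus-strand hits are
    flipped); the assignment carries the read's SSR loci so it can feed
    ``tabulation.build_read_dataset`` directly.  A hit against a subject id
    absent from the genome raises ``KeyError``.
    """
    out: list[ReadAssignment] = []
    for qid, hit in accepted.items():
        if hit.subject_id not in chromosome_lengths:
            raise KeyError(f"hit subject {hit.subject_id!r} not in genome")
        s, e = sorted((hit.subject_start, hit.subject_end))
        ann = annotated.get(qid)
        loci = ann.loci if ann is not None else ()
        length = ann.read.length if ann is not None else e - s + 1
        out.append(ReadAssignment(qid, hit.subject_id, s, e, length, loci))
    out.sort(key=lambda a: a.read_id)
    return out


def _pct(numer: int, denom: int) -> float | None:
    if denom == 0:
        return None
    return float(
        (Decimal(100) * Decimal(numer) / Decimal(denom)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def summarize_library(
    total_reads: int,
    reads_over_80bp: int,
    reads_with_ssr: int,
    primer_designed: int | None = None,
) -> LibrarySummary:
    """Library summary with the three nested percentages.

    ``primer_designed`` is an externally supplied count (primer design is
    performed by a downstream tool, never here); when absent the primer
    percentage is omitted.
    """
    if not 0 <= reads_with_ssr <= reads_over_80bp <= total_reads:
        raise ValueError("counts must satisfy with_ssr <= over80 <= total")
    return LibrarySummary(
        total_reads,
        reads_over_80bp,
        reads_with_ssr,
        primer_designed,
        _pct(reads_over_80bp, total_reads),
        _pct(reads_with_ssr, reads_over_80bp),
        None if primer_designed is None else _pct(primer_designed, reads_with_ssr),
    )
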