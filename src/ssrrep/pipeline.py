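"""End-to-end orchestration: digest -> scan -> tabulate -> compare.

These functions tie the stage modules together so that a genome FASTA plus
an enriched read library (with mapping hits) can be turned into the full
battery of representativeness statistics in one call.  Each stage remains
usable on its own.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import repstats
from .digestion import Fragment, digest, scan_fragments
from .read_pipeline import (
    AnnotatedRead,
    MappingHit,
    ReadAssignment,
    ReadRecord,
    assign_reads,
    filter_hits,
    filter_reads,
    select_ssr_reads,
)
from .repeatscan import PROBE_SETS, SSRLocus
from .repstats import TestResult
from .tabulation import (
    AXES,
    FourWayTable,
    ReferenceDistribution,
    build_genome_dataset,
    build_read_dataset,
    marginalize,
    reference_probabilities,
)

__all__ = ["GenomeScan", "ReadPipelineResult", "ComparisonReport",
           "genome_fourway", "run_read_pipeline", "compare_tables"]

TWO_WAY_PAIRS = ("ij", "ik", "il", "jk", "jl", "kl")


@dataclass
class GenomeScan:
    """Digested and scanned genome with its four-way table."""

    table: FourWayTable
    chromosome_lengths: dict[str, int]
    fragment_loci: dict[str, list[tuple[Fragment, list[SSRLocus]]]]

    @property
    def reference(self) -> ReferenceDistribution:
        return reference_probabilities(self.table)


def genome_fourway(
    sequences: Mapping[str, str],
    probe_set: Iterable[str] = PROBE_SETS[8],
    min_repeats: int = 4,
    motif_lengths: Sequence[int] = range(2, 7),
    motifs: Sequence[str] | None = None,
) -> GenomeScan:
    """Digest every chromosome with RsaI, scan fragments, build the table."""
    lengths = {name: len(seq) for name, seq in sequences.items()}
    fragment_loci: dict[str, list[tuple[Fragment, list[SSRLocus]]]] = {}
    for name, seq in sequences.items():
        frags = digest(seq, chromosome_id=name)
        fragment_loci[name] = scan_fragments(seq, frags, min_repeats, motif_lengths)
    table = build_genome_dataset(
        itertools.chain.from_iterable(fragment_loci.values()),
        lengths,
        probe_set,
        motifs=motifs,
    )
    return GenomeScan(table, lengths, fragment_loci)


@dataclass
class ReadPipelineResult:
    table: FourWayTable
    assignments: list[ReadAssignment]
    annotated: dict[str, AnnotatedRead]
    total_reads: int
    reads_over_80bp: int
    reads_with_ssr: int


def run_read_pipeline(
    reads: Iterable[ReadRecord],
    hits: Iterable[MappingHit],
    chromosome_lengths: Mapping[str, int],
    probe_set: Iterable[str] = PROBE_SETS[8],
    min_repeats: int = 4,
    min_length: int = 80,
    min_query_coverage: float = 0.90,
    max_evalue: float = 1e-40,
    motifs: Sequence[str] | None = None,
) -> ReadPipelineResult:
    """Length filter, SSR selection, hit filter, assignment, tabulation."""
    reads = list(reads)
    kept = filter_reads(reads, min_length)
    annotated = {
        a.read.read_id: a
        for a in select_ssr_reads(kept, min_repeats, probe_set=probe_set)
    }
    read_lengths = {rid: a.read.length for rid, a in annotated.items()}
    best = filter_hits(hits, read_lengths, min_query_coverage, max_evalue)
    assignments = assign_reads(best, annotated, chromosome_lengths)
    table = build_read_dataset(
        assignments, chromosome_lengths, probe_set, motifs=motifs
    )
    return ReadPipelineResult(
        table, assignments, annotated, len(reads), len(kept), len(annotated)
    )


@dataclass
class ComparisonReport:
    """Battery of comparisons between a read table and its genome reference."""

    one_way: dict[str, TestResult]
    one_way_envelopes: dict[str, tuple]
    two_way: dict[str, TestResult]
    cell_results: dict[str, list]
    global_gof: TestResult
    counts_outside_support: int
    n_observed: int
    n_reference: int


def compare_tables(
    read_table: FourWayTable,
    genome_table: FourWayTable,
    B: int = 9999,
    seed: int | None = None,
    alpha: float = 0.05,
    level: float = 0.95,
) -> ComparisonReport:
    """One-way GOF tests, envelopes, two-way independence tests, cell tests.

    One-way comparisons test each marginal of the read table against the
    corresponding marginal of the genome-digest reference; two-way tests
    are independence tests on marginals of the read table itself.  The
    global four-way GOF is computed on the reference support (counts in
    reference-empty cells are reported separately, see
    ``repstats.restrict_to_support``).  Monte-Carlo p-values (seeded) are
    used whenever expected counts drop below 5.
    """
    if read_table.chromosomes != genome_table.chromosomes:
        raise ValueError("read and genome tables index different chromosomes")
    ref = reference_probabilities(genome_table)
    n = read_table.n
    one_way: dict[str, TestResult] = {}
    envelopes: dict[str, tuple] = {}
    cell_results: dict[str, list] = {}
    for axis in AXES:
        obs = marginalize(read_table, axis).to_numpy()
        gen = marginalize(genome_table, axis).to_numpy().astype(float)
        probs = gen / gen.sum()
        res = repstats.global_gof(obs, probs, B=B, seed=seed)
        one_way[axis] = res
        envelopes[axis] = repstats.expected_envelope(n, probs, level)
        if res.p < alpha:
            cell_results[axis] = repstats.cell_tests(obs, probs, alpha)
    two_way: dict[str, TestResult] = {}
    for pair in TWO_WAY_PAIRS:
        tab = marginalize(read_table, pair).to_numpy().astype(float)
        try:
            res = repstats.chi2_independence(tab)
        except ValueError:
            continue
        t = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        E = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        if (E < 5).any():
            res = repstats.mc_null_pvalue(tab, independence=True, B=B, seed=seed)
        two_way[pair] = res
        if res.p < alpha:
            probs = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum() ** 2
            cell_results[pair] = repstats.cell_tests(
                t.astype(int), probs / probs.sum(), alpha
            )
    obs_sub, p_sub, outside = repstats.restrict_to_support(
        read_table.counts, ref.probabilities
    )
    overall = repstats.global_gof(obs_sub, p_sub, B=B, seed=seed)
    return ComparisonReport(
        one_way, envelopes, two_way, cell_results, overall, outside, n, genome_table.n
    )


def chromosome_region_cell_chi2(
    read_table: FourWayTable, genome_table: FourWayTable
) -> np.ndarray:
    """Per-cell chi2 contributions of the chromosome x region comparison.

    The observed chromosome x region marginal of the read table is compared
    against the genome-digest marginal; the (O-E)^2/E contribution of every
    cell on the reference support is returned as a flat array.  These
    contributions are the quantities whose distributions are compared
    across probe sets with the two-sample KS test.
    """
    obs = marginalize(read_table, "ij").to_numpy().astype(float).ravel()
    gen = marginalize(genome_table, "ij").to_numpy().astype(float).ravel()
    mask = gen > 0
    p = gen[mask] / gen[mask].sum()
    E = obs[mask].sum() * p
    return (obs[mask] - E) ** 2 / E
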