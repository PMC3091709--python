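"""Synthetic genomes and enriched read libraries with known ground truth.

The genome simulator emulates the features that matter to the analysis:
chromosome- and region-heterogeneous densities of perfect SSRs over chosen
motif classes, and embedded GTAC restriction sites.  Planted repeats are
*inserted into* (not overlaid on) a random background, so their truth
coordinates are exact; the single background base flanking each planted
locus is adjusted when necessary so that the locus stays maximal and no
restriction site straddles its boundary.  Incidental background repeats
and incidental GTAC occurrences remain possible and are intentional.

The enrichment simulator samples restriction fragments with replacement,
with probability proportional to a capture weight (probe-matching fragments
vs background) times a length-class multiplier, emulating motif-capture
enrichment and the length bias of the sequencing chemistry.  It emits the
reads, a truth table of their origins, and a synthetic 12-column mapping
hit table (full coverage, e-value 0) so the read pipeline can run without
an aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import repstats
from .digestion import Fragment, digest, scan_fragments
from .pipeline import genome_fourway, run_read_pipeline
from .read_pipeline import MappingHit, ReadRecord
from .repeatscan import PROBE_SETS, SSRLocus, reverse_complement
from .repstats import restrict_to_support
from .tabulation import (
    N_REGIONS,
    length_class,
    marginalize,
    reference_probabilities,
)

__all__ = [
    "GenomeSimConfig",
    "EnrichmentSimConfig",
    "GenomeSim",
    "EnrichedReads",
    "simulate_genome",
    "simulate_enriched_reads",
    "recovery_experiment",
    "neutral_null_experiment",
    "RecoveryReport",
    "NeutralNullReport",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class GenomeSimConfig:
    """Study conditions for a synthetic genome.

    ``intensity_per_mb`` is the expected number of planted loci per Mb -
    either one rate for every motif or a per-motif mapping.  The default
    mirrors the order of magnitude reported for real vertebrate and insect
    genomes, where common dinucleotides reach ~250 loci/Mb while rare
    motifs such as ACG sit near 2.5-5/Mb; ``region_motif_factors``
    multiplies it for specific
    (region 1-10, motif) cells, ``chromosome_scale`` rescales whole
    chromosomes, and ``chromosome_region_factors`` plants per-chromosome
    regional hotspots ((chromosome 1-based, region 1-based, factor),
    applied to all motifs), giving region-, chromosome- and
    interaction-level heterogeneity.
    ``site_rate_per_kb`` is the rate of *planted* GTAC sites; incidental
    GTAC occurrences arising from the background composition add to it
    (about 3.9/kb at uniform composition).  Planted repeat counts are
    ``min_repeats`` plus a geometric tail with success probability
    ``repeat_geom_p``.
    """

    chromosome_lengths: tuple[int, ...] = (2_500_000,) * 4
    motifs: tuple[str, ...] = PROBE_SETS[8]
    intensity_per_mb: float | tuple[tuple[str, float], ...] = (
        ("AC", 250.0), ("AG", 250.0), ("AAC", 25.0), ("AAG", 25.0),
        ("ACG", 5.0), ("AGG", 25.0), ("ACAT", 10.0), ("AGAT", 10.0),
    )
    region_motif_factors: tuple[tuple[int, str, float], ...] = ()
    chromosome_scale: tuple[float, ...] | None = None
    chromosome_region_factors: tuple[tuple[int, int, float], ...] = ()
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    site_rate_per_kb: float = 1.0
    min_repeats: int = 4
    repeat_geom_p: float = 0.5

    def intensity_matrix(self, chromosome: int | None = None) -> np.ndarray:
        """(10, n_motifs) expected loci per Mb, for one chromosome (1-based)."""
        if isinstance(self.intensity_per_mb, (int, float)):
            base = np.full(len(self.motifs), float(self.intensity_per_mb))
        else:
            rates = dict(self.intensity_per_mb)
            base = np.array([float(rates.get(m, 0.0)) for m in self.motifs])
        mat = np.tile(base, (N_REGIONS, 1))
        for region, motif, factor in self.region_motif_factors:
            mat[region - 1, self.motifs.index(motif)] *= factor
        if chromosome is not None:
            for chrom, region, factor in self.chromosome_region_factors:
                if chrom == chromosome:
                    mat[region - 1, :] *= factor
        return mat

    def validate(self) -> None:
        if any(L < 1000 for L in self.chromosome_lengths):
            raise ConfigError("chromosome lengths must be >= 1 kb")
        comp = np.asarray(self.base_composition, float)
        if (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
            raise ConfigError("base composition must be a probability vector")
        if (self.intensity_matrix() < 0).any():
            raise ConfigError("intensities must be >= 0")
        if self.site_rate_per_kb < 0:
            raise ConfigError("site rate must be >= 0")
        if not 0 < self.repeat_geom_p <= 1:
            raise ConfigError("repeat_geom_p must be in (0, 1]")
        if self.chromosome_scale is not None and len(self.chromosome_scale) != len(
            self.chromosome_lengths
        ):
            raise ConfigError("chromosome_scale length mismatch")
        # saturation guard: expected planted bp must stay under 30% per region
        mean_units = self.min_repeats + (1 - self.repeat_geom_p) / self.repeat_geom_p
        scales = self.chromosome_scale or (1.0,) * len(self.chromosome_lengths)
        unit_lens = np.array([len(m) for m in self.motifs], float)
        for c, scale in enumerate(scales, start=1):
            per_mb = self.intensity_matrix(c) * scale  # (10, M)
            bp_per_mb = (per_mb * unit_lens[None, :] * mean_units).sum(axis=1)
            if (bp_per_mb > 0.30e6).any():
                raise ConfigError("planted SSRs would occupy > 30% of a region")


@dataclass(frozen=True)
class EnrichmentSimConfig:
    """Study conditions for a probe-enriched, length-biased read library.

    A fragment containing at least one probe-class SSR is sampled with
    ``capture_weight`` (vs ``background_weight`` otherwise), multiplied by
    the per-length-class bias.  The default bias elevates the 161-320 bp
    classes threefold, mirroring the distortion direction seen in
    pyrosequenced libraries, and gives fragments outside 81-480 bp zero
    weight (the analysis window of the protocol).  With ``truncate_at``
    None, each sampled fragment yields one full-length read.
    """

    probe_set: tuple[str, ...] = PROBE_SETS[8]
    capture_weight: float = 25.0
    background_weight: float = 1.0
    length_bias: tuple[tuple[str, float], ...] = (
        ("80", 1.0), ("160", 3.0), ("240", 3.0), ("320", 1.0), ("400", 1.0),
        ("other", 0.0),
    )
    read_count: int = 20_000
    truncate_at: int | None = None
    min_repeats: int = 4

    @classmethod
    def neutral(cls, probe_set=PROBE_SETS[8], read_count: int = 20_000,
                min_repeats: int = 4) -> "EnrichmentSimConfig":
        """Uniform fragment sampling over the 81-480 bp window (no bias)."""
        return cls(
            tuple(probe_set), 1.0, 1.0,
            (("80", 1.0), ("160", 1.0), ("240", 1.0), ("320", 1.0), ("400", 1.0),
             ("other", 0.0)),
            read_count, None, min_repeats,
        )

    def bias_of(self, k_class: str | None) -> float:
        table = dict(self.length_bias)
        return table.get(k_class if k_class is not None else "other",
                         table.get("other", 0.0))

    def validate(self) -> None:
        if self.capture_weight < 0 or self.background_weight < 0:
            raise ConfigError("weights must be >= 0")
        if any(v < 0 for _, v in self.length_bias):
            raise ConfigError("length bias multipliers must be >= 0")
        if self.read_count < 1:
            raise ConfigError("read_count must be >= 1")


@dataclass
class GenomeSim:
    sequences: dict[str, str]
    truth: pd.DataFrame  # chromosome, start, end, motif, repeats, observed_motif
    sites: pd.DataFrame  # chromosome, position (1-based start of planted GTAC)
    n_dropped: int  # plantings discarded for violating the spacing rule


@dataclass
class EnrichedReads:
    reads: list[ReadRecord]
    truth: pd.DataFrame  # read_id, chromosome, start, end, length, strand
    hits: list[MappingHit]

    def hit_rows(self) -> list[tuple]:
        return [
            (h.query_id, h.subject_id, h.percent_identity, h.alignment_length,
             h.mismatches, h.gap_openings, h.query_start, h.query_end,
             h.subject_start, h.subject_end, h.e_value, h.bit_score)
            for h in self.hits
        ]


def _rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


def _safe_orientations(motif: str) -> list[str]:
    """Orientations of a motif whose tandem repetition never contains GTAC."""
    out = []
    for unit in _rotations(motif) + _rotations(reverse_complement(motif)):
        if "GTAC" not in unit * 4:
            out.append(unit)
    return out


def _site_covers(seq: bytearray, idx: int) -> bool:
    """True when a GTAC occurrence includes position *idx*."""
    for a in range(max(0, idx - 3), min(len(seq) - 4, idx) + 1):
        if seq[a : a + 4] == b"GTAC":
            return True
    return False


def _fix_neighbor(seq: bytearray, idx: int, other_idx: int, rng) -> None:
    """Adjust one background base flanking a planted locus.

    Ensures the locus is not extendable through position *idx*
    (seq[idx] != seq[other_idx]) and that no GTAC occurrence covers the
    boundary base (a cut derived from such a site could fall inside the
    locus).  The current base is kept when it already satisfies both; a
    satisfying base always exists (at most three of ACGT are excluded).
    """
    if seq[idx] != seq[other_idx] and not _site_covers(seq, idx):
        return
    old = seq[idx]
    for b in rng.permutation(_BASES):
        if b == seq[other_idx]:
            continue
        seq[idx] = b
        if _site_covers(seq, idx):
            seq[idx] = old
            continue
        return


def simulate_genome(config: GenomeSimConfig, seed: int) -> GenomeSim:
    """Generate a genome with planted SSRs and GTAC sites, plus truth tables.

    Deterministic for a given (config, seed): same seed, byte-identical
    sequences.  Planted loci are spaced at least 8 bp apart (plantings that
    would violate the spacing are dropped and counted) so that the boundary
    adjustments of neighbouring loci cannot interact.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    comp = np.asarray(config.base_composition, float)
    scales = config.chromosome_scale or (1.0,) * len(config.chromosome_lengths)
    unit_choices = {m: _safe_orientations(m) for m in config.motifs}
    for m, options in unit_choices.items():
        if not options:
            raise ConfigError(f"motif {m!r} cannot be planted without a GTAC site")
    sequences: dict[str, str] = {}
    truth_rows, site_rows = [], []
    n_dropped = 0
    for c, (L, scale) in enumerate(zip(config.chromosome_lengths, scales)):
        name = f"chr{c + 1}"
        intensity = config.intensity_matrix(c + 1)
        bg = _BASES[rng.choice(4, size=L, p=comp)]
        inserts: list[tuple[int, str, str | None, int, str]] = []
        n_sites = rng.poisson(config.site_rate_per_kb * L / 1000.0)
        for pos in rng.integers(0, L, size=n_sites):
            inserts.append((int(pos), "GTAC", None, 0, ""))
        for region in range(N_REGIONS):
            lo = (region * L) // N_REGIONS
            hi = ((region + 1) * L) // N_REGIONS
            for mi, motif in enumerate(config.motifs):
                lam = intensity[region, mi] * scale * (hi - lo) / 1e6
                for pos in rng.integers(lo, hi, size=rng.poisson(lam)):
                    units = unit_choices[motif]
                    unit = units[rng.integers(len(units))]
                    reps = config.min_repeats + int(rng.geometric(config.repeat_geom_p)) - 1
                    inserts.append((int(pos), unit * reps, motif, reps, unit))
        inserts.sort(key=lambda t: t[0])
        kept: list[tuple[int, str, str | None, int, str]] = []
        last = -10**9
        for ins in inserts:
            if ins[0] - last < 8 or ins[0] < 4 or ins[0] > L - 4:
                n_dropped += 1
                continue
            kept.append(ins)
            last = ins[0]
        pieces: list[np.ndarray] = []
        meta: list[tuple[int, int, str | None, int, str]] = []  # final coords
        prev = 0
        offset = 0
        for pos, text, motif, reps, unit in kept:
            pieces.append(bg[prev:pos])
            start0 = pos + offset
            pieces.append(np.frombuffer(text.encode("ascii"), dtype=np.uint8))
            meta.append((start0, start0 + len(text), motif, reps, unit))
            offset += len(text)
            prev = pos
        pieces.append(bg[prev:])
        final = bytearray(np.concatenate(pieces).tobytes())
        for start0, end0, motif, reps, unit in meta:
            if motif is None:
                site_rows.append((name, start0 + 1))
                continue
            m = len(unit)
            if start0 - 1 >= 0:
                _fix_neighbor(final, start0 - 1, start0 - 1 + m, rng)
            if end0 < len(final):
                _fix_neighbor(final, end0, end0 - m, rng)
            truth_rows.append((name, start0 + 1, end0, motif, reps, unit))
        sequences[name] = final.decode("ascii")
    truth = pd.DataFrame(
        truth_rows,
        columns=["chromosome", "start", "end", "motif", "repeats", "observed_motif"],
    )
    sites = pd.DataFrame(site_rows, columns=["chromosome", "position"])
    return GenomeSim(sequences, truth, sites, n_dropped)


def simulate_enriched_reads(
    sequences: Mapping[str, str],
    config: EnrichmentSimConfig,
    seed: int,
    prescanned: Mapping[str, list[tuple[Fragment, list[SSRLocus]]]] | None = None,
) -> EnrichedReads:
    """Sample an enriched read library from the digested genome.

    Fragments are drawn with replacement with probability proportional to
    capture weight x length-class multiplier; each draw yields one read
    (the fragment sequence, reverse-complemented on a random strand, and
    truncated to ``truncate_at`` when set) plus one synthetic mapping hit
    recording the true placement at 100% identity and full coverage.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    probes = frozenset(config.probe_set)
    frags: list[Fragment] = []
    weights: list[float] = []
    for name, seq in sequences.items():
        if prescanned is not None and name in prescanned:
            scanned = prescanned[name]
        else:
            scanned = scan_fragments(
                seq, digest(seq, chromosome_id=name), config.min_repeats
            )
        for frag, loci in scanned:
            has_probe = any(loc.motif in probes for loc in loci)
            w = config.capture_weight if has_probe else config.background_weight
            w *= config.bias_of(length_class(frag.length))
            frags.append(frag)
            weights.append(w)
    w = np.asarray(weights, float)
    total = w.sum()
    if total <= 0:
        raise ConfigError("total sampling weight is zero")
    picks = rng.choice(len(frags), size=config.read_count, p=w / total)
    strands = rng.integers(0, 2, size=config.read_count)
    reads, truth_rows, hits = [], [], []
    for i, (fi, minus) in enumerate(zip(picks.tolist(), strands.tolist())):
        frag = frags[fi]
        seq = sequences[frag.chromosome_id][frag.start - 1 : frag.end]
        if config.truncate_at is not None:
            seq = seq[: config.truncate_at]
        s, e = frag.start, frag.start + len(seq) - 1
        if minus:
            seq = reverse_complement(seq)
        rid = f"r{i + 1:07d}"
        reads.append(ReadRecord(rid, seq))
        truth_rows.append(
            (rid, frag.chromosome_id, s, e, len(seq), "-" if minus else "+")
        )
        sstart, send = (e, s) if minus else (s, e)
        hits.append(
            MappingHit(rid, frag.chromosome_id, 100.0, len(seq), 0, 0,
                       1, len(seq), sstart, send, 0.0, 2.0 * len(seq))
        )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "chromosome", "start", "end", "length", "strand"]
    )
    return EnrichedReads(reads, truth, hits)


@dataclass
class RecoveryReport:
    n_runs: int
    n_detected: int
    false_flags: int
    n_other_cells: int
    runs: list[dict] = field(default_factory=list)

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_runs

    @property
    def false_flag_rate(self) -> float:
        return self.false_flags / max(self.n_other_cells, 1)


@dataclass
class NeutralNullReport:
    n_runs: int
    n_significant: int
    p_values: list[float]
    counts_outside_support: list[int]

    @property
    def nonsignificant_rate(self) -> float:
        return 1.0 - self.n_significant / self.n_runs


def _run_seeds(seed: int, n_runs: int) -> list[int]:
    """Three independent sub-seeds per run (genome, library, Monte-Carlo)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(3 * n_runs)]


def recovery_experiment(
    genome_config: GenomeSimConfig,
    enrich_config: EnrichmentSimConfig,
    bias_region: int,
    bias_motif: str,
    n_runs: int,
    seed: int,
    alpha: float = 0.05,
    B: int = 2000,
) -> RecoveryReport:
    """Full-pipeline detection of a planted (region, motif) enrichment bias.

    ``genome_config`` should plant exactly one biased (region, motif) cell
    (via ``region_motif_factors``) on an otherwise homogeneous genome.  Per
    run the complete pipeline is executed and the region x motif two-way
    table of the mapped reads is tested for independence; when the global
    test is significant, per-cell binomial tests (BH-FDR at *alpha*) are
    run and the planted cell counts as detected when flagged
    over-represented.  Flags on any other cell are tallied as false flags.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = _run_seeds(seed, n_runs)
    motifs = tuple(sorted(enrich_config.probe_set))
    li = motifs.index(bias_motif)
    n_detected = 0
    false_flags = 0
    runs = []
    n_cells = N_REGIONS * len(motifs)
    for run in range(n_runs):
        gseed, rseed, mseed = seeds[3 * run : 3 * run + 3]
        gsim = simulate_genome(genome_config, gseed)
        scan = genome_fourway(gsim.sequences, enrich_config.probe_set,
                              genome_config.min_repeats, motifs=motifs)
        lib = simulate_enriched_reads(
            gsim.sequences, enrich_config, rseed, prescanned=scan.fragment_loci
        )
        result = run_read_pipeline(
            lib.reads, lib.hits, scan.chromosome_lengths,
            enrich_config.probe_set, genome_config.min_repeats, motifs=motifs,
        )
        jl = marginalize(result.table, "jl").to_numpy().astype(float)
        res = repstats.chi2_independence(jl)
        E = np.outer(jl.sum(axis=1), jl.sum(axis=0)) / jl.sum()
        if (E < 5).any():
            res = repstats.mc_null_pvalue(jl, independence=True, B=B, seed=mseed)
        detected = False
        flags_elsewhere = 0
        if res.p < alpha:
            probs = np.outer(jl.sum(axis=1), jl.sum(axis=0)) / jl.sum() ** 2
            cells = repstats.cell_tests(jl.astype(int), probs / probs.sum(), alpha)
            for cell in cells:
                if cell.index == (bias_region - 1, li):
                    detected = cell.direction == "over"
                elif cell.direction != "none":
                    flags_elsewhere += 1
        n_detected += detected
        false_flags += flags_elsewhere
        runs.append({"seed": gseed, "p_global": res.p, "detected": detected,
                     "false_flags": flags_elsewhere, "n": int(jl.sum())})
    return RecoveryReport(n_runs, n_detected, false_flags,
                          n_runs * (n_cells - 1), runs)


def neutral_null_experiment(
    genome_config: GenomeSimConfig,
    enrich_config: EnrichmentSimConfig,
    n_runs: int,
    seed: int,
    alpha: float = 0.05,
    B: int = 2000,
) -> NeutralNullReport:
    """Global four-way GOF of neutrally enriched reads vs the genome reference.

    With all capture weights equal and no length bias, the read table is a
    multinomial draw from the genome-digest reference (on its support), so
    the global test should be non-significant in about 1 - alpha of runs.
    Counts outside the reference support (midpoint-binning discretisation,
    see ``repstats.restrict_to_support``) are reported per run.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = _run_seeds(seed, n_runs)
    motifs = tuple(sorted(enrich_config.probe_set))
    p_values: list[float] = []
    outside_counts: list[int] = []
    n_sig = 0
    for run in range(n_runs):
        gseed, rseed, mseed = seeds[3 * run : 3 * run + 3]
        gsim = simulate_genome(genome_config, gseed)
        scan = genome_fourway(gsim.sequences, enrich_config.probe_set,
                              genome_config.min_repeats, motifs=motifs)
        lib = simulate_enriched_reads(
            gsim.sequences, enrich_config, rseed, prescanned=scan.fragment_loci
        )
        result = run_read_pipeline(
            lib.reads, lib.hits, scan.chromosome_lengths,
            enrich_config.probe_set, genome_config.min_repeats, motifs=motifs,
        )
        ref = reference_probabilities(scan.table)
        obs_sub, p_sub, outside = restrict_to_support(
            result.table.counts, ref.probabilities
        )
        res = repstats.global_gof(obs_sub, p_sub, B=B, seed=rseed)
        p_values.append(res.p)
        outside_counts.append(outside)
        n_sig += res.p < alpha
    return NeutralNullReport(n_runs, n_sig, p_values, outside_counts)
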