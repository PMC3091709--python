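"""Four-way contingency tabulation of SSR loci and reference distributions.

Each qualifying SSR locus contributes one count indexed by

* ``i`` - the chromosome,
* ``j`` - the chromosome decile region (1-10, equal physical length),
* ``k`` - the length class of the carrying fragment or read
  (80: 81-160 bp, 160: 161-240 bp, 240: 241-320 bp, 320: 321-400 bp,
  400: 401-480 bp; lengths <= 80 or > 480 are excluded),
* ``l`` - the canonical motif class.

Dividing the genome table by its total gives the reference probability
p_ijkl = n_ijkl / n of a microsatellite being found in a particular cell;
an equiprobability reference (uniform, optionally length-weighted) is
available as the alternative null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import Fragment
from .repeatscan import PROBE_SETS, SSRLocus

__all__ = [
    "LENGTH_CLASSES",
    "AXES",
    "FourWayTable",
    "ReferenceDistribution",
    "length_class",
    "region_index",
    "midpoint_region",
    "build_genome_dataset",
    "build_read_dataset",
    "marginalize",
    "reference_probabilities",
    "equiprobability_reference",
]

#: Length-class labels, named by the lower bound of each 80-bp band.
LENGTH_CLASSES: tuple[str, ...] = ("80", "160", "240", "320", "400")

N_REGIONS = 10

#: Axis letters of the four-way table, in storage order.
AXES = "ijkl"
_AXIS_POS = {"i": 0, "j": 1, "k": 2, "l": 3}
_AXIS_NAMES = {"i": "chromosome", "j": "region", "k": "length_class", "l": "motif"}


def length_class(length: int) -> str | None:
    """Length-class label for a fragment/read length, or None if excluded.

    The 0-80 and >480 ranges are excluded (None); classes are labelled by
    their lower bound: 81-160 -> "80", ..., 401-480 -> "400".
    """
    if length < 0:
        raise ValueError("length must be non-negative")
    if 80 < length <= 480:
        return LENGTH_CLASSES[(length - 81) // 80]
    return None


def region_index(position: int, chromosome_length: int) -> int:
    """Decile region (1-10) of an integer position on a chromosome.

    Region m covers the half-open real interval ((m-1)*L/10, m*L/10], so
    position 1 maps to region 1 and position L to region 10 for any L.
    """
    if not 1 <= position <= chromosome_length:
        raise ValueError(
            f"position {position} outside chromosome of length {chromosome_length}"
        )
    # ceil(10 * position / L) in exact integer arithmetic
    return -((-N_REGIONS * position) // chromosome_length)


def midpoint_region(start: int, end: int, chromosome_length: int) -> int:
    """Region of the (possibly half-integer) midpoint of [start, end]."""
    if not 1 <= start <= end <= chromosome_length:
        raise ValueError("interval outside chromosome")
    # midpoint = (start + end) / 2; ceil(10 * midpoint / L) exactly:
    return -((-N_REGIONS * (start + end)) // (2 * chromosome_length))


@dataclass
class FourWayTable:
    """Counts n_ijkl over chromosome x region x length class x motif."""

    counts: np.ndarray  # shape (S, 10, 5, M), non-negative ints
    chromosomes: tuple[str, ...]
    motifs: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = (len(self.chromosomes), N_REGIONS, len(LENGTH_CLASSES), len(self.motifs))
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def empty(cls, chromosomes: Sequence[str], motifs: Sequence[str]) -> "FourWayTable":
        shape = (len(chromosomes), N_REGIONS, len(LENGTH_CLASSES), len(motifs))
        return cls(np.zeros(shape, dtype=np.int64), tuple(chromosomes), tuple(motifs))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def axis_labels(self, axis: str) -> list:
        if axis == "i":
            return list(self.chromosomes)
        if axis == "j":
            return list(range(1, N_REGIONS + 1))
        if axis == "k":
            return list(LENGTH_CLASSES)
        if axis == "l":
            return list(self.motifs)
        raise ValueError(f"unknown axis {axis!r}")

    def add(self, chromosome: str, region: int, k_class: str, motif: str) -> None:
        i = self.chromosomes.index(chromosome)
        k = LENGTH_CLASSES.index(k_class)
        l = self.motifs.index(motif)
        self.counts[i, region - 1, k, l] += 1

    def to_frame(self) -> pd.DataFrame:
        """Long format with deterministic (lexicographic index) row order."""
        idx = pd.MultiIndex.from_product(
            [self.axis_labels(a) for a in AXES],
            names=[_AXIS_NAMES[a] for a in AXES],
        )
        return pd.DataFrame({"count": self.counts.ravel()}, index=idx).reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FourWayTable":
        chroms = tuple(dict.fromkeys(frame["chromosome"].astype(str)))
        motifs = tuple(dict.fromkeys(frame["motif"].astype(str)))
        table = cls.empty(chroms, motifs)
        for row in frame.itertuples(index=False):
            i = chroms.index(str(row.chromosome))
            k = LENGTH_CLASSES.index(str(row.length_class))
            l = motifs.index(str(row.motif))
            table.counts[i, int(row.region) - 1, k, l] += int(row.count)
        return table


@dataclass
class ReferenceDistribution:
    """Cell probabilities p_ijkl with their provenance."""

    probabilities: np.ndarray
    provenance: str  # "genome-digest" | "equiprobability"
    chromosomes: tuple[str, ...] = ()
    motifs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if (p < 0).any():
            raise ValueError("negative probabilities")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        self.probabilities = p


def _qualifying(locus: SSRLocus, probe_set: frozenset) -> bool:
    return locus.motif in probe_set


def build_genome_dataset(
    fragment_loci: Iterable[tuple[Fragment, Sequence[SSRLocus]]],
    chromosome_lengths: Mapping[str, int],
    probe_set: Iterable[str] = PROBE_SETS[8],
    motifs: Sequence[str] | None = None,
    per_sequence: bool = False,
) -> FourWayTable:
    """Four-way table of the digested genome.

    One count per SSR locus whose class is in *probe_set* and whose carrying
    fragment has an in-range length class: i = chromosome, j = region of the
    locus midpoint, k = length class of the fragment, l = motif class.
    Loci in excluded-length fragments contribute nothing.

    With ``per_sequence=True`` a fragment contributes at most one count per
    motif class (position taken from the first such locus).
    """
    probes = frozenset(probe_set)
    motif_order = tuple(motifs) if motifs is not None else tuple(sorted(probes))
    table = FourWayTable.empty(tuple(chromosome_lengths), motif_order)
    for frag, loci in fragment_loci:
        chrom = frag.chromosome_id
        if chrom not in chromosome_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        k_class = length_class(frag.length)
        if k_class is None:
            continue
        L = chromosome_lengths[chrom]
        seen: set[str] = set()
        for locus in loci:
            if locus.motif not in probes:
                continue
            if per_sequence and locus.motif in seen:
                continue
            seen.add(locus.motif)
            j = midpoint_region(locus.start, locus.end, L)
            table.add(chrom, j, k_class, locus.motif)
    return table


def build_read_dataset(
    assignments: Iterable,
    chromosome_lengths: Mapping[str, int],
    probe_set: Iterable[str] = PROBE_SETS[8],
    motifs: Sequence[str] | None = None,
    per_sequence: bool = False,
) -> FourWayTable:
    """Four-way table of mapped enriched-library reads.

    *assignments* are read assignments (see ``read_pipeline.ReadAssignment``)
    carrying the mapped chromosome, oriented subject interval, read length
    and the read's SSR loci.  Binning mirrors :func:`build_genome_dataset`
    with k = read length class and (i, j) from the mapped interval midpoint.
    Reads with out-of-range length classes contribute nothing; an unmapped
    read (no chromosome) is an error - filtering happens upstream.
    """
    probes = frozenset(probe_set)
    motif_order = tuple(motifs) if motifs is not None else tuple(sorted(probes))
    table = FourWayTable.empty(tuple(chromosome_lengths), motif_order)
    for asg in assignments:
        if asg.chromosome is None:
            raise ValueError(f"read {asg.read_id!r} is unmapped")
        if asg.chromosome not in chromosome_lengths:
            raise KeyError(f"unknown chromosome {asg.chromosome!r}")
        k_class = length_class(asg.read_length)
        if k_class is None:
            continue
        L = chromosome_lengths[asg.chromosome]
        j = midpoint_region(asg.start, asg.end, L)
        seen: set[str] = set()
        for locus in asg.loci:
            if locus.motif not in probes:
                continue
            if per_sequence and locus.motif in seen:
                continue
            seen.add(locus.motif)
            table.add(asg.chromosome, j, k_class, locus.motif)
    return table


def marginalize(table: FourWayTable, keep_axes: str):
    """One- or two-way marginal of the four-way table.

    *keep_axes* is a subset of "ijkl" of size 1 or 2 (e.g. ``"jl"``).
    Returns a labelled pandas Series (one-way) or DataFrame (two-way, first
    kept axis as rows); the grand total is preserved.
    """
    axes = [a for a in AXES if a in set(keep_axes)]
    if set(keep_axes) - set(AXES):
        raise ValueError(f"unknown axes in {keep_axes!r}")
    if len(axes) not in (1, 2):
        raise ValueError("keep_axes must name one or two axes")
    drop = tuple(_AXIS_POS[a] for a in AXES if a not in axes)
    marg = table.counts.sum(axis=drop)
    if len(axes) == 1:
        return pd.Series(
            marg, index=table.axis_labels(axes[0]), name="count"
        ).rename_axis(_AXIS_NAMES[axes[0]])
    return pd.DataFrame(
        marg,
        index=pd.Index(table.axis_labels(axes[0]), name=_AXIS_NAMES[axes[0]]),
        columns=pd.Index(table.axis_labels(axes[1]), name=_AXIS_NAMES[axes[1]]),
    )


def reference_probabilities(table: FourWayTable) -> ReferenceDistribution:
    """Genome-digest reference: p_ijkl = n_ijkl / n."""
    n = table.n
    if n == 0:
        raise ValueError("cannot derive probabilities from an empty table")
    return ReferenceDistribution(
        table.counts / n, "genome-digest", table.chromosomes, table.motifs
    )


def equiprobability_reference(
    axis_sizes: Sequence[int],
    weights: Mapping[int, Sequence[float]] | None = None,
) -> ReferenceDistribution:
    """Equiprobability null: uniform per category, optionally weighted.

    *weights* maps an axis position to per-category weights (e.g. physical
    chromosome lengths for axis 0); the cell probability is the product of
    the normalized per-axis probabilities.
    """
    if any(s < 1 for s in axis_sizes):
        raise ValueError("axis sizes must be >= 1")
    factors = []
    for pos, size in enumerate(axis_sizes):
        if weights is not None and pos in weights:
            w = np.asarray(weights[pos], dtype=float)
            if w.shape != (size,) or (w <= 0).any():
                raise ValueError(f"invalid weights for axis {pos}")
            factors.append(w / w.sum())
        else:
            factors.append(np.full(size, 1.0 / size))
    p = factors[0]
    for f in factors[1:]:
        p = np.multiply.outer(p, f)
    return ReferenceDistribution(p, "equiprobability")
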