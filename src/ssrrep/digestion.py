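"""In-silico restriction digestion of linear chromosomes.

The default enzyme is RsaI, which recognizes GTAC and cuts bluntly between
T and A (GT^AC).  Digestion is complete: every occurrence of the site is
cut.  The resulting fragments tile the chromosome exactly, so joining their
sequences in order reproduces the input.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

from .repeatscan import SSRLocus, find_ssrs

__all__ = ["Fragment", "digest", "locate_fragment", "scan_fragments"]

RSAI_SITE = "GTAC"
RSAI_CUT_OFFSET = 2


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment, 1-based inclusive genomic coordinates."""

    chromosome_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def digest(
    sequence: str,
    site: str = RSAI_SITE,
    cut_offset: int = RSAI_CUT_OFFSET,
    chromosome_id: str = "",
) -> list[Fragment]:
    """Cut *sequence* at every occurrence of *site* (case-insensitive).

    The cut falls after position ``site_start + cut_offset - 1``, so GTAC
    with offset 2 gives the blunt GT^AC cut.  Returns occurrence_count + 1
    fragments for a linear molecule.  Raises ``ValueError`` on an empty
    sequence or an invalid site/offset.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    site = site.upper()
    if not site or any(c not in "ACGT" for c in site):
        raise ValueError(f"invalid recognition site {site!r}")
    if not 0 < cut_offset < len(site):
        raise ValueError("cut_offset must satisfy 0 < cut_offset < len(site)")
    seq = sequence.upper()
    n = len(seq)
    cuts: list[int] = []  # 1-based position of the last base of a left fragment
    i = seq.find(site)
    while i != -1:
        cuts.append(i + cut_offset)
        i = seq.find(site, i + 1)
    bounds = [0] + cuts + [n]
    return [
        Fragment(chromosome_id, bounds[k] + 1, bounds[k + 1])
        for k in range(len(bounds) - 1)
    ]


def locate_fragment(position: int, fragments: Sequence[Fragment]) -> Fragment:
    """The unique fragment containing *position* (binary search).

    *fragments* must be the ordered tiling produced by :func:`digest`.
    Raises ``IndexError`` when the position lies outside the chromosome.
    """
    if not fragments:
        raise IndexError("no fragments")
    if position < fragments[0].start or position > fragments[-1].end:
        raise IndexError(
            f"position {position} outside chromosome "
            f"({fragments[0].start}-{fragments[-1].end})"
        )
    starts = [f.start for f in fragments]
    idx = bisect_right(starts, position) - 1
    return fragments[idx]


def scan_fragments(
    sequence: str,
    fragments: Sequence[Fragment],
    min_repeats: int = 4,
    motif_lengths: Sequence[int] = range(2, 7),
) -> list[tuple[Fragment, list[SSRLocus]]]:
    """Scan each fragment of a chromosome independently for SSRs.

    Fragment-local loci are lifted to genomic coordinates (their
    ``sequence_id`` becomes the chromosome id).  An SSR spanning a cut site
    is truncated per fragment and must independently satisfy *min_repeats*,
    i.e. digest-then-scan semantics.
    """
    out: list[tuple[Fragment, list[SSRLocus]]] = []
    for frag in fragments:
        sub = sequence[frag.start - 1 : frag.end]
        loci = [
            loc.shifted(frag.start - 1, frag.chromosome_id)
            for loc in find_ssrs(sub, min_repeats, motif_lengths)
        ]
        out.append((frag, loci))
    return out
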