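"""Detection of maximal perfect microsatellites (simple sequence repeats).

A perfect SSR is an uninterrupted tandem repetition of a short motif
(here 2-6 bp).  Motifs are grouped into *canonical classes* that merge all
rotations of a repeat unit together with all rotations of its reverse
complement, so GT, TG, CA and AC all belong to class ``AC``.  The canonical
name is the lexicographically smallest member of the class, which yields the
familiar names AC, AG, AAC, AAG, ACG, AGG, ACAT, AGAT for the eight motifs
targeted by multiplex enrichment probes.

Scanning reports every *maximal* perfect run: a run that cannot be extended
by one base on either side while remaining a perfect repetition of its unit.
The repeat count of a run is the number of *complete* units it contains
(a trailing partial unit lengthens the span but not the count).  Lowercase
(soft-masked) bases are treated as normal; any character outside ACGT
terminates a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "InvalidAlphabetError",
    "NonPrimitiveMotifError",
    "MotifClass",
    "SSRLocus",
    "PROBE_SETS",
    "canonical_motif",
    "reverse_complement",
    "is_primitive",
    "find_ssrs",
    "is_target_motif",
]


class InvalidAlphabetError(ValueError):
    """A motif contains characters outside {A, C, G, T}."""


class NonPrimitiveMotifError(ValueError):
    """A motif is a whole-number repetition of a shorter motif (e.g. ACAC)."""


_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Probe cocktails used for 2-, 5- and 8-probe multiplex enrichment.
PROBE_SETS: dict[int, tuple[str, ...]] = {
    2: ("AC", "AG"),
    5: ("AC", "AG", "AAC", "AGG", "ACAT"),
    8: ("AC", "AG", "AAC", "AGG", "ACAT", "AAG", "ACG", "AGAT"),
}

#: Alias for readers who think of a motif class as a type.
MotifClass = str


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(unit: str) -> bool:
    """True if *unit* is not a whole-number repetition of a shorter string."""
    m = len(unit)
    for d in range(1, m):
        if m % d == 0 and unit == unit[:d] * (m // d):
            return False
    return True


@lru_cache(maxsize=None)
def canonical_motif(unit: str) -> MotifClass:
    """Canonical class name of a repeat unit.

    The class merges all rotations of *unit* and of its reverse complement;
    the canonical representative is the lexicographic minimum over both.
    Idempotent: ``canonical_motif(canonical_motif(u)) == canonical_motif(u)``.

    Raises
    ------
    InvalidAlphabetError
        If *unit* contains characters outside ACGT (after uppercasing).
    NonPrimitiveMotifError
        If *unit* has a period shorter than its length (e.g. ``ACAC``),
        or its length is outside 2-6.
    """
    unit = unit.upper()
    if not unit or any(c not in "ACGT" for c in unit):
        raise InvalidAlphabetError(f"motif {unit!r} contains non-ACGT characters")
    m = len(unit)
    if not 2 <= m <= 6:
        raise NonPrimitiveMotifError(f"motif length must be 2-6, got {m}")
    if not is_primitive(unit):
        raise NonPrimitiveMotifError(f"motif {unit!r} is not primitive")
    rc = reverse_complement(unit)
    candidates = [unit[i:] + unit[:i] for i in range(m)]
    candidates += [rc[i:] + rc[:i] for i in range(m)]
    return min(candidates)


def is_target_motif(cls: MotifClass, probe_set: Iterable[MotifClass]) -> bool:
    """True iff canonical class *cls* belongs to *probe_set*."""
    return cls in set(probe_set)


@dataclass(frozen=True)
class SSRLocus:
    """One maximal perfect repeat run.

    Coordinates are 1-based inclusive on the scanned sequence.  ``repeats``
    counts complete units; ``observed_motif`` is the literal unit as it
    appears at the start of the run (e.g. ``TG`` for a class-AC locus on the
    minus-strand orientation).
    """

    sequence_id: str
    start: int
    end: int
    motif: MotifClass
    repeats: int
    observed_motif: str

    @property
    def run_length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def shifted(self, offset: int, sequence_id: str | None = None) -> "SSRLocus":
        """Copy with coordinates shifted by *offset* (fragment -> genome)."""
        return SSRLocus(
            sequence_id if sequence_id is not None else self.sequence_id,
            self.start + offset,
            self.end + offset,
            self.motif,
            self.repeats,
            self.observed_motif,
        )


_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def find_ssrs(
    sequence: str,
    min_repeats: int = 4,
    motif_lengths: Sequence[int] = range(2, 7),
    sequence_id: str = "",
) -> list[SSRLocus]:
    """All maximal perfect SSRs with at least *min_repeats* complete units.

    One locus is returned per (maximal run, canonical class); runs of
    different classes may overlap.  An empty sequence yields an empty list.
    Runs whose unit is non-primitive at a given window length are not
    reported at that length (they are reported at their true period).

    The scan is linear-time per motif length: positions where
    ``seq[i] == seq[i + m]`` are located with numpy and maximal stretches of
    such positions correspond one-to-one to maximal period-``m`` runs.
    """
    if min_repeats < 1:
        raise ValueError("min_repeats must be >= 1")
    lengths = sorted(set(int(m) for m in motif_lengths))
    if lengths and (lengths[0] < 2 or lengths[-1] > 6):
        raise ValueError("motif lengths must lie in [2, 6]")
    seq = sequence.upper()
    n = len(seq)
    loci: list[SSRLocus] = []
    if n == 0:
        return loci
    arr = np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)
    valid = (arr == 65) | (arr == 67) | (arr == 71) | (arr == 84)
    for m in lengths:
        if n < m * max(min_repeats, 1):
            continue
        ok = (arr[:-m] == arr[m:]) & valid[:-m] & valid[m:]
        edges = np.flatnonzero(np.diff(np.concatenate(([False], ok, [False]))))
        starts, ends = edges[0::2], edges[1::2]
        for s0, e0 in zip(starts.tolist(), ends.tolist()):
            run_len = (e0 - s0) + m
            reps = run_len // m
            if reps < min_repeats:
                continue
            unit = seq[s0 : s0 + m]
            if not is_primitive(unit):
                continue  # reported at its true (shorter) period
            loci.append(
                SSRLocus(sequence_id, s0 + 1, s0 + run_len, canonical_motif(unit), reps, unit)
            )
        if min_repeats == 1:
            # Isolated single units: windows not extendable on either side.
            for i in range(0, n - m + 1):
                if not valid[i : i + m].all():
                    continue
                if i - 1 >= 0 and i - 1 < ok.size and ok[i - 1]:
                    continue
                if i < ok.size and ok[i]:
                    continue
                unit = seq[i : i + m]
                if not is_primitive(unit):
                    continue
                loci.append(SSRLocus(sequence_id, i + 1, i + m, canonical_motif(unit), 1, unit))
    loci.sort(key=lambda x: (x.start, len(x.observed_motif), x.motif))
    return loci
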