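"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ssrrep.repeatscan import canonical_motif, is_primitive


def brute_force_ssrs(sequence: str, min_repeats: int = 4,
                     motif_lengths=range(2, 7)) -> set[tuple]:
    """Quadratic reference scanner, independent of the production path.

    For every start position and unit length, counts how far the periodic
    pattern extends, then keeps maximal spans per canonical class.
    Returns a set of (start, end, class, repeats) with 1-based inclusive
    coordinates.
    """
    seq = sequence.upper()
    n = len(seq)
    valid = [c in "ACGT" for c in seq]
    spans: dict[str, set[tuple[int, int]]] = {}
    for m in motif_lengths:
        for i in range(n - m + 1):
            unit = seq[i : i + m]
            if not all(valid[i : i + m]) or not is_primitive(unit):
                continue
            # skip non-maximal starts (the run extends to the left)
            if i >= 1 and valid[i - 1] and seq[i - 1] == seq[i - 1 + m]:
                continue
            j = i + m
            while j < n and valid[j] and seq[j] == seq[j - m]:
                j += 1
            run_len = j - i
            reps = run_len // m
            if reps < min_repeats:
                continue
            spans.setdefault(canonical_motif(unit), set()).add((i + 1, j))
    out = set()
    for cls, ss in spans.items():
        for s, e in ss:
            # keep only spans not strictly contained in another of same class
            if any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in ss):
                continue
            out.add((s, e, cls, (e - s + 1) // len(cls)))
    return out


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_genome():
    """A small synthetic genome with its scan, shared across tests."""
    from ssrrep.pipeline import genome_fourway
    from ssrrep.simulate import GenomeSimConfig, simulate_genome

    cfg = GenomeSimConfig(chromosome_lengths=(250_000,) * 3, intensity_per_mb=40.0)
    sim = simulate_genome(cfg, 424242)
    scan = genome_fourway(sim.sequences)
    return cfg, sim, scan
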