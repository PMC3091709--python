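"""Readers and writers for the plain-text formats used by the pipeline.

FASTA handling is delegated to Biopython (multi-record, wrapped lines,
transparent gzip); tabular outputs are UTF-8 TSV files with header lines
and 1-based inclusive coordinates.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digestion import Fragment
from .read_pipeline import LibrarySummary
from .repeatscan import SSRLocus

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_loci_tsv",
    "read_loci_tsv",
    "write_fragments_tsv",
    "write_table_tsv",
    "write_hits_tsv",
    "write_summaries_tsv",
]


def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str) -> list[tuple[str, str]]:
    """(record id, sequence) pairs from a (possibly gzipped) FASTA file."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_loci_tsv(path: str, loci: Iterable[SSRLocus]) -> None:
    rows = [
        (x.sequence_id, x.start, x.end, x.motif, x.repeats, x.run_length)
        for x in loci
    ]
    pd.DataFrame(
        rows, columns=["sequence_id", "start", "end", "class", "repeats", "run_length"]
    ).to_csv(path, sep="\t", index=False)


def read_loci_tsv(path: str) -> list[SSRLocus]:
    df = pd.read_csv(path, sep="\t")
    return [
        SSRLocus(str(r.sequence_id), int(r.start), int(r.end), str(getattr(r, "_3")),
                 int(r.repeats), str(getattr(r, "_3")))
        for r in df.itertuples(index=False)
    ]


def write_fragments_tsv(path: str, fragments: Iterable[Fragment]) -> None:
    rows = [(f.chromosome_id, f.start, f.end, f.length) for f in fragments]
    pd.DataFrame(rows, columns=["chromosome_id", "start", "end", "length"]).to_csv(
        path, sep="\t", index=False
    )


def write_table_tsv(path: str, table) -> None:
    """Four-way table in long format (deterministic lexicographic order)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_hits_tsv(path: str, rows: Iterable[Sequence]) -> None:
    """12-column BLAST tabular text, no header (outfmt 6 convention)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_summaries_tsv(
    path: str, summaries: Mapping[str, LibrarySummary]
) -> None:
    rows = []
    for name, s in summaries.items():
        rows.append(
            (
                name,
                s.total_reads,
                s.reads_over_80bp,
                s.reads_with_ssr,
                "" if s.primer_designed is None else s.primer_designed,
                _fmt_pct(s.pct_over_80),
                _fmt_pct(s.pct_with_ssr),
                _fmt_pct(s.pct_with_primer),
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "library",
            "total",
            "over_80bp",
            "with_ssr",
            "primer_designed",
            "pct_over_80",
            "pct_with_ssr",
            "pct_with_primer",
        ],
    ).to_csv(path, sep="\t", index=False)


def _fmt_pct(value: float | None) -> str:
    return "NA" if value is None else f"{value:.1f}"
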