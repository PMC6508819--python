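"""Exact-match probe counting over streamed sequencing reads.

A read counts as "alt" if it contains the deletion-allele probe (either
orientation) as an exact substring, "ref" likewise for the reference
probe, and "ambiguous" if it contains both. Each read contributes to at
most one category regardless of how many occurrences it carries.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Union

import pandas as pd

from .errors import FastqFormatError, InputError
from .probe_design import ProbeSet

ReadSource = Union[str, Path, Iterable[tuple[str, str]]]

_MATE_SUFFIX = re.compile(r"(/[12]$)|([._][12]$)")


def _open_text(path: Path) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def iter_fastq(handle: io.TextIOBase) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTQ, enforcing strict 4-line records."""
    record_index = 0
    while True:
        header = handle.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise FastqFormatError("expected '@' header line", record_index)
        seq = handle.readline().rstrip("\n")
        plus = handle.readline().rstrip("\n")
        qual = handle.readline().rstrip("\n")
        if not plus.startswith("+"):
            raise FastqFormatError("expected '+' separator line", record_index)
        if not seq or not qual:
            raise FastqFormatError("truncated record (non-4-line block)", record_index)
        if len(qual) != len(seq):
            raise FastqFormatError("quality length != sequence length", record_index)
        yield header[1:].split()[0], seq.upper()
        record_index += 1


def iter_fasta(handle: io.TextIOBase) -> Iterator[tuple[str, str]]:
    name, chunks = None, []
    for line in handle:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if name is not None:
                yield name, "".join(chunks).upper()
            name, chunks = line[1:].split()[0] if len(line) > 1 else "", []
        elif name is not None:
            chunks.append(line)
    if name is not None:
        yield name, "".join(chunks).upper()


def iter_reads(source: ReadSource) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) pairs from FASTQ/FASTA (optionally .gz)."""
    if isinstance(source, (str, Path)):
        with _open_text(Path(source)) as fh:
            first = fh.read(1)
            if not first:
                return
            fh.seek(0)
            parser = iter_fastq if first == "@" else iter_fasta
            yield from parser(fh)
    else:
        yield from source


@dataclass
class AlleleCountTable:
    """Per-sample tally of probe-classified reads."""

    sample_id: str
    n_alt: int = 0
    n_ref: int = 0
    n_ambiguous: int = 0
    n_scanned: int = 0

    def __post_init__(self):
        if min(self.n_alt, self.n_ref, self.n_ambiguous, self.n_scanned) < 0:
            raise InputError("counts must be non-negative")
        if self.n_alt + self.n_ref + self.n_ambiguous > self.n_scanned:
            raise InputError("classified reads exceed reads scanned")

    def merged(self, other: "AlleleCountTable") -> "AlleleCountTable":
        """Combine chunk counts for the same sample."""
        if other.sample_id != self.sample_id:
            raise InputError("cannot merge tables from different samples")
        return AlleleCountTable(
            self.sample_id,
            self.n_alt + other.n_alt,
            self.n_ref + other.n_ref,
            self.n_ambiguous + other.n_ambiguous,
            self.n_scanned + other.n_scanned,
        )


def _fragment_id(read_id: str) -> str:
    return _MATE_SUFFIX.sub("", read_id)


def count_probe_matches(reads: ReadSource, probes: ProbeSet,
                        sample_id: str = "sample",
                        paired_dedup: bool = False) -> AlleleCountTable:
    """Classify reads by exact probe occurrence on either strand.

    With ``paired_dedup`` mates sharing a fragment id (``/1``/``/2``
    suffixes stripped) are merged so each fragment counts once; mates
    disagreeing in category make the fragment ambiguous.
    """
    alt_f = probes.alt_probe.residues
    alt_r = probes.alt_probe_rc.residues
    ref_f = probes.ref_probe.residues
    ref_r = probes.ref_probe_rc.residues

    if not paired_dedup:
        n_alt = n_ref = n_amb = n_scanned = 0
        for _rid, seq in iter_reads(reads):
            n_scanned += 1
            is_alt = alt_f in seq or alt_r in seq
            is_ref = ref_f in seq or ref_r in seq
            if is_alt and is_ref:
                n_amb += 1
            elif is_alt:
                n_alt += 1
            elif is_ref:
                n_ref += 1
        return AlleleCountTable(sample_id, n_alt, n_ref, n_amb, n_scanned)

    # fragment id -> bitmask: 1 = alt seen, 2 = ref seen
    frags: dict[str, int] = {}
    for rid, seq in iter_reads(reads):
        mask = (1 if (alt_f in seq or alt_r in seq) else 0) | (
            2 if (ref_f in seq or ref_r in seq) else 0
        )
        fid = _fragment_id(rid)
        frags[fid] = frags.get(fid, 0) | mask
    n_alt = sum(1 for m in frags.values() if m == 1)
    n_ref = sum(1 for m in frags.values() if m == 2)
    n_amb = sum(1 for m in frags.values() if m == 3)
    return AlleleCountTable(sample_id, n_alt, n_ref, n_amb, len(frags))


def count_report(tables: list[AlleleCountTable]) -> pd.DataFrame:
    """Tidy long-format summary: one row per (sample, category).

    Rows for ``alt`` and ``ref`` are always emitted; ``ambiguous`` only
    when non-zero. Totals are preserved exactly.
    """
    if not tables:
        raise InputError("need at least one count table")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate sample ids: {dupes}")
    rows = []
    for t in tables:
        rows.append({"sample": t.sample_id, "category": "alt", "count": t.n_alt})
        rows.append({"sample": t.sample_id, "category": "ref", "count": t.n_ref})
        if t.n_ambiguous:
            rows.append(
                {"sample": t.sample_id, "category": "ambiguous", "count": t.n_ambiguous}
            )
    return pd.DataFrame(rows, columns=["sample", "category", "count"])
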