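"""Paralog-unique, allele-discriminating probe construction.

A probe pair consists of a reference-allele window around a deletion site
and the same window with the deletion applied. Both probes (and their
reverse complements) must be absent, as exact substrings, from every
other paralog on either strand — mirroring exact ``grep``-style read
classification downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Optional

from .errors import InputError, OutOfBoundsError, ProbeUniquenessError
from .seqcore import DeletionSpec, NucSeq, apply_deletion, reverse_complement

# Default flanks reproduce a 39-nt reference probe with the variant base
# 32 nt from the 5' end (38-nt deletion probe).
DEFAULT_FLANK_LEFT = 32
DEFAULT_FLANK_RIGHT = 6


@dataclass
class HomeologSet:
    """Named paralog references plus the copy/allele structure of a locus."""

    paralogs: dict[str, NucSeq]
    copies_per_paralog: int = 1
    alleles_per_copy: int = 2

    def __post_init__(self):
        if len(self.paralogs) < 2:
            raise InputError("a HomeologSet needs >= 2 paralogs")
        if self.copies_per_paralog < 1 or self.alleles_per_copy < 1:
            raise InputError("copy/allele counts must be positive")
        for pid, seq in self.paralogs.items():
            if pid != seq.id:
                raise InputError(f"paralog key {pid!r} != sequence id {seq.id!r}")

    @property
    def total_alleles(self) -> int:
        """Alleles per paralogous locus (m), e.g. 6 for three diploid copies."""
        return self.copies_per_paralog * self.alleles_per_copy

    def ids(self) -> list[str]:
        return list(self.paralogs)

    @classmethod
    def from_fasta(cls, path: str | Path, copies_per_paralog: int = 1,
                   alleles_per_copy: int = 2) -> "HomeologSet":
        from .seqcore import read_fasta

        seqs = read_fasta(path)
        return cls({s.id: s for s in seqs}, copies_per_paralog, alleles_per_copy)


class ProbeHit(NamedTuple):
    paralog: str
    offset: int
    strand: str  # "+" or "-"


@dataclass(frozen=True)
class ProbeSet:
    """Reference/deletion probe pair with both orientations and provenance."""

    target_paralog: str
    ref_probe: NucSeq
    alt_probe: NucSeq
    ref_probe_rc: NucSeq
    alt_probe_rc: NucSeq
    variant: DeletionSpec  # in probe coordinates
    source_window: tuple[int, int]  # [start, end) in the target paralog

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            ("ref", self.ref_probe.residues),
            ("alt", self.alt_probe.residues),
            ("ref_rc", self.ref_probe_rc.residues),
            ("alt_rc", self.alt_probe_rc.residues),
        ]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["# target", self.target_paralog])
            w.writerow(["# window", self.source_window[0], self.source_window[1]])
            w.writerow(["# variant", self.variant.position, self.variant.length])
            for role, seq in rows:
                w.writerow([role, seq])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeSet":
        meta: dict[str, list[str]] = {}
        probes: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row:
                    continue
                if row[0].startswith("#"):
                    meta[row[0].lstrip("# ")] = row[1:]
                else:
                    probes[row[0]] = row[1]
        missing = {"ref", "alt", "ref_rc", "alt_rc"} - set(probes)
        if missing:
            raise InputError(f"probe file {path} missing roles: {sorted(missing)}")
        target = meta.get("target", ["?"])[0]
        window = tuple(int(x) for x in meta.get("window", [0, 0])[:2])
        vpos, vlen = (int(x) for x in meta.get("variant", [0, 1])[:2])
        return cls(
            target_paralog=target,
            ref_probe=NucSeq(f"{target}_ref_probe", probes["ref"]),
            alt_probe=NucSeq(f"{target}_alt_probe", probes["alt"]),
            ref_probe_rc=NucSeq(f"{target}_ref_probe_rc", probes["ref_rc"]),
            alt_probe_rc=NucSeq(f"{target}_alt_probe_rc", probes["alt_rc"]),
            variant=DeletionSpec(vpos, vlen),
            source_window=(window[0], window[1]),
        )


def _occurrences(haystack: str, needle: str) -> Iterator[int]:
    start = haystack.find(needle)
    while start != -1:
        yield start
        start = haystack.find(needle, start + 1)


def check_uniqueness(probe: NucSeq, refs: HomeologSet,
                     exclude: Optional[str] = None) -> list[ProbeHit]:
    """Exact occurrences of ``probe`` (either strand) outside ``exclude``.

    Hits on the minus strand are reported at the forward-strand offset of
    the reverse-complemented occurrence. An empty list means the probe is
    unique to the excluded paralog.
    """
    if len(probe) < 1:
        raise InputError("probe must be non-empty")
    probe_rc = reverse_complement(probe)
    hits: list[ProbeHit] = []
    for pid, seq in refs.paralogs.items():
        if pid == exclude:
            continue
        for off in _occurrences(seq.residues, probe.residues):
            hits.append(ProbeHit(pid, off, "+"))
        for off in _occurrences(seq.residues, probe_rc.residues):
            hits.append(ProbeHit(pid, off, "-"))
    return hits


def design_probes(refs: HomeologSet, target: str, variant: DeletionSpec,
                  flank_left: int = DEFAULT_FLANK_LEFT,
                  flank_right: int = DEFAULT_FLANK_RIGHT) -> ProbeSet:
    """Build an allele-discriminating probe pair around a deletion site.

    The window is anchored on the canonical (leftmost) variant position:
    ``flank_left`` bases, the deleted bases, then ``flank_right`` bases.
    Fails with :class:`ProbeUniquenessError` when any of the four probe
    strings occurs in a non-target paralog on either strand.
    """
    if target not in refs.paralogs:
        raise InputError(f"unknown target paralog {target!r}")
    if flank_left < 0 or flank_right < 0:
        raise InputError("flanks must be non-negative")
    target_seq = refs.paralogs[target]
    canon = variant.normalized(target_seq)

    start = canon.position - flank_left
    end = canon.position + canon.length + flank_right
    if start < 0 or end > len(target_seq):
        raise OutOfBoundsError(
            f"probe window [{start}, {end}) outside {target!r} "
            f"(length {len(target_seq)})"
        )

    ref_probe = NucSeq(f"{target}_ref_probe", target_seq.residues[start:end])
    probe_variant = DeletionSpec(flank_left, canon.length)
    alt_probe_seq = apply_deletion(ref_probe, probe_variant)
    alt_probe = NucSeq(f"{target}_alt_probe", alt_probe_seq.residues)

    hits = check_uniqueness(ref_probe, refs, exclude=target)
    hits += check_uniqueness(alt_probe, refs, exclude=target)
    if hits:
        raise ProbeUniquenessError(
            f"no unique probe at window [{start}, {end}) of {target!r}; "
            f"offending hits: {hits}",
            hits=hits,
        )

    return ProbeSet(
        target_paralog=target,
        ref_probe=ref_probe,
        alt_probe=alt_probe,
        ref_probe_rc=reverse_complement(ref_probe),
        alt_probe_rc=reverse_complement(alt_probe),
        variant=probe_variant,
        source_window=(start, end),
    )
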