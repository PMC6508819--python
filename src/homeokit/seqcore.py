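"""Nucleotide/protein sequence primitives.

Orientation, indel application with canonical (leftmost) placement,
standard-code translation, frameshift-consequence reporting, and
identity-based paralog assignment of cloned cDNA sequences.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, InputError, OutOfBoundsError

NUC_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code (NCBI table 1); codons containing N render as X.
_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
_CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})


@dataclass(frozen=True)
class NucSeq:
    """A named nucleotide sequence, 5'->3', over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise AlphabetError(f"{self.id!r}: empty sequence")
        bad = set(self.residues) - NUC_ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.id!r}: invalid characters {sorted(bad)!r} "
                "(alphabet is A,C,G,T,N)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DeletionSpec:
    """A deletion of ``length`` bases starting at 0-based ``position``."""

    position: int
    length: int = 1

    def __post_init__(self):
        if self.position < 0:
            raise OutOfBoundsError(f"deletion position {self.position} < 0")
        if self.length < 1:
            raise InputError(f"deletion length must be >= 1, got {self.length}")

    def check_bounds(self, seq: NucSeq) -> None:
        if self.position + self.length > len(seq):
            raise OutOfBoundsError(
                f"deletion [{self.position}, {self.position + self.length}) "
                f"exceeds length {len(seq)} of {seq.id!r}"
            )

    def normalized(self, seq: NucSeq) -> "DeletionSpec":
        """Leftmost-normalize within any homopolymer/repeat run.

        Deleting any base of a homopolymer run yields the same edited
        sequence; the canonical representation uses the leftmost position
        producing that result.
        """
        self.check_bounds(seq)
        pos = self.position
        s = seq.residues
        while pos > 0 and s[pos - 1] == s[pos + self.length - 1]:
            pos -= 1
        return DeletionSpec(pos, self.length)


@dataclass(frozen=True)
class FrameshiftReport:
    """Consequence of comparing a reference CDS with an edited CDS."""

    first_divergent_codon: int  # 1-based codon index
    premature_stop_codon: Optional[int]  # 1-based, None if absent
    ref_protein: str
    alt_protein: str
    fraction_intact: float


@dataclass(frozen=True)
class ParalogAssignment:
    clone_id: str
    best_paralog: str  # paralog id or "ambiguous"
    identities: Mapping[str, float] = field(default_factory=dict)


def reverse_complement(seq: NucSeq) -> NucSeq:
    """Watson-Crick reverse complement (N self-complements)."""
    return NucSeq(id=f"{seq.id}_rc", residues=seq.residues[::-1].translate(_COMPLEMENT))


def apply_deletion(seq: NucSeq, deletion: DeletionSpec) -> NucSeq:
    """Remove ``deletion.length`` bases; result is independent of which
    equivalent position inside a homopolymer run was specified."""
    canon = deletion.normalized(seq)
    res = seq.residues[: canon.position] + seq.residues[canon.position + canon.length :]
    return NucSeq(id=f"{seq.id}_del{canon.position}+{canon.length}", residues=res)


def translate(seq: NucSeq, frame: int = 0, to_stop: bool = True) -> str:
    """Translate with the standard genetic code.

    Trailing partial codons are ignored. Codons containing N render as X.
    With ``to_stop`` the protein is truncated at the first stop; otherwise
    stops appear as ``*``.
    """
    if frame not in (0, 1, 2):
        raise InputError(f"frame must be 0, 1 or 2, got {frame}")
    s = seq.residues[frame:]
    aas = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        aa = _CODON_TABLE.get(codon, "X")
        if aa == "*" and to_stop:
            break
        aas.append(aa)
    return "".join(aas)


def frameshift_consequence(ref_cds: NucSeq, alt_cds: NucSeq) -> Optional[FrameshiftReport]:
    """Compare translations of two frame-0 CDS variants.

    Returns None when the proteins are identical. Divergence is assessed
    on the full translations (stops included) so a stop replacing a
    residue counts as divergence; the reported protein strings are
    truncated at the first stop for readability.
    """
    ref_full = translate(ref_cds, 0, to_stop=False)
    alt_full = translate(alt_cds, 0, to_stop=False)
    if ref_full == alt_full:
        return None

    n = max(len(ref_full), len(alt_full))
    first_div = next(
        i + 1
        for i in range(n)
        if (ref_full[i : i + 1] or None) != (alt_full[i : i + 1] or None)
    )

    ref_stop = ref_full.find("*")
    alt_stop = alt_full.find("*")
    premature = None
    if alt_stop != -1 and (ref_stop == -1 or alt_stop < ref_stop):
        premature = alt_stop + 1

    ref_prot = ref_full[:ref_stop] if ref_stop != -1 else ref_full
    alt_prot = alt_full[:alt_stop] if alt_stop != -1 else alt_full

    prefix = 0
    for a, b in zip(ref_prot, alt_prot):
        if a != b:
            break
        prefix += 1
    fraction = prefix / len(ref_prot) if ref_prot else 0.0

    return FrameshiftReport(
        first_divergent_codon=first_div,
        premature_stop_codon=premature,
        ref_protein=ref_prot,
        alt_protein=alt_prot,
        fraction_intact=fraction,
    )


def _global_identity(aligner: PairwiseAligner, a: str, b: str) -> float:
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / total if total else 0.0


def assign_paralog(clone: NucSeq, refs: "HomeologSet | Mapping[str, NucSeq]") -> ParalogAssignment:
    """Assign a clone to the paralog it matches best.

    Identity = matches / alignment length under global alignment with
    match=1, mismatch=0, linear gap=-1. Ties are reported as "ambiguous"
    rather than broken arbitrarily.
    """
    paralogs = getattr(refs, "paralogs", refs)
    if len(paralogs) < 2:
        raise InputError("paralog assignment needs >= 2 reference paralogs")
    if not clone.residues:
        raise InputError("empty clone sequence")

    aligner = PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    identities = {
        pid: _global_identity(aligner, clone.residues, ref.residues)
        for pid, ref in paralogs.items()
    }
    best_val = max(identities.values())
    winners = [pid for pid, v in identities.items() if math.isclose(v, best_val, rel_tol=0, abs_tol=1e-12)]
    best = winners[0] if len(winners) == 1 else "ambiguous"
    return ParalogAssignment(clone_id=clone.id, best_paralog=best, identities=identities)


# --- FASTA I/O -------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucSeq]:
    """Read a (possibly line-wrapped) multi-record FASTA file."""
    return [
        NucSeq(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[NucSeq], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
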