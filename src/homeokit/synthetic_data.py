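"""Synthetic data generators with the statistical structure the analysis
pipeline assumes.

Everything is a pure function of its parameters and a seed: homeologous
paralog sets, deletion genotypes and allele pools, error-prone short
reads, multinomially sampled clone sets, negative-binomial expression
count matrices, and noisy logistic growth trajectories.

A single global seed is split into named per-stage substreams so stages
can be rerun independently while staying reproducible bit-for-bit.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InputError, OutOfBoundsError
from .growth import GrowthTrajectory
from .probe_design import HomeologSet
from .quant import CountMatrix
from .seqcore import DeletionSpec, NucSeq, apply_deletion, reverse_complement

_BASES = np.array(list("ACGT"))

RngLike = Union[int, np.random.Generator]


def substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one global seed."""
    key = int.from_bytes(stage.encode("utf-8"), "big") % (2**63)
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _rng(rng: RngLike, stage: str = "default") -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return substream(int(rng), stage)


# --- genotypes -------------------------------------------------------------

REF, DEL = "REF", "DEL"
_COPY_CODES = {
    "-": (DEL, DEL),   # copy homozygous for the deletion
    "TT": (REF, REF),  # copy homozygous for the reference base
    "T-": (REF, DEL),  # heterozygous copy
    "-T": (REF, DEL),
}


@dataclass(frozen=True)
class GenotypeConfig:
    """Allele pair per gene copy, over {REF, DEL}."""

    copies: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for pair in self.copies:
            if len(pair) != 2 or set(pair) - {REF, DEL}:
                raise InputError(f"invalid allele pair {pair!r}")

    @property
    def m(self) -> int:
        return 2 * len(self.copies)

    @property
    def n_del(self) -> int:
        return sum(a == DEL for pair in self.copies for a in pair)

    @property
    def deletion_fraction(self) -> float:
        return self.n_del / self.m

    @classmethod
    def from_label(cls, label: str) -> "GenotypeConfig":
        """Parse labels like "(-,-,TT)" or "(TT,TT,T-)".

        "-" denotes a copy homozygous for the deletion, "TT" homozygous
        reference, "T-" heterozygous. Unicode dashes are accepted.
        """
        text = label.strip().strip("()")
        for dash in "‐‑‒–—−":
            text = text.replace(dash, "-")
        copies = []
        for tok in text.split(","):
            tok = tok.strip()
            if tok not in _COPY_CODES:
                raise InputError(f"cannot parse copy genotype {tok!r} in {label!r}")
            copies.append(_COPY_CODES[tok])
        if not copies:
            raise InputError(f"empty genotype label {label!r}")
        return cls(tuple(copies))


# --- simulation spec -------------------------------------------------------

@dataclass
class SimulationSpec:
    """Bundle of generator parameters; ``seed`` fixes all outputs."""

    seed: int = 0
    n_paralogs: int = 3
    sequence_length: int = 2000
    divergence: float = 0.05
    read_length: int = 100
    n_reads: int = 10000
    error_rate: float = 0.001
    # expression model
    n_genes: int = 50
    replicates: int = 3
    library_size: float = 1e6
    dispersion: float = 0.1
    # growth model
    growth_noise_sd_frac: float = 0.05

    def __post_init__(self):
        if not (0 <= self.divergence < 0.25):
            raise InputError("divergence must lie in [0, 0.25)")


# --- sequence generators ---------------------------------------------------

def make_paralogs(n_paralogs: int, length: int, divergence: float,
                  rng: RngLike, ids: Optional[Sequence[str]] = None,
                  copies_per_paralog: int = 1,
                  alleles_per_copy: int = 2) -> HomeologSet:
    """Mutate one ancestor independently into ``n_paralogs`` sequences.

    Each paralog substitutes each site with probability divergence/2, so
    realized pairwise divergence is close to the requested value.
    """
    if n_paralogs < 2:
        raise InputError("need >= 2 paralogs")
    if not (0 <= divergence < 0.25):
        raise InputError("divergence must lie in [0, 0.25)")
    if length < 1:
        raise InputError("sequence length must be positive")
    if divergence > 0 and length * divergence < 1:
        raise InputError("divergence incompatible with sequence length")
    g = _rng(rng, "make_paralogs")
    if ids is None:
        ids = [f"paralog{str(i + 1).zfill(2)}" for i in range(n_paralogs)]
    if len(ids) != n_paralogs or len(set(ids)) != n_paralogs:
        raise InputError("ids must be unique and match n_paralogs")

    ancestor = g.integers(0, 4, size=length)
    paralogs: dict[str, NucSeq] = {}
    for pid in ids:
        seq = ancestor.copy()
        mutate = g.random(length) < divergence / 2.0
        # substitute to a uniformly chosen *different* base
        shift = g.integers(1, 4, size=length)
        seq[mutate] = (seq[mutate] + shift[mutate]) % 4
        paralogs[pid] = NucSeq(pid, "".join(_BASES[seq]))
    return HomeologSet(paralogs, copies_per_paralog, alleles_per_copy)


def pairwise_divergence(a: NucSeq, b: NucSeq) -> float:
    if len(a) != len(b):
        raise InputError("divergence defined for equal-length sequences")
    diff = sum(x != y for x, y in zip(a.residues, b.residues))
    return diff / len(a)


def apply_genotype(refs: HomeologSet, target: str, variant: DeletionSpec,
                   config: GenotypeConfig) -> list[NucSeq]:
    """Expand the target paralog into its m allele sequences.

    DEL alleles carry the deletion; copy/allele provenance is encoded in
    the sequence ids.
    """
    if target not in refs.paralogs:
        raise InputError(f"unknown target paralog {target!r}")
    if len(config.copies) != refs.copies_per_paralog:
        raise InputError(
            f"genotype has {len(config.copies)} copies but locus expects "
            f"{refs.copies_per_paralog}"
        )
    ref_seq = refs.paralogs[target]
    del_seq = apply_deletion(ref_seq, variant)
    pool = []
    for ci, pair in enumerate(config.copies):
        for ai, allele in enumerate(pair):
            seq = del_seq if allele == DEL else ref_seq
            pool.append(NucSeq(f"{target}|copy{ci + 1}|allele{ai + 1}|{allele}",
                               seq.residues))
    return pool


# --- read simulation -------------------------------------------------------

def simulate_reads(templates: Sequence[NucSeq], n_reads: int, read_length: int,
                   error_rate: float, rng: RngLike,
                   region: Optional[tuple[int, int]] = None) -> list[tuple[str, str]]:
    """Uniform short reads with i.i.d. substitution errors.

    Templates are sampled uniformly (pass duplicates to weight them),
    start positions uniformly over valid starts, strand by fair coin.
    ``region`` restricts start positions to [start, end) on every
    template (useful for concentrating reads near a locus of interest).
    Returns (read_id, sequence) tuples.
    """
    if n_reads < 0:
        raise InputError("n_reads must be >= 0")
    if not templates:
        raise InputError("need at least one template sequence")
    if not (0 <= error_rate < 1):
        raise InputError("error_rate must lie in [0, 1)")
    min_len = min(len(t) for t in templates)
    if read_length > min_len:
        raise OutOfBoundsError(
            f"read length {read_length} exceeds shortest template ({min_len} bp)"
        )
    g = _rng(rng, "simulate_reads")
    base_idx = {b: i for i, b in enumerate("ACGT")}

    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        tmpl = templates[int(g.integers(0, len(templates)))]
        max_start = len(tmpl) - read_length
        lo, hi = 0, max_start
        if region is not None:
            lo = max(0, region[0])
            hi = min(max_start, region[1] - 1)
            if hi < lo:
                raise InputError("region leaves no valid read start positions")
        start = int(g.integers(lo, hi + 1))
        frag = tmpl.residues[start : start + read_length]
        if error_rate > 0:
            arr = np.array([base_idx.get(b, 0) for b in frag])
            err = g.random(read_length) < error_rate
            if err.any():
                shift = g.integers(1, 4, size=read_length)
                arr[err] = (arr[err] + shift[err]) % 4
                frag = "".join(_BASES[arr])
        if g.random() < 0.5:
            frag = reverse_complement(NucSeq("tmp", frag)).residues
        reads.append((f"read_{i}|{tmpl.id}|{start}", frag))
    return reads


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write reads as FASTQ with constant Phred+33 qualities ('I')."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# --- clone sampling --------------------------------------------------------

def simulate_clones(transcripts: Sequence[NucSeq], proportions: Sequence[float],
                    n_clones: int, rng: RngLike) -> list[NucSeq]:
    """Multinomial clone sampling proportional to transcript abundance.

    Truth labels are retained in the clone ids ("...|truth=<paralog>").
    """
    props = np.asarray(proportions, dtype=float)
    if len(props) != len(transcripts):
        raise InputError("need one proportion per transcript")
    if (props < 0).any() or not np.isclose(props.sum(), 1.0):
        raise InputError("proportions must be non-negative and sum to 1")
    if n_clones < 0:
        raise InputError("n_clones must be >= 0")
    g = _rng(rng, "simulate_clones")
    draws = g.multinomial(n_clones, props)
    clones = []
    i = 0
    for tmpl, count in zip(transcripts, draws):
        for _ in range(count):
            clones.append(NucSeq(f"clone_{i}|truth={tmpl.id}", tmpl.residues))
            i += 1
    return clones


# --- expression counts -----------------------------------------------------

def simulate_rnaseq_counts(
    gene_lengths: pd.Series,
    baseline_fpkm: pd.Series,
    fold_effects: pd.DataFrame,
    genotypes: Sequence[str],
    treatments: Sequence[str],
    n_replicates: int,
    library_size: float,
    dispersion: float,
    rng: RngLike,
) -> CountMatrix:
    """Negative-binomial counts for a genotype x treatment x replicate design.

    ``fold_effects`` is genes x conditions with columns named
    "<genotype>:<treatment>"; the mean count of gene g in sample s is
    baseline_fpkm[g] * fold[g, cond(s)] * length[g]/1e3 * library/1e6,
    i.e. the programmed group-mean FPKM is baseline * fold. Dispersion
    follows var = mu + dispersion * mu^2 (0 -> Poisson).
    """
    if n_replicates < 1:
        raise InputError("need >= 1 replicate")
    if library_size <= 0:
        raise InputError("library size must be positive")
    if dispersion < 0:
        raise InputError("dispersion must be >= 0")
    genes = gene_lengths.index
    conditions = [f"{g}:{t}" for g in genotypes for t in treatments]
    missing = set(conditions) - set(fold_effects.columns)
    if missing:
        raise InputError(f"fold_effects missing conditions {sorted(missing)}")

    g = _rng(rng, "simulate_rnaseq_counts")
    samples, meta_rows = [], []
    data = {}
    for geno in genotypes:
        for treat in treatments:
            mu = (
                baseline_fpkm.values
                * fold_effects[f"{geno}:{treat}"].values
                * gene_lengths.values / 1e3
                * library_size / 1e6
            )
            for rep in range(1, n_replicates + 1):
                sid = f"{geno}_{treat}_r{rep}"
                if dispersion == 0:
                    counts = g.poisson(mu)
                else:
                    n_param = 1.0 / dispersion
                    p_param = n_param / (n_param + np.maximum(mu, 1e-300))
                    counts = np.where(
                        mu > 0, g.negative_binomial(n_param, p_param), 0
                    )
                data[sid] = counts
                samples.append(sid)
                meta_rows.append({"sample": sid, "genotype": geno,
                                  "treatment": treat, "replicate": rep})

    counts_df = pd.DataFrame(data, index=genes)[samples]
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(
        counts=counts_df, gene_lengths=gene_lengths, meta=meta,
        library_sizes=pd.Series(float(library_size), index=samples),
    )


# --- growth trajectories ---------------------------------------------------

@dataclass(frozen=True)
class GrowthGroupSpec:
    genotype: str
    vernalization_weeks: int
    A: float
    r: float
    t_half: float
    noise_sd: float
    n_plants: int


def simulate_growth(groups: Sequence[GrowthGroupSpec], rng: RngLike,
                    times: Optional[np.ndarray] = None) -> list[GrowthTrajectory]:
    """Weekly logistic heights plus Gaussian noise, truncated at zero.

    A winter-annual unvernalized (non-bolting) group is representable by
    a near-zero rate r.
    """
    g = _rng(rng, "simulate_growth")
    if times is None:
        times = np.arange(0.0, 9.0)
    times = np.asarray(times, dtype=float)
    trajs = []
    for spec in groups:
        for i in range(1, spec.n_plants + 1):
            mean = spec.A / (1.0 + np.exp(-spec.r * (times - spec.t_half)))
            noise = g.normal(0.0, spec.noise_sd, size=times.size) if spec.noise_sd > 0 else 0.0
            heights = np.maximum(mean + noise, 0.0)
            trajs.append(GrowthTrajectory(
                plant_id=f"{spec.genotype}_v{spec.vernalization_weeks}_p{i}",
                genotype=spec.genotype,
                vernalization_weeks=spec.vernalization_weeks,
                times=times.copy(), heights=heights,
            ))
    return trajs
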