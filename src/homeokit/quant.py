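"""Expression quantification, filtering and set-partition logic.

FPKM computation, the "expressed in all replicates of at least one
treatment" filter, Benjamini-Hochberg FDR, fold-change estimation
between groups, and the unique/common/opposite partition of two
per-genotype differential-expression tables.

The differential test itself is pluggable: any per-gene p-value column
may be supplied. A simple built-in two-group overdispersed-Poisson Wald
test with fixed dispersion is provided for synthetic pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError


@dataclass
class CountMatrix:
    """Integer fragment counts (genes x samples) with gene/sample metadata.

    ``meta`` is indexed by sample and must carry ``genotype``,
    ``treatment`` and ``replicate`` columns. Library sizes default to
    column sums when not provided.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    meta: pd.DataFrame
    library_sizes: Optional[pd.Series] = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise InputError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            raise InputError("gene_lengths missing for some genes")
        if (self.gene_lengths <= 0).any():
            raise InputError("gene lengths must be positive")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise InputError(f"sample metadata missing for {sorted(missing)}")
        for col in ("genotype", "treatment", "replicate"):
            if col not in self.meta.columns:
                raise InputError(f"metadata lacks required column {col!r}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                raise InputError("library_sizes missing for some samples")

    def samples_where(self, **conditions) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        for col, val in conditions.items():
            mask &= self.meta[col] == val
        return [s for s in self.counts.columns if s in self.meta.index[mask]]


def fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * library_size[s])
    """
    lib = cm.library_sizes
    if (lib <= 0).any():
        raise InputError("library sizes must be positive")
    return cm.counts * 1e9 / np.outer(cm.gene_lengths.values, lib.values)


def filter_expressed(fpkm_matrix: pd.DataFrame, groups: Mapping[str, str],
                     threshold: float = 5.0) -> pd.Index:
    """Genes whose FPKM meets ``threshold`` in every replicate of at
    least one group (treatment)."""
    missing = set(fpkm_matrix.columns) - set(groups)
    if missing:
        raise InputError(f"group label missing for samples {sorted(missing)}")
    by_group: dict[str, list[str]] = {}
    for sample in fpkm_matrix.columns:
        by_group.setdefault(groups[sample], []).append(sample)
    keep = pd.Series(False, index=fpkm_matrix.index)
    for samples in by_group.values():
        keep |= (fpkm_matrix[samples] >= threshold).all(axis=1)
    return fpkm_matrix.index[keep]


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(cm: CountMatrix, genotype: str, pre: str, post: str,
            dispersion: float = 0.1) -> pd.DataFrame:
    """Built-in stand-in differential test: post vs pre within a genotype.

    Per gene, group rates are estimated as (sum counts)/(sum library
    sizes); the Wald statistic compares log rates with a negative-
    binomial variance at the given fixed dispersion. Returns a DataFrame
    with log2fc (post relative to pre), pvalue and fdr columns.
    """
    pre_s = cm.samples_where(genotype=genotype, treatment=pre)
    post_s = cm.samples_where(genotype=genotype, treatment=post)
    if not pre_s or not post_s:
        raise InputError(f"no samples for genotype {genotype!r} in one of the groups")

    def _group_stats(samples):
        y = cm.counts[samples].values.astype(float)
        s = cm.library_sizes[samples].values
        tot = y.sum(axis=1)
        rate = tot / s.sum()
        mu = rate[:, None] * s[None, :]
        var_tot = (mu + dispersion * mu**2).sum(axis=1)
        # delta method on log(total counts)
        var_log = np.divide(var_tot, np.maximum(tot, 1.0) ** 2)
        return rate, var_log

    rate_pre, v_pre = _group_stats(pre_s)
    rate_post, v_post = _group_stats(post_s)

    eps = 0.5 / float(cm.library_sizes.sum())  # pseudo-rate for zero groups
    lfc = np.log2((rate_post + eps) / (rate_pre + eps))
    z = np.log((rate_post + eps) / (rate_pre + eps)) / np.sqrt(v_pre + v_post + 1e-300)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, 0.0, 1.0)

    return pd.DataFrame(
        {"log2fc": lfc, "pvalue": pvals, "fdr": bh_fdr(pvals)},
        index=cm.counts.index,
    )


@dataclass(frozen=True)
class GenotypeSummary:
    n_expressed: int
    n_significant: int
    n_up2x: int
    n_down2x: int
    n_unique: int
    n_unique_up2x: int
    n_unique_down2x: int


@dataclass(frozen=True)
class PartitionSummary:
    """Unique/common/opposite partition of two significant-gene sets."""

    genotypes: tuple[str, str]
    per_genotype: dict
    n_common: int
    n_common_up: int
    n_common_down: int
    n_opposite: int

    def to_frame(self) -> pd.DataFrame:
        a, b = self.genotypes
        ga, gb = self.per_genotype[a], self.per_genotype[b]
        rows = [
            ("expressed", ga.n_expressed, gb.n_expressed),
            ("significant", ga.n_significant, gb.n_significant),
            ("up_2fold", ga.n_up2x, gb.n_up2x),
            ("down_2fold", ga.n_down2x, gb.n_down2x),
            ("unique", ga.n_unique, gb.n_unique),
            ("unique_up_2fold", ga.n_unique_up2x, gb.n_unique_up2x),
            ("unique_down_2fold", ga.n_unique_down2x, gb.n_unique_down2x),
            ("common", self.n_common, self.n_common),
            ("common_up", self.n_common_up, self.n_common_up),
            ("common_down", self.n_common_down, self.n_common_down),
            ("common_opposite", self.n_opposite, self.n_opposite),
        ]
        return pd.DataFrame(rows, columns=["statistic", a, b]).set_index("statistic")


def partition_sets(de_a: pd.DataFrame, de_b: pd.DataFrame,
                   expressed_a: pd.Index, expressed_b: pd.Index,
                   fdr_cut: float = 0.05, fold_cut: float = 2.0,
                   genotypes: tuple[str, str] = ("A", "B")) -> PartitionSummary:
    """Partition significant genes of two genotypes into unique / common /
    opposite-direction sets.

    significant = expressed AND FDR <= fdr_cut; direction = sign of
    log2fc; the >=fold classes use |log2fc| >= log2(fold_cut).
    """
    lf = np.log2(fold_cut)

    def _sets(de: pd.DataFrame, expressed: pd.Index):
        sig = de.index[(de["fdr"] <= fdr_cut)].intersection(expressed)
        up = set(sig[(de.loc[sig, "log2fc"] >= lf)])
        down = set(sig[(de.loc[sig, "log2fc"] <= -lf)])
        return set(sig), up, down

    sig_a, up_a, down_a = _sets(de_a, expressed_a)
    sig_b, up_b, down_b = _sets(de_b, expressed_b)

    common = sig_a & sig_b
    uniq_a = sig_a - common
    uniq_b = sig_b - common

    sign_a = np.sign(de_a.loc[sorted(common), "log2fc"]) if common else pd.Series(dtype=float)
    sign_b = np.sign(de_b.loc[sorted(common), "log2fc"]) if common else pd.Series(dtype=float)
    same_up = int(((sign_a > 0) & (sign_b > 0)).sum())
    same_down = int(((sign_a < 0) & (sign_b < 0)).sum())
    opposite = len(common) - same_up - same_down

    a, b = genotypes
    per = {
        a: GenotypeSummary(
            len(expressed_a), len(sig_a), len(up_a), len(down_a),
            len(uniq_a), len(up_a & uniq_a), len(down_a & uniq_a),
        ),
        b: GenotypeSummary(
            len(expressed_b), len(sig_b), len(up_b), len(down_b),
            len(uniq_b), len(up_b & uniq_b), len(down_b & uniq_b),
        ),
    }
    return PartitionSummary(
        genotypes=genotypes, per_genotype=per, n_common=len(common),
        n_common_up=same_up, n_common_down=same_down, n_opposite=opposite,
    )


@dataclass(frozen=True)
class FoldEstimate:
    gene: str
    ratio: float
    mean_numerator: float
    mean_denominator: float
    infinite: bool = False


def estimate_fold(fpkm_matrix: pd.DataFrame, gene: str,
                  numerator_samples: Sequence[str],
                  denominator_samples: Sequence[str]) -> FoldEstimate:
    """Ratio of group-mean FPKM for one gene (numerator / denominator)."""
    if gene not in fpkm_matrix.index:
        raise InputError(f"gene {gene!r} not in expression matrix")
    if not numerator_samples or not denominator_samples:
        raise InputError("each group needs at least one replicate")
    num = float(fpkm_matrix.loc[gene, list(numerator_samples)].mean())
    den = float(fpkm_matrix.loc[gene, list(denominator_samples)].mean())
    if den == 0.0:
        return FoldEstimate(gene, float("inf"), num, den, infinite=True)
    return FoldEstimate(gene, num / den, num, den)
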