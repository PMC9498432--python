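"""Per-locus and pairwise-population differentiation statistics.

Everything here consumes the :class:`AlleleCountTable`, the per-cohort
allele-count summary that is the sufficient statistic for the estimators:

* Weir–Cockerham F_st (theta) per locus, in its allele-count form — the
  analysis-of-variance decomposition of allele frequencies into a between-
  population component ``a`` and a within-population component ``b``
  computed on sampled allele copies. Diploid genotypes contribute two
  copies each; the heterozygosity-based component ``c`` of the full
  genotypic estimator needs per-genotype data the count table does not
  carry and is identically zero here.
* Reynolds coancestry distance between cohort pairs: the least-squares
  estimator with finite-sample bias correction, accumulated over loci as a
  ratio of sums and clamped at zero (no ``-ln(1-theta)`` transform).
* Top-quantile ranking used by the outlier criterion (top 1% by default
  downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, LocusRecord

logger = logging.getLogger(__name__)


@dataclass
class AlleleCountTable:
    """Per-cohort, per-locus allele counts.

    ``n_a2[c, l]`` is the number of copies of allele_a2 among non-missing
    calls of cohort ``c`` at locus ``l``; ``n_total[c, l]`` the number of
    non-missing allele copies (2 per called diploid genotype).
    """

    cohorts: list[str]
    loci: list[LocusRecord]
    n_a2: np.ndarray  # int, (n_cohorts, n_loci)
    n_total: np.ndarray

    def __post_init__(self) -> None:
        self.n_a2 = np.asarray(self.n_a2, dtype=np.int64)
        self.n_total = np.asarray(self.n_total, dtype=np.int64)
        shape = (len(self.cohorts), len(self.loci))
        if self.n_a2.shape != shape or self.n_total.shape != shape:
            raise ValueError("count array shapes do not match cohorts x loci")
        if (self.n_a2 < 0).any() or (self.n_a2 > self.n_total).any():
            raise ValueError("require 0 <= n_a2 <= n_total")

    @property
    def n_cohorts(self) -> int:
        return len(self.cohorts)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def frequencies(self) -> np.ndarray:
        """Per-cohort allele_a2 frequency; NaN where no calls."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_total > 0, self.n_a2 / self.n_total, np.nan)

    def subset_cohorts(self, labels: list[str]) -> "AlleleCountTable":
        index = {c: i for i, c in enumerate(self.cohorts)}
        missing = [c for c in labels if c not in index]
        if missing:
            raise KeyError(f"cohorts absent from table: {missing}")
        rows = [index[c] for c in labels]
        return AlleleCountTable(
            cohorts=list(labels),
            loci=list(self.loci),
            n_a2=self.n_a2[rows].copy(),
            n_total=self.n_total[rows].copy(),
        )

    def subset_loci(self, locus_ids: list[str]) -> "AlleleCountTable":
        index = {l.id: i for i, l in enumerate(self.loci)}
        missing = [i for i in locus_ids if i not in index]
        if missing:
            raise KeyError(f"loci absent from table: {missing}")
        cols = [index[i] for i in locus_ids]
        return AlleleCountTable(
            cohorts=list(self.cohorts),
            loci=[self.loci[c] for c in cols],
            n_a2=self.n_a2[:, cols].copy(),
            n_total=self.n_total[:, cols].copy(),
        )


@dataclass
class FstVector:
    """Per-locus Weir–Cockerham theta with its variance components.

    ``theta`` may be negative (sampling noise around zero differentiation);
    it is NaN, with ``defined`` False, where the locus is monomorphic
    across all cohorts and the estimator is 0/0.
    """

    loci: list[LocusRecord]
    theta: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    defined: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        lines = ["snp\tchrom\tbp\ttheta\ta\tb\tc"]
        for i, l in enumerate(self.loci):
            lines.append(
                f"{l.id}\t{l.chrom}\t{l.bp}\t{self.theta[i]:.10g}"
                f"\t{self.a[i]:.10g}\t{self.b[i]:.10g}\t{self.c[i]:.10g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix over cohort labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    def write_phylip(self, path: str | Path) -> None:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab + "  " + " ".join(f"{x:.10f}" for x in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_phylip(cls, path: str | Path) -> "DistanceMatrix":
        raw = Path(path).read_text().split("\n")
        n = int(raw[0].split()[0])
        labels, rows = [], []
        for line in raw[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels=labels, d=np.asarray(rows))


def count_alleles(
    gm: GenotypeMatrix, cohort_assignment: list[str] | None = None
) -> AlleleCountTable:
    """Tally allele_a2 copies and called copies per cohort per locus.

    Missing genotypes contribute to neither count. Cohort order follows
    first appearance in the sample list.
    """
    assignment = cohort_assignment if cohort_assignment is not None else gm.cohort_assignment()
    if len(assignment) != gm.n_samples:
        raise ValueError("cohort assignment length mismatch")
    cohorts: list[str] = []
    for c in assignment:
        if c not in cohorts:
            cohorts.append(c)
    n_a2 = np.zeros((len(cohorts), gm.n_loci), dtype=np.int64)
    n_total = np.zeros_like(n_a2)
    assign = np.asarray(assignment)
    for ci, c in enumerate(cohorts):
        rows = gm.calls[assign == c]
        if rows.shape[0] == 0:
            raise ValueError(f"empty cohort: {c}")
        called = rows != MISSING
        n_total[ci] = 2 * called.sum(axis=0)
        n_a2[ci] = np.where(called, rows, 0).sum(axis=0)
    return AlleleCountTable(cohorts=cohorts, loci=list(gm.loci), n_a2=n_a2, n_total=n_total)


def wc_fst(counts: AlleleCountTable, cohorts: list[str] | None = None) -> FstVector:
    """Weir–Cockerham theta per locus over the given cohorts (default: all).

    Allele-count form of the variance-component estimator: with ``m_i``
    sampled allele copies and sample frequency ``p_i`` in population ``i``
    (populations with no calls at a locus drop out),

        n_bar = mean(m_i),  n_c = (sum m_i - sum m_i^2 / sum m_i)/(r - 1)
        p_bar = sum(m_i p_i)/sum(m_i)
        s2    = sum(m_i (p_i - p_bar)^2) / ((r - 1) n_bar)
        inner = p_bar(1-p_bar) - (r-1)/r * s2
        a = n_bar/n_c * (s2 - inner/(n_bar - 1))
        b = n_bar/(n_bar - 1) * inner
        theta = a / (a + b)

    Reciprocally fixed cohorts give exactly 1; loci monomorphic across all
    cohorts are flagged undefined.
    """
    tab = counts if cohorts is None else counts.subset_cohorts(cohorts)
    if tab.n_cohorts < 2:
        raise ValueError("wc_fst needs at least two cohorts")
    m = tab.n_total.astype(float)  # (r, L) allele copies
    present = m > 0
    r = present.sum(axis=0).astype(float)  # populations with data per locus
    if (r < 2).any():
        n_bad = int((r < 2).sum())
        logger.warning("wc_fst: %d loci have <2 cohorts with data; flagged undefined", n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(present, tab.n_a2 / np.where(present, m, 1), 0.0)
        m_sum = m.sum(axis=0)
        n_bar = m_sum / r
        n_c = (m_sum - (m**2).sum(axis=0) / m_sum) / (r - 1)
        p_bar = (m * p).sum(axis=0) / m_sum
        s2 = (m * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
        a = n_bar / n_c * (s2 - inner / (n_bar - 1))
        b = n_bar / (n_bar - 1) * inner
        denom = a + b
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1), np.nan)
    defined = (r >= 2) & (denom != 0) & np.isfinite(theta)
    theta = np.where(defined, theta, np.nan)
    return FstVector(
        loci=list(tab.loci),
        theta=theta,
        a=np.where(defined, a, np.nan),
        b=np.where(defined, b, np.nan),
        c=np.zeros_like(theta),
        defined=defined,
    )


def reynolds_distance(counts: AlleleCountTable) -> DistanceMatrix:
    """Pairwise Reynolds coancestry distance between cohorts.

    Per locus with sample frequencies ``p1, p2`` from ``m1, m2`` allele
    copies, using the unbiased within-population gene-diversity estimate
    ``v_i = m_i/(m_i - 1) p_i (1 - p_i)``:

        num_l = (p1 - p2)^2 - v1/m1 - v2/m2
        den_l = num_l + v1 + v2

    and the distance is ``max(0, sum_l num_l / sum_l den_l)`` over loci
    where both cohorts have at least 2 called copies. Loci unusable for a
    pair are skipped for that pair only.
    """
    if counts.n_cohorts < 2:
        raise ValueError("reynolds_distance needs at least two cohorts")
    m = counts.n_total.astype(float)
    usable = m >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(usable, counts.n_a2 / np.where(usable, m, 1), np.nan)
        v = np.where(usable, m / (m - 1) * p * (1 - p), np.nan)
    r = counts.n_cohorts
    d = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            ok = usable[i] & usable[j]
            if not ok.any():
                raise ValueError(
                    f"no usable loci for cohort pair ({counts.cohorts[i]}, {counts.cohorts[j]})"
                )
            num = (p[i, ok] - p[j, ok]) ** 2 - v[i, ok] / m[i, ok] - v[j, ok] / m[j, ok]
            den = num + v[i, ok] + v[j, ok]
            den_sum = den.sum()
            val = num.sum() / den_sum if den_sum > 0 else 0.0
            d[i, j] = d[j, i] = max(0.0, val)
    return DistanceMatrix(labels=list(counts.cohorts), d=d)


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


def top_fraction(
    scores: np.ndarray | FstVector,
    fraction: float,
    loci: list[LocusRecord] | None = None,
) -> list[str]:
    """Ids of the top ``ceil(fraction * L_defined)`` loci by descending score.

    NaN scores are excluded from both ranking and the denominator. Ties are
    broken deterministically by (chrom, bp) ascending.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if isinstance(scores, FstVector):
        loci = scores.loci
        values = scores.theta
    else:
        values = np.asarray(scores, dtype=float)
        if loci is None:
            raise ValueError("loci required when scores is a plain array")
    if len(loci) != len(values):
        raise ValueError("scores/loci length mismatch")
    defined = np.isfinite(values)
    n_def = int(defined.sum())
    if n_def == 0:
        logger.warning("top_fraction: no defined scores; returning empty set")
        return []
    k = int(np.ceil(fraction * n_def))
    order = sorted(
        (i for i in range(len(values)) if defined[i]),
        key=lambda i: (-values[i], _chrom_sort_key(loci[i].chrom), loci[i].bp),
    )
    return [loci[i].id for i in order[:k]]
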