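"""Multi-cohort contrast orchestration: scenario enumeration, MDS cohort
outlier screening, meta-population pooling, dual significance criteria,
cross-contrast consensus and gene-window annotation.

The experimental design mirrors a three-scenario selection-signature
study: (1) every grey test breed against every non-grey reference breed,
(2) a pooled grey meta-population against each reference, and (3) each
grey breed against a single same-lineage reference. A locus is flagged per
contrast when its q-value falls below 0.05 or it sits in the top 1% of the
F_st ranking, and the consensus step keeps loci supported by enough test
breeds across enough references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import bayes_outlier, diff_stats
from .genotype_io import MISSING, GenotypeMatrix, LocusRecord

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """One of the three contrast designs.

    * scenario 1 — every test cohort against every reference cohort;
    * scenario 2 — the pooled test meta-population against each reference
      (``pool_tests`` forced true);
    * scenario 3 — each test cohort against a single reference cohort.
    """

    scenario_id: int
    test_cohorts: list[str]
    reference_cohorts: list[str]
    pool_tests: bool = False
    excluded_cohorts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scenario_id not in (1, 2, 3):
            raise ValueError("scenario_id must be 1, 2 or 3")
        if self.scenario_id == 2:
            self.pool_tests = True
        if self.scenario_id == 3 and len(self.reference_cohorts) != 1:
            raise ValueError("scenario 3 requires exactly one reference cohort")
        if set(self.test_cohorts) & set(self.reference_cohorts):
            raise ValueError("test and reference cohorts must be disjoint")
        if not self.test_cohorts or not self.reference_cohorts:
            raise ValueError("empty test or reference cohort set")


META_LABEL = "META"


def enumerate_contrasts(cfg: ScenarioConfig) -> list[tuple[str, str]]:
    """(test, reference) pairs in deterministic test-major config order."""
    tests = [t for t in cfg.test_cohorts if t not in cfg.excluded_cohorts]
    refs = [r for r in cfg.reference_cohorts if r not in cfg.excluded_cohorts]
    if not tests or not refs:
        raise ValueError("no test or reference cohorts remain after exclusions")
    if cfg.scenario_id == 2:
        return [(META_LABEL, r) for r in refs]
    return [(t, r) for t in tests for r in refs]


def ibs_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise sample distance 1 - IBS similarity, pairwise-complete.

    IBS similarity between two samples is the mean over co-called loci of
    (shared allele fraction) = 1 - |g_i - g_j| / 2.
    """
    calls = gm.calls.astype(float)
    miss = gm.calls == MISSING
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        ok = ~miss[i] & ~miss[i + 1 :]
        diff = np.abs(calls[i] - calls[i + 1 :]) / 2.0
        with np.errstate(invalid="ignore"):
            row = np.where(ok, diff, 0.0).sum(axis=1) / np.maximum(ok.sum(axis=1), 1)
        d[i, i + 1 :] = d[i + 1 :, i] = row
    return d


def classical_mds(d: np.ndarray, n_axes: int = 2) -> np.ndarray:
    """Classical (metric) MDS: eigendecomposition of the double-centred
    squared-distance matrix; returns the first ``n_axes`` coordinates."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_axes]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return coords


@dataclass
class MdsCheckResult:
    flagged: list[str]
    coordinates: pd.DataFrame  # sample, cohort, axis1, axis2
    cohort_distances: pd.DataFrame  # cohort, centroid distance


def mds_cohort_check(
    gm: GenotypeMatrix, cohorts: list[str] | None = None, k: float = 2.5
) -> MdsCheckResult:
    """Flag cohorts whose MDS centroid is an outlier.

    A cohort is flagged when the distance of its centroid from the grand
    centroid (in the first two MDS axes) exceeds ``k`` times the median
    cohort-centroid distance. The quantitative rule replaces visual
    inspection of the scatter; the coordinates are returned for plotting.
    """
    if gm.n_samples < 3:
        raise ValueError("mds_cohort_check needs at least 3 samples")
    wanted = cohorts if cohorts is not None else gm.cohorts
    keep = np.asarray([s.cohort in wanted for s in gm.samples])
    sub = gm.subset_samples(keep)
    if len(sub.cohorts) < 2:
        raise ValueError("mds_cohort_check needs at least 2 cohorts")
    d = ibs_distance(sub)
    if np.allclose(d, 0):
        logger.warning("mds_cohort_check: degenerate (all-zero) distance matrix; no flags")
        coords = np.zeros((sub.n_samples, 2))
    else:
        coords = classical_mds(d, n_axes=2)
    coord_df = pd.DataFrame(
        {
            "sample": [s.sample_id for s in sub.samples],
            "cohort": [s.cohort for s in sub.samples],
            "axis1": coords[:, 0],
            "axis2": coords[:, 1],
        }
    )
    centroids = coord_df.groupby("cohort", sort=False)[["axis1", "axis2"]].mean()
    grand = centroids.mean(axis=0)
    dist = np.sqrt(((centroids - grand) ** 2).sum(axis=1))
    med = float(np.median(dist))
    flagged = [] if med == 0 else sorted(dist.index[dist > k * med])
    return MdsCheckResult(
        flagged=flagged,
        coordinates=coord_df,
        cohort_distances=dist.rename("centroid_distance").reset_index(),
    )


def plot_mds(result: MdsCheckResult, path: str | Path) -> None:
    """Scatter of the first two MDS axes, coloured by cohort."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for cohort, grp in result.coordinates.groupby("cohort", sort=False):
        marker = "x" if cohort in result.flagged else "o"
        ax.scatter(grp["axis1"], grp["axis2"], label=cohort, marker=marker, s=18)
    ax.set_xlabel("MDS axis 1")
    ax.set_ylabel("MDS axis 2")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pool_meta_population(
    gm: GenotypeMatrix,
    test_cohorts: list[str],
    excluded: list[str] | None = None,
    meta_label: str = META_LABEL,
) -> tuple[GenotypeMatrix, int]:
    """Relabel all non-excluded test-cohort samples to one meta-cohort.

    Samples of excluded cohorts are dropped; everything else is kept
    unchanged. Returns the relabelled panel and the pooled sample count.
    """
    excluded = excluded or []
    if not set(excluded) <= set(test_cohorts):
        raise ValueError("excluded cohorts must be a subset of test cohorts")
    pooled_set = [c for c in test_cohorts if c not in excluded]
    keep = np.asarray([s.cohort not in excluded for s in gm.samples])
    sub = gm.subset_samples(keep)
    assignment = [
        meta_label if s.cohort in pooled_set else s.cohort for s in sub.samples
    ]
    n_pooled = sum(1 for a in assignment if a == meta_label)
    if n_pooled < 2:
        raise ValueError("pooling leaves fewer than 2 samples")
    logger.info("pooled %d samples from %d cohorts into %s", n_pooled, len(pooled_set), meta_label)
    return sub.with_cohorts(assignment), n_pooled


@dataclass
class Criteria:
    """The dual outlier-significance criteria."""

    q_max: float = 0.05
    top_fraction: float = 0.01


@dataclass
class ContrastResult:
    """Per-locus outcome of one test-vs-reference contrast."""

    test: str
    reference: str
    loci: list[LocusRecord]
    score: np.ndarray  # F_st used for ranking (posterior mean or WC theta)
    q: np.ndarray | None
    sig_q: np.ndarray
    sig_top: np.ndarray

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.locus_ids,
                "chrom": [l.chrom for l in self.loci],
                "bp": [l.bp for l in self.loci],
                "score": self.score,
                "q": self.q if self.q is not None else np.nan,
                "sig_q": self.sig_q,
                "sig_top": self.sig_top,
            }
        )


def run_contrast(
    gm: GenotypeMatrix,
    test: str,
    reference: str,
    criteria: Criteria | None = None,
    engine: str = "wc",
    mcmc: bayes_outlier.McmcConfig | None = None,
) -> ContrastResult:
    """Score one contrast and apply both significance criteria.

    ``engine`` chooses the ranking score: ``"wc"`` ranks Weir–Cockerham
    theta (no q-values); ``"bayes"`` runs the reversible-jump chain and
    ranks the posterior mean F_st, with q-values from the posterior
    inclusion probabilities.
    """
    criteria = criteria or Criteria()
    counts = diff_stats.count_alleles(gm).subset_cohorts([test, reference])
    # restrict to loci informative in this pair
    informative = (counts.n_total > 0).all(axis=0) & ~(
        (counts.n_a2.sum(axis=0) == 0)
        | (counts.n_a2.sum(axis=0) == counts.n_total.sum(axis=0))
    )
    counts = counts.subset_loci([l.id for l, k in zip(counts.loci, informative) if k])

    if engine == "bayes":
        if mcmc is None:
            raise ValueError("engine='bayes' requires an McmcConfig")
        summary = bayes_outlier.fit(counts, mcmc)
        loci = summary.loci
        score = summary.fst_mean
        q = summary.q
        sig_q = q < criteria.q_max
    elif engine == "wc":
        fst = diff_stats.wc_fst(counts)
        loci = fst.loci
        score = fst.theta
        q = None
        sig_q = np.zeros(len(loci), dtype=bool)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    top = set(diff_stats.top_fraction(score, criteria.top_fraction, loci))
    sig_top = np.asarray([l.id in top for l in loci])
    return ContrastResult(
        test=test, reference=reference, loci=loci, score=score, q=q,
        sig_q=sig_q, sig_top=sig_top,
    )


@dataclass
class ConsensusTable:
    """Cross-contrast sharing summary (one row per locus kept or not)."""

    table: pd.DataFrame  # snp, chrom, bp, n_tests_per_ref..., n_refs, retained, contrasts
    min_tests: int
    min_refs: int
    criterion: str

    def retained_loci(self) -> list[str]:
        return self.table.loc[self.table["retained"], "snp"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def consensus(
    results: list[ContrastResult],
    min_tests: int = 4,
    min_refs: int = 3,
    criterion: str = "sig_top",
) -> ConsensusTable:
    """Keep loci significant in >= ``min_tests`` test cohorts for at least
    ``min_refs`` reference cohorts.

    ``criterion`` selects which flag counts: ``"sig_top"``, ``"sig_q"`` or
    ``"either"``. For single-reference designs (scenario 3) ``min_refs``
    degenerates to 1 and ``min_tests`` counts contrasts.
    """
    if criterion not in ("sig_top", "sig_q", "either"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if not results:
        raise ValueError("no contrast results")

    id_sets = [set(r.locus_ids) for r in results]
    common = set.intersection(*id_sets)
    if any(common != s for s in id_sets):
        logger.warning(
            "consensus: contrasts disagree on locus sets; intersecting to %d loci",
            len(common),
        )
    base = next(r for r in results)
    loci = [l for l in base.loci if l.id in common]
    ids = [l.id for l in loci]

    def flags(r: ContrastResult) -> dict[str, bool]:
        if criterion == "sig_top":
            f = r.sig_top
        elif criterion == "sig_q":
            f = r.sig_q
        else:
            f = r.sig_q | r.sig_top
        return dict(zip(r.locus_ids, f))

    refs: list[str] = []
    for r in results:
        if r.reference not in refs:
            refs.append(r.reference)
    per_ref_counts = {ref: np.zeros(len(ids), dtype=int) for ref in refs}
    support: list[list[str]] = [[] for _ in ids]
    for r in results:
        fl = flags(r)
        for i, sid in enumerate(ids):
            if fl.get(sid, False):
                per_ref_counts[r.reference][i] += 1
                support[i].append(f"{r.test}|{r.reference}")

    n_refs_ok = np.zeros(len(ids), dtype=int)
    for ref in refs:
        n_refs_ok += per_ref_counts[ref] >= min_tests
    retained = n_refs_ok >= min_refs

    data: dict[str, object] = {
        "snp": ids,
        "chrom": [l.chrom for l in loci],
        "bp": [l.bp for l in loci],
    }
    for ref in refs:
        data[f"n_tests_{ref}"] = per_ref_counts[ref]
    data["n_refs"] = n_refs_ok
    data["retained"] = retained
    data["contrasts"] = [";".join(s) for s in support]
    return ConsensusTable(
        table=pd.DataFrame(data), min_tests=min_tests, min_refs=min_refs,
        criterion=criterion,
    )


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval, 1-based inclusive coordinates."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start > end")


def read_annotation(path: str | Path, fmt: str | None = None) -> list[GeneAnnotation]:
    """Read a gene table from BED or GFF3.

    BED input is 0-based half-open and converted to 1-based inclusive
    (start+1, end); GFF3 is already 1-based inclusive. Format is inferred
    from the suffix when not given.
    """
    import pyranges as pr

    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if fmt == "bed":
        df = pr.read_bed(str(path)).df
        logger.info("read_annotation: converting BED 0-based half-open to 1-based inclusive")
        name_col = "Name" if "Name" in df.columns else None
        return [
            GeneAnnotation(
                gene=str(row["Name"]) if name_col else f"feature{i}",
                chrom=str(row["Chromosome"]),
                start=int(row["Start"]) + 1,
                end=int(row["End"]),
            )
            for i, row in df.iterrows()
        ]
    if fmt == "gff3":
        df = pr.read_gff3(str(path)).df
        # pyranges internalises GFF3 to 0-based half-open as well
        out = []
        for i, row in df.iterrows():
            name = row.get("Name") or row.get("ID") or f"feature{i}"
            out.append(
                GeneAnnotation(
                    gene=str(name),
                    chrom=str(row["Chromosome"]),
                    start=int(row["Start"]) + 1,
                    end=int(row["End"]),
                )
            )
        return out
    raise ValueError(f"unknown annotation format {fmt!r}")


def annotate_windows(
    loci: list[LocusRecord],
    annotation: list[GeneAnnotation],
    half_window: int = 250_000,
) -> dict[str, list[tuple[str, bool]]]:
    """Genes overlapping the +/- ``half_window`` bp window around each SNP.

    Intervals are closed on both sides and 1-based throughout: a gene is
    reported when [start, end] intersects [bp - half_window, bp +
    half_window] on the same chromosome, and flagged ``within=True`` when
    the SNP position falls inside the gene body itself.
    """
    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        # IntervalTree is half-open; +1 on the end closes the interval
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    out: dict[str, list[tuple[str, bool]]] = {}
    for locus in loci:
        tree = trees.get(locus.chrom)
        if tree is None:
            logger.info("annotate_windows: chromosome %s absent from annotation", locus.chrom)
            out[locus.id] = []
            continue
        lo = max(1, locus.bp - half_window)
        hi = locus.bp + half_window
        hits = sorted(tree.overlap(lo, hi + 1), key=lambda iv: (iv.begin, iv.data.gene))
        out[locus.id] = [
            (iv.data.gene, iv.data.start <= locus.bp <= iv.data.end) for iv in hits
        ]
    return out
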