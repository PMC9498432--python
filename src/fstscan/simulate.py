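"""Structured-population genotype simulation with planted selected loci.

Generates multi-breed SNP panels under a hierarchical Balding–Nichols
model: each locus draws an ancestral frequency, each lineage (e.g. taurine
vs indicine) drifts from the ancestor with divergence ``f_between``, and
each cohort drifts from its lineage with ``f_within`` — Beta-distributed
frequencies with dispersion F at both levels. Genotypes are then binomial
draws of two allele copies, with i.i.d. missingness.

"Planted" loci emulate differential selection for a shared phenotype: in
every designated grey cohort (in whichever lineage) the cohort frequency
receives a common derived-allele shift, so the planted signal crosses the
lineage split the way a shared-origin coat-colour variant would — the
ground truth every downstream detection stage is scored against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, LocusRecord, SampleRecord

logger = logging.getLogger(__name__)

_N_CHROM = 29  # bovine autosomes
_BP_SPACING = 100_000
_FREQ_CLAMP = 1e-6


@dataclass(frozen=True)
class CohortSpec:
    label: str
    n_samples: int
    lineage: str
    grey: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"cohort {self.label}: n_samples must be >= 1")


@dataclass
class PlantedSet:
    """A group of loci under planted differential selection.

    In the default *sweep* mode the derived allele is ancestrally rare
    (its ancestral frequency is redrawn low) and driven up by ``shift``
    in every target cohort — a shared selective sweep, the shape expected
    of a common-origin phenotype variant. Setting ``fst`` instead redraws
    the target-cohort frequencies Balding–Nichols style at that elevated
    F, giving undirected excess divergence.

    ``target_cohorts=None`` targets all grey cohorts.
    """

    indices: list[int]
    target_cohorts: list[str] | None = None
    shift: float = 0.85
    fst: float | None = None

    def __post_init__(self) -> None:
        if self.fst is not None and not (0 < self.fst < 1):
            raise ValueError("planted fst must lie in (0, 1)")
        if not (0 < self.shift < 1):
            raise ValueError("planted shift must lie in (0, 1)")


@dataclass
class SimulationConfig:
    """All knobs of one simulation; the seed fully determines the output."""

    n_loci: int
    cohorts: list[CohortSpec]
    f_between: float = 0.15  # lineage divergence from the common ancestor
    f_within: float = 0.05  # cohort divergence from its lineage
    planted: list[PlantedSet] = field(default_factory=list)
    missing_rate: float = 0.01
    maf_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.f_between, self.f_within):
            if not (0 < f < 1):
                raise ValueError("F parameters must lie in (0, 1)")
        if not (0 <= self.missing_rate <= 0.5):
            raise ValueError("missing_rate must lie in [0, 0.5]")
        seen: set[int] = set()
        for ps in self.planted:
            for i in ps.indices:
                if not (0 <= i < self.n_loci):
                    raise ValueError("planted index out of range")
                if i in seen:
                    raise ValueError(f"locus index {i} planted twice")
                seen.add(i)
        labels = [c.label for c in self.cohorts]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate cohort labels")

    def resolve_targets(self, ps: PlantedSet) -> list[str]:
        if ps.target_cohorts is not None:
            unknown = set(ps.target_cohorts) - {c.label for c in self.cohorts}
            if unknown:
                raise ValueError(f"unknown planted target cohorts: {sorted(unknown)}")
            return list(ps.target_cohorts)
        grey = [c.label for c in self.cohorts if c.grey]
        if not grey:
            raise ValueError("planted set targets grey cohorts but none are grey")
        return grey


def _beta_drift(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F) around p."""
    scale = (1.0 - f) / f
    a = np.maximum(p * scale, _FREQ_CLAMP)
    b = np.maximum((1.0 - p) * scale, _FREQ_CLAMP)
    return np.clip(rng.beta(a, b), _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)


def simulate(cfg: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw one panel; returns the genotypes and the per-locus truth table.

    The truth table has columns ``locus``, ``is_planted``, ``effect`` (the
    shift or elevated F actually used) and ``target_cohorts``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    p_anc = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, L)

    # sweep-mode planted loci: the derived allele starts rare everywhere
    sweep_idx = np.concatenate(
        [np.asarray(ps.indices, dtype=int) for ps in cfg.planted if ps.fst is None]
    ) if any(ps.fst is None for ps in cfg.planted) else np.array([], dtype=int)
    if sweep_idx.size:
        p_anc[sweep_idx] = rng.uniform(
            cfg.maf_floor, min(0.25, 2 * cfg.maf_floor + 0.15), sweep_idx.size
        )

    lineages: list[str] = []
    for c in cfg.cohorts:
        if c.lineage not in lineages:
            lineages.append(c.lineage)
    lineage_freq = {lin: _beta_drift(rng, p_anc, cfg.f_between) for lin in lineages}
    cohort_freq = {
        c.label: _beta_drift(rng, lineage_freq[c.lineage], cfg.f_within)
        for c in cfg.cohorts
    }

    planted = np.zeros(L, dtype=bool)
    target_lists: dict[int, list[str]] = {}
    effect = np.zeros(L)
    for ps in cfg.planted:
        targets = cfg.resolve_targets(ps)
        idx = np.asarray(ps.indices, dtype=int)
        planted[idx] = True
        for i in ps.indices:
            target_lists[i] = targets
        if ps.fst is not None:
            effect[idx] = ps.fst
            for label in targets:
                elevated = _beta_drift(rng, p_anc, ps.fst)
                cohort_freq[label][idx] = elevated[idx]
        else:
            effect[idx] = ps.shift
            for label in targets:
                # sweep: derived allele driven high but kept polymorphic
                cohort_freq[label][idx] = np.clip(
                    p_anc[idx] + ps.shift, _FREQ_CLAMP, 0.95
                )

    samples: list[SampleRecord] = []
    blocks: list[np.ndarray] = []
    for c in cfg.cohorts:
        g = rng.binomial(2, cohort_freq[c.label][None, :], size=(c.n_samples, L))
        blocks.append(g.astype(np.int8))
        samples += [
            SampleRecord(
                sample_id=f"{c.label}_{i + 1}", cohort=c.label, subspecies_tag=c.lineage
            )
            for i in range(c.n_samples)
        ]
    calls = np.concatenate(blocks, axis=0)
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    per_chrom = int(np.ceil(L / _N_CHROM))
    loci = [
        LocusRecord(
            id=f"snp{i:06d}",
            chrom=str(1 + i // per_chrom),
            bp=(i % per_chrom) * _BP_SPACING + 1,
            allele_a1="A",
            allele_a2="B",
        )
        for i in range(L)
    ]
    gm = GenotypeMatrix(samples=samples, loci=loci, calls=calls)
    truth = pd.DataFrame(
        {
            "locus": [l.id for l in loci],
            "is_planted": planted,
            "effect": effect,
            "target_cohorts": [
                ",".join(target_lists.get(i, [])) for i in range(L)
            ],
        }
    )
    return gm, truth


#: Table-1-shaped cohort panel: seven grey indicine breeds, one non-grey
#: indicine reference, four non-grey taurine references.
PAPER_COHORTS: tuple[CohortSpec, ...] = (
    CohortSpec("Bhagnari", 9, "indicine", grey=True),
    CohortSpec("Dajal", 9, "indicine", grey=True),
    CohortSpec("Guzerat", 3, "indicine", grey=True),
    CohortSpec("Hariana", 10, "indicine", grey=True),
    CohortSpec("Hissar", 9, "indicine", grey=True),
    CohortSpec("Kankrej", 10, "indicine", grey=True),
    CohortSpec("Tharparkar", 12, "indicine", grey=True),
    CohortSpec("Sahiwal", 10, "indicine", grey=False),
    CohortSpec("Angus", 20, "taurine", grey=False),
    CohortSpec("Holstein", 24, "taurine", grey=False),
    CohortSpec("Charolais", 33, "taurine", grey=False),
    CohortSpec("Limousin", 35, "taurine", grey=False),
)


def make_paper_shaped_config(
    n_loci: int = 23_000,
    n_planted: int = 30,
    n_planted_single: int = 0,
    n_taurine_grey: int = 0,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """A study-shaped simulation: 12 cohorts with the real breed-panel
    sample sizes (62 grey-indicine animals, 112 taurine), ~23k SNPs, and
    ``n_planted`` loci planted in every grey cohort.

    ``n_planted_single`` additionally plants loci in just one grey cohort
    (the largest, Tharparkar-shaped one) — signal that cross-cohort
    consensus should reject. ``n_taurine_grey`` appends grey taurine
    cohorts (15 animals each, Podolian-style) so phenotype-versus-lineage
    clustering can be exercised across the subspecies split; the default
    0 keeps exactly the 12-cohort panel.
    """
    cohorts = list(PAPER_COHORTS)
    for i in range(n_taurine_grey):
        cohorts.append(CohortSpec(f"GreyTaurine{i + 1}", 15, "taurine", grey=True))
    n_total = n_planted + n_planted_single
    stride = max(1, n_loci // max(n_total, 1))
    indices = list(range(0, n_loci, stride))[:n_total]
    planted = []
    if n_planted:
        planted.append(PlantedSet(indices=indices[:n_planted]))
    if n_planted_single:
        planted.append(
            PlantedSet(indices=indices[n_planted:], target_cohorts=["Tharparkar"])
        )
    return SimulationConfig(
        n_loci=n_loci,
        cohorts=cohorts,
        planted=planted,
        seed=seed,
        **overrides,
    )
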