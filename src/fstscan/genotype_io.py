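"""Read, merge, QC-filter and write SNP genotype panels in PLINK formats.

The central container is :class:`GenotypeMatrix`: diploid genotypes stored
as the per-sample count of copies of the second allele (``allele_a2``) at
each locus, with an explicit out-of-band sentinel for missing calls so that
a missing genotype can never be conflated with a homozygote.

Both the PLINK text dialect (``.ped``/``.map``) and the binary SNP-major
dialect (``.bed``/``.bim``/``.fam``) are supported, and write→read is the
identity on (samples, loci, calls) for either dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call. Kept negative so it can never be
#: mistaken for an allele count in {0, 1, 2}.
MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major variant ordering

# PLINK .bed 2-bit codes -> count of allele_a2 copies
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


class PlinkParseError(ValueError):
    """Malformed PLINK input; the message names the offending file/line."""


@dataclass(frozen=True)
class LocusRecord:
    """One biallelic SNP: identifier, map position and allele codes."""

    id: str
    chrom: str
    bp: int
    allele_a1: str
    allele_a2: str

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise ValueError(f"locus {self.id}: bp must be >= 1, got {self.bp}")


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped animal with its cohort (breed) assignment."""

    sample_id: str
    cohort: str
    subspecies_tag: str = ""

    def __post_init__(self) -> None:
        if not self.cohort:
            raise ValueError(f"sample {self.sample_id}: cohort must be non-empty")


@dataclass
class GenotypeMatrix:
    """Diploid SNP calls for a set of samples.

    ``calls[s, l]`` is the number of copies of ``loci[l].allele_a2`` carried
    by ``samples[s]``: 0, 1, 2 or :data:`MISSING`.
    """

    samples: list[SampleRecord]
    loci: list[LocusRecord]
    calls: np.ndarray  # int8, shape (n_samples, n_loci)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate SNP ids: {dupes}")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"invalid call values: {np.unique(self.calls[bad])}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    @property
    def cohorts(self) -> list[str]:
        """Distinct cohort labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.cohort, None)
        return list(seen)

    def cohort_assignment(self) -> list[str]:
        return [s.cohort for s in self.samples]

    def subset_loci(self, locus_ids: list[str]) -> "GenotypeMatrix":
        """Restrict to the listed loci, in the given order."""
        index = {l.id: i for i, l in enumerate(self.loci)}
        missing = [i for i in locus_ids if i not in index]
        if missing:
            raise KeyError(f"loci absent from panel: {missing}")
        cols = [index[i] for i in locus_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[c] for c in cols],
            calls=self.calls[:, cols].copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=[s for s, k in zip(self.samples, keep) if k],
            loci=list(self.loci),
            calls=self.calls[keep].copy(),
        )

    def with_cohorts(self, assignment: list[str]) -> "GenotypeMatrix":
        """Return a copy with the cohort labels replaced."""
        if len(assignment) != self.n_samples:
            raise ValueError("assignment length mismatch")
        return GenotypeMatrix(
            samples=[replace(s, cohort=c) for s, c in zip(self.samples, assignment)],
            loci=list(self.loci),
            calls=self.calls.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class QcReport:
    """Bookkeeping for one :func:`apply_qc` pass.

    Each removed locus is counted exactly once: loci failing the
    missing-rate filter are charged to ``n_removed_missing`` even if they
    also fail the MAF filter, so ``n_loci_out + n_removed_missing +
    n_removed_maf == n_loci_in`` always holds.
    """

    n_loci_in: int
    n_loci_out: int
    n_removed_maf: int
    n_removed_missing: int
    maf_min: float
    geno_max: float

    def __post_init__(self) -> None:
        if self.n_loci_out + self.n_removed_maf + self.n_removed_missing != self.n_loci_in:
            raise ValueError("QcReport counts do not reconcile")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["metric\tvalue"]
        for k in (
            "n_loci_in",
            "n_loci_out",
            "n_removed_maf",
            "n_removed_missing",
            "maf_min",
            "geno_max",
        ):
            lines.append(f"{k}\t{getattr(self, k)}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PLINK text dialect (.ped / .map)
# ---------------------------------------------------------------------------


def _read_map(path: Path) -> list[LocusRecord]:
    loci: list[tuple[str, str, int]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise PlinkParseError(f"{path}:{ln}: expected 4 MAP columns, got {len(parts)}")
        chrom, snp_id, _cm, bp = parts
        try:
            bp_i = int(bp)
        except ValueError as exc:
            raise PlinkParseError(f"{path}:{ln}: non-integer bp {bp!r}") from exc
        loci.append((snp_id, chrom, bp_i))
    return loci  # allele codes are filled in from the PED body


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    map_loci = _read_map(prefix.with_suffix(".map"))
    n_loci = len(map_loci)
    samples: list[SampleRecord] = []
    allele_rows: list[list[tuple[str, str]]] = []
    ped = prefix.with_suffix(".ped")
    for ln, line in enumerate(ped.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_loci:
            raise PlinkParseError(
                f"{ped}:{ln}: expected {6 + 2 * n_loci} fields "
                f"(6 + 2 x {n_loci} loci), got {len(parts)}"
            )
        fid, iid = parts[0], parts[1]
        samples.append(SampleRecord(sample_id=iid, cohort=fid))
        allele_rows.append(list(zip(parts[6::2], parts[7::2])))

    # The PED body does not designate which allele is A1, so orientation is
    # fixed deterministically: observed alleles sorted alphabetically.
    n_samples = len(samples)
    calls = np.full((n_samples, n_loci), MISSING, dtype=np.int8)
    loci: list[LocusRecord] = []
    for j, (snp_id, chrom, bp) in enumerate(map_loci):
        observed: set[str] = set()
        for s in range(n_samples):
            observed.update(a for a in allele_rows[s][j] if a != "0")
        if len(observed) > 2:
            raise PlinkParseError(
                f"{ped}: locus {snp_id}: more than two alleles {sorted(observed)}"
            )
        ordered = sorted(observed)
        a1 = ordered[0] if ordered else "0"
        a2 = ordered[1] if len(ordered) > 1 else "0"
        for s in range(n_samples):
            x, y = allele_rows[s][j]
            if x == "0" or y == "0":
                if x != y:
                    raise PlinkParseError(
                        f"{ped}: sample {samples[s].sample_id} locus {snp_id}: "
                        f"half-missing genotype {x}/{y}"
                    )
                continue  # stays MISSING
            calls[s, j] = (x == a2) + (y == a2)
        loci.append(LocusRecord(id=snp_id, chrom=chrom, bp=bp, allele_a1=a1, allele_a2=a2))
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


def _write_ped_map(gm: GenotypeMatrix, prefix: Path) -> None:
    map_lines = [f"{l.chrom}\t{l.id}\t0\t{l.bp}" for l in gm.loci]
    prefix.with_suffix(".map").write_text("\n".join(map_lines) + ("\n" if map_lines else ""))
    ped_lines = []
    for s, sample in enumerate(gm.samples):
        fields = [sample.cohort, sample.sample_id, "0", "0", "0", "-9"]
        for j, locus in enumerate(gm.loci):
            c = gm.calls[s, j]
            if c == MISSING:
                fields += ["0", "0"]
            elif c == 0:
                fields += [locus.allele_a1, locus.allele_a1]
            elif c == 1:
                fields += [locus.allele_a1, locus.allele_a2]
            else:
                fields += [locus.allele_a2, locus.allele_a2]
        ped_lines.append(" ".join(fields))
    prefix.with_suffix(".ped").write_text("\n".join(ped_lines) + ("\n" if ped_lines else ""))


# ---------------------------------------------------------------------------
# PLINK binary dialect (.bed / .bim / .fam), SNP-major
# ---------------------------------------------------------------------------


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bim = prefix.with_suffix(".bim")
    loci: list[LocusRecord] = []
    for ln, line in enumerate(bim.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise PlinkParseError(f"{bim}:{ln}: expected 6 BIM columns, got {len(parts)}")
        chrom, snp_id, _cm, bp, a1, a2 = parts
        loci.append(LocusRecord(id=snp_id, chrom=chrom, bp=int(bp), allele_a1=a1, allele_a2=a2))

    samples: list[SampleRecord] = []
    fam = prefix.with_suffix(".fam")
    for ln, line in enumerate(fam.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise PlinkParseError(f"{fam}:{ln}: expected 6 FAM columns, got {len(parts)}")
        samples.append(SampleRecord(sample_id=parts[1], cohort=parts[0]))

    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkParseError(f"{prefix.with_suffix('.bed')}: bad magic bytes (not SNP-major BED)")
    n_samples, n_loci = len(samples), len(loci)
    bytes_per_snp = (n_samples + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * n_loci:
        raise PlinkParseError(
            f"{prefix.with_suffix('.bed')}: expected {bytes_per_snp * n_loci} body bytes, "
            f"got {body.size}"
        )
    body = body.reshape(n_loci, bytes_per_snp)
    # unpack 2-bit codes, sample index runs LSB-first within each byte
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(n_loci, -1)[:, :n_samples]
    calls = _BED_DECODE[codes].T.astype(np.int8)
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls.copy())


def _write_bed(gm: GenotypeMatrix, prefix: Path) -> None:
    bim_lines = [
        f"{l.chrom}\t{l.id}\t0\t{l.bp}\t{l.allele_a1}\t{l.allele_a2}" for l in gm.loci
    ]
    prefix.with_suffix(".bim").write_text("\n".join(bim_lines) + ("\n" if bim_lines else ""))
    fam_lines = [f"{s.cohort}\t{s.sample_id}\t0\t0\t0\t-9" for s in gm.samples]
    prefix.with_suffix(".fam").write_text("\n".join(fam_lines) + ("\n" if fam_lines else ""))

    n_samples = gm.n_samples
    enc = np.zeros_like(gm.calls, dtype=np.uint8)
    for val, code in _BED_ENCODE.items():
        enc[gm.calls == val] = code
    pad = (-n_samples) % 4
    if pad:
        enc = np.concatenate([enc, np.zeros((pad, gm.n_loci), dtype=np.uint8)], axis=0)
    enc = enc.T.reshape(gm.n_loci, -1, 4)  # (loci, bytes, 4 samples)
    packed = (
        enc[:, :, 0] | (enc[:, :, 1] << 2) | (enc[:, :, 2] << 4) | (enc[:, :, 3] << 6)
    ).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def read_plink(path_prefix: str | Path, dialect: str = "text") -> GenotypeMatrix:
    """Read a PLINK panel; ``dialect`` is ``"text"`` (PED/MAP) or ``"binary"``.

    The binary dialect carries the A1/A2 designation in the BIM and round
    trips exactly. The text dialect does not encode allele order, so the
    reader orients each locus alphabetically (A1 = smaller allele code);
    panels written with alphabetical allele pairs and both alleles observed
    round trip exactly, others round trip up to the equivalent recoding.
    """
    prefix = Path(path_prefix)
    if dialect == "text":
        return _read_ped_map(prefix)
    if dialect == "binary":
        return _read_bed(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_plink(gm: GenotypeMatrix, path_prefix: str | Path, dialect: str = "text") -> None:
    """Write a panel in the chosen PLINK dialect (inverse of :func:`read_plink`)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "text":
        _write_ped_map(gm, prefix)
    elif dialect == "binary":
        _write_bed(gm, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def merge_panels(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two panels on the intersection of their SNP ids.

    Allele coding of ``b`` is reconciled to ``a``: when the allele pair is
    transposed, calls are complemented (2 - calls). Strand-ambiguous or
    irreconcilable loci are dropped and the count logged; no strand flipping
    is attempted.
    """
    idx_a = {l.id: i for i, l in enumerate(a.loci)}
    idx_b = {l.id: i for i, l in enumerate(b.loci)}
    shared = [l.id for l in a.loci if l.id in idx_b]

    keep_cols_a: list[int] = []
    keep_cols_b: list[int] = []
    flip: list[bool] = []
    n_dropped = 0
    for sid in shared:
        la, lb = a.loci[idx_a[sid]], b.loci[idx_b[sid]]
        pair_a = (la.allele_a1, la.allele_a2)
        pair_b = (lb.allele_a1, lb.allele_a2)
        if pair_b == pair_a:
            swap = False
        elif pair_b == pair_a[::-1]:
            swap = True
        else:
            n_dropped += 1
            continue
        keep_cols_a.append(idx_a[sid])
        keep_cols_b.append(idx_b[sid])
        flip.append(swap)
    if n_dropped:
        logger.warning("merge_panels: dropped %d loci with irreconcilable alleles", n_dropped)

    calls_a = a.calls[:, keep_cols_a]
    calls_b = b.calls[:, keep_cols_b].copy()
    flip_arr = np.asarray(flip, dtype=bool)
    if flip_arr.any():
        block = calls_b[:, flip_arr]
        nonmiss = block != MISSING
        block[nonmiss] = 2 - block[nonmiss]
        calls_b[:, flip_arr] = block
    return GenotypeMatrix(
        samples=list(a.samples) + list(b.samples),
        loci=[a.loci[c] for c in keep_cols_a],
        calls=np.concatenate([calls_a, calls_b], axis=0),
    )


def allele_frequencies(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-locus (freq of allele_a2, non-missing call count)."""
    miss = gm.calls == MISSING
    n_called = (~miss).sum(axis=0)
    tot = np.where(miss, 0, gm.calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, tot / (2.0 * n_called), np.nan)
    return freq, n_called


def apply_qc(
    gm: GenotypeMatrix, maf_min: float = 0.05, geno_max: float = 0.1
) -> tuple[GenotypeMatrix, QcReport]:
    """Locus-level QC: drop loci with MAF < ``maf_min`` (pooled samples) or
    missing-call fraction > ``geno_max``.

    Defaults match routine SNP-chip filtering (``--maf 0.05 --geno 0.1``).
    A locus failing both filters is charged to the missingness count only.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= geno_max <= 1):
        raise ValueError("geno_max must be in [0, 1]")

    miss_frac = (gm.calls == MISSING).mean(axis=0) if gm.n_samples else np.zeros(gm.n_loci)
    miss = gm.calls == MISSING
    n_called = (~miss).sum(axis=0)
    tot = np.where(miss, 0, gm.calls).sum(axis=0)
    # integer minor-allele count keeps the MAF exactly symmetric in A1/A2
    minor = np.minimum(tot, 2 * n_called - tot)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n_called > 0, minor / (2.0 * n_called), np.nan)

    fail_missing = (miss_frac > geno_max) | (n_called == 0)
    fail_maf = ~fail_missing & (maf < maf_min)
    keep = ~(fail_missing | fail_maf)

    out = GenotypeMatrix(
        samples=list(gm.samples),
        loci=[l for l, k in zip(gm.loci, keep) if k],
        calls=gm.calls[:, keep].copy(),
    )
    report = QcReport(
        n_loci_in=gm.n_loci,
        n_loci_out=int(keep.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int(fail_missing.sum()),
        maf_min=maf_min,
        geno_max=geno_max,
    )
    return out, report
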