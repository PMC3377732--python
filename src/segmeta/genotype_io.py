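"""Cohort genotype/phenotype I/O.

Two on-disk dialects are supported:

* PLINK 1 binary (``.bed``/``.bim``/``.fam``), SNP-major mode only, the de
  facto interchange format for hard-call case/control genotype data.
* A whitespace-delimited plain-text fixture format, convenient for tests and
  documentation (see :func:`read_text_cohort`).

Dosages count copies of the A1 allele as stored (0/1/2, missing as -1 in
memory).  SNP positions are 1-based base pairs, as in ``.bim``; genomic
intervals elsewhere in the package are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1  # in-memory missing dosage sentinel

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# PLINK 1 two-bit genotype codes -> A1-allele dosage.
# 00 = hom A1 (2 copies), 10 = het (1), 11 = hom A2 (0), 01 = missing.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised for malformed or unsupported PLINK binary input."""


class PhenotypeError(ValueError):
    """Raised for phenotype codes outside the supported domain."""


class TextFormatError(ValueError):
    """Raised for malformed text fixture input."""


@dataclass(frozen=True)
class SnpRecord:
    """One SNP of the map: identifier, autosome, 1-based position, alleles."""

    id: str
    chrom: int
    pos_bp: int
    allele_ref: str = "A"
    allele_alt: str = "B"

    def __post_init__(self) -> None:
        if not 1 <= self.chrom <= 22:
            raise ValueError(f"SNP {self.id}: chrom {self.chrom} outside autosomes 1-22")
        if self.pos_bp < 1:
            raise ValueError(f"SNP {self.id}: pos_bp must be >= 1, got {self.pos_bp}")


@dataclass
class Cohort:
    """In-memory case/control cohort.

    Attributes
    ----------
    snps
        SNP map sorted by (chrom, pos_bp), strictly increasing positions
        within each chromosome.
    genotypes
        ``(n_individuals, n_snps)`` int8 matrix of A1-allele counts in
        {0, 1, 2}, with missing stored as :data:`MISSING`.
    phenotype
        Length ``n_individuals`` vector of {0 = control, 1 = case}.
    cohort_id
        Free-form label used in outputs.
    """

    snps: list[SnpRecord]
    genotypes: np.ndarray
    phenotype: np.ndarray
    cohort_id: str = "cohort"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.validate()

    # -- structural invariants -------------------------------------------------

    def validate(self) -> None:
        n_ind, n_snp = self.genotypes.shape if self.genotypes.ndim == 2 else (len(self.genotypes), -1)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix (individuals x SNPs)")
        if n_snp != len(self.snps):
            raise ValueError(f"genotype columns ({n_snp}) != SNP count ({len(self.snps)})")
        if len(self.phenotype) != n_ind:
            raise ValueError(f"phenotype length ({len(self.phenotype)}) != individuals ({n_ind})")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"genotypes contain values outside {{0,1,2,missing}}: "
                             f"{np.unique(self.genotypes[bad])}")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise PhenotypeError("phenotype must be 0 (control) or 1 (case)")
        if n_ind > 0 and (0 not in self.phenotype or 1 not in self.phenotype):
            raise PhenotypeError("both phenotype classes must be present")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("SNP ids are not unique")
        keys = [(s.chrom, s.pos_bp) for s in self.snps]
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("SNP map must be strictly increasing by (chrom, pos_bp)")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos_bp for s in self.snps], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps], dtype=np.int64)

    def equals(self, other: "Cohort") -> bool:
        return (self.snps == other.snps
                and np.array_equal(self.genotypes, other.genotypes)
                and np.array_equal(self.phenotype, other.phenotype))


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

def _decode_bed_bytes(raw: np.ndarray, n_individuals: int) -> np.ndarray:
    """Unpack one SNP-major byte block into per-individual dosages."""
    # two-bit fields, individual i at bits (2*(i%4), +1) of byte i//4
    codes = np.empty(len(raw) * 4, dtype=np.uint8)
    for k in range(4):
        codes[k::4] = (raw >> (2 * k)) & 0b11
    return _CODE_TO_DOSAGE[codes[:n_individuals]]


def _encode_bed_bytes(dosages: np.ndarray) -> np.ndarray:
    n = len(dosages)
    n_bytes = (n + 3) // 4
    codes = np.full(n_bytes * 4, 0b11, dtype=np.uint8)  # pad with hom A2
    lut = np.zeros(4, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        lut[dos if dos != MISSING else 3] = code  # map -1 -> slot 3
    idx = np.where(dosages == MISSING, 3, dosages)
    codes[:n] = lut[idx]
    out = np.zeros(n_bytes, dtype=np.uint8)
    for k in range(4):
        out |= codes[k::4] << (2 * k)
    return out


def read_plink(bed_path, bim_path=None, fam_path=None, cohort_id: str | None = None) -> Cohort:
    """Read a PLINK 1 binary trio into a :class:`Cohort`.

    ``bim_path``/``fam_path`` default to the ``.bed`` path with the extension
    swapped.  Non-autosomal SNPs are dropped (logged); individuals with
    missing phenotype (-9) are dropped (logged warning).
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    fam_rows = [ln.split() for ln in fam_path.read_text().splitlines() if ln.strip()]
    n_ind_all = len(fam_rows)
    pheno_raw = np.array([int(float(r[5])) for r in fam_rows], dtype=np.int64)
    bad_pheno = ~np.isin(pheno_raw, (1, 2, -9))
    if bad_pheno.any():
        raise PhenotypeError(
            f"{fam_path}: phenotype codes outside {{1,2,-9}}: {np.unique(pheno_raw[bad_pheno])}")
    keep_ind = pheno_raw != -9
    n_dropped_ind = int((~keep_ind).sum())
    if n_dropped_ind:
        logger.warning("%s: dropping %d individuals with missing (-9) phenotype",
                       fam_path, n_dropped_ind)

    snps_all: list[SnpRecord | None] = []
    for i, ln in enumerate(bim_path.read_text().splitlines()):
        if not ln.strip():
            continue
        f = ln.split()
        chrom_s, snp_id, pos, a1, a2 = f[0], f[1], f[3], f[4], f[5]
        try:
            chrom = int(chrom_s)
        except ValueError:
            chrom = -1
        if 1 <= chrom <= 22:
            snps_all.append(SnpRecord(snp_id, chrom, int(pos), a1, a2))
        else:
            snps_all.append(None)
    n_snps_all = len(snps_all)
    keep_snp = np.array([s is not None for s in snps_all], dtype=bool)
    n_dropped_snp = int((~keep_snp).sum())
    if n_dropped_snp:
        logger.info("%s: dropping %d non-autosomal SNPs", bim_path, n_dropped_snp)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not a PLINK 1 .bed file)")
    if bytes(raw[2:3]) != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: individual-major mode is not supported")
    body = raw[3:]
    bps = (n_ind_all + 3) // 4  # bytes per SNP
    if len(body) != bps * n_snps_all:
        raise PlinkFormatError(
            f"{bed_path}: expected {bps * n_snps_all} data bytes for "
            f"{n_ind_all} individuals x {n_snps_all} SNPs, found {len(body)}")

    geno = np.empty((int(keep_ind.sum()), int(keep_snp.sum())), dtype=np.int8)
    out_j = 0
    for j in range(n_snps_all):
        if not keep_snp[j]:
            continue
        dos = _decode_bed_bytes(body[j * bps:(j + 1) * bps], n_ind_all)
        geno[:, out_j] = dos[keep_ind]
        out_j += 1

    phenotype = (pheno_raw[keep_ind] - 1).astype(np.int8)  # 1->0 control, 2->1 case
    snps = [s for s in snps_all if s is not None]
    return Cohort(snps=snps, genotypes=geno, phenotype=phenotype,
                  cohort_id=cohort_id or bed_path.stem)


def write_plink(cohort: Cohort, prefix) -> tuple[Path, Path, Path]:
    """Write ``prefix.bed/.bim/.fam`` (SNP-major). Returns the three paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed, bim, fam = (prefix.with_suffix(ext) for ext in (".bed", ".bim", ".fam"))

    with open(fam, "w") as fh:
        for i, ph in enumerate(cohort.phenotype):
            fh.write(f"F{i} I{i} 0 0 0 {int(ph) + 1}\n")
    with open(bim, "w") as fh:
        for s in cohort.snps:
            fh.write(f"{s.chrom} {s.id} 0 {s.pos_bp} {s.allele_ref} {s.allele_alt}\n")
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR)
        for j in range(cohort.n_snps):
            fh.write(_encode_bed_bytes(cohort.genotypes[:, j]).tobytes())
    return bed, bim, fam


# ---------------------------------------------------------------------------
# Text fixture dialect
# ---------------------------------------------------------------------------
#
#   #cohort <id>              (optional)
#   snp     <id> <id> ...
#   chrom   <c> <c> ...
#   pos     <p> <p> ...
#   <pheno> <dos> <dos> ...   one row per individual; NA = missing
#

def read_text_cohort(path, cohort_id: str | None = None) -> Cohort:
    """Parse the whitespace-delimited text fixture dialect."""
    path = Path(path)
    header: dict[str, list[str]] = {}
    pheno: list[int] = []
    rows: list[list[int]] = []
    file_id = None
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        f = ln.split()
        if f[0] == "#cohort":
            file_id = f[1] if len(f) > 1 else None
            continue
        if f[0] in ("snp", "chrom", "pos"):
            header[f[0]] = f[1:]
            continue
        if not {"snp", "chrom", "pos"} <= header.keys():
            raise TextFormatError(f"{path}:{lineno}: data row before complete header")
        n_snp = len(header["snp"])
        if len(f) != n_snp + 1:
            raise TextFormatError(
                f"{path}:{lineno}: expected {n_snp + 1} fields (phenotype + dosages), got {len(f)}")
        try:
            ph = int(f[0])
        except ValueError:
            raise TextFormatError(f"{path}:{lineno}: bad phenotype {f[0]!r}") from None
        dos = []
        for tok in f[1:]:
            if tok == "NA":
                dos.append(MISSING)
            else:
                try:
                    d = int(tok)
                except ValueError:
                    raise TextFormatError(f"{path}:{lineno}: bad dosage {tok!r}") from None
                if d not in (0, 1, 2):
                    raise TextFormatError(f"{path}:{lineno}: dosage {d} outside {{0,1,2,NA}}")
                dos.append(d)
        pheno.append(ph)
        rows.append(dos)
    if not {"snp", "chrom", "pos"} <= header.keys():
        raise TextFormatError(f"{path}: missing snp/chrom/pos header lines")
    if not (len(header["snp"]) == len(header["chrom"]) == len(header["pos"])):
        raise TextFormatError(f"{path}: header rows have unequal lengths")
    snps = [SnpRecord(i, int(c), int(p))
            for i, c, p in zip(header["snp"], header["chrom"], header["pos"])]
    geno = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(snps)), dtype=np.int8)
    return Cohort(snps=snps, genotypes=geno, phenotype=np.array(pheno, dtype=np.int8),
                  cohort_id=cohort_id or file_id or path.stem)


def write_text_cohort(cohort: Cohort, path) -> Path:
    """Write the text fixture dialect (inverse of :func:`read_text_cohort`)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"#cohort {cohort.cohort_id}\n")
        fh.write("snp " + " ".join(s.id for s in cohort.snps) + "\n")
        fh.write("chrom " + " ".join(str(s.chrom) for s in cohort.snps) + "\n")
        fh.write("pos " + " ".join(str(s.pos_bp) for s in cohort.snps) + "\n")
        for i in range(cohort.n_individuals):
            dos = ("NA" if d == MISSING else str(d) for d in cohort.genotypes[i])
            fh.write(f"{int(cohort.phenotype[i])} " + " ".join(dos) + "\n")
    return path
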