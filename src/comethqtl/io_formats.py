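"""Readers and writers for the tabular formats the pipeline touches.

All coordinates are 1-based and inclusive internally (VCF convention).
BED-like inputs (0-based, half-open) are converted on read. Chromosome
names are normalized by stripping a leading ``chr``. Missing values are
represented as NaN in the numeric matrices and written as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = {".", "NA", "nan", "NaN", ""}

METHQTL_COLUMNS = [
    "cpg_id",
    "snp_id",
    "chrom",
    "cpg_pos",
    "snp_pos",
    "distance",
    "slope",
    "se",
    "p_value",
    "n_samples",
]


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so mixed-source inputs agree."""
    chrom = str(chrom)
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _sort_by_position(chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Stable ordering by (chromosome, position)."""
    return np.lexsort((pos, chrom))


@dataclass
class MethylationMatrix:
    """CpG x sample beta values with genomic coordinates.

    ``beta`` holds methylation levels in [0, 1]; NaN marks missing calls.
    Rows are kept sorted by position within each chromosome.
    """

    cpg_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    beta: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray([normalize_chrom(c) for c in self.chrom], dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.beta = np.asarray(self.beta, dtype=float)
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ParseError("duplicate CpG ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParseError("duplicate sample ids")
        if self.beta.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValueError(
                f"beta shape {self.beta.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        finite = self.beta[np.isfinite(self.beta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ParseError("beta values outside [0, 1]")
        order = _sort_by_position(self.chrom, self.pos)
        if not np.array_equal(order, np.arange(len(order))):
            self.cpg_ids = [self.cpg_ids[i] for i in order]
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.beta = self.beta[order]

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, cpg_id: str) -> np.ndarray:
        return self.beta[self.cpg_ids.index(cpg_id)]

    def subset_cpgs(self, keep: Sequence[str]) -> "MethylationMatrix":
        keep_set = set(keep)
        idx = [i for i, c in enumerate(self.cpg_ids) if c in keep_set]
        return MethylationMatrix(
            cpg_ids=[self.cpg_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            beta=self.beta[idx],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, keep: Sequence[str]) -> "MethylationMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return MethylationMatrix(
            cpg_ids=list(self.cpg_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            beta=self.beta[:, idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class GenotypeMatrix:
    """SNP x sample alt-allele dosages (0/1/2, NaN = missing) with alleles."""

    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    dosage: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray([normalize_chrom(c) for c in self.chrom], dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ParseError("duplicate SNP ids")
        if self.dosage.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("dosage shape does not match ids")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
            raise ParseError("dosage entries must be 0, 1, 2 or missing")
        for allele in np.concatenate([self.ref_allele, self.alt_allele]):
            if allele not in ("A", "C", "G", "T"):
                raise ParseError(f"unknown allele code {allele!r}")
        order = _sort_by_position(self.chrom, self.pos)
        if not np.array_equal(order, np.arange(len(order))):
            self.snp_ids = [self.snp_ids[i] for i in order]
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref_allele = self.ref_allele[order]
            self.alt_allele = self.alt_allele[order]
            self.dosage = self.dosage[order]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, snp_id: str) -> np.ndarray:
        return self.dosage[self.snp_ids.index(snp_id)]

    def subset_snps(self, keep: Sequence[str]) -> "GenotypeMatrix":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.snp_ids) if s in keep_set]
        return GenotypeMatrix(
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            dosage=self.dosage[idx],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return GenotypeMatrix(
            snp_ids=list(self.snp_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
            dosage=self.dosage[:, idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class CovariateTable:
    """Per-sample covariates; each column is tagged continuous or categorical."""

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ParseError("duplicate sample ids in covariate table")
        for name in self.data.columns:
            kind = self.kinds.get(name)
            if kind is None:
                kind = (
                    "continuous"
                    if pd.api.types.is_numeric_dtype(self.data[name])
                    else "categorical"
                )
                self.kinds[name] = kind
            if kind not in ("continuous", "categorical"):
                raise ValueError(f"unknown covariate kind {kind!r} for {name}")
            if kind == "categorical" and self.data[name].dropna().nunique() < 1:
                raise ParseError(f"categorical covariate {name} has no levels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def design_columns(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Expand to a numeric design block; categoricals become 0/1 indicators
        dropping one reference level."""
        names = list(self.data.columns) if names is None else list(names)
        blocks = []
        for name in names:
            col = self.data[name]
            if self.kinds[name] == "continuous":
                blocks.append(col.astype(float).to_frame(name))
            else:
                dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
                blocks.append(dummies)
        if not blocks:
            return pd.DataFrame(index=self.data.index)
        return pd.concat(blocks, axis=1)


# ---------------------------------------------------------------------------
# methylation I/O


def _parse_beta_field(token: str, path: str, lineno: int) -> float:
    if token in MISSING_TOKENS:
        return np.nan
    try:
        value = float(token)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-numeric beta value {token!r}") from exc
    if not 0.0 <= value <= 1.0:
        raise ParseError(f"{path}:{lineno}: beta value {value} outside [0, 1]")
    return value


def read_methylation(path: str | Path, format: str = "matrix-tsv") -> MethylationMatrix:
    """Read a methylation beta matrix.

    ``matrix-tsv``: columns cpg_id, chrom, pos (1-based), then one column per
    sample. ``bed-like``: columns chrom, start (0-based), end, cpg_id, then
    samples; position becomes start + 1.
    """
    if format not in ("matrix-tsv", "bed-like"):
        raise ValueError(f"unknown methylation format {format!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if format == "matrix-tsv":
            expected, n_meta = ["cpg_id", "chrom", "pos"], 3
        else:
            expected, n_meta = ["chrom", "start", "end", "cpg_id"], 4
        if header[:n_meta] != expected:
            raise ParseError(
                f"{path}:1: malformed header, expected leading columns {expected}"
            )
        sample_ids = header[n_meta:]
        if not sample_ids:
            raise ParseError(f"{path}:1: no sample columns")
        cpg_ids: list[str] = []
        chroms: list[str] = []
        positions: list[int] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_meta + len(sample_ids):
                raise ParseError(f"{path}:{lineno}: wrong number of fields")
            if format == "matrix-tsv":
                cpg, chrom, pos = parts[0], parts[1], int(parts[2])
            else:
                chrom, start, _end, cpg = parts[0], int(parts[1]), parts[2], parts[3]
                pos = start + 1
            if cpg in set(cpg_ids):
                raise ParseError(f"{path}:{lineno}: duplicate CpG id {cpg!r}")
            cpg_ids.append(cpg)
            chroms.append(chrom)
            positions.append(pos)
            rows.append(
                [_parse_beta_field(tok, str(path), lineno) for tok in parts[n_meta:]]
            )
    beta = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return MethylationMatrix(cpg_ids, np.array(chroms, dtype=object),
                             np.array(positions), beta, sample_ids)


def write_methylation(matrix: MethylationMatrix, path: str | Path) -> None:
    """Write ``matrix-tsv`` format readable by :func:`read_methylation`."""
    with open(path, "w") as fh:
        fh.write("\t".join(["cpg_id", "chrom", "pos", *matrix.sample_ids]) + "\n")
        for i, cpg in enumerate(matrix.cpg_ids):
            values = [
                "NA" if not np.isfinite(v) else format(v, ".10g")
                for v in matrix.beta[i]
            ]
            fh.write(
                "\t".join([cpg, str(matrix.chrom[i]), str(matrix.pos[i]), *values])
                + "\n"
            )


# ---------------------------------------------------------------------------
# genotype I/O

_GT_CODES = {
    (0, 0): 0.0,
    (0, 1): 1.0,
    (1, 0): 1.0,
    (1, 1): 2.0,
}


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    snp_ids, chroms, positions, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    seen = set()
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping multi-allelic record %s:%d", variant.CHROM, variant.POS
            )
            continue
        gts = variant.genotypes
        if gts is None:
            raise ParseError(f"{path}: record {variant.CHROM}:{variant.POS} lacks GT")
        ref, alt = variant.REF, variant.ALT[0]
        for allele in (ref, alt):
            if allele not in ("A", "C", "G", "T"):
                raise ParseError(
                    f"{path}: unknown allele code {allele!r} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
        row = []
        for gt in gts:
            a, b = gt[0], gt[1]  # third entry is phasing; phased == unphased here
            if a < 0 or b < 0:
                row.append(np.nan)
            else:
                try:
                    row.append(_GT_CODES[(a, b)])
                except KeyError as exc:
                    raise ParseError(
                        f"{path}: unexpected GT allele index ({a},{b})"
                    ) from exc
        snp_id = variant.ID or f"{normalize_chrom(variant.CHROM)}:{variant.POS}"
        if snp_id in seen:
            raise ParseError(f"{path}: duplicate SNP id {snp_id!r}")
        seen.add(snp_id)
        snp_ids.append(snp_id)
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        refs.append(ref)
        alts.append(alt)
        rows.append(row)
    if n_skipped:
        logger.info("skipped %d multi-allelic records", n_skipped)
    dosage = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return GenotypeMatrix(
        snp_ids,
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        dosage,
        sample_ids,
    )


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    expected = ["snp_id", "chrom", "pos", "ref", "alt"]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != expected:
            raise ParseError(f"{path}:1: malformed header, expected {expected}")
        sample_ids = header[5:]
        snp_ids, chroms, positions, refs, alts, rows = [], [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5 + len(sample_ids):
                raise ParseError(f"{path}:{lineno}: wrong number of fields")
            snp_ids.append(parts[0])
            chroms.append(parts[1])
            positions.append(int(parts[2]))
            refs.append(parts[3])
            alts.append(parts[4])
            row = []
            for tok in parts[5:]:
                if tok in MISSING_TOKENS:
                    row.append(np.nan)
                elif tok in ("0", "1", "2"):
                    row.append(float(tok))
                else:
                    raise ParseError(f"{path}:{lineno}: invalid dosage {tok!r}")
            rows.append(row)
    dosage = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return GenotypeMatrix(
        snp_ids,
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        dosage,
        sample_ids,
    )


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from VCF (GT field) or a dosage TSV.

    VCF GT codes map 0/0 -> 0, 0/1 and 1/0 -> 1, 1/1 -> 2, ./. -> missing;
    phased separators are treated identically. Multi-allelic records are
    skipped with a logged warning.
    """
    path = Path(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "dosage-tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the ``dosage-tsv`` format readable by :func:`read_genotypes`."""
    with open(path, "w") as fh:
        fh.write("\t".join(["snp_id", "chrom", "pos", "ref", "alt",
                            *matrix.sample_ids]) + "\n")
        for i, snp in enumerate(matrix.snp_ids):
            values = [
                "NA" if not np.isfinite(v) else str(int(v)) for v in matrix.dosage[i]
            ]
            fh.write(
                "\t".join(
                    [
                        snp,
                        str(matrix.chrom[i]),
                        str(matrix.pos[i]),
                        str(matrix.ref_allele[i]),
                        str(matrix.alt_allele[i]),
                        *values,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# covariates and methQTL tables


def read_covariates(
    path: str | Path, kinds: dict[str, str] | None = None
) -> CovariateTable:
    """Read a TSV with a ``sample_id`` column; other columns are covariates."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    df = df.set_index("sample_id")
    return CovariateTable(df, kinds or {})


def write_methqtl_table(records: Iterable, path: str | Path) -> None:
    """Write methQTL summary statistics as a TSV with a fixed column order."""
    rows = []
    for rec in records:
        if isinstance(rec, dict):
            rows.append({col: rec[col] for col in METHQTL_COLUMNS})
        else:
            rows.append({col: getattr(rec, col) for col in METHQTL_COLUMNS})
    df = pd.DataFrame(rows, columns=METHQTL_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_methqtl_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "snp_id": str, "chrom": str})
    missing = set(METHQTL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
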