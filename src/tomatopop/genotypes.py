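"""Core genotype containers and readers/writers.

Genotypes are diploid biallelic calls stored as reference-allele dosage
(0, 1, 2) in an ``int8`` accessions x markers array; missing calls use the
sentinel :data:`MISSING` (-1), never 0. Marker metadata (chromosome, genetic
map position in cM, allele pair) lives in a pandas DataFrame aligned with the
call columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

_NUCLEOTIDES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

MARKER_COLUMNS = ["id", "chromosome", "position_cm", "allele_a", "allele_b"]


class GenotypeError(ValueError):
    """Raised on malformed or inconsistent genotype data."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP marker on the genetic map.

    ``allele_a`` is the reference/design allele whose copies the dosage
    counts; ``position_cm`` is the genetic-map position in centimorgan.
    """

    id: str
    chromosome: str = ""
    position_cm: float = float("nan")
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise GenotypeError(f"marker {self.id}: alleles must be distinct")
        if not (np.isnan(self.position_cm) or self.position_cm >= 0):
            raise GenotypeError(f"marker {self.id}: position_cm must be >= 0")


def complement_alleles(pair: tuple[str, str]) -> tuple[str, str]:
    """Reverse-complement an allele pair (strand flip), e.g. (A, G) -> (T, C)."""
    return (_COMPLEMENT[pair[0]], _COMPLEMENT[pair[1]])


def is_strand_ambiguous(pair: tuple[str, str]) -> bool:
    """A/T and C/G pairs equal their own complement and cannot be oriented
    from allele labels alone."""
    return set(pair) in ({"A", "T"}, {"C", "G"})


@dataclass
class GenotypeMatrix:
    """Accessions x markers dosage matrix with aligned marker metadata.

    Attributes
    ----------
    calls : ndarray of int8, shape (n_accessions, n_markers)
        Reference-allele dosage in {0, 1, 2}; missing = :data:`MISSING`.
    accessions : list of str
        Unique accession identifiers, one per row.
    markers : DataFrame
        One row per column of ``calls`` with columns ``id``, ``chromosome``,
        ``position_cm``, ``allele_a``, ``allele_b``.
    """

    calls: np.ndarray
    accessions: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.accessions = list(self.accessions)
        self.markers = self.markers.reset_index(drop=True)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_acc, n_mark = self.calls.shape
        if len(self.accessions) != n_acc:
            raise GenotypeError("accession list does not match call rows")
        if len(self.markers) != n_mark:
            raise GenotypeError("marker table does not match call columns")
        if len(set(self.accessions)) != n_acc:
            raise GenotypeError("accession ids are not unique")
        ids = self.markers["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise GenotypeError(f"duplicate marker id {dup!r}")
        bad = (self.calls < MISSING) | (self.calls > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"dosage {self.calls[i, j]} outside {{0,1,2,NA}} at "
                f"accession {self.accessions[i]!r}, marker {ids.iloc[j]!r}"
            )

    # -- basic accessors ----------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["id"].tolist()

    def marker(self, marker_id: str) -> Marker:
        row = self.markers.loc[self.markers["id"] == marker_id]
        if row.empty:
            raise KeyError(marker_id)
        r = row.iloc[0]
        return Marker(r["id"], r["chromosome"], r["position_cm"],
                      r["allele_a"], r["allele_b"])

    def accession_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accessions)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as exc:
            raise GenotypeError(f"unknown accession {exc.args[0]!r}") from exc

    def subset(self, accession_ids: Sequence[str] | None = None,
               marker_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given accessions/markers."""
        calls = self.calls
        acc = self.accessions
        if accession_ids is not None:
            rows = self.accession_index(accession_ids)
            calls = calls[rows]
            acc = [self.accessions[i] for i in rows]
        markers = self.markers
        if marker_mask is not None:
            marker_mask = np.asarray(marker_mask, dtype=bool)
            calls = calls[:, marker_mask]
            markers = markers.loc[marker_mask]
        return GenotypeMatrix(calls.copy(), acc, markers.copy())

    def missing_fraction_per_marker(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def allele_frequencies(self) -> np.ndarray:
        """Reference-allele frequency per marker from non-missing calls
        (NaN where a marker has no data)."""
        obs = self.calls != MISSING
        dose = np.where(obs, self.calls, 0).astype(float)
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dose.sum(axis=0) / (2 * n), np.nan)


@dataclass
class PassportTable:
    """Per-accession passport data: class label, optional GPS and climate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if "accession_id" not in t.columns or "passport_class" not in t.columns:
            raise GenotypeError("passport table needs accession_id and passport_class")
        if t["accession_id"].duplicated().any():
            raise GenotypeError("duplicate accession_id in passport table")
        for col, lo, hi in (("latitude", -90, 90), ("longitude", -180, 180)):
            if col in t.columns:
                v = t[col].dropna()
                if ((v < lo) | (v > hi)).any():
                    raise GenotypeError(f"{col} outside [{lo}, {hi}]")
        self.table = t.reset_index(drop=True)

    @property
    def climate_columns(self) -> list[str]:
        reserved = {"accession_id", "passport_class", "latitude", "longitude"}
        return [c for c in self.table.columns if c not in reserved]


MIXTURE = "mixture"


@dataclass
class Classification:
    """Three-level genetic labels (species > group > subgroup) with a mixture flag.

    Mixture accessions carry no label below the level at which they were
    flagged; unresolved levels hold the empty string.
    """

    table: pd.DataFrame  # accession_id, species, group, subgroup, is_mixture

    LEVELS = ("species", "group", "subgroup")

    def __post_init__(self) -> None:
        required = {"accession_id", "species", "group", "subgroup", "is_mixture"}
        missing = required - set(self.table.columns)
        if missing:
            raise GenotypeError(f"classification lacks columns {sorted(missing)}")
        if self.table["accession_id"].duplicated().any():
            raise GenotypeError("duplicate accession_id in classification")
        mix = self.table["is_mixture"].astype(bool)
        if (self.table.loc[mix, "subgroup"] != "").any():
            raise GenotypeError("mixture accessions must not carry a subgroup label")
        self.table = self.table.reset_index(drop=True)

    def labels(self, level: str) -> pd.Series:
        if level not in self.LEVELS:
            raise ValueError(f"level must be one of {self.LEVELS}")
        return self.table.set_index("accession_id")[level]

    def groups_at(self, level: str, include_mixture: bool = False) -> dict[str, list[str]]:
        """Map label -> accession ids at a level, dropping unlabelled rows and,
        by default, mixture accessions and mixture-named classes."""
        t = self.table
        if not include_mixture:
            t = t[~t["is_mixture"].astype(bool)]
        out: dict[str, list[str]] = {}
        for label, sub in t.groupby(level):
            if label == "":
                continue
            if not include_mixture and MIXTURE in str(label).lower():
                continue
            out[str(label)] = sub["accession_id"].tolist()
        return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _default_marker_table(ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({
        "id": list(ids),
        "chromosome": "",
        "position_cm": np.nan,
        "allele_a": "A",
        "allele_b": "B",
    })


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the TSV genotype dialect: header of marker ids, first column the
    accession id, cells in {0, 1, 2, NA}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise GenotypeError(f"{path}: malformed header (need accession column + markers)")
    acc = df.iloc[:, 0].tolist()
    body = df.iloc[:, 1:]
    calls = np.full(body.shape, MISSING, dtype=np.int8)
    values = body.to_numpy(dtype=object)
    for (i, j), cell in np.ndenumerate(values):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "NA":
            continue
        try:
            d = int(cell)
        except (TypeError, ValueError):
            raise GenotypeError(
                f"{path}: non-dosage cell {cell!r} at accession {acc[i]!r}, "
                f"marker {body.columns[j]!r}") from None
        if d not in (0, 1, 2):
            raise GenotypeError(
                f"{path}: dosage {d} outside {{0,1,2}} at accession {acc[i]!r}, "
                f"marker {body.columns[j]!r}")
        calls[i, j] = d
    return GenotypeMatrix(calls, acc, _default_marker_table(body.columns))


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    body = pd.DataFrame(matrix.calls.astype(object), columns=matrix.marker_ids)
    body = body.mask(matrix.calls == MISSING, "NA")
    body.insert(0, "accession", matrix.accessions)
    body.to_csv(path, sep="\t", index=False)


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    """Read a genetic map TSV (marker id, chromosome, position_cm and,
    optionally, allele_a/allele_b)."""
    m = pd.read_csv(path, sep="\t", dtype={"id": str, "chromosome": str})
    required = {"id", "chromosome", "position_cm"}
    if not required <= set(m.columns):
        raise GenotypeError(f"{path}: genetic map needs columns {sorted(required)}")
    if (m["position_cm"].dropna() < 0).any():
        raise GenotypeError(f"{path}: negative cM position")
    return m


def attach_map(matrix: GenotypeMatrix, genetic_map: pd.DataFrame) -> GenotypeMatrix:
    """Return a copy of ``matrix`` with chromosome/position/allele columns
    filled in from a genetic-map table; unmapped markers keep NaN positions."""
    gmap = genetic_map.set_index("id")
    markers = matrix.markers.copy()
    for col in ("chromosome", "position_cm", "allele_a", "allele_b"):
        if col in gmap.columns:
            mapped = markers["id"].map(gmap[col])
            markers[col] = mapped.where(mapped.notna(), markers[col])
    return GenotypeMatrix(matrix.calls.copy(), matrix.accessions, markers)


@dataclass
class VcfReadReport:
    n_records: int = 0
    n_kept: int = 0
    skipped: list[str] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def read_genotype_vcf(path: str | Path) -> tuple[GenotypeMatrix, VcfReadReport]:
    """Read biallelic SNP records from a VCF (v4.x) into a dosage matrix.

    Dosage counts copies of the REF allele. Multiallelic records, indels and
    records without a GT field are skipped and listed in the report.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    acc = list(vcf.samples)
    report = VcfReadReport()
    columns: list[np.ndarray] = []
    rows = []
    for rec in vcf:
        report.n_records += 1
        rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1 or not rec.is_snp:
            report.skipped.append(rid)
            continue
        gts = rec.genotype.array()  # (n_samples, ploidy+1)
        alleles = gts[:, :2]
        miss = (alleles < 0).any(axis=1)
        # dosage of REF = 2 - (# alt alleles)
        dose = 2 - alleles.clip(min=0).sum(axis=1)
        dose = np.where(miss, MISSING, dose).astype(np.int8)
        columns.append(dose)
        rows.append({
            "id": rid, "chromosome": rec.CHROM, "position_cm": np.nan,
            "allele_a": rec.REF, "allele_b": rec.ALT[0],
        })
        report.n_kept += 1
    if not columns:
        raise GenotypeError(f"{path}: no biallelic SNP records")
    calls = np.stack(columns, axis=1)
    return GenotypeMatrix(calls, acc, pd.DataFrame(rows)), report


def read_genotype_matrix(path: str | Path, format: str = "tsv"):
    """Dispatching reader; ``format`` is ``"tsv"`` or ``"vcf"``.

    TSV returns a :class:`GenotypeMatrix`; VCF returns
    ``(GenotypeMatrix, VcfReadReport)``.
    """
    if format == "tsv":
        return read_genotype_tsv(path)
    if format == "vcf":
        return read_genotype_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def read_passport_tsv(path: str | Path) -> PassportTable:
    return PassportTable(pd.read_csv(path, sep="\t", dtype={"accession_id": str}))


def read_classification_tsv(path: str | Path) -> Classification:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df["is_mixture"] = df["is_mixture"].map(
        {"True": True, "False": False, "1": True, "0": False})
    return Classification(df)


def write_classification_tsv(classes: Classification, path: str | Path) -> None:
    classes.table.to_csv(path, sep="\t", index=False)
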