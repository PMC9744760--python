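"""Data model and I/O for GWAS summary statistics and LD matrices.

A summary-statistics table holds one row per variant: identifier, position,
allele pair, effect-allele frequency (EAF), additive effect estimate with its
standard error, association p-value and sample size.  For a continuous trait
the effect is in outcome-SD units; for a binary trait it is a log odds ratio
and the table also carries the case fraction of the contributing study.

Files are plain delimited text (TSV by default) with a header row.  Column
names are mapped through a user-supplied schema; the default follows the
common ``SNP/CHR/BP/EA/OA/EAF/BETA/SE/P/N`` convention.  Validation is strict
by default: rows violating an invariant raise :class:`~summr.errors.ValidationError`
with row-indexed diagnostics rather than being silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: canonical internal column order
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

#: default file-column names for each canonical field
DEFAULT_SCHEMA = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "BP",
    "effect_allele": "EA", "other_allele": "OA",
    "eaf": "EAF", "beta": "BETA", "se": "SE", "pvalue": "P", "n": "N",
}

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_NUMERIC_FIELDS = ["pos", "eaf", "beta", "se", "pvalue", "n"]


@dataclass
class SummaryStatsTable:
    """A validated table of per-variant summary associations for one trait.

    Parameters
    ----------
    trait_name:
        Human-readable trait label.
    trait_type:
        ``"continuous"`` or ``"binary"``.
    variants:
        DataFrame with the :data:`CANONICAL_COLUMNS`.
    case_fraction:
        Proportion of cases among the outcome sample; required iff binary.
    rejected:
        Rows dropped during reading when ``drop_invalid=True`` (diagnostics
        with columns ``row``, ``snp_id``, ``reason``); empty otherwise.
    """

    trait_name: str
    trait_type: str
    variants: pd.DataFrame
    case_fraction: float | None = None
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "snp_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        if (self.case_fraction is not None) != (self.trait_type == "binary"):
            raise ValueError("case_fraction must be present exactly when trait_type is binary")
        if self.case_fraction is not None and not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        dup = self.variants["snp_id"][self.variants["snp_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                [(-1, s, "duplicate_snp_id") for s in dup.unique()],
                f"duplicate snp_id: {', '.join(map(str, dup.unique()[:10]))}",
            )
        self.variants = self.variants[CANONICAL_COLUMNS].reset_index(drop=True)

    # -- convenience ------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.variants)

    def subset(self, snp_ids) -> "SummaryStatsTable":
        """Return a new table restricted to ``snp_ids`` (input order kept)."""
        wanted = set(snp_ids)
        mask = self.variants["snp_id"].isin(wanted)
        return replace(self, variants=self.variants[mask].reset_index(drop=True),
                       rejected=self.rejected)


def _validate_rows(df: pd.DataFrame) -> list[tuple[int, str, str]]:
    """Collect invariant violations as (1-based row, snp_id, reason)."""
    problems: list[tuple[int, str, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        snp = str(row.snp_id)
        ea, oa = str(row.effect_allele), str(row.other_allele)
        if any(pd.isna(getattr(row, f)) for f in _NUMERIC_FIELDS):
            bad = [f for f in _NUMERIC_FIELDS if pd.isna(getattr(row, f))]
            problems.append((i, snp, f"unparseable_or_missing:{','.join(bad)}"))
            continue
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            problems.append((i, snp, "non_snp_alleles"))
            continue
        if ea == oa:
            problems.append((i, snp, "identical_alleles"))
            continue
        if not 0.0 <= row.eaf <= 1.0:
            problems.append((i, snp, "eaf_out_of_range"))
        if not row.se > 0:
            problems.append((i, snp, "nonpositive_se"))
        if not 0.0 < row.pvalue <= 1.0:
            problems.append((i, snp, "pvalue_out_of_range"))
        if not (row.n > 0 and float(row.n) == int(row.n)):
            problems.append((i, snp, "invalid_n"))
        if not (row.pos > 0 and float(row.pos) == int(row.pos)):
            problems.append((i, snp, "invalid_pos"))
    return problems


def read_sumstats(
    path,
    schema: dict | None = None,
    *,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    case_fraction: float | None = None,
    delimiter: str | None = None,
    drop_invalid: bool = False,
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    ``schema`` maps canonical field names to the file's column names; omitted
    fields fall back to :data:`DEFAULT_SCHEMA`.  The delimiter is auto-detected
    (tab or comma) unless given.  With ``drop_invalid=False`` (default) any
    invariant violation raises :class:`ValidationError`; with ``True`` the
    offending rows are dropped and reported in ``table.rejected``.
    """
    path = Path(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(DEFAULT_SCHEMA)
        if unknown:
            raise SchemaError(f"unknown schema field(s): {sorted(unknown)}")
        colmap.update(schema)

    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    missing = [colmap[f] for f in CANONICAL_COLUMNS if colmap[f] not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = pd.DataFrame({f: raw[colmap[f]] for f in CANONICAL_COLUMNS})
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    for f in _NUMERIC_FIELDS:
        df[f] = pd.to_numeric(df[f], errors="coerce")

    problems = _validate_rows(df)
    if problems and not drop_invalid:
        raise ValidationError(problems)
    rejected = pd.DataFrame(problems, columns=["row", "snp_id", "reason"])
    if problems:
        bad = {r - 1 for r, _, _ in problems}
        df = df.drop(index=sorted(bad)).reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)

    return SummaryStatsTable(
        trait_name=trait_name or path.stem,
        trait_type=trait_type,
        case_fraction=case_fraction,
        variants=df,
        rejected=rejected,
    )


def write_sumstats(table: SummaryStatsTable, path) -> None:
    """Write a table as TSV in canonical column order at full float precision.

    Floats are serialized with Python's shortest round-trip representation, so
    ``write_sumstats`` followed by :func:`read_sumstats` reproduces every field
    exactly.
    """
    out = table.variants[CANONICAL_COLUMNS].rename(columns=DEFAULT_SCHEMA)
    out.to_csv(path, sep="\t", index=False)


@dataclass
class LDMatrix:
    """A symmetric matrix of squared allelic correlations (r²) between variants."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValidationError([], f"LD matrix shape {self.r2.shape} does not match "
                                      f"{n} labels")
        if len(set(self.snp_ids)) != n:
            raise ValidationError([], "duplicate snp_id in LD matrix labels")
        bad = np.argwhere((self.r2 < 0) | (self.r2 > 1))
        if len(bad):
            i, j = bad[0]
            raise ValidationError([], f"r² out of [0,1] at ({self.snp_ids[i]}, "
                                      f"{self.snp_ids[j]}): {self.r2[i, j]}")
        asym = np.abs(self.r2 - self.r2.T).max(initial=0.0)
        if asym > 1e-8:
            raise ValidationError([], f"LD matrix asymmetric (max |M-Mᵀ| = {asym:g})")
        self.r2 = (self.r2 + self.r2.T) / 2.0
        if np.abs(np.diag(self.r2) - 1.0).max(initial=0.0) > 1e-8:
            raise ValidationError([], "LD matrix diagonal must be 1")
        np.fill_diagonal(self.r2, 1.0)
        self._index = {s: k for k, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        """r² between two variants."""
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def subset(self, snp_ids) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r2[np.ix_(idx, idx)])


def read_ld(path) -> LDMatrix:
    """Read a labeled square TSV (header + row labels) into an :class:`LDMatrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValidationError([], "LD matrix row labels do not match column labels")
    return LDMatrix(list(df.columns.astype(str)), df.to_numpy(dtype=float))


def write_ld(ld: LDMatrix, path) -> None:
    """Write an LD matrix as a labeled square TSV."""
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")
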