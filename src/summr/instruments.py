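"""Instrument selection, harmonization, strength metrics and power analysis.

The forward workflow is: keep genome-wide-significant variants (p < 5e-8,
strict), prune them to approximate linkage equilibrium by greedy clumping
(r² < 0.001 within 10,000 kb by default), align exposure and outcome tables to
a common effect allele (harmonization), then screen instrument strength with
the per-variant F-statistic (F < 10 flags a weak instrument).

Harmonization conventions
-------------------------
Alleles may be recorded on either strand and in either order between two GWAS.
For each exposure instrument found in the outcome table we resolve the outcome
record to the exposure's allele orientation: a swapped effect/other pair
negates the outcome effect and reflects its EAF; a strand complement relabels
alleles via A<->T, C<->G.  Palindromic variants (A/T or C/G) cannot be
resolved from allele labels alone: those with intermediate exposure EAF
(within ``palindrome_eaf_window`` of 0.5, default 0.08) are excluded, the rest
are oriented by matching which side of 0.5 the two EAFs fall on.  Finally each
record is re-oriented so the exposure effect is positive (exposure-increasing
allele convention), giving all downstream ratio estimates a consistent sign.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, LDMismatchError
from .sumstats import COMPLEMENT, LDMatrix, SummaryStatsTable

HARMONIZED_COLUMNS = [
    "snp_id", "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "sign_flipped", "strand_complemented",
]

#: exclusion reasons emitted by :func:`harmonize`
EXCLUSION_REASONS = ("palindromic_intermediate_eaf", "allele_mismatch", "missing_in_outcome")


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a common effect allele.

    ``records`` has one row per retained instrument (columns
    :data:`HARMONIZED_COLUMNS`); ``excluded`` lists dropped instruments with
    their reason.  Every exposure instrument appears exactly once across the
    two frames.
    """

    records: pd.DataFrame
    excluded: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    outcome_type: str = "continuous"
    case_fraction: float | None = None

    @property
    def nsnp(self) -> int:
        return len(self.records)

    @property
    def outcome_binary(self) -> bool:
        return self.outcome_type == "binary"

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.records)

    # array accessors used throughout the estimators
    @property
    def snp_ids(self) -> np.ndarray:
        return self.records["snp_id"].to_numpy()

    @property
    def beta_exp(self) -> np.ndarray:
        return self.records["beta_exp"].to_numpy(dtype=float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.records["se_exp"].to_numpy(dtype=float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.records["beta_out"].to_numpy(dtype=float)

    @property
    def se_out(self) -> np.ndarray:
        return self.records["se_out"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out,
                    snp_ids=None, eaf_exp=None, eaf_out=None, **meta) -> "HarmonizedSet":
        """Build a set directly from effect arrays (testing / simulation)."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        j = len(beta_exp)
        rec = pd.DataFrame({
            "snp_id": snp_ids if snp_ids is not None else [f"snp{i + 1}" for i in range(j)],
            "beta_exp": beta_exp,
            "se_exp": np.asarray(se_exp, dtype=float),
            "beta_out": np.asarray(beta_out, dtype=float),
            "se_out": np.asarray(se_out, dtype=float),
            "eaf_exp": np.full(j, np.nan) if eaf_exp is None else np.asarray(eaf_exp, float),
            "eaf_out": np.full(j, np.nan) if eaf_out is None else np.asarray(eaf_out, float),
            "sign_flipped": False,
            "strand_complemented": False,
        })
        excl = pd.DataFrame(columns=["snp_id", "reason"])
        return cls(records=rec, excluded=excl, **meta)

    def drop(self, snp_ids) -> "HarmonizedSet":
        """Return a copy without the given instruments (excluded unchanged)."""
        wanted = set(snp_ids)
        rec = self.records[~self.records["snp_id"].isin(wanted)].reset_index(drop=True)
        return HarmonizedSet(rec, self.excluded, self.exposure_name, self.outcome_name,
                             self.outcome_type, self.case_fraction)

    def exclusion_report(self) -> pd.DataFrame:
        """TSV-ready (snp_id, reason) frame for the dropped instruments."""
        return self.excluded.copy()


def select_significant(table: SummaryStatsTable, p_threshold: float = 5e-8) -> SummaryStatsTable:
    """Keep variants with association p strictly below ``p_threshold``."""
    mask = table.variants["pvalue"] < p_threshold
    return table.subset(table.variants.loc[mask, "snp_id"])


def clump(
    table: SummaryStatsTable,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> SummaryStatsTable:
    """Greedy LD clumping: retain index variants, discard their LD partners.

    Variants are visited by ascending p (ties broken by snp_id).  Each visit
    takes the most significant unassigned variant as an index and discards all
    unassigned variants on the same chromosome within ``window_kb`` of it whose
    r² with it is >= ``r2_threshold``.  Without an LD matrix this degrades to
    distance-only pruning (every same-chromosome variant inside the window is
    discarded), which is announced with a warning.
    """
    df = table.variants
    if ld is not None:
        missing = [s for s in df["snp_id"] if s not in ld]
        if missing:
            raise LDMismatchError(missing)
    else:
        warnings.warn(
            "clumping without an LD matrix: falling back to distance-only pruning",
            stacklevel=2,
        )

    order = df.sort_values(["pvalue", "snp_id"], kind="mergesort").index.to_numpy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    ids = df["snp_id"].to_numpy()
    window_bp = int(window_kb) * 1000

    assigned = np.zeros(len(df), dtype=bool)
    kept: list[str] = []
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        kept.append(ids[i])
        near = (~assigned) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        for j in np.flatnonzero(near):
            if ld is None or ld.lookup(ids[i], ids[j]) >= r2_threshold:
                assigned[j] = True
    return table.subset(kept)


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome records to the exposure's allele orientation.

    Returns a :class:`HarmonizedSet`; exclusions (palindromic with
    intermediate EAF, unresolvable allele pairs, missing in outcome) are data,
    not failures.
    """
    exp = exposure.variants
    out = outcome.variants.set_index("snp_id")

    records: list[dict] = []
    excluded: list[tuple[str, str]] = []
    lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window

    for row in exp.itertuples(index=False):
        snp = row.snp_id
        if snp not in out.index:
            excluded.append((snp, "missing_in_outcome"))
            continue
        o = out.loc[snp]
        ea, oa = row.effect_allele, row.other_allele
        cea, coa = COMPLEMENT.get(ea), COMPLEMENT.get(oa)
        oea, ooa = o["effect_allele"], o["other_allele"]
        beta_out, eaf_out = float(o["beta"]), float(o["eaf"])
        flipped = complemented = False

        palindromic = cea == oa  # A/T or C/G pair
        if palindromic:
            if lo <= row.eaf <= hi:
                excluded.append((snp, "palindromic_intermediate_eaf"))
                continue
            if {oea, ooa} != {ea, oa}:
                excluded.append((snp, "allele_mismatch"))
                continue
            if oea == oa:  # nominally swapped
                beta_out, eaf_out, flipped = -beta_out, 1.0 - eaf_out, True
            # strand ambiguity resolved by matching frequency sides
            if (row.eaf < 0.5) != (eaf_out < 0.5):
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                complemented = True
        else:
            if (oea, ooa) == (ea, oa):
                pass
            elif (oea, ooa) == (oa, ea):
                beta_out, eaf_out, flipped = -beta_out, 1.0 - eaf_out, True
            elif (oea, ooa) == (cea, coa):
                complemented = True
            elif (oea, ooa) == (coa, cea):
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                flipped = complemented = True
            else:
                excluded.append((snp, "allele_mismatch"))
                continue

        beta_exp, eaf_exp = float(row.beta), float(row.eaf)
        if beta_exp < 0:  # orient to the exposure-increasing allele
            beta_exp, beta_out = -beta_exp, -beta_out
            eaf_exp, eaf_out = 1.0 - eaf_exp, 1.0 - eaf_out
        records.append({
            "snp_id": snp,
            "beta_exp": beta_exp, "se_exp": float(row.se),
            "beta_out": beta_out, "se_out": float(o["se"]),
            "eaf_exp": eaf_exp, "eaf_out": eaf_out,
            "sign_flipped": flipped, "strand_complemented": complemented,
        })

    rec_df = pd.DataFrame(records, columns=HARMONIZED_COLUMNS)
    excl_df = pd.DataFrame(excluded, columns=["snp_id", "reason"])
    return HarmonizedSet(
        records=rec_df,
        excluded=excl_df,
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
        case_fraction=outcome.case_fraction,
    )


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------

def variant_r2(beta: float, eaf: float, se: float, n: int) -> float:
    """Variance of the exposure explained by one variant.

    Computed as ``2·b²·p(1-p) / [2·b²·p(1-p) + 2·se²·N·p(1-p)]`` with
    ``p = eaf``; algebraically identical to ``b² / (b² + se²·N)``.
    """
    if not 0.0 < eaf < 1.0:
        raise DomainError(f"eaf must be in (0,1), got {eaf}")
    if not se > 0:
        raise DomainError("se must be positive")
    if n < 3:
        raise DomainError("n must be at least 3")
    pq = eaf * (1.0 - eaf)
    num = 2.0 * beta * beta * pq
    return num / (num + 2.0 * se * se * n * pq)


def f_statistic(r2: float, n: int) -> float:
    """Single-instrument F-statistic, ``F = r²·(N-2)/(1-r²)``."""
    if not 0.0 <= r2 < 1.0:
        raise DomainError(f"r2 must be in [0,1), got {r2}")
    if n < 3:
        raise DomainError("n must be at least 3")
    return r2 * (n - 2) / (1.0 - r2)


WEAK_F_THRESHOLD = 10.0


def instrument_strength(table: SummaryStatsTable) -> tuple[pd.DataFrame, float]:
    """Per-variant r², F and weak flag (F < 10), plus the summed r²."""
    rows = []
    for row in table.variants.itertuples(index=False):
        r2 = variant_r2(row.beta, row.eaf, row.se, int(row.n))
        f = f_statistic(r2, int(row.n))
        rows.append({"snp_id": row.snp_id, "r2": r2, "f": f,
                     "weak": f < WEAK_F_THRESHOLD})
    df = pd.DataFrame(rows, columns=["snp_id", "r2", "f", "weak"])
    return df, float(df["r2"].sum()) if len(df) else 0.0


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Inputs for the binary-outcome MR power approximation.

    ``odds_ratio`` is the causal OR per SD of exposure, ``case_fraction`` the
    outcome case proportion K, ``r2`` the exposure variance explained by the
    instruments, ``alpha`` the two-sided significance level and
    ``target_power`` the desired power; ``n`` (total outcome sample size) is
    needed only for :func:`power_at_n`.
    """

    odds_ratio: float
    case_fraction: float
    r2: float
    alpha: float = 0.05
    target_power: float = 0.80
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.odds_ratio > 0:
            raise DomainError("odds_ratio must be positive")
        for name in ("case_fraction", "r2", "alpha", "target_power"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DomainError(f"{name} must lie in (0,1), got {v}")


def required_sample_size(spec: PowerSpec) -> int:
    """Smallest outcome sample size achieving ``target_power``.

    ``N = ceil[(z_{1-a/2} + z_{power})² / (b²·r²·K·(1-K))]`` with
    ``b = ln(odds_ratio)``.
    """
    b = math.log(spec.odds_ratio)
    if b == 0.0:
        raise DomainError("odds_ratio = 1 implies no effect: required N is infinite")
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0) + stats.norm.ppf(spec.target_power)
    k = spec.case_fraction
    n = z * z / (b * b * spec.r2 * k * (1.0 - k))
    # relative guard so float roundoff cannot bump an exact-integer boundary
    return math.ceil(n * (1.0 - 1e-12))


def power_at_n(spec: PowerSpec) -> float:
    """Power of the two-sided test at sample size ``spec.n`` (same model)."""
    if spec.n is None or spec.n <= 0:
        raise DomainError("spec.n must be a positive sample size")
    b = math.log(spec.odds_ratio)
    k = spec.case_fraction
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(math.sqrt(spec.n * spec.r2 * k * (1.0 - k)) * abs(b) - z_a))
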