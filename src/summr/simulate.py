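"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the summary-level structure a two-sample MR analysis
consumes: an exposure GWAS of a continuous trait (variance standardized to 1)
and an outcome GWAS on the log-odds scale for a binary disease (or SD scale
for a continuous outcome), estimated in two independent samples.

Data-generating model for instrument j with effect-allele frequency p_j drawn
uniformly from ``eaf_range`` (c_j = p_j(1-p_j)):

* true exposure effects gamma_j are standard-normal draws rescaled so the
  summed explained variance  sum_j 2 c_j gamma_j²  equals ``total_r2``;
* the true outcome effect is theta_j = b·gamma_j + sign(gamma_j)·alpha_j with
  b = ``causal_beta``; the direct (pleiotropic) effect alpha_j is zero for
  valid instruments and N(mu, sigma) for the invalid fraction.  Direct effects
  are defined relative to the exposure-increasing allele (allele coding is
  arbitrary, so "directional" pleiotropy is only meaningful in that frame);
* sampling noise uses the standard summary-statistic approximations
  se_exp = 1/sqrt(2 N_exp c) and, for a binary outcome with case fraction K,
  se_out = 1/sqrt(2 N_out K(1-K) c); exposure and outcome draws come from
  independent streams (the two-sample assumption);
* optional extras: outlier instruments with grossly inflated direct effects,
  LD blocks (block-diagonal r² matrix), and variants associated with the
  outcome only (gamma = 0) so the reverse direction has instruments to select.

Per-SNP randomness is keyed by ``(seed, snp index)``, so enlarging the panel
never reshuffles earlier variants.  Defaults mirror a large educational-
attainment-to-endometrial-cancer style design: 306 instruments, exposure
N = 1,131,881, outcome N = 121,885 with case fraction 12906/121885, causal
OR 0.72 per SD, and instruments jointly explaining 1% of exposure variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .sumstats import CANONICAL_COLUMNS, COMPLEMENT, LDMatrix, SummaryStatsTable

#: ordered, non-palindromic allele pairs assigned to simulated variants
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]

_GLOBAL_STREAM_KEY = 982451653  # stream for cross-SNP choices (invalid/outlier sets)


@dataclass
class PleiotropySpec:
    """Horizontal-pleiotropy configuration for the invalid instruments.

    ``fraction_invalid`` of instruments receive a direct effect
    alpha ~ N(mu, sigma) on the outcome.  With ``inside_violated`` the draws
    gain a component correlated (coefficient ``inside_rho``) with instrument
    strength |gamma|, breaking the InSIDE assumption.
    """

    fraction_invalid: float = 0.0
    mu: float = 0.0
    sigma: float = 0.0
    inside_violated: bool = False
    inside_rho: float = 0.5


@dataclass
class OutlierSpec:
    """``count`` instruments get direct effects inflated by ``multiplier``.

    An outlier that is not already pleiotropic receives
    alpha = multiplier x se_out (its direct effect sized in units of its own
    outcome-association SE); one that is has its drawn alpha multiplied.
    """

    count: int = 0
    multiplier: float = 1.0


@dataclass
class SimulationModel:
    """Ground-truth parameters of the synthetic two-sample design."""

    n_snps: int = 306
    n_exp: int = 1_131_881
    n_out: int = 121_885
    case_fraction: float | None = 12906 / 121885
    causal_beta: float = math.log(0.72)
    total_r2: float = 0.01
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    outliers: OutlierSpec = field(default_factory=OutlierSpec)
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    n_outcome_specific: int = 0
    outcome_specific_beta: tuple[float, float] = (0.15, 0.02)
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    se_exp_const: float | None = None  # override per-SNP SEs (noiseless-limit tests)
    se_out_const: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if not 0.0 < self.total_r2 < 1.0:
            raise ConfigError(f"total_r2 must lie in (0,1), got {self.total_r2}")
        if not 0.0 <= self.pleiotropy.fraction_invalid <= 1.0:
            raise ConfigError("fraction_invalid must lie in [0,1]")
        if self.case_fraction is not None and not 0.0 < self.case_fraction < 1.0:
            raise ConfigError("case_fraction must lie in (0,1)")
        lo, hi = self.eaf_range
        if not 0.0 < lo < hi < 1.0:
            raise ConfigError("eaf_range must satisfy 0 < low < high < 1")
        if sum(size for size, _ in self.ld_blocks) > self.n_snps:
            raise ConfigError("ld_blocks cover more variants than n_snps")


@dataclass
class SimulationTruth:
    """Realized ground truth: per-SNP effects and the generating parameters."""

    per_snp: pd.DataFrame  # snp_id, eaf, gamma, alpha, invalid, outlier, outcome_specific
    realized_r2: float
    causal_beta: float
    model: SimulationModel


def _per_snp_draws(seed: int, j: int):
    """All randomness for SNP ``j``: keyed stream (seed, j)."""
    g = np.random.default_rng([seed, j])
    u = g.random()
    z = g.standard_normal(5)  # gamma, alpha, alpha2, exposure noise, outcome noise
    pair = int(g.integers(0, len(_ALLELE_PAIRS)))
    return u, z, pair


def _positions(model: SimulationModel, n_total: int):
    """Chromosome/position layout: LD-block members share a locus, everything
    else is spaced far beyond the clumping window."""
    chrom = np.empty(n_total, dtype=object)
    pos = np.empty(n_total, dtype=np.int64)
    slot = 0
    i = 0
    for size, _ in model.ld_blocks:
        c, base = str(slot % 22 + 1), 10_000_000 + (slot // 22) * 25_000_000
        for k in range(size):
            chrom[i], pos[i] = c, base + k * 10_000
            i += 1
        slot += 1
    while i < n_total:
        chrom[i] = str(slot % 22 + 1)
        pos[i] = 10_000_000 + (slot // 22) * 25_000_000
        slot += 1
        i += 1
    return chrom, pos


def _ld_matrix(model: SimulationModel, ids) -> LDMatrix:
    n = len(ids)
    r2 = np.eye(n)
    i = 0
    for size, block_r2 in model.ld_blocks:
        r2[i:i + size, i:i + size] = block_r2
        i += size
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(list(ids), r2)


def simulate_two_sample(
    model: SimulationModel, seed: int | None = None,
) -> tuple[SummaryStatsTable, SummaryStatsTable, LDMatrix, SimulationTruth]:
    """Generate one realization of the two-sample design.

    Returns ``(exposure, outcome, ld, truth)``.  ``seed`` overrides
    ``model.seed`` (convenient in replicate loops); identical model and seed
    give bitwise-identical output.
    """
    seed = model.seed if seed is None else seed
    j_exp, j_all = model.n_snps, model.n_snps + model.n_outcome_specific
    binary = model.case_fraction is not None

    eaf = np.empty(j_all)
    z = np.empty((j_all, 5))
    pairs = np.empty(j_all, dtype=int)
    lo, hi = model.eaf_range
    for j in range(j_all):
        u, zj, pair = _per_snp_draws(seed, j)
        eaf[j] = lo + (hi - lo) * u
        z[j] = zj
        pairs[j] = pair
    c = eaf * (1.0 - eaf)

    # exposure effects rescaled to hit total_r2 exactly
    gamma = np.zeros(j_all)
    raw = z[:j_exp, 0]
    denom = float((2.0 * c[:j_exp] * raw ** 2).sum())
    if denom == 0.0:
        raise ConfigError("degenerate draw: all raw exposure effects are zero")
    gamma[:j_exp] = raw * math.sqrt(model.total_r2 / denom)

    # standard errors
    se_exp = np.full(j_all, model.se_exp_const) if model.se_exp_const is not None \
        else 1.0 / np.sqrt(2.0 * model.n_exp * c)
    if model.se_out_const is not None:
        se_out = np.full(j_all, model.se_out_const)
    elif binary:
        k = model.case_fraction
        se_out = 1.0 / np.sqrt(2.0 * model.n_out * k * (1.0 - k) * c)
    else:
        se_out = 1.0 / np.sqrt(2.0 * model.n_out * c)

    # pleiotropic direct effects (exposure-increasing-allele frame)
    g0 = np.random.default_rng([seed, _GLOBAL_STREAM_KEY])
    alpha = np.zeros(j_all)
    invalid = np.zeros(j_all, dtype=bool)
    pl = model.pleiotropy
    n_invalid = round(pl.fraction_invalid * j_exp)
    if n_invalid:
        chosen = g0.choice(j_exp, size=n_invalid, replace=False)
        invalid[chosen] = True
        z_a = z[chosen, 1]
        if pl.inside_violated:
            t = (np.abs(z[chosen, 0]) - math.sqrt(2.0 / math.pi)) / math.sqrt(1.0 - 2.0 / math.pi)
            rho = pl.inside_rho
            z_a = rho * t + math.sqrt(1.0 - rho * rho) * z_a
        alpha[chosen] = pl.mu + pl.sigma * z_a

    outlier = np.zeros(j_all, dtype=bool)
    if model.outliers.count:
        chosen = g0.choice(j_exp, size=model.outliers.count, replace=False)
        outlier[chosen] = True
        for i in chosen:
            alpha[i] = alpha[i] * model.outliers.multiplier if invalid[i] \
                else model.outliers.multiplier * se_out[i]

    # outcome-only associations (instruments for the reverse direction)
    spec_mask = np.zeros(j_all, dtype=bool)
    if model.n_outcome_specific:
        spec_mask[j_exp:] = True
        mu_s, sd_s = model.outcome_specific_beta
        sign = np.where(z[j_exp:, 2] >= 0, 1.0, -1.0)
        alpha[j_exp:] = sign * (mu_s + sd_s * z[j_exp:, 1])

    sign_gamma = np.where(gamma >= 0, 1.0, -1.0)
    theta = model.causal_beta * gamma + sign_gamma * alpha

    beta_exp = gamma + se_exp * z[:, 3]
    beta_out = theta + se_out * z[:, 4]
    p_exp = np.maximum(2.0 * stats.norm.sf(np.abs(beta_exp / se_exp)), 1e-300)
    p_out = np.maximum(2.0 * stats.norm.sf(np.abs(beta_out / se_out)), 1e-300)

    ids = [f"rs{j + 1:06d}" for j in range(j_all)]
    chrom, pos = _positions(model, j_all)
    ea = [_ALLELE_PAIRS[p][0] for p in pairs]
    oa = [_ALLELE_PAIRS[p][1] for p in pairs]

    def _table(beta, se, pval, n, name, trait_type, case_fraction):
        df = pd.DataFrame({
            "snp_id": ids, "chrom": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa, "eaf": eaf,
            "beta": beta, "se": se, "pvalue": pval,
            "n": np.full(j_all, n, dtype=np.int64),
        }, columns=CANONICAL_COLUMNS)
        return SummaryStatsTable(name, trait_type, df, case_fraction)

    exposure = _table(beta_exp, se_exp, p_exp, model.n_exp,
                      model.exposure_name, "continuous", None)
    outcome = _table(beta_out, se_out, p_out, model.n_out, model.outcome_name,
                     "binary" if binary else "continuous",
                     model.case_fraction if binary else None)
    ld = _ld_matrix(model, ids)
    truth = SimulationTruth(
        per_snp=pd.DataFrame({
            "snp_id": ids, "eaf": eaf, "gamma": gamma, "alpha": alpha,
            "se_exp": se_exp, "se_out": se_out,
            "invalid": invalid, "outlier": outlier, "outcome_specific": spec_mask,
        }),
        realized_r2=float((2.0 * c[:j_exp] * gamma[:j_exp] ** 2).sum()),
        causal_beta=model.causal_beta,
        model=model,
    )
    return exposure, outcome, ld, truth


def inject_harmonization_noise(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    swap_fraction: float = 0.0,
    complement_fraction: float = 0.0,
    palindrome_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[SummaryStatsTable, SummaryStatsTable, pd.DataFrame]:
    """Corrupt allele bookkeeping the way real GWAS files disagree.

    Disjoint random subsets of the shared variants are: *swapped* (outcome
    effect/other alleles exchanged, beta negated, EAF reflected),
    *strand-complemented* (outcome allele labels complemented), or rewritten
    as *palindromic* A/T pairs with EAF 0.5 in both tables (which makes them
    unresolvable by design).  Returns new tables plus a ledger
    ``(snp_id, action)`` for round-trip verification.
    """
    for name, frac in (("swap", swap_fraction), ("complement", complement_fraction),
                       ("palindrome", palindrome_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ConfigError(f"{name}_fraction must lie in [0,1]")
    if swap_fraction + complement_fraction + palindrome_fraction > 1.0 + 1e-12:
        raise ConfigError("corruption fractions must sum to at most 1")

    exp_df = exposure.variants.copy()
    out_df = outcome.variants.copy()
    common = [s for s in exp_df["snp_id"] if s in set(out_df["snp_id"])]
    n = len(common)
    g = np.random.default_rng(seed)
    perm = g.permutation(n)
    n_swap = round(swap_fraction * n)
    n_comp = round(complement_fraction * n)
    n_pal = round(palindrome_fraction * n)

    chosen = [common[i] for i in perm[: n_swap + n_comp + n_pal]]
    actions = (["swap"] * n_swap + ["complement"] * n_comp + ["palindrome"] * n_pal)
    ledger = pd.DataFrame({"snp_id": chosen, "action": actions})

    out_idx = out_df.set_index("snp_id").index
    exp_idx = exp_df.set_index("snp_id").index
    for snp, action in zip(chosen, actions):
        o = out_df.index[out_idx.get_loc(snp)]
        e = exp_df.index[exp_idx.get_loc(snp)]
        if action == "swap":
            ea, oa = out_df.at[o, "effect_allele"], out_df.at[o, "other_allele"]
            out_df.at[o, "effect_allele"], out_df.at[o, "other_allele"] = oa, ea
            out_df.at[o, "beta"] = -out_df.at[o, "beta"]
            out_df.at[o, "eaf"] = 1.0 - out_df.at[o, "eaf"]
        elif action == "complement":
            out_df.at[o, "effect_allele"] = COMPLEMENT[out_df.at[o, "effect_allele"]]
            out_df.at[o, "other_allele"] = COMPLEMENT[out_df.at[o, "other_allele"]]
        else:  # palindrome with intermediate frequency: unresolvable by design
            for df, i in ((exp_df, e), (out_df, o)):
                df.at[i, "effect_allele"], df.at[i, "other_allele"] = "A", "T"
                df.at[i, "eaf"] = 0.5

    exposure2 = replace(exposure, variants=exp_df)
    outcome2 = replace(outcome, variants=out_df)
    return exposure2, outcome2, ledger
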