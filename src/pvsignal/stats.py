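"""Disproportionality statistics for 2x2 pharmacovigilance tables.

Given the per-drug table

              event   no event
    drug        a        b
    no drug     c        d          N = a + b + c + d

four measures of disproportionate reporting are computed:

ROR (reporting odds ratio)
    ROR = (a/c)/(b/d) = ad/bc, with the log-normal Woolf interval
    exp(ln ROR ± 1.96·SE), SE² = 1/a + 1/b + 1/c + 1/d.

PRR (proportional reporting ratio)
    PRR = [a/(a+b)] / [c/(c+d)], SE² = 1/a − 1/(a+b) + 1/c − 1/(c+d),
    accompanied by the Yates-corrected chi-square of the table.

BCPNN information component
    IC = log2 of the observed-over-expected reporting ratio with Bayesian
    shrinkage.  With beta-binomial priors on the margins (hyperparameters
    γ11, α1, β1 for the joint and marginal cells, α, β for the marginal
    totals) the posterior expectation and variance have the closed forms

        γ     = γ11 (N+α)(N+β) / [(a+b+α1)(a+c+β1)]
        E[IC] = log2 [ (a+γ11)(N+α)(N+β) / ((N+γ)(a+b+α1)(a+c+β1)) ]
        V[IC] = (1/ln2)² [ (N−a+γ−γ11)/((a+γ11)(1+N+γ))
                         + (N−(a+b)+α−α1)/((a+b+α1)(1+N+α))
                         + (N−(a+c)+β−β1)/((a+c+β1)(1+N+β)) ]

    and the signal bound is IC025 = E[IC] − 2·sqrt(V[IC]).  The default
    prior (γ11 = α1 = β1 = 1, α = β = 2) makes E[IC] = 0 exactly for a
    perfectly balanced table.

EBGM (empirical Bayes geometric mean)
    Implemented in its relative-reporting-ratio closed form
    EBGM = aN/((a+b)(a+c)) with the log-normal interval
    exp(ln EBGM ± 1.96·SE), SE² = 1/a + 1/b + 1/c + 1/d.  This is the form
    conventionally tabulated alongside the other three statistics; the full
    MGPS gamma-mixture fit is deliberately out of scope.

Signal rules (all requiring at least ``min_cases`` co-reports):
ROR lower CI > 1; PRR lower CI > 1 (or the alternative PRR > 2 with
χ² > 4); IC025 > 0; EBGM05 > 2.  A drug is a consensus signal when all
four criteria hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._util import UndefinedResultError, round_half_up

Z95 = 1.96
LN2 = math.log(2.0)

SIGNAL_COLUMNS = [
    "drug", "a", "ror", "ror_lo", "ror_hi", "prr", "prr_lo", "prr_hi",
    "chisq", "ic", "ic025", "ebgm", "ebgm05", "ebgm95",
    "ror_pos", "prr_pos", "bcpnn_pos", "ebgm_pos", "consensus",
]


@dataclass(frozen=True)
class BcpnnPrior:
    """Hyperparameters of the BCPNN beta-binomial priors."""

    gamma11: float = 1.0
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0


@dataclass(frozen=True)
class Thresholds:
    """Signal-detection criteria applied to the computed statistics."""

    min_cases: int = 3
    ror_ci_gt: float = 1.0
    prr_rule: str = "ci_gt_1"  # or "prr2_chi4"
    prr_ci_gt: float = 1.0
    prr_gt: float = 2.0
    chisq_gt: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0

    def __post_init__(self) -> None:
        if self.prr_rule not in ("ci_gt_1", "prr2_chi4"):
            raise ValueError(f"unknown prr_rule {self.prr_rule!r}")
        for name in ("ror_ci_gt", "prr_ci_gt", "prr_gt", "chisq_gt",
                     "ic025_gt", "ebgm05_gt"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")


class Flags(NamedTuple):
    ror_pos: bool
    prr_pos: bool
    bcpnn_pos: bool
    ebgm_pos: bool
    consensus: bool


@dataclass
class SignalResult:
    """All four statistics with interval bounds and per-method flags."""

    drug: str
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chisq: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ebgm95: float
    flags: Flags | None = field(default=None)

    @property
    def consensus(self) -> bool:
        return bool(self.flags and self.flags.consensus)


class BcpnnResult(NamedTuple):
    ic_raw: float
    e_ic: float
    v_ic: float
    ic025: float


def _check_cells(a: float, b: float, c: float, d: float, correction: bool
                 ) -> tuple[float, float, float, float]:
    cells = {"a": a, "b": b, "c": c, "d": d}
    for name, v in cells.items():
        if v < 0:
            raise ValueError(f"cell {name} is negative ({v})")
    if correction:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    for name, v in cells.items():
        if v == 0:
            raise UndefinedResultError(
                f"cell {name} is zero; the statistic is undefined without a "
                f"continuity correction (pass correction=True for "
                f"Haldane-Anscombe +0.5)"
            )
    return a, b, c, d


def ror(a: float, b: float, c: float, d: float, *, correction: bool = False
        ) -> tuple[float, float, float]:
    """Reporting odds ratio with its 95% log-normal interval."""
    a, b, c, d = _check_cells(a, b, c, d, correction)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se)


def prr_chisq(a: float, b: float, c: float, d: float, *, correction: bool = False
              ) -> tuple[float, float, float, float]:
    """Proportional reporting ratio, its 95% interval, and Yates chi-square.

    The chi-square always refers to the uncorrected observed table
    (continuity correction for zero cells applies to the ratio only).
    """
    chi = yates_chisq(a, b, c, d)
    a, b, c, d = _check_cells(a, b, c, d, correction)
    est = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), chi


def yates_chisq(a: float, b: float, c: float, d: float) -> float:
    """Continuity-corrected chi-square of a 2x2 table, floored at zero."""
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0 or n == 0:
        return 0.0
    diff = abs(a * d - b * c) - n / 2
    if diff <= 0:
        return 0.0
    return n * diff * diff / margins


def bcpnn(a: float, b: float, c: float, d: float,
          prior: BcpnnPrior = BcpnnPrior()) -> BcpnnResult:
    """BCPNN information component: raw IC, posterior E and V, and IC025."""
    n = a + b + c + d
    if n <= 0:
        raise UndefinedResultError("empty table: N must be positive")
    if a + b == 0 or a + c == 0:
        raise UndefinedResultError(
            "a zero drug or event margin leaves the information component "
            "undefined"
        )
    ic_raw = (
        math.log2(a * n / ((a + b) * (a + c))) if a > 0 else -math.inf
    )
    g11, a1, b1 = prior.gamma11, prior.alpha1, prior.beta1
    al, be = prior.alpha, prior.beta
    gamma = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be)
        / ((n + gamma) * (a + b + a1) * (a + c + b1))
    )
    v_ic = (1 / LN2**2) * (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
        + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be))
    )
    return BcpnnResult(ic_raw, e_ic, v_ic, e_ic - 2 * math.sqrt(v_ic))


def ebgm(a: float, b: float, c: float, d: float, *, correction: bool = False
         ) -> tuple[float, float, float]:
    """Relative-reporting-ratio EBGM with its 95% log-normal interval."""
    a, b, c, d = _check_cells(a, b, c, d, correction)
    n = a + b + c + d
    est = a * n / ((a + b) * (a + c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se)


def compute_signal(drug: str, a: int, b: int, c: int, d: int, *,
                   prior: BcpnnPrior = BcpnnPrior(),
                   correction: bool = False) -> SignalResult:
    """All four statistics for one table (flags not yet applied)."""
    ror_e, ror_lo, ror_hi = ror(a, b, c, d, correction=correction)
    prr_e, prr_lo, prr_hi, chi = prr_chisq(a, b, c, d, correction=correction)
    bc = bcpnn(a, b, c, d, prior)
    eb, eb05, eb95 = ebgm(a, b, c, d, correction=correction)
    return SignalResult(
        drug=drug, a=int(a),
        ror=ror_e, ror_lo=ror_lo, ror_hi=ror_hi,
        prr=prr_e, prr_lo=prr_lo, prr_hi=prr_hi, chisq=chi,
        ic=bc.e_ic, ic025=bc.ic025,
        ebgm=eb, ebgm05=eb05, ebgm95=eb95,
    )


def classify(result: SignalResult, thresholds: Thresholds = Thresholds()
             ) -> Flags:
    """Apply the per-method signal criteria and the consensus rule.

    All inequalities are strict; IC025 exactly 0 or EBGM05 exactly 2 is
    not a signal.
    """
    enough = result.a >= thresholds.min_cases
    ror_pos = enough and result.ror_lo > thresholds.ror_ci_gt
    if thresholds.prr_rule == "ci_gt_1":
        prr_pos = enough and result.prr_lo > thresholds.prr_ci_gt
    else:
        prr_pos = (enough and result.prr > thresholds.prr_gt
                   and result.chisq > thresholds.chisq_gt)
    bcpnn_pos = result.ic025 > thresholds.ic025_gt
    ebgm_pos = result.ebgm05 > thresholds.ebgm05_gt
    return Flags(ror_pos, prr_pos, bcpnn_pos, ebgm_pos,
                 ror_pos and prr_pos and bcpnn_pos and ebgm_pos)


def compute_signals(tables: pd.DataFrame,
                    thresholds: Thresholds = Thresholds(),
                    prior: BcpnnPrior = BcpnnPrior(),
                    correction: bool = False) -> pd.DataFrame:
    """Statistics plus flags for every row of a contingency table frame."""
    rows = []
    for rec in tables.itertuples(index=False):
        res = compute_signal(rec.drug, rec.a, rec.b, rec.c, rec.d,
                             prior=prior, correction=correction)
        res.flags = classify(res, thresholds)
        rows.append({
            "drug": res.drug, "a": res.a,
            "ror": res.ror, "ror_lo": res.ror_lo, "ror_hi": res.ror_hi,
            "prr": res.prr, "prr_lo": res.prr_lo, "prr_hi": res.prr_hi,
            "chisq": res.chisq, "ic": res.ic, "ic025": res.ic025,
            "ebgm": res.ebgm, "ebgm05": res.ebgm05, "ebgm95": res.ebgm95,
            "ror_pos": res.flags.ror_pos, "prr_pos": res.flags.prr_pos,
            "bcpnn_pos": res.flags.bcpnn_pos, "ebgm_pos": res.flags.ebgm_pos,
            "consensus": res.flags.consensus,
        })
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS)


def rank_signals(signals: pd.DataFrame, by: str = "ror", top_n: int | None = None
                 ) -> pd.DataFrame:
    """Sort signals for reporting.

    ``by="ror"`` sorts by ROR descending (ties: larger a first, then drug
    label); ``by="cases"`` sorts by case count descending.
    """
    if by == "ror":
        keys, ascending = ["ror", "a", "drug"], [False, False, True]
    elif by == "cases":
        keys, ascending = ["a", "ror", "drug"], [False, False, True]
    else:
        raise ValueError(f"unknown ranking key {by!r}")
    out = signals.sort_values(keys, ascending=ascending, kind="mergesort",
                              ignore_index=True)
    return out.head(top_n) if top_n is not None else out


def format_signals(signals: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Report-facing copy with statistics rounded half-up."""
    out = signals.copy()
    stat_cols = ["ror", "ror_lo", "ror_hi", "prr", "prr_lo", "prr_hi",
                 "chisq", "ic", "ic025", "ebgm", "ebgm05", "ebgm95"]
    for col in stat_cols:
        if col in out.columns:
            out[col] = out[col].map(lambda v: round_half_up(v, ndigits))
    return out


def write_signals(signals: pd.DataFrame, path) -> None:
    signals.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_reference_signals() -> pd.DataFrame:
    """Published top-50 reference statistics bundled with the package."""
    from importlib import resources

    ref = resources.files("pvsignal.data") / "dialh_top50_reference.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def classify_reference(reference: pd.DataFrame,
                       thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Apply the four signal criteria to pre-computed (published) statistics.

    Only the fields each rule needs are consulted, so tables without the
    unpublished b/c/d cells can still be classified.
    """
    enough = reference["a"] >= thresholds.min_cases
    ror_pos = enough & (reference["ror_lo"] > thresholds.ror_ci_gt)
    if thresholds.prr_rule == "ci_gt_1":
        prr_pos = enough & (reference["prr_lo"] > thresholds.prr_ci_gt)
    else:
        prr_pos = (enough & (reference["prr"] > thresholds.prr_gt)
                   & (reference["chisq"] > thresholds.chisq_gt))
    bcpnn_pos = reference["ic025"] > thresholds.ic025_gt
    ebgm_pos = reference["ebgm05"] > thresholds.ebgm05_gt
    out = reference.copy()
    out["ror_pos"] = ror_pos
    out["prr_pos"] = prr_pos
    out["bcpnn_pos"] = bcpnn_pos
    out["ebgm_pos"] = ebgm_pos
    out["consensus"] = ror_pos & prr_pos & bcpnn_pos & ebgm_pos
    return out


def signals_array(tables: pd.DataFrame) -> pd.DataFrame:
    """Vectorized ROR/interval for many tables (no flags, no Bayesian stats).

    Used where only the frequentist screen is needed on thousands of
    simulated tables; semantics match :func:`ror` exactly.
    """
    a = tables["a"].to_numpy(float)
    b = tables["b"].to_numpy(float)
    c = tables["c"].to_numpy(float)
    d = tables["d"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = est * np.exp(-Z95 * se)
        hi = est * np.exp(Z95 * se)
    return pd.DataFrame({"drug": tables["drug"], "a": tables["a"],
                         "ror": est, "ror_lo": lo, "ror_hi": hi})
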