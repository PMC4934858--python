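"""Association between metabolic flux changes and transcriptional changes.

The pipeline compares two culture conditions (e.g. anaerobic vs aerobic):

1. gene-level differential-expression calls are filtered on fold change,
   abundance and FDR (:func:`de_filter`);
2. gene fold changes are mapped to reaction level through the GPR — the
   subunit with the smallest fold change caps a complex, and isoenzyme
   fold changes are averaged (:func:`aggregate_fold_change`,
   :func:`reaction_fold_change`);
3. fluxes of reactions sharing an enzyme-set signature are lumped as the
   sum of absolute fluxes (:func:`lump_fluxes`), removing spurious
   variability among cofactor variants of the same enzyme;
4. a lumped flux is called differential when the condition difference
   exceeds a threshold and its FVA intervals do not overlap
   (:func:`differential_flux`);
5. flux differences and fold changes are associated by Spearman rank
   correlation with a linear-regression summary (:func:`correlate`).
"""

from __future__ import annotations

import ast
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fba_core import FVAInterval

#: Differential-expression thresholds used for the correlation analysis.
DE_PROFILE_CORRELATION = {"min_fc": 1.25, "min_logcpm": 2.0, "max_fdr": 0.05}
#: Stricter general-purpose profile (fold change 2, no abundance filter).
DE_PROFILE_STRICT = {"min_fc": 2.0, "min_logcpm": None, "max_fdr": 0.05}

#: Minimal lumped-flux difference (mmol h^-1 gDCW^-1) to call differential.
DEFAULT_MIN_FLUX_DIFF = 0.25


@dataclass
class CorrelationReport:
    """Spearman + OLS summary of paired (flux difference, logFC) points."""

    n: int
    rho: float
    p_value: float
    slope: float
    intercept: float
    #: pointwise 95% confidence band of the regression mean, per input point
    band_lower: np.ndarray
    band_upper: np.ndarray
    p_method: str = "asymptotic"
    constant_input: bool = False

    def to_dict(self) -> dict:
        return {"n": self.n, "rho": self.rho, "p": self.p_value,
                "slope": self.slope, "intercept": self.intercept,
                "p_method": self.p_method}


# ---------------------------------------------------------------------------
# Fold-change aggregation over GPR structure


def aggregate_fold_change(isoenzyme_logfcs: Sequence[Sequence[float]],
                          mode: str = "min_abs") -> float:
    """Reaction-level logFC from per-subunit logFCs of its isoenzymes.

    Within each isoenzyme (an AND-group of subunits) the subunit with the
    least fold change is taken — by default the value of minimal |logFC|
    with its sign preserved, so a barely-changing subunit caps the apparent
    change of the whole complex (``mode="min_signed"`` instead takes the
    smallest signed value).  Across isoenzymes (OR-groups catalyzing the
    same reaction) the arithmetic mean is returned.
    """
    if not isoenzyme_logfcs or any(len(iso) == 0 for iso in isoenzyme_logfcs):
        raise ValueError("need at least one isoenzyme, each with >= 1 subunit")
    if mode == "min_abs":
        per_iso = [min(iso, key=lambda x: (abs(x), x)) for iso in isoenzyme_logfcs]
    elif mode == "min_signed":
        per_iso = [min(iso) for iso in isoenzyme_logfcs]
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return float(np.mean(per_iso))


def _gpr_isoenzymes(node) -> list[frozenset[str]]:
    """Flatten a GPR AST to a list of gene sets, one per isoenzyme (DNF)."""
    if isinstance(node, ast.Name):
        return [frozenset([node.id])]
    if isinstance(node, ast.BoolOp):
        parts = [_gpr_isoenzymes(v) for v in node.values]
        if isinstance(node.op, ast.Or):
            return [iso for part in parts for iso in part]
        # And: cartesian product of the operands' isoenzyme lists
        out = []
        for combo in itertools.product(*parts):
            out.append(frozenset().union(*combo))
        return out
    raise ValueError(f"unsupported GPR node {type(node).__name__}")


def reaction_fold_change(gpr_rule: str, gene_logfc: Mapping[str, float],
                         mode: str = "min_abs") -> float:
    """Apply :func:`aggregate_fold_change` to a GPR rule string.

    Genes missing from ``gene_logfc`` drop their isoenzyme; if no isoenzyme
    has complete data a ``KeyError`` is raised.
    """
    import cobra

    gpr = cobra.core.gene.GPR.from_string(gpr_rule)
    if gpr.body is None:
        raise ValueError("empty GPR has no associated genes")
    isoenzymes = _gpr_isoenzymes(gpr.body)
    groups = []
    for iso in isoenzymes:
        if all(g in gene_logfc for g in iso):
            groups.append([gene_logfc[g] for g in sorted(iso)])
    if not groups:
        raise KeyError(f"no isoenzyme of '{gpr_rule}' fully covered by the DE table")
    return aggregate_fold_change(groups, mode=mode)


# ---------------------------------------------------------------------------
# Differential expression filter


def de_filter(table: pd.DataFrame, min_fc: float = 1.25,
              min_logcpm: float | None = 2.0,
              max_fdr: float = 0.05) -> pd.DataFrame:
    """Filter a differential-expression table (gene, logFC, logCPM, FDR).

    Keeps genes with |fold change| >= ``min_fc`` (i.e. |logFC| >=
    log2(min_fc)), mean logCPM >= ``min_logcpm`` (skipped when ``None``),
    and FDR <= ``max_fdr``.  All conditions are conjunctive.
    """
    if min_fc <= 0 or max_fdr < 0:
        raise ValueError("thresholds must be positive")
    mask = (table["logFC"].abs() >= math.log2(min_fc)) & (table["FDR"] <= max_fdr)
    if min_logcpm is not None:
        mask &= table["logCPM"] >= min_logcpm
    return table[mask]


# ---------------------------------------------------------------------------
# Flux lumping and differential-flux calls


def lump_fluxes(fluxes: Mapping[str, float] | pd.Series,
                signatures: Mapping[str, frozenset[str]],
                ) -> dict[frozenset[str], float]:
    """Sum of absolute fluxes per enzyme-set signature.

    ``signatures`` maps reaction id -> gene-set signature (reactions with
    empty signatures must already be excluded).  Reactions absent from
    ``fluxes`` count as zero flux.
    """
    sums: dict[frozenset[str], float] = {}
    for rid, sig in signatures.items():
        if not sig:
            continue
        v = float(fluxes.get(rid, 0.0))
        sums[sig] = sums.get(sig, 0.0) + abs(v)
    return sums


def differential_flux(sum_a: float, sum_b: float,
                      fva_a: FVAInterval | tuple[float, float],
                      fva_b: FVAInterval | tuple[float, float],
                      min_diff: float = DEFAULT_MIN_FLUX_DIFF,
                      criteria: str = "both") -> bool:
    """Differential-flux call for one lumped reaction group.

    Two criteria: (1) |sum_a - sum_b| >= ``min_diff``; (2) the two FVA
    intervals are disjoint (closed intervals — touching endpoints count as
    overlapping).  ``criteria="both"`` requires the conjunction (default,
    stricter); ``"either"`` accepts one.
    """
    def _bounds(x):
        if isinstance(x, FVAInterval):
            return x.minimum, x.maximum
        lo, hi = x
        return float(lo), float(hi)

    a_lo, a_hi = _bounds(fva_a)
    b_lo, b_hi = _bounds(fva_b)
    big_enough = abs(sum_a - sum_b) >= min_diff
    disjoint = a_hi < b_lo or b_hi < a_lo
    if criteria == "both":
        return big_enough and disjoint
    if criteria == "either":
        return big_enough or disjoint
    raise ValueError(f"criteria must be 'both' or 'either', got {criteria!r}")


# ---------------------------------------------------------------------------
# Correlation


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float,
                      chunk: int = 200_000) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    Enumerates all n! assignments of y-ranks to x-ranks; feasible up to
    n = 10 (chunked).  Ranks handle ties by midranking.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    if denom == 0:
        return float("nan")
    count = 0
    total = 0
    perms = itertools.permutations(range(n))
    target = abs(rho_obs) - 1e-12
    while True:
        block = list(itertools.islice(perms, chunk))
        if not block:
            break
        perm_ranks = ry_c[np.array(block)]
        rhos = perm_ranks @ rx_c / denom
        count += int(np.sum(np.abs(rhos) >= target))
        total += len(block)
    return count / total


def correlate(points: Iterable[tuple[float, float]],
              exact_max_n: int = 10) -> CorrelationReport:
    """Spearman correlation and OLS summary of (flux difference, logFC) pairs.

    The p-value is an exact permutation value for n <= ``exact_max_n`` and
    the usual t-approximation otherwise.  The regression line comes with a
    pointwise 95% confidence band evaluated at the input x values.  A
    constant input vector makes rho undefined; the report flags it.
    """
    import statsmodels.api as sm

    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    n = len(x)

    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationReport(n=n, rho=float("nan"), p_value=float("nan"),
                                 slope=float("nan"), intercept=float("nan"),
                                 band_lower=np.full(n, np.nan),
                                 band_upper=np.full(n, np.nan),
                                 constant_input=True)

    rho, p_asym = stats.spearmanr(x, y)
    rho = float(rho)
    if n <= exact_max_n:
        p = _spearman_exact_p(x, y, rho)
        method = "exact-permutation"
    else:
        p = float(p_asym)
        method = "asymptotic"

    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    pred = ols.get_prediction(X).summary_frame(alpha=0.05)
    return CorrelationReport(
        n=n, rho=rho, p_value=float(p),
        slope=float(ols.params[1]), intercept=float(ols.params[0]),
        band_lower=pred["mean_ci_lower"].to_numpy(),
        band_upper=pred["mean_ci_upper"].to_numpy(),
        p_method=method,
    )


def scatter_plot(points, report: CorrelationReport, path: str) -> None:
    """Basic scatter of the paired points with the regression line and band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = np.asarray(list(points), dtype=float)
    order = np.argsort(pts[:, 0])
    x, y = pts[order, 0], pts[order, 1]
    fig, axis = plt.subplots(figsize=(5, 4))
    axis.scatter(pts[:, 0], pts[:, 1], color="tab:blue")
    if not report.constant_input:
        axis.plot(x, report.intercept + report.slope * x, color="black")
        axis.fill_between(x, report.band_lower[order], report.band_upper[order],
                          color="red", alpha=0.2)
        axis.set_title(f"Spearman rho={report.rho:.2f}, p={report.p_value:.3g}")
    axis.set_xlabel("flux difference (mmol h$^{-1}$ gDCW$^{-1}$)")
    axis.set_ylabel("logFC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
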