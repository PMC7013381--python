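"""Measurement statistics for competition and infection assays.

Implements the assay arithmetic used throughout the package:

* competitor fractions from paired quantities (colony counts or qPCR
  quantities), ``f1 = q1 / (q1 + q2)``;
* relative fitness of a focal competitor between two timepoints in the
  odds-ratio form ``[f_x (1 - f_0)] / [f_0 (1 - f_x)]``;
* efficiency of centres of infection,
  ``ECOI = centres / (pre-adsorbed cells * MOI)``, and the ratio of ECOI
  on a CRISPR-resistant host to ECOI on a CRISPR-knockout host as a
  direct estimate of the lysis probability ``phi``;
* one-sample t tests (one- or two-tailed, optionally on the log scale)
  with Student-t 95% confidence intervals, and the Bonferroni-corrected
  significance threshold ``alpha / n_comparisons``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

TAILS = ("two-sided", "greater", "less")


class StatsError(ValueError):
    """Invalid statistical inputs."""


def fraction(q1: float, q2: float) -> float:
    """Fraction of competitor 1 among paired quantities."""
    q1, q2 = float(q1), float(q2)
    if q1 < 0 or q2 < 0:
        raise StatsError(f"quantities must be >= 0, got ({q1}, {q2})")
    total = q1 + q2
    if total == 0:
        raise StatsError("undefined fraction: both quantities are zero")
    return q1 / total


class RelativeFitness(float):
    """A relative-fitness value.

    Behaves as a float; carries a ``boundary`` attribute naming the
    detection-limit boundary (if any) that forced a 0 or infinite
    sentinel, so boundary cases are never silent numeric infinities.
    """

    boundary: str | None

    def __new__(cls, value: float, boundary: str | None = None):
        obj = super().__new__(cls, value)
        obj.boundary = boundary
        return obj

    @property
    def is_boundary(self) -> bool:
        return self.boundary is not None


def relative_fitness(fraction_t0: float, fraction_tx: float) -> RelativeFitness:
    """Relative fitness of the focal competitor: the change in its odds
    between the start and end of the competition.

    Interior fractions give a positive real; a fraction of exactly 0 or 1
    (one competitor below the detection limit) yields a flagged 0 or
    infinite sentinel naming the boundary.
    """
    f0, fx = float(fraction_t0), float(fraction_tx)
    for name, f in (("fraction_t0", f0), ("fraction_tx", fx)):
        if not 0.0 <= f <= 1.0:
            raise StatsError(f"{name} must lie in [0, 1], got {f}")
    boundaries = []
    if f0 == 0.0:
        boundaries.append("focal absent at t0")
    if f0 == 1.0:
        boundaries.append("reference absent at t0")
    if fx == 0.0:
        boundaries.append("focal absent at tx")
    if fx == 1.0:
        boundaries.append("reference absent at tx")
    if boundaries:
        detail = "; ".join(boundaries)
        # Direction: focal vanishing -> 0, reference vanishing -> inf.
        # Contradictory boundaries (e.g. focal absent at both ends) keep
        # the tx boundary's direction.
        if fx == 0.0 or (f0 == 1.0 and fx != 1.0):
            value = 0.0
        else:
            value = math.inf
        logger.warning("boundary fraction in relative fitness: %s", detail)
        return RelativeFitness(value, boundary=detail)
    odds0 = f0 / (1.0 - f0)
    oddsx = fx / (1.0 - fx)
    return RelativeFitness(oddsx / odds0)


@dataclass(frozen=True)
class ECOIObservation:
    """One efficiency-of-centres-of-infection measurement."""

    centres: float          # plaques on the indicator lawn
    cells: float            # pre-adsorbed cell count
    moi: float              # multiplicity of infection used
    host: str = ""          # e.g. "bim1" or "crispr_ko"

    def __post_init__(self):
        if self.centres < 0 or self.cells < 0:
            raise StatsError("counts must be >= 0")
        if self.moi <= 0:
            raise StatsError(f"MOI must be > 0, got {self.moi}")

    def ecoi(self) -> float:
        return ecoi(self.centres, self.cells, self.moi)


def ecoi(centres: float, cells: float, moi: float) -> float:
    """Efficiency of centres of infection: the fraction of pre-adsorbed
    cells that yield a productive infection."""
    centres, cells, moi = float(centres), float(cells), float(moi)
    if centres < 0:
        raise StatsError(f"centres must be >= 0, got {centres}")
    if cells <= 0:
        raise StatsError(f"pre-adsorbed cell count must be > 0, got {cells}")
    if moi <= 0:
        raise StatsError(f"MOI must be > 0, got {moi}")
    value = centres / (cells * moi)
    if value > 1.0:
        logger.warning("ECOI %.4g exceeds 1 (noisy counts); not clamped",
                       value)
    return value


def phi_estimate(ecoi_resistant: float, ecoi_knockout: float) -> float:
    """Estimate the lysis probability phi as the ratio of ECOI on a
    CRISPR-resistant host to ECOI on a CRISPR-knockout host."""
    ecoi_resistant, ecoi_knockout = float(ecoi_resistant), float(ecoi_knockout)
    if ecoi_resistant < 0:
        raise StatsError("resistant-host ECOI must be >= 0")
    if ecoi_knockout <= 0:
        raise StatsError("knockout-host ECOI must be > 0 to normalise")
    value = ecoi_resistant / ecoi_knockout
    if value > 1.0:
        logger.warning("phi estimate %.4g exceeds 1: inconsistent with the "
                       "infection model", value)
    return value


@dataclass(frozen=True)
class TestResult:
    """One-sample t-test outcome with a 95% confidence interval.

    ``estimate`` and ``ci`` are reported on the original scale (back-
    transformed when the test ran on the log scale); ``t``, ``df`` and
    ``p`` are on the analysis scale.
    """

    estimate: float
    ci: tuple
    t: float
    df: int
    p: float
    n: int
    tail: str
    null_value: float
    log_scale: bool
    zero_variance: bool = False

    def significant(self, threshold: float = 0.05) -> bool:
        return self.p < threshold


def one_sample_test(values, null_value: float, tail: str = "two-sided",
                    log_scale: bool = False,
                    ci_level: float = 0.95) -> TestResult:
    """Test whether per-replicate estimates differ from a theoretical
    value (e.g. relative fitness vs 1).

    ``tail`` must name the direction explicitly: ``two-sided``,
    ``greater`` (mean exceeds the null) or ``less``.  With
    ``log_scale=True`` the test is run on log-transformed values against
    log(null), the appropriate analysis scale for ratio-type measurements;
    the estimate and CI are back-transformed for reporting.
    """
    if tail not in TAILS:
        raise StatsError(f"tail must be one of {TAILS}, got {tail!r}")
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise StatsError(f"need at least 2 replicates, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise StatsError("values must be finite")
    null = float(null_value)
    if log_scale:
        if np.any(x <= 0) or null <= 0:
            raise StatsError("log-scale test needs strictly positive values "
                             "and null")
        y, y_null = np.log(x), math.log(null)
    else:
        y, y_null = x, null

    n = int(x.size)
    df = n - 1
    mean = float(np.mean(y))
    sd = float(np.std(y, ddof=1))

    if sd == 0.0:
        # All replicates identical: degenerate fast path, flagged.
        logger.warning("zero variance across replicates; exact-equality path")
        if mean == y_null:
            t_stat, p = 0.0, 1.0 if tail == "two-sided" else 0.5
        else:
            t_stat = math.inf if mean > y_null else -math.inf
            if tail == "two-sided":
                p = 0.0
            elif tail == "greater":
                p = 0.0 if mean > y_null else 1.0
            else:
                p = 0.0 if mean < y_null else 1.0
        ci_lo = ci_hi = mean
        zero_var = True
    else:
        res = sps.ttest_1samp(y, y_null, alternative=tail)
        t_stat, p = float(res.statistic), float(res.pvalue)
        half = sps.t.ppf(0.5 + ci_level / 2.0, df) * sd / math.sqrt(n)
        ci_lo, ci_hi = mean - half, mean + half
        zero_var = False

    if log_scale:
        estimate = math.exp(mean)
        ci = (math.exp(ci_lo), math.exp(ci_hi))
    else:
        estimate = mean
        ci = (ci_lo, ci_hi)
    return TestResult(estimate=estimate, ci=ci, t=t_stat, df=df, p=p, n=n,
                      tail=tail, null_value=null, log_scale=log_scale,
                      zero_variance=zero_var)


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Bonferroni-corrected significance threshold alpha / n."""
    alpha = float(alpha)
    if not 0.0 < alpha < 1.0:
        raise StatsError(f"alpha must lie in (0, 1), got {alpha}")
    if int(n_comparisons) != n_comparisons or n_comparisons < 1:
        raise StatsError(f"n_comparisons must be an integer >= 1, "
                         f"got {n_comparisons}")
    return alpha / int(n_comparisons)


def normality_check(values, log_scale: bool = False) -> float:
    """Advisory Shapiro-Wilk check; logs (never branches on) the result.

    Returns the Shapiro-Wilk p-value.
    """
    x = np.asarray(list(values), dtype=float)
    if log_scale:
        x = np.log(x)
    p = float(sps.shapiro(x).pvalue)
    if p < 0.05:
        logger.warning("Shapiro-Wilk p = %.3g: data look non-Gaussian on "
                       "the analysis scale", p)
    return p


def competition_fitness(table: pd.DataFrame, focal: str,
                        t0: float = 0.0, tx: float = 3.0,
                        per_replicate: bool = True) -> pd.Series:
    """Per-replicate relative fitness of ``focal`` from a long-form
    competition table with columns replicate, timepoint, competitor,
    quantity.

    With ``per_replicate=False`` quantities are first averaged across
    replicates at each timepoint (as when fractions are formed from mean
    qPCR quantities) and a single fitness value is returned, indexed
    ``"pooled"``.

    Boundary fitness values (a competitor below detection at either
    timepoint) are returned flagged; callers running t tests should
    exclude them (see :func:`one_sample_test`).
    """
    required = {"replicate", "timepoint", "competitor", "quantity"}
    missing = required - set(table.columns)
    if missing:
        raise StatsError(f"competition table missing columns: {sorted(missing)}")
    competitors = table["competitor"].unique()
    if focal not in competitors:
        raise StatsError(f"focal competitor {focal!r} not in table "
                         f"({sorted(competitors)})")
    others = [c for c in competitors if c != focal]
    if len(others) != 1:
        raise StatsError(f"expected exactly 2 competitors, got {sorted(competitors)}")
    ref = others[0]

    wide = (table.pivot_table(index=["replicate", "timepoint"],
                              columns="competitor", values="quantity",
                              aggfunc="sum")
            .reset_index())

    def _fit_from(q: pd.DataFrame) -> RelativeFitness:
        row0 = q[q["timepoint"] == t0]
        rowx = q[q["timepoint"] == tx]
        if row0.empty or rowx.empty:
            raise StatsError(f"missing timepoint {t0} or {tx}")
        f0 = fraction(float(row0[focal].iloc[0]), float(row0[ref].iloc[0]))
        fx = fraction(float(rowx[focal].iloc[0]), float(rowx[ref].iloc[0]))
        return relative_fitness(f0, fx)

    if per_replicate:
        out = {}
        for rep, grp in wide.groupby("replicate"):
            out[rep] = _fit_from(grp)
        return pd.Series(out, name="relative_fitness")
    pooled = wide.groupby("timepoint")[[focal, ref]].mean().reset_index()
    return pd.Series({"pooled": _fit_from(pooled)}, name="relative_fitness")
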