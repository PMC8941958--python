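"""Joint analysis of the gene-order clock and the point-mutation clock.

This module joins an SI distance matrix and a JC (16S) distance matrix into a
pair table and provides the four analyses run on it:

- the within-clique regression whose reciprocal slope is the ratio of
  gene-order signal to point-mutation signal (the "PMTH ratio", ≈ 7);
- the global exponential phase-transition fit  E(P_PM) = A * exp(B * SI);
- the elasticity profile  E = (dSI/SI) / (dP_PM/P_PM)  over binned data;
- the two crossing points that locate the phase transition: where the fitted
  curve's derivative equals 1 and where the elasticity crosses 1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cliques import CliquePartition
from .containers import DistanceMatrix
from .errors import DomainError
from .rearrangement import ModelParams, expected_events

logger = logging.getLogger(__name__)

PAIR_TABLE_COLUMNS = ["genome_a", "genome_b", "si_distance", "ppm_distance", "clique_id"]


@dataclass(frozen=True)
class PMTHResult:
    """Within-clique regression summary.

    ``slope`` is the change in P_PM per unit of the gene-order measure;
    ``pmth_ratio = 1/slope`` is the factor by which the gene-order clock
    outruns the point-mutation clock among closely related species.
    """

    slope: float
    r_squared: float
    df: int
    ci95: tuple[float, float]
    n_filtered: int
    pmth_ratio: float


@dataclass(frozen=True)
class ExponentialFit:
    """Coefficients of the phase-transition curve ``E(P_PM) = A exp(B SI)``."""

    A: float
    B: float
    residual_sse: float
    degenerate: bool = False


@dataclass(frozen=True)
class ElasticityCurve:
    """Binned, moving-average-smoothed elasticity profile.

    ``bin_centers`` are the mean SI values of the retained bins (trimmed to
    the centered-moving-average window); ``elasticity`` holds one value per
    interval between consecutive smoothed points, so it is one shorter than
    ``smoothed_ppm``.
    """

    bin_centers: np.ndarray
    smoothed_ppm: np.ndarray
    elasticity: np.ndarray
    ma_period: int = 3
    bin_width: float = 0.01

    def __post_init__(self):
        if len(self.smoothed_ppm) != len(self.bin_centers):
            raise ValueError("smoothed_ppm and bin_centers lengths differ")
        if len(self.elasticity) != len(self.bin_centers) - 1:
            raise ValueError("elasticity must have one fewer entry than the smoothed series")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly ascending")

    @property
    def interval_midpoints(self) -> np.ndarray:
        """SI abscissae at which the per-interval elasticities live."""
        return (self.bin_centers[:-1] + self.bin_centers[1:]) / 2.0


# ---------------------------------------------------------------------------
# pair table


def build_pair_table(si_m: DistanceMatrix, jc_m: DistanceMatrix,
                     partition: CliquePartition | None = None) -> pd.DataFrame:
    """One row per unordered pair of genomes shared by the two matrices.

    ``clique_id`` is filled where both members belong to the same clique of
    ``partition`` and left ``None`` otherwise.
    """
    shared = sorted(set(si_m.labels) & set(jc_m.labels))
    if len(shared) < 2:
        raise ValueError("fewer than 2 genome ids shared between the two matrices")
    member_of: dict[str, str | None] = {}
    if partition is not None:
        member_of = partition.membership()
    rows = []
    for i, a in enumerate(shared):
        for b in shared[i + 1:]:
            ca = member_of.get(a)
            cb = member_of.get(b)
            rows.append({
                "genome_a": a,
                "genome_b": b,
                "si_distance": si_m.get(a, b),
                "ppm_distance": jc_m.get(a, b),
                "clique_id": ca if (ca is not None and ca == cb) else None,
            })
    return pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# within-clique regression (PMTH ratio)


def pmth_regression(table: pd.DataFrame, ppm_filter: float = 0.1,
                    through_origin: bool = True,
                    gene_order_model: ModelParams | None = None,
                    orientation: str = "ppm_on_gr") -> PMTHResult:
    """Within-clique linear relation between the two clocks.

    Only pairs inside a clique enter; pairs with ``ppm_distance >
    ppm_filter`` are removed first (and counted in ``n_filtered``) — they are
    the candidate 16S-transfer outliers, not part of the clock relation.

    The x variable is the gene-order measure: the expected number of
    translocation events per gene obtained by inverting the translocation
    model on the observed SI distance when ``gene_order_model`` is given,
    or the raw SI distance otherwise.  By default P_PM is regressed on that
    measure through the origin, so ``slope`` ≈ 0.14 corresponds to a
    ``pmth_ratio`` of ≈ 7; set ``orientation="gr_on_ppm"`` to flip the axes
    and ``through_origin=False`` to add an intercept.
    """
    if orientation not in ("ppm_on_gr", "gr_on_ppm"):
        raise ValueError(f"bad orientation {orientation!r}")
    rows = table[table["clique_id"].notna()].copy()
    kept = rows[rows["ppm_distance"] <= ppm_filter]
    n_filtered = len(rows) - len(kept)
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} usable within-clique pairs (need >= 3)")

    si = kept["si_distance"].to_numpy()
    if gene_order_model is not None:
        x = np.array([expected_events(s, gene_order_model) for s in si]) / gene_order_model.n
    else:
        x = si
    y = kept["ppm_distance"].to_numpy()
    if orientation == "gr_on_ppm":
        x, y = y, x

    design = x[:, None] if through_origin else sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    slope = float(res.params[-1])
    ci = res.conf_int(alpha=0.05)
    ci95 = (float(ci[-1][0]), float(ci[-1][1]))
    return PMTHResult(
        slope=slope,
        r_squared=float(res.rsquared),
        df=int(res.df_resid),
        ci95=ci95,
        n_filtered=n_filtered,
        pmth_ratio=(math.inf if slope == 0 else 1.0 / slope),
    )


# ---------------------------------------------------------------------------
# global exponential phase-transition fit


def fit_exponential(table: pd.DataFrame, method: str = "log") -> ExponentialFit:
    """Least-squares fit of ``E(P_PM) = A exp(B SI)`` over all pairs.

    The default fits in the log domain — ordinary least squares of
    ``ln(P_PM)`` on SI — which is closed-form and deterministic; rows with
    non-positive P_PM are excluded with a warning.  ``method="nls"`` refines
    the log-domain solution by nonlinear least squares in the original
    domain.  ``residual_sse`` is always reported in the original domain.
    """
    if method not in ("log", "nls"):
        raise ValueError(f"bad method {method!r}")
    si = table["si_distance"].to_numpy(dtype=float)
    ppm = table["ppm_distance"].to_numpy(dtype=float)
    pos = ppm > 0
    if np.count_nonzero(~pos):
        logger.warning("fit_exponential: excluding %d rows with non-positive P_PM",
                       int(np.count_nonzero(~pos)))
    si, ppm = si[pos], ppm[pos]
    if len(ppm) < 3:
        raise ValueError(f"only {len(ppm)} rows with positive P_PM (need >= 3)")

    coeffs = np.polyfit(si, np.log(ppm), 1)
    b, log_a = float(coeffs[0]), float(coeffs[1])
    a = math.exp(log_a)
    if method == "nls":
        from scipy.optimize import curve_fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(lambda x, A, B: A * np.exp(B * x), si, ppm,
                                p0=[a, b], maxfev=10000)
        a, b = float(popt[0]), float(popt[1])

    sse = float(np.sum((ppm - a * np.exp(b * si)) ** 2))
    degenerate = abs(b) < 1e-8
    if degenerate:
        logger.warning("fit_exponential: rate B ≈ 0, fit is degenerate (constant P_PM)")
    return ExponentialFit(A=a, B=b, residual_sse=sse, degenerate=degenerate)


def derivative_unity_point(fit: ExponentialFit) -> float:
    """SI value where the fitted curve's derivative ``A B exp(B SI)`` equals 1.

    This is the phase-transition point: below it the gene-order clock carries
    the stronger signal, above it the point-mutation clock does.
    """
    if fit.A * fit.B <= 0:
        raise DomainError("derivative crossing needs A*B > 0")
    return math.log(1.0 / (fit.A * fit.B)) / fit.B


# ---------------------------------------------------------------------------
# elasticity


def moving_average(values: np.ndarray, period: int) -> np.ndarray:
    """Centered moving average; output is ``period - 1`` entries shorter."""
    if period < 1:
        raise ValueError("period must be >= 1")
    values = np.asarray(values, dtype=float)
    if len(values) < period:
        raise ValueError(f"need at least {period} values for MA({period})")
    return np.convolve(values, np.ones(period) / period, mode="valid")


def elasticity_curve(table: pd.DataFrame, bin_width: float = 0.01,
                     ma_period: int = 3) -> ElasticityCurve:
    """Binned elasticity of SI with respect to P_PM.

    Pairs are binned by SI distance into fixed-width bins; per-bin mean SI
    and mean P_PM are computed (empty bins dropped), the P_PM means are
    smoothed with a centered moving average, and the elasticity between
    consecutive smoothed points is ``(ΔSI/SI) / (ΔP_PM/P_PM)`` evaluated at
    interval midpoints.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    si = table["si_distance"].to_numpy(dtype=float)
    ppm = table["ppm_distance"].to_numpy(dtype=float)
    bins = np.floor(si / bin_width).astype(int)
    order = np.unique(bins)
    mean_si = np.array([si[bins == b].mean() for b in order])
    mean_ppm = np.array([ppm[bins == b].mean() for b in order])
    if len(order) < ma_period + 2:
        raise ValueError(
            f"only {len(order)} non-empty SI bins; need at least {ma_period + 2}"
        )
    sm_ppm = moving_average(mean_ppm, ma_period)
    # align SI with the centers of the MA windows
    trim = (ma_period - 1) // 2
    centers = mean_si[trim: trim + len(sm_ppm)]
    if np.any(sm_ppm <= 0):
        raise ValueError("smoothed P_PM has non-positive values; elasticity undefined")

    d_si = np.diff(centers)
    d_ppm = np.diff(sm_ppm)
    mid_si = (centers[:-1] + centers[1:]) / 2.0
    mid_ppm = (sm_ppm[:-1] + sm_ppm[1:]) / 2.0
    with np.errstate(divide="ignore"):
        elasticity = (d_si / mid_si) / (d_ppm / mid_ppm)
    return ElasticityCurve(bin_centers=centers, smoothed_ppm=sm_ppm,
                           elasticity=elasticity, ma_period=ma_period,
                           bin_width=bin_width)


def elasticity_unity_point(curve: ElasticityCurve) -> float | None:
    """First SI (ascending) where the elasticity crosses from > 1 to <= 1.

    Located by linear interpolation between the bracketing interval
    midpoints; ``None`` when no such crossing exists.
    """
    e = curve.elasticity
    x = curve.interval_midpoints
    for j in range(len(e) - 1):
        if e[j] > 1 >= e[j + 1]:
            if math.isinf(e[j]):
                return float(x[j + 1])
            frac = (e[j] - 1.0) / (e[j] - e[j + 1])
            return float(x[j] + frac * (x[j + 1] - x[j]))
    return None
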