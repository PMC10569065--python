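"""The erf dose-response model of peptide import.

The response of a reporter to an extracellular signalling-peptide
concentration c follows

    halfmax convention (default):
        Y(c) = Emin + (Emax - Emin) * (1 + erf(log10(c / K) / n)) / 2

    literal convention:
        Y(c) = Emin + (Emax - Emin) * erf(log10(c / K) / n)

where Emin is the expression floor (AU), Emax the plateau (AU), K the
half-maximal concentration (uM) and n the log10-width of the
transition.  Under the halfmax convention Y(K) = (Emin + Emax)/2 so K
is literally the half-maximal concentration; the literal convention is
the same erf form without the affine remap (Y(K) = Emin,
Y(0) = 2 Emin - Emax), kept as a first-class alternative because the
two parameterizations trace the same curve family with remapped
plateaus.  Fitting is multi-start least squares on per-concentration
replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "DoseResponseModel",
    "DoseResponseData",
    "FitResult",
    "KComparison",
    "predict_response",
    "fit_dose_response",
    "compare_K",
    "threshold_fraction",
]

_CONVENTIONS = ("halfmax", "literal")


@dataclass(frozen=True)
class DoseResponseModel:
    emin: float  # expression floor, AU
    emax: float  # expression plateau, AU
    k: float  # half-maximal concentration, uM
    n: float = 1.0  # log10-width of the transition, dimensionless
    convention: str = "halfmax"

    def __post_init__(self):
        if not (self.emax >= self.emin >= 0):
            raise ValueError("require Emax >= Emin >= 0")
        if self.k <= 0:
            raise ValueError("require K > 0")
        if self.n <= 0:
            raise ValueError("require n > 0")
        if self.convention not in _CONVENTIONS:
            raise ValueError(f"convention must be one of {_CONVENTIONS}")


def predict_response(model: DoseResponseModel, c) -> np.ndarray | float:
    """Model response at concentration(s) ``c`` (uM, >= 0); c = 0
    returns the c -> 0 limit of the erf."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        x = np.where(c_arr > 0, np.log10(np.maximum(c_arr, 1e-300) / model.k), -np.inf)
    e = special.erf(x / model.n)  # erf(-inf) = -1 handles c = 0
    span = model.emax - model.emin
    if model.convention == "halfmax":
        y = model.emin + span * (1.0 + e) / 2.0
    else:
        y = model.emin + span * e
    return float(y) if np.isscalar(c) or np.ndim(c) == 0 else y


class DoseResponseData:
    """Tidy replicate table: columns concentration_uM, replicate, value."""

    COLUMNS = ("concentration_uM", "replicate", "value")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if len(frame) == 0:
            raise ValueError("empty dose-response table")
        if (frame["concentration_uM"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, concentrations, replicates, values) -> "DoseResponseData":
        return cls(
            pd.DataFrame(
                {
                    "concentration_uM": np.asarray(concentrations, dtype=float),
                    "replicate": np.asarray(replicates, dtype=int),
                    "value": np.asarray(values, dtype=float),
                }
            )
        )

    @classmethod
    def read_tsv(cls, path) -> "DoseResponseData":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.frame["concentration_uM"].unique())

    def means(self) -> Tuple[np.ndarray, np.ndarray]:
        g = self.frame.groupby("concentration_uM")["value"].mean().sort_index()
        return g.index.to_numpy(), g.to_numpy()

    def sems(self) -> Tuple[np.ndarray, np.ndarray]:
        g = self.frame.groupby("concentration_uM")["value"].sem().sort_index()
        return g.index.to_numpy(), g.to_numpy()


@dataclass
class FitResult:
    model: DoseResponseModel
    se: Dict[str, float]  # keys: emin, emax, k, log10_k, n
    rss: float
    converged: bool
    warnings: List[str] = field(default_factory=list)
    n_points: int = 0

    @property
    def se_log10_k(self) -> float:
        return self.se["log10_k"]


def _predict_theta(theta: np.ndarray, logc: np.ndarray, zero: np.ndarray, convention: str) -> np.ndarray:
    emin, de, log10k, ln_n = theta
    n = np.exp(ln_n)
    e = special.erf((logc - log10k) / n)
    if convention == "halfmax":
        y = emin + de * (1.0 + e) / 2.0
        y0 = emin
    else:
        y = emin + de * e
        y0 = emin - de  # c -> 0 limit: 2 Emin - Emax
    return np.where(zero, y0, y)


def fit_dose_response(
    data: DoseResponseData,
    convention: str = "halfmax",
    weighted: bool = False,
) -> FitResult:
    """Least squares on per-concentration replicate means.

    Parameters are optimized as (Emin, Emax - Emin, log10 K, ln n) so
    the model invariants hold by construction; 5 starts on a log10 K
    grid spanning the positive concentration range guard against local
    minima; c = 0 rows are pinned to the analytic c -> 0 limit.
    Standard errors come from the Jacobian at the optimum.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    conc, means = data.means()
    if len(conc) < 4:
        raise ValueError("need >= 4 distinct concentrations to fit")
    pos = conc > 0
    if not pos.any():
        raise ValueError("need at least one positive concentration")
    weights = np.ones_like(means)
    if weighted:
        _, sems = data.sems()
        w = np.where(np.isfinite(sems) & (sems > 0), 1.0 / sems, np.nan)
        if np.isfinite(w).all():
            weights = w
    logc = np.where(pos, np.log10(np.maximum(conc, 1e-300)), 0.0)
    zero = ~pos

    lo_c, hi_c = logc[pos].min(), logc[pos].max()
    y_lo, y_hi = float(means.min()), float(means.max())
    de0 = max(y_hi - y_lo, 1e-6 * max(abs(y_hi), 1.0), 1e-12)

    def residuals(theta):
        return (_predict_theta(theta, logc, zero, convention) - means) * weights

    bounds = (
        np.array([0.0, 0.0, lo_c - 3.0, -3.0]),
        np.array([np.inf, np.inf, hi_c + 3.0, 3.0]),
    )
    best = None
    for log10k0 in np.linspace(lo_c, hi_c, 5):
        x0 = np.array([max(y_lo, 0.0), de0, log10k0, 0.0])
        try:
            res = optimize.least_squares(
                residuals, x0, bounds=bounds, method="trf",
                ftol=1e-8, xtol=1e-8, gtol=1e-8, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("dose-response fit failed to converge from all starts")

    emin, de, log10k, ln_n = best.x
    model = DoseResponseModel(
        emin=float(emin),
        emax=float(emin + de),
        k=float(10.0 ** log10k),
        n=float(np.exp(ln_n)),
        convention=convention,
    )
    rss = float(2.0 * best.cost)
    m, p = len(means), 4
    warnings: List[str] = []
    if not best.success:
        # flat ridge: parameters unidentifiable although the residual is
        # minimized; keep the fit and flag it
        warnings.append("optimizer stopped before meeting tolerances")
    se = {k: float("nan") for k in ("emin", "emax", "k", "log10_k", "n")}
    if m > p:
        s2 = rss / (m - p)
        J = best.jac
        cov = s2 * np.linalg.pinv(J.T @ J)
        var = np.clip(np.diag(cov), 0.0, np.inf)
        se["emin"] = float(np.sqrt(var[0]))
        se["emax"] = float(np.sqrt(max(var[0] + var[1] + 2.0 * cov[0, 1], 0.0)))
        se["log10_k"] = float(np.sqrt(var[2]))
        se["k"] = float(np.log(10.0) * model.k * se["log10_k"])
        se["n"] = float(model.n * np.sqrt(var[3]))
    else:
        warnings.append("no residual degrees of freedom; standard errors undefined")
    cmin, cmax = 10.0 ** lo_c, 10.0 ** hi_c
    if not (cmin <= model.k <= cmax):
        warnings.append("fitted K outside the sampled concentration range")
    if np.isfinite(se["log10_k"]) and se["log10_k"] > 1.0:
        warnings.append("SE(log10 K) > 1: K poorly identified")
    return FitResult(
        model=model, se=se, rss=rss, converged=True,
        warnings=warnings, n_points=m,
    )


@dataclass(frozen=True)
class KComparison:
    ratio: float
    se_log10: float
    ci_low: float
    ci_high: float


def compare_K(fit_a: FitResult, fit_b: FitResult) -> KComparison:
    """Fold difference in half-maximal concentration K_a / K_b with
    log10-scale standard error propagated from the two fits and a
    geometric +-1 SE interval."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    ratio = fit_a.model.k / fit_b.model.k
    sa, sb = fit_a.se_log10_k, fit_b.se_log10_k
    se = float(np.sqrt(sa * sa + sb * sb)) if np.isfinite(sa) and np.isfinite(sb) else float("nan")
    spread = 10.0 ** se if np.isfinite(se) else 1.0
    return KComparison(
        ratio=float(ratio),
        se_log10=se,
        ci_low=float(ratio / spread),
        ci_high=float(ratio * spread),
    )


def threshold_fraction(values: Sequence[float], background: float, fold: float = 10.0) -> float:
    """Fraction of single-cell expression values at or above
    ``fold`` x ``background`` (the ON-cell readout)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    if background <= 0:
        raise ValueError("background must be > 0")
    return float(np.mean(v >= fold * background))
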