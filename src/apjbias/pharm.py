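"""Quantitative pharmacology of recruitment assays.

Three curve models cover the analysis of a luminescence-based
beta-arrestin recruitment assay:

* saturation binding with Hill slope,
  ``B(x) = Bmax * x**h / (Kd**h + x**h)``;
* the Black-Leff operational model of partial agonism with slope ``n``,
  ``E(A) = Em * tau**n * A**n / ((KA + A)**n + tau**n * A**n)``,
  where ``tau`` is efficacy (the inverse of the receptor fraction the
  agonist must occupy for half-maximal response) and ``KA`` the functional
  affinity;
* a monotone Hill inhibition curve,
  ``R(x) = bottom + (top - bottom) / (1 + (x / IC50)**s)``.

Scale parameters (Bmax, Kd, tau, KA, IC50, slopes) are fitted in log10
space, which keeps them positive by construction; each fit starts from a
deterministic multi-start grid and refines the best candidates with
damped least squares, so fits are reproducible with no randomness in the
optimiser.  Bmax values can be normalised against a reference ligand
(the natural agonist) and reported as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateFitError

__all__ = [
    "DoseResponseTable", "BindingFit", "OperationalFit", "InhibitionFit",
    "hill_binding_curve", "operational_curve", "inhibition_curve",
    "fit_binding_hill", "fit_operational", "fit_inhibition",
    "normalize_bmax", "read_dose_response",
]


@dataclass
class DoseResponseTable:
    """Concentration/response pairs from one assay group."""

    concentration_M: np.ndarray
    response: np.ndarray
    replicate_id: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.concentration_M = np.asarray(self.concentration_M, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration_M.shape != self.response.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentration_M <= 0):
            raise ValueError("concentrations must be positive")

    def __len__(self) -> int:
        return len(self.concentration_M)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"concentration_M": self.concentration_M, "response": self.response}
        )
        if self.replicate_id is not None:
            df["replicate_id"] = self.replicate_id
        if self.label:
            df["group"] = self.label
        return df


def read_dose_response(path, group: Optional[str] = None) -> DoseResponseTable:
    """Read a delimited table with columns concentration_M, response[, group]."""
    df = pd.read_csv(path)
    if not {"concentration_M", "response"} <= set(df.columns):
        raise DegenerateFitError(
            "input table needs 'concentration_M' and 'response' columns")
    if group is not None:
        if "group" not in df.columns:
            raise DegenerateFitError("no 'group' column to select from")
        df = df[df["group"] == group]
        if df.empty:
            raise DegenerateFitError(f"group {group!r} not present in table")
    return DoseResponseTable(
        df["concentration_M"].to_numpy(),
        df["response"].to_numpy(),
        label=group or "",
    )


@dataclass
class BindingFit:
    Bmax: float
    Kd: float
    h: float
    residual_sse: float


@dataclass
class OperationalFit:
    Em: float
    tau: float
    KA: float
    n: float
    residual_sse: float


@dataclass
class InhibitionFit:
    top: float
    bottom: float
    IC50: float
    slope: float
    residual_sse: float
    monotone_flag: bool = False  # True when the data do not decrease with dose


# ---------------------------------------------------------------------------
# Model curves (positive-parameter forms, numerically stable in log space)

def hill_binding_curve(x, Bmax, Kd, h):
    x = np.asarray(x, dtype=float)
    return Bmax / (1.0 + np.exp(h * (np.log(Kd) - np.log(x))))


def operational_curve(A, Em, tau, KA, n):
    A = np.asarray(A, dtype=float)
    # E = Em / (1 + ((KA + A) / (tau * A))**n)
    ratio = np.log(KA + A) - np.log(tau) - np.log(A)
    return Em / (1.0 + np.exp(n * ratio))


def inhibition_curve(x, top, bottom, IC50, s=1.0):
    x = np.asarray(x, dtype=float)
    # logistic in log-dose, evaluated via expit for overflow safety
    from scipy.special import expit
    return bottom + (top - bottom) * expit(-s * (np.log(x) - np.log(IC50)))


# ---------------------------------------------------------------------------
# Deterministic multi-start least squares

def _multistart_least_squares(residual, starts, refine_top: int = 5):
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    sse0 = np.array([float(np.sum(residual(x) ** 2)) for x in starts])
    order = np.argsort(sse0, kind="stable")[:refine_top]
    best_x, best_sse = None, np.inf
    for k in order:
        try:
            res = optimize.least_squares(
                residual, starts[k], method="lm",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun ** 2))
        if sse < best_sse:
            best_x, best_sse = res.x, sse
    if best_x is None:
        raise DegenerateFitError("all optimisation starts failed")
    return best_x, best_sse


def _check_design(data: DoseResponseTable, min_doses: int) -> None:
    if len(np.unique(data.concentration_M)) < min_doses:
        raise DegenerateFitError(
            f"need >= {min_doses} distinct concentrations")
    if np.allclose(data.response, data.response[0]):
        raise DegenerateFitError("responses are constant; nothing to fit")


def _log_dose_grid(doses: np.ndarray, n: int = 5) -> np.ndarray:
    lo, hi = np.log10(doses.min()), np.log10(doses.max())
    return np.linspace(lo, hi, n)


def fit_binding_hill(data: DoseResponseTable) -> BindingFit:
    """Least-squares fit of the saturation-binding Hill model.

    Parameters are fitted as (log10 Bmax, log10 Kd, log10 h) from a
    deterministic 3 x 5 x 5 start grid spanning the response ceiling, the
    dose range, and slopes from shallow to steep.
    """
    _check_design(data, 4)
    x, y = data.concentration_M, data.response

    def residual(theta):
        b, kd, h = 10.0 ** theta
        return hill_binding_curve(x, b, kd, h) - y

    top = max(y.max(), 1e-12)
    starts = [
        (np.log10(top * fb), lkd, lh)
        for fb in (1.0, 1.3, 2.0)
        for lkd in _log_dose_grid(x, 5)
        for lh in np.log10([0.1, 0.3, 1.0, 3.0, 10.0])
    ]
    theta, sse = _multistart_least_squares(residual, starts)
    b, kd, h = 10.0 ** theta
    return BindingFit(float(b), float(kd), float(h), sse)


def fit_operational(
    data: DoseResponseTable,
    Em_policy: str = "free",
    Em: Optional[float] = None,
) -> OperationalFit:
    """Least-squares fit of the operational model of partial agonism.

    ``Em_policy="free"`` fits the system maximum Em together with
    (tau, KA, n); ``"shared"`` holds Em fixed at the supplied value, for
    joint analyses that share one system maximum across ligands.
    """
    if Em_policy not in ("free", "shared"):
        raise ValueError("Em_policy must be 'free' or 'shared'")
    if Em_policy == "shared" and (Em is None or Em <= 0):
        raise DegenerateFitError("shared Em_policy requires a positive Em")
    _check_design(data, 5)
    A, y = data.concentration_M, data.response
    tau_grid = np.linspace(-1.0, 2.0, 5)
    ka_grid = _log_dose_grid(A, 5)
    n_grid = np.log10([0.2, 0.7, 2.0])

    if Em_policy == "free":
        def residual(theta):
            em, tau, ka, n = 10.0 ** theta
            return operational_curve(A, em, tau, ka, n) - y

        em_grid = np.log10(max(y.max(), 1e-12) * np.array([1.05, 1.5, 3.0]))
        starts = [(lem, lt, lk, ln)
                  for lem in em_grid
                  for lt in tau_grid for lk in ka_grid for ln in n_grid]
        theta, sse = _multistart_least_squares(residual, starts)
        em, tau, ka, n = 10.0 ** theta
    else:
        def residual(theta):
            tau, ka, n = 10.0 ** theta
            return operational_curve(A, Em, tau, ka, n) - y

        starts = [(lt, lk, ln)
                  for lt in tau_grid for lk in ka_grid for ln in n_grid]
        theta, sse = _multistart_least_squares(residual, starts)
        tau, ka, n = 10.0 ** theta
        em = Em
    return OperationalFit(float(em), float(tau), float(ka), float(n), sse)


def fit_inhibition(
    data: DoseResponseTable,
    normalized_to: Optional[float] = None,
) -> InhibitionFit:
    """Least-squares fit of a monotone decreasing Hill inhibition curve.

    With ``normalized_to`` the responses are first rescaled to percent of
    that reference value (e.g. the uninhibited maximum), so ``top`` and
    ``bottom`` come out on the percent scale.  Data that increase with
    dose are flagged (``monotone_flag``) but the best fit is still
    returned.
    """
    _check_design(data, 4)
    x = data.concentration_M
    y = data.response.astype(float)
    if normalized_to is not None:
        if normalized_to <= 0:
            raise DegenerateFitError("normalized_to must be positive")
        y = y / normalized_to * 100.0

    rho = stats.spearmanr(np.log(x), y).statistic
    monotone_flag = bool(rho > 0)

    # theta = (bottom, log10 span, log10 IC50, log10 slope); top = bottom + span
    def residual(theta):
        bottom = theta[0]
        span, ic50, s = 10.0 ** theta[1:]
        return inhibition_curve(x, bottom + span, bottom, ic50, s) - y

    span0 = max(y.max() - y.min(), 1e-9)
    starts = [
        (y.min(), np.log10(span0 * fs), lic, ls)
        for fs in (1.0, 1.5)
        for lic in _log_dose_grid(x, 5)
        for ls in np.log10([0.5, 1.0, 2.0])
    ]
    theta, sse = _multistart_least_squares(residual, starts)
    bottom = float(theta[0])
    span, ic50, s = (float(v) for v in 10.0 ** theta[1:])
    return InhibitionFit(bottom + span, bottom, ic50, s, sse, monotone_flag)


def normalize_bmax(
    fits: Mapping[str, Union[BindingFit, float]],
    reference_label: str,
) -> pd.DataFrame:
    """Express each ligand's Bmax as a percentage of a reference ligand's.

    Accepts a mapping of group label to :class:`BindingFit` (or bare Bmax
    value).  Percentages are rounded to one decimal, the report precision.
    The result is scale-invariant: rescaling every Bmax by a common factor
    leaves the percentages unchanged.
    """
    if reference_label not in fits:
        raise KeyError(f"reference label {reference_label!r} not among fits")

    def bmax(v) -> float:
        return float(v.Bmax) if isinstance(v, BindingFit) else float(v)

    ref = bmax(fits[reference_label])
    if ref <= 0:
        raise DegenerateFitError("reference Bmax must be positive")
    rows = [
        {
            "group": label,
            "Bmax": bmax(v),
            "percent_of_reference": round(bmax(v) / ref * 100.0, 1),
        }
        for label, v in fits.items()
    ]
    return pd.DataFrame(rows)
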