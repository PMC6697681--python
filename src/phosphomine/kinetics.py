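"""Steady-state kinetics of cytidylyltransferases.

Initial-rate data (substrate concentration S in mM, velocity v in M/s) are
fit by bounded non-linear least squares to the Michaelis-Menten law

    v = kcat * E0 * S / (KM + S)

or, when velocity declines at high substrate, to the substrate-inhibition law

    v = kcat * E0 * S / (KM + S * (1 + S / KS))

with asymptotic (linearized) standard errors from the Jacobian at the
optimum. Specificity constants kcat/KM (M^-1 s^-1) and their ratios
quantify substrate preference, e.g. of a phosphonyl tailoring
cytidylyltransferase (PntC) for 2-aminoethylphosphonate over phosphocholine.

Concentration convention: substrate concentrations and KM/KS are carried in
mM (as printed in kinetics tables); enzyme concentration E0 and velocities
are molar. ``specificity_constant`` converts KM to M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticModel",
    "KineticFit",
    "fit_michaelis_menten",
    "fit_substrate_inhibition",
    "specificity_constant",
    "specificity_ratio",
]


class KineticModel(str, Enum):
    MM = "MM"
    SUBSTRATE_INHIBITION = "SUBSTRATE_INHIBITION"


class FitError(RuntimeError):
    """Non-convergence or an unphysical optimum."""


@dataclass(frozen=True)
class KineticFit:
    """Fitted steady-state parameters.

    ``kcat`` in s^-1, ``KM`` (and ``KS`` for substrate inhibition) in mM,
    ``E0`` in M. ``KS`` is None exactly when ``model`` is plain
    Michaelis-Menten. ``rss`` is the residual sum of squares at the optimum.
    """

    model: KineticModel
    kcat: float
    KM: float
    kcat_se: float
    KM_se: float
    E0: float
    rss: float
    converged: bool
    KS: float | None = None
    KS_se: float | None = None
    warnings: tuple[str, ...] = ()

    @property
    def specificity_constant(self) -> float:
        """kcat/KM in M^-1 s^-1 (KM converted from mM)."""
        return specificity_constant(self.kcat, self.KM)

    def to_dict(self) -> dict:
        return {
            "model": self.model.value,
            "kcat_per_s": self.kcat,
            "kcat_se": self.kcat_se,
            "KM_mM": self.KM,
            "KM_se": self.KM_se,
            "KS_mM": self.KS,
            "KS_se": self.KS_se,
            "E0_M": self.E0,
            "kcat_over_KM_per_M_per_s": self.specificity_constant,
            "rss": self.rss,
            "converged": self.converged,
            "warnings": list(self.warnings),
        }


def _validate_rate_table(table: pd.DataFrame, E0: float) -> tuple[np.ndarray, np.ndarray]:
    if E0 <= 0:
        raise ValueError("E0 must be positive")
    if not {"S", "v"} <= set(table.columns):
        raise ValueError("rate table needs columns 'S' (mM) and 'v' (M/s)")
    S = np.asarray(table["S"], dtype=float)
    v = np.asarray(table["v"], dtype=float)
    if np.any(S < 0) or np.any(v < 0):
        raise ValueError("negative concentration or velocity")
    if len(np.unique(S[S > 0])) < 3:
        raise ValueError("need at least 3 distinct positive substrate concentrations")
    return S, v


def _initial_guesses(S: np.ndarray, v: np.ndarray, E0: float) -> tuple[float, float]:
    # kcat0 from the observed plateau; KM0 from S nearest half-max.
    kcat0 = float(np.max(v)) / E0
    half = np.max(v) / 2.0
    KM0 = float(S[np.argmin(np.abs(v - half))])
    if KM0 <= 0:
        KM0 = float(np.median(S[S > 0]))
    return max(kcat0, 1e-12), max(KM0, 1e-12)


def _se_from_jacobian(res, n_obs: int) -> np.ndarray:
    """Asymptotic standard errors: sigma^2 * (J^T J)^-1 diagonal."""
    _, s, VT = np.linalg.svd(res.jac, full_matrices=False)
    threshold = np.finfo(float).eps * max(res.jac.shape) * s[0]
    s = s[s > threshold]
    VT = VT[: s.size]
    cov = VT.T / s**2 @ VT
    dof = max(n_obs - res.x.size, 1)
    sigma2 = 2.0 * res.cost / dof
    return np.sqrt(np.diag(sigma2 * cov))


def mm_rate(S, kcat: float, KM: float, E0: float):
    """Michaelis-Menten velocity (S, KM in mM; result in units of kcat*E0)."""
    S = np.asarray(S, dtype=float)
    return kcat * E0 * S / (KM + S)


def substrate_inhibition_rate(S, kcat: float, KM: float, KS: float, E0: float):
    """Substrate-inhibition velocity; KS = inf recovers Michaelis-Menten."""
    S = np.asarray(S, dtype=float)
    return kcat * E0 * S / (KM + S * (1.0 + S / KS))


def fit_michaelis_menten(table: pd.DataFrame, E0: float) -> KineticFit:
    """Least-squares Michaelis-Menten fit of an initial-rate table.

    ``table`` holds columns ``S`` (mM) and ``v`` (M/s); ``E0`` is the total
    enzyme concentration in M. Parameters are bounded positive. Raises
    :class:`FitError` on non-convergence.
    """
    S, v = _validate_rate_table(table, E0)
    kcat0, KM0 = _initial_guesses(S, v, E0)
    y = v / E0  # turnover scale (s^-1): keeps gradients well-conditioned

    def resid(p):
        return p[0] * S / (p[1] + S) - y

    res = least_squares(
        resid, x0=[kcat0, KM0], bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        method="trf", x_scale=[kcat0, KM0],
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not res.success:
        raise FitError(f"Michaelis-Menten fit did not converge: {res.message}")
    se = _se_from_jacobian(res, len(S))
    return KineticFit(
        model=KineticModel.MM,
        kcat=float(res.x[0]),
        KM=float(res.x[1]),
        kcat_se=float(se[0]),
        KM_se=float(se[1]),
        E0=E0,
        rss=float(2.0 * res.cost) * E0**2,
        converged=True,
    )


def fit_substrate_inhibition(table: pd.DataFrame, E0: float) -> KineticFit:
    """Least-squares substrate-inhibition fit (kcat, KM, KS all positive).

    The sampling design should extend beyond the velocity maximum at
    S = sqrt(KM*KS), otherwise KS is weakly identified; a KS estimate above
    100x max(S) triggers an "inhibition not identifiable" warning on the
    returned fit.
    """
    S, v = _validate_rate_table(table, E0)
    kcat0, KM0 = _initial_guesses(S, v, E0)
    KS0 = float(np.max(S))
    y = v / E0

    def resid(p):
        return p[0] * S / (p[1] + S * (1.0 + S / p[2])) - y

    res = least_squares(
        resid, x0=[kcat0, KM0, KS0],
        bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
        method="trf", x_scale=[kcat0, KM0, KS0],
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not res.success:
        raise FitError(f"substrate-inhibition fit did not converge: {res.message}")
    se = _se_from_jacobian(res, len(S))
    warns: tuple[str, ...] = ()
    if res.x[2] > 100.0 * np.max(S):
        warns = ("inhibition not identifiable",)
        warnings.warn(
            "KS estimate exceeds 100x the largest assayed substrate "
            "concentration; substrate inhibition is not identifiable",
            RuntimeWarning,
            stacklevel=2,
        )
    return KineticFit(
        model=KineticModel.SUBSTRATE_INHIBITION,
        kcat=float(res.x[0]),
        KM=float(res.x[1]),
        kcat_se=float(se[0]),
        KM_se=float(se[1]),
        KS=float(res.x[2]),
        KS_se=float(se[2]),
        E0=E0,
        rss=float(2.0 * res.cost) * E0**2,
        converged=True,
        warnings=warns,
    )


def specificity_constant(kcat: float, KM_mM: float) -> float:
    """kcat/KM in M^-1 s^-1 from kcat in s^-1 and KM in mM."""
    if kcat <= 0 or KM_mM <= 0:
        raise ValueError("kcat and KM must be positive")
    return kcat / (KM_mM * 1e-3)


def round_sig(x: float, sig_figs: int) -> float:
    """Round half away from zero to ``sig_figs`` significant figures."""
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    shift = sig_figs - d.adjusted() - 1
    rounded = d.scaleb(shift).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return float(rounded.scaleb(-shift))


def specificity_ratio(
    sc_numerator: float,
    sc_denominator: float,
    sig_figs: int = 2,
) -> float:
    """Ratio of two specificity constants, rounded to significant figures.

    A fold-preference, e.g. (kcat/KM)_P-Cho over (kcat/KM)_AEP. Rounding is
    half-away-from-zero at ``sig_figs`` significant figures, matching how
    fold preferences are conventionally reported (195.7 -> 200).
    """
    if sc_numerator <= 0 or sc_denominator <= 0:
        raise ValueError("specificity constants must be positive")
    return round_sig(sc_numerator / sc_denominator, sig_figs)
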