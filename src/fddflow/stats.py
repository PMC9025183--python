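"""Statistical stage: profile validation, distribution tests, outcome rule.

Profile validation compares a solved axial velocity profile in a straight
circular tube against the analytic Poiseuille solution

    v(r) = (P1 - P2) / (4 L eta) * (R^2 - r^2)

with a Pearson chi-square statistic on the sampled stations,
chi^2 = sum (v_num - v_exact)^2 / v_exact.  The wall station (zero expected
velocity) is excluded; by default the degrees of freedom are the number of
retained stations minus one, and an explicit dof may be supplied.  The
statistic is evaluated on dimensional velocities (m/s); an optional
normalization by the peak velocity is available since chi-square is
unit-sensitive.

Outcome classification applies the two-threshold rule to the cycle series
of maximum dWSS at t1..t4: a series whose cycle minimum exceeds the
stenosis threshold (1.23 Pa) predicts in-stent stenosis (endothelial
over-proliferation); otherwise a series whose cycle maximum stays below
the occlusion threshold (1.68 Pa) predicts insufficient endothelialization
and no occlusion; everything between is the norm.  Values are rounded to
two decimals before comparison, matching the precision at which the
thresholds are stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps


class Outcome(str, Enum):
    STENOSIS = "STENOSIS"
    NORM = "NORM"
    NO_OCCLUSION = "NO_OCCLUSION"


@dataclass(frozen=True)
class PoiseuilleSpec:
    """Analytic tube-flow parameters: pressures (Pa), length (m),
    viscosity (Pa*s), radius (m)."""

    P1: float
    P2: float
    L: float
    eta: float
    R: float

    def __post_init__(self) -> None:
        if self.P1 <= self.P2:
            raise ValueError("P1 must exceed P2")
        if min(self.L, self.eta, self.R) <= 0:
            raise ValueError("L, eta and R must be positive")

    @classmethod
    def from_mean_velocity(cls, v_mean: float, L: float, eta: float,
                           R: float, P2: float = 0.0) -> "PoiseuilleSpec":
        """Pressure drop implied by a mean (bulk) velocity via
        Hagen-Poiseuille: P1-P2 = 8 eta L v_mean / R^2."""
        return cls(P1=P2 + 8.0 * eta * L * v_mean / R ** 2, P2=P2,
                   L=L, eta=eta, R=R)


def poiseuille_profile(r, spec: PoiseuilleSpec):
    """Axial velocity at radius r (m/s); r must lie within the tube."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > spec.R):
        raise ValueError("r must lie in [0, R]")
    return (spec.P1 - spec.P2) / (4.0 * spec.L * spec.eta) \
        * (spec.R ** 2 - r ** 2)


def pearson_profile_pvalue(numerical: np.ndarray, exact: np.ndarray,
                           dof: Optional[int] = None,
                           normalize: bool = False,
                           zero_tol: float = 1e-12
                           ) -> tuple[float, float, int]:
    """Pearson goodness of fit between sampled velocity profiles.

    Stations with (near-)zero expected velocity — the wall — are dropped;
    a negative expected value in a retained station raises.  Returns
    ``(chi2, p, dof)`` with ``p`` the upper tail of the chi-square
    distribution; ``dof`` defaults to retained stations - 1.
    """
    v = np.asarray(numerical, dtype=float)
    e = np.asarray(exact, dtype=float)
    if v.shape != e.shape or v.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D arrays")
    keep = np.abs(e) > zero_tol
    v, e = v[keep], e[keep]
    if np.any(e < 0):
        raise ValueError("non-positive expected velocity in a retained "
                         "station")
    if v.size < 2:
        raise ValueError("too few stations")
    if normalize:
        scale = e.max()
        v, e = v / scale, e / scale
    chi2 = float(np.sum((v - e) ** 2 / e))
    k = int(v.size - 1) if dof is None else int(dof)
    return chi2, float(sps.chi2.sf(chi2, k)), k


def shapiro_wilk(samples) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (statistic, p)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 samples")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test; returns
    (statistic, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = sps.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ClassifierConfig:
    """Two-threshold outcome rule.

    ``theta_stenosis`` (Pa): cycle-minimum dWSS above it predicts in-stent
    stenosis.  ``theta_occlusion`` (Pa): cycle-maximum dWSS below it
    predicts no occlusion.  ``decimals``: rounding applied to the series
    before comparison.
    """

    theta_stenosis: float = 1.23
    theta_occlusion: float = 1.68
    decimals: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.theta_stenosis < self.theta_occlusion:
            raise ValueError("need 0 < theta_stenosis < theta_occlusion")


def classify_outcome(series: Sequence[float] | Mapping[str, float],
                     config: Optional[ClassifierConfig] = None) -> Outcome:
    """Classify a cycle series of maximum dWSS values at t1..t4."""
    config = config or ClassifierConfig()
    if isinstance(series, Mapping):
        missing = {"t1", "t2", "t3", "t4"} - set(series)
        if missing:
            raise ValueError(f"missing time points {sorted(missing)}")
        vals = [series[k] for k in ("t1", "t2", "t3", "t4")]
    else:
        vals = list(series)
    if len(vals) != 4 or not all(np.isfinite(vals)):
        raise ValueError("need four finite dWSS maxima (t1..t4)")
    v = np.round(np.asarray(vals, dtype=float), config.decimals)
    if v.min() > config.theta_stenosis:
        return Outcome.STENOSIS
    if v.max() < config.theta_occlusion:
        return Outcome.NO_OCCLUSION
    return Outcome.NORM
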