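"""Per-wing genotoxicity scores and compound-level dose-response analysis.

Four per-wing scores summarize the *mwh* burden: (1) mwh hairs normalized
by the analyzed wing surface area, (2) mwh cell count, (3) mwh spot count,
and (4) a dichotomous indicator of more than 2 mwh hairs.  Cell counts are
the headline score.

A compound's dose-response curve (DRC) is the per-dose average wing score.
Genotoxicity is first assessed with the dose-dependency test: ordinary
least squares of mean score on dose, with a one-sided Student's t-test of
slope <= 0; rejection at P < 0.05 calls the compound genotoxic.  Genotoxic
compounds are then characterized by a constrained Hill-form sigmoid

    score(c) = bottom + (top - bottom) / (1 + (EC50 / c)^slope)

with the saturation (top) enforced, because toxic high doses keep the data
from reaching the plateau.  Wald 95% confidence intervals and a covariance
envelope follow MATLAB nlinfit/nlparci semantics (t quantile, df = n - p).
Bottom and range absorb the affine scaling between measurement protocols,
so EC50 and slope can be compared between automated and manual scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats

from .classify import MwhGrouping

__all__ = [
    "WingScore",
    "DoseResponse",
    "SigmoidFit",
    "FitError",
    "compute_wing_scores",
    "dose_dependency_test",
    "two_sample_test",
    "fit_sigmoid",
    "scale_measures",
]


class FitError(RuntimeError):
    """Sigmoid fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass
class WingScore:
    """The four per-wing genotoxicity scores."""

    wing_id: str
    dose_mM: float
    n_hairs: int
    analyzed_area_um2: float
    score_hairs_per_mm2: float
    score_cells: int
    score_spots: int
    score_dichotomous: bool


def compute_wing_scores(
    grouping: MwhGrouping,
    analyzed_area_um2: float,
    wing_id: str = "",
    dose_mM: float = 0.0,
    n_hairs_analyzed: int = 0,
) -> WingScore:
    """Build the per-wing score record from the mutant grouping.

    The area-normalized score is expressed per mm^2 of analyzed wing
    surface.  A wing with zero analyzed area and a nonzero hair count is an
    inconsistency and raises.
    """
    if analyzed_area_um2 <= 0:
        if grouping.n_mwh_hairs > 0:
            raise ValueError("zero analyzed area with nonzero mwh hairs")
        per_mm2 = 0.0
    else:
        per_mm2 = grouping.n_mwh_hairs / (analyzed_area_um2 / 1e6)
    return WingScore(
        wing_id=wing_id,
        dose_mM=dose_mM,
        n_hairs=n_hairs_analyzed,
        analyzed_area_um2=analyzed_area_um2,
        score_hairs_per_mm2=per_mm2,
        score_cells=grouping.n_cells,
        score_spots=grouping.n_spots,
        score_dichotomous=grouping.n_mwh_hairs > 2,
    )


@dataclass
class DoseResponse:
    """Per-dose wing-score lists for one compound and measure type."""

    compound: str
    measure: str                       # "auto" | "manual"
    scores: dict[float, np.ndarray]    # dose -> per-wing scores
    excluded_doses: tuple[float, ...] = ()  # toxicity exclusions

    @classmethod
    def from_table(cls, table: pd.DataFrame, compound: str = "", measure: str = "auto",
                   dose_col: str = "dose_mM", score_col: str = "score"):
        groups = {
            float(d): g[score_col].to_numpy(dtype=float)
            for d, g in table.groupby(dose_col)
        }
        return cls(compound=compound, measure=measure, scores=groups)

    @property
    def doses(self) -> np.ndarray:
        return np.array(sorted(d for d in self.scores if d not in self.excluded_doses))

    @property
    def means(self) -> np.ndarray:
        return np.array([self.scores[d].mean() for d in self.doses])

    @property
    def n_wings(self) -> np.ndarray:
        return np.array([len(self.scores[d]) for d in self.doses])

    def validate(self) -> None:
        if len(self.doses) < 2:
            raise ValueError("need >= 2 non-excluded doses")
        if 0.0 not in self.scores:
            raise ValueError("control dose (0) missing")


def dose_dependency_test(drc: DoseResponse, alpha: float = 0.05):
    """One-sided test for a positive dose trend in the mean scores.

    OLS of per-dose mean score on dose; H0: slope <= 0.  Returns
    ``(slope, one-sided P, verdict)`` where the verdict is "genotoxic" iff
    P < alpha.  Toxic doses must have been excluded beforehand.
    """
    doses, means = drc.doses, drc.means
    if len(doses) < 3:
        raise ValueError("insufficient doses for the dose-dependency test (need >= 3)")
    res = sstats.linregress(doses, means)
    df_resid = len(doses) - 2
    if res.stderr == 0:
        p_one = 0.0 if res.slope > 0 else 1.0
    else:
        t = res.slope / res.stderr
        p_one = float(sstats.t.sf(t, df_resid))
    verdict = "genotoxic" if p_one < alpha else "non-genotoxic"
    return float(res.slope), p_one, verdict


def two_sample_test(dose_scores, control_scores, method: str = "welch") -> float:
    """Compare wing scores at one dose against the control group.

    Default is Welch's unequal-variance t-test (one-sided, dose > control);
    ``method="ranksum"`` switches to a one-sided Mann-Whitney U.  Identical
    zero-variance groups return P = 1 by convention.
    """
    a = np.asarray(dose_scores, dtype=float)
    b = np.asarray(control_scores, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    if method == "welch":
        res = sstats.ttest_ind(a, b, equal_var=False, alternative="greater")
    elif method == "ranksum":
        res = sstats.mannwhitneyu(a, b, alternative="greater")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.pvalue)


@dataclass
class SigmoidFit:
    """Constrained sigmoid fit result (top enforced, not estimated)."""

    bottom: float
    top: float
    ec50_mM: float
    slope: float
    covariance: np.ndarray             # 3x3 over (bottom, ec50, slope)
    ci_bottom: tuple[float, float]
    ci_ec50: tuple[float, float]
    ci_slope: tuple[float, float]
    n_points: int
    dose_offset: float
    extrapolated: bool = False         # EC50 far outside the dose range

    @property
    def range(self) -> float:
        return self.top - self.bottom

    def predict(self, dose) -> np.ndarray:
        return _sigmoid(
            dose, self.top, self.dose_offset, self.bottom, self.ec50_mM, self.slope
        )

    def envelope(self, dose, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise confidence band from the parameter covariance."""
        dose = np.atleast_1d(np.asarray(dose, dtype=float))
        theta = np.array([self.bottom, self.ec50_mM, self.slope])
        grads = np.empty((dose.size, 3))
        for j in range(3):
            step = 1e-6 * max(abs(theta[j]), 1e-6)
            tp, tm = theta.copy(), theta.copy()
            tp[j] += step
            tm[j] -= step
            fp = _sigmoid(dose, self.top, self.dose_offset, *tp)
            fm = _sigmoid(dose, self.top, self.dose_offset, *tm)
            grads[:, j] = (fp - fm) / (2 * step)
        var = np.einsum("ij,jk,ik->i", grads, self.covariance, grads)
        tq = sstats.t.ppf(0.5 + level / 2, max(self.n_points - 3, 1))
        half = tq * np.sqrt(np.maximum(var, 0))
        mid = self.predict(dose)
        return mid - half, mid + half


def _sigmoid(dose, top, offset, bottom, ec50, slope):
    # the control (zero) dose is the baseline by definition; the Hill form
    # applies only at positive concentrations
    c = np.atleast_1d(np.asarray(dose, dtype=float)) + offset
    out = np.full(c.shape, float(bottom))
    pos = c > 0
    with np.errstate(over="ignore"):  # (ec50/c)^slope -> inf is a valid limit
        out[pos] = bottom + (top - bottom) / (1.0 + (ec50 / c[pos]) ** slope)
    return out


def fit_sigmoid(
    drc: DoseResponse,
    top: float,
    weights: np.ndarray | None = None,
    level: float = 0.95,
) -> SigmoidFit:
    """Least-squares fit of the constrained sigmoid to the per-dose means.

    ``top`` is the enforced saturation.  Internally EC50 and slope are fit
    on a log scale for conditioning; the covariance and CIs are mapped back
    to the natural parameters (delta method), with t-based Wald intervals
    (df = n - 3).  The control dose contributes the baseline directly
    (score(0) = bottom), which chiefly identifies the bottom parameter.

    ``weights`` (per dose point, e.g. wing counts) switch to weighted least
    squares.  Needs >= 4 dose points including the control.
    """
    drc.validate()
    doses, means = drc.doses, drc.means
    if len(doses) < 4:
        raise ValueError("sigmoid fit needs >= 4 dose points including control")
    nonzero = doses[doses > 0]
    offset = 0.0
    w = np.ones_like(means) if weights is None else np.sqrt(np.asarray(weights, float))

    span = max(top - means.min(), 1e-9)
    half = means.min() + 0.5 * span
    above = doses[means >= half]
    ec50_0 = float(above.min()) if above.size else float(np.sqrt(nonzero.min() * nonzero.max()))
    ec50_0 = max(ec50_0, offset * 10)

    def resid(theta):
        bottom, lec, lsl = theta
        # clamp the log parameters so solver excursions cannot overflow exp
        ec = float(np.exp(np.clip(lec, -60.0, 60.0)))
        sl = float(np.exp(np.clip(lsl, -60.0, 60.0)))
        pred = _sigmoid(doses, top, offset, bottom, ec, sl)
        return w * (pred - means)

    # shallow slopes put the optimum on a long flat ridge; a few log-spaced
    # EC50 starts make the solver land in the global basin
    starts = [
        np.array([means.min(), math.log(c0), math.log(s0)])
        for c0 in (ec50_0, float(doses.max()), 30.0 * float(doses.max()), 1e3 * float(doses.max()))
        for s0 in (1.0, 0.3)
    ]
    sol = None
    for x0 in starts:
        cand = optimize.least_squares(
            resid, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=20000
        )
        if sol is None or (cand.success and cand.cost < sol.cost - 1e-15):
            sol = cand
    if not sol.success:
        raise FitError(f"sigmoid fit did not converge: {sol.message}", last_params=sol.x)
    bottom, lec, lsl = sol.x
    ec50, slope = math.exp(lec), math.exp(lsl)

    n, p = len(doses), 3
    dof = max(n - p, 1)
    rss = float(sol.fun @ sol.fun)
    s2 = rss / dof
    J = sol.jac
    try:
        cov_log = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov_log = s2 * np.linalg.pinv(J.T @ J)
    # delta method: d(ec50)/d(log ec50) = ec50, same for slope
    scale = np.diag([1.0, ec50, slope])
    cov = scale @ cov_log @ scale

    tq = sstats.t.ppf(0.5 + level / 2, dof)
    se_log = np.sqrt(np.maximum(np.diag(cov_log), 0))
    ci_bottom = (bottom - tq * se_log[0], bottom + tq * se_log[0])
    # log-scale intervals keep EC50/slope positive (exact for the log fit);
    # np.exp overflows to inf for unidentified parameters instead of raising
    ci_ec50 = (float(np.exp(lec - tq * se_log[1])), float(np.exp(lec + tq * se_log[1])))
    ci_slope = (float(np.exp(lsl - tq * se_log[2])), float(np.exp(lsl + tq * se_log[2])))

    extrapolated = ec50 > 1e3 * float(doses.max())
    return SigmoidFit(
        bottom=float(bottom), top=float(top), ec50_mM=float(ec50), slope=float(slope),
        covariance=cov, ci_bottom=ci_bottom, ci_ec50=ci_ec50, ci_slope=ci_slope,
        n_points=n, dose_offset=offset, extrapolated=extrapolated,
    )


def scale_measures(fit_a: SigmoidFit, fit_b: SigmoidFit) -> dict:
    """Compare EC50/slope between two measures after bottom/range scaling.

    Scores under each measure map to (score - bottom)/range, removing the
    affine offset and scale between protocols; EC50 and slope are invariant
    under that map and are reported side by side with CI overlap.
    """
    for f in (fit_a, fit_b):
        if abs(f.range) < 1e-12:
            raise ValueError("degenerate scaling: sigmoid range is ~0")

    def overlap(ci1, ci2):
        return ci1[0] <= ci2[1] and ci2[0] <= ci1[1]

    ec50_overlap = overlap(fit_a.ci_ec50, fit_b.ci_ec50)
    return {
        "ec50": (fit_a.ec50_mM, fit_b.ec50_mM),
        "ec50_ratio": fit_a.ec50_mM / fit_b.ec50_mM,
        "ec50_ci": (fit_a.ci_ec50, fit_b.ci_ec50),
        "ec50_ci_overlap": ec50_overlap,
        "ec50_verdict": "consistent" if ec50_overlap else "distinct",
        "slope": (fit_a.slope, fit_b.slope),
        "slope_ci": (fit_a.ci_slope, fit_b.ci_slope),
        "slope_ci_overlap": overlap(fit_a.ci_slope, fit_b.ci_slope),
    }
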