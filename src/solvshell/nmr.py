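"""Karplus-equation machinery: torsions from three-bond couplings, the
three-rotamer hydroxymethyl population solver, J-modulated HMBC fitting and
anomeric-ratio integration.

A Karplus curve maps a dihedral angle theta (degrees) to a three-bond scalar
coupling (Hz):

    3J(theta) = A cos^2(x) + B cos(x) + C
                + sin1 sin(x) + cos2 cos(2x) + sin2 sin(2x),   x = theta + phase

The quadratic-in-cosine terms cover the glycosidic H-C-O-C curves; the
Fourier extension covers the hydroxymethyl 3J_H5,H6R / 3J_H5,H6S relationships
needed by the rotamer solver.  Numeric coefficients live in a config-resident
constants file (``data/karplus.yaml``), not in code.

Torsion inversion selects the root of 3J(theta) = J inside a stated branch
(default 0-90 degrees, the syn region for glycosidic torsions) and applies the
curve's reporting sign convention (psi_H is reported negative for the syn
conformer).  Uncertainties propagate as the half-spread of inverting J +/- dJ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq, curve_fit

from .analysis import ROTAMER_REFS, RotamerPopulations

__all__ = [
    "KarplusCurve",
    "CouplingMeasurement",
    "JModSeries",
    "TorsionEstimate",
    "load_karplus_curves",
    "karplus_forward",
    "karplus_invert",
    "fit_jmod",
    "rotamer_populations_from_couplings",
    "anomeric_ratio",
    "UnattainableCouplingError",
    "AmbiguousBranchError",
    "DegenerateFitError",
]


class UnattainableCouplingError(ValueError):
    """The requested J lies outside the curve's attainable range on the branch."""


class AmbiguousBranchError(ValueError):
    """More than one torsion in the branch reproduces the requested J."""


class DegenerateFitError(RuntimeError):
    """The regression has no information to determine J (e.g. zero signal)."""


@dataclass(frozen=True)
class KarplusCurve:
    name: str
    A: float
    B: float
    C: float
    phase: float = 0.0
    sin1: float = 0.0
    cos2: float = 0.0
    sin2: float = 0.0
    report_sign: int = 1

    def __post_init__(self):
        for v in (self.A, self.B, self.C, self.phase, self.sin1, self.cos2, self.sin2):
            if not np.isfinite(v):
                raise ValueError("Karplus coefficients must be finite")

    def __call__(self, theta_deg):
        x = np.radians(np.asarray(theta_deg, dtype=float) + self.phase)
        c = np.cos(x)
        J = (self.A * c * c + self.B * c + self.C
             + self.sin1 * np.sin(x) + self.cos2 * np.cos(2 * x)
             + self.sin2 * np.sin(2 * x))
        return float(J) if J.ndim == 0 else J

    def attainable_range(self, branch=(-180.0, 180.0)) -> tuple:
        grid = np.linspace(branch[0], branch[1], 7201)
        J = self(grid)
        return float(J.min()), float(J.max())


def load_karplus_curves(path: str | Path | None = None) -> dict:
    """Load named curves from a YAML constants file (package default if None)."""
    if path is None:
        import importlib.resources
        text = (importlib.resources.files("solvshell.data") / "karplus.yaml").read_text()
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"Karplus constants file not found: {path}")
        text = path.read_text()
    raw = yaml.safe_load(text)
    curves = {}
    for name, coef in raw.items():
        curves[name] = KarplusCurve(
            name=name,
            A=float(coef.get("A", 0.0)),
            B=float(coef.get("B", 0.0)),
            C=float(coef.get("C", 0.0)),
            phase=float(coef.get("phase", 0.0)),
            sin1=float(coef.get("sin1", 0.0)),
            cos2=float(coef.get("cos2", 0.0)),
            sin2=float(coef.get("sin2", 0.0)),
            report_sign=int(coef.get("report_sign", 1)),
        )
    return curves


@dataclass(frozen=True)
class CouplingMeasurement:
    name: str
    value: float        # Hz
    uncertainty: float = 0.0

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("coupling magnitudes are non-negative")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


@dataclass
class JModSeries:
    """Cross-peak intensities versus polarization-transfer mixing time."""

    tau: np.ndarray         # seconds, strictly increasing
    intensity: np.ndarray   # arbitrary units
    coupling_name: str = ""

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.tau) != len(self.intensity):
            raise ValueError("tau and intensity lengths differ")
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau values must be strictly increasing")


@dataclass(frozen=True)
class TorsionEstimate:
    angle: float            # degrees, sign convention applied
    uncertainty: float      # degrees
    branch: tuple
    sign_convention: int = 1
    one_sided: bool = False


def karplus_forward(theta_deg: float, curve: KarplusCurve) -> float:
    """Closed-form evaluation of the coupling at a torsion angle."""
    return curve(theta_deg)


def _roots_in_branch(curve: KarplusCurve, J: float, branch, tol=1e-10):
    lo, hi = branch
    grid = np.linspace(lo, hi, 2001)
    f = curve(grid) - J
    roots = []
    for i in range(len(grid) - 1):
        if f[i] == 0.0:
            roots.append(float(grid[i]))
        elif f[i] * f[i + 1] < 0:
            roots.append(float(brentq(lambda t: curve(t) - J, grid[i], grid[i + 1],
                                      xtol=1e-12)))
    if f[-1] == 0.0:
        roots.append(float(grid[-1]))
    # deduplicate near-identical roots
    out = []
    for r in sorted(roots):
        if not out or abs(r - out[-1]) > 1e-6:
            out.append(r)
    return out


def karplus_invert(J, curve: KarplusCurve, branch=(0.0, 90.0)) -> TorsionEstimate:
    """Torsion angle whose coupling matches a measurement, within a branch.

    At the curve's extremum the inversion is one-sided: the angle of the
    extremum is returned with an uncertainty from the attainable side only.
    """
    if isinstance(J, CouplingMeasurement):
        value, dJ = J.value, J.uncertainty
    else:
        value, dJ = float(J), 0.0
    jmin, jmax = curve.attainable_range(branch)
    one_sided = False
    if value > jmax or value < jmin:
        slack = 1e-9 * max(1.0, abs(jmax))
        if value > jmax + slack or value < jmin - slack:
            raise UnattainableCouplingError(
                f"J = {value} Hz outside attainable range "
                f"[{jmin:.3f}, {jmax:.3f}] Hz on branch {branch}")
        value = np.clip(value, jmin, jmax)
    roots = _roots_in_branch(curve, value, branch)
    if len(roots) == 0:
        # extremum touch: locate by argmin distance
        grid = np.linspace(branch[0], branch[1], 7201)
        theta = float(grid[np.argmin(np.abs(curve(grid) - value))])
        roots = [theta]
        one_sided = True
    if len(roots) > 1:
        raise AmbiguousBranchError(
            f"{len(roots)} roots in branch {branch}: {np.round(roots, 2)}")
    theta = roots[0]
    # uncertainty = half-spread of inverting J +/- dJ (clipped to attainability)
    if dJ > 0:
        spread = []
        for jj in (value - dJ, value + dJ):
            jj_c = np.clip(jj, jmin, jmax)
            if jj != jj_c:
                one_sided = True
            rr = _roots_in_branch(curve, jj_c, branch)
            if rr:
                spread.append(min(rr, key=lambda r: abs(r - theta)))
        unc = 0.5 * (max(spread) - min(spread)) if len(spread) == 2 else (
            abs(spread[0] - theta) if spread else 0.0)
    else:
        unc = 0.0
    return TorsionEstimate(curve.report_sign * theta, unc, tuple(branch),
                           curve.report_sign, one_sided)


def fit_jmod(series: JModSeries):
    """Fit I(tau) = A sin(pi J tau) by nonlinear least squares.

    J is restricted to the alias-free band for the sampling design
    (J < 1 / (2 min-spacing)); the initial guess comes from a grid search over
    that band.  Returns (J_hz, amplitude, diagnostics dict with uncertainties
    and residuals).
    """
    tau, I = series.tau, series.intensity
    if len(tau) < 4:
        raise ValueError("at least 4 mixing-time points are required")
    if np.allclose(I, 0.0):
        raise DegenerateFitError("all-zero intensities: J undefined, amplitude 0")
    j_nyq = 1.0 / (2.0 * np.min(np.diff(tau)))
    j_grid = np.linspace(0.05, j_nyq * 0.999, 400)
    best_j, best_sse = None, np.inf
    for j in j_grid:
        s = np.sin(np.pi * j * tau)
        denom = float(s @ s)
        if denom < 1e-12:
            continue
        a = float(I @ s) / denom
        sse = float(np.sum((I - a * s) ** 2))
        if sse < best_sse:
            best_j, best_sse = j, sse

    def model(t, a, j):
        return a * np.sin(np.pi * j * t)

    s0 = np.sin(np.pi * best_j * tau)
    a0 = float(I @ s0) / float(s0 @ s0)
    popt, pcov = curve_fit(model, tau, I, p0=(a0, best_j), maxfev=10000)
    amplitude, j_fit = float(popt[0]), float(popt[1])
    if amplitude < 0:  # fold sign into the phase convention
        amplitude, j_fit = -amplitude, j_fit
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
    resid = I - model(tau, *popt)
    diagnostics = {
        "J_sigma": float(perr[1]),
        "amplitude_sigma": float(perr[0]),
        "rss": float(resid @ resid),
        "residuals": resid,
        "alias_free_band": (0.0, j_nyq),
    }
    return abs(j_fit), amplitude, diagnostics


def rotamer_populations_from_couplings(
        J_R, J_S, curve_R: KarplusCurve, curve_S: KarplusCurve,
        references: dict | None = None) -> RotamerPopulations:
    """Solve the three-state rotamer populations from averaged couplings.

    The measured couplings are modeled as population-weighted averages over the
    staggered hydroxymethyl conformers (gt +65, gg -65, tg 180 degrees):

        J_R = P_gt J_R(gt) + P_gg J_R(gg) + P_tg J_R(tg)   (same for J_S)
        P_gt + P_gg + P_tg = 1

    Small negative solutions (measurement noise) are clamped to zero and
    renormalized, flagged on the result.
    """
    refs = references or ROTAMER_REFS
    jr = {k: curve_R(v) for k, v in refs.items()}
    js = {k: curve_S(v) for k, v in refs.items()}
    M = np.array([
        [jr["gt"], jr["gg"], jr["tg"]],
        [js["gt"], js["gg"], js["tg"]],
        [1.0, 1.0, 1.0],
    ])
    if abs(np.linalg.det(M)) < 1e-9:
        raise ValueError("degenerate predicted couplings: rotamer system singular")
    vr = J_R.value if isinstance(J_R, CouplingMeasurement) else float(J_R)
    vs = J_S.value if isinstance(J_S, CouplingMeasurement) else float(J_S)
    p = np.linalg.solve(M, np.array([vr, vs, 1.0]))
    clamped = bool(np.any(p < -1e-12))
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    return RotamerPopulations(float(p[0]), float(p[1]), float(p[2]), clamped=clamped)


def anomeric_ratio(integral_alpha: float, integral_beta: float) -> tuple:
    """Percent alpha:beta from anomeric-signal integrals."""
    if integral_alpha < 0 or integral_beta < 0:
        raise ValueError("integrals must be non-negative")
    total = integral_alpha + integral_beta
    if total == 0:
        raise ValueError("both integrals are zero")
    return 100.0 * integral_alpha / total, 100.0 * integral_beta / total
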