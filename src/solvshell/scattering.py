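"""Neutron-weighted structure factors and the S(Q) <-> g(r) Fourier pair.

Conventions
-----------
The total structure factor is the interference-only Faber-Ziman sum

    F(Q) = sum_{alpha <= beta} (2 - delta_ab) c_a c_b b_a b_b (S_ab(Q) - 1)

with number fractions ``c`` and coherent scattering lengths ``b`` in fm, so
F carries fm^2 units and decays to zero at large Q.  The partial structure
factor and radial distribution function are related by the sine transforms

    S(Q) = 1 + (4 pi rho / Q) \\int r (g(r) - 1) sin(Qr) dr
    g(r) = 1 + 1 / (2 pi^2 rho r) \\int Q (S(Q) - 1) sin(Qr) dQ

evaluated by trapezoid quadrature on uniform grids, with an optional Lorch
taper to suppress truncation ripple.  Isotopomer contrast enters through
effective scattering lengths: an exchangeable hydrogen class with deuterium
fraction f scatters with b = (1 - f) b_H + f b_D.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ScatteringLengthTable",
    "Rdf",
    "PartialStructureFactor",
    "TotalStructureFactor",
    "CLASS_ELEMENTS",
    "effective_b",
    "effective_b_map",
    "sq_from_rdf",
    "rdf_from_sq",
    "total_fq",
    "chi_squared",
    "debye_partials",
    "lorch_window",
    "default_q_grid",
]

# element carried by each coarse site class
CLASS_ELEMENTS = {"Cs": "C", "Hc": "H", "Oh": "O", "Ho": "H", "Oe": "O",
                  "Ow": "O", "Hw": "H"}


def default_q_grid(q_min: float = 0.1, q_max: float = 30.0, dq: float = 0.05) -> np.ndarray:
    return np.arange(q_min, q_max + 0.5 * dq, dq)


class ScatteringLengthTable(dict):
    """Coherent scattering lengths b (fm) by element/isotope symbol."""

    @classmethod
    def default(cls) -> "ScatteringLengthTable":
        ref = importlib.resources.files("solvshell.data") / "scattering_lengths.yaml"
        table = cls(yaml.safe_load(ref.read_text()))
        table.validate()
        return table

    def validate(self) -> None:
        for el in ("H", "D", "C", "O"):
            if el not in self:
                raise ValueError(f"scattering-length table missing {el}")
        if not (self["H"] < 0 < self["D"]):
            raise ValueError("expected b_H < 0 < b_D")


def _uniform_step(grid: np.ndarray, what: str) -> float:
    steps = np.diff(grid)
    if len(steps) == 0 or not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError(f"{what} grid must be uniform")
    return float(steps[0])


def _canonical_pair(pair) -> tuple:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass
class Rdf:
    """Radial distribution function g(r) for one atom-class pair."""

    pair: tuple
    r: np.ndarray
    g: np.ndarray
    rho: float          # total atomic number density, A^-3
    c_beta: float       # number fraction of the partner class
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pair = tuple(self.pair)
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < -1e-9):
            raise ValueError("g(r) must be non-negative")
        _uniform_step(self.r, "r")


@dataclass
class PartialStructureFactor:
    pair: tuple
    Q: np.ndarray
    S: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pair = tuple(self.pair)
        self.Q = np.asarray(self.Q, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if np.any(self.Q <= 0):
            raise ValueError("Q grid must be positive")
        _uniform_step(self.Q, "Q")


@dataclass
class TotalStructureFactor:
    scheme: str
    Q: np.ndarray
    F: np.ndarray                   # fm^2, interference-only (decays to 0)
    composition: dict = field(default_factory=dict)
    effective_b: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.F = np.asarray(self.F, dtype=float)


def effective_b(scheme, site_class: str, table: ScatteringLengthTable | None = None,
                class_elements: dict | None = None) -> float:
    """Effective coherent scattering length (fm) of a site class under a scheme.

    Exchangeable hydrogen classes mix linearly between b_H and b_D according to
    the scheme's deuterium fraction; every other class scatters with its
    element's tabulated value.
    """
    table = table if table is not None else ScatteringLengthTable.default()
    elements = class_elements or CLASS_ELEMENTS
    if site_class not in elements:
        raise KeyError(f"unknown site class {site_class!r}")
    el = elements[site_class]
    deut = getattr(scheme, "deuteration", scheme or {}) if scheme is not None else {}
    if site_class in deut:
        if el != "H":
            raise ValueError(f"non-hydrogen class {site_class!r} cannot be deuterated")
        f = float(deut[site_class])
        return (1.0 - f) * table["H"] + f * table["D"]
    return float(table[el])


def effective_b_map(scheme, classes, table=None, class_elements=None) -> dict:
    return {c: effective_b(scheme, c, table, class_elements) for c in classes}


def lorch_window(x: np.ndarray, x_max: float) -> np.ndarray:
    arg = np.pi * x / x_max
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(arg > 1e-12, np.sin(arg) / arg, 1.0)
    return np.where(x <= x_max, w, 0.0)


def sq_from_rdf(rdf: Rdf, Q: np.ndarray | None = None, window: bool = False) -> PartialStructureFactor:
    """Forward sine transform g(r) -> S(Q)."""
    Q = default_q_grid() if Q is None else np.asarray(Q, dtype=float)
    _uniform_step(Q, "Q")
    r = rdf.r
    h = rdf.g - 1.0
    if window:
        h = h * lorch_window(r, r[-1])
    # integrand[i_Q, i_r] = r (g-1) sin(Q r)
    kernel = np.sin(np.outer(Q, r))
    integral = np.trapezoid(kernel * (r * h)[None, :], r, axis=1)
    S = 1.0 + 4.0 * np.pi * rdf.rho / Q * integral
    return PartialStructureFactor(rdf.pair, Q, S,
                                  meta={"rho": rdf.rho, "c_beta": rdf.c_beta,
                                        "window": window})


def rdf_from_sq(sq: PartialStructureFactor, rho: float,
                r: np.ndarray | None = None, window: bool = False) -> Rdf:
    """Inverse sine transform S(Q) -> g(r).

    The r < 0.5 A region is physically meaningless for atomic pairs and is
    flagged in the result metadata; a Q_max below 15 inverse angstrom earns a
    truncation warning in the metadata as well.
    """
    if r is None:
        r = np.arange(0.01, 12.0, 0.02)
    r = np.asarray(r, dtype=float)
    _uniform_step(r, "r")
    Q = sq.Q
    h = sq.S - 1.0
    if window:
        h = h * lorch_window(Q, Q[-1])
    kernel = np.sin(np.outer(r, Q))
    integral = np.trapezoid(kernel * (Q * h)[None, :], Q, axis=1)
    g = 1.0 + integral / (2.0 * np.pi**2 * rho * r)
    g = np.clip(g, 0.0, None)
    meta = {"untrusted_below_A": 0.5}
    if Q[-1] < 15.0:
        meta["warning"] = f"Q_max = {Q[-1]:.2f} < 15 A^-1: sub-angstrom detail unreliable"
    return Rdf(sq.pair, r, g, rho, sq.meta.get("c_beta", float("nan")), meta=meta)


def total_fq(partials, composition: dict, b_map: dict,
             scheme: str = "", require_all_pairs: bool = True) -> TotalStructureFactor:
    """Faber-Ziman weighted sum of partials into a total structure factor."""
    by_pair = {_canonical_pair(p.pair): p for p in partials}
    classes = sorted(composition)
    expected = [(a, b) for i, a in enumerate(classes) for b in classes[i:]
                if composition[a] > 0 and composition[b] > 0]
    missing = [p for p in expected if p not in by_pair]
    if missing and require_all_pairs:
        raise ValueError(f"missing partial structure factors for pairs: {missing}")
    Q = next(iter(by_pair.values())).Q
    F = np.zeros_like(Q)
    for pair, sq in by_pair.items():
        if not np.allclose(sq.Q, Q):
            raise ValueError("partials must share one Q grid")
        a, b = pair
        delta = 1.0 if a == b else 0.0
        w = (2.0 - delta) * composition[a] * composition[b] * b_map[a] * b_map[b]
        F = F + w * (sq.S - 1.0)
    return TotalStructureFactor(scheme, Q, F, dict(composition), dict(b_map))


def chi_squared(model: TotalStructureFactor, target: TotalStructureFactor) -> float:
    """Mean squared F(Q) residual between model and target on a shared grid."""
    if model.Q.shape != target.Q.shape or not np.allclose(model.Q, target.Q):
        raise ValueError("Q grids differ")
    return float(np.mean((model.F - target.F) ** 2))


def debye_partials(positions: np.ndarray, site_class: np.ndarray,
                   Q: np.ndarray) -> dict:
    """Finite-cluster partial interference functions by direct double sum.

    S_ab(Q) - 1 = 1 / (N c_a c_b) sum_{i in a, j in b, i != j} sinc(Q r_ij);
    intended as the brute-force oracle for small open clusters (no periodicity).
    """
    Q = np.asarray(Q, dtype=float)
    n = len(positions)
    classes = sorted(set(site_class))
    comp = {c: np.count_nonzero(site_class == c) / n for c in classes}
    out = {}
    for i, a in enumerate(classes):
        for b in classes[i:]:
            ia = np.flatnonzero(site_class == a)
            ib = np.flatnonzero(site_class == b)
            d = np.linalg.norm(positions[ia, None, :] - positions[None, ib, :], axis=-1)
            if a == b:
                np.fill_diagonal(d, np.nan)
            rij = d[np.isfinite(d)]
            qr = np.outer(Q, rij)
            s = np.sum(np.sinc(qr / np.pi), axis=1) / (n * comp[a] * comp[b])
            out[(a, b)] = PartialStructureFactor((a, b), Q, 1.0 + s,
                                                 meta={"c_beta": comp[b]})
    return out, comp
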