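"""Two-state thermal denaturation of a monomeric protein followed by CD.

The observable is the ellipticity at a single wavelength (222 nm for the
melts this package was written around).  A two-state folded/unfolded
equilibrium with linear pre- and post-transition baselines gives

    y(T) = alpha(T) * (B_F(T) - B_U(T)) + B_U(T)

with baselines B_F(T) = eps_F + C_F*(T - T_F0) and
B_U(T) = eps_U + C_U*(T - T_U0), the fraction folded

    alpha(T) = 1 / (1 + exp(-dG(T) * 1000 / (R * T)))

and the Gibbs-Helmholtz free energy of unfolding (kJ/mol)

    dG(T) = dH * (1 - T/Tm) - dCp * ((Tm - T) + T * ln(T/Tm)).

dG is the unfolding free energy: positive below Tm (folded favoured),
zero at Tm, negative above, so alpha runs 1 -> 0 as T rises when dH > 0.
Baselines are anchored at fixed reference temperatures (25 degC and 80 degC
by default) so eps_F/eps_U keep the meaning of extrapolated folded and
unfolded ellipticities at those temperatures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import lmfit
import numpy as np
from scipy import stats

__all__ = [
    "R_GAS",
    "MeltingCurve",
    "UnfoldingParams",
    "UnfoldingFit",
    "gibbs_energy",
    "fraction_folded",
    "predicted_ellipticity",
    "fit_melting_curve",
    "convert_millideg_to_molar_ellipticity",
    "compare_stability",
    "read_melting_curve",
]

#: gas constant, J mol-1 K-1
R_GAS = 8.314

#: anchor temperatures (K) at which eps_folded / eps_unfolded are defined
ANCHOR_T_FOLDED = 298.15
ANCHOR_T_UNFOLDED = 353.15

_PARAM_NAMES = ("tm", "dH", "dCp", "eps_folded", "eps_unfolded",
                "slope_folded", "slope_unfolded")


@dataclass(frozen=True)
class MeltingCurve:
    """A single-wavelength protein melt: ellipticity vs temperature (K)."""

    temperatures: np.ndarray
    ellipticities: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        y = np.asarray(self.ellipticities, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("temperatures and ellipticities must be 1-D and equal length")
        if t.size < 10:
            raise ValueError(f"melting curve needs >= 10 points, got {t.size}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in melting curve")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "ellipticities", y)

    def __len__(self) -> int:
        return self.temperatures.size


@dataclass
class UnfoldingParams:
    """Parameters of the two-state model.

    tm in K, dH (van't Hoff enthalpy) in kJ/mol, dCp in kJ/mol/K,
    eps_* in ellipticity units at their anchor temperatures, slopes in
    ellipticity per K.
    """

    tm: float
    dH: float
    dCp: float = 0.0
    eps_folded: float = 0.0
    eps_unfolded: float = 0.0
    slope_folded: float = 0.0
    slope_unfolded: float = 0.0
    anchor_T_folded: float = ANCHOR_T_FOLDED
    anchor_T_unfolded: float = ANCHOR_T_UNFOLDED

    def __post_init__(self):
        if self.tm <= 0:
            raise ValueError("tm must be positive (Kelvin)")
        if self.dH <= 0:
            raise ValueError("dH (van't Hoff enthalpy of unfolding) must be positive")


@dataclass
class UnfoldingFit:
    """Result of fitting the two-state model to one melting curve."""

    params: UnfoldingParams
    free: tuple[str, ...]
    stderr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rss: float
    converged: bool
    message: str = ""
    n_points: int = 0

    def to_dict(self) -> dict:
        d = {
            "params": asdict(self.params),
            "free": list(self.free),
            "stderr": self.stderr,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "rss": self.rss,
            "converged": self.converged,
            "message": self.message,
            "n_points": self.n_points,
        }
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def gibbs_energy(dH: float, dCp: float, tm: float, T) -> float | np.ndarray:
    """Unfolding free energy (kJ/mol) at temperature T (K).

    dG(T) = dH*(1 - T/Tm) - dCp*((Tm - T) + T*ln(T/Tm)); zero at T = Tm.
    """
    T = np.asarray(T, dtype=float)
    if tm <= 0:
        raise ValueError("tm must be positive")
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    g = dH * (1.0 - T / tm) - dCp * ((tm - T) + T * np.log(T / tm))
    return float(g) if g.ndim == 0 else g


def fraction_folded(dG, T) -> float | np.ndarray:
    """Fraction of folded protein alpha at unfolding free energy dG (kJ/mol).

    alpha = 1 / (1 + exp(-dG*1000/(R*T))); 0.5 at dG = 0, -> 1 for large
    positive dG (stable fold).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    x = np.asarray(dG, dtype=float) * 1000.0 / (R_GAS * T)
    # clipped logistic: exp(+-500) stays finite in float64
    x = np.clip(x, -500.0, 500.0)
    a = 1.0 / (1.0 + np.exp(-x))
    return float(a) if a.ndim == 0 else a


def predicted_ellipticity(params: UnfoldingParams, T) -> float | np.ndarray:
    """Model ellipticity at temperature T (K) under the two-state model."""
    T = np.asarray(T, dtype=float)
    bf = params.eps_folded + params.slope_folded * (T - params.anchor_T_folded)
    bu = params.eps_unfolded + params.slope_unfolded * (T - params.anchor_T_unfolded)
    a = fraction_folded(gibbs_energy(params.dH, params.dCp, params.tm, T), T)
    y = a * (bf - bu) + bu
    return float(y) if y.ndim == 0 else y


def _default_init(curve: MeltingCurve) -> UnfoldingParams:
    t, y = curve.temperatures, curve.ellipticities
    k = max(3, len(t) // 10)
    y_lo = float(np.mean(y[:k]))      # low-T end ~ folded
    y_hi = float(np.mean(y[-k:]))     # high-T end ~ unfolded
    half = 0.5 * (y_lo + y_hi)
    # temperature where the signal crosses half amplitude
    idx = int(np.argmin(np.abs(y - half)))
    tm0 = float(t[idx])
    tm0 = min(max(tm0, t[0] + 1.0), t[-1] - 1.0)
    return UnfoldingParams(
        tm=tm0, dH=250.0, dCp=0.0,
        eps_folded=y_lo, eps_unfolded=y_hi,
        slope_folded=0.0, slope_unfolded=0.0,
    )


def fit_melting_curve(
    curve: MeltingCurve,
    init: UnfoldingParams | None = None,
    fixed: Iterable[str] = ("dCp", "slope_folded", "slope_unfolded"),
) -> UnfoldingFit:
    """Nonlinear least-squares fit of the two-state model to a melt.

    Parameters named in ``fixed`` are held at their ``init`` values
    (``dCp`` defaults to fixed at 0: it is weakly identifiable from a
    single melt).  95% confidence intervals are asymptotic, estimate
    +/- t(0.975, n-k) * SE, matching commercial curve-fit conventions.

    A flat curve (no transition inside the grid) is reported as a
    non-converged fit, never silently.
    """
    fixed = tuple(fixed)
    for name in fixed:
        if name not in _PARAM_NAMES:
            raise ValueError(f"unknown parameter in fixed mask: {name!r}")
    if init is None:
        init = _default_init(curve)
    t, y = curve.temperatures, curve.ellipticities

    span = float(np.ptp(y))
    scale = max(abs(float(np.mean(y))), 1.0)
    if span < 1e-9 * scale:
        return UnfoldingFit(params=init, free=(), stderr={}, ci95={},
                            rss=float(np.sum((y - np.mean(y)) ** 2)),
                            converged=False,
                            message="flat curve: no transition within the grid",
                            n_points=len(curve))

    p = lmfit.Parameters()
    p.add("tm", value=init.tm, min=t[0] - 50.0, max=t[-1] + 50.0, vary="tm" not in fixed)
    p.add("dH", value=init.dH, min=1e-3, vary="dH" not in fixed)
    p.add("dCp", value=init.dCp, vary="dCp" not in fixed)
    p.add("eps_folded", value=init.eps_folded, vary="eps_folded" not in fixed)
    p.add("eps_unfolded", value=init.eps_unfolded, vary="eps_unfolded" not in fixed)
    p.add("slope_folded", value=init.slope_folded, vary="slope_folded" not in fixed)
    p.add("slope_unfolded", value=init.slope_unfolded, vary="slope_unfolded" not in fixed)

    def _residual(pars):
        prm = UnfoldingParams(
            tm=pars["tm"].value, dH=max(pars["dH"].value, 1e-6),
            dCp=pars["dCp"].value,
            eps_folded=pars["eps_folded"].value,
            eps_unfolded=pars["eps_unfolded"].value,
            slope_folded=pars["slope_folded"].value,
            slope_unfolded=pars["slope_unfolded"].value,
            anchor_T_folded=init.anchor_T_folded,
            anchor_T_unfolded=init.anchor_T_unfolded,
        )
        return predicted_ellipticity(prm, t) - y

    result = lmfit.minimize(_residual, p, method="least_squares")

    v = result.params.valuesdict()
    est = UnfoldingParams(
        tm=v["tm"], dH=v["dH"], dCp=v["dCp"],
        eps_folded=v["eps_folded"], eps_unfolded=v["eps_unfolded"],
        slope_folded=v["slope_folded"], slope_unfolded=v["slope_unfolded"],
        anchor_T_folded=init.anchor_T_folded,
        anchor_T_unfolded=init.anchor_T_unfolded,
    )
    free = tuple(n for n in _PARAM_NAMES if result.params[n].vary)
    resid = _residual(result.params)
    rss = float(np.sum(resid ** 2))
    dof = max(len(curve) - len(free), 1)
    tq = stats.t.ppf(0.975, dof)
    stderr, ci95 = {}, {}
    for name in free:
        se = result.params[name].stderr
        if se is not None and np.isfinite(se):
            stderr[name] = float(se)
            val = result.params[name].value
            ci95[name] = (float(val - tq * se), float(val + tq * se))

    # honesty checks: transition midpoint inside the grid, amplitude
    # resolvable above the residual noise
    amp = abs((est.eps_folded + est.slope_folded * (est.tm - est.anchor_T_folded))
              - (est.eps_unfolded + est.slope_unfolded * (est.tm - est.anchor_T_unfolded)))
    rms = math.sqrt(rss / len(curve))
    ok = bool(result.success) and t[0] < est.tm < t[-1] and amp > max(3.0 * rms, 1e-9 * scale)
    msg = result.message if isinstance(result.message, str) else ""
    if ok and not free:
        ok = True
    if not ok and not msg:
        msg = "fit did not converge to a resolvable transition inside the grid"

    return UnfoldingFit(params=est, free=free, stderr=stderr, ci95=ci95,
                        rss=rss, converged=ok, message=msg, n_points=len(curve))


def convert_millideg_to_molar_ellipticity(
    theta_mdeg,
    path_length_cm: float,
    molar_conc: float,
    n_residues: int = 1,
    mode: str = "molar",
):
    """Convert raw CD signal (millidegrees) to molar ellipticity.

    [theta] = theta_mdeg / (10 * l * c)  [deg cm^2 dmol^-1]

    with l the path length in cm and c the molar concentration in mol/L.
    ``mode="mean_residue"`` divides additionally by ``n_residues`` to give
    mean residue ellipticity.
    """
    if path_length_cm <= 0:
        raise ValueError("path length must be positive")
    if molar_conc <= 0:
        raise ValueError("concentration must be positive")
    if mode not in ("molar", "mean_residue"):
        raise ValueError(f"unknown mode {mode!r}")
    denom = 10.0 * path_length_cm * molar_conc
    if mode == "mean_residue":
        if n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        denom *= n_residues
    out = np.asarray(theta_mdeg, dtype=float) / denom
    return float(out) if out.ndim == 0 else out


def compare_stability(fit_a: UnfoldingFit, fit_b: UnfoldingFit) -> dict[str, float]:
    """Stability difference between two fitted variants.

    Returns ``delta_tm`` = Tm(b) - Tm(a) and ``dG_a_at_tm_b``, the
    unfolding free energy of model *a* evaluated at Tm(b) (negative when
    b melts higher, i.e. a is already unstable at b's midpoint).
    """
    for f, tag in ((fit_a, "a"), (fit_b, "b")):
        if not f.converged:
            raise ValueError(f"fit {tag} did not converge; cannot compare stability")
    a, b = fit_a.params, fit_b.params
    return {
        "delta_tm": b.tm - a.tm,
        "dG_a_at_tm_b": gibbs_energy(a.dH, a.dCp, a.tm, b.tm),
    }


def read_melting_curve(path: str | Path, temperature_unit: str = "K",
                       label: str | None = None) -> MeltingCurve:
    """Read a 2-column (temperature, ellipticity) delimited text file.

    Comma, tab or whitespace separated; one optional non-numeric header
    line.  ``temperature_unit`` is "K" or "C" (degC converted with 273.15).
    """
    if temperature_unit not in ("K", "C"):
        raise ValueError("temperature_unit must be 'K' or 'C'")
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (ValueError, IndexError):
            continue  # header line
    if not rows:
        raise ValueError(f"no numeric data rows in {path}")
    t = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    if temperature_unit == "C":
        t = t + 273.15
    return MeltingCurve(t, y, label=label or Path(path).stem)


def write_melting_curve(curve: MeltingCurve, path: str | Path) -> None:
    """Write a melt as 2-column tab-separated text with a one-line header."""
    lines = ["temperature_K\tellipticity"]
    lines += [f"{t:.4f}\t{y:.6f}" for t, y in
              zip(curve.temperatures, curve.ellipticities)]
    Path(path).write_text("\n".join(lines) + "\n")
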