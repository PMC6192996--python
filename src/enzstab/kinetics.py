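"""Michaelis-Menten kinetics: fitting, derived constants, activity metrics.

Estimation is always by nonlinear least squares on v = Vmax*S/(Km+S);
the Lineweaver-Burk transform is provided for presentation only (the
double-reciprocal regression is biased and is never used to estimate
parameters).  Internal units: substrate in uM, velocity in uM/s, enzyme
in uM; kcat = Vmax/E0 in 1/s and catalytic efficiency kcat/Km in
1/s/mM (Km converted uM -> mM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticsDataset",
    "MichaelisMentenFit",
    "ActivityRecord",
    "fit_michaelis_menten",
    "lineweaver_burk_points",
    "specific_activity",
    "relative_activity_profile",
    "two_sample_t_test",
    "read_kinetics_csv",
    "write_kinetics_csv",
]


@dataclass(frozen=True)
class KineticsDataset:
    """Initial-rate data: one row per (substrate level, replicate)."""

    substrate_um: np.ndarray
    velocities: np.ndarray      # uM/s, parallel to substrate_um
    enzyme_um: float
    substrate: str = ""
    temperature_c: float | None = None
    ph: float | None = None
    label: str = ""

    def __post_init__(self):
        s = np.asarray(self.substrate_um, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        if s.ndim != 1 or v.shape != s.shape:
            raise ValueError("substrate and velocity arrays must be 1-D and equal length")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be positive")
        if self.enzyme_um <= 0:
            raise ValueError("enzyme concentration must be positive")
        object.__setattr__(self, "substrate_um", s)
        object.__setattr__(self, "velocities", v)

    @property
    def n_levels(self) -> int:
        return np.unique(self.substrate_um).size


@dataclass
class MichaelisMentenFit:
    vmax: float                 # uM/s
    km: float                   # uM
    kcat: float                 # 1/s
    efficiency: float           # kcat/Km, 1/s/mM
    vmax_se: float
    km_se: float
    kcat_se: float
    efficiency_se: float
    rss: float
    converged: bool
    message: str = ""
    n_points: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "vmax", "km", "kcat", "efficiency", "vmax_se", "km_se",
            "kcat_se", "efficiency_se", "rss", "converged", "message",
            "n_points")}


@dataclass(frozen=True)
class ActivityRecord:
    """One chromogenic end-point assay (p-nitrophenol release at 400 nm)."""

    delta_absorbance: float
    assay_volume_l: float
    time_min: float
    protein_mg: float
    extinction_m1cm1: float = 18300.0   # pNP at 400 nm, alkaline stop (default, configurable)
    path_length_cm: float = 1.0

    def __post_init__(self):
        for name in ("assay_volume_l", "time_min", "protein_mg",
                     "extinction_m1cm1", "path_length_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _mm_model(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(data: KineticsDataset) -> MichaelisMentenFit:
    """Nonlinear least-squares fit of v = Vmax*S/(Km+S).

    Requires >= 4 distinct substrate levels.  Non-convergence and
    degenerate (constant-velocity) inputs are flagged, never silent.
    """
    if data.n_levels < 4:
        raise ValueError(f"need >= 4 distinct substrate levels, got {data.n_levels}")
    s, v = data.substrate_um, data.velocities
    n = s.size

    fail = MichaelisMentenFit(*(math.nan,) * 8, rss=math.nan, converged=False,
                              n_points=n)
    if np.ptp(v) < 1e-12 * max(abs(float(np.mean(v))), 1.0):
        fail.message = "degenerate input: velocities do not vary with substrate"
        return fail

    vmax0 = 1.1 * float(np.max(v))
    half = 0.5 * vmax0
    km0 = float(s[np.argmin(np.abs(v - half))])
    km0 = max(km0, 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            _mm_model, s, v, p0=(vmax0, km0),
            bounds=((0, 0), (np.inf, np.inf)), maxfev=10000,
            ftol=1e-14, xtol=1e-14, gtol=1e-14)
    except RuntimeError as exc:
        fail.message = f"fit did not converge: {exc}"
        return fail

    vmax, km = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    vmax_se, km_se = float(perr[0]), float(perr[1])
    kcat = vmax / data.enzyme_um
    kcat_se = vmax_se / data.enzyme_um
    km_mm = km / 1000.0
    eff = kcat / km_mm
    # first-order error propagation for the ratio (covariance included)
    if np.all(np.isfinite(pcov)):
        d = np.array([1.0 / data.enzyme_um / km_mm,
                      -kcat / (km_mm ** 2) / 1000.0])
        eff_se = float(np.sqrt(d @ pcov @ d))
    else:
        eff_se = math.nan
    rss = float(np.sum((v - _mm_model(s, vmax, km)) ** 2))
    ok = km > 0 and vmax > 0 and np.all(np.isfinite(popt))
    return MichaelisMentenFit(vmax, km, kcat, eff, vmax_se, km_se, kcat_se,
                              eff_se, rss=rss, converged=bool(ok), n_points=n)


def lineweaver_burk_points(data: KineticsDataset,
                           fit: MichaelisMentenFit | None = None):
    """Double-reciprocal (1/S, 1/v) points plus the line implied by the
    *nonlinear* fit: slope Km/Vmax, intercept 1/Vmax.

    Presentation only; zero velocities or concentrations are rejected.
    """
    if np.any(data.velocities == 0):
        raise ValueError("zero velocities cannot be reciprocal-transformed")
    if fit is None:
        fit = fit_michaelis_menten(data)
    if not fit.converged:
        raise ValueError("underlying Michaelis-Menten fit did not converge")
    inv_s = 1.0 / data.substrate_um
    inv_v = 1.0 / data.velocities
    return {
        "inv_s": inv_s,
        "inv_v": inv_v,
        "slope": fit.km / fit.vmax,
        "intercept": 1.0 / fit.vmax,
    }


def specific_activity(rec: ActivityRecord) -> float:
    """Specific activity in U/mg (umol p-nitrophenol released per min per mg).

    mol product = (dA / (eps * l)) * V; converted to umol, divided by
    assay time (min) and protein mass (mg).
    """
    moles = rec.delta_absorbance / (rec.extinction_m1cm1 * rec.path_length_cm) \
        * rec.assay_volume_l
    return moles * 1e6 / rec.time_min / rec.protein_mg


def relative_activity_profile(values, reference: str | None = None):
    """Percent-of-reference activity profile.

    ``values`` is a sequence of (condition, activity).  The reference is
    an explicit condition name, or the maximum activity when None.
    """
    values = list(values)
    if not values or all(v <= 0 for _, v in values):
        raise ValueError("need at least one positive activity")
    if reference is None:
        ref = max(v for _, v in values)
    else:
        matches = [v for c, v in values if c == reference]
        if not matches:
            raise ValueError(f"reference condition {reference!r} not in profile")
        ref = matches[0]
    if ref <= 0:
        raise ValueError("reference activity must be positive")
    return [(c, 100.0 * v / ref) for c, v in values]


def two_sample_t_test(group_a, group_b) -> dict[str, float]:
    """Two-tailed two-sample t test assuming equal variances (homoscedastic).

    Returns the pooled-variance t statistic, df = n_a + n_b - 2 and the
    two-tailed p value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / df
    if sp2 == 0:
        if np.mean(a) == np.mean(b):
            return {"t": 0.0, "df": df, "p_two_tailed": 1.0}
        t = math.inf if np.mean(a) > np.mean(b) else -math.inf
        return {"t": t, "df": df, "p_two_tailed": 0.0}
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "df": df, "p_two_tailed": float(p)}


def read_kinetics_csv(path: str | Path) -> KineticsDataset:
    """Read a kinetics CSV: '# key = value' metadata header lines followed
    by columns substrate_um, replicate, velocity_um_s."""
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "=" in line:
                k, _, v = line.lstrip("# ").partition("=")
                meta[k.strip()] = v.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise ValueError(f"no data rows in {path}")
    df = pd.read_csv(Path(path), comment="#")
    if "substrate_um" not in df or "velocity_um_s" not in df:
        raise ValueError("kinetics CSV needs columns substrate_um, velocity_um_s")
    if "enzyme_um" not in meta:
        raise ValueError("kinetics CSV metadata must declare enzyme_um")

    def _maybe(key):
        return float(meta[key]) if key in meta else None

    return KineticsDataset(
        substrate_um=df["substrate_um"].to_numpy(),
        velocities=df["velocity_um_s"].to_numpy(),
        enzyme_um=float(meta["enzyme_um"]),
        substrate=meta.get("substrate", ""),
        temperature_c=_maybe("temperature_c"),
        ph=_maybe("ph"),
        label=meta.get("label", Path(path).stem),
    )


def write_kinetics_csv(data: KineticsDataset, path: str | Path) -> None:
    lines = [f"# enzyme_um = {data.enzyme_um}"]
    if data.substrate:
        lines.append(f"# substrate = {data.substrate}")
    if data.temperature_c is not None:
        lines.append(f"# temperature_c = {data.temperature_c}")
    if data.ph is not None:
        lines.append(f"# ph = {data.ph}")
    if data.label:
        lines.append(f"# label = {data.label}")
    lines.append("substrate_um,replicate,velocity_um_s")
    rep = 0
    last = None
    for s, v in zip(data.substrate_um, data.velocities):
        rep = rep + 1 if s == last else 1
        last = s
        lines.append(f"{s:.10g},{rep},{v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
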