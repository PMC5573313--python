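"""Hill/Michaelis kinetics fitting and the beta-cell RAI / GSIR-T model.

Glucokinase is a cooperative monomeric enzyme; its glucose dependence is
described by a Hill function and its ATP dependence by a Michaelis factor:

    A(G, ATP) = kcat * G^nH / (S0.5^nH + G^nH) * ATP / (ATP + KM_ATP)

Two derived quantities summarise a variant's physiological impact:

* RAI (relative activity index): the variant's activity at the physiological
  operating point (5 mM glucose, 2.5 mM ATP by default) relative to wild
  type.  Wild type is 1.00 by construction; values below 0.01 are reported
  censored as "<0.01" (inactive alleles).
* GSIR-T (threshold for glucose-stimulated insulin release): the blood
  glucose level at which a heterozygous beta-cell — half wild-type, half
  variant enzyme — regains the wild-type reference phosphorylation rate.
  Wild type sits at the 5.0 mM setpoint; inactivating variants shift the
  threshold upward (mild fasting hyperglycemia, GCK-MODY), activating ones
  downward (hypoglycemia, PHHI).  Values at or above 7.1 mM are reported
  censored as ">=7.1" (null alleles).

The heterozygote model, allele dose and operating point are all explicit in
:class:`BetaCellModelConfig`; published alternatives (different ATP, wild-type
allele compensation) are configuration changes, not code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import optimize

__all__ = [
    "KineticAssay",
    "KineticParams",
    "BetaCellModelConfig",
    "CensoredValue",
    "FitResult",
    "activity",
    "fit_hill",
    "fit_michaelis",
    "fit_ic50",
    "stability_index",
    "compute_rai",
    "gsir_threshold",
]

AssayKind = Literal["glucose_titration", "atp_titration", "inhibitor_titration", "stability_pair"]


@dataclass
class KineticAssay:
    """One titration (or stability pair) for one enzyme preparation.

    ``x`` are substrate/inhibitor concentrations (mM for glucose and ATP,
    uM for GlcNAc); ``rate`` are initial velocities in s^-1 per enzyme.
    """

    assay_kind: AssayKind
    x: np.ndarray
    rate: np.ndarray
    variant: str = ""
    glucose_mM: float | None = None
    atp_mM: float | None = None
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.x.shape != self.rate.shape:
            raise ValueError("x and rate must have equal length")
        if np.any(self.x < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")
        if self.assay_kind != "stability_pair" and np.unique(self.x).size < 5:
            raise ValueError(
                f"{self.assay_kind} needs >= 5 distinct concentrations, "
                f"got {np.unique(self.x).size}"
            )


@dataclass
class CensoredValue:
    """A number that may only be known as a bound (Table-1-style censoring).

    ``censor`` is None for an observed value, "lt" for "< value" and
    "ge" for ">= value".
    """

    value: float
    censor: Literal["lt", "ge"] | None = None

    @property
    def censored(self) -> bool:
        return self.censor is not None

    def __str__(self) -> str:
        if self.censor == "lt":
            return f"<{self.value:g}"
        if self.censor == "ge":
            return f">={self.value:g}"
        return f"{self.value:g}"


@dataclass
class KineticParams:
    """Fitted kinetic constants for one protein variant."""

    name: str = ""
    s05: float | None = None           # mM glucose, at the reference ATP
    n_h: float | None = None           # Hill coefficient
    kcat: float | None = None          # s^-1
    km_atp: float | None = None        # mM ATP (at S0.5 unless noted)
    s05_low_atp: float | None = None   # mM glucose at 500 uM ATP
    km_atp_50mM: float | None = None   # mM ATP at 50 mM glucose
    stability_pct: float | None = None
    ic50_glcnac: float | None = None   # uM
    se: dict = field(default_factory=dict)
    no_activity: bool = False

    def __post_init__(self) -> None:
        if self.no_activity:
            return
        if self.s05 is not None and self.s05 <= 0:
            raise ValueError("s05 must be > 0")
        if self.n_h is not None and not (0.5 < self.n_h < 4):
            raise ValueError("n_h must lie in (0.5, 4)")
        if self.kcat is not None and self.kcat < 0:
            raise ValueError("kcat must be >= 0")
        if self.km_atp is not None and self.km_atp <= 0:
            raise ValueError("km_atp must be > 0")

    @property
    def complete(self) -> bool:
        return (
            not self.no_activity
            and None not in (self.s05, self.n_h, self.kcat, self.km_atp)
        )


@dataclass(frozen=True)
class BetaCellModelConfig:
    """Constants of the heterozygous beta-cell threshold model."""

    g_ref: float = 5.0        # mM glucose, wild-type GSIR setpoint
    atp_mM: float = 2.5       # intracellular ATP at the operating point
    gsirt_cap: float = 7.1    # mM; censor GSIR-T at/above this ("null allele")
    rai_floor: float = 0.01   # censor RAI below this ("<0.01")
    het_fraction: float = 0.5  # allele dose of each allele in the heterozygote
    compensation: float = 1.0  # multiplier on the wild-type allele's activity
    tol_mM: float = 1e-6      # bisection tolerance

    def __post_init__(self) -> None:
        if self.g_ref <= 0:
            raise ValueError("g_ref must be > 0")
        if self.gsirt_cap <= self.g_ref:
            raise ValueError("gsirt_cap must exceed g_ref")
        if not (0 < self.het_fraction <= 1):
            raise ValueError("het_fraction must lie in (0, 1]")
        if self.tol_mM <= 0:
            raise ValueError("tol_mM must be > 0")


def activity(params: KineticParams, glucose: float, atp: float) -> float:
    """Phosphorylation rate (s^-1) at the given glucose and ATP (mM).

    Hill glucose dependence times a Michaelis ATP factor; a ``no_activity``
    variant contributes zero.  ``km_atp = 0`` means ATP-saturated.
    """
    if params.no_activity:
        return 0.0
    if None in (params.s05, params.n_h, params.kcat):
        raise ValueError(f"variant {params.name!r}: incomplete parameters for activity()")
    if glucose < 0:
        raise ValueError("glucose must be >= 0")
    if atp <= 0:
        raise ValueError("atp must be > 0")
    if glucose == 0:
        return 0.0
    km = params.km_atp if params.km_atp is not None else 0.0
    gl = glucose ** params.n_h
    return params.kcat * gl / (params.s05 ** params.n_h + gl) * atp / (atp + km)


@dataclass
class FitResult:
    """Parameter estimates with standard errors and convergence diagnostics."""

    params: dict
    se: dict
    converged: bool
    no_activity: bool = False
    censor: Literal["gt"] | None = None  # used by IC50 when no inhibition seen
    message: str = ""


def _curve_fit(model, x, y, p0, bounds):
    popt, pcov = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=20000)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return popt, perr


def fit_hill(assay: KineticAssay, detection_limit: float = 0.0) -> FitResult:
    """Fit v = vmax * x^n / (s05^n + x^n) to a glucose titration.

    Rates are per-enzyme turnovers, so ``vmax`` is ``kcat`` directly.
    A curve whose maximum rate does not exceed ``detection_limit``
    (e.g., twice the blank SD) is flagged ``no_activity`` and not fitted.
    """
    if assay.assay_kind != "glucose_titration":
        raise ValueError("fit_hill requires a glucose_titration assay")
    x, y = assay.x, assay.rate
    if float(np.max(y)) <= detection_limit:
        return FitResult({}, {}, converged=False, no_activity=True,
                         message="no activity above detection limit")

    vmax0 = float(np.max(y))
    half = vmax0 / 2.0
    s05_0 = float(x[np.argmin(np.abs(y - half))])
    s05_0 = max(s05_0, float(np.min(x[x > 0], initial=1.0)))
    p0 = [s05_0, 1.5, vmax0]
    bounds = ([1e-9, 0.5, 1e-12], [np.inf, 4.0, np.inf])

    def model(g, s05, n, vmax):
        g = np.asarray(g, dtype=float)
        gl = np.power(g, n, where=g > 0, out=np.zeros_like(g))
        return vmax * gl / (s05 ** n + gl)

    try:
        (s05, n, vmax), (se_s05, se_n, se_v) = _curve_fit(model, x, y, p0, bounds)
    except RuntimeError as exc:
        return FitResult({}, {}, converged=False, message=f"non-convergence: {exc}")
    return FitResult(
        {"s05": float(s05), "n_h": float(n), "vmax": float(vmax), "kcat": float(vmax)},
        {"s05": float(se_s05), "n_h": float(se_n), "vmax": float(se_v)},
        converged=True,
    )


def fit_michaelis(assay: KineticAssay, detection_limit: float = 0.0) -> FitResult:
    """Fit v = vmax * x / (km + x) to an ATP titration at fixed glucose."""
    if assay.assay_kind != "atp_titration":
        raise ValueError("fit_michaelis requires an atp_titration assay")
    x, y = assay.x, assay.rate
    if float(np.max(y)) <= detection_limit:
        return FitResult({}, {}, converged=False, no_activity=True,
                         message="no activity above detection limit")
    vmax0 = float(np.max(y))
    km0 = float(x[np.argmin(np.abs(y - vmax0 / 2))]) or float(np.median(x))

    def model(a, km, vmax):
        return vmax * a / (km + a)

    try:
        (km, vmax), (se_km, se_v) = _curve_fit(
            model, x, y, [max(km0, 1e-6), vmax0], ([1e-12, 1e-12], [np.inf, np.inf])
        )
    except RuntimeError as exc:
        return FitResult({}, {}, converged=False, message=f"non-convergence: {exc}")
    return FitResult(
        {"km": float(km), "vmax": float(vmax), "glucose_mM": assay.glucose_mM},
        {"km": float(se_km), "vmax": float(se_v)},
        converged=True,
    )


def fit_ic50(assay: KineticAssay) -> FitResult:
    """Four-parameter logistic fit of an inhibitor titration.

    The top plateau is constrained to the uninhibited (dose-0) rate.  If the
    rates do not decrease with dose the result is censored as
    "IC50 > max dose".
    """
    if assay.assay_kind != "inhibitor_titration":
        raise ValueError("fit_ic50 requires an inhibitor_titration assay")
    x, y = assay.x, assay.rate
    if 0.0 not in x:
        raise ValueError("inhibitor titration must include a zero dose")
    top = float(np.mean(y[x == 0]))
    xmax = float(np.max(x))
    # no inhibition: mean rate at the two highest doses not below 90% of top
    hi = y[np.argsort(x)][-2:]
    if float(np.mean(hi)) >= 0.9 * top:
        return FitResult({"ic50": xmax}, {}, converged=True, censor="gt",
                         message="no inhibition detected; IC50 censored above max dose")

    def model(d, ic50, hill, bottom):
        d = np.asarray(d, dtype=float)
        with np.errstate(over="ignore"):
            frac = np.where(d > 0, 1.0 / (1.0 + (d / ic50) ** hill), 1.0)
        return bottom + (top - bottom) * frac

    p0 = [float(np.median(x[x > 0])), 1.0, float(np.min(y))]
    bounds = ([1e-9, 0.2, 0.0], [np.inf, 10.0, top])
    try:
        (ic50, hill, bottom), (se_ic50, se_h, se_b) = _curve_fit(model, x, y, p0, bounds)
    except RuntimeError as exc:
        return FitResult({}, {}, converged=False, message=f"non-convergence: {exc}")
    return FitResult(
        {"ic50": float(ic50), "hill": float(hill), "bottom": float(bottom), "top": top},
        {"ic50": float(se_ic50), "hill": float(se_h), "bottom": float(se_b)},
        converged=True,
    )


def stability_index(rate_incubated: float, rate_control: float) -> float:
    """Residual activity after incubation, percent of the unincubated control."""
    if rate_control <= 0:
        raise ValueError("control rate must be > 0")
    if rate_incubated < 0:
        raise ValueError("incubated rate must be >= 0")
    return 100.0 * rate_incubated / rate_control


def compute_rai(
    var: KineticParams, wt: KineticParams, cfg: BetaCellModelConfig | None = None
) -> CensoredValue:
    """Relative activity index at the physiological operating point.

    RAI = A_var(g_ref, atp) / A_wt(g_ref, atp).  Values below
    ``cfg.rai_floor`` (including no-activity alleles) are censored "<0.01".
    """
    cfg = cfg or BetaCellModelConfig()
    if not wt.complete:
        raise ValueError("wild-type parameters must be complete")
    if not var.no_activity and not var.complete:
        raise ValueError(
            f"variant {var.name!r} has incomplete parameters and no no_activity flag"
        )
    a_wt = activity(wt, cfg.g_ref, cfg.atp_mM)
    a_var = activity(var, cfg.g_ref, cfg.atp_mM)
    rai = a_var / a_wt
    if rai < cfg.rai_floor:
        return CensoredValue(cfg.rai_floor, censor="lt")
    return CensoredValue(rai)


def gsir_threshold(
    var: KineticParams, wt: KineticParams, cfg: BetaCellModelConfig | None = None
) -> CensoredValue:
    """Glucose level restoring the wild-type reference rate in a heterozygote.

    Solves ``het*comp*A_wt(G) + het*A_var(G) = A_wt(g_ref)`` for the smallest
    root G* > 0 by bracket expansion and bisection, reports it rounded to
    0.1 mM, and censors results at or above ``gsirt_cap`` as ">=7.1".
    An identical variant returns exactly ``g_ref``.
    """
    cfg = cfg or BetaCellModelConfig()
    if not wt.complete:
        raise ValueError("wild-type parameters must be complete")
    if not var.no_activity and not var.complete:
        raise ValueError(
            f"variant {var.name!r} has incomplete parameters and no no_activity flag"
        )
    target = activity(wt, cfg.g_ref, cfg.atp_mM)

    def f(g: float) -> float:
        combined = cfg.het_fraction * (
            cfg.compensation * activity(wt, g, cfg.atp_mM) + activity(var, g, cfg.atp_mM)
        )
        return combined - target

    if (
        var.s05 == wt.s05 and var.n_h == wt.n_h and var.kcat == wt.kcat
        and var.km_atp == wt.km_atp and cfg.compensation == 1.0
        and cfg.het_fraction == 0.5
    ):
        return CensoredValue(cfg.g_ref)

    lo, hi = 0.1, 50.0
    while f(lo) > 0 and lo > 0.01:
        lo = max(lo / 2.0, 0.01)
    while f(hi) < 0 and hi < 500.0:
        hi = min(hi * 2.0, 500.0)
    if f(lo) > 0 or f(hi) < 0:
        # combined activity never reaches the wild-type setpoint rate
        return CensoredValue(cfg.gsirt_cap, censor="ge")
    root = optimize.bisect(f, lo, hi, xtol=cfg.tol_mM)
    rounded = round(root, 1)
    if rounded >= cfg.gsirt_cap:
        return CensoredValue(cfg.gsirt_cap, censor="ge")
    return CensoredValue(rounded)
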