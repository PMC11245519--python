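"""Quantitative binding-assay analysis: ITC one-site fits and TSA Tm calls.

Isothermal titration calorimetry (ITC): serial injections of ligand
(syringe concentration X0) into protein (cell concentration M0, active
volume V0) release heats that trace out a binding isotherm.  Raw heats are
corrected for ligand-dilution heats, normalised per mole of injectant,
the first (small, partially mixed) injection is dropped, and the remaining
points are fitted with the single-site total-heat model:

    Mt_i = M0 (1 - dV_i/2V0) / (1 + dV_i/2V0)
    Xt_i = X0 (dV_i/V0)     / (1 + dV_i/2V0)
    Q_i  = (n Mt_i ΔH V0 / 2) [ b_i - sqrt(b_i² - 4 Xt_i / (n Mt_i)) ]
    b_i  = 1 + Xt_i/(n Mt_i) + 1/(n K_A Mt_i)
    ΔQ_i = Q_i - Q_{i-1} + (v_i/V0)(Q_i + Q_{i-1})/2

where dV_i is the cumulative injected volume, n the stoichiometry, K_A
the association constant (K_D = 1/K_A) and ΔH the molar binding enthalpy.
The displaced-volume corrections are the standard single-cell
perfusion-calorimeter conventions.

Units: raw heats in µcal, volumes in litres, concentrations in mol/L,
ΔH reported in kcal/mol, K_D in mol/L.

Thermal shift assays (TSA/DSF): the melting temperature Tm is the maximum
of the smoothed first derivative of fluorescence over temperature; a
ligand-induced increase of more than 2 °C over the apo protein counts as a
significant (binding-indicative) shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

KCAL_TO_UCAL = 1e9
CAL_TO_KCAL = 1e-3

#: default active cell volume (L) of a single-cell perfusion calorimeter
DEFAULT_CELL_VOLUME = 1.4e-3


@dataclass
class TitrationSeries:
    """Protocol and per-injection heats of one ITC experiment."""

    cell_volume: float  # L
    cell_conc_M0: float  # mol/L protein in the cell
    syringe_conc_X0: float  # mol/L ligand in the syringe
    injection_volumes: list[float]  # L
    raw_heats: list[float]  # µcal per injection
    dilution_heats: list[float] | float | None = None  # µcal (list or scalar mean)

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.cell_conc_M0 <= 0 or self.syringe_conc_X0 <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")
        if len(self.raw_heats) != len(self.injection_volumes):
            raise ValueError("raw_heats and injection_volumes must have equal length")
        if self.dilution_heats is not None and not np.isscalar(self.dilution_heats):
            if len(np.atleast_1d(self.dilution_heats)) != len(self.raw_heats):
                raise ValueError("dilution heat list must match the number of injections")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def molar_ratios(self) -> np.ndarray:
        """Cumulative ligand/protein molar ratio Xt/Mt after each injection."""
        _, mt, xt = _displaced_concentrations(
            self.cell_volume, self.cell_conc_M0, self.syringe_conc_X0, self.injection_volumes
        )
        return xt / mt


@dataclass
class CorrectedSeries:
    """Dilution-corrected, per-mole-normalised heats (kcal/mol injectant)."""

    series: TitrationSeries
    normalized: np.ndarray  # kcal per mol injectant, all injections
    first_dropped: int = 1  # leading injections excluded from fitting
    dilution_missing: bool = False

    @property
    def usable(self) -> np.ndarray:
        return self.normalized[self.first_dropped :]


@dataclass
class OneSiteFit:
    kd: float  # mol/L
    kd_se: float
    dh: float  # kcal/mol
    dh_se: float
    n: float
    n_se: float
    residual_norm: float
    converged: bool
    outcome: str = "ok"  # {"ok", "no binding detectable", "not converged"}

    def to_mapping(self) -> dict:
        return {
            "kd": self.kd,
            "kd_se": self.kd_se,
            "dh": self.dh,
            "dh_se": self.dh_se,
            "n": self.n,
            "n_se": self.n_se,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "outcome": self.outcome,
        }


@dataclass
class FoldChange:
    ratio: float
    rounded: int


@dataclass
class MeltCurve:
    """A fluorescence-vs-temperature unfolding trace."""

    temperatures: np.ndarray  # °C, strictly increasing
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.size != self.fluorescence.size:
            raise ValueError("temperature and fluorescence lengths differ")
        if self.temperatures.size < 10:
            raise ValueError("melt curve needs at least 10 points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class TmCall:
    tm: float | None  # °C; None when no transition detected
    derivative_peak_height: float
    transition: bool
    significant_vs_reference: bool | None = None

    def to_mapping(self) -> dict:
        return {
            "tm": self.tm,
            "derivative_peak_height": self.derivative_peak_height,
            "transition": self.transition,
            "significant_vs_reference": self.significant_vs_reference,
        }


# ---------------------------------------------------------------------------
# ITC model


def _displaced_concentrations(
    v0: float, m0: float, x0: float, volumes: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dv = np.cumsum(np.asarray(volumes, dtype=float))
    mt = m0 * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
    xt = x0 * (dv / v0) / (1 + dv / (2 * v0))
    return dv, mt, xt


def one_site_heats(
    v0: float,
    m0: float,
    x0: float,
    volumes: Sequence[float],
    n: float,
    ka: float,
    dh_kcal: float,
) -> np.ndarray:
    """Per-injection heats (kcal/mol injectant) of the one-site model."""
    volumes = np.asarray(volumes, dtype=float)
    _, mt, xt = _displaced_concentrations(v0, m0, x0, volumes)
    dh_cal = dh_kcal * 1e3
    b = 1 + xt / (n * mt) + 1 / (n * ka * mt)
    disc = np.maximum(b * b - 4 * xt / (n * mt), 0.0)
    q = (n * mt * dh_cal * v0 / 2) * (b - np.sqrt(disc))  # cal
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (volumes / v0) * (q + q_prev) / 2
    per_mole = dq / (x0 * volumes)  # cal per mol injectant
    return per_mole * CAL_TO_KCAL


def correct_and_normalize(series: TitrationSeries) -> CorrectedSeries:
    """Subtract dilution heats, normalise per mole injectant, drop injection 1.

    Missing dilution data proceeds with zero correction and sets a warning
    flag.  The first injection stays in the record but is excluded from
    fitting (standard practice for the small lead-off injection).
    """
    raw = np.asarray(series.raw_heats, dtype=float)
    missing = series.dilution_heats is None
    if missing:
        dil = np.zeros_like(raw)
    elif np.isscalar(series.dilution_heats):
        dil = np.full_like(raw, float(series.dilution_heats))
    else:
        dil = np.asarray(series.dilution_heats, dtype=float)
    corrected_ucal = raw - dil
    moles = series.syringe_conc_X0 * np.asarray(series.injection_volumes)
    normalized = corrected_ucal * 1e-6 / moles * CAL_TO_KCAL  # µcal -> kcal/mol
    return CorrectedSeries(series, normalized, first_dropped=1, dilution_missing=missing)


def _no_binding(corrected: CorrectedSeries) -> bool:
    """Flat-signal heuristic mirroring the 'no binding observed' call."""
    h = corrected.usable
    span = float(np.ptp(h)) if h.size else 0.0
    if span == 0.0:
        return True
    # compare the isotherm's span against point-to-point scatter
    noise = float(np.median(np.abs(np.diff(h)))) if h.size > 2 else 0.0
    return span < 3 * noise or span < 1e-6 * max(1.0, float(np.max(np.abs(h))))


def fit_one_site(
    series: TitrationSeries,
    init: tuple[float, float, float] | None = None,
) -> OneSiteFit:
    """Least-squares fit of the one-site model to a corrected titration.

    ``init`` optionally supplies (n, K_A, ΔH_kcal) starting values;
    otherwise three deterministic starts are tried (a c≈10 heuristic,
    an n = 1 start, and the best of a log-spaced K_A grid) and the best
    final residual wins.  Standard errors are asymptotic (from the
    Jacobian at the optimum).
    """
    corrected = correct_and_normalize(series)
    h = corrected.usable
    if h.size < 5:
        raise ValueError("need at least 5 usable injections after dropping the first")
    if _no_binding(corrected):
        return OneSiteFit(
            np.inf, np.nan, 0.0, np.nan, np.nan, np.nan,
            float(np.linalg.norm(h)), False, outcome="no binding detectable",
        )

    v0, m0, x0 = series.cell_volume, series.cell_conc_M0, series.syringe_conc_X0
    vols = series.injection_volumes

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_ka, dh, n = theta
        model = one_site_heats(v0, m0, x0, vols, n, 10.0 ** log_ka, dh)
        return model[corrected.first_dropped :] - h

    dh0 = float(h[np.argmax(np.abs(h))])
    starts: list[np.ndarray]
    if init is not None:
        n0, ka0, dh_init = init
        starts = [np.array([np.log10(ka0), dh_init, n0])]
    else:
        starts = [
            np.array([np.log10(10.0 / m0), dh0, 1.0]),  # c ≈ 10 heuristic
            np.array([np.log10(1.0 / m0), dh0, 1.0]),  # weak-binding start
        ]
        grid = [10.0 ** e for e in (3, 4, 5, 6, 7, 8)]
        best_ka = min(
            grid,
            key=lambda ka: float(
                np.sum(residuals(np.array([np.log10(ka), dh0, 1.0])) ** 2)
            ),
        )
        starts.append(np.array([np.log10(best_ka), dh0, 1.0]))

    lo = np.array([0.0, -1e4, 1e-2])
    hi = np.array([14.0, 1e4, 1e2])
    best_res = None
    for x_start in starts:
        x_start = np.clip(x_start, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(residuals, x_start, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best_res is None or res.cost < best_res.cost:
            best_res = res
    if best_res is None or not best_res.success:
        return OneSiteFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            np.nan, False, outcome="not converged",
        )

    log_ka, dh, n = best_res.x
    ka = 10.0 ** log_ka
    kd = 1.0 / ka
    dof = max(h.size - 3, 1)
    s2 = 2 * best_res.cost / dof
    jac = best_res.jac
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    se_ka = np.log(10.0) * ka * se[0]
    kd_se = se_ka / ka**2
    return OneSiteFit(
        kd=float(kd),
        kd_se=float(kd_se),
        dh=float(dh),
        dh_se=float(se[1]),
        n=float(n),
        n_se=float(se[2]),
        residual_norm=float(np.sqrt(2 * best_res.cost)),
        converged=True,
    )


def fold_reduction(kd_mutant: float, kd_reference: float) -> FoldChange:
    """Affinity fold-change of a mutant relative to the reference protein.

    The ratio is rounded half-away-from-zero to the printed integer.
    """
    if kd_mutant <= 0 or kd_reference <= 0:
        raise ValueError("dissociation constants must be positive")
    ratio = kd_mutant / kd_reference
    rounded = int(np.floor(ratio + 0.5))
    return FoldChange(ratio=ratio, rounded=rounded)


# ---------------------------------------------------------------------------
# thermal shift assays


def call_tm(curve: MeltCurve, smoothing_window: int = 7, noise_factor: float = 3.0) -> TmCall:
    """Melting temperature from the first derivative of fluorescence.

    The trace is moving-average smoothed (odd ``smoothing_window``), the
    derivative taken by central differences, and Tm read at the derivative
    maximum over the interior (the first and last window excluded).  When
    the peak does not rise above ``noise_factor`` × the median absolute
    derivative the curve is called "no transition" (flat or pure drift).
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    t = curve.temperatures
    f = curve.fluorescence
    w = smoothing_window
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        fp = np.pad(f, pad, mode="edge")
        f_smooth = np.convolve(fp, kernel, mode="valid")
    else:
        f_smooth = f
    deriv = np.gradient(f_smooth, t)
    interior = slice(w, len(t) - w)
    d_int = deriv[interior]
    t_int = t[interior]
    if d_int.size == 0:
        return TmCall(None, 0.0, False)
    peak_idx = int(np.argmax(d_int))
    peak = float(d_int[peak_idx])
    floor = noise_factor * float(np.median(np.abs(d_int)))
    if peak <= floor or peak <= 0:
        return TmCall(None, peak, False)
    return TmCall(float(t_int[peak_idx]), peak, True)


def screen_delta_tm(tm_ligand: float, tm_apo: float, threshold: float = 2.0) -> bool:
    """Significant iff the ligand raises Tm by strictly more than ``threshold`` °C."""
    return (tm_ligand - tm_apo) > threshold
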