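"""Noncompartmental analysis of concentration-time profiles.

Implements the standard extravascular NCA parameter set: C_peak and T_max by
direct maximum, linear-trapezoid AUC, terminal slope lambda_z by log-linear
regression with automatic terminal-point selection (best adjusted R^2 over
the last 3-6 points after T_max), extrapolated AUC(0-inf), and the
bioavailability-scaled clearance and distribution volume

    Cl_tot = F * dose / AUC(0-inf),    V_d = Cl_tot / lambda_z,

with F = 0.60 for erlotinib unless stated otherwise. V_d is the terminal
(lambda_z-based) volume, consistent with the Cl/lambda_z arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import ConcTimeProfile


@dataclass
class NCAResult:
    C_peak: float  # ug/ml
    T_max: float  # h
    C_last: float  # ug/ml
    C_trough: Optional[float]  # ug/ml at 24 h (pre-dose of next day)
    AUC_0_24: Optional[float]  # ug*h/ml
    AUC_0_last: float  # ug*h/ml
    AUC_0_inf: Optional[float]  # ug*h/ml
    lambda_z: Optional[float]  # 1/h
    T_half_el: Optional[float]  # h
    V_d: Optional[float]  # l
    Cl_tot: Optional[float]  # l/h
    n_lambda_z: int = 0
    lambda_z_r2adj: Optional[float] = None


def trapezoid_auc(times: np.ndarray, conc: np.ndarray,
                  t_end: Optional[float] = None) -> float:
    """Linear-trapezoid AUC over observed points, optionally cut at t_end.

    A cut point inside the sampled range is interpolated linearly, so the
    AUC is invariant under insertion of points on the linear interpolant.
    """
    times = np.asarray(times, float)
    conc = np.asarray(conc, float)
    if t_end is not None:
        if t_end > times[-1] + 1e-9:
            raise ValueError("t_end beyond the sampled range")
        c_end = float(np.interp(t_end, times, conc))
        keep = times < t_end - 1e-12
        times = np.append(times[keep], t_end)
        conc = np.append(conc[keep], c_end)
    return float(np.trapezoid(conc, times))


def _loglinear_fit(t: np.ndarray, c: np.ndarray):
    """OLS fit of ln(c) on t; returns (slope, intercept, r2_adjusted)."""
    y = np.log(c)
    n = len(t)
    slope, intercept = np.polyfit(t, y, 1)
    yhat = slope * t + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return slope, intercept, -np.inf
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, intercept, r2_adj


def select_lambda_z(times: np.ndarray, conc: np.ndarray):
    """Automatic terminal-slope selection.

    Candidate sets are the last k = 3..6 positive-concentration points
    strictly after T_max; the set with the best adjusted R^2 and a negative
    slope wins. Returns (lambda_z, n_points, r2_adj) or (None, 0, None).
    """
    times = np.asarray(times, float)
    conc = np.asarray(conc, float)
    i_max = int(np.argmax(conc))
    mask = (np.arange(len(times)) > i_max) & (conc > 0)
    t_tail, c_tail = times[mask], conc[mask]
    best = None
    for k in range(3, 7):
        if len(t_tail) < k:
            break
        slope, _, r2_adj = _loglinear_fit(t_tail[-k:], c_tail[-k:])
        if slope < 0 and (best is None or r2_adj > best[2]):
            best = (-slope, k, r2_adj)
    if best is None:
        return None, 0, None
    return best


def compute_nca(profile: ConcTimeProfile, dose: float,
                F: float = 0.60) -> NCAResult:
    """Noncompartmental parameters of a single-dose profile.

    Requires at least three samples, two of them positive. When fewer than
    three declining terminal points exist, lambda_z and its dependent
    parameters (T_half, AUC(0-inf), Cl_tot, V_d) are None.
    """
    t = np.asarray(profile.times, float)
    c = np.asarray(profile.plasma_conc, float)
    if len(c) < 3 or np.sum(c > 0) < 2:
        raise ValueError("need >= 3 samples with >= 2 positive concentrations")
    i_max = int(np.argmax(c))
    c_peak, t_max = float(c[i_max]), float(t[i_max])
    # last positive observation
    i_last = int(np.max(np.nonzero(c > 0)))
    c_last, t_last = float(c[i_last]), float(t[i_last])
    auc_last = float(np.trapezoid(c[:i_last + 1], t[:i_last + 1]))
    auc24 = (trapezoid_auc(t, c, t_end=min(24.0, t[-1]))
             if t[-1] >= 24.0 - 1e-9 else None)
    c_trough = profile.at(24.0) if t[-1] >= 24.0 - 1e-9 else None

    lam, n_lam, r2 = select_lambda_z(t, c)
    t_half = auc_inf = cl = vd = None
    if lam is not None:
        t_half = float(np.log(2.0) / lam)
        auc_inf = auc_last + c_last / lam
        cl = F * dose / auc_inf  # (ug/ml * h) -> l/h with dose in mg
        vd = cl / lam
    return NCAResult(
        C_peak=c_peak, T_max=t_max, C_last=c_last, C_trough=c_trough,
        AUC_0_24=auc24, AUC_0_last=auc_last, AUC_0_inf=auc_inf,
        lambda_z=lam, T_half_el=t_half, V_d=vd, Cl_tot=cl,
        n_lambda_z=n_lam, lambda_z_r2adj=r2)
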