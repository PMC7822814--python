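"""Saturation-recovery T1 fitting and PO2 conversion per placenta ROI.

The two-parameter model fitted to the per-ROI mean SNR curve is

    SNR(TR) = S0 * (1 - exp(-TR / T1))

by trust-region nonlinear least squares with bounds S0 > 0 and
T1 in (0.05, 30] s, initialized at S0 = SNR(TR_max), T1 = 1.5 s.  Fits are
ROI-mean based (voxel-wise PO2 is dominated by error propagation); no TR
weighting is applied by default.  PO2 follows from the fitted T1 via the
PFCE calibration; physically impossible values (< 0 or > 760 mmHg) are kept
and flagged rather than censored.

A multi-exponential variant fits a sum of compartment curves; with only a
few TRs it is generally non-identifiable, which the bootstrap confidence
intervals are there to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .calibration import DEFAULT_CALIBRATION, OxygenCalibration, t1_to_po2
from .synthetic import saturation_recovery_signal

__all__ = [
    "SatRecFit",
    "MultiExpFit",
    "fit_saturation_recovery",
    "fit_multiexponential",
    "records_from_fits",
    "PLACENTA_RECORD_COLUMNS",
]

T1_BOUNDS_S = (0.05, 30.0)
T1_INIT_S = 1.5
PO2_PHYSIOLOGICAL_RANGE = (0.0, 760.0)


@dataclass(frozen=True)
class SatRecFit:
    """Result of one saturation-recovery fit."""

    s0: float
    t1_s: float
    rss: float
    residuals: np.ndarray
    converged: bool
    message: str = ""

    def predict(self, tr_ms) -> np.ndarray:
        return saturation_recovery_signal(tr_ms, self.s0, self.t1_s)


def fit_saturation_recovery(
    snr_means,
    tr_list_ms,
    weights=None,
) -> SatRecFit:
    """Fit (S0, T1) to a per-ROI mean SNR curve.

    Requires >= 3 finite (TR, SNR) points.  A degenerate all-zero curve (or
    optimizer failure) yields a flagged, non-converged record rather than an
    exception.  ``weights`` optionally gives per-TR weights for weighted
    least squares (default: ordinary least squares).
    """
    snr = np.asarray(snr_means, dtype=float)
    tr = np.asarray(tr_list_ms, dtype=float)
    if snr.size != tr.size:
        raise ValueError("snr_means and tr_list_ms must align")
    if snr.size < 3:
        raise ValueError("need at least 3 (TR, SNR) points for a 2-parameter fit")
    if not np.all(np.isfinite(snr)) or not np.all(np.isfinite(tr)):
        raise ValueError("SNR and TR values must be finite")
    w = np.ones_like(snr) if weights is None else np.sqrt(np.asarray(weights, float))

    if np.all(snr <= 0):
        return SatRecFit(
            s0=np.nan, t1_s=np.nan, rss=np.nan,
            residuals=np.full_like(snr, np.nan), converged=False,
            message="all-zero SNR curve",
        )

    order = np.argsort(tr)
    tr_sorted, snr_sorted, w_sorted = tr[order], snr[order], w[order]
    s0_init = max(snr_sorted[-1], 1e-6)

    def resid(p):
        return w_sorted * (
            saturation_recovery_signal(tr_sorted, p[0], p[1]) - snr_sorted
        )

    try:
        sol = least_squares(
            resid,
            x0=[s0_init, T1_INIT_S],
            bounds=([1e-9, T1_BOUNDS_S[0]], [np.inf, T1_BOUNDS_S[1]]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
    except Exception as exc:  # optimizer failure -> flagged record
        return SatRecFit(
            s0=np.nan, t1_s=np.nan, rss=np.nan,
            residuals=np.full_like(snr, np.nan), converged=False, message=str(exc),
        )

    res_unsorted = np.empty_like(snr)
    res_unsorted[order] = sol.fun / np.where(w_sorted == 0, 1, w_sorted)
    return SatRecFit(
        s0=float(sol.x[0]),
        t1_s=float(sol.x[1]),
        rss=float(np.sum(sol.fun**2)),
        residuals=res_unsorted,
        converged=bool(sol.success),
        message=sol.message,
    )


@dataclass(frozen=True)
class MultiExpFit:
    """Multi-compartment fit: amplitudes A_c = S0*w_c*f_c and T1s per pool."""

    amplitudes: np.ndarray
    t1_s: np.ndarray
    rss: float
    converged: bool
    bootstrap_ci: pd.DataFrame | None = None   # per-parameter 2.5/97.5% bounds
    message: str = ""

    def predict(self, tr_ms) -> np.ndarray:
        tr = np.asarray(tr_ms, dtype=float)
        out = np.zeros_like(tr)
        for a, t1 in zip(self.amplitudes, self.t1_s):
            out += saturation_recovery_signal(tr, a, t1)
        return out


def _multiexp_curve(tr, amps, t1s):
    out = np.zeros_like(tr)
    for a, t1 in zip(amps, t1s):
        out += saturation_recovery_signal(tr, a, t1)
    return out


def fit_multiexponential(
    snr_means,
    tr_list_ms,
    n_compartments: int,
    fixed_fractions=None,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> MultiExpFit:
    """Fit a sum of saturation-recovery compartments.

    With free amplitudes the model has ``2 * n_compartments`` parameters and
    needs at least one more data point than that; with ``fixed_fractions``
    the amplitudes share a single scale (``n_compartments + 1`` parameters).
    Residual-bootstrap confidence intervals (``n_bootstrap`` > 0) quantify
    identifiability: at few TRs they are typically so wide the fit carries
    no compartment-level information.
    """
    snr = np.asarray(snr_means, dtype=float)
    tr = np.asarray(tr_list_ms, dtype=float)
    k = int(n_compartments)
    if k < 1:
        raise ValueError("need at least one compartment")
    if fixed_fractions is not None:
        frac = np.asarray(fixed_fractions, dtype=float)
        if frac.size != k or np.any(frac < 0) or abs(frac.sum() - 1) > 1e-9:
            raise ValueError("fixed fractions must be nonnegative and sum to 1")
        n_params = k + 1
    else:
        frac = None
        n_params = 2 * k
    if snr.size < n_params:
        raise ValueError(
            f"{snr.size} points cannot determine {n_params} parameters; "
            "supply fixed fractions or more TRs"
        )
    if fixed_fractions is None and snr.size < 2 * k + 1:
        raise ValueError(
            f"free-amplitude fit needs >= {2 * k + 1} points; "
            "supply fixed fractions or more TRs"
        )

    order = np.argsort(tr)
    tr_s, snr_s = tr[order], snr[order]
    t1_init = np.geomspace(0.3, 3.0, k)
    s0_init = max(snr_s[-1], 1e-6)

    def unpack(p):
        if frac is not None:
            return p[0] * frac, p[1:]
        return p[:k], p[k:]

    def fit_once(y):
        def resid(p):
            amps, t1s = unpack(p)
            return _multiexp_curve(tr_s, amps, t1s) - y

        if frac is not None:
            x0 = np.concatenate([[s0_init], t1_init])
            lb = np.concatenate([[1e-9], np.full(k, T1_BOUNDS_S[0])])
            ub = np.concatenate([[np.inf], np.full(k, T1_BOUNDS_S[1])])
        else:
            x0 = np.concatenate([np.full(k, s0_init / k), t1_init])
            lb = np.concatenate([np.full(k, 1e-9), np.full(k, T1_BOUNDS_S[0])])
            ub = np.concatenate([np.full(k, np.inf), np.full(k, T1_BOUNDS_S[1])])
        return least_squares(resid, x0=x0, bounds=(lb, ub), method="trf",
                             xtol=1e-12, ftol=1e-12)

    sol = fit_once(snr_s)
    amps, t1s = unpack(sol.x)

    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        fitted = _multiexp_curve(tr_s, amps, t1s)
        resid0 = snr_s - fitted
        draws = []
        for _ in range(n_bootstrap):
            y_b = fitted + rng.choice(resid0, size=resid0.size, replace=True)
            try:
                sb = fit_once(y_b)
                a_b, t_b = unpack(sb.x)
                draws.append(np.concatenate([a_b, t_b]))
            except Exception:
                continue
        if draws:
            draws = np.asarray(draws)
            names = [f"A{i+1}" for i in range(k)] + [f"T1_{i+1}" for i in range(k)]
            ci = pd.DataFrame(
                {
                    "parameter": names,
                    "estimate": np.concatenate([amps, t1s]),
                    "ci_lo": np.percentile(draws, 2.5, axis=0),
                    "ci_hi": np.percentile(draws, 97.5, axis=0),
                }
            )

    return MultiExpFit(
        amplitudes=np.asarray(amps, dtype=float),
        t1_s=np.asarray(t1s, dtype=float),
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
        bootstrap_ci=ci,
        message=sol.message,
    )


PLACENTA_RECORD_COLUMNS = [
    "mother_id", "genotype", "placenta_id", "oxygen_percent",
    "snr_tr1", "snr_tr2", "snr_tr3", "snr_tr4",
    "s0", "t1_s", "po2_mmhg", "n_voxels",
    "qc_unusable", "qc_nonconverged", "qc_po2_out_of_range",
]


def records_from_fits(
    rows: list[dict],
    calibration: OxygenCalibration = DEFAULT_CALIBRATION,
) -> pd.DataFrame:
    """Assemble the canonical per-placenta x condition record table.

    Each input row carries design fields plus ``snr_means`` (length-4 array
    or None), ``n_voxels`` and a ``fit`` (SatRecFit or None).  PO2 is
    derived from T1 via the calibration; out-of-range values are retained
    with a QC flag.
    """
    out = []
    for row in rows:
        fit: SatRecFit | None = row.get("fit")
        snr = row.get("snr_means")
        unusable = snr is None
        converged = bool(fit is not None and fit.converged)
        rec = {
            "mother_id": row["mother_id"],
            "genotype": row["genotype"],
            "placenta_id": row["placenta_id"],
            "oxygen_percent": row["oxygen_percent"],
            "n_voxels": int(row.get("n_voxels", 0)),
            "qc_unusable": unusable,
            "qc_nonconverged": (not unusable) and (not converged),
        }
        for i in range(4):
            rec[f"snr_tr{i+1}"] = float(snr[i]) if snr is not None and len(snr) > i else np.nan
        if converged:
            po2 = t1_to_po2(fit.t1_s, calibration)
            rec.update(s0=fit.s0, t1_s=fit.t1_s, po2_mmhg=po2)
            rec["qc_po2_out_of_range"] = not (
                PO2_PHYSIOLOGICAL_RANGE[0] <= po2 <= PO2_PHYSIOLOGICAL_RANGE[1]
            )
        else:
            rec.update(s0=np.nan, t1_s=np.nan, po2_mmhg=np.nan)
            rec["qc_po2_out_of_range"] = False
        out.append(rec)
    return pd.DataFrame(out, columns=PLACENTA_RECORD_COLUMNS)
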