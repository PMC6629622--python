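"""Derived model covariates from raw monitoring tracks and dose records.

Three constructions feed the distance-regression design: principal-component
scores summarizing the (highly correlated) total midazolam and fentanyl
doses; pulse-validated oxygenation durations (hyperoxia = seconds with
SpO2 > 97%, hypoxemia = seconds with SpO2 < 90%, both strict); and the
baseline/peak transcutaneous CO2 summary (baseline averaged over a
pre-sedation window, peak over the whole procedure).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def pca_dose_scores(
    midazolam: np.ndarray | pd.Series, fentanyl: np.ndarray | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of the two standardized sedation doses.

    The doses are standardized, the 2x2 correlation matrix is
    eigen-decomposed (eigenvalues ``1 ± r``), and the scores are the
    standardized data projected onto the eigenvectors, ordered by
    descending eigenvalue. Sign convention: each loading vector's
    largest-magnitude element is positive. Returns ``(scores_1, scores_2)``;
    score variances (ddof=0) equal the eigenvalues.
    """
    m = np.asarray(midazolam, dtype=float)
    f = np.asarray(fentanyl, dtype=float)
    if m.size != f.size or m.size < 3:
        raise ValueError("need >= 3 patients with both doses")
    Z = np.column_stack([m, f])
    sd = Z.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("a dose column has zero variance")
    Z = (Z - Z.mean(axis=0)) / sd
    corr = (Z.T @ Z) / len(Z)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(2):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Z @ evecs
    return scores[:, 0], scores[:, 1]


def oxygen_durations(
    spo2: np.ndarray | pd.Series,
    pulse_detected: np.ndarray | pd.Series,
    high_thresh: float = 97.0,
    low_thresh: float = 90.0,
) -> tuple[int, int, int]:
    """Pulse-validated hyperoxia/hypoxemia durations in seconds.

    Seconds where no pulse was detected are filtered out first (oximetry is
    unreliable there); thresholds are strict: hyperoxia is SpO2 > 97,
    hypoxemia SpO2 < 90. Returns ``(hyperoxia_s, hypoxemia_s, valid_s)``.
    """
    spo2 = np.asarray(spo2, dtype=float)
    pulse = np.asarray(pulse_detected, dtype=bool)
    if spo2.shape != pulse.shape:
        raise ValueError("spo2 and pulse tracks differ in length")
    valid = spo2[pulse]
    return (
        int(np.sum(valid > high_thresh)),
        int(np.sum(valid < low_thresh)),
        int(valid.size),
    )


def tcco2_summary(
    tcco2: np.ndarray | pd.Series, baseline_window_s: int = 60
) -> tuple[float, float]:
    """Baseline (mean over the pre-sedation window, default first 60 s) and
    peak (maximum over the procedure) transcutaneous CO2 in mmHg."""
    x = np.asarray(tcco2, dtype=float)
    if x.size == 0:
        raise ValueError("empty TcCO2 track")
    w = min(max(baseline_window_s, 1), x.size)
    return float(x[:w].mean()), float(x.max())


def derive_covariates(
    monitoring: pd.DataFrame,
    covariates: pd.DataFrame,
    baseline_window_s: int = 60,
) -> pd.DataFrame:
    """Join raw per-patient covariates with the monitoring-derived ones.

    Adds ``pca_dose_1/pca_dose_2`` (cohort-level PCA of total doses),
    ``hyperoxia_s/hypoxemia_s/valid_spo2_s`` and
    ``tcco2_baseline/tcco2_peak`` per patient.
    """
    out = covariates.copy()
    s1, s2 = pca_dose_scores(out["midazolam_dose"], out["fentanyl_dose"])
    out["pca_dose_1"], out["pca_dose_2"] = s1, s2
    rows = []
    for pid, g in monitoring.groupby("patient_id", sort=True):
        hyper, hypo, valid = oxygen_durations(g["spo2"], g["pulse_detected"])
        base, peak = tcco2_summary(g["tcco2"], baseline_window_s)
        rows.append(
            {
                "patient_id": pid, "hyperoxia_s": hyper, "hypoxemia_s": hypo,
                "valid_spo2_s": valid, "tcco2_baseline": base, "tcco2_peak": peak,
            }
        )
    derived = pd.DataFrame(rows)
    derived["patient_id"] = derived["patient_id"].astype(out["patient_id"].dtype)
    return out.merge(derived, on="patient_id", how="left")
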