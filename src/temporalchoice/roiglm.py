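"""ROI-level GLM with parametric value modulation and PPI coupling analysis.

Operates on already-extracted ROI time series.  Design matrices are built by
convolving 3-second boxcars (and mean-centered parametric modulators) with
the canonical double-gamma hemodynamic response function on an oversampled
grid, then sampling at scan times.  Drift removal uses a discrete cosine
basis (default cutoff 128 s).  The PPI regressor is the element-wise product
of the (filtered, mean-centered) seed series with the value-modulated
psychological regressor — no deconvolution step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TR",
    "RoiSeries",
    "GlmFit",
    "canonical_hrf",
    "hrf_continuous",
    "build_design",
    "highpass_filter",
    "dct_basis",
    "fit_glm",
    "ppi_regressor",
    "simulate_bold",
    "ppi_session_contrast",
]

#: Scan repetition time in seconds (acquisition protocol default).
DEFAULT_TR = 2.438

# Double-gamma HRF constants: response/undershoot delays 6 s and 16 s,
# unit dispersions, undershoot ratio 1/6.
_HRF_DELAY, _HRF_UNDERSHOOT, _HRF_RATIO = 6.0, 16.0, 1.0 / 6.0


@dataclass(frozen=True)
class RoiSeries:
    """One ROI's BOLD vector (arbitrary units) with its repetition time."""

    values: np.ndarray
    tr: float = DEFAULT_TR

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "values", values)

    @property
    def n_scans(self) -> int:
        return self.values.size


def hrf_continuous(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (seconds).

    Gamma-density response peaking near 5 s minus a scaled undershoot
    peaking near 15 s; normalized to unit peak on a dense grid.
    """
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    h = gamma.pdf(t, _HRF_DELAY) - _HRF_RATIO * gamma.pdf(t, _HRF_UNDERSHOOT)
    dense = np.linspace(0.0, 32.0, 3201)
    peak = (gamma.pdf(dense, _HRF_DELAY) - _HRF_RATIO * gamma.pdf(dense, _HRF_UNDERSHOOT)).max()
    return h / peak


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """HRF kernel sampled on the scan grid, unit peak normalization."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration + 1e-9, tr)
    return hrf_continuous(t)


def _convolve_oversampled(stim: np.ndarray, dt: float, scan_idx: np.ndarray) -> np.ndarray:
    kernel = hrf_continuous(np.arange(0.0, 32.0 + 1e-9, dt))
    full = np.convolve(stim, kernel)[: stim.size]
    return full[scan_idx]


def build_design(
    events: pd.DataFrame,
    tr: float = DEFAULT_TR,
    n_scans: int = 300,
    oversampling: int = 16,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Build an HRF-convolved design matrix from an event table.

    ``events`` needs columns ``onset_s``, ``duration_s``, ``condition`` and
    optionally ``modulator``.  Each condition contributes a boxcar column
    (duration 0 events become delta sticks, e.g. motor responses); conditions
    with a modulator additionally contribute a ``<condition>_x_mod`` column
    holding the mean-centered modulator weighting the boxcar.  Duplicate
    overlapping events sum.  Columns are sampled at scan acquisition times.
    """
    required = {"onset_s", "duration_s", "condition"}
    if missing := required - set(events.columns):
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if np.any(events["onset_s"] < 0) or np.any(events["onset_s"] >= n_scans * tr):
        raise ValueError("event onsets must fall within the scan window")
    dt = tr / oversampling
    n_fine = int(np.ceil(n_scans * tr / dt))
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    scan_idx = np.clip(scan_idx, 0, n_fine - 1)

    columns: dict[str, np.ndarray] = {}
    if add_intercept:
        columns["intercept"] = np.ones(n_scans)
    for condition, grp in events.groupby("condition", sort=True):
        stim = np.zeros(n_fine)
        mod_stim = np.zeros(n_fine)
        has_mod = "modulator" in grp.columns and grp["modulator"].notna().any()
        if has_mod:
            centered = grp["modulator"].to_numpy(dtype=float)
            centered = centered - centered.mean()
        for j, (_, ev) in enumerate(grp.iterrows()):
            start = int(np.round(ev["onset_s"] / dt))
            stop = max(start + 1, int(np.round((ev["onset_s"] + ev["duration_s"]) / dt)))
            stop = min(stop, n_fine)
            stim[start:stop] += 1.0
            if has_mod:
                mod_stim[start:stop] += centered[j]
        columns[str(condition)] = _convolve_oversampled(stim, dt, scan_idx)
        if has_mod:
            columns[f"{condition}_x_mod"] = _convolve_oversampled(mod_stim, dt, scan_idx)
    return pd.DataFrame(columns)


def dct_basis(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete cosine drift basis: components with period > ``cutoff``.

    Returns an (n_scans, K+1) matrix whose first column is constant; K is
    ``floor(2 * n_scans * tr / cutoff)``.
    """
    if cutoff <= 2 * tr:
        raise ValueError("cutoff must exceed 2 * tr")
    K = int(np.floor(2.0 * n_scans * tr / cutoff))
    n = np.arange(n_scans)
    cols = [np.ones(n_scans)]
    for k in range(1, K + 1):
        cols.append(np.cos(np.pi * k * (n + 0.5) / n_scans))
    return np.column_stack(cols)


def highpass_filter(series: RoiSeries | np.ndarray, tr: float | None = None,
                    cutoff: float = 128.0) -> np.ndarray:
    """Remove drift (period > ``cutoff`` seconds) by DCT-basis projection.

    The constant term is part of the basis, so the output is zero-mean.
    """
    if isinstance(series, RoiSeries):
        y, tr = series.values, series.tr
    else:
        y = np.asarray(series, dtype=float)
        if tr is None:
            raise ValueError("tr required when passing a bare array")
    X = dct_basis(y.size, tr, cutoff)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class GlmFit:
    """Least-squares effect estimates with a contrast utility."""

    params: pd.Series
    residuals: np.ndarray
    design_columns: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.design_columns = tuple(self.params.index)

    def contrast(self, weights) -> float:
        """Evaluate a named-dict or vector contrast on the estimates."""
        if isinstance(weights, dict):
            w = np.array([weights.get(c, 0.0) for c in self.design_columns])
        else:
            w = np.asarray(weights, dtype=float)
            if w.size != len(self.design_columns):
                raise ValueError("contrast length does not match design columns")
        return float(w @ self.params.to_numpy())


def fit_glm(y: RoiSeries | np.ndarray, X: pd.DataFrame) -> GlmFit:
    """Ordinary least squares of an ROI series on a design matrix.

    Raises on rank deficiency, naming the (near-)collinear columns found via
    the smallest singular vectors.
    """
    values = y.values if isinstance(y, RoiSeries) else np.asarray(y, dtype=float)
    if len(X.columns) != len(set(X.columns)):
        raise ValueError("design matrix has duplicate column names")
    A = X.to_numpy(dtype=float)
    if values.size <= A.shape[1]:
        raise ValueError("need more scans than design columns")
    U, sv, Vt = np.linalg.svd(A, full_matrices=False)
    if sv[-1] < 1e-10 * sv[0]:
        involved = [X.columns[j] for j in np.flatnonzero(np.abs(Vt[-1]) > 1e-8)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {involved}")
    beta = Vt.T @ ((U.T @ values) / sv)
    resid = values - A @ beta
    return GlmFit(params=pd.Series(beta, index=X.columns), residuals=resid)


def ppi_regressor(seed: RoiSeries | np.ndarray, psych: np.ndarray) -> np.ndarray:
    """Element-wise product of a seed series with a psychological regressor.

    Callers are expected to pass a drift-filtered, mean-centered seed; the
    product is returned as-is for inclusion alongside both main effects.
    """
    s = seed.values if isinstance(seed, RoiSeries) else np.asarray(seed, dtype=float)
    psych = np.asarray(psych, dtype=float)
    if s.size != psych.size:
        raise ValueError("seed and psychological regressor must have equal length")
    return s * psych


def simulate_bold(
    design: pd.DataFrame,
    true_effects: dict[str, float],
    coupling: float,
    noise_sd: float,
    rng: np.random.Generator,
    psych_column: str | None = None,
    ar_coef: float = 0.0,
    tr: float = DEFAULT_TR,
) -> tuple[RoiSeries, RoiSeries]:
    """Generate coupled (seed, target) ROI series from a design matrix.

    Seed = design effects + noise.  Target = design effects + ``coupling``
    times the product of the centered seed with the psychological regressor
    (``psych_column``, default: last modulator column) + noise.  Noise is
    white Gaussian, optionally AR(1).
    """
    n = len(design)
    base = np.zeros(n)
    for name, beta in true_effects.items():
        if name not in design.columns:
            raise ValueError(f"unknown design column {name!r}")
        base = base + beta * design[name].to_numpy()
    if psych_column is None:
        mods = [c for c in design.columns if c.endswith("_x_mod")]
        if not mods:
            raise ValueError("no modulator column found; pass psych_column")
        psych_column = mods[-1]
    psych = design[psych_column].to_numpy()

    def noise() -> np.ndarray:
        eps = noise_sd * rng.standard_normal(n)
        if ar_coef:
            for i in range(1, n):
                eps[i] += ar_coef * eps[i - 1]
        return eps

    seed_vals = base + noise()
    seed_centered = seed_vals - seed_vals.mean()
    target_vals = base + coupling * seed_centered * psych + noise()
    return RoiSeries(seed_vals, tr), RoiSeries(target_vals, tr)


def ppi_session_contrast(
    design: pd.DataFrame,
    true_effects: dict[str, float],
    coupling_pre: float,
    coupling_post: float,
    noise_sd: float,
    rng: np.random.Generator,
    cutoff: float = 128.0,
) -> tuple[float, float]:
    """Simulate two sessions and return their fitted PPI coupling estimates.

    Each session's seed/target pair is generated independently with its own
    coupling; both series are high-pass filtered, the PPI model (main
    effects + interaction) is fit to the target, and the interaction
    estimates ``(pre, post)`` are returned.
    """
    out = []
    for coupling in (coupling_pre, coupling_post):
        seed, target = simulate_bold(design, true_effects, coupling, noise_sd, rng)
        mods = [c for c in design.columns if c.endswith("_x_mod")]
        psych = design[mods[-1]].to_numpy()
        seed_f = highpass_filter(seed, cutoff=cutoff)
        target_f = highpass_filter(target, cutoff=cutoff)
        ppi = ppi_regressor(seed_f - seed_f.mean(), psych)
        X = pd.DataFrame({
            "intercept": np.ones(len(design)),
            "physio": seed_f,
            "psych": psych,
            "ppi": ppi,
        })
        fit = fit_glm(target_f, X)
        out.append(fit.params["ppi"])
    return out[0], out[1]
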