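"""Per-window feature extractors and train-referenced normalization.

Each extractor maps one observation window (a 1-D voltage segment) to a
scalar or short vector; no state is shared across windows. The "power
based" statistics (MAV, VAR, WL, DFT energy) track the variance modulation
that afferent activity imposes on the cuff signal; WDEN looks for sparse
burst structure via wavelet hard-thresholding; AR/CEPS summarize the
short-window spectrum parametrically; HOS2/HOS3 are eigen-features of
Toeplitz matrices built from second-/third-order statistics; ACORR captures
dominant periodicity through the first autocorrelation minimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.linalg import toeplitz

from .errors import DegenerateWindowError, InvalidConfigError, SchemaError
from .types import FrameSet

logger = logging.getLogger(__name__)

#: Composite feature sets: combinations of the best-performing single features.
MULTI_SETS = {
    "MULTI1": ("MAV", "WL"),
    "MULTI2": ("MAV", "VAR", "WL"),
    "MULTI3": ("MAV", "VAR", "WL", "DFT"),
    "MULTI4": ("MAV", "WL", "HOS3"),
}

SCALAR_FEATURES = ("MAV", "VAR", "WL", "WDEN", "DFT", "HOS2", "HOS3", "ACORR")
VECTOR_FEATURES = ("AR", "CEPS")
ALL_FEATURES = SCALAR_FEATURES + VECTOR_FEATURES + tuple(MULTI_SETS)


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered list of feature names plus extractor parameters.

    MULTI names expand to their constituent scalars; AR and CEPS expand to
    ``ar_order`` columns each.
    """

    names: tuple[str, ...] = ("MULTI3",)
    ar_order: int = 4
    hos_matrix_dim: int = 10
    wavelet_level: int = 4

    def __post_init__(self) -> None:
        if self.ar_order < 1:
            raise InvalidConfigError("ar_order must be >= 1")
        if self.hos_matrix_dim < 2:
            raise InvalidConfigError("hos_matrix_dim must be >= 2")
        unknown = [n for n in self.names if n not in ALL_FEATURES]
        if unknown:
            raise InvalidConfigError(f"unknown feature names: {unknown}")

    def expanded(self) -> tuple[str, ...]:
        out: list[str] = []
        for n in self.names:
            out.extend(MULTI_SETS.get(n, (n,)))
        return tuple(out)

    def column_names(self) -> tuple[str, ...]:
        cols: list[str] = []
        for n in self.expanded():
            if n in VECTOR_FEATURES:
                cols.extend(f"{n}{i + 1}" for i in range(self.ar_order))
            else:
                cols.append(n)
        return tuple(cols)


@dataclass
class FeatureMatrix:
    """n_windows × n_features matrix with names, labels and norm constants."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    window_labels: np.ndarray
    window_times: np.ndarray
    normalization_constants: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] != len(self.feature_names):
            raise SchemaError("values width must match feature_names")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("feature matrix contains non-finite entries")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------- scalar ops


def mav(window: np.ndarray) -> float:
    """Mean absolute value, (1/N)·Σ|x_n|."""
    window = np.asarray(window)
    if window.size == 0:
        raise DegenerateWindowError("empty window")
    return float(np.mean(np.abs(window)))


def var_unbiased(window: np.ndarray) -> float:
    """Unbiased sample variance (divisor N − 1)."""
    window = np.asarray(window)
    if window.size < 2:
        raise DegenerateWindowError("variance needs at least 2 samples")
    return float(np.var(window, ddof=1))


def waveform_length(window: np.ndarray) -> float:
    """Cumulative path length Σ|x_{n+1} − x_n| — amplitude × frequency sensitive."""
    window = np.asarray(window)
    if window.size < 2:
        raise DegenerateWindowError("waveform length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(window))))


def wden_threshold(sigma: float, n: int) -> float:
    """Hard threshold θ = σ·(0.3936 + 0.1829·log2 N)."""
    return sigma * (0.3936 + 0.1829 * np.log2(n))


def wden(window: np.ndarray, level: int = 4, wavelet: str = "sym7") -> float:
    """MAV of the wavelet-denoised window.

    Symlet-7 decomposition to ``level``; noise σ estimated robustly from the
    finest detail coefficients (MAD/0.6745); hard threshold applied to all
    detail coefficients; the feature is the MAV of the reconstruction. A
    window of pure stationary noise reconstructs to nearly nothing, while
    superimposed bursts survive the threshold.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.size < 2**level:
        raise InvalidConfigError(
            f"window of {window.size} samples too short for level-{level} decomposition"
        )
    coeffs = pywt.wavedec(window, wavelet, level=level)
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest)) / 0.6745)
    theta = wden_threshold(sigma, window.size)
    thresholded = [coeffs[0]] + [
        pywt.threshold(d, theta, mode="hard") for d in coeffs[1:]
    ]
    rec = pywt.waverec(thresholded, wavelet)[: window.size]
    return float(np.mean(np.abs(rec)))


def dft_energy(window: np.ndarray) -> float:
    """Spectral energy (1/N)·Σ_k |X[k]|², equal to Σ x_n² by Parseval."""
    window = np.asarray(window)
    if window.size == 0:
        raise DegenerateWindowError("empty window")
    X = np.fft.fft(window)
    return float(np.sum(np.abs(X) ** 2) / window.size)


def ar_coeffs(window: np.ndarray, order: int = 4) -> np.ndarray:
    """Forward-backward least-squares AR coefficients.

    Returns ``a_1 … a_P`` in the monic-polynomial convention
    ``A(z) = 1 + Σ a_i z^{-i}`` (i.e. ``x[n] + Σ a_i x[n-i] = e[n]``), the
    convention the cepstrum recursion expects. The estimate minimizes the
    summed squared residuals of the forward model and of the analogous
    time-reversed model.
    """
    x = np.asarray(window, dtype=np.float64)
    n = x.size
    if n <= 2 * order:
        raise DegenerateWindowError(f"AR({order}) needs more than {2 * order} samples")
    # forward: predict x[p:] from lags; backward: the same on the reversed series
    rows = []
    targets = []
    for series in (x, x[::-1]):
        design = np.column_stack([series[order - i - 1 : n - i - 1] for i in range(order)])
        rows.append(design)
        targets.append(series[order:])
    A = np.vstack(rows)
    b = np.concatenate(targets)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < order:
        raise DegenerateWindowError("singular normal equations in AR fit")
    return -sol  # predictor coefficients -> polynomial convention


def cepstral_coeffs(a: np.ndarray) -> np.ndarray:
    """Cepstral coefficients from AR polynomial coefficients.

    ``c_1 = −a_1``; ``c_m = −a_m − Σ_{k=1}^{m−1} (k/m)·c_k·a_{m−k}`` — the
    power-series coefficients of −log A(z).
    """
    a = np.asarray(a, dtype=np.float64)
    p = a.size
    if p < 1:
        raise InvalidConfigError("need at least one AR coefficient")
    c = np.zeros(p)
    for m in range(1, p + 1):
        acc = -a[m - 1]
        for k in range(1, m):
            acc -= (k / m) * c[k - 1] * a[m - k - 1]
        c[m - 1] = acc
    return c


def _autocorr_biased(x: np.ndarray, nlags: int) -> np.ndarray:
    """Biased autocorrelation r(0..nlags-1), divisor N (positive semidefinite)."""
    n = x.size
    full = np.correlate(x, x, mode="full")[n - 1 : n - 1 + nlags]
    return full / n


def hos2(window: np.ndarray, m: int = 10) -> float:
    """Eigen-spread of the autocorrelation Toeplitz matrix.

    White noise gives a near-multiple-of-identity matrix (small spread);
    correlated in-band activity concentrates power in few eigen-directions
    (large spread). Returns largest − smallest singular value.
    """
    if m < 2:
        raise InvalidConfigError("hos2 matrix dimension must be >= 2")
    x = np.asarray(window, dtype=np.float64)
    if x.size <= m:
        raise DegenerateWindowError(f"hos2 needs more than {m} samples")
    r = _autocorr_biased(x, m)
    s = np.linalg.svd(toeplitz(r), compute_uv=False)
    return float(s[0] - s[-1])


def _third_cumulant_diag(x: np.ndarray, nlags: int) -> np.ndarray:
    """Diagonal third-order cumulant slice C3(τ, τ) = (1/N)·Σ x[n]·x[n+τ]²."""
    n = x.size
    out = np.empty(nlags)
    for tau in range(nlags):
        out[tau] = np.dot(x[: n - tau], x[tau:] ** 2) / n
    return out


def hos3(window: np.ndarray, m: int = 10) -> float:
    """Largest singular value of the third-order-cumulant Toeplitz matrix.

    The third-order cumulant of a zero-mean Gaussian vanishes in
    expectation, so this statistic responds to skewed / non-Gaussian
    structure rather than raw power.
    """
    if m < 2:
        raise InvalidConfigError("hos3 matrix dimension must be >= 2")
    x = np.asarray(window, dtype=np.float64)
    if x.size <= 2 * m:
        raise DegenerateWindowError(f"hos3 needs more than {2 * m} samples")
    c3 = _third_cumulant_diag(x, m)
    s = np.linalg.svd(toeplitz(c3), compute_uv=False)
    return float(s[0])


def acorr_min(window: np.ndarray) -> float:
    """Value of the first local minimum of the normalized autocorrelation.

    r is the biased estimate normalized so r(0) = 1; the first minimum after
    lag 0 reflects the dominant period (hence conduction-velocity structure)
    of in-band activity. If no interior local minimum exists, the global
    minimum over lags is returned.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.size < 4:
        raise DegenerateWindowError("acorr needs at least 4 samples")
    r = _autocorr_biased(x, x.size)
    if r[0] <= 0:
        return 0.0
    r = r / r[0]
    for i in range(1, r.size - 1):
        if r[i] < r[i - 1] and r[i] <= r[i + 1]:
            return float(r[i])
    return float(r[1:].min())


# ------------------------------------------------------------- matrix level


def extract_features(frames: FrameSet, spec: FeatureSpec) -> FeatureMatrix:
    """One feature row per window, columns ordered by the spec."""
    scalar_fns = {
        "MAV": mav,
        "VAR": var_unbiased,
        "WL": waveform_length,
        "WDEN": lambda w: wden(w, level=spec.wavelet_level),
        "DFT": dft_energy,
        "HOS2": lambda w: hos2(w, m=spec.hos_matrix_dim),
        "HOS3": lambda w: hos3(w, m=spec.hos_matrix_dim),
        "ACORR": acorr_min,
    }
    names = spec.expanded()
    cols = spec.column_names()
    rows = np.empty((frames.n_windows, len(cols)))
    for i in range(frames.n_windows):
        w = frames.frames[i]
        j = 0
        try:
            ar = None
            for name in names:
                if name == "AR":
                    ar = ar_coeffs(w, spec.ar_order)
                    rows[i, j : j + spec.ar_order] = ar
                    j += spec.ar_order
                elif name == "CEPS":
                    if ar is None:
                        ar = ar_coeffs(w, spec.ar_order)
                    rows[i, j : j + spec.ar_order] = cepstral_coeffs(ar)
                    j += spec.ar_order
                else:
                    rows[i, j] = scalar_fns[name](w)
                    j += 1
        except Exception as exc:  # annotate with the offending window
            raise type(exc)(f"window {i}: {exc}") from exc
    return FeatureMatrix(
        values=rows,
        feature_names=cols,
        window_labels=frames.window_labels.copy(),
        window_times=frames.window_times.copy(),
    )


def normalize_train_test(
    train: FeatureMatrix, test: FeatureMatrix
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Divide each column by its training-set maximum absolute value.

    Test columns reuse the training constants (so test entries may exceed
    1). An all-zero training column is left unscaled with a warning.
    """
    if train.feature_names != test.feature_names:
        raise SchemaError(
            f"feature columns differ: {train.feature_names} vs {test.feature_names}"
        )
    if train.n_windows == 0:
        raise SchemaError("empty training matrix")
    consts = np.max(np.abs(train.values), axis=0)
    zero = consts == 0
    if zero.any():
        bad = [train.feature_names[i] for i in np.where(zero)[0]]
        warnings.warn(f"all-zero training columns left unscaled: {bad}")
        logger.warning("all-zero training columns left unscaled: %s", bad)
        consts = np.where(zero, 1.0, consts)

    def _apply(fm: FeatureMatrix) -> FeatureMatrix:
        return FeatureMatrix(
            values=fm.values / consts,
            feature_names=fm.feature_names,
            window_labels=fm.window_labels,
            window_times=fm.window_times,
            normalization_constants=consts.copy(),
        )

    return _apply(train), _apply(test)
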