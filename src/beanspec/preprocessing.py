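"""Spectral pre-treatments for scatter correction and resolution enhancement.

All steps operate row-wise on an (n, B) matrix of spectra and have no
cross-row coupling except through state fitted on the calibration set
(the MSC reference spectrum and the mean-centering column means). That
makes every step applicable to a single spectrum — including a single
image pixel — exactly as to a batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "snv", "msc", "savgol_derivative", "detrend", "normalize", "baseline",
    "PreprocessingChain", "parse_chain",
]


def _as_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[None, :] if X.ndim == 1 else X


def snv(X: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: per-row standardization (n-1 denominator)."""
    X = _as_matrix(X)
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"SNV undefined for constant spectrum (row {bad})")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def msc(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative Scatter Correction against a reference spectrum.

    Each row is regressed as x ~ a + b * reference (ordinary least
    squares) and corrected to (x - a) / b.
    """
    X = _as_matrix(X)
    ref = np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < 1e-12):
        bad = int(np.nonzero(np.abs(b) < 1e-12)[0][0])
        raise ValueError(f"spectrum {bad} is orthogonal to the MSC reference")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def savgol_derivative(X: np.ndarray, order: int = 1, window: int = 9, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay derivative per row, in AU per band step.

    Edges are handled by the polynomial fitted on the truncated window
    (scipy's ``interp`` mode).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if order not in (1, 2) or order > polyorder:
        raise ValueError("derivative order must be 1 or 2 and <= polyorder")
    X = _as_matrix(X)
    if X.shape[1] < window:
        raise ValueError(f"need at least {window} bands for window={window}")
    return savgol_filter(X, window_length=window, polyorder=polyorder,
                         deriv=order, delta=1.0, axis=1, mode="interp")


def detrend(X: np.ndarray, degree: int = 2) -> np.ndarray:
    """Subtract a per-row least-squares polynomial of the band index."""
    X = _as_matrix(X)
    t = np.arange(X.shape[1], dtype=float)
    V = np.vander(t, degree + 1)
    coef, *_ = np.linalg.lstsq(V, X.T, rcond=None)
    return X - (V @ coef).T


def normalize(X: np.ndarray) -> np.ndarray:
    """Scale each row to unit Euclidean norm."""
    X = _as_matrix(X)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = int(np.nonzero(norms == 0)[0][0])
        raise ValueError(f"cannot normalize zero spectrum (row {bad})")
    return X / norms[:, None]


def baseline(X: np.ndarray) -> np.ndarray:
    """Subtract each row's minimum (simple baseline offset removal)."""
    X = _as_matrix(X)
    return X - X.min(axis=1, keepdims=True)


_STEP_NAMES = ("none", "mean_center", "snv", "msc", "savgol_derivative",
               "detrend", "normalize", "baseline")


@dataclass
class PreprocessingChain:
    """Ordered pre-treatment steps with fitted state.

    ``steps`` is a list of (name, params) pairs. ``fit`` runs the chain
    over the calibration spectra, storing the MSC reference (column mean
    of its input) and mean-centering means where those steps occur;
    ``transform`` re-applies the chain with that state frozen.
    """

    steps: list[tuple[str, dict]] = field(default_factory=list)
    _state: list[dict] = field(default_factory=list, repr=False)
    _fitted: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        for name, _ in self.steps:
            if name not in _STEP_NAMES:
                raise ValueError(f"unknown pre-treatment step {name!r}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.steps]

    def spec_string(self) -> str:
        parts = []
        for name, params in self.steps:
            if name == "savgol_derivative":
                parts.append(f"savgol:{params.get('order', 1)}")
            else:
                parts.append(name)
        return ",".join(parts) or "none"

    def clone_unfitted(self) -> "PreprocessingChain":
        return PreprocessingChain([(n, dict(p)) for n, p in self.steps])

    def has_step(self, name: str) -> bool:
        return name in self.names

    def _apply_step(self, name: str, params: dict, X: np.ndarray, state: dict,
                    fitting: bool) -> np.ndarray:
        if name == "none":
            return X
        if name == "snv":
            return snv(X)
        if name == "msc":
            if fitting:
                state["reference"] = X.mean(axis=0)
            return msc(X, state["reference"])
        if name == "savgol_derivative":
            return savgol_derivative(X, **params)
        if name == "detrend":
            return detrend(X, **params)
        if name == "normalize":
            return normalize(X)
        if name == "baseline":
            return baseline(X)
        if name == "mean_center":
            if fitting:
                state["column_means"] = X.mean(axis=0)
            return X - state["column_means"]
        raise AssertionError(name)

    def fit(self, X: np.ndarray) -> "PreprocessingChain":
        X = _as_matrix(X)
        if self.has_step("msc") and X.shape[0] < 2:
            raise ValueError("MSC needs at least 2 calibration spectra")
        self._state = [dict() for _ in self.steps]
        for (name, params), state in zip(self.steps, self._state):
            X = self._apply_step(name, params, X, state, fitting=True)
        self._fitted = True
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("chain must be fitted before transform")
        single = np.asarray(X).ndim == 1
        X = _as_matrix(X)
        for (name, params), state in zip(self.steps, self._state):
            X = self._apply_step(name, params, X, state, fitting=False)
        return X[0] if single else X

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        self.fit(X)
        return self.transform(X)


#: shorthand names accepted by :func:`parse_chain`
_ALIASES = {
    "log1r": "none", "log(1/r)": "none", "raw": "none",
    "sg1": "savgol:1", "sg2": "savgol:2",
    "first_derivative": "savgol:1", "second_derivative": "savgol:2",
}

#: default Savitzky-Golay windows per derivative order
_SAVGOL_DEFAULTS = {1: {"window": 9, "polyorder": 2}, 2: {"window": 11, "polyorder": 2}}


def parse_chain(spec: str | None) -> PreprocessingChain:
    """Build a chain from a comma-separated spec, e.g. ``"snv,savgol:1"``.

    Recognized steps: none/log1r, mean_center, snv, msc, savgol:1,
    savgol:2 (optionally savgol:ORDER:WINDOW:POLYORDER), detrend,
    normalize, baseline.
    """
    if not spec or spec.lower() in ("none",):
        return PreprocessingChain([("none", {})])
    steps: list[tuple[str, dict]] = []
    for item in spec.split(","):
        item = item.strip().lower()
        item = _ALIASES.get(item, item)
        if item.startswith("savgol"):
            parts = item.split(":")
            order = int(parts[1]) if len(parts) > 1 else 1
            params = dict(_SAVGOL_DEFAULTS[order], order=order)
            if len(parts) > 2:
                params["window"] = int(parts[2])
            if len(parts) > 3:
                params["polyorder"] = int(parts[3])
            steps.append(("savgol_derivative", params))
        elif item == "detrend":
            steps.append(("detrend", {"degree": 2}))
        else:
            steps.append((item, {}))
    return PreprocessingChain(steps)
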