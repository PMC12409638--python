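"""Regression layer: single-wavenumber linear models, NIPALS PLS1, VIP.

The precipitant is quantified either by ordinary least squares on the
980 cm^-1 sulfate band intensity or by PLS1 regression on a spectral
interval; the product models are PLS1 on protein-associated intervals.
Latent-variable counts are chosen by a single random 80/20 split, and
variable importance in projection (VIP) scores provide the data-driven
interval selection for the refined precipitant models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .preprocess import PipelineConfig, ScalerState
from .spectra import SpectrumSet

__all__ = [
    "LinearModel", "PLSModel", "VIPResult", "FitReport",
    "fit_linear", "predict", "nipals_pls_fit", "cv_select_components",
    "vip_scores", "select_vip_intervals", "metrics",
    "model_to_json", "model_from_json",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class LinearModel:
    """Ordinary least squares of concentration on one band intensity."""

    wavenumber: float
    slope: float
    intercept: float
    pipeline: PipelineConfig | None = None


@dataclass
class PLSModel:
    """PLS1 regression model fitted by NIPALS with X (and y) deflation.

    ``b`` is the compact regression coefficient vector assembled from the
    weight matrix W, x-loadings P and y-loadings q, so that predictions are
    ``(X - x_mean) @ b + y_mean``.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray          # (p, A) unit-norm weight vectors
    P: np.ndarray          # (p, A) x-loadings
    q: np.ndarray          # (A,) y-loadings
    b: np.ndarray          # (p,) regression coefficients
    retained_wavenumbers: np.ndarray | None = None
    scaler: ScalerState | None = None
    pipeline: PipelineConfig | None = None
    scores: np.ndarray | None = None   # (n, A) training scores, for VIP
    truncated: bool = False


@dataclass
class VIPResult:
    scores: np.ndarray
    wavenumbers: np.ndarray
    threshold: float = 1.0
    intervals: list[tuple[float, float]] = field(default_factory=list)
    empty_selection: bool = False


@dataclass
class FitReport:
    rmse: float
    r2: float | None
    n_test: int
    predictions: np.ndarray


def _xy_from_set(spectrum_set: SpectrumSet) -> tuple[np.ndarray, np.ndarray]:
    if spectrum_set.reference is None:
        raise ValueError("spectrum set carries no reference concentrations")
    return spectrum_set.intensity_matrix, spectrum_set.reference


def fit_linear(trainset: SpectrumSet, wavenumber: float = 980.0) -> LinearModel:
    """Least-squares line mapping band intensity to concentration."""
    X, y = _xy_from_set(trainset)
    x = X[:, trainset.axis.index_of(wavenumber)]
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 distinct reference values")
    if np.ptp(x) == 0:
        raise ValueError(f"constant intensities at {wavenumber} cm^-1")
    slope, intercept = np.polyfit(x, y, 1)
    return LinearModel(wavenumber=float(wavenumber), slope=float(slope),
                       intercept=float(intercept))


def nipals_pls_fit(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """Mean-centered PLS1 via NIPALS with per-component deflation.

    For a single response the inner NIPALS loop collapses to one pass per
    component: w_a = X^T y / ||X^T y||, t_a = X w_a, followed by deflation of
    X and y.  ``A`` beyond min(n-1, p) or beyond the informative rank is
    truncated (flagged), not an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    a_max = min(n - 1, p)
    truncated = A > a_max
    A_eff = min(A, a_max)
    W = np.zeros((p, A_eff))
    P = np.zeros((p, A_eff))
    q = np.zeros(A_eff)
    T = np.zeros((n, A_eff))
    scale = float(np.linalg.norm(X - x_mean)) or 1.0
    a = 0
    for a in range(A_eff):
        cov = Xc.T @ yc
        nw = np.linalg.norm(cov)
        if nw <= 1e-14 * scale * max(1.0, float(np.abs(yc).max())):
            truncated = True
            break
        w = cov / nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 0:
            truncated = True
            break
        pvec = Xc.T @ t / tt
        qa = float(yc @ t / tt)
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        Xc = Xc - np.outer(t, pvec)
        yc = yc - qa * t
        a += 1
    W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
    if a == 0:
        raise ValueError("no informative component could be extracted")
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(n_components=a, x_mean=x_mean, y_mean=y_mean,
                    W=W, P=P, q=q, b=b, scores=T, truncated=truncated)


def predict(model: LinearModel | PLSModel, data) -> np.ndarray:
    """Predict concentrations from a preprocessed SpectrumSet or matrix.

    Negative predictions are reported as-is; clipping them would hide the
    transfer diagnostics that oversaturated spectra produce.
    """
    if isinstance(model, LinearModel):
        if isinstance(data, SpectrumSet):
            x = data.intensity_matrix[:, data.axis.index_of(model.wavenumber)]
        else:
            x = np.asarray(data, dtype=float).ravel()
        return model.slope * x + model.intercept
    if isinstance(data, SpectrumSet):
        if (model.retained_wavenumbers is not None
                and not np.array_equal(data.axis.values, model.retained_wavenumbers)):
            raise ValueError("spectrum axis does not match the model's retained wavenumbers")
        X = data.intensity_matrix
    else:
        X = np.asarray(data, dtype=float)
    if X.shape[1] != model.b.size:
        raise ValueError(f"expected {model.b.size} wavenumbers, got {X.shape[1]}")
    return (X - model.x_mean) @ model.b + model.y_mean


def cv_select_components(X: np.ndarray, y: np.ndarray,
                         a_range=range(2, 11), split_fraction: float = 0.8,
                         seed: int = 0, parsimony: bool = True,
                         parsimony_tol: float = 0.05):
    """Select the PLS component count by a single random train/validation split.

    Fits each candidate A on the training fraction and scores RMSE on the
    held-out fraction.  With the parsimony rule (default) the smallest A
    whose validation RMSE is within ``parsimony_tol`` of the minimum wins;
    ``parsimony=False`` gives the pure argmin.  Returns ``(A, table)`` where
    ``table`` maps A -> validation RMSE.
    """
    a_range = list(a_range)
    if not a_range:
        raise ValueError("empty component range")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    n_val = max(3, int(round(n * (1.0 - split_fraction))))
    n_train = n - n_val
    if n_train < 3:
        raise ValueError(f"too few samples (n={n}) for a validation split of {n_val}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    a_cap = min(n_train - 1, X.shape[1])
    table: dict[int, float] = {}
    for A in a_range:
        model = nipals_pls_fit(X[train_idx], y[train_idx], min(A, a_cap))
        pred = predict(model, X[val_idx])
        table[A] = float(np.sqrt(np.mean((pred - y[val_idx]) ** 2)))
    best = min(table.values())
    if parsimony:
        # absolute floor keeps the rule well defined when every candidate
        # fits to numerical precision
        cutoff = best * (1 + parsimony_tol) + 1e-12 * float(np.abs(y).max() or 1.0)
        selected = next(A for A in sorted(table) if table[A] <= cutoff)
    else:
        selected = min(table, key=lambda A: (table[A], A))
    return selected, table


def vip_scores(model: PLSModel, wavenumbers: np.ndarray | None = None) -> VIPResult:
    """Variable importance in projection for a fitted PLS1 model.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) with
    SSY_a the response variance explained by component a; the scores satisfy
    sum_j VIP_j^2 = p.
    """
    if model.scores is None:
        raise ValueError("model carries no training scores; refit to compute VIP")
    W, q, T = model.W, model.q, model.scores
    p, A = W.shape
    wnorm = np.linalg.norm(W, axis=0)
    if np.any(wnorm == 0):
        raise ValueError("degenerate zero-norm weight vector")
    ssy = q ** 2 * np.einsum("ia,ia->a", T, T)  # variance explained per component
    vip = np.sqrt(p * ((W / wnorm) ** 2 @ ssy) / ssy.sum())
    if wavenumbers is None:
        wavenumbers = (model.retained_wavenumbers
                       if model.retained_wavenumbers is not None
                       else np.arange(p, dtype=float))
    return VIPResult(scores=vip, wavenumbers=np.asarray(wavenumbers, dtype=float))


def select_vip_intervals(vip: VIPResult, threshold: float = 1.0,
                         min_width: int = 5, merge_gap: float = 5.0) -> list[tuple[float, float]]:
    """Group above-threshold wavenumbers into inclusive intervals.

    Runs separated by at most ``merge_gap`` cm^-1 are merged; merged runs
    spanning fewer than ``min_width`` points are dropped.  An empty
    selection is allowed and flagged on the VIPResult.
    """
    wn = vip.wavenumbers
    above = np.flatnonzero(vip.scores >= threshold)
    vip.threshold = threshold
    if above.size == 0:
        vip.intervals = []
        vip.empty_selection = True
        return []
    runs: list[list[int]] = [[above[0], above[0]]]
    for i in above[1:]:
        if wn[i] - wn[runs[-1][1]] <= merge_gap:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    intervals = [(float(wn[a]), float(wn[b])) for a, b in runs
                 if b - a + 1 >= min_width]
    vip.intervals = intervals
    vip.empty_selection = not intervals
    return intervals


def metrics(pred: np.ndarray, ref: np.ndarray) -> FitReport:
    """Root mean squared error and coefficient of determination."""
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.size != ref.size or pred.size < 2:
        raise ValueError("pred and ref must have equal length >= 2")
    rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - float(np.sum((pred - ref) ** 2)) / ss_tot
    return FitReport(rmse=rmse, r2=r2, n_test=pred.size, predictions=pred)


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------

def model_to_json(model: LinearModel | PLSModel) -> str:
    doc: dict = {"format_version": MODEL_FORMAT_VERSION}
    if isinstance(model, LinearModel):
        doc["kind"] = "linear"
        doc["wavenumber"] = model.wavenumber
        doc["slope"] = model.slope
        doc["intercept"] = model.intercept
    else:
        doc["kind"] = "pls"
        doc["n_components"] = model.n_components
        doc["x_mean"] = model.x_mean.tolist()
        doc["y_mean"] = model.y_mean
        doc["W"] = model.W.tolist()
        doc["P"] = model.P.tolist()
        doc["q"] = model.q.tolist()
        doc["b"] = model.b.tolist()
        if model.retained_wavenumbers is not None:
            doc["retained_wavenumbers"] = model.retained_wavenumbers.tolist()
        if model.scaler is not None:
            doc["scaler"] = {"wavenumbers": model.scaler.wavenumbers.tolist(),
                             "mean": model.scaler.mean.tolist(),
                             "sd": model.scaler.sd.tolist()}
    if model.pipeline is not None:
        doc["pipeline"] = model.pipeline.to_dict()
    return json.dumps(doc)


def model_from_json(text: str) -> LinearModel | PLSModel:
    doc = json.loads(text)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')}")
    pipeline = (PipelineConfig.from_dict(doc["pipeline"])
                if "pipeline" in doc else None)
    if doc["kind"] == "linear":
        return LinearModel(wavenumber=doc["wavenumber"], slope=doc["slope"],
                           intercept=doc["intercept"], pipeline=pipeline)
    scaler = None
    if "scaler" in doc:
        s = doc["scaler"]
        scaler = ScalerState(wavenumbers=np.array(s["wavenumbers"]),
                             mean=np.array(s["mean"]), sd=np.array(s["sd"]))
    return PLSModel(
        n_components=doc["n_components"], x_mean=np.array(doc["x_mean"]),
        y_mean=doc["y_mean"], W=np.array(doc["W"]), P=np.array(doc["P"]),
        q=np.array(doc["q"]), b=np.array(doc["b"]),
        retained_wavenumbers=(np.array(doc["retained_wavenumbers"])
                              if "retained_wavenumbers" in doc else None),
        scaler=scaler, pipeline=pipeline)
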