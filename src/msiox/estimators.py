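"""SO2 estimators: inverse Monte-Carlo spectral fitting and a small
feed-forward neural network trained on synthetic spectra.

The network maps the 16 fully-normalized band values to SO2 in percent
through a single hidden layer (5-20 tanh units) and a linear output; the
output is deliberately *not* clipped to [0, 100], so non-physiological
estimates remain visible.  Training minimizes the mean-square error with a
Levenberg-Marquardt loop (analytic Jacobian via backpropagation, adaptive
damping) and stops early when the validation error fails to improve for
``patience`` consecutive accepted steps.

The inverse MC estimator fits all seven tissue-model parameters by
nonlinear least squares on the relative difference between modeled and
measured normalized spectra, with Latin-hypercube multi-start for the
first frame of a time series and warm starts thereafter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .camera import MSISpectrum, N_BANDS, model_intensity, normalize
from .spectra import CANONICAL_GRID, Spectrum
from .synth import ForwardModels, tissue_reflectance
from .tissue import TissueParams

__all__ = [
    "AnnModel", "TrainReport", "FitResult", "ann_predict", "train_ann",
    "repeat_train", "inverse_mc_fit", "estimate_timeseries", "default_fit_bounds",
]

HIDDEN_SIZES = (5, 10, 15, 20)


@dataclass
class AnnModel:
    """16 -> H -> 1 regression network (tanh hidden layer, linear output)."""

    W1: np.ndarray  # (H, 16)
    b1: np.ndarray  # (H,)
    W2: np.ndarray  # (H,)
    b2: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        h = self.W1.shape[0]
        if self.W1.shape != (h, N_BANDS) or self.b1.shape != (h,) or self.W2.shape != (h,):
            raise ValueError("inconsistent network weight shapes")

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass for (16,) or (n, 16) inputs; output SO2 in %."""
        x = np.asarray(x, dtype=float)
        h = np.tanh(x @ self.W1.T + self.b1)
        return h @ self.W2 + self.b2

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"W1": self.W1.tolist(), "b1": self.b1.tolist(),
                       "W2": self.W2.tolist(), "b2": self.b2,
                       "input": "fully_normalized 16-band MSI spectrum",
                       "output": "SO2 percent, unclipped",
                       "meta": self.meta}, fh)

    @classmethod
    def from_json(cls, path) -> "AnnModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(W1=np.asarray(p["W1"]), b1=np.asarray(p["b1"]),
                   W2=np.asarray(p["W2"]), b2=float(p["b2"]),
                   meta=p.get("meta", {}))


def ann_predict(model: AnnModel, spectrum: MSISpectrum) -> float:
    """Predict SO2 (%) from one fully-normalized MSI spectrum."""
    if spectrum.state != "fully_normalized":
        raise ValueError("ann_predict requires a fully_normalized spectrum, "
                         f"got state {spectrum.state!r}")
    return float(model.predict(spectrum.values))


@dataclass
class TrainReport:
    n_iter: int
    train_mse: float
    val_mse: float
    test_mse: float
    stopped: str  # early_stop | max_epochs | converged
    degenerate: bool = False


def _init_weights(h: int, rng: np.random.Generator) -> AnnModel:
    """Nguyen-Widrow-style initialization for the tanh layer.

    Hidden-unit hyperplanes get a common weight magnitude and evenly
    spread biases so their active regions tile the (standardized) input
    space; this makes repeated trainings converge far more consistently
    than plain random Gaussian weights.
    """
    beta = 0.7 * h ** (1.0 / N_BANDS)
    w = rng.normal(0.0, 1.0, (h, N_BANDS))
    w *= beta / np.linalg.norm(w, axis=1, keepdims=True)
    b1 = beta * np.linspace(-1.0, 1.0, h) * rng.choice([-1.0, 1.0], h)
    return AnnModel(W1=w, b1=b1,
                    W2=rng.normal(0.0, 1.0, h) / np.sqrt(h),
                    b2=0.0)


def _pack(m: AnnModel) -> np.ndarray:
    return np.concatenate([m.W1.ravel(), m.b1, m.W2, [m.b2]])


def _unpack(theta: np.ndarray, h: int) -> AnnModel:
    i = h * N_BANDS
    return AnnModel(W1=theta[:i].reshape(h, N_BANDS), b1=theta[i:i + h],
                    W2=theta[i + h:i + 2 * h], b2=float(theta[-1]))


def _forward_jac(theta: np.ndarray, h: int, X: np.ndarray):
    """Predictions and the (n, P) Jacobian d yhat / d theta."""
    m = _unpack(theta, h)
    a = X @ m.W1.T + m.b1
    hid = np.tanh(a)
    yhat = hid @ m.W2 + m.b2
    dtanh = (1.0 - hid ** 2) * m.W2  # (n, h)
    n = X.shape[0]
    J = np.empty((n, theta.size))
    J[:, :h * N_BANDS] = (dtanh[:, :, None] * X[:, None, :]).reshape(n, h * N_BANDS)
    J[:, h * N_BANDS:h * N_BANDS + h] = dtanh
    J[:, h * N_BANDS + h:h * N_BANDS + 2 * h] = hid
    J[:, -1] = 1.0
    return yhat, J


def train_ann(train_set, hidden: int = 15, seed: int = 0, max_epochs: int = 500,
              patience: int = 50, min_epochs: int = 150, mu0: float = 1e-3,
              mu_inc: float = 10.0, mu_dec: float = 0.1, mu_max: float = 1e10):
    """Train one network with Levenberg-Marquardt on the training split.

    Returns ``(AnnModel, TrainReport)``.  The weights returned are those of
    the best validation error seen; ``test_mse`` is evaluated on the test
    split with those weights.
    """
    if hidden not in HIDDEN_SIZES:
        raise ValueError(f"hidden size must be one of {HIDDEN_SIZES}")
    X_tr, y_tr = train_set.subset("train")
    X_va, y_va = train_set.subset("val")
    X_te, y_te = train_set.subset("test")
    degenerate = bool(np.ptp(y_tr) == 0)
    # standardize inputs internally (the normalized bands cluster tightly
    # around 1, which conditions the LM normal equations poorly); the
    # affine map is folded back into the first-layer weights afterwards,
    # so the returned model consumes raw normalized spectra
    x_mu = X_tr.mean(axis=0)
    x_sd = np.where(X_tr.std(axis=0) > 0, X_tr.std(axis=0), 1.0)
    X_tr = (X_tr - x_mu) / x_sd
    X_va = (X_va - x_mu) / x_sd
    X_te = (X_te - x_mu) / x_sd
    rng = np.random.default_rng(seed)
    theta = _pack(_init_weights(hidden, rng))

    def sse(th, X, y):
        m = _unpack(th, hidden)
        r = m.predict(X) - y
        return float(r @ r)

    mu = mu0
    best_val = np.inf
    best_theta = theta.copy()
    fails = 0
    stopped = "max_epochs"
    it = 0
    train_sse = sse(theta, X_tr, y_tr)
    for it in range(1, max_epochs + 1):
        yhat, J = _forward_jac(theta, hidden, X_tr)
        r = yhat - y_tr
        g = J.T @ r
        A = J.T @ J
        accepted = False
        while mu <= mu_max:
            try:
                delta = np.linalg.solve(A + mu * np.eye(theta.size), -g)
            except np.linalg.LinAlgError:
                mu *= mu_inc
                continue
            cand = theta + delta
            cand_sse = sse(cand, X_tr, y_tr)
            if cand_sse < train_sse:
                theta, train_sse = cand, cand_sse
                mu = max(mu * mu_dec, 1e-20)
                accepted = True
                break
            mu *= mu_inc
        if not accepted:
            stopped = "converged"
            break
        val_mse = sse(theta, X_va, y_va) / max(len(y_va), 1)
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_theta = theta.copy()
            fails = 0
        else:
            fails += 1
            # LM descent often plateaus early before a later drop; do not
            # allow the validation patience to fire in the first epochs
            if fails >= patience and it >= min_epochs:
                stopped = "early_stop"
                break
    model = _unpack(best_theta, hidden)
    # fold the input standardization into the first layer
    model.W1 = model.W1 / x_sd
    model.b1 = model.b1 - (model.W1 @ x_mu)
    model.meta = {"hidden": hidden, "seed": seed, "n_train": len(y_tr)}
    report = TrainReport(
        n_iter=it,
        train_mse=sse(best_theta, X_tr, y_tr) / max(len(y_tr), 1),
        val_mse=best_val if np.isfinite(best_val) else sse(best_theta, X_va, y_va) / max(len(y_va), 1),
        test_mse=sse(best_theta, X_te, y_te) / max(len(y_te), 1),
        stopped=stopped, degenerate=degenerate)
    return model, report


def repeat_train(train_set, hidden: int = 15, n_repeats: int = 10,
                 base_seed: int = 0, X_common: np.ndarray | None = None,
                 **train_kwargs):
    """Train ``n_repeats`` networks with distinct random initializations.

    Returns ``(models, reports, stats)`` where ``stats`` contains the
    per-sample standard deviation of the ensemble predictions on
    ``X_common`` (default: the training set's test split) and its average.
    """
    models, reports = [], []
    for i in range(n_repeats):
        m, rep = train_ann(train_set, hidden=hidden, seed=base_seed + i,
                           **train_kwargs)
        models.append(m)
        reports.append(rep)
    if X_common is None:
        X_common = train_set.subset("test")[0]
    preds = np.stack([m.predict(X_common) for m in models])  # (reps, n)
    per_sample_std = preds.std(axis=0, ddof=0)
    stats = {"per_sample_std": per_sample_std,
             "mean_std": float(per_sample_std.mean()),
             "test_mse": [r.test_mse for r in reports]}
    return models, reports, stats


# ---------------------------------------------------------------------------
# Inverse Monte Carlo fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: TissueParams
    residual: np.ndarray  # per-band relative differences
    mape: float  # mean absolute relative difference, %
    converged: bool
    start_points_used: int
    cost: float
    nfev: int

    @property
    def so2_percent(self) -> float:
        return 100.0 * self.params.s


def default_fit_bounds(models: ForwardModels) -> tuple[np.ndarray, np.ndarray]:
    """Box bounds (t_epi, f_mel, f_blood, s, D, alpha, beta) for the fitter,
    tied to the LUT's epidermis-thickness axis."""
    lut = models.lut
    lo = np.array([lut.t_epi_axis[0], 0.0, 1e-4, -0.2, 2e-3, 1.0, 0.5])
    hi = np.array([lut.t_epi_axis[-1], 1.0, 0.3, 1.2, 0.5, 6.0, 2.5])
    return lo, hi


def _model_normalized(theta: np.ndarray, models: ForwardModels) -> np.ndarray:
    params = TissueParams.from_array(theta)
    T = tissue_reflectance(params, models, clip=True)
    I_T = model_intensity(models.response, models.optics, T)
    I_W = model_intensity(models.response, models.optics,
                          Spectrum(np.ones(len(CANONICAL_GRID))))
    return normalize(I_T, I_W).values


def inverse_mc_fit(measured: MSISpectrum, models: ForwardModels,
                   starts: int = 8, warm_start: TissueParams | None = None,
                   seed: int = 0, bounds=None, xtol: float = 1e-10,
                   screen: int = 1024, polish: int = 3) -> FitResult:
    """Fit the seven tissue parameters to one measured normalized spectrum.

    The objective is the elementwise relative difference
    (N_model - N_meas)/N_meas.  Without a warm start, ``starts`` initial
    points are drawn by seeded Latin-hypercube sampling over the bounds and
    the best-residual solution is returned; with a warm start only that
    single optimization is run.
    """
    if measured.state != "fully_normalized":
        raise ValueError("inverse_mc_fit requires a fully_normalized spectrum")
    n_meas = measured.values
    lo, hi = bounds if bounds is not None else default_fit_bounds(models)

    # optimize the spread-magnitude parameters (t_epi, f_blood, D, alpha)
    # on a log scale; f_mel, s, beta stay linear (f_mel may be exactly 0)
    log_axes = (0, 2, 4, 5)
    floor = 1e-8

    def to_internal(x):
        u = np.array(x, dtype=float)
        for k in log_axes:
            u[k] = np.log(max(u[k], floor))
        return u

    def to_external(u):
        x = np.array(u, dtype=float)
        for k in log_axes:
            x[k] = np.exp(x[k])
        return np.clip(x, lo, hi)

    u_lo, u_hi = to_internal(np.maximum(lo, floor)), to_internal(hi)

    def resid(u):
        return (_model_normalized(to_external(u), models) - n_meas) / n_meas

    if warm_start is not None:
        x0s = [to_internal(np.clip(warm_start.as_array(), np.maximum(lo, floor), hi))]
    else:
        # screen a large Latin-hypercube cloud with the cheap forward model
        # and polish only the most promising basins
        sampler = qmc.LatinHypercube(d=7, seed=seed)
        unit = sampler.random(max(screen, starts))
        cloud = [u_lo + u * (u_hi - u_lo) for u in unit]
        costs = [float(np.sum(resid(u) ** 2)) for u in cloud]
        order = np.argsort(costs)
        x0s = [cloud[i] for i in order[:starts]]

    best = None
    nfev = 0
    any_success = False
    for x0 in x0s:
        sol = least_squares(resid, x0, bounds=(u_lo, u_hi), method="trf",
                            xtol=xtol, ftol=xtol, max_nfev=400)
        nfev += sol.nfev
        any_success = any_success or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if warm_start is None and polish > 0:
        # the piecewise-multilinear LUT surface leaves shallow local
        # minima; perturbation restarts around the incumbent escape them
        rng = np.random.default_rng(seed + 1)
        for _ in range(polish):
            x0 = np.clip(best.x + 0.1 * (u_hi - u_lo) * rng.standard_normal(7),
                         u_lo, u_hi)
            sol = least_squares(resid, x0, bounds=(u_lo, u_hi), method="trf",
                                xtol=xtol, ftol=xtol, max_nfev=400)
            nfev += sol.nfev
            if sol.cost < best.cost:
                best = sol
    best.x = to_external(best.x)
    residual = best.fun
    return FitResult(
        params=TissueParams.from_array(best.x),
        residual=residual,
        mape=float(np.mean(np.abs(residual)) * 100.0),
        converged=bool(any_success),
        start_points_used=len(x0s),
        cost=float(best.cost),
        nfev=nfev)


def estimate_timeseries(spectra, estimator, models: ForwardModels | None = None,
                        ann: AnnModel | None = None, starts: int = 8,
                        seed: int = 0):
    """Per-frame SO2 (%) for a sequence of fully-normalized spectra.

    ``estimator`` is "ann" (frame-independent) or "inverse_mc" (the first
    frame uses multi-start, later frames warm-start from the previous
    solution).  Returns an array of SO2 percentages; for inverse MC the
    list of FitResults is returned alongside.
    """
    if estimator == "ann":
        if ann is None:
            raise ValueError("ann estimator requires a model")
        return np.array([ann_predict(ann, s) for s in spectra])
    if estimator != "inverse_mc":
        raise ValueError(f"unknown estimator {estimator!r}")
    if models is None:
        raise ValueError("inverse_mc estimator requires forward models")
    results = []
    prev = None
    for s in spectra:
        fit = inverse_mc_fit(s, models, starts=starts, warm_start=prev, seed=seed)
        results.append(fit)
        prev = fit.params
    return np.array([r.so2_percent for r in results]), results
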