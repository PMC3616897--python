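"""Linear feed-forward neural-network multivariate calibration.

A single-hidden-layer network maps the mean-centered absorbance vector
(110 inputs, the 230-340 nm window at 1 nm) through 10 hidden units to
the three mean-centered concentrations.  Both transfers are linear
("purelin") by default, so the trained network is an affine map and its
converged predictions coincide with multivariate ordinary least squares
on the same centered data; the network parametrization plus validation
early stopping is what regularizes it.  A tansig hidden transfer is
available behind a flag for nonlinear data.

Training uses Levenberg-Marquardt: damped Gauss-Newton steps on the full
parameter vector, with the damping coefficient initialized at ``lc``,
multiplied by ``lci`` when a step is rejected and by ``lcd`` when it is
accepted.  After every accepted step the validation RMSEP is recorded;
training stops when it has not improved for ``patience`` checks (or on
``max_iter`` / numerical convergence), and the returned model is the
iterate with the smallest validation RMSEP.

Because the residual count (samples x 3) is far below the parameter
count (1143 for the 110-10-3 architecture), the LM step is solved in
residual space via the push-through identity
``(J'J + mu I)^-1 J' r = J' (JJ' + mu I)^-1 r``, which makes one
iteration cost milliseconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import TRAINING, VALIDATION
from .spectra import ANN_WINDOW, SpectralWindow, Spectrum

__all__ = [
    "AnnHyper",
    "CalibrationDataset",
    "AnnModel",
    "TrainingDivergence",
    "mean_center",
    "train",
    "predict",
    "rmsep",
]


class TrainingDivergence(RuntimeError):
    """The training loss became non-finite."""


@dataclass(frozen=True)
class AnnHyper:
    """Network and optimizer hyperparameters.

    Defaults follow the optimized settings for this assay: 10 hidden
    neurons, learning coefficient 0.001 with decrease factor 0.1 and
    increase factor 10, linear transfers at both layers.
    """

    hidden_units: int = 10
    lc: float = 0.001          # initial LM damping coefficient
    lcd: float = 0.1           # damping decrease on an accepted step
    lci: float = 10.0          # damping increase on a rejected step
    max_iter: int = 200
    patience: int = 6
    early_stopping: bool = True
    hidden_transfer: str = "purelin"   # or "tansig"
    init_scale: float = 0.01
    loss_tol: float = 1e-14

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if min(self.lc, self.lcd) <= 0 or self.lci <= 1:
            raise ValueError("invalid damping schedule")
        if self.hidden_transfer not in ("purelin", "tansig"):
            raise ValueError(f"unknown transfer {self.hidden_transfer!r}")


@dataclass
class CalibrationDataset:
    """Absorbance matrix, concentration targets and partition tags."""

    spectra_matrix: np.ndarray          # (n_samples, n_wavelengths) AU
    targets: np.ndarray                 # (n_samples, n_analytes) ug/mL
    partition: np.ndarray               # (n_samples,) {training, validation}
    wavelengths_nm: np.ndarray
    analytes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.spectra_matrix = np.asarray(self.spectra_matrix, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        self.partition = np.asarray(self.partition, dtype=object)
        if self.spectra_matrix.shape[0] != self.targets.shape[0] or \
                self.spectra_matrix.shape[0] != self.partition.shape[0]:
            raise ValueError("row counts of spectra, targets and partition differ")
        if self.spectra_matrix.shape[1] != self.wavelengths_nm.size:
            raise ValueError("spectra width does not match the wavelength axis")

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum], targets: pd.DataFrame,
                     partition: Sequence[str],
                     window: SpectralWindow = ANN_WINDOW) -> "CalibrationDataset":
        """Restrict spectra to the input window and stack into a matrix."""
        sub = [s.restrict(window) for s in spectra]
        return cls(
            spectra_matrix=np.vstack([s.absorbance_au for s in sub]),
            targets=targets.to_numpy(dtype=float),
            partition=np.asarray(partition, dtype=object),
            wavelengths_nm=sub[0].wavelengths_nm,
            analytes=tuple(targets.columns),
        )

    def mask(self, tag: str) -> np.ndarray:
        return self.partition == tag


def mean_center(dataset: CalibrationDataset
                ) -> tuple[CalibrationDataset, np.ndarray, np.ndarray]:
    """Subtract the training-set column means from inputs and targets.

    Validation rows are centered with the *training* means, never their
    own, so no information leaks from the validation set into the model.
    Returns the centered dataset and the two centering vectors.
    """
    tr = dataset.mask(TRAINING)
    if tr.sum() < 2:
        raise ValueError("need at least 2 training samples to center")
    x_center = dataset.spectra_matrix[tr].mean(axis=0)
    y_center = dataset.targets[tr].mean(axis=0)
    centered = replace(
        dataset,
        spectra_matrix=dataset.spectra_matrix - x_center,
        targets=dataset.targets - y_center,
    )
    return centered, x_center, y_center


@dataclass
class AnnModel:
    """A trained network with its centering vectors and training trace."""

    w_in: np.ndarray            # (n_inputs, hidden)
    b_hidden: np.ndarray        # (hidden,)
    w_out: np.ndarray           # (hidden, n_outputs)
    b_out: np.ndarray           # (n_outputs,)
    x_center: np.ndarray
    y_center: np.ndarray
    hyper: AnnHyper
    wavelengths_nm: np.ndarray
    analytes: tuple[str, ...]
    trace: dict[str, list[float]] = field(default_factory=dict)

    @property
    def transfer(self) -> tuple[str, str]:
        return (self.hyper.hidden_transfer, "purelin")

    def predict(self, spectra_matrix: np.ndarray) -> np.ndarray:
        return predict(self, spectra_matrix)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "w_in": self.w_in.tolist(), "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(), "b_out": self.b_out.tolist(),
            "x_center": self.x_center.tolist(), "y_center": self.y_center.tolist(),
            "hyper": self.hyper.__dict__, "trace": self.trace,
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "analytes": list(self.analytes),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "AnnModel":
        d = json.loads(Path(path).read_text())
        return cls(
            w_in=np.array(d["w_in"]), b_hidden=np.array(d["b_hidden"]),
            w_out=np.array(d["w_out"]), b_out=np.array(d["b_out"]),
            x_center=np.array(d["x_center"]), y_center=np.array(d["y_center"]),
            hyper=AnnHyper(**d["hyper"]), trace=d["trace"],
            wavelengths_nm=np.array(d["wavelengths_nm"]),
            analytes=tuple(d["analytes"]),
        )


def rmsep(predicted: np.ndarray, actual: np.ndarray
          ) -> tuple[float, np.ndarray]:
    """Root mean square error of prediction.

    Returns the overall RMSEP over all samples and analytes together and
    the per-analyte (per-column) breakdown.
    """
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    a = np.atleast_2d(np.asarray(actual, dtype=float))
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {a.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    sq = (p - a) ** 2
    return float(np.sqrt(sq.mean())), np.sqrt(sq.mean(axis=0))


# -- forward pass and Jacobian -------------------------------------------

def _forward(x: np.ndarray, w1, b1, w2, b2, transfer: str):
    pre = x @ w1 + b1
    h = np.tanh(pre) if transfer == "tansig" else pre
    return h @ w2 + b2, h


def _residual_jacobian(x: np.ndarray, w1, b1, w2, b2, transfer: str):
    """Jacobian of vec(residual) wrt (w1, b1, w2, b2), shape (n*k, P)."""
    n, p = x.shape
    hdim = w1.shape[1]
    k = w2.shape[1]
    pre = x @ w1 + b1
    if transfer == "tansig":
        h = np.tanh(pre)
        dh = 1.0 - h ** 2                      # (n, hdim)
    else:
        h = pre
        dh = np.ones_like(pre)
    # d r[n,k] / d w1[j,m] = x[n,j] * dh[n,m] * w2[m,k]
    j_w1 = np.einsum("nj,nm,mk->nkjm", x, dh, w2).reshape(n * k, p * hdim)
    j_b1 = np.einsum("nm,mk->nkm", dh, w2).reshape(n * k, hdim)
    j_w2 = np.zeros((n, k, hdim, k))
    idx = np.arange(k)
    j_w2[:, idx, :, idx] = np.transpose(np.broadcast_to(h, (k, n, hdim)), (0, 1, 2))
    j_w2 = j_w2.reshape(n * k, hdim * k)
    j_b2 = np.tile(np.eye(k), (n, 1))
    return np.hstack([j_w1, j_b1, j_w2, j_b2]), h


def _unpack(theta: np.ndarray, p: int, hdim: int, k: int):
    o = 0
    w1 = theta[o:o + p * hdim].reshape(p, hdim); o += p * hdim
    b1 = theta[o:o + hdim]; o += hdim
    w2 = theta[o:o + hdim * k].reshape(hdim, k); o += hdim * k
    b2 = theta[o:o + k]
    return w1, b1, w2, b2


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def train(dataset: CalibrationDataset, hyper: AnnHyper | None = None,
          seed: int = 0) -> AnnModel:
    """Levenberg-Marquardt training with validation early stopping.

    Weights are initialized from a seeded uniform distribution scaled by
    fan-in, so identical seeds give identical models.  The returned model
    is the accepted iterate whose validation RMSEP is minimal over the
    whole run (early-stopping contract).
    """
    hyper = hyper or AnnHyper()
    tr = dataset.mask(TRAINING)
    va = dataset.mask(VALIDATION)
    if tr.sum() == 0 or va.sum() == 0:
        raise ValueError("both training and validation partitions must be non-empty")

    centered, x_center, y_center = mean_center(dataset)
    xt, yt = centered.spectra_matrix[tr], centered.targets[tr]
    xv, yv = centered.spectra_matrix[va], centered.targets[va]
    p, hdim, k = xt.shape[1], hyper.hidden_units, yt.shape[1]

    rng = np.random.default_rng(seed)
    w1 = rng.uniform(-1, 1, (p, hdim)) * hyper.init_scale / np.sqrt(p)
    b1 = np.zeros(hdim)
    w2 = rng.uniform(-1, 1, (hdim, k)) * hyper.init_scale / np.sqrt(hdim)
    b2 = np.zeros(k)
    theta = _pack(w1, b1, w2, b2)

    def loss_of(th):
        w1, b1, w2, b2 = _unpack(th, p, hdim, k)
        pred, _ = _forward(xt, w1, b1, w2, b2, hyper.hidden_transfer)
        r = (pred - yt).ravel()
        return r, 0.5 * float(r @ r)

    def val_rmsep_of(th):
        w1, b1, w2, b2 = _unpack(th, p, hdim, k)
        pred, _ = _forward(xv, w1, b1, w2, b2, hyper.hidden_transfer)
        return rmsep(pred, yv)[0]

    mu = hyper.lc
    r, loss = loss_of(theta)
    if not np.isfinite(loss):
        raise TrainingDivergence("initial loss is not finite")

    train_trace: list[float] = []
    val_trace: list[float] = []
    best_theta = theta.copy()
    best_val = val_rmsep_of(theta)
    since_best = 0

    for _ in range(hyper.max_iter):
        w1, b1, w2, b2 = _unpack(theta, p, hdim, k)
        jac, _ = _residual_jacobian(xt, w1, b1, w2, b2, hyper.hidden_transfer)
        accepted = False
        for _try in range(25):
            # residual-space LM step (n_res << n_params)
            gram = jac @ jac.T
            gram[np.diag_indices_from(gram)] += mu
            try:
                step = -jac.T @ np.linalg.solve(gram, r)
            except np.linalg.LinAlgError:
                mu *= hyper.lci
                continue
            trial = theta + step
            r_new, loss_new = loss_of(trial)
            if not np.isfinite(loss_new):
                raise TrainingDivergence("training loss became non-finite")
            if loss_new < loss:
                theta, r = trial, r_new
                gain = loss - loss_new
                loss = loss_new
                mu = max(mu * hyper.lcd, 1e-15)
                accepted = True
                break
            mu *= hyper.lci
            if mu > 1e12:
                break
        if not accepted:
            break

        train_trace.append(float(np.sqrt(r @ r / r.size)))
        v = val_rmsep_of(theta)
        val_trace.append(v)
        if v < best_val:
            best_val, best_theta, since_best = v, theta.copy(), 0
        else:
            since_best += 1
            if hyper.early_stopping and since_best >= hyper.patience:
                break
        if gain < hyper.loss_tol * max(loss, 1.0):
            break

    if not hyper.early_stopping:
        best_theta, best_val = theta, val_rmsep_of(theta)
    w1, b1, w2, b2 = _unpack(best_theta, p, hdim, k)
    return AnnModel(
        w_in=w1, b_hidden=b1, w_out=w2, b_out=b2,
        x_center=x_center, y_center=y_center, hyper=hyper,
        wavelengths_nm=dataset.wavelengths_nm, analytes=dataset.analytes,
        trace={"train_rmsep": train_trace, "val_rmsep": val_trace,
               "best_val_rmsep": [best_val]},
    )


def predict(model: AnnModel, spectra_matrix: np.ndarray) -> np.ndarray:
    """Concentrations (ug/mL) for absorbance rows on the model window.

    ``y = transfer2(transfer1((x - x_center) W_in + b_h) W_out + b_out)
    + y_center``; the model is never mutated.
    """
    x = np.atleast_2d(np.asarray(spectra_matrix, dtype=float))
    if x.shape[1] != model.w_in.shape[0]:
        raise ValueError(
            f"input width {x.shape[1]} does not match the model window "
            f"({model.w_in.shape[0]} points)"
        )
    out, _ = _forward(x - model.x_center, model.w_in, model.b_hidden,
                      model.w_out, model.b_out, model.hyper.hidden_transfer)
    return out + model.y_center
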