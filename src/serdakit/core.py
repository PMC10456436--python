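"""SERDA: systematic error removal using a denoising autoencoder.

Drift and batch effects in large GC-MS acquisitions are *sample-wise*
phenomena: at a given injection, most compounds are biased together by
instrument state, derivatization completeness and injection behaviour. SERDA
exploits this by training a single-hidden-layer denoising autoencoder on the
pooled-QC profiles (on a glog / auto-scaled space). Because every QC
injection is the same material, the autoencoder's reconstruction of a
profile captures its systematic component; subtracting the mean-centered
reconstruction from any target profile removes the systematic error while
preserving each compound's mean level.

Pipeline (training QCs = x1, targets = x2, d compounds):

1.  glog-transform both matrices: ``g(x) = log2((x + sqrt(x^2 + lam^2))/2)``.
2.  per-compound noise scale ``sigma_j = max(sd(x2_j) - sd(x1_j), 0)``.
3.  corrupt the training profiles with Gaussian noise ``N(0, sigma_j^2)``
    (optionally oversampling: n extra noisy replicates of each QC).
4.  auto-scale (per-compound mean 0 / sd 1; one affine map for both sets).
5.  train the autoencoder ``phi(x) = s(W' s(W x + b) + b')`` (s = elu,
    mean-absolute-error loss, mini-batch Adam) with random input dropout;
    early stopping on a held-out 20% of QCs picks the epoch count n_e, then
    the model is retrained from scratch on all QCs for n_e epochs.
6.  corrected target = ``x2 - (phi(x2) - colmean(phi(x2)))``; optional
    per-batch median equalization; invert auto-scaling and glog.

Hyperparameters (hidden width d', dropout rate nu, oversampling n,
mini-batch size b) are selected by k-fold cross-validation on the QCs,
scored by the median per-compound RSD of the pooled held-out corrected
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import FeatureTable, RoleSelection, select_samples
from .sumnorm import NormalizationError, median_normalize

logger = logging.getLogger("serdakit")

_SD_FLOOR = 1e-8  # constant-compound guard for auto-scaling


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class HyperParams:
    """Training settings for the denoising autoencoder."""

    n_oversample: int = 0
    nu: float = 0.1
    d_prime: int = 32
    batch_size: int = 16
    activation: str = "elu"
    patience: int = 50
    max_epochs: int = 2000
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_prime < 1:
            raise NormalizationError("hidden width d_prime must be >= 1")
        if not 0.0 <= self.nu < 1.0:
            raise NormalizationError("dropout rate nu must lie in [0, 1)")
        if self.n_oversample < 0:
            raise NormalizationError("oversampling count must be >= 0")
        if self.batch_size < 1:
            raise NormalizationError("batch_size must be >= 1")
        if self.activation != "elu":
            raise NormalizationError(f"unsupported activation {self.activation!r}")


@dataclass(frozen=True)
class CorruptionSpec:
    """Per-compound Gaussian noise scale plus input-dropout proportion."""

    sigma: np.ndarray
    nu: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if (self.sigma < 0).any():
            raise NormalizationError("noise sigma must be nonnegative")
        if not 0.0 <= self.nu < 1.0:
            raise NormalizationError("dropout proportion nu must lie in [0, 1)")


# ----------------------------------------------------------------------
# transforms
# ----------------------------------------------------------------------
def glog_transform(
    matrix, lam: float = 0.0, zero_offset: float = 1.0
) -> np.ndarray:
    """Generalized log (base 2): ``g(x) = log2((x + sqrt(x^2 + lam^2))/2)``.

    Behaves like log2 for ``x >> lam`` and linearly near zero. With
    ``lam = 0`` this is plain log2; exact zeros are then lifted to
    ``zero_offset`` (a one-ion-count noise floor) so the transform stays
    finite.
    """
    x = np.asarray(matrix, dtype=float)
    if lam < 0:
        raise NormalizationError("glog lambda must be >= 0")
    if (x < 0).any():
        raise NormalizationError("glog input must be nonnegative")
    if lam == 0.0:
        x = np.where(x == 0.0, zero_offset, x)
        return np.log2(x)
    return np.log2((x + np.sqrt(x * x + lam * lam)) / 2.0)


def inverse_glog(matrix, lam: float = 0.0) -> np.ndarray:
    """Algebraic inverse of :func:`glog_transform`: ``x = u - lam^2/(4u)``
    with ``u = 2^g`` (clipped at 0 for lam > 0 round-off)."""
    g = np.asarray(matrix, dtype=float)
    with np.errstate(over="raise"):
        u = np.exp2(g)
    if lam == 0.0:
        return u
    return np.maximum(u - lam * lam / (4.0 * u), 0.0)


def estimate_noise_sigma(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Per-compound corruption scale ``max(sd(x2_j) - sd(x1_j), 0)``.

    x1/x2 are glog-scale training/target matrices; sd uses the n-1
    denominator. The clamp at zero covers compounds where the QCs already
    vary more than the targets.
    """
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise NormalizationError("sigma estimation needs >= 2 rows per matrix")
    return np.maximum(x2.std(axis=0, ddof=1) - x1.std(axis=0, ddof=1), 0.0)


def _dropout_mask(rng: np.random.Generator, shape, nu: float) -> np.ndarray:
    """Row-wise mask zeroing exactly floor(nu * d) entries per row."""
    n, d = shape
    k = int(np.floor(nu * d))
    mask = np.ones((n, d))
    if k > 0:
        for i in range(n):
            mask[i, rng.choice(d, size=k, replace=False)] = 0.0
    return mask


def corrupt(
    x1: np.ndarray, spec: CorruptionSpec, rng: np.random.Generator
) -> np.ndarray:
    """Corrupted copy ``(x + r)_`` : Gaussian noise then elementwise dropout."""
    x1 = np.asarray(x1, float)
    noisy = x1 + rng.standard_normal(x1.shape) * spec.sigma
    return noisy * _dropout_mask(rng, noisy.shape, spec.nu)


def oversample(
    x1: np.ndarray, n: int, spec: CorruptionSpec, rng: np.random.Generator
) -> np.ndarray:
    """Stack ``x1`` with ``n`` fresh Gaussian-noise replicates of its rows."""
    if n < 0:
        raise NormalizationError("oversampling count must be >= 0")
    x1 = np.asarray(x1, float)
    reps = [x1]
    for _ in range(n):
        reps.append(x1 + rng.standard_normal(x1.shape) * spec.sigma)
    return np.vstack(reps)


@dataclass
class Autoscaler:
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd

    def invert(self, x: np.ndarray) -> np.ndarray:
        return x * self.sd + self.mean


def autoscale_fit_apply(
    train: np.ndarray, target: np.ndarray, fit_on: str = "both"
) -> tuple[np.ndarray, np.ndarray, Autoscaler]:
    """Per-compound standardization; one affine map for both matrices.

    ``fit_on="both"`` pools training and target rows for the statistics
    (default), ``"train"`` uses the training rows only. Constant compounds
    get an sd floor so they scale to zeros rather than blowing up.
    """
    if fit_on not in {"both", "train"}:
        raise NormalizationError(f"unknown fit_on {fit_on!r}")
    ref = np.vstack([train, target]) if fit_on == "both" else np.asarray(train)
    sd = ref.std(axis=0, ddof=1)
    n_const = int((sd < _SD_FLOOR).sum())
    if n_const:
        logger.info("autoscale: %d constant compounds floored", n_const)
    scaler = Autoscaler(mean=ref.mean(axis=0), sd=np.maximum(sd, _SD_FLOOR))
    return scaler.apply(train), scaler.apply(target), scaler


# ----------------------------------------------------------------------
# the autoencoder
# ----------------------------------------------------------------------
def _elu(a: np.ndarray) -> np.ndarray:
    return np.where(a > 0, a, np.expm1(np.minimum(a, 0.0)))


def _elu_grad(a: np.ndarray) -> np.ndarray:
    return np.where(a > 0, 1.0, np.exp(np.minimum(a, 0.0)))


@dataclass
class SerdaModel:
    """Trained autoencoder: ``phi(x) = elu(W' elu(W x + b_enc) + b_dec)``."""

    W: np.ndarray  # (d_prime, d)
    b_enc: np.ndarray  # (d_prime,)
    W_prime: np.ndarray  # (d, d_prime)
    b_dec: np.ndarray  # (d,)
    activation: str = "elu"
    n_epochs: int = 0
    scaler: Autoscaler | None = None
    glog_lambda: float = 0.0
    hyperparams: HyperParams | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[1] != self.W.shape[1]:
            raise NormalizationError(
                f"input has {x.shape[1]} compounds, model expects {self.W.shape[1]}"
            )
        y = _elu(x @ self.W.T + self.b_enc)
        return _elu(y @ self.W_prime.T + self.b_dec)


def init_params(d: int, d_prime: int, rng: np.random.Generator) -> SerdaModel:
    """Glorot-uniform weights (limit sqrt(6/(d + d'))), zero biases."""
    if d < 1 or d_prime < 1:
        raise NormalizationError("dimensions must be positive")
    limit = np.sqrt(6.0 / (d + d_prime))
    return SerdaModel(
        W=rng.uniform(-limit, limit, size=(d_prime, d)),
        b_enc=np.zeros(d_prime),
        W_prime=rng.uniform(-limit, limit, size=(d, d_prime)),
        b_dec=np.zeros(d),
    )


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _mae(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean(np.abs(pred - target)))


def _train_epochs(
    model: SerdaModel,
    noisy: np.ndarray,
    clean: np.ndarray,
    hp: HyperParams,
    rng: np.random.Generator,
    n_epochs: int,
    val_noisy: np.ndarray | None = None,
    val_clean: np.ndarray | None = None,
):
    """Mini-batch Adam on MAE; returns (best_val_mae, best_epoch, snapshot).

    Each epoch applies a fresh input-dropout mask to the noisy rows, then
    one full pass over shuffled mini-batches. Validation (if given) is the
    clean-target MAE on the corrupted held-out rows, no dropout.
    """
    n = noisy.shape[0]
    params = [model.W, model.b_enc, model.W_prime, model.b_dec]
    opt = _Adam(params, lr=hp.learning_rate)
    best = (np.inf, 0, None)
    bad_epochs = 0
    for epoch in range(1, n_epochs + 1):
        x_in = noisy * _dropout_mask(rng, noisy.shape, hp.nu)
        order = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xb, tb = x_in[idx], clean[idx]
            a1 = xb @ model.W.T + model.b_enc
            y = _elu(a1)
            a2 = y @ model.W_prime.T + model.b_dec
            z = _elu(a2)
            if not np.isfinite(z).all():
                raise NormalizationError("non-finite activations during training")
            dz = np.sign(z - tb) / z.size
            da2 = dz * _elu_grad(a2)
            dWp = da2.T @ y
            dbd = da2.sum(axis=0)
            dy = da2 @ model.W_prime
            da1 = dy * _elu_grad(a1)
            dW = da1.T @ xb
            dbe = da1.sum(axis=0)
            opt.step(params, [dW, dbe, dWp, dbd])
        if val_noisy is not None:
            val = _mae(model.forward(val_noisy), val_clean)
            if val < best[0]:
                best = (
                    val,
                    epoch,
                    [p.copy() for p in params],
                )
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= hp.patience:
                    break
        if epoch % 50 == 0:
            logger.debug("epoch %d", epoch)
    return best


def fit_dae(
    noisy: np.ndarray,
    clean: np.ndarray,
    hp: HyperParams,
) -> SerdaModel:
    """Two-phase denoising-autoencoder fit on auto-scaled QC profiles.

    Phase A holds out a random 20% of rows, trains with early stopping
    (no improvement of held-out MAE for ``hp.patience`` epochs) and records
    the best epoch count n_e. Phase B reinitializes and trains n_e epochs on
    all rows. Deterministic for fixed (data, hp): all randomness is drawn
    from streams fanned out of ``hp.seed``.
    """
    noisy = np.asarray(noisy, float)
    clean = np.asarray(clean, float)
    if noisy.shape != clean.shape:
        raise NormalizationError("noisy/clean shape mismatch")
    n, d = noisy.shape
    if n < 5:
        raise NormalizationError("need >= 5 training rows")
    if hp.batch_size > n:
        raise NormalizationError(
            f"batch_size {hp.batch_size} exceeds {n} training rows"
        )
    ss = np.random.SeedSequence(hp.seed)
    rng_split, rng_init_a, rng_train_a, rng_init_b, rng_train_b = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # phase A: 80/20 split, early stopping
    perm = rng_split.permutation(n)
    n_val = max(1, int(round(0.2 * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    model = init_params(d, hp.d_prime, rng_init_a)
    best_val, n_e, _ = _train_epochs(
        model,
        noisy[tr_idx],
        clean[tr_idx],
        hp,
        rng_train_a,
        hp.max_epochs,
        val_noisy=noisy[val_idx],
        val_clean=clean[val_idx],
    )
    n_e = max(n_e, 1)
    logger.info("early stopping: n_e=%d, held-out MAE=%.4g", n_e, best_val)

    # phase B: retrain n_e epochs on everything
    model = init_params(d, hp.d_prime, rng_init_b)
    _train_epochs(model, noisy, clean, hp, rng_train_b, n_e)
    model.n_epochs = n_e
    model.hyperparams = hp
    return model


# ----------------------------------------------------------------------
# the full normalization
# ----------------------------------------------------------------------
@dataclass
class NormalizationResult:
    """Corrected target table plus the fitted model and run provenance."""

    normalized: FeatureTable
    x2_prime: np.ndarray | None = None
    predicted_error_mean: np.ndarray | None = None
    model: object | None = None
    provenance: dict = field(default_factory=dict)


def serda_normalize(
    table: FeatureTable,
    selection: RoleSelection | None = None,
    hp: HyperParams | None = None,
    median_norm: bool = False,
    glog_lambda: float = 0.0,
    scale_fit_on: str = "both",
) -> NormalizationResult:
    """Run the full SERDA pipeline and return the corrected target table."""
    selection = selection or RoleSelection()
    hp = hp or HyperParams()
    train_tbl, target_tbl = select_samples(table, selection)
    if train_tbl.n_samples < 5:
        raise NormalizationError(
            f"SERDA needs >= 5 training QCs, got {train_tbl.n_samples}"
        )

    x1 = glog_transform(train_tbl.intensities, glog_lambda)
    x2 = glog_transform(target_tbl.intensities, glog_lambda)
    sigma = estimate_noise_sigma(x1, x2)

    # distinct stream from the ones fit_dae derives from hp.seed
    rng_corrupt = np.random.default_rng(
        np.random.SeedSequence(entropy=hp.seed, spawn_key=(999,))
    )
    spec = CorruptionSpec(sigma=sigma, nu=hp.nu)

    # Gaussian corruption (+ oversampling); dropout happens inside training
    clean = np.tile(x1, (hp.n_oversample + 1, 1))
    noisy = clean + rng_corrupt.standard_normal(clean.shape) * sigma

    x1s, x2s, scaler = autoscale_fit_apply(x1, x2, fit_on=scale_fit_on)
    noisy_s = scaler.apply(noisy)
    clean_s = scaler.apply(clean)

    model = fit_dae(noisy_s, clean_s, hp)
    model.scaler = scaler
    model.glog_lambda = glog_lambda

    phi = model.forward(x2s)
    phi_mean = phi.mean(axis=0)
    x2_prime = x2s - (phi - phi_mean)
    if median_norm:
        x2_prime = median_normalize(
            x2_prime, target_tbl.samples["batch"].to_numpy()
        )
    corrected = inverse_glog(scaler.invert(x2_prime), glog_lambda)
    if not np.isfinite(corrected).all():
        raise NormalizationError("non-finite corrected intensities")

    return NormalizationResult(
        normalized=target_tbl.with_intensities(corrected),
        x2_prime=x2_prime,
        predicted_error_mean=phi_mean,
        model=model,
        provenance={
            "method": "serda",
            "seed": hp.seed,
            "n_training": train_tbl.n_samples,
            "n_target": target_tbl.n_samples,
            "n_epochs": model.n_epochs,
            "median_norm": median_norm,
            "glog_lambda": glog_lambda,
            "sigma_median": float(np.median(spec.sigma)),
        },
    )


# ----------------------------------------------------------------------
# hyperparameter selection
# ----------------------------------------------------------------------
def injection_order_folds(order: np.ndarray, k: int) -> np.ndarray:
    """Round-robin fold labels over samples sorted by injection order.

    Every fold then spans the whole acquisition period instead of being a
    contiguous (and drift-confounded) block.
    """
    order = np.asarray(order)
    if len(order) < k:
        raise NormalizationError(
            f"{len(order)} QCs cannot form {k} folds; use a smaller k"
        )
    folds = np.empty(len(order), dtype=int)
    folds[np.argsort(order, kind="stable")] = np.arange(len(order)) % k
    return folds


def default_grid(n_train: int, d: int, seed: int = 0) -> list[HyperParams]:
    """A small robust grid: the method is insensitive to these choices."""
    grid = []
    for d_prime in (8, 32, min(128, d)):
        for nu in (0.1, 0.3):
            grid.append(
                HyperParams(
                    d_prime=d_prime,
                    nu=nu,
                    batch_size=min(16, max(2, n_train // 2)),
                    seed=seed,
                )
            )
    return grid


def tune_hyperparameters(
    table: FeatureTable,
    selection: RoleSelection | None = None,
    grid: list[HyperParams] | None = None,
    k: int = 5,
    glog_lambda: float = 0.0,
) -> tuple[HyperParams, list[dict]]:
    """k-fold CV over training QCs; score = median per-compound RSD of the
    pooled held-out corrected values. Ties break to smaller d', then smaller
    oversampling count."""
    from .evaluation import compound_rsd_matrix  # local import: no cycle at load

    selection = selection or RoleSelection()
    table = table.sorted_by_injection()
    train_mask, _ = selection.masks(table)
    qc_ids = np.asarray(table.sample_ids)[train_mask]
    qc_order = table.samples["injection_order"].to_numpy()[train_mask]
    if grid is None:
        grid = default_grid(len(qc_ids), table.n_compounds)
    if not grid:
        raise NormalizationError("hyperparameter grid is empty")
    folds = injection_order_folds(qc_order, k)

    scores: list[dict] = []
    for hp in grid:
        held = []
        for f in range(k):
            sel = RoleSelection(
                training_roles=selection.training_roles,
                training_ids=tuple(qc_ids[folds != f]),
                target_ids=tuple(qc_ids[folds == f]),
            )
            res = serda_normalize(table, sel, hp, glog_lambda=glog_lambda)
            held.append(res.normalized.intensities)
        pooled = np.vstack(held)
        rsd = compound_rsd_matrix(pooled)
        score = float(np.nanmedian(rsd))
        scores.append({"hyperparams": hp, "cv_median_rsd": score})
        logger.info(
            "CV d'=%d nu=%.2f n=%d -> median RSD %.2f%%",
            hp.d_prime,
            hp.nu,
            hp.n_oversample,
            score,
        )
    best = min(
        scores,
        key=lambda s: (
            s["cv_median_rsd"],
            s["hyperparams"].d_prime,
            s["hyperparams"].n_oversample,
        ),
    )
    return best["hyperparams"], scores
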