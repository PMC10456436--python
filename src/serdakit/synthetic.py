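"""Synthetic multi-batch GC-MS acquisition with known ground truth.

Emulates the study design that QC-based normalization assumes: a long
injection sequence split into batches, pooled QCs injected every
``qc_interval`` study samples, an independent validation-QC material,
blinded duplicate pairs, and systematic error composed of

* smooth shared drift — a few latent factor paths (smoothed random walks
  with a jump at every batch boundary) times per-compound loadings,
* compound-specific batch offsets (maintenance discontinuities),
* a per-injection scalar effect shared by all compounds (injection/
  derivatization variability — random in time, so time-smoothers cannot
  catch it, but profile-based methods can),
* iid per-cell noise.

All terms act on the log2 scale; study samples add iid biological
variation, validation QCs add a fixed compositional shift relative to the
pool, and a configurable fraction of compounds is drift-immune so the
correlation structure is heterogeneous. The returned
:class:`SyntheticTruth` exposes the exact systematic term per injection so
recovery by a normalizer is directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import FeatureTable, FeatureTableError


@dataclass(frozen=True)
class SyntheticConfig:
    """Defaults mirror a large cohort acquisition: ~960 injections over 7
    batches with a pool QC and a validation QC every 10 study samples, and a
    raw pool-QC median RSD around 50-60%."""

    d: int = 200
    n_study: int = 800
    n_batches: int = 7
    qc_interval: int = 10
    validation_interval: int = 10
    n_factors: int = 3
    drift_scale: float = 0.95  # log2 sd of the factor-drift term
    batch_offset_scale: float = 0.45  # log2 sd of compound x batch offsets
    sample_effect_scale: float = 0.10  # log2 sd of the per-injection scalar
    noise_scale: float = 0.12  # log2 sd of iid cell noise
    bio_scale: float = 0.25  # log2 sd of study-sample biology
    qc_bio_shift_scale: float = 0.10  # validation-QC compositional shift
    immune_fraction: float = 0.10  # drift-immune compounds
    drift_smooth: int = 15  # moving-average window (injections)
    replicate_pairs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.d, self.n_study, self.n_batches, self.n_factors) < 1:
            raise FeatureTableError("all counts must be positive")
        if self.qc_interval > self.n_study or self.validation_interval > self.n_study:
            raise FeatureTableError("QC interval exceeds the study sample count")
        for name in (
            "drift_scale",
            "batch_offset_scale",
            "sample_effect_scale",
            "noise_scale",
            "bio_scale",
            "qc_bio_shift_scale",
        ):
            if getattr(self, name) < 0:
                raise FeatureTableError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    """Latent generative state of one simulated acquisition."""

    mu: np.ndarray  # (d,) log2 baselines
    loadings: np.ndarray  # (d, n_factors)
    factor_paths: np.ndarray  # (n_injections, n_factors)
    batch_offsets: np.ndarray  # (d, n_batches)
    sample_effects: np.ndarray  # (n_injections,)
    qc_bio_shift: np.ndarray  # (d,)
    systematic: np.ndarray  # (n_injections, d) drift+batch+sample term
    sample_ids: list = field(default_factory=list)
    seed: int = 0


def correlated_drift_config(seed: int = 0, d: int = 150) -> SyntheticConfig:
    """Method-comparison regime: many weakly-shared drift modes plus strong
    per-injection random systematic error and cell noise.

    This is the situation that motivates profile-based correction:
    time-smoothers cannot remove error that is random in time, and
    per-compound regression on correlated neighbours degrades when the
    correlation structure is heterogeneous and noisy.
    """
    return SyntheticConfig(
        d=d,
        n_study=800,
        n_factors=12,
        noise_scale=0.18,
        sample_effect_scale=0.3,
        replicate_pairs=4,
        seed=seed,
    )


def uncorrelated_smooth_drift_config(seed: int = 0, d: int = 100) -> SyntheticConfig:
    """Smooth slow drift with weak cross-compound correlation (many
    independent drift modes, no shared per-injection effect) — the regime
    where a time-smoother shines and correlation-based methods struggle."""
    return SyntheticConfig(
        d=d,
        n_study=400,
        n_factors=60,
        noise_scale=0.12,
        sample_effect_scale=0.0,
        replicate_pairs=0,
        seed=seed,
    )


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = np.pad(x, (window, window), mode="edge")
    return np.convolve(pad, kernel, mode="same")[window:-window]


def _build_sequence(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Injection sequence: leading QCs, then study samples with pool /
    validation QCs interleaved at their intervals and duplicate pairs
    embedded (half adjacent, half ~half-a-batch apart)."""
    rows = [("pool_qc", None), ("validation_qc", None)]
    n_rep = 2 * cfg.replicate_pairs
    if n_rep > cfg.n_study:
        raise FeatureTableError("more replicate members than study samples")

    study_payload: list[tuple[str, str | None]] = [
        ("study", None) for _ in range(cfg.n_study - n_rep)
    ]
    # adjacent pairs first, nonadjacent pairs spread ~40 slots apart
    n_adj = cfg.replicate_pairs // 2
    for p in range(cfg.replicate_pairs):
        g = f"rep{p}"
        if p < n_adj:
            pos = rng.integers(0, max(1, len(study_payload) - 1))
            study_payload.insert(pos, ("replicate", g))
            study_payload.insert(pos + 1, ("replicate", g))
        else:
            pos = rng.integers(0, max(1, len(study_payload) - 45))
            study_payload.insert(pos, ("replicate", g))
            study_payload.insert(pos + 41, ("replicate", g))

    for i, item in enumerate(study_payload, start=1):
        rows.append(item)
        if i % cfg.qc_interval == 0:
            rows.append(("pool_qc", None))
        if i % cfg.validation_interval == 0:
            rows.append(("validation_qc", None))

    n = len(rows)
    batch_len = int(np.ceil(n / cfg.n_batches))
    seq = pd.DataFrame(
        {
            "role": [r for r, _ in rows],
            "replicate_group": [g for _, g in rows],
            "injection_order": np.arange(1, n + 1),
            "batch": [f"B{i // batch_len + 1}" for i in range(n)],
            "batch_index": [i // batch_len for i in range(n)],
        }
    )
    counters: dict[str, int] = {}
    ids = []
    for role in seq["role"]:
        counters[role] = counters.get(role, 0) + 1
        # seed tag keeps ids distinct across simulations, so a table can be
        # matched to the truth object it was generated with
        ids.append(f"{role}_{counters[role]:04d}_r{cfg.seed}")
    seq.index = pd.Index(ids, name="sample_id")
    return seq


def simulate_study(cfg: SyntheticConfig) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate one acquisition; same seed gives a bit-identical result."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_layout, rng_truth, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    seq = _build_sequence(cfg, rng_layout)
    n = len(seq)

    mu = rng_truth.uniform(10.0, 20.0, size=cfg.d)
    loadings = rng_truth.normal(
        0.0, cfg.drift_scale / np.sqrt(cfg.n_factors), size=(cfg.d, cfg.n_factors)
    )
    n_immune = int(np.floor(cfg.immune_fraction * cfg.d))
    if n_immune:
        immune = rng_truth.choice(cfg.d, size=n_immune, replace=False)
        loadings[immune] *= 0.05

    batch_idx = seq["batch_index"].to_numpy()
    paths = np.empty((n, cfg.n_factors))
    for f in range(cfg.n_factors):
        walk = np.cumsum(rng_truth.standard_normal(n))
        walk = _smooth(walk, cfg.drift_smooth)
        jumps = rng_truth.normal(0.0, 1.0, size=cfg.n_batches)
        walk = walk + jumps[batch_idx] * walk.std() * 0.5
        paths[:, f] = (walk - walk.mean()) / max(walk.std(), 1e-12)

    batch_offsets = rng_truth.normal(
        0.0, cfg.batch_offset_scale, size=(cfg.d, cfg.n_batches)
    )
    sample_effects = rng_truth.normal(0.0, cfg.sample_effect_scale, size=n)
    qc_bio_shift = rng_truth.normal(0.0, cfg.qc_bio_shift_scale, size=cfg.d)

    systematic = (
        paths @ loadings.T + batch_offsets.T[batch_idx] + sample_effects[:, None]
    )

    log2x = mu[None, :] + systematic.copy()
    roles = seq["role"].to_numpy()
    rep_bio: dict[str, np.ndarray] = {}
    for i, (role, rg) in enumerate(zip(roles, seq["replicate_group"])):
        if role == "validation_qc":
            log2x[i] += qc_bio_shift
        elif role == "replicate":
            if rg not in rep_bio:
                rep_bio[rg] = rng_noise.normal(0.0, cfg.bio_scale, size=cfg.d)
            log2x[i] += rep_bio[rg]
        elif role == "study":
            log2x[i] += rng_noise.normal(0.0, cfg.bio_scale, size=cfg.d)
    log2x += rng_noise.normal(0.0, cfg.noise_scale, size=(n, cfg.d))

    compounds = pd.DataFrame(
        index=pd.Index([f"C{j:04d}" for j in range(cfg.d)], name="compound_id")
    )
    compounds["is_identified"] = True
    compounds["is_istd"] = False
    compounds["is_fame"] = False
    samples = seq[["injection_order", "batch", "role", "replicate_group"]].copy()

    table = FeatureTable(
        intensities=np.exp2(log2x), samples=samples, compounds=compounds
    )
    truth = SyntheticTruth(
        mu=mu,
        loadings=loadings,
        factor_paths=paths,
        batch_offsets=batch_offsets,
        sample_effects=sample_effects,
        qc_bio_shift=qc_bio_shift,
        systematic=systematic,
        sample_ids=list(seq.index),
        seed=cfg.seed,
    )
    return table, truth


def truth_drift_correlation(
    table: FeatureTable, truth: SyntheticTruth, role: str = "pool_qc"
) -> pd.Series:
    """Per-compound Pearson r between log2 intensities of ``role`` samples
    and the true systematic term at those injections.

    High |r| means the drift is still present; a good normalizer drives it
    toward 0. Compounds whose systematic term is (near-)constant are
    reported as 0.
    """
    pos = {sid: i for i, sid in enumerate(truth.sample_ids)}
    missing = [s for s in table.sample_ids if s not in pos]
    if missing:
        raise FeatureTableError(
            f"table/truth provenance mismatch: unknown samples {missing[:3]}"
        )
    mask = table.role_mask(role)
    if mask.sum() < 3:
        raise FeatureTableError(f"need >= 3 samples of role {role!r}")
    rows = np.where(mask)[0]
    truth_rows = np.array([pos[table.sample_ids[i]] for i in rows])
    logx = np.log2(np.maximum(table.intensities[rows], 1e-12))
    sys_term = truth.systematic[truth_rows]

    out = np.zeros(table.n_compounds)
    for j in range(table.n_compounds):
        s = sys_term[:, j]
        x = logx[:, j]
        if s.std() < 1e-9 or x.std() < 1e-12:
            continue
        out[j] = np.corrcoef(x, s)[0, 1]
    return pd.Series(out, index=table.compound_ids)
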