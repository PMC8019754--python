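"""Synthetic two-group data with planted, unit-specific discriminative moments.

``generate_fc_dataset`` draws, for every subject and ROI-pair unit, a
stationary AR(1) Gaussian FC sequence with subject-level random effects on
its mean and spread. At *planted* units the patient group's designated
moment order is shifted by an effect size Delta expressed in pooled-SD units
of that moment's null subject-level distribution:

- order 1: additive mean shift (exact);
- order 2: within-sequence SD inflation (exact in expectation), paired with a
  tail-lightening shape compensation so the 4th and 6th central moments —
  which co-move with any variance change — stay close to their null
  expectations and the *designated* moment alone carries the group
  difference;
- orders >= 3: a sinh-arcsinh shape transform of the innovations whose
  parameter is calibrated numerically (bisection on a fixed reference sample)
  so the target central moment shifts by approximately Delta; the marginal is
  re-standardized so mean and variance stay put. Exactness is not claimed for
  these orders.

Unplanted units are identically distributed in both groups, so they carry no
signal by construction. ``generate_bold_dataset`` instead plants signal at
the ROI *time-series* level through group-dependent covariance regimes, so
the whole pipeline (window correlation onward) can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dfcn import RoiTimeSeries

__all__ = [
    "PlantedDesign",
    "FCDataset",
    "generate_fc_dataset",
    "generate_bold_dataset",
]

_CAL_SEED = 20_210_322  # fixed internal seed for the calibration reference sample
_N_CAL = 4000


@dataclass
class PlantedDesign:
    """Two-group FC-sequence design with per-unit planted moment differences.

    ``plant_map`` maps a unit (i, j), 0-based with i < j, to (d*, Delta):
    the moment order carrying the group difference and its effect size in
    pooled-SD units. ``phi`` is the lag-1 autocorrelation of every sequence
    (overlapping windows make consecutive FC values correlated); the
    subject-level random effects ``between_sd`` (sequence mean) and
    ``log_sd_jitter`` (log of the sequence spread) give features realistic
    between-subject variability.
    """

    m: int
    k: int
    n_per_group: int
    plant_map: dict[tuple[int, int], tuple[int, float]] = field(default_factory=dict)
    phi: float = 0.3
    clip: bool = False
    seed: int = 0
    base_mean: float = 0.2
    between_sd: float = 0.1
    within_sd: float = 0.15
    log_sd_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.m < 2 or self.k < 2 or self.n_per_group < 2:
            raise ValueError("need M >= 2, K >= 2 and n_per_group >= 2")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("AR coefficient must lie in [0, 1)")
        for (i, j), (d, delta) in self.plant_map.items():
            if not (0 <= i < j < self.m):
                raise ValueError(f"planted unit ({i}, {j}) is not a valid pair (i < j < M)")
            if d < 1:
                raise ValueError(f"planted order must be >= 1 at unit ({i}, {j})")
            if delta < 0:
                raise ValueError(f"effect size must be >= 0 at unit ({i}, {j})")

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "k": self.k,
            "n_per_group": self.n_per_group,
            "plant_map": {f"{i},{j}": [d, delta] for (i, j), (d, delta) in self.plant_map.items()},
            "phi": self.phi,
            "clip": self.clip,
            "seed": self.seed,
            "base_mean": self.base_mean,
            "between_sd": self.between_sd,
            "within_sd": self.within_sd,
            "log_sd_jitter": self.log_sd_jitter,
        }


@dataclass
class FCDataset:
    """Per-subject FC sequences for all units, plus binary labels."""

    sequences: np.ndarray  # (n_subjects, n_units, K)
    labels: np.ndarray
    units: list[tuple[int, int]]
    m: int
    design: PlantedDesign
    subject_ids: list[str]

    def feature_tensors(self, n_orders: int = 7) -> np.ndarray:
        """Moment features per subject as a stacked (n, D, M, M) array."""
        seqs = self.sequences
        mean = seqs.mean(axis=2)
        dev = seqs - mean[..., None]
        n = seqs.shape[0]
        out = np.zeros((n, n_orders, self.m, self.m))
        iu = np.array([u[0] for u in self.units])
        ju = np.array([u[1] for u in self.units])
        out[:, 0, iu, ju] = mean
        out[:, 0, ju, iu] = mean
        for d in range(2, n_orders + 1):
            md = np.mean(dev**d, axis=2)
            out[:, d - 1, iu, ju] = md
            out[:, d - 1, ju, iu] = md
        return out


def _ar_sequences(rng: np.random.Generator, shape: tuple[int, ...], k: int, phi: float) -> np.ndarray:
    """Stationary AR(1) sequences with N(0, 1) marginals, shape (*shape, K)."""
    eps = rng.standard_normal(shape + (k,))
    z = np.empty_like(eps)
    z[..., 0] = eps[..., 0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, k):
        z[..., t] = phi * z[..., t - 1] + scale * eps[..., t]
    return z


def _central_moment(seqs: np.ndarray, d: int) -> np.ndarray:
    if d == 1:
        return seqs.mean(axis=-1)
    dev = seqs - seqs.mean(axis=-1, keepdims=True)
    return np.mean(dev**d, axis=-1)


def _sinh_arcsinh(z: np.ndarray, eps: float, inv_delta: float) -> np.ndarray:
    """Jones-Pewsey transform; eps skews, inv_delta > 1 fattens the tails."""
    return np.sinh(inv_delta * np.arcsinh(z) + eps)


class _Calibrator:
    """Null reference sample and shape-parameter calibration for one design.

    Built from a fixed internal seed, so calibration depends only on the
    design's distributional parameters, never on the generated dataset.
    """

    def __init__(self, design: PlantedDesign) -> None:
        rng = np.random.default_rng(_CAL_SEED)
        self.design = design
        self.z = _ar_sequences(rng, (_N_CAL,), design.k, design.phi)
        self.mu = design.base_mean + design.between_sd * rng.standard_normal(_N_CAL)
        self.s = design.within_sd * np.exp(design.log_sd_jitter * rng.standard_normal(_N_CAL))
        self.w = rng.standard_normal(200_000)  # marginal standardization sample
        self._null_stats: dict[int, tuple[float, float]] = {}
        self._shape_cache: dict[tuple[int, float], tuple[float, float, float, float]] = {}

    def _features(self, z: np.ndarray, d: int, s_factor: float = 1.0) -> np.ndarray:
        x = self.mu[:, None] + (self.s[:, None] * s_factor) * z
        return _central_moment(x, d)

    def null_stats(self, d: int) -> tuple[float, float]:
        """(mean, SD) of the order-d feature across null subjects."""
        if d not in self._null_stats:
            f = self._features(self.z, d)
            self._null_stats[d] = (float(f.mean()), float(f.std()))
        return self._null_stats[d]

    def mean_shift(self, d: int, delta: float) -> float:
        _, sd = self.null_stats(1)
        return delta * sd if d == 1 else 0.0

    def variance_plant(self, delta: float) -> tuple[float, float, float, float]:
        """(scale c, inv_delta, marginal mean, marginal sd) for an order-2 plant.

        Pure scaling of the sequence spread by c shifts the variance feature
        by exactly (c^2 - 1) * E[f2], but drags the 4th and 6th central
        moments along (they scale as c^4 and c^6). To keep the planted
        difference in the designated moment only, a tail-lightening
        sinh-arcsinh compensation (inv_delta < 1) is calibrated so the
        4th-moment expectation returns to (or toward) its null value; c is
        then set so the variance shift equals delta pooled SDs. The
        compensation is best-effort: if no feasible shape removes the
        4th-moment shift entirely, the lightest searched tail is used.
        """
        key = (2, float(delta))
        if key in self._shape_cache:
            return self._shape_cache[key]
        mean2, sd2 = self.null_stats(2)
        mean4, _ = self.null_stats(4)
        target2 = mean2 + delta * sd2

        def _shape(theta: float) -> tuple[float, float, float, np.ndarray]:
            inv_delta = 1.0 / (1.0 + theta)
            t = _sinh_arcsinh(self.w, 0.0, inv_delta)
            zt = (_sinh_arcsinh(self.z, 0.0, inv_delta) - t.mean()) / t.std()
            return inv_delta, float(t.mean()), float(t.std()), zt

        def _m4_excess(theta: float) -> float:
            _, _, _, zt = _shape(theta)
            c2 = target2 / float(self._features(zt, 2).mean())
            return c2**2 * float(self._features(zt, 4, s_factor=1.0).mean()) - mean4

        lo, hi = 0.0, 3.0
        if _m4_excess(hi) > 0.0:
            theta = hi  # compensation saturates; accept the residual shift
        else:
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                if _m4_excess(mid) > 0.0:
                    lo = mid
                else:
                    hi = mid
            theta = 0.5 * (lo + hi)
        inv_delta, t_mean, t_sd, zt = _shape(theta)
        c = float(np.sqrt(target2 / float(self._features(zt, 2).mean())))
        out = (c, inv_delta, t_mean, t_sd)
        self._shape_cache[key] = out
        return out

    def shape_params(self, d: int, delta: float, unit: tuple[int, int]) -> tuple[float, float, float, float]:
        """(eps, inv_delta, marginal mean, marginal sd) achieving the order-d shift."""
        key = (d, float(delta))
        if key in self._shape_cache:
            return self._shape_cache[key]
        mean_d, sd_d = self.null_stats(d)
        target = mean_d + delta * sd_d
        skew = d % 2 == 1  # odd orders via skewness, even via tail weight

        def shifted_mean(theta: float) -> float:
            eps, inv_delta = (theta, 1.0) if skew else (0.0, 1.0 + theta)
            t = _sinh_arcsinh(self.w, eps, inv_delta)
            zt = (_sinh_arcsinh(self.z, eps, inv_delta) - t.mean()) / t.std()
            return float(self._features(zt, d).mean())

        lo, hi = 0.0, 3.0
        if shifted_mean(hi) < target:
            raise ValueError(
                f"infeasible shape parameters: cannot shift order-{d} moment by "
                f"{delta} pooled SDs at unit {unit}"
            )
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if shifted_mean(mid) < target:
                lo = mid
            else:
                hi = mid
        theta = 0.5 * (lo + hi)
        eps, inv_delta = (theta, 1.0) if skew else (0.0, 1.0 + theta)
        t = _sinh_arcsinh(self.w, eps, inv_delta)
        out = (eps, inv_delta, float(t.mean()), float(t.std()))
        self._shape_cache[key] = out
        return out


def generate_fc_dataset(design: PlantedDesign) -> FCDataset:
    """Draw a two-group collection of FC sequences with planted moments.

    Group 0 (controls) is always drawn from the null model; group 1
    (patients) differs only at the planted units, in the designated moment.
    Deterministic under ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n = 2 * design.n_per_group
    labels = np.repeat([0, 1], design.n_per_group)
    iu, ju = np.triu_indices(design.m, k=1)
    units = list(zip(iu.tolist(), ju.tolist()))
    n_units = len(units)
    unit_pos = {u: p for p, u in enumerate(units)}

    mu = design.base_mean + design.between_sd * rng.standard_normal((n, n_units))
    s = design.within_sd * np.exp(design.log_sd_jitter * rng.standard_normal((n, n_units)))
    z = _ar_sequences(rng, (n, n_units), design.k, design.phi)

    if design.plant_map:
        cal = _Calibrator(design)
        patients = labels == 1
        for unit, (d, delta) in design.plant_map.items():
            u = unit_pos[unit]
            if delta == 0.0:
                continue
            if d == 1:
                mu[patients, u] += cal.mean_shift(1, delta)
            elif d == 2:
                c, inv_delta, t_mean, t_sd = cal.variance_plant(delta)
                zt = _sinh_arcsinh(z[patients, u], 0.0, inv_delta)
                z[patients, u] = (zt - t_mean) / t_sd
                s[patients, u] *= c
            else:
                eps, inv_delta, t_mean, t_sd = cal.shape_params(d, delta, unit)
                zt = _sinh_arcsinh(z[patients, u], eps, inv_delta)
                z[patients, u] = (zt - t_mean) / t_sd

    seqs = mu[..., None] + s[..., None] * z
    if design.clip:
        np.clip(seqs, -1.0, 1.0, out=seqs)
    ids = [f"sub-{i:04d}" for i in range(n)]
    return FCDataset(
        sequences=seqs, labels=labels, units=units, m=design.m,
        design=design, subject_ids=ids,
    )


def generate_bold_dataset(
    m: int,
    t: int,
    n_per_group: int,
    covariance_regimes: dict[int, list[np.ndarray]],
    seed: int = 0,
) -> tuple[list[RoiTimeSeries], np.ndarray]:
    """Two-group ROI time series from group-dependent covariance regimes.

    Each group's scan is a concatenation of equal-length Gaussian segments,
    one per covariance matrix in its regime list, so windowed correlations
    differ between groups exactly where the regime covariances differ.
    """
    for g in (0, 1):
        if g not in covariance_regimes or not covariance_regimes[g]:
            raise ValueError(f"covariance_regimes must list at least one matrix for group {g}")
    chols: dict[int, list[np.ndarray]] = {}
    for g, sigmas in covariance_regimes.items():
        chols[g] = []
        for idx, sigma in enumerate(sigmas):
            sigma = np.asarray(sigma, dtype=float)
            if sigma.shape != (m, m) or not np.allclose(sigma, sigma.T):
                raise ValueError(f"group {g} regime {idx}: covariance must be symmetric {m}x{m}")
            try:
                chols[g].append(np.linalg.cholesky(sigma))
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"group {g} regime {idx}: covariance is not positive definite"
                ) from None

    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n_per_group)
    subjects = []
    for idx, label in enumerate(labels):
        regime_chols = chols[int(label)]
        bounds = np.linspace(0, t, len(regime_chols) + 1).astype(int)
        segments = [
            rng.standard_normal((b - a, m)) @ chol.T
            for (a, b), chol in zip(zip(bounds[:-1], bounds[1:]), regime_chols)
        ]
        subjects.append(
            RoiTimeSeries(
                subject_id=f"sub-{idx:04d}",
                data=np.vstack(segments),
                label=int(label),
            )
        )
    return subjects, labels
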