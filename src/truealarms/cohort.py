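"""Two-wave synthetic cohort generator with persistent latent risk.

The generator emulates the statistical skeleton of a two-wave adolescent
survey in which a one-dimensional latent liability drives both the baseline
(wave-1) suicide-attempt status and, through its persistence between waves,
first-time attempts reported at wave 2.  Observed severity scales are noisy
monotone (here: linear-Gaussian) functions of the wave-1 latent liability;
additional pure-noise features carry no signal.  Wave-2 participation and
item-level missingness are both missing-completely-at-random.

Marginal rates (wave-1 attempt prevalence, first-attempt prevalence among
wave-2 responders, participation, item missingness) are controlled exactly
by calibrating logistic intercepts against the latent distribution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit, roots_hermitenorm

__all__ = [
    "GeneratorConfig",
    "CohortTable",
    "CohortValidationError",
    "CalibrationError",
    "calibrate_intercept",
    "calibrate_intercept_on_sample",
    "generate_cohort",
    "inject_missingness",
    "impute_simple",
    "read_cohort",
    "write_cohort",
]

DEFAULT_LOADINGS = (0.85, 0.80, 0.75, 0.70, 0.65, 0.60)

LABEL_COLUMNS = ("subject_id", "y1", "t2_responded", "y2_first")
LATENT_COLUMNS = ("latent_z1", "latent_z2")


class CohortValidationError(ValueError):
    """A cohort table or generator configuration violates its contract."""


class CalibrationError(RuntimeError):
    """Intercept calibration failed to bracket or converge."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the two-wave generative model.

    Defaults reproduce the study conditions this package targets: a
    wave-1 attempt prevalence of 8.43%, 74% wave-2 participation, 2.1%
    first-time attempts among wave-2 responders without a wave-1 attempt,
    7.52% item missingness, and a latent liability persisting between
    waves with correlation 0.8.
    """

    n_subjects: int = 10832
    n_signal_scales: int = 6
    n_noise_features: int = 14
    loadings: tuple[float, ...] = DEFAULT_LOADINGS
    persistence: float = 0.8
    beta1: float = 2.2
    beta2: float = 1.8
    target_prev_t1: float = 0.0843
    target_prev_t2: float = 0.021
    followup_rate: float = 0.74
    missing_rate: float = 0.0752
    likert_bins: int | None = None
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 1:
            problems.append("n_subjects must be positive")
        if self.n_signal_scales < 0:
            problems.append("n_signal_scales must be >= 0")
        if self.n_noise_features < 0:
            problems.append("n_noise_features must be >= 0")
        if len(self.loadings) != self.n_signal_scales:
            problems.append(
                f"loadings has length {len(self.loadings)}, expected "
                f"n_signal_scales={self.n_signal_scales}"
            )
        if any(not (0.0 < lam < 1.0) for lam in self.loadings):
            problems.append("every loading must lie in (0, 1)")
        if not (0.0 <= self.persistence <= 1.0):
            problems.append("persistence must lie in [0, 1]")
        for name in ("target_prev_t1", "target_prev_t2"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                problems.append(f"{name} must lie in (0, 1)")
        for name in ("followup_rate",):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            problems.append("missing_rate must lie in [0, 1)")
        if self.likert_bins is not None and self.likert_bins < 2:
            problems.append("likert_bins must be >= 2 when set")
        if problems:
            raise CohortValidationError("; ".join(problems))

    @property
    def feature_names(self) -> list[str]:
        return [f"scale_{k + 1}" for k in range(self.n_signal_scales)] + [
            f"noise_{j + 1}" for j in range(self.n_noise_features)
        ]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loadings"] = list(self.loadings)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "loadings" in d:
            d["loadings"] = tuple(d["loadings"])
        return cls(**d)


@dataclass
class CohortTable:
    """Per-subject table of one simulated (or user-supplied) cohort.

    ``data`` holds subject_id, wave-1 label ``y1``, wave-2 participation
    flag ``t2_responded``, the first-attempt label ``y2_first`` (pandas
    nullable integer: defined only for wave-2 responders without a wave-1
    attempt) and the feature columns.  Missing feature cells are NaN.
    ``latent`` optionally carries the hidden liabilities (z1, z2); they
    exist for test oracles only and are never consumed downstream.
    """

    data: pd.DataFrame
    feature_names: list[str]
    latent: pd.DataFrame | None = None
    config: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing_cols = [c for c in LABEL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortValidationError(f"missing label columns: {missing_cols}")
        absent = [c for c in self.feature_names if c not in df.columns]
        if absent:
            raise CohortValidationError(f"missing feature columns: {absent}")
        if df["subject_id"].duplicated().any():
            raise CohortValidationError("subject_id values must be unique")
        defined = df["y2_first"].notna()
        bad = defined & ((df["y1"] == 1) | (df["t2_responded"] == 0))
        if bad.any():
            raise CohortValidationError(
                "y2_first must be undefined when y1=1 or t2_responded=0 "
                f"(violated for {int(bad.sum())} subjects)"
            )
        if self.latent is not None and len(self.latent) != len(df):
            raise CohortValidationError("latent table length mismatch")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean mask of missing feature cells."""
        return self.features.isna()

    def subset(self, subject_ids: np.ndarray) -> "CohortTable":
        idx = self.data["subject_id"].isin(np.asarray(subject_ids)).to_numpy()
        latent = self.latent.loc[idx].reset_index(drop=True) if self.latent is not None else None
        return CohortTable(
            data=self.data.loc[idx].reset_index(drop=True),
            feature_names=list(self.feature_names),
            latent=latent,
            config=self.config,
        )

    def copy(self) -> "CohortTable":
        return CohortTable(
            data=self.data.copy(),
            feature_names=list(self.feature_names),
            latent=None if self.latent is None else self.latent.copy(),
            config=self.config,
        )


def calibrate_intercept(
    beta: float,
    target_prev: float,
    *,
    tol: float = 1e-6,
    n_nodes: int = 96,
) -> float:
    """Intercept alpha with E[logistic(alpha + beta*Z)] = target_prev, Z ~ N(0,1).

    The Gaussian expectation is evaluated by fixed-order Gauss–Hermite
    quadrature (probabilists' weights) and inverted with Brent's method.
    """
    if not (0.0 < target_prev < 1.0):
        raise ValueError("target_prev must lie in (0, 1)")
    if beta == 0.0:
        return float(logit(target_prev))
    nodes, weights = roots_hermitenorm(n_nodes)
    weights = weights / weights.sum()

    def prev_minus_target(alpha: float) -> float:
        return float(np.sum(weights * expit(alpha + beta * nodes)) - target_prev)

    lo, hi = -40.0, 40.0
    if prev_minus_target(lo) > 0 or prev_minus_target(hi) < 0:
        raise CalibrationError(
            f"cannot bracket intercept for beta={beta}, target={target_prev}"
        )
    return float(brentq(prev_minus_target, lo, hi, xtol=tol, maxiter=200))


def calibrate_intercept_on_sample(
    beta: float, z: np.ndarray, target_prev: float, *, tol: float = 1e-9
) -> float:
    """Intercept alpha with mean(logistic(alpha + beta*z)) = target_prev on a sample."""
    if not (0.0 < target_prev < 1.0):
        raise ValueError("target_prev must lie in (0, 1)")
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise CalibrationError("empty calibration sample")

    def prev_minus_target(alpha: float) -> float:
        return float(np.mean(expit(alpha + beta * z)) - target_prev)

    lo, hi = -50.0, 50.0
    if prev_minus_target(lo) > 0 or prev_minus_target(hi) < 0:
        raise CalibrationError(
            f"cannot bracket sample intercept for beta={beta}, target={target_prev}"
        )
    return float(brentq(prev_minus_target, lo, hi, xtol=tol, maxiter=200))


def _likert_discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-probability binning of a standard-normal variate into 1..n_bins."""
    from scipy.stats import norm

    edges = norm.ppf(np.linspace(0, 1, n_bins + 1)[1:-1])
    return (np.searchsorted(edges, x) + 1).astype(float)


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw one cohort from the two-wave latent-liability model.

    Wave 1: z1 ~ N(0,1); scale_k = lam_k*z1 + sqrt(1-lam_k^2)*eps;
    y1 ~ Bernoulli(logistic(a1 + beta1*z1)) with a1 calibrated so the
    marginal prevalence equals ``target_prev_t1``.

    Wave 2: z2 = rho*z1 + sqrt(1-rho^2)*fresh noise; participation is
    MCAR at ``followup_rate``; among responders without a wave-1 attempt,
    y2_first ~ Bernoulli(logistic(a2 + beta2*z2)) with a2 calibrated on
    that group's realized z2 so its prevalence equals ``target_prev_t2``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    K, J = config.n_signal_scales, config.n_noise_features

    z1 = rng.standard_normal(n)
    lam = np.array(config.loadings)
    signal = lam * z1[:, None] + np.sqrt(1.0 - lam**2) * rng.standard_normal((n, K))
    noise = rng.standard_normal((n, J))
    if config.likert_bins is not None:
        signal = _likert_discretize(signal, config.likert_bins)
        noise = _likert_discretize(noise, config.likert_bins)

    a1 = calibrate_intercept(config.beta1, config.target_prev_t1)
    y1 = (rng.random(n) < expit(a1 + config.beta1 * z1)).astype(np.int8)

    rho = config.persistence
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    t2 = (rng.random(n) < config.followup_rate).astype(np.int8)

    eligible = (y1 == 0) & (t2 == 1)
    y2 = pd.array([pd.NA] * n, dtype="Int8")
    if eligible.any():
        a2 = calibrate_intercept_on_sample(
            config.beta2, z2[eligible], config.target_prev_t2
        )
        draws = rng.random(int(eligible.sum())) < expit(
            a2 + config.beta2 * z2[eligible]
        )
        y2[np.flatnonzero(eligible)] = draws.astype("int8")

    data = pd.DataFrame({"subject_id": np.arange(n, dtype=np.int64)})
    data["y1"] = y1
    data["t2_responded"] = t2
    data["y2_first"] = y2
    for k in range(K):
        data[f"scale_{k + 1}"] = signal[:, k]
    for j in range(J):
        data[f"noise_{j + 1}"] = noise[:, j]

    latent = pd.DataFrame({"latent_z1": z1, "latent_z2": z2})
    cohort = CohortTable(
        data=data, feature_names=config.feature_names, latent=latent, config=config
    )
    if config.missing_rate > 0:
        cohort = inject_missingness(
            cohort, config.missing_rate, seed=int(rng.integers(2**31))
        )
    return cohort


def inject_missingness(cohort: CohortTable, rate: float, seed: int) -> CohortTable:
    """Mask each feature cell independently with probability ``rate`` (MCAR).

    Labels are never masked.  ``rate`` must lie in [0, 1): total predictor
    destruction is rejected.
    """
    if not (0.0 <= rate < 1.0):
        raise CohortValidationError("missingness rate must lie in [0, 1)")
    if rate == 0.0:
        return cohort
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    values = out.data[out.feature_names].to_numpy(dtype=float, copy=True)
    values[rng.random(values.shape) < rate] = np.nan
    out.data[out.feature_names] = values
    return out


def impute_simple(
    cohort: CohortTable, train_ids: np.ndarray | None = None
) -> CohortTable:
    """Fill missing feature cells with training-split means (or modes).

    Imputation statistics are computed on the subjects in ``train_ids``
    only and reused everywhere, so no information flows from a held-out
    split into the fill values.  Numeric columns get the mean of observed
    training values; non-numeric columns get the mode.  A feature with no
    observed training value is an explicit failure.
    """
    out = cohort.copy()
    if train_ids is None:
        ref = out.data
    else:
        sel = out.data["subject_id"].isin(np.asarray(train_ids))
        if not sel.any():
            raise CohortValidationError("train_ids select no subjects")
        ref = out.data.loc[sel]
    for col in out.feature_names:
        observed = ref[col].dropna()
        if observed.empty:
            raise CohortValidationError(
                f"feature {col!r} has no observed training values to impute from"
            )
        if pd.api.types.is_numeric_dtype(observed):
            fill = float(observed.mean())
        else:
            fill = observed.mode().iloc[0]
        out.data[col] = out.data[col].fillna(fill)
    return out


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    """Write a cohort as CSV (empty string = missing) plus a JSON sidecar.

    Latent liabilities, when present, are written as extra columns so a
    round trip preserves the full object.  The sidecar stores the
    generator configuration, including its seed.
    """
    path = Path(path)
    df = cohort.data.copy()
    if cohort.latent is not None:
        for c in LATENT_COLUMNS:
            df[c] = cohort.latent[c].to_numpy()
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "feature_names": list(cohort.feature_names),
        "config": None if cohort.config is None else cohort.config.to_dict(),
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort` (or user-supplied).

    Schema violations (duplicate ids, y2_first defined for a wave-1
    positive or a non-responder) are rejected with the offending count.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortValidationError(f"{path} is empty or unreadable") from exc
    for col in LABEL_COLUMNS:
        if col not in df.columns:
            raise CohortValidationError(f"{path} lacks required column {col!r}")
    df["y1"] = df["y1"].astype(np.int8)
    df["t2_responded"] = df["t2_responded"].astype(np.int8)
    df["y2_first"] = df["y2_first"].astype("Int8")

    sidecar = path.with_suffix(path.suffix + ".json")
    config = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        feature_names = meta["feature_names"]
        if meta.get("config") is not None:
            config = GeneratorConfig.from_dict(meta["config"])
    else:
        feature_names = [
            c for c in df.columns if c not in LABEL_COLUMNS and c not in LATENT_COLUMNS
        ]
    latent = None
    if all(c in df.columns for c in LATENT_COLUMNS):
        latent = df[list(LATENT_COLUMNS)].copy().reset_index(drop=True)
        df = df.drop(columns=list(LATENT_COLUMNS))
    return CohortTable(data=df, feature_names=feature_names, latent=latent, config=config)
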