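"""Synthetic trial-data generator for kit secondary-distribution studies.

Emulates the statistical structure of a 309-index secondary-distribution
trial: each index participant carries a set of baseline covariates, six
leadership-scale items (0-4 each), and a count of alters reached, from which
the three key-influencer labels are derived:

- key distributor: distributed kits to at least 2 alters;
- key promoter: at least 1 alter was a first-time tester;
- key detector: at least 1 alter tested HIV-positive.

The generative model is a latent-propensity model.  A linear combination of
(standardised) covariates plus an intercept gives a latent distribution
propensity theta_i = logistic(eta_i).  Alter counts follow a zero-inflated
Poisson whose Poisson mean is scaled by theta_i, so covariate signal
propagates into the labels.  Leadership-scale items are drawn from a
discretised latent-Gaussian factor model sharing the propensity factor at a
configurable correlation strength (``scale_signal``), making the human
baseline informative but imperfect.

Default parameters are calibrated so the expected marginals match the trial's
printed counts (309 indexes, ~269 alters, ~60 distributors, ~73 promoters,
~23 detectors, ~103 first-time-tester alters, ~25 positive alters) to well
within 15%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import expit

from peerselect.errors import ConfigurationError, IntegrityError, ParseError

ARMS = ("SD", "SD-M", "SD-M-PR")

SCALE_COLS = [f"scale_{i}" for i in range(1, 7)]
COUNT_COLS = ["n_alters", "n_first_time_alters", "n_positive_alters"]
LABEL_COLS = ["is_key_distributor", "is_key_promoter", "is_key_detector"]

#: marginal level probabilities for a single 0-4 scale item; chosen so that
#: whole-sample totals clump near the 80th percentile (the dual-cutoff regime)
_ITEM_LEVEL_PROBS = (0.25, 0.30, 0.25, 0.15, 0.05)


class CovariateSpec(BaseModel):
    """One baseline covariate: its name, measurement kind and distribution."""

    name: str
    kind: Literal["binary", "ordinal", "continuous"]
    # binary: {"p": ...}; ordinal: {"probs": [...]} levels 0..k-1;
    # continuous: {"mean": ..., "sd": ...} (lognormal if "log" is true)
    params: dict

    @model_validator(mode="after")
    def _check_params(self) -> "CovariateSpec":
        if self.kind == "binary":
            p = self.params.get("p")
            if p is None or not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"covariate {self.name!r}: binary p must be in [0,1]")
        elif self.kind == "ordinal":
            probs = self.params.get("probs")
            if not probs or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigurationError(
                    f"covariate {self.name!r}: ordinal probs must be non-negative and sum to 1"
                )
        else:
            if "mean" not in self.params or "sd" not in self.params:
                raise ConfigurationError(
                    f"covariate {self.name!r}: continuous needs mean and sd"
                )
            if self.params["sd"] < 0:
                raise ConfigurationError(f"covariate {self.name!r}: sd must be >= 0")
        return self


def default_covariates() -> list[CovariateSpec]:
    """A plausible MSM-trial covariate schema (the real survey instrument is
    not public); fully overridable through :class:`GeneratorConfig`."""
    return [
        CovariateSpec(name="age", kind="continuous", params={"mean": 28.0, "sd": 7.0}),
        CovariateSpec(name="education", kind="ordinal", params={"probs": [0.1, 0.3, 0.4, 0.2]}),
        CovariateSpec(name="income_band", kind="ordinal", params={"probs": [0.25, 0.35, 0.25, 0.15]}),
        CovariateSpec(name="ever_tested", kind="binary", params={"p": 0.7}),
        CovariateSpec(
            name="months_since_last_test", kind="continuous",
            params={"mean": 2.0, "sd": 0.8, "log": True},
        ),
        CovariateSpec(
            name="partner_count", kind="continuous",
            params={"mean": 1.0, "sd": 0.7, "log": True},
        ),
        CovariateSpec(name="app_use_freq", kind="ordinal", params={"probs": [0.2, 0.2, 0.25, 0.2, 0.15]}),
        CovariateSpec(name="disclosed_orientation", kind="binary", params={"p": 0.35}),
    ]


def default_propensity_coefficients() -> dict[str, float]:
    """Weights of each covariate on the latent distribution propensity.

    Only a subset of covariates carries signal; the rest are noise predictors
    the identification system should learn to ignore.
    """
    return {
        "partner_count": 0.8,
        "app_use_freq": 0.5,
        "disclosed_orientation": 0.5,
        "ever_tested": 0.4,
    }


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic trial generator.

    Defaults reproduce the trial's printed marginals in expectation (see
    module docstring).  ``zip_inflation``/``zip_mean`` are the zero-inflated
    Poisson parameters of the alter-count model; the Poisson mean for index i
    is ``zip_mean * theta_i`` with theta_i the latent propensity.
    """

    n_indexes: int = Field(default=309, ge=10)
    covariates: list[CovariateSpec] = Field(default_factory=default_covariates)
    propensity_coefficients: dict[str, float] = Field(
        default_factory=default_propensity_coefficients
    )
    propensity_intercept: float = -2.2
    scale_signal: float = Field(default=0.5, ge=0.0, le=1.0)
    zip_inflation: float = Field(default=0.1, ge=0.0, le=1.0)
    zip_mean: float = Field(default=6.5, ge=0.0)
    p_first_time: float = Field(default=103 / 269, ge=0.0, le=1.0)
    p_positive: float = Field(default=25 / 269, ge=0.0, le=1.0)
    rng_seed: int = 0

    @field_validator("n_indexes")
    @classmethod
    def _n_ok(cls, v: int) -> int:
        if v < 10:
            raise ConfigurationError("n_indexes: must be >= 10")
        return v

    @model_validator(mode="after")
    def _coefs_reference_covariates(self) -> "GeneratorConfig":
        names = {c.name for c in self.covariates}
        unknown = set(self.propensity_coefficients) - names
        if unknown:
            raise ConfigurationError(
                f"propensity_coefficients: unknown covariate(s) {sorted(unknown)}"
            )
        return self


@dataclass
class TrialDataset:
    """A full synthetic trial: one row per index, one row per alter."""

    indexes: pd.DataFrame
    alters: pd.DataFrame
    config: GeneratorConfig
    seed: int

    def covariate_names(self) -> list[str]:
        return [c.name for c in self.config.covariates]

    def __eq__(self, other: object) -> bool:  # structural equality
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return (
            self.indexes.equals(other.indexes)
            and self.alters.equals(other.alters)
            and self.config == other.config
            and self.seed == other.seed
        )


def _draw_covariate(spec: CovariateSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "binary":
        return rng.binomial(1, spec.params["p"], size=n).astype(float)
    if spec.kind == "ordinal":
        probs = np.asarray(spec.params["probs"], dtype=float)
        return rng.choice(len(probs), size=n, p=probs).astype(float)
    mean, sd = spec.params["mean"], spec.params["sd"]
    if spec.params.get("log"):
        return np.exp(rng.normal(mean, sd, size=n))
    return rng.normal(mean, sd, size=n)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _draw_scale_items(
    eta: np.ndarray, signal: float, rng: np.random.Generator
) -> np.ndarray:
    """Six 0-4 items from a discretised latent-Gaussian factor model.

    Each item's latent score shares the standardised propensity factor with
    loading ``signal``; item-level thresholds are standard-normal quantiles of
    the cumulative level probabilities.
    """
    n = eta.shape[0]
    factor = _zscore(eta)
    cuts = np.asarray(np.cumsum(_ITEM_LEVEL_PROBS[:-1]))
    from scipy.stats import norm

    thresholds = norm.ppf(cuts)
    items = np.empty((n, 6), dtype=int)
    noise_sd = float(np.sqrt(max(0.0, 1.0 - signal**2)))
    for j in range(6):
        latent = signal * factor + noise_sd * rng.normal(size=n)
        items[:, j] = np.searchsorted(thresholds, latent, side="left")
    return items


def generate_trial(config: GeneratorConfig) -> TrialDataset:
    """Generate one synthetic trial dataset.

    Deterministic given ``config.rng_seed``; all randomness flows from one
    :class:`numpy.random.SeedSequence` through spawned child streams.
    """
    if not isinstance(config, GeneratorConfig):
        raise ConfigurationError("config: expected a GeneratorConfig")
    n = config.n_indexes
    ss = np.random.SeedSequence(config.rng_seed)
    (cov_ss, arm_ss, count_ss, flag_ss, scale_ss) = ss.spawn(5)
    cov_rng = np.random.default_rng(cov_ss)
    arm_rng = np.random.default_rng(arm_ss)
    count_rng = np.random.default_rng(count_ss)
    flag_rng = np.random.default_rng(flag_ss)
    scale_rng = np.random.default_rng(scale_ss)

    cov_values = {spec.name: _draw_covariate(spec, n, cov_rng) for spec in config.covariates}
    arm = np.asarray(ARMS)[arm_rng.integers(0, len(ARMS), size=n)]

    eta = np.full(n, config.propensity_intercept, dtype=float)
    for name, coef in config.propensity_coefficients.items():
        eta += coef * _zscore(cov_values[name])
    theta = expit(eta)

    lam = config.zip_mean * theta
    structural_zero = count_rng.random(n) < config.zip_inflation
    n_alters = np.where(structural_zero, 0, count_rng.poisson(lam))

    # per-alter outcome flags
    alter_rows: list[tuple[str, str, int, int]] = []
    for i in range(n):
        for k in range(int(n_alters[i])):
            is_ft = int(flag_rng.random() < config.p_first_time)
            is_pos = int(flag_rng.random() < config.p_positive)
            alter_rows.append((f"A{i:04d}_{k}", f"I{i:04d}", is_ft, is_pos))
    alters = pd.DataFrame(
        alter_rows, columns=["alter_id", "index_id", "is_first_time", "is_positive"]
    )

    items = _draw_scale_items(eta, config.scale_signal, scale_rng)

    indexes = pd.DataFrame({"index_id": [f"I{i:04d}" for i in range(n)], "arm": arm})
    for name in (spec.name for spec in config.covariates):
        indexes[name] = cov_values[name]
    for j, col in enumerate(SCALE_COLS):
        indexes[col] = items[:, j]

    dataset = TrialDataset(indexes=indexes, alters=alters, config=config, seed=config.rng_seed)
    dataset.indexes = derive_labels(dataset.indexes, dataset.alters)
    return dataset


def derive_labels(indexes: pd.DataFrame, alters: pd.DataFrame) -> pd.DataFrame:
    """Recompute alter counts and the three key-influencer flags from the
    alter table.  Idempotent; raises :class:`IntegrityError` on a dangling
    alter reference.
    """
    known = set(indexes["index_id"])
    dangling = set(alters["index_id"]) - known if len(alters) else set()
    if dangling:
        raise IntegrityError(f"alters reference unknown index id(s): {sorted(dangling)[:5]}")

    out = indexes.copy()
    if len(alters):
        grouped = alters.groupby("index_id")
        counts = grouped.size()
        ft = grouped["is_first_time"].sum()
        pos = grouped["is_positive"].sum()
    else:
        counts = ft = pos = pd.Series(dtype=int)
    out["n_alters"] = out["index_id"].map(counts).fillna(0).astype(int)
    out["n_first_time_alters"] = out["index_id"].map(ft).fillna(0).astype(int)
    out["n_positive_alters"] = out["index_id"].map(pos).fillna(0).astype(int)
    out["is_key_distributor"] = (out["n_alters"] >= 2).astype(int)
    out["is_key_promoter"] = (out["n_first_time_alters"] >= 1).astype(int)
    out["is_key_detector"] = (out["n_positive_alters"] >= 1).astype(int)
    return out


def write_dataset(dataset: TrialDataset, path: str | Path) -> None:
    """Write a dataset to ``path`` as indexes.csv + alters.csv + config.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # shortest-repr floats round-trip float64 through text exactly
    dataset.indexes.to_csv(
        path / "indexes.csv", index=False, float_format=lambda v: repr(float(v))
    )
    dataset.alters.to_csv(path / "alters.csv", index=False)
    meta = {"seed": dataset.seed, "config": dataset.config.model_dump()}
    (path / "config.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_dataset(path: str | Path) -> TrialDataset:
    """Read a dataset written by :func:`write_dataset`; validates referential
    integrity and label consistency."""
    path = Path(path)
    try:
        indexes = pd.read_csv(path / "indexes.csv", float_precision="round_trip")
        alters = pd.read_csv(
            path / "alters.csv",
            dtype={"alter_id": str, "index_id": str, "is_first_time": int, "is_positive": int},
        )
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise ParseError(str(exc)) from exc
    if len(alters) == 0:
        alters = pd.DataFrame(columns=["alter_id", "index_id", "is_first_time", "is_positive"])
    missing = {"alter_id", "index_id"} - set(alters.columns)
    if missing or "index_id" not in indexes.columns:
        raise ParseError(f"missing required column(s): {sorted(missing) or ['index_id']}")
    meta = json.loads((path / "config.json").read_text())
    config = GeneratorConfig.model_validate(meta["config"])
    indexes = derive_labels(indexes.drop(columns=COUNT_COLS + LABEL_COLS, errors="ignore"), alters)
    return TrialDataset(indexes=indexes, alters=alters, config=config, seed=meta["seed"])
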