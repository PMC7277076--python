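"""Synthetic survey data with the two-level factor structure of the C-IGDC.

Generates seeded datasets emulating the validation sample: N persons answer
34 three-category ordinal items (0 = never, 1 = sometimes, 2 = often)
organised as nine subconstructs under one general Internet-gaming-disorder
factor, plus a 9-item binary DSM-5 criterion checklist and criterion
variables (Internet-addiction score, depression score, weekly gameplay
frequency, monetary expenditure band, preferred gaming device).

The generating model is the measurement model the analysis assumes:

* general factor ``G ~ N(0, 1)``;
* subconstruct ``F_j = gamma_j * G + sqrt(1 - gamma_j^2) * d_j`` so each
  factor is marginally standard normal;
* latent item response ``y*_i = lambda_i * F_j(i) + sqrt(1 - lambda_i^2) * e_i``,
  discretized at per-item thresholds ``(tau1, tau2)``;
* DSM-5 criterion ``k`` endorsed iff ``a_k * G + noise > c_k``;
* continuous/ordinal criteria are affine transforms of ``b * G + noise``.

All defaults reproduce the published study conditions: loadings from the
34-item development results, DSM-5 probable-case prevalence (sum >= 5 of 9)
of about 12.9%, and sum-score correlations of about 0.45 / 0.40 / 0.28 with
the Internet-addiction, gameplay-frequency, and depression criteria.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .reference import FACTOR_MAP, LOADINGS_34, SECOND_ORDER_34

__all__ = [
    "GeneratorConfig",
    "ItemResponseMatrix",
    "SyntheticDataset",
    "generate_latent",
    "generate_item_responses",
    "generate_criteria",
    "generate_dataset",
]

# Calibration constants, derived once from the default configuration and
# frozen (see docs/methods.md for the derivation):
#   - DSM threshold c with discrimination 0.7 solves P(sum of 9 >= 5) = 0.129
#     under the binomial mixture over G (Gauss-Hermite quadrature);
#   - _R_SUM_G is the model-implied correlation of the 27-item sum with G;
#   - _FREQ_ATTENUATION is the variance-ratio attenuation from discretizing
#     the gameplay-frequency latent into its four ordinal bands.
_DSM_LOADING_DEFAULT = 0.70
_DSM_THRESHOLD_DEFAULT = 0.8575
_R_SUM_G = 0.9391
_FREQ_ATTENUATION = 0.8277

#: marginal band probabilities observed in the study sample
FREQ_BAND_PROBS = (0.233, 0.086, 0.086, 0.595)   # <1 day ... >3 days / week
SPEND_BAND_PROBS = (0.677, 0.209, 0.114)          # none, <=100 MOP, >100 MOP
DEVICE_PROBS = (0.593, 0.315, 0.067, 0.026)       # phone, computer, tablet, console
DEVICE_LABELS = ("smartphone", "computer", "tablet", "console")

_SPEND_LOADING = 0.25   # expenditure tracks severity weakly (no published target)

_IA_LOC, _IA_SCALE, _IA_RANGE = 44.0, 14.0, (20.0, 100.0)
_DEP_LOC, _DEP_SCALE, _DEP_RANGE = 9.5, 5.0, (0.0, 30.0)


def _default_thresholds() -> dict[str, tuple[float, float]]:
    return {item: (-0.25, 0.84) for items in FACTOR_MAP.values() for item in items}


@dataclass
class GeneratorConfig:
    """Full specification of the generating model.

    Attributes
    ----------
    n_persons : int
        Sample size (the study used 464).
    seed : int
        Root seed; every component draws from a documented substream.
    factor_map : dict[str, list[str]]
        Ordered subconstruct -> item labels; each item in exactly one
        subconstruct, each subconstruct with at least three items.
    loadings, second_order : dict
        Standardized first-order (per item) and second-order (per factor)
        loadings, all strictly inside (0, 1).
    thresholds : dict[str, tuple[float, float]]
        Per-item cutpoints (tau1 < tau2) on the standard-normal latent
        response, giving codes {0, 1, 2}.
    dsm_loading, dsm_threshold : tuple[float, ...]
        Per-criterion discrimination in (0, 1) and real cutpoint for the
        nine binary DSM-5 items.
    criterion_targets : dict[str, float]
        Desired product-moment correlations of the 27-item sum with the
        ``ia``, ``frequency`` and ``depression`` criteria, each in (-1, 1).
    """

    n_persons: int = 464
    seed: int = 0
    factor_map: dict[str, list[str]] = field(
        default_factory=lambda: copy.deepcopy(FACTOR_MAP))
    loadings: dict[str, float] = field(default_factory=lambda: dict(LOADINGS_34))
    second_order: dict[str, float] = field(
        default_factory=lambda: dict(SECOND_ORDER_34))
    thresholds: dict[str, tuple[float, float]] = field(
        default_factory=_default_thresholds)
    dsm_loading: tuple[float, ...] = (_DSM_LOADING_DEFAULT,) * 9
    dsm_threshold: tuple[float, ...] = (_DSM_THRESHOLD_DEFAULT,) * 9
    criterion_targets: dict[str, float] = field(
        default_factory=lambda: {"ia": 0.45, "frequency": 0.40, "depression": 0.28})

    def __post_init__(self) -> None:
        self.validate()

    @property
    def items(self) -> list[str]:
        return [i for items in self.factor_map.values() for i in items]

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError(f"n_persons must be positive, got {self.n_persons}")
        seen: set[str] = set()
        for factor, items in self.factor_map.items():
            if len(items) < 3:
                raise ValueError(f"subconstruct {factor} has < 3 items")
            dup = seen.intersection(items)
            if dup:
                raise ValueError(f"items in more than one subconstruct: {sorted(dup)}")
            seen.update(items)
        for item in seen:
            lam = self.loadings.get(item)
            if lam is None:
                raise ValueError(f"item {item} has no loading")
            if not 0.0 < lam < 1.0:
                raise ValueError(f"loading for {item} must be in (0,1), got {lam}")
            t1, t2 = self.thresholds[item]
            if not t1 < t2:
                raise ValueError(f"thresholds for {item} must satisfy tau1 < tau2")
        for factor in self.factor_map:
            gam = self.second_order.get(factor)
            if gam is None or not 0.0 < gam < 1.0:
                raise ValueError(
                    f"second-order loading for {factor} must be in (0,1), got {gam}")
        for a in self.dsm_loading:
            if not 0.0 < a < 1.0:
                raise ValueError(f"dsm_loading must be in (0,1), got {a}")
        for name, rho in self.criterion_targets.items():
            if not -1.0 < rho < 1.0:
                raise ValueError(f"criterion target {name}={rho} outside (-1,1)")

    def to_yaml(self, path) -> None:
        payload = {
            "n_persons": self.n_persons,
            "seed": self.seed,
            "factor_map": {k: list(v) for k, v in self.factor_map.items()},
            "loadings": dict(self.loadings),
            "second_order": dict(self.second_order),
            "thresholds": {k: list(v) for k, v in self.thresholds.items()},
            "dsm_loading": list(self.dsm_loading),
            "dsm_threshold": list(self.dsm_threshold),
            "criterion_targets": dict(self.criterion_targets),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["thresholds"] = {k: tuple(v) for k, v in raw["thresholds"].items()}
        raw["dsm_loading"] = tuple(raw["dsm_loading"])
        raw["dsm_threshold"] = tuple(raw["dsm_threshold"])
        return cls(**raw)


@dataclass
class ItemResponseMatrix:
    """Person x item ordinal codes plus the 9-factor blueprint."""

    data: pd.DataFrame
    factor_map: dict[str, list[str]]

    def __post_init__(self) -> None:
        mapped = [i for items in self.factor_map.values() for i in items]
        missing = [i for i in mapped if i not in self.data.columns]
        if missing:
            raise ValueError(f"items without response columns: {missing}")
        vals = self.data[mapped].to_numpy()
        if not np.isin(vals[~pd.isna(vals)], [0, 1, 2]).all():
            raise ValueError("response codes must be in {0, 1, 2}")

    @property
    def items(self) -> list[str]:
        return [i for items in self.factor_map.values() for i in items]

    @property
    def n_persons(self) -> int:
        return len(self.data)

    def factor_of(self, item: str) -> str:
        for factor, items in self.factor_map.items():
            if item in items:
                return factor
        raise KeyError(item)


@dataclass
class SyntheticDataset:
    responses: ItemResponseMatrix
    dsm_items: pd.DataFrame
    ia_score: pd.Series
    depression_score: pd.Series
    gameplay_frequency: pd.Series
    expenditure_band: pd.Series
    device: pd.Series
    truth: GeneratorConfig

    def __post_init__(self) -> None:
        n = self.responses.n_persons
        for name in ("dsm_items", "ia_score", "depression_score",
                     "gameplay_frequency", "expenditure_band", "device"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has wrong row count")
        if not np.isin(self.dsm_items.to_numpy(), [0, 1]).all():
            raise ValueError("dsm codes must be binary")

    @property
    def dsm_sum(self) -> pd.Series:
        return self.dsm_items.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        out = self.responses.data[self.responses.items].copy()
        out = pd.concat([out, self.dsm_items], axis=1)
        out["ia"] = self.ia_score
        out["dep"] = self.depression_score
        out["freq"] = self.gameplay_frequency
        out["spend"] = self.expenditure_band
        out["device"] = self.device
        out.insert(0, "person_id", np.arange(1, len(out) + 1))
        return out

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# Substream derivation: one root SeedSequence per config seed, children
# spawned in a fixed order (0: latent factors, 1: item responses,
# 2: criterion variables).
_STREAM_LATENT, _STREAM_ITEMS, _STREAM_CRITERIA = 0, 1, 2


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    root = np.random.SeedSequence(config.seed)
    return np.random.default_rng(root.spawn(3)[stream])


def generate_latent(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the general factor G and the nine subconstruct scores.

    Column ``G`` is standard normal; factor ``j`` equals
    ``gamma_j * G + disturbance`` with disturbance variance ``1 - gamma_j**2``,
    so every factor is marginally standard normal. Deterministic given seed.
    """
    config.validate()
    rng = _rng(config, _STREAM_LATENT)
    n = config.n_persons
    g = rng.standard_normal(n)
    cols = {"G": g}
    for factor in config.factor_map:
        gam = config.second_order[factor]
        cols[factor] = gam * g + np.sqrt(1.0 - gam * gam) * rng.standard_normal(n)
    return pd.DataFrame(cols)


def generate_item_responses(factors: pd.DataFrame,
                            config: GeneratorConfig) -> ItemResponseMatrix:
    """Discretize latent item responses into ordinal codes {0, 1, 2}.

    Code 0 iff ``y* <= tau1``, 1 iff ``tau1 < y* <= tau2``, 2 iff
    ``y* > tau2``; marginal category proportions converge to
    ``Phi(tau1), Phi(tau2) - Phi(tau1), 1 - Phi(tau2)``.
    """
    rng = _rng(config, _STREAM_ITEMS)
    n = len(factors)
    out = {}
    for factor, items in config.factor_map.items():
        if factor not in factors.columns:
            raise ValueError(f"item group {factor} has no factor-score column")
        f = factors[factor].to_numpy()
        for item in items:
            lam = config.loadings[item]
            y = lam * f + np.sqrt(1.0 - lam * lam) * rng.standard_normal(n)
            t1, t2 = config.thresholds[item]
            out[item] = ((y > t1).astype(np.int8) + (y > t2).astype(np.int8))
    data = pd.DataFrame(out)
    return ItemResponseMatrix(data=data, factor_map=copy.deepcopy(config.factor_map))


def _target_to_slope(target: float, attenuation: float = 1.0) -> float:
    """Map a desired sum-score correlation to the loading of the criterion
    latent on G, correcting for the sum/G correlation (and, for ordinal
    criteria, discretization attenuation)."""
    b = target / (_R_SUM_G * attenuation)
    if not -1.0 < b < 1.0:
        raise ValueError(f"criterion target {target} implies slope {b} outside (-1,1)")
    return b


def generate_criteria(factors: pd.DataFrame, config: GeneratorConfig):
    """Generate the DSM-5 checklist and the five criterion variables.

    All criteria are driven by the general factor G only. Returns a dict
    with keys ``dsm_items, ia_score, depression_score, gameplay_frequency,
    expenditure_band, device``.
    """
    rng = _rng(config, _STREAM_CRITERIA)
    g = factors["G"].to_numpy()
    n = len(g)

    dsm = {}
    for k, (a, c) in enumerate(zip(config.dsm_loading, config.dsm_threshold), start=1):
        y = a * g + np.sqrt(1.0 - a * a) * rng.standard_normal(n)
        dsm[f"dsm_{k}"] = (y > c).astype(np.int8)
    dsm_items = pd.DataFrame(dsm)

    def latent(target: float, attenuation: float = 1.0) -> np.ndarray:
        b = _target_to_slope(target, attenuation)
        return b * g + np.sqrt(1.0 - b * b) * rng.standard_normal(n)

    ia = np.clip(_IA_LOC + _IA_SCALE * latent(config.criterion_targets["ia"]),
                 *_IA_RANGE)
    dep = np.clip(_DEP_LOC + _DEP_SCALE * latent(config.criterion_targets["depression"]),
                  *_DEP_RANGE)

    from scipy.stats import norm  # local import keeps module import light
    freq_cuts = norm.ppf(np.cumsum(FREQ_BAND_PROBS[:-1]))
    freq = np.searchsorted(freq_cuts,
                           latent(config.criterion_targets["frequency"],
                                  _FREQ_ATTENUATION))
    spend_cuts = norm.ppf(np.cumsum(SPEND_BAND_PROBS[:-1]))
    spend_latent = _SPEND_LOADING * g + np.sqrt(1 - _SPEND_LOADING**2) \
        * rng.standard_normal(n)
    spend = np.searchsorted(spend_cuts, spend_latent)
    # published shares sum to 1.001 from rounding; renormalize
    device_p = np.asarray(DEVICE_PROBS) / np.sum(DEVICE_PROBS)
    device = rng.choice(DEVICE_LABELS, size=n, p=device_p)

    return {
        "dsm_items": dsm_items,
        "ia_score": pd.Series(ia, name="ia"),
        "depression_score": pd.Series(dep, name="dep"),
        "gameplay_frequency": pd.Series(freq.astype(np.int8), name="freq"),
        "expenditure_band": pd.Series(spend.astype(np.int8), name="spend"),
        "device": pd.Series(device, name="device"),
    }


def generate_dataset(config: GeneratorConfig | None = None,
                     csv_path=None, yaml_path=None) -> SyntheticDataset:
    """Compose the three generators into one seeded dataset.

    Optionally writes the dataset as UTF-8 CSV and the generating
    configuration as YAML.
    """
    config = config if config is not None else GeneratorConfig()
    factors = generate_latent(config)
    responses = generate_item_responses(factors, config)
    criteria = generate_criteria(factors, config)
    dataset = SyntheticDataset(responses=responses, truth=config, **criteria)
    if csv_path is not None:
        dataset.write_csv(csv_path)
    if yaml_path is not None:
        config.to_yaml(yaml_path)
    return dataset
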