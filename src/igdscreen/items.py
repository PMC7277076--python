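"""Item reduction and scale scoring.

The reduction rule keeps, within every subconstruct, the k items with the
highest standardized first-order loadings (k = 3 by default), so each
subconstruct carries equal weight in the shortened scale.  Ties are broken
by questionnaire order and logged.  Loadings are compared at full floating
precision; on the published 2-dp loadings the selection is identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = ["ScaleDefinition", "select_top_items", "sum_score"]


@dataclass
class ScaleDefinition:
    """Retained item labels grouped by subconstruct."""

    items_by_factor: dict[str, list[str]]

    @property
    def items(self) -> list[str]:
        return [i for items in self.items_by_factor.values() for i in items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def score_range(self) -> tuple[int, int]:
        return (0, 2 * self.n_items)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"factors": {k: list(v) for k, v in
                                        self.items_by_factor.items()}},
                           fh, sort_keys=False)


def _model_of(fitted):
    """Accept a CFAResult, a MeasurementModel, or anything with the fields."""
    return getattr(fitted, "model", fitted)


def select_top_items(fitted, k: int = 3) -> ScaleDefinition:
    """Keep the k highest-loading items of every subconstruct.

    ``fitted`` is a converged CFA result (or a measurement model carrying
    loadings).  Ties on the loading are broken by item order within the
    questionnaire; any tie that affects the cut is logged.
    """
    model = _model_of(fitted)
    converged = getattr(fitted, "converged", True)
    if not converged:
        raise ValueError("item selection requires a converged fit")
    retained: dict[str, list[str]] = {}
    for factor, items in model.factor_map.items():
        if len(items) < k:
            raise ValueError(f"subconstruct {factor} has {len(items)} items, "
                             f"cannot retain {k}")
        loadings = [model.loadings[i] for i in items]
        # stable sort on descending loading preserves questionnaire order on ties
        order = sorted(range(len(items)), key=lambda i: -loadings[i])
        keep_idx = sorted(order[:k])
        if len(items) > k:
            cut_val = loadings[order[k - 1]]
            if any(np.isclose(loadings[order[j]], cut_val)
                   for j in range(k, len(items))):
                logger.info("tie at the cut in %s resolved by questionnaire order",
                            factor)
        retained[factor] = [items[i] for i in keep_idx]
    return ScaleDefinition(items_by_factor=retained)


def sum_score(responses, scale: ScaleDefinition) -> pd.Series:
    """Per-person integer sum over the scale's items.

    Refuses rows with missing scale items (handle missingness upstream,
    listwise).  Raises on unknown item labels.
    """
    data = getattr(responses, "data", responses)
    missing_cols = [i for i in scale.items if i not in data.columns]
    if missing_cols:
        raise KeyError(f"unknown item labels: {missing_cols}")
    sub = data[scale.items]
    bad = sub.isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} rows have missing scale items; drop them first")
    return sub.sum(axis=1).astype(int)
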