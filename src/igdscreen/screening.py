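"""Screening-efficacy indices and optimal-cutoff selection.

A screen-positive means sum score >= cutoff; the diagnostic reference is
the binary DSM-5 classification (>= 5 of 9 criteria).  For every integer
cutoff the 2x2 confusion table yields sensitivity, specificity, positive
and negative predictive rates (as percentages), Cohen's kappa, Youden's J,
and the diagnostic odds ratio.  The optimal cutoff is chosen by a
three-step rule:

1. keep cutoffs with sensitivity AND specificity strictly above the
   minimum (75% by default);
2. keep those whose kappa, rounded to 2 decimals, equals the maximum
   rounded kappa (the published tie only exists after rounding);
3. break remaining ties by higher sensitivity, then higher Youden, then
   higher DOR, then lower cutoff.

Percentages are rounded half-up to 1 dp and kappa/Youden to 2 dp when
reported, matching the published table formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .reference import (PUBLISHED_CUTOFF_ROWS, REFERENCE_NEGATIVES,
                        REFERENCE_POSITIVES)

__all__ = [
    "ConfusionTable",
    "EfficacyIndices",
    "CutoffScan",
    "SelectionResult",
    "round_half_up",
    "confusion_table",
    "efficacy_indices",
    "roc_auc",
    "scan_cutoffs",
    "select_optimal_cutoff",
    "classify",
    "reconstruct_confusion_tables",
    "scores_from_tables",
]


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal round-half-up (table convention; banker's rounding differs).

    Absorbs binary floating-point noise (e.g. 41/80*100 = 51.249999...997,
    exactly 51.25 as a rational) by pre-quantizing well below the target
    precision before the half-up step.
    """
    if math.isnan(x):
        return math.nan
    q = Decimal(1).scaleb(-digits)
    guard = Decimal(1).scaleb(-(digits + 8))
    d = Decimal(repr(float(x))).quantize(guard, rounding=ROUND_HALF_UP)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @property
    def screen_positives(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class EfficacyIndices:
    """Seven screening statistics; rates are percentages in [0, 100].

    Ratios with an empty denominator are NaN and listed in ``undefined``
    rather than silently zeroed.  ``youden`` is, by construction,
    ``sensitivity/100 + specificity/100 - 1``.
    """

    sensitivity: float
    specificity: float
    ppr: float
    npr: float
    kappa: float
    youden: float
    dor: float
    undefined: tuple[str, ...] = ()


def confusion_table(scores, reference, cutoff: int) -> ConfusionTable:
    """Cross-classify screen (score >= cutoff) against the binary reference."""
    s = np.asarray(scores)
    r = np.asarray(reference)
    if s.size == 0:
        raise ValueError("empty input")
    if s.shape != r.shape:
        raise ValueError("scores and reference must have equal length")
    if np.any(pd.isna(s)) or np.any(pd.isna(r)):
        raise ValueError("missing values are not allowed here")
    pos = s >= cutoff
    ref = r.astype(bool)
    return ConfusionTable(tp=int(np.sum(pos & ref)), fp=int(np.sum(pos & ~ref)),
                          fn=int(np.sum(~pos & ref)), tn=int(np.sum(~pos & ~ref)))


def efficacy_indices(t: ConfusionTable) -> EfficacyIndices:
    """Sens/spec/PPR/NPR (percent), Cohen's kappa, Youden's J, and DOR.

    kappa uses chance agreement from the marginal products; the DOR is the
    cross-product ratio with the Haldane +0.5 continuity correction applied
    to every cell iff any cell is zero.
    """
    if t.n == 0:
        raise ValueError("empty table")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sens = ratio(t.tp, t.positives, "sensitivity")
    spec = ratio(t.tn, t.negatives, "specificity")
    ppr = ratio(t.tp, t.screen_positives, "ppr")
    npr = ratio(t.tn, t.fn + t.tn, "npr")

    p_o = (t.tp + t.tn) / t.n
    p_e = (t.screen_positives * t.positives
           + (t.fn + t.tn) * t.negatives) / (t.n * t.n)
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else math.nan
    if p_e >= 1.0:
        undefined.append("kappa")

    youden = sens + spec - 1.0 if not (math.isnan(sens) or math.isnan(spec)) \
        else math.nan

    cells = (t.tp, t.fp, t.fn, t.tn)
    if 0 in cells:
        a, b, c, d = (x + 0.5 for x in cells)
    else:
        a, b, c, d = cells
    dor = (a * d) / (b * c)

    return EfficacyIndices(
        sensitivity=100.0 * sens, specificity=100.0 * spec,
        ppr=100.0 * ppr, npr=100.0 * npr,
        kappa=kappa, youden=youden, dor=dor,
        undefined=tuple(undefined))


def roc_auc(scores, reference):
    """Trapezoidal AUC over all distinct thresholds, plus the ROC points.

    Equals the rank-based pair statistic (ties counted half) to machine
    precision.  Requires both reference classes to be present.
    """
    s = np.asarray(scores, dtype=float)
    r = np.asarray(reference).astype(int)
    if len(np.unique(r)) < 2:
        raise ValueError("reference must contain both classes")
    fpr, tpr, thresholds = _roc_curve(r, s)
    return float(_trapezoid_auc(fpr, tpr)), list(zip(fpr, tpr, thresholds))


@dataclass
class CutoffScan:
    """Per-integer-cutoff efficacy rows (cutoffs strictly increasing)."""

    rows: list[tuple[int, ConfusionTable, EfficacyIndices]]

    def __post_init__(self) -> None:
        cuts = [c for c, _, _ in self.rows]
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must be strictly increasing")

    @property
    def cutoffs(self) -> list[int]:
        return [c for c, _, _ in self.rows]

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        recs = []
        for cutoff, tab, ix in self.rows:
            rec = {"cutoff": cutoff,
                   "sensitivity": ix.sensitivity, "specificity": ix.specificity,
                   "ppr": ix.ppr, "npr": ix.npr,
                   "kappa": ix.kappa, "youden": ix.youden, "dor": ix.dor,
                   "tp": tab.tp, "fp": tab.fp, "fn": tab.fn, "tn": tab.tn}
            if rounded:
                for key in ("sensitivity", "specificity", "ppr", "npr"):
                    rec[key] = round_half_up(rec[key], 1)
                for key in ("kappa", "youden"):
                    rec[key] = round_half_up(rec[key], 2)
                rec["dor"] = round_half_up(rec["dor"], 2)
            recs.append(rec)
        return pd.DataFrame(recs)


def scan_cutoffs(scores, reference, cutoffs) -> CutoffScan:
    """One efficacy row per integer cutoff in ``cutoffs`` (e.g. a range)."""
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("empty cutoff range")
    rows = []
    for c in cutoffs:
        tab = confusion_table(scores, reference, c)
        rows.append((int(c), tab, efficacy_indices(tab)))
    return CutoffScan(rows=rows)


@dataclass
class SelectionResult:
    selected: int | None
    candidates: list[int]
    kappa_max_set: list[int]
    audit: list[dict] = field(default_factory=list)


def select_optimal_cutoff(scan: CutoffScan, min_sens: float = 75.0,
                          min_spec: float = 75.0) -> SelectionResult:
    """Three-step cutoff selection with a full audit trail.

    Step 1 keeps rows with sensitivity > min_sens AND specificity >
    min_spec (strict); Step 2 keeps rows whose kappa rounded to 2 decimals
    equals the maximum rounded kappa; Step 3 picks the highest sensitivity,
    then highest Youden, then highest DOR, then the lowest cutoff.
    An empty candidate set yields ``selected=None``.
    """
    if not scan.rows:
        raise ValueError("empty scan")
    audit = []
    candidates = [(c, ix) for c, _, ix in scan.rows
                  if ix.sensitivity > min_sens and ix.specificity > min_spec]
    audit.append({"step": "screen",
                  "rule": f"sensitivity > {min_sens} and specificity > {min_spec} "
                          "(strict)",
                  "kept": [c for c, _ in candidates]})
    if not candidates:
        audit.append({"step": "result", "selected": None,
                      "reason": "no admissible cutoff"})
        return SelectionResult(selected=None, candidates=[], kappa_max_set=[],
                               audit=audit)

    rounded = {c: round_half_up(ix.kappa, 2) for c, ix in candidates}
    k_max = max(rounded.values())
    tie = [(c, ix) for c, ix in candidates if rounded[c] == k_max]
    audit.append({"step": "kappa",
                  "rule": "maximal kappa rounded to 2 decimals",
                  "rounded_kappa": rounded, "max": k_max,
                  "kept": [c for c, _ in tie]})

    ranked = sorted(tie, key=lambda ci: (-ci[1].sensitivity, -ci[1].youden,
                                         -ci[1].dor, ci[0]))
    selected = ranked[0][0]
    audit.append({"step": "tie_break",
                  "rule": "higher sensitivity, then Youden, then DOR, "
                          "then lower cutoff",
                  "order": [c for c, _ in ranked], "selected": selected})
    return SelectionResult(selected=selected,
                           candidates=[c for c, _ in candidates],
                           kappa_max_set=[c for c, _ in tie],
                           audit=audit)


def classify(scores, cutoff: int):
    """Binary screen labels (1 iff score >= cutoff) and the group sizes."""
    s = np.asarray(scores)
    labels = (s >= cutoff).astype(int)
    sizes = {"positive": int(labels.sum()), "negative": int(len(labels) - labels.sum())}
    return labels, sizes


# ---------------------------------------------------------------------------
# Reconstruction of the published cutoff tables from their printed rates.
# The printed rows give four percentages per cutoff; with the reference
# margins fixed (60 positives / 404 negatives) the integer table behind each
# row is recovered by exhaustive search and verified unique.
# ---------------------------------------------------------------------------

def reconstruct_confusion_tables(published=None,
                                 n_pos: int = REFERENCE_POSITIVES,
                                 n_neg: int = REFERENCE_NEGATIVES,
                                 ) -> dict[int, ConfusionTable]:
    """Unique integer 2x2 tables matching the printed rate columns.

    For every cutoff row, searches all tp in [0, n_pos] x tn in [0, n_neg]
    and keeps tables whose sensitivity, specificity, PPR and NPR all round
    (half-up, 1 dp) to the printed values.  Raises unless exactly one table
    matches per cutoff.
    """
    published = published if published is not None else PUBLISHED_CUTOFF_ROWS
    out: dict[int, ConfusionTable] = {}
    for cutoff, row in published.items():
        matches = []
        for tp in range(n_pos + 1):
            fn = n_pos - tp
            sens = round_half_up(100.0 * tp / n_pos, 1)
            if sens != row["sensitivity"]:
                continue
            for tn in range(n_neg + 1):
                fp = n_neg - tn
                if round_half_up(100.0 * tn / n_neg, 1) != row["specificity"]:
                    continue
                if tp + fp == 0 or tn + fn == 0:
                    continue
                if round_half_up(100.0 * tp / (tp + fp), 1) != row["ppr"]:
                    continue
                if round_half_up(100.0 * tn / (tn + fn), 1) != row["npr"]:
                    continue
                matches.append(ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn))
        if len(matches) != 1:
            raise ValueError(
                f"cutoff {cutoff}: {len(matches)} integer tables match the "
                "printed rates; expected exactly one")
        out[cutoff] = matches[0]
    return out


def scores_from_tables(tables: dict[int, ConfusionTable]):
    """Synthesize (scores, reference) vectors consistent with a cutoff scan.

    The per-cutoff true/false positive counts of a nested family of tables
    imply the score distribution in each class; persons below the lowest
    cutoff get lowest-cutoff - 1.  Scanning the returned vectors reproduces
    every input table exactly.
    """
    cuts = sorted(tables)
    lo = cuts[0]
    n_pos = tables[lo].positives
    n_neg = tables[lo].negatives
    scores, labels = [], []
    for label, count_of in (("tp", 1), ("fp", 0)):
        counts = [getattr(tables[c], label) for c in cuts]
        total = n_pos if count_of else n_neg
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("tables are not nested (counts must be "
                             "non-increasing in the cutoff)")
        # persons with score exactly cuts[i]: counts[i] - counts[i+1];
        # the top bin keeps counts[-1], everyone else sits below the scan
        below = total - counts[0]
        scores.extend([lo - 1] * below)
        labels.extend([count_of] * below)
        for i, c in enumerate(cuts):
            n_at = counts[i] - (counts[i + 1] if i + 1 < len(cuts) else 0)
            scores.extend([c] * n_at)
            labels.extend([count_of] * n_at)
    return np.asarray(scores), np.asarray(labels)
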