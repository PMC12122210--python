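"""Confusion counts and classification metrics for homologous pairs.

A pair is an unordered object, but the transfer it validates is
directional: each member serves once as the annotated truth and once as
the transferred prediction.  A concordant pair therefore contributes two
correct directed calls (2 TP for P-P, 2 TN for N-N) while a discordant
N-P pair contributes exactly one false negative (P predicted from the N
partner) and one false positive (N predicted from the P partner).
Pair-level accuracy and directional accuracy coincide algebraically under
this expansion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .pairs import PAIR_MODES, HomologousPair, select_mode


@dataclass(frozen=True)
class ConfusionCounts:
    """Pair-class counts and their directional TP/TN/FP/FN expansion."""

    pp_pairs: int
    nn_pairs: int
    np_pairs: int

    def __post_init__(self):
        if min(self.pp_pairs, self.nn_pairs, self.np_pairs) < 0:
            raise ValueError("pair counts must be non-negative")

    @property
    def TP(self) -> int:
        return 2 * self.pp_pairs

    @property
    def TN(self) -> int:
        return 2 * self.nn_pairs

    @property
    def FP(self) -> int:
        return self.np_pairs

    @property
    def FN(self) -> int:
        return self.np_pairs

    @property
    def total_pairs(self) -> int:
        return self.pp_pairs + self.nn_pairs + self.np_pairs

    @property
    def concordant_pairs(self) -> int:
        return self.pp_pairs + self.nn_pairs


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity/specificity/accuracy/MCC; None when a denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    mcc: float | None
    total_pairs: int
    concordant_pairs: int


def confusion(pairs: Iterable[HomologousPair]) -> ConfusionCounts:
    """Count pairs by concordance class (N-N, P-P, N-P)."""
    pp = nn = np_ = 0
    for p in pairs:
        c = p.concordance
        if c == "PP":
            pp += 1
        elif c == "NN":
            nn += 1
        else:
            np_ += 1
    return ConfusionCounts(pp_pairs=pp, nn_pairs=nn, np_pairs=np_)


def metrics(cc: ConfusionCounts) -> MetricsReport:
    tp, tn, fp, fn = cc.TP, cc.TN, cc.FP, cc.FN

    def ratio(num: float, den: float) -> float | None:
        return num / den if den else None

    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return MetricsReport(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        accuracy=ratio(tp + tn, tp + tn + fp + fn),
        mcc=(tp * tn - fp * fn) / mcc_den if mcc_den else None,
        total_pairs=cc.total_pairs,
        concordant_pairs=cc.concordant_pairs,
    )


def round_half_up(x: float | None, ndigits: int = 2) -> float | None:
    """Display rounding; raw values are kept in machine output."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def evaluate_table(
    pairs: Sequence[HomologousPair],
    modes: Sequence[str] = PAIR_MODES,
    identity_thresholds: Sequence[float] = (0.30,),
) -> pd.DataFrame:
    """Metrics per (mode, identity stratum), one row each.

    Strata are "all" plus one ``>t`` stratum per threshold; the default
    reproduces the four-mode by {all, >0.30} report layout.
    """
    rows = []
    strata: list[tuple[str, float | None]] = [("all", None)]
    strata += [(f">{t:g}", t) for t in identity_thresholds]
    for mode in modes:
        for stratum_name, thr in strata:
            selected = select_mode(pairs, mode=mode, min_identity=thr)
            cc = confusion(selected)
            rep = metrics(cc)
            rows.append(
                {
                    "mode": mode,
                    "stratum": stratum_name,
                    "nn_pairs": cc.nn_pairs,
                    "pp_pairs": cc.pp_pairs,
                    "np_pairs": cc.np_pairs,
                    "total_pairs": cc.total_pairs,
                    "concordant_pairs": cc.concordant_pairs,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "accuracy": rep.accuracy,
                    "mcc": rep.mcc,
                    "sensitivity_2dp": round_half_up(rep.sensitivity),
                    "specificity_2dp": round_half_up(rep.specificity),
                    "accuracy_2dp": round_half_up(rep.accuracy),
                    "mcc_2dp": round_half_up(rep.mcc),
                }
            )
    return pd.DataFrame(rows)


def write_metrics(table: pd.DataFrame, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    table.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(table.to_dict(orient="records"), indent=2) + "\n"
        )
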