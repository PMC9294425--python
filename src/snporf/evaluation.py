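"""Set comparison and performance metrics for ORF prediction.

Two ORFs are "identical" when they share seq_id, strand and the exact list
of genomic blocks; transcript-relative coordinates are never compared, so
the comparison is isoform-robust.  Accuracy is the fraction of predicted
ORFs that match the reference, recall the fraction of reference ORFs
recovered, and the F-score their harmonic mean.  The degree of
mass-spectrometry support of an ORF class is
log10(n_supported / (n_total * mean expression)).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Iterable

from .io_formats import OrfTableRow

__all__ = [
    "SetComparison",
    "PredictionMetrics",
    "MsSupportInput",
    "orf_identity",
    "compare_sets",
    "metrics",
    "ms_support",
    "normalized_ms_support",
    "three_group_split",
    "write_metrics_report",
]


def orf_identity(orf) -> Hashable:
    """Genomic identity key of an ORF (rows pass through unchanged keys)."""
    if isinstance(orf, OrfTableRow):
        return orf.identity
    return orf


@dataclass
class SetComparison:
    n_pred: int
    n_ref: int
    n_common: int
    common: frozenset
    pred_only: frozenset
    ref_only: frozenset


@dataclass
class PredictionMetrics:
    """Accuracy/recall/F-score; None where a denominator was zero."""

    accuracy: float | None
    recall: float | None
    f_score: float | None

    @staticmethod
    def _pct(x: float | None) -> float | None:
        if x is None:
            return None
        return float(
            Decimal(x * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
        )

    @property
    def accuracy_percent(self) -> float | None:
        return self._pct(self.accuracy)

    @property
    def recall_percent(self) -> float | None:
        return self._pct(self.recall)

    @property
    def f_score_percent(self) -> float | None:
        return self._pct(self.f_score)


@dataclass
class MsSupportInput:
    """Counts and class-mean expression entering the MS-support formula."""

    n_supported: int
    n_total: int
    expression: float

    def __post_init__(self):
        if not (0 <= self.n_supported <= self.n_total):
            raise ValueError("need 0 <= n_supported <= n_total")
        if self.expression <= 0:
            raise ValueError("expression level must be positive")


def compare_sets(pred: Iterable, ref: Iterable) -> SetComparison:
    """Exact-match intersection of two ORF sets by genomic identity."""
    pred_keys = frozenset(orf_identity(o) for o in pred)
    ref_keys = frozenset(orf_identity(o) for o in ref)
    common = pred_keys & ref_keys
    return SetComparison(
        n_pred=len(pred_keys),
        n_ref=len(ref_keys),
        n_common=len(common),
        common=common,
        pred_only=frozenset(pred_keys - ref_keys),
        ref_only=frozenset(ref_keys - pred_keys),
    )


def metrics(comparison: SetComparison) -> PredictionMetrics:
    """Accuracy, recall and F-score of a prediction-vs-reference comparison."""
    acc = comparison.n_common / comparison.n_pred if comparison.n_pred else None
    rec = comparison.n_common / comparison.n_ref if comparison.n_ref else None
    if acc is None or rec is None:
        f = None
    elif acc + rec == 0:
        f = 0.0
    else:
        f = 2.0 * rec * acc / (rec + acc)
    return PredictionMetrics(accuracy=acc, recall=rec, f_score=f)


def ms_support(inp: MsSupportInput) -> float | None:
    """log10(n_supported / (n_total * expression)); None when unsupported."""
    if inp.n_supported == 0:
        return None
    return math.log10(inp.n_supported / (inp.n_total * inp.expression))


def normalized_ms_support(novel: MsSupportInput, annotated: MsSupportInput) -> float:
    """Ratio of the novel-class MS support to the annotated-class support."""
    s_novel = ms_support(novel)
    s_ann = ms_support(annotated)
    if s_novel is None or s_ann is None:
        raise ValueError("MS support undefined for one of the classes")
    if s_ann == 0:
        raise ValueError("annotated-class support is 0; ratio undefined")
    return s_novel / s_ann


def three_group_split(
    snp_set: Iterable, rpf_set: Iterable, universe: Iterable
) -> dict[Hashable, str]:
    """Partition `universe` into common / snp_only / not_predicted groups."""
    snp = {orf_identity(o) for o in snp_set}
    rpf = {orf_identity(o) for o in rpf_set}
    out = {}
    for o in universe:
        key = orf_identity(o)
        if key in snp and key in rpf:
            out[key] = "common"
        elif key in snp:
            out[key] = "snp_only"
        else:
            out[key] = "not_predicted"
    return out


def write_metrics_report(m: PredictionMetrics, comparison: SetComparison, path,
                         as_json: bool = False) -> None:
    payload = {
        "n_pred": comparison.n_pred,
        "n_ref": comparison.n_ref,
        "n_common": comparison.n_common,
        "accuracy_percent": m.accuracy_percent,
        "recall_percent": m.recall_percent,
        "f_score_percent": m.f_score_percent,
    }
    with open(path, "w") as fh:
        if as_json:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
        else:
            fh.write("metric\tvalue\n")
            for key, val in payload.items():
                fh.write(f"{key}\t{'NA' if val is None else val}\n")
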