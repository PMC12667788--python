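"""Frame-level evaluation protocol.

Accuracy is a poor headline metric for behavioral data, where a dominant
"other" state can swamp rare but meaningful actions.  The protocol instead
reports rank-based mean average precision (mAP) computed from the continuous
per-frame probabilities, with the background class excluded from the
average, plus macro-averaged F1/precision/recall computed after discretizing
the probabilities into an ethogram, per-video fractions of fully correct
frames, and (single-label) a confusion matrix.

Tied scores in average precision are resolved analytically: the reported AP
is the exact expectation of the standard rank AP over a uniformly random
ordering of each tie block, which is deterministic and oracle-checkable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from feral.inference import Ethogram
from feral.labels import MULTI_LABEL, SINGLE_LABEL, ClassCatalog, FrameLabelTrack
from feral.inference import FrameProbabilityTrack

__all__ = [
    "MetricReport",
    "average_precision",
    "frame_map",
    "macro_prf",
    "fraction_correct",
    "confusion",
    "evaluate",
]


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AP of one class: sum_k precision@k * delta-recall@k.

    ``labels`` is binary; at least one positive is required.  Ties are
    averaged analytically over all orderings of each tie block: conditioned
    on the item at within-block rank j being positive, the expected number
    of earlier in-block positives is (j-1)(P-1)/(B-1), which gives the
    expected precision at that rank by linearity of expectation.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positive labels")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    total = 0.0
    f_prev = 0  # items ranked before this block
    tp_prev = 0  # positives ranked before this block
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        block = y[i:j]
        B = j - i
        P = int(block.sum())
        if P > 0:
            if B == 1:
                total += (tp_prev + 1) / (f_prev + 1)
            else:
                within = np.arange(1, B + 1)
                exp_tp = tp_prev + 1 + (within - 1) * (P - 1) / (B - 1)
                total += (P / B) * np.sum(exp_tp / (f_prev + within))
        f_prev += B
        tp_prev += P
        i = j
    return total / n_pos


def frame_map(
    track: FrameProbabilityTrack,
    truth: FrameLabelTrack,
    catalog: ClassCatalog,
) -> tuple[float, dict[str, float]]:
    """One-vs-rest AP per class from probability columns; mean excludes background.

    Classes with no positive frames in the truth are skipped with a warning
    (their AP is undefined) and dropped from the mean.
    """
    if track.n_frames != truth.n_frames:
        raise ValueError("probability track and truth track lengths differ")
    truth.validate_against(catalog)
    per_class: dict[str, float] = {}
    for c in catalog.foreground_indices():
        name = catalog.names[c]
        pos = (
            (truth.targets == c) if truth.mode == SINGLE_LABEL else truth.targets[:, c] == 1
        )
        if not pos.any():
            warnings.warn(f"class {name!r} has no positive frames; AP skipped", stacklevel=2)
            continue
        per_class[name] = average_precision(track.probs[:, c], pos)
    if not per_class:
        raise ValueError("no class with positive frames to evaluate")
    return float(np.mean(list(per_class.values()))), per_class


def _binary_calls(etho: Ethogram, catalog: ClassCatalog) -> np.ndarray:
    if etho.mode == SINGLE_LABEL:
        calls = np.zeros((len(etho.labels), catalog.n_classes), dtype=np.uint8)
        calls[np.arange(len(etho.labels)), etho.labels] = 1
        return calls
    return etho.labels


def macro_prf(
    etho: Ethogram,
    truth: FrameLabelTrack,
    catalog: ClassCatalog,
) -> tuple[float, float, float, dict[str, dict[str, float]]]:
    """Macro precision/recall/F1 on discrete calls, background excluded.

    Classes never predicted and never true in this split are excluded from
    the macro averages with a warning (a macro term for them is undefined).
    Returns (macro_precision, macro_recall, macro_f1, per_class).
    """
    if len(etho.labels) != truth.n_frames:
        raise ValueError("ethogram and truth lengths differ")
    truth.validate_against(catalog)
    pred = _binary_calls(etho, catalog)
    true = _binary_calls(
        Ethogram(truth.video_id, truth.fps, truth.targets), catalog
    ) if truth.mode == SINGLE_LABEL else truth.targets
    per_class: dict[str, dict[str, float]] = {}
    for c in catalog.foreground_indices():
        name = catalog.names[c]
        p, t = pred[:, c].astype(bool), true[:, c].astype(bool)
        if not p.any() and not t.any():
            warnings.warn(
                f"class {name!r} never predicted and never true; excluded from macro average",
                stacklevel=2,
            )
            continue
        tp = int((p & t).sum())
        fp = int((p & ~t).sum())
        fn = int((~p & t).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[name] = {"precision": precision, "recall": recall, "f1": f1}
    if not per_class:
        raise ValueError("no evaluable class")
    macro = {
        k: float(np.mean([v[k] for v in per_class.values()]))
        for k in ("precision", "recall", "f1")
    }
    return macro["precision"], macro["recall"], macro["f1"], per_class


def fraction_correct(etho: Ethogram, truth: FrameLabelTrack) -> float:
    """Fraction of frames whose full prediction matches the annotation.

    Single-label: label equality.  Multi-label: subset accuracy — the whole
    binary vector must match (one extra predicted class makes the frame
    incorrect).
    """
    if len(etho.labels) != truth.n_frames:
        raise ValueError("ethogram and truth lengths differ")
    if truth.mode == SINGLE_LABEL:
        if etho.mode != SINGLE_LABEL:
            raise ValueError("mode mismatch between ethogram and truth")
        return float(np.mean(etho.labels == truth.targets))
    return float(np.mean((etho.labels == truth.targets).all(axis=1)))


def confusion(etho: Ethogram, truth: FrameLabelTrack, catalog: ClassCatalog) -> np.ndarray:
    """C x C counts, entry (i, j) = frames with truth i predicted j (single-label)."""
    if truth.mode != SINGLE_LABEL or etho.mode != SINGLE_LABEL:
        raise ValueError("confusion matrix is defined for single-label tracks only")
    truth.validate_against(catalog)
    C = catalog.n_classes
    mat = np.zeros((C, C), dtype=np.int64)
    np.add.at(mat, (truth.targets, etho.labels), 1)
    return mat


@dataclass
class MetricReport:
    """Everything the evaluation protocol reports for one video or split."""

    mAP: float
    per_class_ap: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class_prf: dict[str, dict[str, float]]
    fraction_correct: float
    confusion: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "mAP": self.mAP,
            "per_class_ap": self.per_class_ap,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class_prf": self.per_class_prf,
            "fraction_correct": self.fraction_correct,
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.tolist()
        return out


def evaluate(
    track: FrameProbabilityTrack,
    etho: Ethogram,
    truth: FrameLabelTrack,
    catalog: ClassCatalog,
) -> MetricReport:
    """Run the full protocol on one probability track + ethogram pair."""
    mAP, per_ap = frame_map(track, truth, catalog)
    mp, mr, mf1, per_prf = macro_prf(etho, truth, catalog)
    fc = fraction_correct(etho, truth)
    conf = confusion(etho, truth, catalog) if truth.mode == SINGLE_LABEL else None
    return MetricReport(
        mAP=mAP,
        per_class_ap=per_ap,
        macro_precision=mp,
        macro_recall=mr,
        macro_f1=mf1,
        per_class_prf=per_prf,
        fraction_correct=fc,
        confusion=conf,
    )
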