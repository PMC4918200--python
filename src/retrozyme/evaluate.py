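"""Benchmark evaluation of predicted elements against planted truth.

Matching is by >=50% reciprocal interval overlap plus class equality;
boundary error statistics are reported for matched elements.  Decoy
truth records (class ``decoy_*``) are never positives — any prediction
over them simply counts as a false positive of its own class.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import RetrozymeElement
from .simulate import TruthRecord

__all__ = ["evaluate", "match_elements"]

_EVAL_CLASSES = ("full_retrozyme", "multimeric_retrozyme", "solo_LTR")


def match_elements(predictions: Sequence[RetrozymeElement],
                   truth: Sequence[TruthRecord],
                   min_reciprocal_overlap: float = 0.5):
    """Greedy one-to-one matching (best overlap first) within each class."""
    pairs = []
    for ti, t in enumerate(truth):
        for pi, p in enumerate(predictions):
            if p.classification != t.cls:
                continue
            ov = p.location.reciprocal_overlap(t.element)
            if ov >= min_reciprocal_overlap:
                pairs.append((ov, ti, pi))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    matches = []
    for ov, ti, pi in pairs:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matches.append((ti, pi, ov))
    return matches


def evaluate(predictions: Sequence[RetrozymeElement],
             truth: Sequence[TruthRecord],
             min_reciprocal_overlap: float = 0.5) -> pd.DataFrame:
    """Per-class precision/recall/F1 and boundary error of matched elements."""
    truth_contigs = {t.element.contig for t in truth}
    bad = {p.location.contig for p in predictions} - truth_contigs
    if bad:
        raise ValueError(f"predictions on contigs absent from truth: {sorted(bad)}")

    matches = match_elements(predictions, truth, min_reciprocal_overlap)
    matched_t = {ti for ti, _, _ in matches}
    matched_p = {pi for _, pi, _ in matches}

    rows = []
    for cls in _EVAL_CLASSES:
        t_idx = [i for i, t in enumerate(truth) if t.cls == cls]
        p_idx = [i for i, p in enumerate(predictions)
                 if p.classification == cls]
        if not t_idx and not p_idx:
            continue
        tp = sum(1 for i in t_idx if i in matched_t)
        fn = len(t_idx) - tp
        fp = sum(1 for i in p_idx if i not in matched_p)
        precision = tp / (tp + fp) if tp + fp else float("nan")
        recall = tp / (tp + fn) if tp + fn else float("nan")
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        errs = []
        for ti, pi, _ in matches:
            if truth[ti].cls != cls:
                continue
            errs.append(abs(predictions[pi].location.start
                            - truth[ti].element.start))
            errs.append(abs(predictions[pi].location.end
                            - truth[ti].element.end))
        rows.append({
            "class": cls, "n_truth": len(t_idx), "n_pred": len(p_idx),
            "tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1,
            "median_boundary_error": float(np.median(errs)) if errs else float("nan"),
            "max_boundary_error": float(np.max(errs)) if errs else float("nan"),
        })
    return pd.DataFrame(rows)
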