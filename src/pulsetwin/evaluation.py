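"""Genuine/impostor scoring and biometric verification metrics.

The test gallery is scored exhaustively: every unordered pair of distinct
test templates is either genuine (same subject) or impostor (different
subjects), and the trained model assigns each a similarity in (0, 1).
From those scores the module computes threshold accuracy, the ROC curve
and its AUC, the FAR/FRR sweep with the interpolated equal error rate, and
the two-class score histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.metrics import roc_curve

from .preprocess import ProcessedCycle
from .verifier import SimilarityModel


@dataclass
class ScoreSet:
    """Similarity scores split by ground-truth pair label."""

    genuine_scores: np.ndarray
    impostor_scores: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.genuine_scores, dtype=float)
        i = np.asarray(self.impostor_scores, dtype=float)
        if (g.size and not np.all(np.isfinite(g))) or (i.size and not np.all(np.isfinite(i))):
            raise ValueError("non-finite scores")
        self.genuine_scores, self.impostor_scores = g, i

    @property
    def total(self) -> int:
        return self.genuine_scores.size + self.impostor_scores.size


@dataclass
class EvalReport:
    """Complete verification evaluation of one trained model."""

    accuracy_at_threshold: float
    threshold: float
    auc: float
    eer: float
    eer_threshold: float
    roc_points: np.ndarray          # (n, 2): FPR, TPR
    far_frr_curve: np.ndarray       # (n, 3): threshold, FAR, FRR
    histogram: np.ndarray           # (bins, 3): bin left edge, genuine, impostor
    n_genuine: int = 0
    n_impostor: int = 0

    def summary_text(self) -> str:
        lines = [
            f"n_genuine: {self.n_genuine}",
            f"n_impostor: {self.n_impostor}",
            f"n_total: {self.n_genuine + self.n_impostor}",
            f"threshold: {self.threshold:.6g}",
            f"accuracy_at_threshold: {self.accuracy_at_threshold:.6f}",
            f"auc: {self.auc:.6f}",
            f"eer: {self.eer:.6f}",
            f"eer_threshold: {self.eer_threshold:.6f}",
        ]
        return "\n".join(lines) + "\n"


def enumerate_pairs(test_labels) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """All unordered index pairs, partitioned into genuine and impostor.

    With ``m`` items per subject over ``s`` subjects the counts are
    s·C(m,2) genuine and C(s·m,2) − s·C(m,2) impostor.
    """
    labels = list(test_labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 test items")
    genuine, impostor = [], []
    for i, j in combinations(range(len(labels)), 2):
        (genuine if labels[i] == labels[j] else impostor).append((i, j))
    return genuine, impostor


def score_pairs(model: SimilarityModel, cycles: list[ProcessedCycle],
                batch_size: int = 4096) -> ScoreSet:
    """Score every unordered pair of the gallery with one embedding pass.

    Embeds each cycle once in evaluation mode, then runs the similarity
    head over all pair differences — mathematically identical to calling
    ``model.similarity`` per pair, and order-stable.
    """
    model.eval_mode()
    genuine, impostor = enumerate_pairs([c.subject_id for c in cycles])
    emb = model.embed_batch(np.stack([c.values for c in cycles]))

    from .verifier import _P_EPS, _linear_forward, _relu_forward, _sigmoid

    def head(pairs):
        out = np.empty(len(pairs))
        for start in range(0, len(pairs), batch_size):
            chunk = pairs[start:start + batch_size]
            ii = np.asarray([p[0] for p in chunk])
            jj = np.asarray([p[1] for p in chunk])
            d = np.abs(emb[ii] - emb[jj])
            h, _ = _linear_forward(d, model.params["fc1_w"], model.params["fc1_b"])
            h, _ = _relu_forward(h)
            z, _ = _linear_forward(h, model.params["fc2_w"], model.params["fc2_b"])
            out[start:start + batch_size] = np.clip(_sigmoid(z[:, 0]), _P_EPS, 1.0 - _P_EPS)
        return out

    return ScoreSet(head(genuine) if genuine else np.empty(0),
                    head(impostor) if impostor else np.empty(0))


def accuracy(scores: ScoreSet, threshold: float) -> float:
    """Fraction of pairs classified correctly; score >= threshold accepts."""
    if scores.total == 0:
        raise ValueError("empty score set")
    correct = int(np.sum(scores.genuine_scores >= threshold))
    correct += int(np.sum(scores.impostor_scores < threshold))
    return correct / scores.total


def roc_auc(scores: ScoreSet) -> tuple[np.ndarray, float]:
    """ROC over all distinct score thresholds and trapezoidal AUC.

    The AUC equals the probability that a random genuine score exceeds a
    random impostor score, ties counting one half.
    """
    if scores.genuine_scores.size == 0 or scores.impostor_scores.size == 0:
        raise ValueError("both classes must be non-empty")
    y = np.concatenate([np.ones_like(scores.genuine_scores),
                        np.zeros_like(scores.impostor_scores)])
    s = np.concatenate([scores.genuine_scores, scores.impostor_scores])
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def far_frr_eer(scores: ScoreSet) -> tuple[np.ndarray, float, float]:
    """FAR/FRR threshold sweep and the interpolated equal error rate.

    FAR(t) is the impostor fraction scored >= t and FRR(t) the genuine
    fraction scored < t; the sweep covers every distinct score plus the
    end points 0 and 1, so FAR is non-increasing and FRR non-decreasing
    across it.  The EER is read off at the FAR = FRR crossing, linearly
    interpolated between the two bracketing sweep points.
    """
    g, im = scores.genuine_scores, scores.impostor_scores
    if g.size == 0 or im.size == 0:
        raise ValueError("both classes must be non-empty")
    thresholds = np.unique(np.concatenate([[0.0], g, im, [1.0]]))
    far = np.searchsorted(np.sort(im), thresholds, side="left")
    far = 1.0 - far / im.size
    frr = np.searchsorted(np.sort(g), thresholds, side="left") / g.size
    curve = np.column_stack([thresholds, far, frr])

    diff = far - frr  # non-increasing; starts >= 0, ends <= 0
    k = int(np.argmax(diff <= 0))
    if diff[k] == 0 or k == 0:
        eer = float((far[k] + frr[k]) / 2.0)
        eer_threshold = float(thresholds[k])
    else:
        t0, t1 = thresholds[k - 1], thresholds[k]
        d0, d1 = diff[k - 1], diff[k]
        w = d0 / (d0 - d1)  # in (0, 1]
        eer_threshold = float(t0 + w * (t1 - t0))
        far_c = far[k - 1] + w * (far[k] - far[k - 1])
        frr_c = frr[k - 1] + w * (frr[k] - frr[k - 1])
        eer = float((far_c + frr_c) / 2.0)
    return curve, eer, eer_threshold


def score_histogram(scores: ScoreSet, bins: int = 50) -> np.ndarray:
    """Two-class histogram over [0, 1]: bin left edge, genuine, impostor counts."""
    edges = np.linspace(0.0, 1.0, bins + 1)
    g, _ = np.histogram(scores.genuine_scores, bins=edges)
    i, _ = np.histogram(scores.impostor_scores, bins=edges)
    return np.column_stack([edges[:-1], g, i])


def evaluate_scores(scores: ScoreSet, threshold: float = 0.5, bins: int = 50) -> EvalReport:
    """Assemble the full report from a score set."""
    roc_points, auc = roc_auc(scores)
    curve, eer, eer_threshold = far_frr_eer(scores)
    return EvalReport(
        accuracy_at_threshold=accuracy(scores, threshold),
        threshold=threshold,
        auc=auc,
        eer=eer,
        eer_threshold=eer_threshold,
        roc_points=roc_points,
        far_frr_curve=curve,
        histogram=score_histogram(scores, bins),
        n_genuine=scores.genuine_scores.size,
        n_impostor=scores.impostor_scores.size,
    )


def n_sweep(manifest, config, n_values, seed: int | None = None):
    """Run the full pipeline once per cycle count N and tabulate the metrics.

    Returns a list of dicts with keys ``n, accuracy, auc, eer`` — the
    synthetic analogue of a cycle-count comparison table.  All runs share
    the same seed so only N varies.
    """
    from .pipeline import run_pipeline

    rows = []
    for n in n_values:
        cfg = config.replace(n_cycles=int(n))
        if seed is not None:
            cfg = cfg.replace(random_seed=int(seed))
        report = run_pipeline(cfg, manifest)
        rows.append({"n": int(n), "accuracy": report.accuracy_at_threshold,
                     "auc": report.auc, "eer": report.eer})
    return rows
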