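"""Shannon-entropy similarity measures on joint histograms.

Entropies are reported in bits (base-2 logarithm).  The registration
objective, normalized mutual information

    NMI(R, F) = (H(R) + H(F)) / H(R, F),

is invariant to the log base; it ranges from 1 (independent gray values) to
2 (perfect functional dependence) and is maximized at alignment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .histograms import JointHistogram, to_probability

__all__ = [
    "SimilarityReport",
    "shannon_entropy",
    "marginal_entropies",
    "joint_entropy",
    "mutual_information",
    "nmi",
    "similarity_report",
]


def shannon_entropy(p) -> float:
    """H(p) = -sum p_i log2 p_i, with 0 log 0 = 0, in bits."""
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def marginal_entropies(hist: JointHistogram) -> tuple:
    """(H_R, H_F): entropies of the row-sum and column-sum distributions."""
    p = to_probability(hist)
    return shannon_entropy(p.sum(axis=1)), shannon_entropy(p.sum(axis=0))


def joint_entropy(hist: JointHistogram) -> float:
    """Entropy of the full joint gray-value distribution, in bits."""
    return shannon_entropy(to_probability(hist))


def mutual_information(hist: JointHistogram) -> float:
    """MI = H_R + H_F - H_RF >= 0, in bits."""
    h_r, h_f = marginal_entropies(hist)
    return h_r + h_f - joint_entropy(hist)


def nmi(hist: JointHistogram) -> float:
    """Normalized mutual information (H_R + H_F) / H_RF in [1, 2].

    A single-occupied-cell histogram has H_RF = 0; the perfect-dependence
    limit 2 is returned by continuity.
    """
    h_r, h_f = marginal_entropies(hist)
    h_rf = joint_entropy(hist)
    if h_rf == 0.0:
        return 2.0
    return (h_r + h_f) / h_rf


@dataclass(frozen=True)
class SimilarityReport:
    """Entropies (bits) and mutual-information measures of an image pair."""

    H_R: float
    H_F: float
    H_RF: float
    MI: float
    NMI: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def similarity_report(hist: JointHistogram) -> SimilarityReport:
    h_r, h_f = marginal_entropies(hist)
    h_rf = joint_entropy(hist)
    mi = h_r + h_f - h_rf
    value = 2.0 if h_rf == 0.0 else (h_r + h_f) / h_rf
    return SimilarityReport(H_R=h_r, H_F=h_f, H_RF=h_rf, MI=mi, NMI=value)
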