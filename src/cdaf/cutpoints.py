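"""Binary cut-point search for prognostic factors on censored outcomes.

For each candidate dichotomization of a variable the partial-likelihood score
test of the resulting two-group indicator is computed; the candidate with the
smallest score-test p-value is returned together with its log-rank p-value.
Candidate grids follow the variable's measurement scale: the single split for
a binary factor, every interior threshold for ordinal scores and counts,
the decile grid of observed values for continuous variables, and one-vs-rest
partitions for nominal factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .coxph import score_test_1d
from .survival import SurvivalDataset, logrank_from_mask

VARIABLE_KINDS = ("binary", "ordinal", "continuous", "categorical")

#: Decile probabilities used as the threshold grid for continuous variables.
DECILE_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


@dataclass(frozen=True)
class BinarySplit:
    """One accepted or candidate dichotomization of a variable.

    For threshold splits the left branch is ``x <= threshold``; for
    categorical splits it is ``x in left_levels`` (one level vs the rest).
    """

    variable: str
    kind: str
    threshold: Optional[float] = None
    left_levels: Optional[frozenset] = None
    score_p: float = float("nan")
    logrank_p: float = float("nan")
    n_left: int = 0
    n_right: int = 0

    @property
    def description(self) -> str:
        if self.kind == "categorical":
            levels = "/".join(sorted(map(str, self.left_levels or ())))
            return f"{self.variable} in {{{levels}}}"
        return f"{self.variable} <= {self.threshold:g}"

    def mask(self, covariates: pd.DataFrame) -> np.ndarray:
        """Boolean left-branch membership for each row."""
        x = covariates[self.variable]
        if self.kind == "categorical":
            return x.isin(list(self.left_levels or ())).to_numpy()
        return (x.to_numpy(dtype=float) <= self.threshold)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "kind": self.kind,
            "threshold": self.threshold,
            "left_levels": sorted(map(str, self.left_levels)) if self.left_levels else None,
            "score_p": self.score_p,
            "logrank_p": self.logrank_p,
            "n_left": self.n_left,
            "n_right": self.n_right,
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinarySplit":
        return cls(
            variable=d["variable"],
            kind=d["kind"],
            threshold=d["threshold"],
            left_levels=frozenset(d["left_levels"]) if d["left_levels"] else None,
            score_p=d["score_p"],
            logrank_p=d["logrank_p"],
            n_left=d["n_left"],
            n_right=d["n_right"],
        )


def _candidate_masks(
    x: pd.Series, kind: str
) -> list[tuple[Optional[float], Optional[frozenset], np.ndarray]]:
    """Enumerate (threshold, left_levels, left_mask) candidates for one variable."""
    if kind not in VARIABLE_KINDS:
        raise ValueError(f"unknown variable kind {kind!r}")
    candidates = []
    if kind == "categorical":
        for level in sorted(x.dropna().unique(), key=str):
            candidates.append((None, frozenset([level]), (x == level).to_numpy()))
        return candidates

    values = x.to_numpy(dtype=float)
    uniq = np.unique(values)
    if kind == "binary":
        if uniq.size != 2:
            return []
        thresholds = uniq[:1]
    elif kind == "ordinal":
        thresholds = uniq[:-1]  # every interior threshold on the observed grid
    else:  # continuous: decile grid of the observed distribution
        qs = np.unique(np.quantile(values, DECILE_GRID))
        thresholds = qs[qs < uniq.max()]
    for thr in thresholds:
        candidates.append((float(thr), None, values <= thr))
    return candidates


def best_binary_split(
    d: SurvivalDataset,
    variable: str,
    kind: str,
    min_size: int = 5,
) -> Optional[BinarySplit]:
    """Best dichotomization of ``variable`` by the Cox score test.

    Returns ``None`` (a no-split result) when no candidate leaves at least
    ``min_size`` subjects on each side, when the variable is constant, or
    when the dataset has no events.
    """
    if variable not in d.covariates.columns:
        raise KeyError(f"variable {variable!r} not in dataset")
    if d.n_events == 0:
        return None
    x = d.covariates[variable]

    best: Optional[tuple[float, Optional[float], Optional[frozenset], np.ndarray]] = None
    for thr, levels, mask in _candidate_masks(x, kind):
        n_left = int(mask.sum())
        n_right = len(d) - n_left
        if n_left < min_size or n_right < min_size:
            continue
        score_p = score_test_1d(d.time, d.event, mask.astype(float)).p_value
        if best is None or score_p < best[0]:
            best = (score_p, thr, levels, mask)

    if best is None:
        return None
    score_p, thr, levels, mask = best
    logrank_p = logrank_from_mask(d, mask).p_value
    return BinarySplit(
        variable=variable,
        kind=kind,
        threshold=thr,
        left_levels=levels,
        score_p=float(score_p),
        logrank_p=float(logrank_p),
        n_left=int(mask.sum()),
        n_right=len(d) - int(mask.sum()),
    )
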