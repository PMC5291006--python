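"""Cohort-level comparison and classification of the lacunarity biomarker.

Per-subject fitted beta values are compared between two groups (e.g. AD
patients vs age-matched controls) with a pooled-variance one-tailed Student
t-test, and subjects are classified by a beta cutoff.  Lower beta
corresponds to a higher degree of mutated frames, so subjects at or below
the cutoff are labelled positive (disease-like); the cutoff may be a fixed
value or the median of the whole sample.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .hypfit import read_fit_json


@dataclass(frozen=True)
class SubjectResult:
    """One subject's fitted parameters and mutation load."""

    subject_id: str
    group: str
    beta: float
    alpha: float
    gamma: float
    n_mutations_homo: int = 0
    n_mutations_hetero: int = 0

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "beta": self.beta,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "n_mutations_homo": self.n_mutations_homo,
            "n_mutations_hetero": self.n_mutations_hetero,
        }


@dataclass
class CohortComparison:
    """Group summaries, one-tailed t-test, and cutoff classification."""

    group_means: dict[str, float]
    group_sds: dict[str, float]
    n_per_group: dict[str, int]
    t_statistic: float
    p_value: float
    cutoff: float
    true_pos: int
    false_pos: int
    true_neg: int
    false_neg: int

    @property
    def sensitivity(self) -> float:
        return self.true_pos / (self.true_pos + self.false_neg)

    @property
    def specificity(self) -> float:
        return self.true_neg / (self.true_neg + self.false_pos)

    def to_dict(self) -> dict:
        return {
            "group_means": self.group_means,
            "group_sds": self.group_sds,
            "n_per_group": self.n_per_group,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "cutoff": self.cutoff,
            "confusion": {
                "true_pos": self.true_pos,
                "false_pos": self.false_pos,
                "true_neg": self.true_neg,
                "false_neg": self.false_neg,
            },
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def t_test_one_tail(values_a, values_b) -> tuple[float, float]:
    """Pooled-variance Student t-test, one-tailed.

    t is signed by the observed difference (mean_a - mean_b); p is the
    one-tailed probability in the direction of that difference, i.e. half
    the two-tailed p.  Degrees of freedom: n_a + n_b - 2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            raise ValueError("zero pooled variance with equal means: t undefined")
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = float(stats.t.sf(abs(t), df=na + nb - 2))
    if t == 0:
        p = 0.5
    return float(t), p


def classify_by_cutoff(
    results: list[SubjectResult],
    cutoff: float | str = "median",
    positive_label: str = "AD",
) -> CohortComparison:
    """Classify subjects as positive when beta <= cutoff and compare groups.

    ``cutoff="median"`` recomputes the cutoff as the median beta of the whole
    sample.  Ties at the cutoff count as positive (conservative for
    screening).  ``positive_label`` names the group treated as the true
    positive class.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 subjects")
    groups = sorted({r.group for r in results})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if positive_label not in groups:
        raise ValueError(f"positive_label {positive_label!r} not among groups {groups}")

    betas = np.array([r.beta for r in results])
    cut = float(np.median(betas)) if cutoff == "median" else float(cutoff)

    tp = fp = tn = fn = 0
    for r in results:
        predicted_pos = r.beta <= cut
        actually_pos = r.group == positive_label
        if predicted_pos and actually_pos:
            tp += 1
        elif predicted_pos:
            fp += 1
        elif actually_pos:
            fn += 1
        else:
            tn += 1

    by_group = {g: np.array([r.beta for r in results if r.group == g]) for g in groups}
    other = next(g for g in groups if g != positive_label)
    try:
        t, p = t_test_one_tail(by_group[positive_label], by_group[other])
    except ValueError:  # degenerate betas (all equal): comparison undefined
        t, p = math.nan, math.nan
    return CohortComparison(
        group_means={g: float(v.mean()) for g, v in by_group.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in by_group.items()},
        n_per_group={g: int(v.size) for g, v in by_group.items()},
        t_statistic=t,
        p_value=p,
        cutoff=cut,
        true_pos=tp,
        false_pos=fp,
        true_neg=tn,
        false_neg=fn,
    )


def load_results(fits_dir: str | Path, groups_tsv: str | Path) -> list[SubjectResult]:
    """Assemble SubjectResults from per-subject fit JSONs and a groups TSV.

    The TSV has columns ``subject_id`` and ``group``; each subject's fit is
    read from ``<fits_dir>/<subject_id>.json``.
    """
    fits_dir = Path(fits_dir)
    df = pd.read_csv(groups_tsv, sep="\t", dtype=str)
    results = []
    for _, row in df.iterrows():
        fit = read_fit_json(fits_dir / f"{row['subject_id']}.json")
        results.append(
            SubjectResult(
                subject_id=row["subject_id"],
                group=row["group"],
                beta=fit.beta,
                alpha=fit.alpha,
                gamma=fit.gamma,
            )
        )
    return results


def write_cohort_json(comparison: CohortComparison, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(comparison.to_dict(), fh, indent=2)
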