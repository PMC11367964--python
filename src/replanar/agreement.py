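"""Agreement statistics for paired categorical scores and paired ratios.

Implements the statistical battery used to compare two acquisition
pathways: percent agreement, Cohen's kappa (two raters or one reader
across two modalities), Fleiss's kappa (multiple raters), Pearson
correlation with least-squares regression, Bland-Altman limits of
agreement, and per-reader concordance/discordance summaries.

Confidence intervals for the kappa statistics use a seeded percentile
bootstrap over subjects (2000 resamples by default) — uniform across both
kappa flavours and robust at small n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoreTable",
    "KappaResult",
    "BlandAltmanResult",
    "RegressionResult",
    "percent_agreement",
    "cohens_kappa",
    "fleiss_kappa",
    "bland_altman",
    "pearson_regression",
    "concordance_summary",
]

CATEGORIES = (0, 1, 2, 3)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    percent_agreement: int
    n_subjects: int
    flavor: str  # "cohen" | "fleiss"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12:
            raise ValueError("kappa out of [-1, 1]")


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class RegressionResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


class ScoreTable:
    """Categorical scores indexed by subject x reader x modality.

    Backed by a long-format DataFrame with columns ``subject_id``,
    ``reader``, ``modality``, ``score`` (the CSV interchange layout).
    """

    COLUMNS = ("subject_id", "reader", "modality", "score")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"score table missing columns {sorted(missing)}")
        frame = frame[list(self.COLUMNS)].copy()
        frame["score"] = frame["score"].astype(int)
        if not frame["score"].isin(CATEGORIES).all():
            raise ValueError("scores must be Perugini categories 0-3")
        counts = frame.groupby(["reader", "modality"])["subject_id"].nunique()
        if counts.nunique() > 1:
            raise ValueError("missing cells: readers/modalities cover different subjects")
        if frame.duplicated(["subject_id", "reader", "modality"]).any():
            raise ValueError("duplicate (subject, reader, modality) cells")
        self.frame = frame

    @property
    def subjects(self) -> list:
        return sorted(self.frame["subject_id"].unique())

    @property
    def readers(self) -> list:
        return sorted(self.frame["reader"].unique())

    @property
    def modalities(self) -> list:
        return sorted(self.frame["modality"].unique())

    def scores(self, reader, modality) -> np.ndarray:
        sub = self.frame[(self.frame["reader"] == reader)
                         & (self.frame["modality"] == modality)]
        sub = sub.set_index("subject_id").loc[self.subjects]
        return sub["score"].to_numpy()

    def rater_matrix(self, modality) -> np.ndarray:
        """(n_subjects, n_readers) matrix for one modality."""
        return np.column_stack([self.scores(r, modality) for r in self.readers])


def _as_scores(a) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 1:
        raise ValueError("scores must be 1D")
    return a


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def percent_agreement(a, b) -> int:
    """100 x (identical pairs) / n, rounded to the nearest integer."""
    a, b = _as_scores(a), _as_scores(b)
    if a.size != b.size:
        raise ValueError("score vectors differ in length")
    if a.size == 0:
        raise ValueError("need at least one pair")
    return _round_half_up(100.0 * np.count_nonzero(a == b) / a.size)


def _cohen_point(a: np.ndarray, b: np.ndarray) -> float:
    cats = np.union1d(a, b)
    n = a.size
    p_o = np.count_nonzero(a == b) / n
    p_e = sum((np.count_nonzero(a == c) / n) * (np.count_nonzero(b == c) / n)
              for c in cats)
    if p_e >= 1.0:
        # both raters constant and equal: observed agreement is perfect but
        # chance-corrected agreement is formally 0/0
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 1")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def _bootstrap_ci(stat_fn, n_subjects: int, n_boot: int, seed: int,
                  estimate: float) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_boot):
            idx = rng.integers(0, n_subjects, size=n_subjects)
            reps[i] = stat_fn(idx)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    # percentile interval widened, if needed, to contain the point estimate
    return min(float(lo), estimate), max(float(hi), estimate)


def cohens_kappa(a, b, ci_method: str = "bootstrap", n_boot: int = 2000,
                 seed: int = 0) -> KappaResult:
    """Chance-corrected agreement between two score vectors.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement from the
    marginal products; 95% CI by seeded percentile bootstrap over subjects.
    """
    a, b = _as_scores(a), _as_scores(b)
    if a.size != b.size:
        raise ValueError("score vectors differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 subjects")
    k = _cohen_point(a, b)
    if ci_method == "bootstrap":
        lo, hi = _bootstrap_ci(lambda idx: _cohen_point(a[idx], b[idx]),
                               a.size, n_boot, seed, k)
    elif ci_method == "none":
        lo = hi = float("nan")
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return KappaResult(kappa=k, ci_low=lo, ci_high=hi,
                       percent_agreement=percent_agreement(a, b),
                       n_subjects=a.size, flavor="cohen")


def _fleiss_point(table: np.ndarray) -> float:
    """Fleiss kappa from a (subjects, raters) categorical matrix."""
    n_sub, n_rat = table.shape
    cats = np.unique(table)
    counts = np.stack([(table == c).sum(axis=1) for c in cats], axis=1)
    p_j = counts.sum(axis=0) / (n_sub * n_rat)
    p_i = ((counts * (counts - 1)).sum(axis=1)) / (n_rat * (n_rat - 1))
    p_bar = p_i.mean()
    p_e = (p_j ** 2).sum()
    if p_e >= 1.0:
        warnings.warn("degenerate category proportions (P_e = 1); kappa defined as 1")
        return 1.0
    return (p_bar - p_e) / (1.0 - p_e)


def fleiss_kappa(table, n_boot: int = 2000, seed: int = 0) -> KappaResult:
    """Multi-rater chance-corrected agreement.

    ``table`` is (n_subjects, n_raters) of categorical scores, equal rater
    count per subject.  CI by seeded percentile subject-bootstrap; a single
    subject leaves the CI undefined (NaN) with a warning.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need a (subjects, >=2 raters) table")
    k = _fleiss_point(table)
    n_sub = table.shape[0]
    if n_sub < 2:
        warnings.warn("single subject: bootstrap CI undefined")
        lo = hi = float("nan")
    else:
        lo, hi = _bootstrap_ci(lambda idx: _fleiss_point(table[idx]),
                               n_sub, n_boot, seed, k)
    # percent agreement across all rater pairs
    pairs = [(i, j) for i in range(table.shape[1]) for j in range(i + 1, table.shape[1])]
    pa = _round_half_up(float(np.mean(
        [100.0 * np.mean(table[:, i] == table[:, j]) for i, j in pairs])))
    return KappaResult(kappa=k, ci_low=lo, ci_high=hi, percent_agreement=pa,
                       n_subjects=n_sub, flavor="fleiss")


def bland_altman(x, y) -> BlandAltmanResult:
    """Bias and 95% limits of agreement for paired measurements.

    Differences are y - x (reprojected minus conventional, the convention
    under which reprojected imaging biases positive); limits of agreement
    are bias +/- 1.96 * SD of the differences (SD with n-1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1D arrays")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd,
                             loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                             means=(x + y) / 2.0, diffs=d)


def pearson_regression(x, y) -> RegressionResult:
    """Pearson r with least-squares slope/intercept and a two-sided p-value
    from the t transform with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(r=float(res.rvalue), p_value=float(res.pvalue),
                            slope=float(res.slope), intercept=float(res.intercept),
                            n=x.size)


def concordance_summary(scores: ScoreTable,
                        modalities: tuple = None) -> pd.DataFrame:
    """Per-reader concordance between two modalities.

    Counts subjects scored identically (concordant), shifted by exactly one
    category (minor discordance) and shifted by more than one (major
    discordance); the three counts partition the cohort.
    """
    mods = modalities or tuple(scores.modalities)
    if len(mods) != 2:
        raise ValueError("concordance needs exactly two modalities")
    rows = []
    for reader in scores.readers:
        a = scores.scores(reader, mods[0])
        b = scores.scores(reader, mods[1])
        shift = np.abs(a - b)
        rows.append({
            "reader": reader,
            "concordant": int(np.count_nonzero(shift == 0)),
            "minor_discordant": int(np.count_nonzero(shift == 1)),
            "major_discordant": int(np.count_nonzero(shift > 1)),
            "percent_agreement": percent_agreement(a, b),
        })
    return pd.DataFrame(rows)
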