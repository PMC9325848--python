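"""Grader-agreement statistics for ordinal 0-5 severity grading.

Tools to compare human graders with each other and with an automated
count: the modal "estimated true" grade per image, per-grader deviation
tables, Cohen's and Fleiss' kappa with Landis-Koch interpretation bands,
Spearman rank correlation, and the two-way random-effects single-rater
intraclass correlation ICC(2,1).

Grading matrices arrive as long-format CSV with columns
``grader, role, experience_years, image_id, session, grade``; grades are
integers 0-5, missing cells are simply absent rows (downstream statistics
use pairwise-complete data).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

GRADES = (0, 1, 2, 3, 4, 5)

#: Landis-Koch interpretation bands (upper bound of the rounded kappa, label)
LANDIS_KOCH_BANDS = (
    (0.20, "slight"), (0.40, "fair"), (0.60, "moderate"),
    (0.80, "substantial"), (1.00, "almost perfect"),
)


@dataclass(frozen=True)
class AgreementReport:
    """One named statistic with its interpretation context."""

    statistic: str
    value: float
    n: int
    label: Optional[str] = None
    p_value: Optional[float] = None
    note: Optional[str] = None

    @property
    def significant(self) -> Optional[bool]:
        return None if self.p_value is None else bool(self.p_value < 0.05)

    def to_dict(self) -> dict:
        d = {"statistic": self.statistic, "value": self.value, "n": self.n}
        if self.label is not None:
            d["label"] = self.label
        if self.p_value is not None:
            d["p_value"] = self.p_value
            d["significant"] = self.significant
        if self.note:
            d["note"] = self.note
        return d


@dataclass
class GradingMatrix:
    """Long-format grading records with grader metadata."""

    records: pd.DataFrame  # grader, role, experience_years, image_id, session, grade

    @property
    def graders(self) -> List[str]:
        return sorted(self.records["grader"].unique())

    @property
    def images(self) -> List:
        return sorted(self.records["image_id"].unique())

    @property
    def sessions(self) -> List[str]:
        return sorted(self.records["session"].unique())

    def pivot(self, session: str | None = None) -> pd.DataFrame:
        """images x graders table of grades (NaN where missing)."""
        df = self.records
        if session is not None:
            df = df[df["session"] == session]
        return df.pivot_table(index="image_id", columns="grader",
                              values="grade", aggfunc="first")


def read_grading_matrix(path: str | os.PathLike) -> GradingMatrix:
    """Read and validate a grading CSV (see module docstring for columns)."""
    df = pd.read_csv(path)
    required = ["grader", "role", "experience_years", "image_id", "session", "grade"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df.dropna(subset=["grade"])
    bad = df[~df["grade"].isin(GRADES)]
    if not bad.empty:
        rows = [int(i) + 2 for i in bad.index[:5]]  # +2: header + 0-base
        raise ValidationError(
            f"{path}: grade outside 0-5 at CSV row(s) {rows}")
    dup = df.duplicated(subset=["grader", "image_id", "session"])
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]
        raise ValidationError(
            f"{path}: duplicate (grader, image, session) at CSV row(s) {rows}")
    df = df.astype({"grade": int})
    return GradingMatrix(df.reset_index(drop=True))


def estimated_true_grade(matrix: GradingMatrix, sessions: str = "all",
                         tie_rule: str = "lower") -> pd.Series:
    """Per-image modal grade over graders (and, by default, all sessions).

    Ties are broken per ``tie_rule``: ``lower`` (default, conservative
    severity), ``higher``, or ``mean`` (mean of tied modes, rounded half-up).
    """
    df = matrix.records
    if sessions != "all":
        df = df[df["session"] == sessions]
        if df.empty:
            raise ValidationError(f"no records for session {sessions!r}")
    out = {}
    for image_id, grp in df.groupby("image_id"):
        counts = grp["grade"].value_counts()
        tied = sorted(counts[counts == counts.max()].index)
        if tie_rule == "lower":
            out[image_id] = int(tied[0])
        elif tie_rule == "higher":
            out[image_id] = int(tied[-1])
        elif tie_rule == "mean":
            out[image_id] = int(np.floor(np.mean(tied) + 0.5))
        else:
            raise ValidationError(f"unknown tie_rule {tie_rule!r}")
    return pd.Series(out, name="estimated_true").sort_index()


def deviation_table(matrix: GradingMatrix, truth: pd.Series) -> pd.DataFrame:
    """Per grader, percentage of gradings at each |grade - truth| in 0..4.

    All sessions pooled; percentages rounded to 2 decimals.  Index is the
    grader, columns ``role, dev0..dev4``.
    """
    df = matrix.records
    missing = set(df["image_id"]) - set(truth.index)
    if missing:
        raise ValidationError(f"truth lacks images: {sorted(missing)[:5]}")
    dev = (df["grade"] - df["image_id"].map(truth)).abs()
    rows = {}
    for grader, grp in df.groupby("grader"):
        d = dev.loc[grp.index]
        n = len(d)
        pct = [round(100.0 * (d == k).sum() / n, 2) for k in range(5)]
        role = grp["role"].iloc[0]
        rows[grader] = [role] + pct
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["role", "dev0", "dev1", "dev2", "dev3", "dev4"])
    out.index.name = "grader"
    return out.sort_index()


def read_deviation_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-grader deviation-percentage CSV (grader, role, dev0..dev4)."""
    df = pd.read_csv(path)
    need = ["grader", "dev0", "dev1", "dev2", "dev3", "dev4"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df.set_index("grader")


def summarize_deviations(table: pd.DataFrame, min_dev: int = 2) -> dict:
    """Headline numbers of a deviation table.

    Returns the number of graders with any nonzero mass at deviation >=
    ``min_dev``, the largest deviation category with nonzero mass over all
    graders, and the maximum of the deviation-0 column.
    """
    dev_cols = [f"dev{k}" for k in range(5)]
    pcts = table[dev_cols].fillna(0.0).to_numpy(dtype=float)
    beyond = (pcts[:, min_dev:] > 0).any(axis=1)
    nonzero_cols = np.flatnonzero((pcts > 0).any(axis=0))
    return {
        "n_graders_at_or_above": int(beyond.sum()),
        "n_graders": int(len(table)),
        "max_deviation": int(nonzero_cols[-1]) if len(nonzero_cols) else 0,
        "max_exact_pct": float(pcts[:, 0].max()) if len(table) else 0.0,
    }


def _landis_label(value: float) -> str:
    r = np.floor(value * 100 + 0.5) / 100  # to the table's printed precision
    if r < 0:
        return "poor"
    for upper, label in LANDIS_KOCH_BANDS:
        if r <= upper:
            return label
    raise ValidationError(f"kappa {value} exceeds 1")


def landis_koch_label(kappa: float) -> str:
    """Landis-Koch verbal band for a kappa value (<=1)."""
    if kappa > 1 + 1e-9:
        raise ValidationError(f"kappa {kappa} exceeds 1")
    return _landis_label(min(kappa, 1.0))


def _pairwise_complete(r1, r2) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(r1, dtype=float)
    b = np.asarray(r2, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("rating lists must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    return a[keep], b[keep]


def cohen_kappa(r1: Sequence, r2: Sequence) -> AgreementReport:
    """Unweighted Cohen's kappa between two raters on grades 0-5.

    ``kappa = (Po - Pe) / (1 - Pe)`` with chance agreement ``Pe`` from the
    marginals.  If both raters use a single identical category, ``Pe = 1``
    and kappa is reported as 1 by convention, flagged in ``note``.
    """
    a, b = _pairwise_complete(r1, r2)
    n = len(a)
    if n < 2:
        raise ValidationError("need at least 2 pairwise-complete ratings")
    po = float(np.mean(a == b))
    pa = np.bincount(a.astype(int), minlength=6) / n
    pb = np.bincount(b.astype(int), minlength=6) / n
    pe = float(pa @ pb)
    if pe >= 1.0 - 1e-12:
        return AgreementReport("cohen_kappa", 1.0, n, label=_landis_label(1.0),
                               note="single-category degenerate; kappa=1 by convention")
    k = (po - pe) / (1.0 - pe)
    return AgreementReport("cohen_kappa", float(k), n, label=_landis_label(k))


def fleiss_kappa(grades: np.ndarray | pd.DataFrame) -> AgreementReport:
    """Fleiss' kappa for an images x graders table of grades 0-5.

    Every image must be rated by the same number of graders (subset to
    pairwise-complete data first if not).
    """
    arr = np.asarray(grades, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D images x graders array")
    if np.isnan(arr).any():
        raise ValidationError(
            "missing grades: subset to pairwise-complete images x graders first")
    n_img, n_rat = arr.shape
    if n_rat < 2 or n_img < 1:
        raise ValidationError("need >= 1 image and >= 2 graders")
    nij = np.stack([(arr == g).sum(axis=1) for g in GRADES], axis=1)
    p_i = (np.sum(nij**2, axis=1) - n_rat) / (n_rat * (n_rat - 1))
    p_bar = float(p_i.mean())
    p_j = nij.sum(axis=0) / (n_img * n_rat)
    pe = float(np.sum(p_j**2))
    if pe >= 1.0 - 1e-12:
        return AgreementReport("fleiss_kappa", 1.0, n_img, label=_landis_label(1.0),
                               note="single-category degenerate; kappa=1 by convention")
    k = (p_bar - pe) / (1.0 - pe)
    return AgreementReport("fleiss_kappa", float(k), n_img, label=_landis_label(k))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> AgreementReport:
    """Spearman's rho with midrank ties and t-approximation p-value."""
    a, b = _pairwise_complete(x, y)
    n = len(a)
    if n < 3:
        raise ValidationError("need at least 3 pairwise-complete values")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValidationError("Spearman's rho is undefined for constant input")
    rho, p = sps.spearmanr(a, b)
    return AgreementReport("spearman_rho", float(rho), n, p_value=float(p))


def icc(ratings: np.ndarray | pd.DataFrame) -> AgreementReport:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D subjects x raters array")
    if np.isnan(arr).any():
        raise ValidationError("ICC needs a complete subjects x raters table")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 raters")
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((arr - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-30:
        raise ValidationError("ICC undefined: zero total variance")
    value = float((msr - mse) / denom)
    return AgreementReport("icc_2_1", value, n)


# ---------------------------------------------------------------------------
# composite report used by the CLI

def intrarater_kappas(matrix: GradingMatrix) -> pd.DataFrame:
    """Cohen's kappa per grader for every session pair (pairwise-complete)."""
    rows = []
    for grader in matrix.graders:
        sub = matrix.records[matrix.records["grader"] == grader]
        piv = sub.pivot_table(index="image_id", columns="session",
                              values="grade", aggfunc="first")
        for s1, s2 in combinations(piv.columns, 2):
            pair = piv[[s1, s2]].dropna()
            if len(pair) < 2:
                continue
            rep = cohen_kappa(pair[s1], pair[s2])
            rows.append({"grader": grader, "session_a": s1, "session_b": s2,
                         "kappa": rep.value, "label": rep.label, "n": rep.n})
    return pd.DataFrame(rows, columns=["grader", "session_a", "session_b",
                                       "kappa", "label", "n"])


def agreement_report(matrix: GradingMatrix,
                     counts_by_image: pd.Series | None = None,
                     tie_rule: str = "lower") -> dict:
    """Full agreement work-up: truth, deviations, kappas, ICC, correlation."""
    truth = estimated_true_grade(matrix, tie_rule=tie_rule)
    table = deviation_table(matrix, truth)
    report = {
        "estimated_true": {str(k): int(v) for k, v in truth.items()},
        "deviation_table": table.reset_index().to_dict(orient="records"),
        "deviation_summary": summarize_deviations(table),
        "intrarater": intrarater_kappas(matrix).to_dict(orient="records"),
        "interrater": {},
    }
    for session in matrix.sessions:
        piv = matrix.pivot(session).dropna(axis=0, how="any")
        if piv.shape[0] >= 1 and piv.shape[1] >= 2:
            report["interrater"][session] = fleiss_kappa(piv).to_dict()
    full = matrix.pivot().dropna(axis=0, how="any")
    if full.shape[0] >= 2 and full.shape[1] >= 2:
        report["icc"] = icc(full).to_dict()
    if counts_by_image is not None:
        common = truth.index.intersection(counts_by_image.index)
        if len(common) >= 3:
            rep = spearman_rho(counts_by_image.loc[common], truth.loc[common])
            report["count_vs_truth"] = rep.to_dict()
    return report
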