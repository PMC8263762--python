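"""Van Krevelen classification and DOM-CH4 Spearman screening.

Ultrahigh-resolution mass spectrometry of dissolved organic matter (DOM)
yields molecular formulas (C, H, N, O, S counts) with per-depth relative
abundances.  Formulas are classified on the van Krevelen plane (H/C vs O/C)
using the modified aromaticity index

    AImod = (1 + C - O/2 - S - H/2) / (C - O/2 - S - N)

(aromatic-like when AImod > 0.5; aliphatic-like when H/C >= 1.5 and
AImod <= 0.5; "other" for the remainder; AImod is taken as 0 when the
denominator is non-positive).

Each formula present at every depth is screened for monotone covariation
with the CH4 depth profile by Spearman rank correlation; with few depths
(n <= 8) the two-sided p-value is computed from the exact permutation
distribution of rho, otherwise from the usual t approximation.  Raw
p-values are binned at 0.005 / 0.01 by sign of rho (no multiple-testing
correction; an FDR column can be added downstream).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FormulaRecord",
    "ClassRules",
    "CorrelationResult",
    "ScreenResult",
    "modified_aromaticity_index",
    "classify_formula",
    "exact_spearman_p",
    "spearman_screen",
    "class_fraction_summary",
    "read_formula_table",
    "write_formula_table",
]


def modified_aromaticity_index(c: int, h: int, n: int, o: int, s: int) -> float:
    """AImod; 0 when the DBE-normalising denominator is non-positive."""
    denom = c - 0.5 * o - s - n
    if denom <= 0:
        return 0.0
    return (1.0 + c - 0.5 * o - s - 0.5 * h) / denom


@dataclass
class FormulaRecord:
    """One molecular formula with element counts and per-depth abundances."""

    formula_id: str
    C: int
    H: int
    N: int
    O: int
    S: int
    abundances: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.C < 1:
            raise ValueError("a formula needs at least one carbon")
        if min(self.H, self.N, self.O, self.S) < 0:
            raise ValueError("element counts must be >= 0")
        self.abundances = np.asarray(self.abundances, dtype=float)
        if (self.abundances < 0).any():
            raise ValueError("abundances must be >= 0")

    @property
    def h_c(self) -> float:
        return self.H / self.C

    @property
    def o_c(self) -> float:
        return self.O / self.C

    @property
    def aimod(self) -> float:
        return modified_aromaticity_index(self.C, self.H, self.N, self.O, self.S)


@dataclass(frozen=True)
class ClassRules:
    """Configurable van Krevelen class thresholds."""

    aromatic_min_aimod: float = 0.5  # aromatic-like: AImod strictly above
    aliphatic_min_h_c: float = 1.5  # aliphatic-like: H/C at or above, AImod at or below


def classify_formula(record: FormulaRecord, rules: ClassRules | None = None) -> str:
    """Deterministic class label: aromatic-like, aliphatic-like, or other."""
    r = rules or ClassRules()
    if record.aimod > r.aromatic_min_aimod:
        return "aromatic-like"
    if record.h_c >= r.aliphatic_min_h_c:
        return "aliphatic-like"
    return "other"


@dataclass
class CorrelationResult:
    """Spearman rho, two-sided p, and the Fig.-3-style significance bin."""

    formula_id: str
    rho: float
    p_value: float
    bin: str  # one of {ns, pos_strong, pos_weak, neg_strong, neg_weak}
    degenerate: bool = False


def _significance_bin(rho: float, p: float) -> str:
    if not (math.isfinite(rho) and math.isfinite(p)) or rho == 0.0:
        return "ns"
    side = "pos" if rho > 0 else "neg"
    if p < 0.005:
        return f"{side}_strong"
    if p < 0.01:
        return f"{side}_weak"
    return "ns"


def exact_spearman_p(x, y) -> tuple[float, float]:
    """Spearman rho and exact two-sided permutation p-value (n <= 8).

    Enumerates all n! pairings of the rank vectors (average ranks for ties)
    and returns the fraction with |rho| at least as large as observed.
    Degenerate inputs (a constant vector) return (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n > 8:
        raise ValueError("exact enumeration supported for n <= 8 only")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return math.nan, math.nan
    rho = _pearson(rx, ry)
    null = _null_abs_rhos(tuple(rx), tuple(sorted(ry)))
    p = float(np.mean(null >= abs(rho) - 1e-12))
    return float(rho), p


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / math.sqrt((a @ a) * (b @ b)))


_NULL_CACHE: dict[tuple, np.ndarray] = {}


def _null_abs_rhos(rx_key: tuple, ry_sorted: tuple) -> np.ndarray:
    """|rho| over all pairings of rank vector rx with permutations of ry."""
    key = (rx_key, ry_sorted)
    cached = _NULL_CACHE.get(key)
    if cached is not None:
        return cached
    rx = np.asarray(rx_key, dtype=float)
    perms = np.array(list(itertools.permutations(ry_sorted)), dtype=float)
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    numer = pc @ rxc
    denom = math.sqrt(float(rxc @ rxc)) * np.sqrt((pc * pc).sum(axis=1))
    null = np.abs(numer / denom)
    _NULL_CACHE[key] = null
    return null


@dataclass
class ScreenResult:
    """Screen output table plus the count of formulas excluded by the
    present-at-all-depths filter."""

    table: pd.DataFrame
    n_excluded: int


def spearman_screen(
    formulas: list[FormulaRecord],
    covariate,
    rules: ClassRules | None = None,
    p_method: str = "auto",
) -> ScreenResult:
    """Screen formula abundances against a per-depth covariate (e.g. CH4).

    Only formulas with strictly positive abundance at every depth enter the
    correlation (the all-depths-present rule); the number excluded is
    reported.  ``p_method`` is "auto" (exact permutation for n <= 8, else
    t approximation), "exact", or "approx".
    """
    cov = np.asarray(covariate, dtype=float)
    n = len(cov)
    if n < 4:
        raise ValueError("need >= 4 depths for the Spearman screen")
    if p_method not in ("auto", "exact", "approx"):
        raise ValueError("p_method must be auto, exact or approx")
    use_exact = p_method == "exact" or (p_method == "auto" and n <= 8)

    rows = []
    n_excluded = 0
    for rec in formulas:
        if len(rec.abundances) != n:
            raise ValueError(
                f"{rec.formula_id}: {len(rec.abundances)} abundances for {n} depths"
            )
        if not (rec.abundances > 0).all():
            n_excluded += 1
            continue
        if use_exact:
            rho, p = exact_spearman_p(rec.abundances, cov)
        else:
            res = stats.spearmanr(rec.abundances, cov)
            rho, p = float(res.statistic), float(res.pvalue)
            if math.isnan(rho):
                rho, p = math.nan, math.nan
        degenerate = math.isnan(rho)
        rows.append(
            {
                "formula_id": rec.formula_id,
                "C": rec.C, "H": rec.H, "N": rec.N, "O": rec.O, "S": rec.S,
                "H_C": rec.h_c,
                "O_C": rec.o_c,
                "AImod": rec.aimod,
                "class": classify_formula(rec, rules),
                "rho": rho,
                "p": p,
                "bin": _significance_bin(rho, p),
                "degenerate": degenerate,
            }
        )
    return ScreenResult(table=pd.DataFrame(rows), n_excluded=n_excluded)


def class_fraction_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class percentages of significantly correlated formulas.

    "Significant" means raw p < 0.01 with the stated sign of rho; the
    denominator is the class size.  Empty classes report NaN percentages
    (undefined, not zero).
    """
    if len(table) == 0:
        raise ValueError("empty screen table")
    out = []
    for cls in ("aliphatic-like", "aromatic-like", "other"):
        sub = table[table["class"] == cls]
        n = len(sub)
        n_pos = int(((sub["p"] < 0.01) & (sub["rho"] > 0)).sum()) if n else 0
        n_neg = int(((sub["p"] < 0.01) & (sub["rho"] < 0)).sum()) if n else 0
        out.append(
            {
                "class": cls,
                "n": n,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "pct_pos": 100.0 * n_pos / n if n else math.nan,
                "pct_neg": 100.0 * n_neg / n if n else math.nan,
            }
        )
    return pd.DataFrame(out).set_index("class")


def read_formula_table(path) -> tuple[list[FormulaRecord], list[str]]:
    """Read the formula CSV dialect.

    Columns: ``formula_id, C, H, N, O, S`` plus one abundance column per
    depth named ``ab_<depth>`` (e.g. ``ab_0, ab_0.5, ...``).  Returns the
    records and the ordered list of abundance column names.
    """
    table = pd.read_csv(path)
    ab_cols = [c for c in table.columns if c.startswith("ab_")]
    if not ab_cols:
        raise ValueError("formula table has no ab_<depth> abundance columns")
    records = [
        FormulaRecord(
            formula_id=str(row["formula_id"]),
            C=int(row["C"]), H=int(row["H"]), N=int(row["N"]),
            O=int(row["O"]), S=int(row["S"]),
            abundances=row[ab_cols].to_numpy(dtype=float),
        )
        for _, row in table.iterrows()
    ]
    return records, ab_cols


def write_formula_table(records: list[FormulaRecord], depths, path) -> None:
    """Write records in the dialect accepted by :func:`read_formula_table`."""
    ab_cols = [f"ab_{d:g}" for d in depths]
    rows = []
    for rec in records:
        row = {"formula_id": rec.formula_id, "C": rec.C, "H": rec.H,
               "N": rec.N, "O": rec.O, "S": rec.S}
        row.update(dict(zip(ab_cols, rec.abundances)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
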