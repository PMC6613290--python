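"""Exploratory term screening: chi-square association, MCC direction,
bootstrap stability ranking, Holm-Bonferroni familywise control.

The 1000 most document-frequent terms (unigrams and adjacent-token bigrams)
become binary presence variables per admission document. Each term's
association with the violent outcome is tested with a 1-df Pearson chi-square
on the 2x2 table (no continuity correction, so the identity chi2 = n * MCC^2
holds exactly); the Matthews correlation coefficient carries the direction of
association. Within-dataset generalizability is the fraction of bootstrap
resamples of admissions in which a term's chi-square ranks in the top decile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist


@dataclass
class TermMatrix:
    """Binary admission-by-term presence matrix with the outcome vector."""

    terms: list[str]
    matrix: np.ndarray           # (n_admissions, n_terms), entries in {0, 1}
    outcome: np.ndarray          # (n_admissions,)
    admission_ids: list[str]


def extract_terms(
    documents: list[list[str]],
    outcome,
    k: int = 1000,
    admission_ids: list[str] | None = None,
    include_bigrams: bool = True,
    use_document_frequency: bool = True,
) -> TermMatrix:
    """Build the binary presence matrix of the k most frequent terms.

    Candidates are unigrams plus adjacent-token bigrams (joined with a
    space); ranking is by document frequency (or raw token count when
    ``use_document_frequency`` is False), ties broken lexicographically.
    If fewer than k candidates exist, all are returned with a warning.
    """
    doc_sets: list[set[str]] = []
    freq: dict[str, int] = {}
    for doc in documents:
        cand = list(doc)
        if include_bigrams:
            cand.extend(f"{a} {b}" for a, b in zip(doc, doc[1:]))
        if use_document_frequency:
            seen = set(cand)
            for t in seen:
                freq[t] = freq.get(t, 0) + 1
            doc_sets.append(seen)
        else:
            for t in cand:
                freq[t] = freq.get(t, 0) + 1
            doc_sets.append(set(cand))
    if len(freq) < k:
        warnings.warn(
            f"only {len(freq)} candidate terms (< k={k}); returning all", stacklevel=2
        )
    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    terms = [t for t, _ in ranked]
    term_idx = {t: i for i, t in enumerate(terms)}
    X = np.zeros((len(documents), len(terms)), dtype=np.int8)
    for i, seen in enumerate(doc_sets):
        for t in seen:
            j = term_idx.get(t)
            if j is not None:
                X[i, j] = 1
    if admission_ids is None:
        admission_ids = [str(i) for i in range(len(documents))]
    return TermMatrix(
        terms=terms,
        matrix=X,
        outcome=np.asarray(outcome, dtype=int),
        admission_ids=list(admission_ids),
    )


def _table(term_column, outcome):
    """2x2 table (a, b, c, d) = (present&pos, absent&pos, present&neg, absent&neg)."""
    t = np.asarray(term_column, dtype=int)
    y = np.asarray(outcome, dtype=int)
    a = int(np.sum((t == 1) & (y == 1)))
    b = int(np.sum((t == 0) & (y == 1)))
    c = int(np.sum((t == 1) & (y == 0)))
    d = int(np.sum((t == 0) & (y == 0)))
    return a, b, c, d


def _chi2_from_table(a, b, c, d, correction: bool):
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0, True
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff**2 / denom
    return float(stat), float(chi2_dist.sf(stat, df=1)), False


def chi2_association(term_column, outcome, correction: bool = False):
    """Pearson chi-square (1 df) of a binary term against the outcome.

    No continuity correction by default (keeps chi2 = n * MCC^2 exact).
    A zero marginal (term always or never present, or single-class outcome)
    yields statistic 0, p 1.
    """
    a, b, c, d = _table(term_column, outcome)
    stat, p, _ = _chi2_from_table(a, b, c, d, correction)
    return stat, p


def mcc(term_column, outcome, ci: bool = False, n_boot: int = 2000, seed: int = 0):
    """Matthews correlation coefficient of term presence and outcome.

    Returns the coefficient, or (coefficient, (lo, hi)) with a percentile
    bootstrap CI over admissions when ``ci`` is True. Zero marginals give 0.
    """
    t = np.asarray(term_column, dtype=int)
    y = np.asarray(outcome, dtype=int)
    point = _mcc_value(*_table(t, y))
    if not ci:
        return point
    rng = np.random.default_rng(seed)
    n = len(t)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        reps[i] = _mcc_value(*_table(t[idx], y[idx]))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, (float(lo), float(hi))


def _mcc_value(a, b, c, d):
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return float((a * d - b * c) / np.sqrt(denom))


def _chi2_columns(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
    """Vectorized per-column chi-square statistics of binary matrix X vs y.

    ``weights`` are per-admission multiplicities (bootstrap resample counts);
    None means the full sample with unit weights.
    """
    Xf = X.astype(float)
    if weights is None:
        w = np.ones(len(y))
    else:
        w = weights.astype(float)
    n = w.sum()
    n_pos = float(w @ (y == 1))
    col = w @ Xf                       # weighted term-present counts
    a = (w * (y == 1)) @ Xf            # present & positive
    b = n_pos - a
    c = col - a
    d = n - n_pos - c
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    stat = np.zeros(X.shape[1])
    ok = denom > 0
    stat[ok] = n * (a[ok] * d[ok] - b[ok] * c[ok]) ** 2 / denom[ok]
    return stat


def stability_selection(
    tm: TermMatrix,
    B: int = 1000,
    top_fraction: float = 0.10,
    seed: int = 0,
    resample: bool = True,
) -> np.ndarray:
    """Bootstrap stability ratio per term.

    In each of B resamples of admissions with replacement, all chi-square
    scores are recomputed and the top ceil(top_fraction * k) terms marked
    (chi-square ties broken lexicographically); the ratio is the fraction of
    resamples in which a term is marked. Resamples with a single outcome
    class are redrawn (logged as a warning). With ``resample=False`` the full
    sample is used in every replicate, so B=1 reduces to a deterministic
    top-decile indicator.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X, y = tm.matrix, tm.outcome
    k = len(tm.terms)
    if k < 10:
        raise ValueError("stability selection needs at least 10 terms")
    top = int(np.ceil(top_fraction * k))
    lex = np.argsort(np.argsort(tm.terms, kind="mergesort"), kind="mergesort")
    rng = np.random.default_rng(seed)
    n = len(y)
    inclusions = np.zeros(k)
    for _ in range(B):
        if resample:
            while True:
                counts = np.bincount(rng.integers(0, n, n), minlength=n)
                if len(np.unique(y[counts > 0])) == 2:
                    break
                warnings.warn(
                    "bootstrap resample had one outcome class; redrawn", stacklevel=2
                )
        else:
            counts = np.ones(n, dtype=int)
        stat = _chi2_columns(X, y, counts)
        order = np.lexsort((lex, -stat))
        inclusions[order[:top]] += 1
    return inclusions / B


def holm_bonferroni(p_values, alpha: float = 0.01):
    """Holm step-down procedure.

    Returns (reject flags, adjusted p-values). Sorted ascending, p(i) is
    compared against alpha / (m - i); rejection stops at the first failure.
    Adjusted p-values are the running maximum of (m - i) * p(i), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    factors = m - np.arange(m)
    adj_sorted = np.maximum.accumulate(p[order] * factors)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if p[order[i]] <= alpha / (m - i):
            reject_sorted[i] = True
        else:
            break
    reject = np.zeros(m, dtype=bool)
    adjusted = np.empty(m)
    reject[order] = reject_sorted
    adjusted[order] = adj_sorted
    return reject, adjusted


def term_report(
    tm: TermMatrix,
    B: int = 1000,
    alpha: float = 0.01,
    top_n: int = 20,
    mcc_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Ranked exploratory-analysis table: stability ratio, MCC (CI), raw and
    Holm-adjusted p-value per term, ordered by stability then chi-square."""
    X, y = tm.matrix, tm.outcome
    stats = _chi2_columns(X, y)
    p_raw = chi2_dist.sf(stats, df=1)  # zero-marginal columns have stat 0 -> p 1
    reject, p_adj = holm_bonferroni(p_raw, alpha=alpha)
    ratios = stability_selection(tm, B=B, seed=seed)
    order = np.lexsort((np.array(tm.terms), -stats, -ratios))[:top_n]
    rows = []
    for rank, j in enumerate(order, start=1):
        point, (lo, hi) = mcc(X[:, j], y, ci=True, n_boot=mcc_boot, seed=seed + j)
        rows.append(
            {
                "rank": rank,
                "term": tm.terms[j],
                "stability_ratio": ratios[j],
                "mcc": point,
                "mcc_ci_low": lo,
                "mcc_ci_high": hi,
                "chi2": stats[j],
                "p_raw": p_raw[j],
                "p_adjusted": p_adj[j],
                "significant": bool(reject[j]),
            }
        )
    return pd.DataFrame(rows)
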