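"""Residue coevolution statistics on a domain MSA.

Four classical covariation measures are computed for every retained column
pair: mutual information (MI, in bits), MI with the average-product
correction removed (MIp), the observed-minus-expected-squared statistic
(OMES), and statistical coupling analysis (SCA, conservation-weighted
covariance norm).  Per-method scores are combined by min-max rescaling to
[0, 1], quantile normalization across methods, and averaging.  Candidate
pairs are the top decile of each method (ties at the threshold included);
coevolving residue pairs (CRPs) are candidates shared by at least two
methods.

Gap handling is pairwise-complete: for each column pair, only sequences
ungapped at both columns contribute, so each pair has its own effective N.
No redundancy-based sequence weighting is applied.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .msa import AlignedFamily

N_AA = 20
METHODS = ("MI", "MIp", "OMES", "SCA")
SCA_LAMBDA = 0.03
DEFAULT_MAX_GAP_FRAC = 0.25
DEFAULT_TOP_FRACTION = 0.10
DEFAULT_MIN_METHODS = 2

Pair = tuple[int, int]


def filter_columns(
    msa: AlignedFamily, max_gap_frac: float = DEFAULT_MAX_GAP_FRAC
) -> np.ndarray:
    """Boolean mask of columns retained for pair scoring.

    Columns with gap fraction above ``max_gap_frac`` or zero residue
    diversity (invariant or all-gap) are dropped: MI with an invariant
    column is identically zero and only dilutes the pair ranking.
    """
    gap_ok = msa.gap_fraction() <= max_gap_frac
    diverse = ~msa.invariant_mask()
    mask = gap_ok & diverse
    if not mask.any():
        raise ValueError("all columns filtered out")
    return mask


def _pair_counts(enc_i: np.ndarray, enc_j: np.ndarray) -> np.ndarray | None:
    """Joint 20x20 counts over sequences ungapped at both columns."""
    keep = (enc_i >= 0) & (enc_j >= 0)
    if keep.sum() < 2:
        return None
    joint = np.zeros((N_AA, N_AA))
    np.add.at(joint, (enc_i[keep], enc_j[keep]), 1.0)
    return joint


def _mi_from_counts(joint: np.ndarray) -> float:
    n = joint.sum()
    pij = joint / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    expected = np.outer(pi, pj)
    nz = pij > 0
    return float((pij[nz] * np.log2(pij[nz] / expected[nz])).sum())


def _omes_from_counts(joint: np.ndarray) -> float:
    n = joint.sum()
    exp = np.outer(joint.sum(axis=1), joint.sum(axis=0)) / n
    return float(((joint - exp) ** 2).sum() / n)


def _sca_weights(freq: np.ndarray, lam: float = SCA_LAMBDA) -> np.ndarray:
    """Conservation weights phi_i^a from regularized frequencies."""
    q = 1.0 / N_AA
    f = (1.0 - lam) * freq + lam * q
    with np.errstate(divide="ignore"):
        phi = np.abs(np.log(f * (1.0 - q) / ((1.0 - f) * q)))
    return phi


def _sca_from_counts(joint: np.ndarray, lam: float = SCA_LAMBDA) -> float:
    n = joint.sum()
    fij = joint / n
    fi = fij.sum(axis=1)
    fj = fij.sum(axis=0)
    cov = fij - np.outer(fi, fj)
    weighted = np.outer(_sca_weights(fi, lam), _sca_weights(fj, lam)) * cov
    return float(np.sqrt((weighted**2).sum()))


@dataclass
class CoevolutionResult:
    methods: dict[str, np.ndarray]
    combined: np.ndarray
    candidates: dict[str, set[Pair]]
    crps: set[Pair]
    column_mask: np.ndarray
    top_fraction: float = DEFAULT_TOP_FRACTION
    min_methods: int = DEFAULT_MIN_METHODS
    combined_candidates: set[Pair] = field(default_factory=set)

    def pair_table(self, msa: AlignedFamily | None = None) -> pd.DataFrame:
        cols = np.flatnonzero(self.column_mask)
        rows = []
        seed_map = msa.seed_column_map() if msa is not None else {}
        for i, j in itertools.combinations(cols, 2):
            row = {"col_i": i, "col_j": j}
            if msa is not None:
                row["seed_i"] = seed_map.get(i)
                row["seed_j"] = seed_map.get(j)
            for m, mat in self.methods.items():
                row[m] = mat[i, j]
            row["combined"] = self.combined[i, j]
            row["is_crp"] = (i, j) in self.crps
            rows.append(row)
        return pd.DataFrame(rows)


def compute_coevolution(
    msa: AlignedFamily,
    method: str,
    column_mask: np.ndarray | None = None,
    sca_lambda: float = SCA_LAMBDA,
) -> np.ndarray:
    """Symmetric column-pair score matrix for one method.

    The diagonal and unscored pairs are NaN.  MIp is derived from the full MI
    matrix via the average-product correction
    APC(i, j) = MI(i,.) * MI(j,.) / <MI> with off-diagonal row means and the
    grand mean over off-diagonal pairs.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "MIp":
        mi = compute_coevolution(msa, "MI", column_mask)
        return _apc_correct(mi)

    if column_mask is None:
        column_mask = filter_columns(msa)
    cols = np.flatnonzero(column_mask)
    if len(cols) < 2:
        raise ValueError("need at least two retained columns")
    if msa.n_seq < 4:
        raise ValueError("need at least four sequences")

    enc = msa.encoded()
    score = {
        "MI": _mi_from_counts,
        "OMES": _omes_from_counts,
        "SCA": lambda j: _sca_from_counts(j, sca_lambda),
    }[method]
    out = np.full((msa.n_col, msa.n_col), np.nan)
    for i, j in itertools.combinations(cols, 2):
        joint = _pair_counts(enc[:, i], enc[:, j])
        if joint is None:
            continue
        out[i, j] = out[j, i] = score(joint)
    return out


def _apc_correct(mi: np.ndarray) -> np.ndarray:
    defined = np.isfinite(mi)
    with np.errstate(invalid="ignore"):
        row_sum = np.where(defined, mi, 0.0).sum(axis=1)
        row_n = defined.sum(axis=1)
        row_mean = np.where(row_n > 0, row_sum / np.maximum(row_n, 1), np.nan)
    iu = np.triu_indices_from(mi, k=1)
    off = mi[iu]
    grand = np.nanmean(off)
    if not np.isfinite(grand) or grand == 0:
        return mi.copy()
    apc = np.outer(row_mean, row_mean) / grand
    out = np.where(defined, mi - apc, np.nan)
    np.fill_diagonal(out, np.nan)
    return out


def candidate_pairs(
    matrix: np.ndarray, top_fraction: float = DEFAULT_TOP_FRACTION
) -> set[Pair]:
    """Top-decile pairs of a score matrix (nearest-rank, ties included)."""
    iu = np.triu_indices_from(matrix, k=1)
    scores = matrix[iu]
    defined = np.isfinite(scores)
    pairs = [(int(i), int(j)) for i, j in zip(*iu)]
    scored = [(p, s) for p, s, d in zip(pairs, scores, defined) if d]
    m = len(scored)
    if m < 10:
        raise ValueError(f"only {m} scored pairs; need at least 10")
    k = max(1, int(np.floor(top_fraction * m)))
    values = np.array([s for _, s in scored])
    threshold = np.sort(values)[::-1][k - 1]
    selected = {p for p, s in scored if s >= threshold}
    if len(selected) == m and values.min() == values.max():
        warnings.warn("all pair scores tied; every pair is a candidate")
    return selected


def define_crps(
    candidates: dict[str, set[Pair]], min_methods: int = DEFAULT_MIN_METHODS
) -> set[Pair]:
    """Pairs present in the candidate sets of >= min_methods methods."""
    if len(candidates) < 2:
        raise ValueError("need candidate sets from at least two methods")
    tally: dict[Pair, int] = {}
    for pairs in candidates.values():
        for p in pairs:
            tally[p] = tally.get(p, 0) + 1
    crps = {p for p, c in tally.items() if c >= min_methods}
    if not crps:
        warnings.warn("no pair shared by the required number of methods")
    return crps


def method_agreement(candidates: dict[str, set[Pair]]) -> pd.DataFrame:
    """Jaccard similarity |A n B| / |A u B| between method candidate sets."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidate sets")
    names = list(candidates)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        union = candidates[a] | candidates[b]
        j = len(candidates[a] & candidates[b]) / len(union) if union else np.nan
        out.loc[a, b] = out.loc[b, a] = j
    return out


def min_max_rescale(x: np.ndarray) -> np.ndarray:
    """(x_i - x_min) / (x_max - x_min); constant vectors map to zeros."""
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def quantile_normalize(columns: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of a (m, k) array.

    The reference distribution is the mean of the sorted columns; tied
    observations receive the average of their tied ranks' reference values.
    """
    m, _ = columns.shape
    reference = np.sort(columns, axis=0).mean(axis=1)
    out = np.empty_like(columns, dtype=float)
    grid = np.arange(1, m + 1)
    for k in range(columns.shape[1]):
        ranks = rankdata(columns[:, k], method="average")
        out[:, k] = np.interp(ranks, grid, reference)
    return out


def combine_scores(methods: dict[str, np.ndarray]) -> np.ndarray:
    """Min-max rescale each method, quantile-normalize, and average."""
    names = list(methods)
    template = methods[names[0]]
    iu = np.triu_indices_from(template, k=1)
    defined = np.ones(len(iu[0]), dtype=bool)
    for m in names:
        defined &= np.isfinite(methods[m][iu])
    stacked = np.column_stack(
        [min_max_rescale(methods[m][iu][defined]) for m in names]
    )
    averaged = quantile_normalize(stacked).mean(axis=1)
    combined = np.full_like(template, np.nan)
    ii = iu[0][defined]
    jj = iu[1][defined]
    combined[ii, jj] = averaged
    combined[jj, ii] = averaged
    return combined


def run_coevolution(
    msa: AlignedFamily,
    max_gap_frac: float = DEFAULT_MAX_GAP_FRAC,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    min_methods: int = DEFAULT_MIN_METHODS,
) -> CoevolutionResult:
    """Full coevolution analysis: four methods, combination, CRP calling."""
    mask = filter_columns(msa, max_gap_frac)
    matrices = {m: compute_coevolution(msa, m, column_mask=mask) for m in METHODS}
    combined = combine_scores(matrices)
    candidates = {
        m: candidate_pairs(matrices[m], top_fraction) for m in METHODS
    }
    crps = define_crps(candidates, min_methods)
    combined_candidates = candidate_pairs(combined, top_fraction)
    return CoevolutionResult(
        methods=matrices,
        combined=combined,
        candidates=candidates,
        crps=crps,
        column_mask=mask,
        top_fraction=top_fraction,
        min_methods=min_methods,
        combined_candidates=combined_candidates,
    )
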