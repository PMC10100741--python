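"""Subclass-determining-site (TSDS) detection.

Alignment columns are scored for subclass specificity by combining, with
equal weights, three per-column statistics computed across motif-defined TF
subclasses:

* relative entropy (RE): mean over subclasses of the Kullback-Leibler
  divergence (base 2) of the subclass residue distribution from the
  whole-family distribution;
* physicochemical divergence (ED): mean pairwise Euclidean distance between
  subclass mean property vectors (five Atchley factors per amino acid);
* evolutionary-rate heterogeneity (ER): ratio of the expected between-subclass
  to within-subclass residue substitution distance, where substitution
  distance is 1 minus min-max-normalized BLOSUM62 similarity.

The three scores are z-scored over columns and averaged; significance comes
from permuting TF -> subclass labels, and columns with permutation P < 0.1
(invariant columns excluded up front) are called TSDSs.

Expectations for ER use the plug-in form c^T D c / n^2 (ordered residue
pairs, self-pairs included) so that subclasses with identical residue
compositions give ER exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from statsmodels.stats.multitest import multipletests

from .msa import AA_ALPHABET, AlignedFamily
from .subclassing import SubclassPartition

N_AA = len(AA_ALPHABET)
DEFAULT_PSEUDOCOUNT = 0.5
TSDS_ALPHA = 0.1
_ER_EPS = 1e-9

# Atchley et al. five-factor solution of amino-acid physicochemical variation:
# I polarity/accessibility, II secondary-structure propensity, III size/bulk,
# IV codon composition/refractivity, V charge.
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

_ATCHLEY = np.array([ATCHLEY_FACTORS[a] for a in AA_ALPHABET])


def _blosum62_distance() -> np.ndarray:
    """20x20 substitution distance: 1 - min-max normalized BLOSUM62."""
    blosum = substitution_matrices.load("BLOSUM62")
    s = np.array(
        [[blosum[a, b] for b in AA_ALPHABET] for a in AA_ALPHABET], dtype=float
    )
    return 1.0 - (s - s.min()) / (s.max() - s.min())


_BLOSUM_DIST = _blosum62_distance()


def exclude_invariant_columns(msa: AlignedFamily) -> np.ndarray:
    """Mask of columns excluded from TSDS scoring (True = excluded).

    Columns whose non-gap residues are 100% identical carry no subclass
    signal; all-gap columns are degenerate and masked too.
    """
    return msa.invariant_mask()


def _one_hot(msa: AlignedFamily) -> np.ndarray:
    """(n_seq, n_col, 20) indicator array; gap rows are all-zero."""
    enc = msa.encoded()
    one_hot = np.zeros((msa.n_seq, msa.n_col, N_AA))
    rows, cols = np.nonzero(enc >= 0)
    one_hot[rows, cols, enc[rows, cols]] = 1.0
    return one_hot


def _scores_from_counts(
    counts: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RE, ED, ER per column from per-subclass residue counts (S, L, 20)."""
    S, L, _ = counts.shape
    n_s = counts.sum(axis=2)  # (S, L)
    present = n_s > 0
    n_tot = n_s.sum(axis=0)  # (L,)
    tot_counts = counts.sum(axis=0)  # (L, 20)

    lam = pseudocount
    f_fam = (tot_counts + lam) / (n_tot[:, None] + lam * N_AA)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_sub = (counts + lam) / (n_s[..., None] + lam * N_AA)
    # f_fam > 0 wherever f_sub > 0, so the ratio is safe where it is used
    ratio = np.ones_like(f_sub)
    np.divide(
        f_sub, np.broadcast_to(f_fam[None], f_sub.shape),
        out=ratio, where=f_sub > 0,
    )
    kl_terms = np.where(f_sub > 0, f_sub * np.log2(ratio), 0.0)
    kl = kl_terms.sum(axis=2)  # (S, L)
    n_present = present.sum(axis=0)
    re_score = np.where(
        n_present > 0, (kl * present).sum(axis=0) / np.maximum(n_present, 1), 0.0
    )

    # ED: mean pairwise distance between subclass mean Atchley vectors
    with np.errstate(invalid="ignore"):
        freqs = counts / n_s[..., None]  # (S, L, 20); nan where absent
    means = np.einsum("slk,kf->slf", np.nan_to_num(freqs), _ATCHLEY)
    ed_score = np.zeros(L)
    er_between = np.zeros(L)
    n_pairs = np.zeros(L)
    for g in range(S):
        for h in range(g + 1, S):
            both = present[g] & present[h]
            d = np.linalg.norm(means[g] - means[h], axis=1)
            ed_score += np.where(both, d, 0.0)
            cross = np.einsum(
                "la,ab,lb->l", freqs_or_zero(freqs, g), _BLOSUM_DIST,
                freqs_or_zero(freqs, h),
            )
            er_between += np.where(both, cross, 0.0)
            n_pairs += both
    with np.errstate(invalid="ignore"):
        ed_score = np.where(n_pairs > 0, ed_score / np.maximum(n_pairs, 1), 0.0)
        er_between = np.where(n_pairs > 0, er_between / np.maximum(n_pairs, 1), 0.0)

    within = np.zeros(L)
    for g in range(S):
        f = freqs_or_zero(freqs, g)
        w = np.einsum("la,ab,lb->l", f, _BLOSUM_DIST, f)
        within += np.where(present[g], w, 0.0)
    within = within / np.maximum(present.sum(axis=0), 1)
    er_score = (er_between + _ER_EPS) / (within + _ER_EPS)
    return re_score, ed_score, er_score


def freqs_or_zero(freqs: np.ndarray, g: int) -> np.ndarray:
    return np.nan_to_num(freqs[g])


def _combined_z(
    re_score: np.ndarray, ed_score: np.ndarray, er_score: np.ndarray,
    scored: np.ndarray,
) -> np.ndarray:
    """Equal-weight mean of column-wise z-scores over the scored columns."""
    z = np.zeros_like(re_score)
    for s in (re_score, ed_score, er_score):
        vals = s[scored]
        sd = vals.std()
        if sd > 0:
            zs = (s - vals.mean()) / sd
        else:
            zs = np.zeros_like(s)
        z = z + zs
    z /= 3.0
    z[~scored] = np.nan
    return z


def speer_like_scores(
    msa: AlignedFamily,
    partition: SubclassPartition,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Score every alignment column for subclass specificity.

    Returns a per-column table with re_score, ed_score, er_score, combined_z
    and the invariant-column exclusion flag.  Only retained subclasses
    (>= minimum size) enter the statistics.
    """
    subclass_of = partition.retained_subclass_of()
    if not subclass_of:
        raise ValueError("no retained subclasses to score against")
    labels = sorted(set(subclass_of.values()))
    if len(labels) < 2:
        raise ValueError("TSDS scoring needs at least two retained subclasses")

    label_vec, row_idx = _label_arrays(msa, subclass_of, labels)
    one_hot = _one_hot(msa)[row_idx]
    counts = _counts_for_labels(one_hot, label_vec, len(labels))

    excluded = exclude_invariant_columns(msa)
    scored = ~excluded
    re_score, ed_score, er_score = _scores_from_counts(counts, pseudocount)
    combined = _combined_z(re_score, ed_score, er_score, scored)

    seed_map = msa.seed_column_map()
    return pd.DataFrame(
        {
            "column": np.arange(msa.n_col),
            "seed_position": [seed_map.get(c) for c in range(msa.n_col)],
            "re_score": re_score,
            "ed_score": ed_score,
            "er_score": er_score,
            "combined_z": combined,
            "excluded_invariant": excluded,
        }
    )


def _label_arrays(
    msa: AlignedFamily, subclass_of: dict[str, int], labels: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    index = {lab: i for i, lab in enumerate(labels)}
    tf_ids = [t for t in msa.ids if t in subclass_of]
    row_idx = np.array([msa.ids.index(t) for t in tf_ids])
    label_vec = np.array([index[subclass_of[t]] for t in tf_ids])
    return label_vec, row_idx


def _counts_for_labels(
    one_hot: np.ndarray, label_vec: np.ndarray, n_labels: int
) -> np.ndarray:
    G = np.zeros((len(label_vec), n_labels))
    G[np.arange(len(label_vec)), label_vec] = 1.0
    return np.einsum("ns,nlk->slk", G, one_hot)


def tsds_permutation_test(
    msa: AlignedFamily,
    partition: SubclassPartition,
    scores: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = TSDS_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Permutation p-values for subclass specificity, and the TSDS call.

    TF -> subclass labels are permuted; for column c,
    p(c) = (1 + #{permuted combined_z >= observed}) / (n_perm + 1).
    Columns with p < alpha (default 0.1) and not invariant are TSDSs.
    BH-adjusted p-values are reported alongside (the call uses raw p).
    """
    if n_perm < 99:
        raise ValueError(f"n_perm={n_perm} below the minimum of 99")
    if scores is None:
        scores = speer_like_scores(msa, partition, pseudocount)
    subclass_of = partition.retained_subclass_of()
    labels = sorted(set(subclass_of.values()))
    label_vec, row_idx = _label_arrays(msa, subclass_of, labels)
    one_hot = _one_hot(msa)[row_idx]

    excluded = scores["excluded_invariant"].to_numpy()
    scored = ~excluded
    observed = scores["combined_z"].to_numpy()

    rng = np.random.default_rng(seed)
    exceed = np.zeros(msa.n_col)
    for _ in range(n_perm):
        perm = rng.permutation(label_vec)
        counts = _counts_for_labels(one_hot, perm, len(labels))
        re_s, ed_s, er_s = _scores_from_counts(counts, pseudocount)
        z = _combined_z(re_s, ed_s, er_s, scored)
        exceed[scored] += z[scored] >= observed[scored]

    p = np.full(msa.n_col, np.nan)
    p[scored] = (1.0 + exceed[scored]) / (n_perm + 1.0)

    out = scores.copy()
    out["p_value"] = p
    adj = np.full(msa.n_col, np.nan)
    if scored.any():
        adj[scored] = multipletests(p[scored], method="fdr_bh")[1]
    out["p_adjusted"] = adj
    out["is_tsds"] = scored & (np.nan_to_num(p, nan=1.0) < alpha)
    return out
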