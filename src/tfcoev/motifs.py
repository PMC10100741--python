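"""Position weight matrices: containers, I/O, similarity, and merging.

DNA binding preferences are represented as 4 x w column-stochastic matrices
over A, C, G, T.  Motif similarity is the maximum Pearson correlation of the
flattened overlapping sub-matrices over all ungapped offsets (and, optionally,
the reverse-complement orientation), the convention used by STAMP-style motif
comparison tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G


class MotifError(ValueError):
    pass


@dataclass
class PositionWeightMatrix:
    tf_id: str
    matrix: np.ndarray  # shape (4, w), columns sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise MotifError(f"{self.tf_id}: PWM must be 4 x w")
        if self.matrix.shape[1] < 1:
            raise MotifError(f"{self.tf_id}: empty PWM")
        if (self.matrix < -1e-12).any():
            raise MotifError(f"{self.tf_id}: negative PWM entries")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise MotifError(f"{self.tf_id}: PWM columns must sum to 1")
        self.matrix = self.matrix / sums  # exact renormalization

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(self.tf_id, self.matrix[_COMPLEMENT][:, ::-1])

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (2 - entropy)."""
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=0)
        return 2.0 - h

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


PwmSet = list[PositionWeightMatrix]


# ---------------------------------------------------------------------------
# I/O: JASPAR-style PFM and MEME minimal motif format
# ---------------------------------------------------------------------------

def write_jaspar(pwms: PwmSet, path, counts_scale: int = 100) -> None:
    """Write JASPAR-style PFM text (counts obtained by scaling probabilities)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_id}\n")
            counts = pwm.matrix * counts_scale
            for b, base in enumerate(BASES):
                row = " ".join(f"{v:.2f}" for v in counts[b])
                fh.write(f"{base} [ {row} ]\n")


def read_jaspar(path) -> PwmSet:
    pwms: PwmSet = []
    name = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(_pfm_to_pwm(name, rows))
                name = line[1:].split()[0]
                rows = {}
            else:
                base = line[0].upper()
                body = line[1:].strip().strip("[]").strip()
                rows[base] = [float(x) for x in body.split()]
    if name is not None:
        pwms.append(_pfm_to_pwm(name, rows))
    return pwms


def _pfm_to_pwm(name: str, rows: dict[str, list[float]]) -> PositionWeightMatrix:
    try:
        counts = np.array([rows[b] for b in BASES], dtype=float)
    except KeyError as exc:
        raise MotifError(f"{name}: missing base row {exc}") from exc
    total = counts.sum(axis=0)
    if (total <= 0).any():
        raise MotifError(f"{name}: zero-count PFM column")
    return PositionWeightMatrix(name, counts / total)


def write_meme(pwms: PwmSet, path, background: np.ndarray | None = None) -> None:
    """Write MEME minimal motif format."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.4f}" for b, f in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.tf_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in pwm.matrix.T:
                fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> PwmSet:
    pwms: PwmSet = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability"
            ):
                i += 1
            if i >= len(lines):
                raise MotifError(f"{name}: truncated MEME motif")
            header = lines[i].strip()
            w = int(header.split("w=")[1].split()[0])
            cols = []
            for j in range(i + 1, i + 1 + w):
                cols.append([float(x) for x in lines[j].split()])
            pwms.append(PositionWeightMatrix(name, np.array(cols).T))
            i += w
        i += 1
    return pwms


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def _best_offset_correlation(
    a: np.ndarray, b: np.ndarray, min_overlap: int
) -> tuple[float, int]:
    """Max Pearson correlation over ungapped offsets; returns (r, offset).

    Offset is the position of b's first column in a's coordinates.
    """
    wa, wb = a.shape[1], b.shape[1]
    best, best_off = -np.inf, 0
    for off in range(-(wb - min_overlap), wa - min_overlap + 1):
        lo_a, hi_a = max(0, off), min(wa, off + wb)
        if hi_a - lo_a < min_overlap:
            continue
        sub_a = a[:, lo_a:hi_a]
        sub_b = b[:, lo_a - off : hi_a - off]
        r = _pearson(sub_a.ravel(), sub_b.ravel())
        if np.isnan(r):
            continue
        if r > best:
            best, best_off = r, off
    return best, best_off


def motif_similarity(
    a: PositionWeightMatrix,
    b: PositionWeightMatrix,
    min_overlap: int = 4,
    use_revcomp: bool = True,
) -> float:
    """Pearson similarity between two motifs.

    Maximum over all ungapped offsets with at least ``min_overlap``
    overlapping columns (and over the reverse-complement orientation of ``b``
    when ``use_revcomp``) of the Pearson correlation between the flattened
    4 x L overlapping sub-matrices.  Symmetric in its arguments.
    """
    if min_overlap > min(a.width, b.width):
        raise MotifError(
            f"min_overlap={min_overlap} exceeds motif widths "
            f"({a.width}, {b.width})"
        )
    best, _ = _best_offset_correlation(a.matrix, b.matrix, min_overlap)
    if use_revcomp:
        r_rc, _ = _best_offset_correlation(
            a.matrix, b.reverse_complement().matrix, min_overlap
        )
        best = max(best, r_rc)
    if not np.isfinite(best):
        warnings.warn(
            f"similarity({a.tf_id}, {b.tf_id}) undefined "
            "(constant sub-matrices at every offset)"
        )
        return np.nan
    return best


@dataclass
class MotifSimilarityMatrix:
    tf_ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.tf_ids)
        if self.values.shape != (n, n):
            raise MotifError("similarity matrix shape mismatch")

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.tf_ids), k=1)
        return self.values[iu]

    def submatrix(self, members: list[str]) -> "MotifSimilarityMatrix":
        idx = [self.tf_ids.index(t) for t in members]
        return MotifSimilarityMatrix(list(members), self.values[np.ix_(idx, idx)])


def similarity_matrix(
    pwms: PwmSet, min_overlap: int = 4, use_revcomp: bool = True
) -> MotifSimilarityMatrix:
    ids = [p.tf_id for p in pwms]
    if len(set(ids)) != len(ids):
        raise MotifError("duplicate tf_id in PWM set")
    if len(pwms) < 2:
        raise MotifError("need at least two PWMs")
    n = len(pwms)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = motif_similarity(
                pwms[i], pwms[j], min_overlap=min_overlap, use_revcomp=use_revcomp
            )
    return MotifSimilarityMatrix(ids, values)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_motifs(
    pwms: PwmSet,
    members: list[str] | None = None,
    min_overlap: int = 4,
    use_revcomp: bool = True,
) -> PositionWeightMatrix:
    """Merge member motifs into a single consensus PWM.

    The member with the highest total information content anchors the
    coordinate system; every other member is aligned to it at its best offset
    (and orientation, if enabled).  The merged matrix is the position-wise
    mean of the aligned columns, restricted to positions covered by every
    member, renormalized.
    """
    by_id = {p.tf_id: p for p in pwms}
    if members is None:
        members = [p.tf_id for p in pwms]
    if not members:
        raise MotifError("empty member list")
    chosen = [by_id[m] for m in members]
    if len(chosen) == 1:
        return PositionWeightMatrix(chosen[0].tf_id, chosen[0].matrix.copy())

    ref = max(chosen, key=lambda p: p.information_content().sum())
    placements: list[tuple[int, np.ndarray]] = [(0, ref.matrix)]
    for p in chosen:
        if p is ref:
            continue
        r_fwd, off_fwd = _best_offset_correlation(ref.matrix, p.matrix, min_overlap)
        mat, off, r = p.matrix, off_fwd, r_fwd
        if use_revcomp:
            rc = p.reverse_complement().matrix
            r_rc, off_rc = _best_offset_correlation(ref.matrix, rc, min_overlap)
            if r_rc > r:
                mat, off = rc, off_rc
        placements.append((off, mat))

    lo = max(off for off, _ in placements)
    hi = min(off + mat.shape[1] for off, mat in placements)
    if hi > lo:
        stack = np.stack([mat[:, lo - off : hi - off] for off, mat in placements])
        merged = stack.mean(axis=0)
    else:
        # no column covered by every member: average over covering members
        # on the reference's footprint instead of failing outright
        warnings.warn("no commonly covered columns; merging on reference footprint")
        width = ref.width
        total = np.zeros((4, width))
        cover = np.zeros(width)
        for off, mat in placements:
            a0, a1 = max(0, off), min(width, off + mat.shape[1])
            if a1 <= a0:
                continue
            total[:, a0:a1] += mat[:, a0 - off : a1 - off]
            cover[a0:a1] += 1
        keep = cover > 0
        merged = total[:, keep] / cover[keep]
    merged /= merged.sum(axis=0)
    return PositionWeightMatrix("merged", merged)
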