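"""Protein-DNA complex structures: parsing, mapping, and distances.

Complexes are read from PDB format (Biopython), filtered by crystallographic
resolution (< 4 Å by default), and required to contain both a protein and a
DNA chain.  Alignment columns are mapped onto chain residues by exact
substring search or global alignment; residue-residue and residue-DNA
distances are the shortest Euclidean distance between any two atoms.  CRPs
with at least one endpoint more than 10 Å from the nearest DNA atom are
flagged as f-CRPs.  FoldX is never executed here; only its mutation-list
input and ΔΔG output text formats are handled.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu, ttest_ind

from .msa import GAP, AlignedFamily

DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DU"}
AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
DEFAULT_MAX_RESOLUTION = 4.0
FCRP_CUTOFF = 10.0
DDG_DISRUPTIVE = 2.0  # kcal/mol; larger mean ΔΔG flags a binding-disrupting mutant
MIN_MAPPING_IDENTITY = 0.6


class ComplexRejectedError(ValueError):
    """Raised when a structure fails the inclusion criteria."""


class MappingError(ValueError):
    pass


@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atoms: np.ndarray  # (n_atoms, 3)

    @property
    def is_dna(self) -> bool:
        return self.name in DNA_RESIDUES


@dataclass
class StructureComplex:
    id: str
    resolution: float | None
    protein_residues: list[Residue]
    dna_residues: list[Residue]

    def chain_sequence(self, chain: str) -> list[tuple[int, str]]:
        """Ordered (residue number, one-letter code) for a protein chain."""
        return [
            (r.number, AA_THREE_TO_ONE[r.name])
            for r in self.protein_residues
            if r.chain == chain and r.name in AA_THREE_TO_ONE
        ]

    def protein_chains(self) -> list[str]:
        return sorted({r.chain for r in self.protein_residues})

    def residue(self, chain: str, number: int) -> Residue:
        for r in self.protein_residues:
            if r.chain == chain and r.number == number:
                return r
        raise KeyError((chain, number))

    def dna_atoms(self) -> np.ndarray:
        return np.vstack([r.atoms for r in self.dna_residues])


def load_complex(
    source,
    max_resolution: float = DEFAULT_MAX_RESOLUTION,
    allow_missing_resolution: bool = False,
    structure_id: str = "complex",
) -> StructureComplex:
    """Parse a PDB file and apply the inclusion filters.

    Structures with resolution >= ``max_resolution`` (i.e. not better than
    the cutoff), without a DNA chain, or without a protein chain are
    rejected.  Disordered atoms contribute their highest-occupancy
    conformer only; waters and other heteroatoms are excluded.
    """
    parser = PDBParser(QUIET=True)
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        structure = parser.get_structure(structure_id, str(source))
    else:
        structure = parser.get_structure(structure_id, io.StringIO(source.read()))
    resolution = structure.header.get("resolution")
    if resolution is None:
        if not allow_missing_resolution:
            raise ComplexRejectedError(f"{structure_id}: missing resolution record")
    elif resolution >= max_resolution:
        raise ComplexRejectedError(
            f"{structure_id}: resolution {resolution:.2f} Å >= {max_resolution} Å"
        )

    protein: list[Residue] = []
    dna: list[Residue] = []
    model = next(iter(structure))
    for chain in model:
        for res in chain:
            hetflag, resseq, _ = res.id
            if hetflag != " ":
                continue  # waters and heteroatoms
            name = res.resname.strip()
            coords = np.array([a.get_coord() for a in res.get_atoms()], float)
            if not np.isfinite(coords).all():
                raise ComplexRejectedError(
                    f"{structure_id}: non-finite coordinates in {name} {resseq}"
                )
            entry = Residue(chain.id, resseq, name, coords)
            if name in DNA_RESIDUES:
                dna.append(entry)
            elif name in AA_THREE_TO_ONE:
                protein.append(entry)
    if not dna:
        raise ComplexRejectedError(f"{structure_id}: no DNA chain")
    if not protein:
        raise ComplexRejectedError(f"{structure_id}: no protein chain")
    return StructureComplex(structure_id, resolution, protein, dna)


# ---------------------------------------------------------------------------
# Column -> residue mapping
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


def map_columns_to_residues(
    msa: AlignedFamily,
    tf_id: str,
    chain_sequence: list[tuple[int, str]],
    min_identity: float = MIN_MAPPING_IDENTITY,
) -> dict[int, int]:
    """Map alignment columns of one TF row onto chain residue numbers.

    The TF's ungapped domain sequence is located in the chain by exact
    substring search; failing that, by global alignment (BLOSUM62, affine
    gaps), keeping only columns aligned to an identical residue.  Mappings
    with identity below ``min_identity`` over the domain are refused.
    """
    row = msa.row(tf_id)
    domain_cols = [c for c in range(msa.n_col) if row[c] != GAP]
    domain_seq = "".join(row[c] for c in domain_cols)
    if not domain_seq:
        raise MappingError(f"{tf_id}: empty domain sequence")
    chain_str = "".join(ch for _, ch in chain_sequence)
    numbers = [num for num, _ in chain_sequence]

    start = chain_str.find(domain_seq)
    if start >= 0:
        return {c: numbers[start + k] for k, c in enumerate(domain_cols)}

    aligner = _make_aligner()
    try:
        alignment = aligner.align(domain_seq, chain_str)[0]
    except (ValueError, IndexError) as exc:
        raise MappingError(f"{tf_id}: alignment failed ({exc})") from exc
    mapping: dict[int, int] = {}
    matched = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for off in range(a_end - a_start):
            qa = a_start + off
            qb = b_start + off
            if domain_seq[qa] == chain_str[qb]:
                mapping[domain_cols[qa]] = numbers[qb]
                matched += 1
    identity = matched / len(domain_seq)
    if identity < min_identity:
        raise MappingError(
            f"{tf_id}: mapping identity {identity:.2f} below {min_identity}"
        )
    return mapping


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMap:
    """Minimum atomic distances keyed by alignment column."""

    pair_distances: dict[tuple[int, int], float]
    dna_distances: dict[int, float]
    column_residues: dict[int, list[tuple[str, int]]] = field(default_factory=dict)

    def pair(self, i: int, j: int) -> float | None:
        if i == j:
            return None
        key = (min(i, j), max(i, j))
        return self.pair_distances.get(key)


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(cdist(a, b).min())


def residue_distances(
    complex_: StructureComplex,
    mapping_by_chain: dict[str, dict[int, int]],
) -> DistanceMap:
    """Column-pair and column-DNA minimum atomic distances.

    Where a column maps to residues in several chains, the minimum over
    chains is taken (for pairs: over all chain combinations of the two
    endpoints).
    """
    if not any(mapping_by_chain.values()):
        raise ValueError("empty column mapping")
    column_residues: dict[int, list[Residue]] = {}
    for chain, mapping in mapping_by_chain.items():
        for col, resnum in mapping.items():
            try:
                res = complex_.residue(chain, resnum)
            except KeyError:
                continue
            column_residues.setdefault(col, []).append(res)

    dna = complex_.dna_atoms()
    dna_distances = {
        col: min(_min_distance(r.atoms, dna) for r in residues)
        for col, residues in column_residues.items()
    }
    cols = sorted(column_residues)
    pair_distances: dict[tuple[int, int], float] = {}
    for a_i, i in enumerate(cols):
        for j in cols[a_i + 1 :]:
            pair_distances[(i, j)] = min(
                _min_distance(ri.atoms, rj.atoms)
                for ri in column_residues[i]
                for rj in column_residues[j]
            )
    return DistanceMap(
        pair_distances,
        dna_distances,
        {c: [(r.chain, r.number) for r in rs] for c, rs in column_residues.items()},
    )


def classify_fcrps(
    crps: set[tuple[int, int]],
    distances: DistanceMap,
    cutoff: float = FCRP_CUTOFF,
    tsds: set[int] | None = None,
) -> dict:
    """Flag CRPs with an endpoint far (> cutoff Å) from the DNA interface.

    A CRP is an f-CRP iff the larger of its two endpoints' DNA-interface
    distances exceeds the cutoff (strict inequality).  CRPs with an unmapped
    endpoint are excluded from the fraction and counted as uncovered.
    """
    rows = []
    uncovered = 0
    for i, j in sorted(crps):
        di = distances.dna_distances.get(i)
        dj = distances.dna_distances.get(j)
        if di is None or dj is None:
            uncovered += 1
            continue
        row = {
            "col_i": i,
            "col_j": j,
            "dna_dist_i": di,
            "dna_dist_j": dj,
            "is_fcrp": max(di, dj) > cutoff,
        }
        if tsds is not None:
            row["tsds_i"] = i in tsds
            row["tsds_j"] = j in tsds
        rows.append(row)
    table = pd.DataFrame(rows)
    n = len(rows)
    return {
        "table": table,
        "fcrp_fraction": float(table["is_fcrp"].mean()) if n else None,
        "n_classified": n,
        "n_uncovered": uncovered,
    }


def compare_spatial(
    crp_distances: list[float], non_crp_distances: list[float]
) -> dict:
    """Are CRP endpoints closer in 3-D than non-CRP pairs? (Welch t-test)."""
    if len(crp_distances) < 2 or len(non_crp_distances) < 2:
        raise ValueError("need at least two distances per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = ttest_ind(crp_distances, non_crp_distances, equal_var=False)
    med_crp = float(np.median(crp_distances))
    med_non = float(np.median(non_crp_distances))
    return {
        "t_statistic": None if np.isnan(stat) else float(stat),
        "p_value": None if np.isnan(p) else float(p),
        "median_crp": med_crp,
        "median_non_crp": med_non,
        "direction": "crp_closer" if med_crp < med_non else
        "non_crp_closer" if med_crp > med_non else "equal",
    }


# ---------------------------------------------------------------------------
# FoldX plumbing (text formats only; FoldX itself is never run here)
# ---------------------------------------------------------------------------

def foldx_mutation_list(
    mutations: list[tuple[str, int, str, str]],
    complex_: StructureComplex | None = None,
) -> str:
    """FoldX ``individual_list`` text: one ``<WT><chain><pos><mut>;`` per line."""
    lines = []
    for chain, number, wild_type, mutant in mutations:
        if complex_ is not None:
            res = complex_.residue(chain, number)
            observed = AA_THREE_TO_ONE.get(res.name)
            if observed != wild_type:
                raise ValueError(
                    f"wild-type mismatch at {chain}{number}: structure has "
                    f"{observed}, mutation list says {wild_type}"
                )
        lines.append(f"{wild_type}{chain}{number}{mutant};")
    return "\n".join(lines) + "\n"


def parse_foldx_ddg(text: str, n_runs: int = 5) -> pd.DataFrame:
    """Average replicate ΔΔG values per mutant from FoldX output text.

    Expects whitespace- or tab-separated lines ``mutant replicate ddg``
    (header lines tolerated).  Replicates are averaged; mutants with mean
    ΔΔG > 2 kcal/mol are flagged as binding-disrupting.
    """
    records = []
    for line in text.splitlines():
        parts = line.split()
        if len(parts) < 3:
            continue
        try:
            ddg = float(parts[2])
            replicate = int(parts[1])
        except ValueError:
            continue  # header
        records.append({"mutant": parts[0], "replicate": replicate, "ddg": ddg})
    if not records:
        raise ValueError("no ΔΔG records parsed")
    df = pd.DataFrame(records)
    out = (
        df.groupby("mutant", sort=True)["ddg"]
        .agg(mean_ddg="mean", n_replicates="count")
        .reset_index()
    )
    for mutant, n in zip(out["mutant"], out["n_replicates"]):
        if n != n_runs:
            warnings.warn(f"{mutant}: {n} replicates, expected {n_runs}")
    out["disruptive"] = out["mean_ddg"] > DDG_DISRUPTIVE
    return out


def compare_ddg_groups(
    group_a: list[float], group_b: list[float], alternative: str = "greater"
) -> dict:
    """One-tailed Wilcoxon rank-sum comparison of two mutant ΔΔG groups."""
    stat, p = mannwhitneyu(group_a, group_b, alternative=alternative)
    return {"statistic": float(stat), "p_value": float(p), "alternative": alternative}
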